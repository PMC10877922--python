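"""Genotype structure for hybrid panels.

Hybrids are single-cross F1s between inbred lines, coded 0/1/2 at each SNP
(reference homozygote / heterozygote / alternate homozygote).  SNPs that are
always inherited together on the panel (pairwise r^2 = 1) form *co-inherited
sets*; a single *reference SNP* per set enters association testing and the
set is re-expanded downstream for gene mapping and QTL co-localization.

This module builds the co-inherited sets, applies the MAF / parental-panel
filters, produces centered additive and dominance design matrices, and
computes alike-in-state (AIS) additive and dominance kinship matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PANEL_BOTH = "both"
PANEL_MALE_ONLY = "male_only"
PANEL_FEMALE_ONLY = "female_only"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeData:
    """Hybrid genotypes plus SNP map and pedigree metadata.

    Parameters
    ----------
    G
        hybrids x SNPs data frame of codes in {0, 1, 2} (float; NaN = missing).
    snp_map
        indexed by SNP id with columns ``chrom`` and ``pos`` (1-based bp).
    parent_of
        optional, indexed by hybrid with columns ``female`` and ``male``.
    panel_presence
        optional SNP-indexed series with values ``both`` / ``male_only`` /
        ``female_only`` (where the variant allele segregates).
    """

    G: pd.DataFrame
    snp_map: pd.DataFrame
    parent_of: pd.DataFrame | None = None
    panel_presence: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.G.columns.duplicated().any():
            raise ValueError("duplicated SNP ids in genotype matrix")
        vals = self.G.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"genotype codes outside {{0,1,2}}: {bad[:5]}")
        missing = self.G.columns.difference(self.snp_map.index)
        if len(missing):
            raise ValueError(f"SNPs absent from snp_map: {list(missing[:5])}")
        if (self.snp_map["pos"] <= 0).any():
            raise ValueError("SNP positions must be strictly positive (1-based)")

    @property
    def n_hybrids(self) -> int:
        return self.G.shape[0]

    @property
    def n_snps(self) -> int:
        return self.G.shape[1]

    def subset_snps(self, snps) -> "GenotypeData":
        snps = list(snps)
        pp = self.panel_presence.loc[snps] if self.panel_presence is not None else None
        return GenotypeData(
            G=self.G[snps],
            snp_map=self.snp_map.loc[snps],
            parent_of=self.parent_of,
            panel_presence=pp,
        )


@dataclass
class CoInheritedSets:
    """Partition of SNPs into complete-LD groups, keyed by reference SNP."""

    sets: dict[str, list[str]]
    reference_of: pd.Series  # member snp id -> reference snp id
    flagged: list[str] = field(default_factory=list)  # all-missing singletons

    def members(self, reference: str) -> list[str]:
        try:
            return self.sets[reference]
        except KeyError:
            raise KeyError(f"unknown reference SNP: {reference}") from None

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def n_snps(self) -> int:
        return int(self.reference_of.size)


@dataclass
class KinshipPair:
    """Additive and dominance AIS relationship matrices (hybrid x hybrid)."""

    K_a: pd.DataFrame
    K_d: pd.DataFrame
    sigma2_a: float | None = None
    sigma2_d: float | None = None
    sigma2_e: float | None = None


@dataclass
class DesignMatrices:
    """Centered additive (x) and dominance (w) marker covariates."""

    X_add: pd.DataFrame
    W_dom: pd.DataFrame
    monomorphic: list[str] = field(default_factory=list)

    @property
    def snps(self) -> list[str]:
        return list(self.X_add.columns)


# ---------------------------------------------------------------------------
# co-inherited sets
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def build_coinherited_sets(g: GenotypeData, r2_tol: float = 1e-9) -> CoInheritedSets:
    """Group same-chromosome SNPs with pairwise r^2 >= 1 - r2_tol.

    r^2 is the squared Pearson correlation of genotype codes over complete
    cases, which is invariant to allele relabeling (g -> 2 - g).  The
    reference SNP of each set is the member with the smallest position
    (ties broken by lexicographic id).  SNPs with all-missing genotypes
    become flagged singletons.
    """
    snps = list(g.G.columns)
    flagged: list[str] = []
    sets: dict[str, list[str]] = {}
    ref_of: dict[str, str] = {}

    for chrom, sub in g.snp_map.loc[snps].groupby("chrom", sort=False):
        cols = [s for s in snps if s in set(sub.index)]
        X = g.G[cols]
        arr = X.to_numpy(dtype=float)
        n_col = len(cols)
        all_missing = np.isnan(arr).all(axis=0)
        varz = np.zeros(n_col)
        if not all_missing.all():
            varz[~all_missing] = np.nanvar(arr[:, ~all_missing], axis=0)

        if np.isnan(arr).any():
            corr = X.corr(min_periods=2).to_numpy()
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(arr, rowvar=False)
            corr = np.atleast_2d(corr)
        r2 = corr**2

        uf = _UnionFind(n_col)
        for i in range(n_col):
            if all_missing[i] or varz[i] == 0:
                continue  # degenerate columns stay singletons
            for j in range(i + 1, n_col):
                if all_missing[j] or varz[j] == 0:
                    continue
                if np.isfinite(r2[i, j]) and r2[i, j] >= 1.0 - r2_tol:
                    uf.union(i, j)

        groups: dict[int, list[int]] = {}
        for i in range(n_col):
            groups.setdefault(uf.find(i), []).append(i)
        pos = g.snp_map.loc[cols, "pos"].to_numpy()
        for idxs in groups.values():
            members = sorted((cols[i] for i in idxs),
                             key=lambda s: (g.snp_map.at[s, "pos"], s))
            ref = min(members, key=lambda s: (g.snp_map.at[s, "pos"], s))
            sets[ref] = members
            for m in members:
                ref_of[m] = ref
        flagged.extend(cols[i] for i in range(n_col) if all_missing[i])
        del pos

    for s in flagged:
        logger.warning("SNP %s has all-missing genotypes; kept as flagged singleton", s)
    reference_of = pd.Series(ref_of, name="reference").loc[snps]
    return CoInheritedSets(sets=sets, reference_of=reference_of, flagged=flagged)


# ---------------------------------------------------------------------------
# reference-SNP filters
# ---------------------------------------------------------------------------

def minor_allele_frequencies(g: GenotypeData) -> pd.Series:
    """Per-SNP MAF from 0/1/2 codes, missing genotypes excluded."""
    freq = g.G.mean(axis=0, skipna=True) / 2.0
    return pd.concat([freq, 1.0 - freq], axis=1).min(axis=1).rename("maf")


def filter_reference_snps(
    g: GenotypeData, sets: CoInheritedSets, maf_min: float = 0.1
) -> list[str]:
    """Keep reference SNPs with MAF >= maf_min that segregate in both
    parental panels.  The rule is strict on the low side (MAF < maf_min is
    removed; MAF exactly at the threshold is kept)."""
    maf = minor_allele_frequencies(g)
    kept = []
    for ref in sets.sets:
        if maf.get(ref, 0.0) < maf_min:
            continue
        if g.panel_presence is not None and g.panel_presence.get(ref, PANEL_BOTH) != PANEL_BOTH:
            continue
        kept.append(ref)
    return sorted(kept, key=lambda s: (g.snp_map.at[s, "chrom"], g.snp_map.at[s, "pos"], s))


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def encode_designs(g: GenotypeData, snps=None) -> DesignMatrices:
    """Centered additive and dominance covariates.

    x = genotype code minus its mean; w = heterozygote indicator minus its
    mean.  Missing genotypes are mean-imputed before centering (so they
    contribute 0).  Monomorphic SNPs yield zero columns and are flagged.
    """
    cols = list(snps) if snps is not None else list(g.G.columns)
    raw = g.G[cols].to_numpy(dtype=float)
    col_mean = np.nanmean(raw, axis=0)
    filled = np.where(np.isnan(raw), col_mean, raw)
    X = filled - filled.mean(axis=0)

    het = np.where(np.isnan(raw), np.nan, (raw == 1.0).astype(float))
    het_mean = np.nanmean(het, axis=0)
    het_filled = np.where(np.isnan(het), het_mean, het)
    W = het_filled - het_filled.mean(axis=0)

    mono = [cols[j] for j in range(len(cols)) if np.allclose(X[:, j], 0.0)]
    for s in mono:
        logger.warning("monomorphic SNP %s: zero design column", s)
    idx = g.G.index
    return DesignMatrices(
        X_add=pd.DataFrame(X, index=idx, columns=cols),
        W_dom=pd.DataFrame(W, index=idx, columns=cols),
        monomorphic=mono,
    )


# ---------------------------------------------------------------------------
# AIS kinships
# ---------------------------------------------------------------------------

def compute_ais_kinship(g: GenotypeData) -> KinshipPair:
    """Alike-in-state kinships.

    K_a[i, j] = mean over SNPs of (1 - |g_i - g_j| / 2): the proportion of
    allele sharing between hybrids i and j.  K_d[i, j] = mean over SNPs of
    1(het_i == het_j): the proportion of SNPs at which i and j share
    heterozygosity state.  Missing genotypes are excluded pairwise.
    """
    if g.n_hybrids < 2:
        raise ValueError("need at least 2 hybrids for kinship")
    X = g.G.to_numpy(dtype=float)
    valid = (~np.isnan(X)).astype(float)
    if (valid.sum(axis=1) == 0).any():
        bad = g.G.index[valid.sum(axis=1) == 0].tolist()
        raise ValueError(f"hybrids with all-missing genotypes: {bad}")

    G0 = ((X == 0.0) & (valid > 0)).astype(float)
    G1 = ((X == 1.0) & (valid > 0)).astype(float)
    G2 = ((X == 2.0) & (valid > 0)).astype(float)

    den = valid @ valid.T
    if (den == 0).any():
        raise ValueError("hybrid pairs with no shared genotyped SNPs")

    # sum over SNPs of |g_i - g_j| for every pair
    abs_diff = 2.0 * (G0 @ G2.T + G2 @ G0.T) + (
        G0 @ G1.T + G1 @ G0.T + G1 @ G2.T + G2 @ G1.T
    )
    K_a = 1.0 - abs_diff / (2.0 * den)

    hom = G0 + G2
    same_state = G1 @ G1.T + hom @ hom.T
    K_d = same_state / den

    K_a = (K_a + K_a.T) / 2.0
    K_d = (K_d + K_d.T) / 2.0
    idx = g.G.index
    return KinshipPair(
        K_a=pd.DataFrame(K_a, index=idx, columns=idx),
        K_d=pd.DataFrame(K_d, index=idx, columns=idx),
    )


def normalize_kinship(K: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Rescale a similarity matrix to a unit-diagonal, zero-baseline kinship.

    AIS similarities carry a large identical-by-state baseline (unrelated
    hybrids still share most alleles by chance), so the raw off-diagonal
    mean is far from 0.  Subtracting the off-diagonal mean and rescaling to
    unit diagonal puts variance components on the phenotypic-variance scale
    (heritabilities then read as variance fractions).  Mixed-model tests
    are invariant to this affine change when an intercept is fitted.
    """
    arr = K.to_numpy() if isinstance(K, pd.DataFrame) else np.asarray(K, float)
    n = arr.shape[0]
    off = ~np.eye(n, dtype=bool)
    base = arr[off].mean()
    if base >= 1.0:
        raise ValueError("degenerate kinship: off-diagonal mean >= diagonal")
    return (arr - base) / (1.0 - base)


def nearest_psd(K: np.ndarray, min_eig: float = -1e-8, ridge: float = 1e-8) -> np.ndarray:
    """Add ridge until the smallest eigenvalue clears min_eig."""
    out = np.asarray(K, dtype=float)
    for _ in range(40):
        w = np.linalg.eigvalsh(out)
        if w.min() >= min_eig:
            return out
        out = out + ridge * np.eye(out.shape[0])
        ridge *= 10.0
    raise np.linalg.LinAlgError("could not regularize kinship to PSD")
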