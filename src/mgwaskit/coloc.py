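"""Two-step linking of associations to trait QTLs.

Reference SNPs carry their whole co-inherited set: a set member
*co-localizes* with a QTL when it lies within a window (default 50 kb,
inclusive) of any SNP defining that QTL on the same chromosome.  Hits are
then propagated back through the reference SNP to the associated LC-MS
features, per trait class, and the full complete-LD SNP list of implicated
sets is exported for candidate-gene mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genostruct import CoInheritedSets

TRAIT_CLASSES = ("drought", "cold", "nutrient", "productivity_development")


@dataclass
class QtlCatalogue:
    """QTLs represented as lists of defining SNP positions.

    ``table`` columns: qtl_id, trait_class, chrom, pos (1-based bp).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"qtl_id", "trait_class", "chrom", "pos"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"QTL catalogue missing columns: {sorted(missing)}")
        if (self.table["pos"] <= 0).any():
            raise ValueError("QTL positions must be positive")
        bad = set(self.table["trait_class"]) - set(TRAIT_CLASSES)
        if bad:
            raise ValueError(f"unknown trait classes: {sorted(bad)}; "
                             f"expected one of {TRAIT_CLASSES}")

    @classmethod
    def from_tsv(cls, path) -> "QtlCatalogue":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_bed(cls, path, trait_class_col: int = 4) -> "QtlCatalogue":
        """BED interval adapter: each interval contributes its two endpoint
        positions as QTL-defining SNPs (name column = qtl id, extra column =
        trait class)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                qtl_id = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
                trait = parts[trait_class_col] if len(parts) > trait_class_col else "drought"
                # BED is 0-based half-open; endpoints as 1-based SNP positions
                rows.append({"qtl_id": qtl_id, "trait_class": trait,
                             "chrom": chrom, "pos": start + 1})
                rows.append({"qtl_id": qtl_id, "trait_class": trait,
                             "chrom": chrom, "pos": end})
        return cls(pd.DataFrame(rows))

    @property
    def qtl_ids(self) -> list[str]:
        return list(pd.unique(self.table["qtl_id"]))


@dataclass
class ColocResult:
    hits: pd.DataFrame              # member_snp, reference_snp, qtl_id, trait_class, qtl_pos, distance
    expanded: pd.DataFrame          # member_snp, reference_snp (the tested LD expansion)
    window_bp: int

    @property
    def colocalizing_members(self) -> list[str]:
        return list(pd.unique(self.hits["member_snp"]))

    @property
    def colocalizing_references(self) -> list[str]:
        return list(pd.unique(self.hits["reference_snp"]))

    @property
    def qtls_hit(self) -> list[str]:
        return list(pd.unique(self.hits["qtl_id"]))


def expand_to_members(reference_snps, sets: CoInheritedSets) -> pd.DataFrame:
    """Expand reference SNPs to their complete-LD members with back-pointers."""
    rows = []
    for ref in reference_snps:
        for m in sets.members(ref):  # KeyError on unknown reference
            rows.append({"member_snp": m, "reference_snp": ref})
    return pd.DataFrame(rows, columns=["member_snp", "reference_snp"])


def colocalize(
    expanded: pd.DataFrame,
    snp_map: pd.DataFrame,
    catalogue: QtlCatalogue,
    window_bp: int = 50_000,
) -> ColocResult:
    """Member SNPs within ``window_bp`` (inclusive) of any QTL-defining SNP.

    A member may hit several QTLs; every hit is recorded.  Raises on QTL
    chromosomes absent from the SNP map (namespace mismatch guard).
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    snp_chroms = set(snp_map["chrom"])
    offenders = sorted(set(catalogue.table["chrom"]) - snp_chroms)
    if offenders:
        raise ValueError(
            f"QTL chromosomes not present in SNP map: {offenders}; "
            f"SNP map has {sorted(snp_chroms)}")

    members = expanded["member_snp"]
    unknown = members[~members.isin(snp_map.index)].tolist()
    if unknown:
        raise KeyError(f"member SNPs absent from SNP map: {unknown[:5]}")

    rows = []
    mpos = snp_map.loc[members, "pos"].to_numpy()
    mchrom = snp_map.loc[members, "chrom"].to_numpy()
    for (qtl_id, trait), sub in catalogue.table.groupby(["qtl_id", "trait_class"], sort=False):
        for chrom, csub in sub.groupby("chrom", sort=False):
            qpos = np.sort(csub["pos"].to_numpy())
            on_chrom = np.where(mchrom == chrom)[0]
            if len(on_chrom) == 0:
                continue
            pos = mpos[on_chrom]
            # nearest QTL SNP by binary search
            j = np.searchsorted(qpos, pos)
            left = np.where(j > 0, np.abs(pos - qpos[np.maximum(j - 1, 0)]), np.inf)
            right = np.where(j < len(qpos), np.abs(qpos[np.minimum(j, len(qpos) - 1)] - pos), np.inf)
            dist = np.minimum(left, right)
            near_q = np.where(right <= left,
                              qpos[np.minimum(j, len(qpos) - 1)],
                              qpos[np.maximum(j - 1, 0)])
            ok = dist <= window_bp
            for i, d, qp in zip(on_chrom[ok], dist[ok], near_q[ok]):
                rows.append({
                    "member_snp": expanded["member_snp"].iloc[i],
                    "reference_snp": expanded["reference_snp"].iloc[i],
                    "qtl_id": qtl_id, "trait_class": trait,
                    "qtl_pos": int(qp), "distance": int(d),
                })
    hits = pd.DataFrame(rows, columns=["member_snp", "reference_snp", "qtl_id",
                                       "trait_class", "qtl_pos", "distance"])
    hits = hits.drop_duplicates(subset=["member_snp", "qtl_id"]).reset_index(drop=True)
    return ColocResult(hits=hits, expanded=expanded, window_bp=window_bp)


@dataclass
class TraitClassReport:
    features: list[str]
    reference_snps: list[str]
    ld_snps: list[str]  # full complete-LD list of implicated sets


@dataclass
class BackpropResult:
    per_class: dict[str, TraitClassReport]
    multi: list[str]  # features implicated in >= 2 trait classes
    feature_qtls: pd.DataFrame  # feature, qtl_id, trait_class, reference_snp


def backpropagate(
    result: ColocResult,
    sets: CoInheritedSets,
    associations: pd.DataFrame,
) -> BackpropResult:
    """Propagate QTL hits back to features and reference SNPs per trait class.

    ``associations`` must have columns ``feature`` and ``reference_snp``
    (the eBIC-selected associations).  Each implicated reference SNP brings
    along all its co-inherited members for candidate-gene mapping.
    """
    assoc_by_ref: dict[str, list[str]] = {}
    for _, row in associations.iterrows():
        assoc_by_ref.setdefault(row["reference_snp"], []).append(row["feature"])

    per_class: dict[str, TraitClassReport] = {}
    feature_rows = []
    for trait, sub in result.hits.groupby("trait_class", sort=False):
        refs = sorted(pd.unique(sub["reference_snp"]))
        feats: set[str] = set()
        ld: set[str] = set()
        for ref in refs:
            feats.update(assoc_by_ref.get(ref, []))
            ld.update(sets.members(ref))
        for _, hrow in sub.drop_duplicates(["reference_snp", "qtl_id"]).iterrows():
            for f in assoc_by_ref.get(hrow["reference_snp"], []):
                feature_rows.append({"feature": f, "qtl_id": hrow["qtl_id"],
                                     "trait_class": trait,
                                     "reference_snp": hrow["reference_snp"]})
        per_class[trait] = TraitClassReport(
            features=sorted(feats), reference_snps=refs, ld_snps=sorted(ld))

    feature_qtls = pd.DataFrame(
        feature_rows, columns=["feature", "qtl_id", "trait_class", "reference_snp"]
    ).drop_duplicates().reset_index(drop=True)
    class_count = feature_qtls.groupby("feature")["trait_class"].nunique() \
        if len(feature_qtls) else pd.Series(dtype=int)
    multi = sorted(class_count.index[class_count >= 2].tolist())
    return BackpropResult(per_class=per_class, multi=multi, feature_qtls=feature_qtls)
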