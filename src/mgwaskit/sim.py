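"""Synthetic study generator with recorded ground truth.

Emulates the design of the field experiment the pipeline is written for:
36 male x 36 female inbred parents crossed in an incomplete factorial to
~450 F1 hybrids; genotypes organized in complete-LD blocks (one latent
biallelic variable per parent per block, so r^2 = 1 within blocks is exact
by construction); metabolite features simulated on log scale with known
additive+dominance QTN effects plus a polygenic background anchored at a
mean genomic heritability of 0.66; a field layout with four replicated
control hybrids over 65 plots sampling a smooth row+column bias; pooled-QC
injections every 10 samples under a smooth intensity drift; and planted
isotope/adduct feature redundancy.

Every stochastic choice flows from a single root seed through one child
stream per operation, recorded in :class:`SimTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genostruct import (
    GenotypeData,
    PANEL_BOTH,
    PANEL_FEMALE_ONLY,
    PANEL_MALE_ONLY,
    compute_ais_kinship,
)
from .metabolome import DEFAULT_DELTA_CATALOGUE, FeatureMatrix

_OP_NAMES = ("parents", "hybrids", "metabolome", "field", "redundancy", "annotation")


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class Qtn:
    """A planted quantitative trait nucleotide.

    ``feature`` names the phenotype column; ``block`` the causal LD block
    (its reference SNP becomes the causal marker).  If ``var_frac`` is set,
    (theta_a, theta_d) are rescaled jointly so the QTN explains exactly that
    fraction of the unit phenotype variance.
    """

    feature: str
    block: str
    theta_a: float = 1.0
    theta_d: float = 0.0
    var_frac: float | None = None


@dataclass
class SimConfig:
    n_males: int = 36
    n_females: int = 36
    n_hybrids: int = 450
    n_chromosomes: int = 5
    n_blocks_per_chr: int = 40
    snps_per_block: int | tuple[int, int] = (1, 8)
    chr_length_bp: int = 50_000_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    qtn_spec: list[Qtn] = field(default_factory=list)
    h2_poly: float = 0.66
    n_features: int = 200
    n_controls: int = 4
    n_control_plots: int = 65
    n_blanks: int = 3
    n_contaminant_features: int = 0
    n_mz_unstable: int = 0
    n_rt_unstable: int = 0
    field_sd: float = 0.2
    drift_amplitude: float = 0.2
    drift_wiggle_sd: float = 0.02
    control_noise_sd: float = 0.05
    qc_interval: int = 10
    qc_noise_sd: float = 0.02
    n_redundant: int = 50
    redundancy_ratio_range: tuple[float, float] = (0.1, 0.8)
    redundancy_rt_jitter_s: float = 0.2
    redundancy_noise_sd: float = 0.0
    mz_range: tuple[float, float] = (100.0, 1000.0)
    rt_range: tuple[float, float] = (60.0, 700.0)
    log_abundance_range: tuple[float, float] = (np.log(1e5), np.log(1e7))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_males", "n_females", "n_hybrids", "n_chromosomes",
                     "n_blocks_per_chr", "chr_length_bp", "n_features"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_hybrids > self.n_males * self.n_females:
            raise ValueError("n_hybrids exceeds the factorial grid")
        per_feature: dict[str, float] = {}
        for q in self.qtn_spec:
            per_feature[q.feature] = per_feature.get(q.feature, 0.0) + (q.var_frac or 0.0)
        for feat, tot in per_feature.items():
            if tot + self.h2_poly >= 1.0:
                raise ValueError(f"variance fractions for {feat} sum to >= 1")
        if self.h2_poly < 0 or self.h2_poly >= 1:
            raise ValueError("h2_poly must lie in [0, 1)")

    def op_rng(self, op: str) -> np.random.Generator:
        """One deterministic child stream per simulation operation."""
        idx = _OP_NAMES.index(op)
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(len(_OP_NAMES))[idx])


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for recovery tests."""

    qtn_positions: dict[str, list[str]] = field(default_factory=dict)
    qtn_effects: dict[str, list[tuple[str, float, float]]] = field(default_factory=dict)
    true_h2: dict[str, float] = field(default_factory=dict)
    block_membership: pd.Series | None = None  # snp id -> block id
    block_reference: dict[str, str] = field(default_factory=dict)  # block -> causal/ref snp
    spatial_surface: dict | None = None  # {'row': {label: eff}, 'col': {...}}
    drift_curve: pd.Series | None = None  # injection index -> factor
    redundancy_map: dict[str, str] = field(default_factory=dict)  # derived -> parent
    op_seeds: dict[str, int] = field(default_factory=dict)


@dataclass
class ParentalPanel:
    parents: pd.DataFrame  # 72 x SNPs, codes {0, 2}
    snp_map: pd.DataFrame  # snp -> chrom, pos
    block_membership: pd.Series  # snp -> block id
    panel_presence: pd.Series  # snp -> both / male_only / female_only
    male_ids: list[str]
    female_ids: list[str]


# ---------------------------------------------------------------------------
# parents and hybrids
# ---------------------------------------------------------------------------

def simulate_parents(config: SimConfig, rng: np.random.Generator | None = None) -> ParentalPanel:
    """Fully homozygous parental genotypes in complete-LD blocks.

    One latent allele per parent per block; every SNP in the block repeats
    the latent variable up to a random allele relabeling, so within-block
    r^2 is exactly 1.  Block allele frequencies are drawn in ``maf_range``
    and redrawn (up to 50 times) until the empirical parental MAF respects
    the lower bound.
    """
    lo, hi = config.maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = rng or config.op_rng("parents")

    males = [f"M{i + 1:02d}" for i in range(config.n_males)]
    females = [f"F{i + 1:02d}" for i in range(config.n_females)]
    parents = females + males
    n_par = len(parents)

    cols: list[np.ndarray] = []
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    blocks: list[str] = []

    spb = config.snps_per_block
    seg = config.chr_length_bp // config.n_blocks_per_chr
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        for b in range(config.n_blocks_per_chr):
            block_id = f"{chrom}_b{b:03d}"
            if isinstance(spb, int):
                n_snp = spb
            else:
                n_snp = int(rng.integers(spb[0], spb[1] + 1))
            # latent allele per parent, empirical MAF kept above the floor
            for _ in range(50):
                p = rng.uniform(lo, hi)
                latent = (rng.random(n_par) < p).astype(float)
                f_emp = latent.mean()
                if lo <= min(f_emp, 1 - f_emp):
                    break
            pos = np.sort(rng.choice(np.arange(b * seg + 1, (b + 1) * seg + 1),
                                     size=n_snp, replace=False))
            for k in range(n_snp):
                flip = rng.random() < 0.5
                geno = 2.0 * (1.0 - latent) if flip else 2.0 * latent
                cols.append(geno)
                snp_ids.append(f"{chrom}_p{pos[k]}")
                chroms.append(chrom)
                positions.append(int(pos[k]))
                blocks.append(block_id)

    G = pd.DataFrame(np.column_stack(cols), index=parents, columns=snp_ids)
    snp_map = pd.DataFrame({"chrom": chroms, "pos": positions}, index=snp_ids)
    block_membership = pd.Series(blocks, index=snp_ids, name="block")

    in_m = (G.loc[males] == 2).any(axis=0)
    in_f = (G.loc[females] == 2).any(axis=0)
    presence = pd.Series(PANEL_BOTH, index=snp_ids, dtype=object)
    presence[in_m & ~in_f] = PANEL_MALE_ONLY
    presence[~in_m & in_f] = PANEL_FEMALE_ONLY
    return ParentalPanel(G, snp_map, block_membership, presence, males, females)


def make_hybrids(
    panel: ParentalPanel,
    design: list[tuple[str, str]] | None = None,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeData:
    """Cross inbred parents to F1 hybrids named ``female_male``.

    The hybrid genotype at each SNP is the sum of the two parental gametes
    (each parent is homozygous, contributing code/2), giving the 0/1/2
    coding.  ``design`` is a list of (female, male) pairs; by default an
    incomplete factorial of ``config.n_hybrids`` pairs is sampled from the
    full grid without replacement.
    """
    if design is None:
        if config is None:
            raise ValueError("provide either a design or a config")
        rng = rng or config.op_rng("hybrids")
        grid = [(f, m) for f in panel.female_ids for m in panel.male_ids]
        idx = rng.choice(len(grid), size=config.n_hybrids, replace=False)
        design = [grid[i] for i in sorted(idx)]

    P = panel.parents
    known = set(P.index)
    rows = []
    names = []
    parents = []
    for female, male in design:
        for pid in (female, male):
            if pid not in known:
                raise KeyError(f"unknown parent id: {pid}")
        rows.append((P.loc[female].to_numpy() + P.loc[male].to_numpy()) / 2.0)
        names.append(f"{female}_{male}")
        parents.append((female, male))

    G = pd.DataFrame(np.vstack(rows), index=names, columns=P.columns)
    parent_of = pd.DataFrame(parents, index=names, columns=["female", "male"])
    return GenotypeData(G=G, snp_map=panel.snp_map.copy(), parent_of=parent_of,
                        panel_presence=panel.panel_presence.copy())


# ---------------------------------------------------------------------------
# metabolome phenotypes
# ---------------------------------------------------------------------------

def _block_reference(snp_map: pd.DataFrame, block_membership: pd.Series, block: str) -> str:
    members = block_membership.index[block_membership == block]
    if len(members) == 0:
        raise KeyError(f"unknown block: {block}")
    return min(members, key=lambda s: (snp_map.at[s, "pos"], s))


def simulate_metabolome(
    genotypes: GenotypeData,
    config: SimConfig,
    block_membership: pd.Series | None = None,
    rng: np.random.Generator | None = None,
    truth: SimTruth | None = None,
) -> tuple[FeatureMatrix, SimTruth]:
    """Log-scale metabolite phenotypes with known genetic architecture.

    Each feature is y = mu + sum x*theta_a + sum w*theta_d + polygenic +
    residual on the (natural) log scale, exponentiated into positive
    right-skewed intensities.  QTN and polygenic components are empirically
    rescaled so their variance fractions are exact on the simulated sample;
    the realized narrow-sense h^2 (additive QTN part + polygenic, over total)
    is recorded per feature in the returned :class:`SimTruth`.
    """
    rng = rng or config.op_rng("metabolome")
    truth = truth or SimTruth()
    truth.op_seeds.setdefault("metabolome", config.seed)
    if block_membership is not None:
        truth.block_membership = block_membership

    n = genotypes.n_hybrids
    G = genotypes.G

    qtn_by_feature: dict[str, list[Qtn]] = {}
    for q in config.qtn_spec:
        qtn_by_feature.setdefault(q.feature, []).append(q)
    for feat, qs in qtn_by_feature.items():
        tot = sum(q.var_frac or 0.0 for q in qs)
        if tot + config.h2_poly >= 1.0:
            raise ValueError(f"variance fractions for {feat} sum to >= 1")

    # polygenic background through the (baseline-normalized) additive AIS
    # kinship, so h2_poly is a fraction of phenotypic variance
    if config.h2_poly > 0:
        from .genostruct import normalize_kinship

        K = normalize_kinship(compute_ais_kinship(genotypes).K_a)
        w, U = np.linalg.eigh(K)
        L = U * np.sqrt(np.clip(w, 0.0, None))
    else:
        L = None

    feature_ids = [f"F{i + 1:04d}" for i in range(config.n_features)]
    cols = np.empty((n, config.n_features))
    for j, feat in enumerate(feature_ids):
        additive = np.zeros(n)
        y = np.zeros(n)
        for q in qtn_by_feature.get(feat, []):
            if truth.block_membership is None:
                raise ValueError("qtn_spec requires block membership")
            snp = _block_reference(genotypes.snp_map, truth.block_membership, q.block)
            g_raw = G[snp].to_numpy(dtype=float)
            x = g_raw - g_raw.mean()
            wdom = (g_raw == 1.0).astype(float)
            wdom = wdom - wdom.mean()
            contrib = q.theta_a * x + q.theta_d * wdom
            ta, td = q.theta_a, q.theta_d
            if q.var_frac is not None:
                v = contrib.var()
                if v <= 0:
                    raise ValueError(f"QTN block {q.block} is monomorphic on the panel")
                s = np.sqrt(q.var_frac / v)
                contrib = contrib * s
                ta, td = ta * s, td * s
            y += contrib
            additive += ta * x
            truth.qtn_positions.setdefault(feat, []).append(snp)
            truth.qtn_effects.setdefault(feat, []).append((snp, ta, td))
            truth.block_reference[q.block] = snp
        if L is not None:
            gpoly = L @ rng.standard_normal(n)
            v = gpoly.var()
            if v > 0:
                gpoly *= np.sqrt(config.h2_poly / v)
            y += gpoly
            additive += gpoly
        frac_qtn = sum(q.var_frac or 0.0 for q in qtn_by_feature.get(feat, []))
        sigma2_e = max(1.0 - frac_qtn - config.h2_poly, 1e-12)
        y += rng.normal(0.0, np.sqrt(sigma2_e), size=n)
        vy = y.var()
        truth.true_h2[feat] = float(additive.var() / vy) if vy > 0 else 0.0
        mu = rng.uniform(*config.log_abundance_range)
        cols[:, j] = np.exp(mu + y)

    mz = rng.uniform(*config.mz_range, size=config.n_features)
    rt = rng.uniform(*config.rt_range, size=config.n_features)
    mz_spread = rng.uniform(0.0, 0.003, size=config.n_features)
    rt_spread = rng.uniform(0.0, 20.0, size=config.n_features)
    # planted stability violations for the filter stage
    unstable = rng.choice(config.n_features,
                          size=min(config.n_mz_unstable + config.n_rt_unstable,
                                   config.n_features), replace=False)
    mz_spread[unstable[: config.n_mz_unstable]] = rng.uniform(
        0.006, 0.02, size=len(unstable[: config.n_mz_unstable]))
    rt_spread[unstable[config.n_mz_unstable:]] = rng.uniform(
        45.0, 120.0, size=len(unstable[config.n_mz_unstable:]))

    feature_meta = pd.DataFrame(
        {"mz": mz, "rt": rt, "mz_spread_da": mz_spread, "rt_spread_s": rt_spread},
        index=feature_ids,
    )
    sample_meta = pd.DataFrame(
        {
            "is_qc": False,
            "is_blank": False,
            "is_control": False,
            "control_id": pd.Series([None] * n, index=G.index, dtype=object),
            "dry_mass_mg": np.clip(rng.normal(10.0, 1.0, size=n), 7.0, 13.0),
        },
        index=G.index,
    )
    fm = FeatureMatrix(
        intensities=pd.DataFrame(cols, index=G.index, columns=feature_ids),
        feature_meta=feature_meta,
        sample_meta=sample_meta,
    )
    return fm, truth


# ---------------------------------------------------------------------------
# field layout, QC drift, blanks
# ---------------------------------------------------------------------------

def _smooth_profile(n: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-sd smooth 1-d profile (Gaussian-smoothed noise)."""
    if n == 1:
        return np.zeros(1)
    raw = rng.standard_normal(n + 8)
    kern = np.exp(-0.5 * (np.arange(-4, 5) / 2.0) ** 2)
    kern /= kern.sum()
    sm = np.convolve(raw, kern, mode="valid")[:n]
    sm = sm - sm.mean()
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def inject_field_and_drift(
    fm: FeatureMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    truth: SimTruth | None = None,
) -> tuple[FeatureMatrix, SimTruth]:
    """Overlay field-plot bias, instrument drift, control plots, QCs, blanks.

    Biological and control plots are placed on a rectangular grid; a smooth
    additive row+column bias (sd ``field_sd`` on log scale) is applied to
    all field plots.  Samples receive a randomized injection order and are
    multiplied by a smooth drift curve of injection index; pooled-QC
    pseudo-samples at the (pre-drift) geometric mean are inserted every
    ``qc_interval`` injections, and blank injections lead the run.
    """
    if config.n_controls < 2:
        raise ValueError("need at least 2 control genotypes for spatial adjustment")
    rng = rng or config.op_rng("field")
    truth = truth or SimTruth()

    bio = list(fm.intensities.index)
    feats = list(fm.intensities.columns)
    n_bio = len(bio)
    n_plots = n_bio + config.n_control_plots

    n_cols_grid = int(np.ceil(np.sqrt(n_plots)))
    n_rows_grid = int(np.ceil(n_plots / n_cols_grid))
    plots = [(r, c) for r in range(n_rows_grid) for c in range(n_cols_grid)][:n_plots]
    plots = [plots[i] for i in rng.permutation(n_plots)]

    # control genotypes replicated over plots (65 over 4 genotypes by default)
    base, extra = divmod(config.n_control_plots, config.n_controls)
    ctrl_counts = [base + (1 if i < extra else 0) for i in range(config.n_controls)]
    ctrl_profile = rng.uniform(*config.log_abundance_range,
                               size=(config.n_controls, len(feats)))

    names = list(bio)
    rows_ix: list[float] = []
    cols_ix: list[float] = []
    is_ctrl: list[bool] = []
    ctrl_id: list[object] = []
    log_int = np.log(fm.intensities.to_numpy(dtype=float))
    blocks = [log_int]
    k = 0
    for r, c in plots[:n_bio]:
        rows_ix.append(r)
        cols_ix.append(c)
        is_ctrl.append(False)
        ctrl_id.append(None)
    plot_iter = iter(plots[n_bio:])
    for i in range(config.n_controls):
        cid = f"CTRL{i + 1}"
        for rep in range(ctrl_counts[i]):
            r, c = next(plot_iter)
            names.append(f"{cid}_r{rep + 1:02d}")
            rows_ix.append(r)
            cols_ix.append(c)
            is_ctrl.append(True)
            ctrl_id.append(cid)
            blocks.append((ctrl_profile[i]
                           + (rng.normal(0, config.control_noise_sd, len(feats))
                              if config.control_noise_sd > 0 else 0.0))[None, :])
            k += 1
    logI = np.vstack(blocks)

    row_eff = config.field_sd * _smooth_profile(n_rows_grid, rng)
    col_eff = config.field_sd * _smooth_profile(n_cols_grid, rng)
    r_arr = np.array(rows_ix, dtype=int)
    c_arr = np.array(cols_ix, dtype=int)
    logI = logI + (row_eff[r_arr] + col_eff[c_arr])[:, None]
    truth.spatial_surface = {
        "row": {int(r): float(v) for r, v in enumerate(row_eff)},
        "col": {int(c): float(v) for c, v in enumerate(col_eff)},
    }

    intens = np.exp(logI)

    # pooled QC level: geometric mean of biological samples before drift
    qc_level = np.exp(log_int.mean(axis=0))

    # injection sequence: blanks first, then randomized samples with a QC
    # leading every block of `qc_interval` injections and one closing QC
    order = rng.permutation(len(names))
    seq: list[tuple[str, str]] = [("blank", f"BLANK{i + 1}") for i in range(config.n_blanks)]
    for i, s in enumerate(order):
        if i % config.qc_interval == 0:
            seq.append(("qc", f"QC{i // config.qc_interval + 1:03d}"))
        seq.append(("sample", names[s]))
    seq.append(("qc", f"QC{len(order) // config.qc_interval + 2:03d}"))

    total_inj = len(seq)
    t = np.arange(total_inj, dtype=float)
    drift = 1.0 - config.drift_amplitude * t / max(total_inj - 1, 1)
    if config.drift_wiggle_sd > 0 and config.drift_amplitude > 0:
        drift = drift * np.exp(config.drift_wiggle_sd * _smooth_profile(total_inj, rng))
    drift = np.clip(drift, 0.05, None)
    truth.drift_curve = pd.Series(drift, index=t.astype(int), name="drift_factor")

    # contaminant features are also present in blanks
    contam = rng.choice(len(feats), size=min(config.n_contaminant_features, len(feats)),
                        replace=False)

    all_names: list[str] = []
    all_rows = []
    name_to_pos = {nm: i for i, nm in enumerate(names)}
    meta_rows = []
    for inj, (kind, nm) in enumerate(seq):
        if kind == "sample":
            i = name_to_pos[nm]
            vec = intens[i] * drift[inj]
            meta_rows.append({
                "injection_index": inj, "is_qc": False, "is_blank": False,
                "is_control": is_ctrl[i], "control_id": ctrl_id[i],
                "row": r_arr[i], "col": c_arr[i],
                "dry_mass_mg": (fm.sample_meta.at[nm, "dry_mass_mg"]
                                if nm in fm.sample_meta.index
                                else float(np.clip(rng.normal(10, 1), 7, 13))),
            })
        elif kind == "qc":
            vec = qc_level * np.exp(rng.normal(0, config.qc_noise_sd, len(feats))) * drift[inj]
            meta_rows.append({
                "injection_index": inj, "is_qc": True, "is_blank": False,
                "is_control": False, "control_id": None,
                "row": np.nan, "col": np.nan, "dry_mass_mg": np.nan,
            })
        else:  # blank
            vec = np.exp(rng.normal(np.log(20.0), 0.5, len(feats)))
            vec[contam] = qc_level[contam] * np.exp(rng.normal(0, 0.2, len(contam)))
            vec = vec * drift[inj]
            meta_rows.append({
                "injection_index": inj, "is_qc": False, "is_blank": True,
                "is_control": False, "control_id": None,
                "row": np.nan, "col": np.nan, "dry_mass_mg": np.nan,
            })
        all_names.append(nm)
        all_rows.append(vec)

    out = FeatureMatrix(
        intensities=pd.DataFrame(np.vstack(all_rows), index=all_names, columns=feats),
        feature_meta=fm.feature_meta.copy(),
        sample_meta=pd.DataFrame(meta_rows, index=all_names),
        flags=dict(fm.flags),
    )
    return out, truth


# ---------------------------------------------------------------------------
# isotope / adduct redundancy
# ---------------------------------------------------------------------------

def inject_redundancy(
    fm: FeatureMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    truth: SimTruth | None = None,
    delta_catalogue: dict[str, float] | None = None,
) -> tuple[FeatureMatrix, SimTruth]:
    """Append derived isotope/adduct columns for randomly chosen parents.

    A derived feature sits at the parent's m/z plus an exact catalogue delta
    and (jittered) retention time, with intensities equal to the parent's
    times a fixed ratio in ``redundancy_ratio_range`` times multiplicative
    noise of sd ``redundancy_noise_sd`` (0 = exact copies).
    """
    rng = rng or config.op_rng("redundancy")
    truth = truth or SimTruth()
    catalogue = delta_catalogue or dict(DEFAULT_DELTA_CATALOGUE)
    if not catalogue:
        raise ValueError("empty delta catalogue")
    names = list(catalogue)

    feats = list(fm.intensities.columns)
    parents = rng.choice(len(feats), size=config.n_redundant, replace=True)
    X = fm.intensities.to_numpy(dtype=float)
    new_cols = []
    new_meta = []
    counter: dict[str, int] = {}
    for pi in parents:
        parent = feats[pi]
        counter[parent] = counter.get(parent, 0) + 1
        did = f"{parent}_d{counter[parent]}"
        delta = catalogue[names[int(rng.integers(len(names)))]]
        ratio = rng.uniform(*config.redundancy_ratio_range)
        noise = (np.exp(rng.normal(0.0, config.redundancy_noise_sd, X.shape[0]))
                 if config.redundancy_noise_sd > 0 else 1.0)
        new_cols.append(X[:, pi] * ratio * noise)
        jitter = float(np.clip(rng.normal(0.0, config.redundancy_rt_jitter_s), -0.5, 0.5))
        meta = fm.feature_meta.loc[parent]
        new_meta.append({
            "mz": meta["mz"] + delta,
            "rt": max(meta["rt"] + jitter, 0.0),
            "mz_spread_da": meta.get("mz_spread_da", 0.0),
            "rt_spread_s": meta.get("rt_spread_s", 0.0),
        })
        truth.redundancy_map[did] = parent

    derived_ids = list(truth.redundancy_map)[-len(new_cols):] if new_cols else []
    if new_cols:
        add = pd.DataFrame(np.column_stack(new_cols), index=fm.intensities.index,
                           columns=derived_ids)
        intens = pd.concat([fm.intensities, add], axis=1)
        meta = pd.concat([fm.feature_meta,
                          pd.DataFrame(new_meta, index=derived_ids)])
    else:
        intens, meta = fm.intensities, fm.feature_meta

    out = FeatureMatrix(intensities=intens, feature_meta=meta,
                        sample_meta=fm.sample_meta.copy(), flags=dict(fm.flags))
    return out, truth


def simulate_redundancy_scene(
    n_parents: int = 2557,
    n_derived: int = 950,
    n_samples: int = 100,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[FeatureMatrix, SimTruth]:
    """Feature table with exactly ``n_derived`` planted isotope/adduct copies.

    Parent features carry independent log-normal intensity profiles (so the
    redundancy-collapse correlation gate cannot link them); derived features
    are exact scaled copies when ``noise_sd`` is 0.  With the defaults the
    table replays the study's redundancy arithmetic: 2557 + 950 = 3507
    features collapsing back to 2557.
    """
    rng = np.random.default_rng(seed)
    ids = [f"F{i + 1:04d}" for i in range(n_parents)]
    logI = rng.normal(13.0, 1.0, size=(n_samples, n_parents)) \
        + rng.normal(0.0, 0.5, size=(1, n_parents))
    fm = FeatureMatrix(
        intensities=pd.DataFrame(np.exp(logI),
                                 index=[f"S{i + 1:03d}" for i in range(n_samples)],
                                 columns=ids),
        feature_meta=pd.DataFrame({
            "mz": rng.uniform(100.0, 1000.0, n_parents),
            "rt": rng.uniform(60.0, 700.0, n_parents),
        }, index=ids),
        sample_meta=pd.DataFrame({
            "is_qc": False, "is_blank": False, "is_control": False,
            "dry_mass_mg": 10.0,
        }, index=[f"S{i + 1:03d}" for i in range(n_samples)]),
    )
    cfg = SimConfig(n_features=n_parents, n_redundant=n_derived,
                    redundancy_noise_sd=noise_sd, seed=seed)
    return inject_redundancy(fm, cfg, rng=rng)


# ---------------------------------------------------------------------------
# auxiliary annotation inputs for end-to-end runs
# ---------------------------------------------------------------------------

def simulate_qtl_catalogue(
    snp_map: pd.DataFrame,
    target_snps: list[str],
    trait_classes: list[str] | None = None,
    n_decoys: int = 5,
    span_bp: int = 20_000,
    rng: np.random.Generator | None = None,
):
    """QTL SNP lists planted over target SNPs plus random decoy QTLs.

    Each target SNP gets one QTL whose defining SNPs straddle it within
    ``span_bp``; decoys are placed at random positions.  Returns a
    :class:`mgwaskit.coloc.QtlCatalogue`.
    """
    from .coloc import TRAIT_CLASSES, QtlCatalogue

    rng = rng or np.random.default_rng(0)
    classes = trait_classes or list(TRAIT_CLASSES)
    rows = []
    for i, snp in enumerate(target_snps):
        chrom = snp_map.at[snp, "chrom"]
        pos = int(snp_map.at[snp, "pos"])
        cls = classes[i % len(classes)]
        for off in (-span_bp, 0, span_bp):
            rows.append({"qtl_id": f"QTL_target{i + 1}", "trait_class": cls,
                         "chrom": chrom, "pos": max(pos + off, 1)})
    chroms = snp_map["chrom"].unique()
    max_pos = int(snp_map["pos"].max())
    for d in range(n_decoys):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, max_pos + 1))
        cls = classes[int(rng.integers(len(classes)))]
        rows.append({"qtl_id": f"QTL_decoy{d + 1}", "trait_class": cls,
                     "chrom": chrom, "pos": pos})
    return QtlCatalogue(pd.DataFrame(rows))


def simulate_gene_annotation(
    snp_map: pd.DataFrame,
    exonic_snps: list[str],
    n_extra_genes: int = 20,
    gene_span_bp: int = 3_000,
    rng: np.random.Generator | None = None,
):
    """Toy gene models: one gene with an exon over each requested SNP plus
    background genes at random positions.  Returns a
    :class:`mgwaskit.genemap.GeneAnnotation`."""
    from .genemap import GeneAnnotation, GeneModel

    rng = rng or np.random.default_rng(0)
    genes: dict[str, GeneModel] = {}
    for i, snp in enumerate(exonic_snps):
        chrom = snp_map.at[snp, "chrom"]
        pos = int(snp_map.at[snp, "pos"])
        start = max(pos - gene_span_bp // 2, 1)
        end = start + gene_span_bp - 1
        exon1 = (start, pos + 50)
        exon2 = (min(pos + 200, end - 10), end)
        gid = f"GENE_t{i + 1:03d}"
        genes[gid] = GeneModel(gene_id=gid, chrom=chrom, start=start, end=end,
                               strand="+", exons=[exon1, exon2], cds=[])
    chroms = list(snp_map["chrom"].unique())
    max_pos = int(snp_map["pos"].max())
    for d in range(n_extra_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, max(max_pos - gene_span_bp, 2)))
        end = start + gene_span_bp - 1
        mid = (start + end) // 2
        gid = f"GENE_x{d + 1:03d}"
        genes[gid] = GeneModel(gene_id=gid, chrom=chrom, start=start, end=end,
                               strand="+", exons=[(start, mid)], cds=[])
    return GeneAnnotation(genes=genes)


# ---------------------------------------------------------------------------
# one-call scene
# ---------------------------------------------------------------------------

@dataclass
class SimScene:
    panel: ParentalPanel
    genotypes: GenotypeData
    features: FeatureMatrix
    truth: SimTruth


def simulate_scene(config: SimConfig) -> SimScene:
    """Run the whole generator: parents -> hybrids -> phenotypes -> field
    effects and drift -> redundancy.  Bit-reproducible for a fixed seed."""
    panel = simulate_parents(config)
    geno = make_hybrids(panel, config=config)
    truth = SimTruth(block_membership=panel.block_membership)
    truth.op_seeds = {op: config.seed for op in _OP_NAMES}
    fm, truth = simulate_metabolome(geno, config, block_membership=panel.block_membership,
                                    truth=truth)
    fm, truth = inject_field_and_drift(fm, config, truth=truth)
    fm, truth = inject_redundancy(fm, config, truth=truth)
    return SimScene(panel=panel, genotypes=geno, features=fm, truth=truth)
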