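"""Curation of untargeted LC-MS feature tables.

A *feature* is an (m/z, retention-time) intensity variable, a proxy for a
metabolite ion, measured across field-grown samples.  Before association
mapping the table is: spatially adjusted with replicated control plots,
drift-corrected with periodic pooled-QC injections, filtered on blank
detection / mass and RT stability / QC repeatability, collapsed for
isotope-adduct redundancy, and normalized by sample dry mass.

Default thresholds: m/z stability 0.005 Da, RT stability 40 s, QC CV 20%,
redundancy correlation 0.9 within a 2 s RT window at 5 ppm mass-delta
tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: catalogue of m/z deltas (Da) searched when collapsing redundant features
DEFAULT_DELTA_CATALOGUE: dict[str, float] = {
    "13C": 1.003355,          # one 13C isotope spacing
    "2x13C": 2.006710,        # two 13C isotopes
    "Na-H": 21.981944,        # sodium adduct replacing a proton
    "NH4": 17.026549,         # ammonium adduct
    "-H2O": -18.010565,       # in-source water loss
}

STATUS_KEPT = "kept"
STATUS_BLANK = "blank_hit"
STATUS_MZ = "mz_unstable"
STATUS_RT = "rt_unstable"
STATUS_QC_CV = "qc_cv_high"
STATUS_REDUNDANT = "redundant"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """samples x features intensity table with feature and sample metadata.

    ``feature_meta`` is indexed by feature id with columns ``mz`` (Da) and
    ``rt`` (seconds); optional ``mz_spread_da`` / ``rt_spread_s`` columns
    carry the across-sample apex variation used by the stability filters.
    ``sample_meta`` is indexed by sample with columns ``injection_index``,
    ``is_qc``, ``is_blank``, ``is_control``, ``control_id``, ``row``,
    ``col``, ``dry_mass_mg`` (any may be absent until the relevant stage).
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    mass_normalized: bool = False
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensities.columns.duplicated().any():
            raise ValueError("duplicated feature ids")
        missing = self.intensities.columns.difference(self.feature_meta.index)
        if len(missing):
            raise ValueError(f"features without metadata: {list(missing[:5])}")
        if (self.feature_meta["mz"] <= 0).any():
            raise ValueError("m/z must be positive")
        if (self.feature_meta["rt"] < 0).any():
            raise ValueError("retention time must be non-negative")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    # -- sample masks -------------------------------------------------------
    def _mask(self, col: str) -> pd.Series:
        if col in self.sample_meta.columns:
            return self.sample_meta[col].fillna(False).astype(bool)
        return pd.Series(False, index=self.sample_meta.index)

    @property
    def qc_mask(self) -> pd.Series:
        return self._mask("is_qc")

    @property
    def blank_mask(self) -> pd.Series:
        return self._mask("is_blank")

    @property
    def control_mask(self) -> pd.Series:
        return self._mask("is_control")

    @property
    def bio_mask(self) -> pd.Series:
        return ~(self.qc_mask | self.blank_mask | self.control_mask)

    @property
    def features(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.index)

    def subset_features(self, keep) -> "FeatureMatrix":
        keep = [f for f in self.intensities.columns if f in set(keep)]
        return replace(
            self,
            intensities=self.intensities[keep],
            feature_meta=self.feature_meta.loc[keep],
            flags=dict(self.flags),
        )

    def subset_samples(self, keep) -> "FeatureMatrix":
        keep = [s for s in self.intensities.index if s in set(keep)]
        return replace(
            self,
            intensities=self.intensities.loc[keep],
            sample_meta=self.sample_meta.loc[keep],
            flags=dict(self.flags),
        )


@dataclass
class FilterReport:
    """Per-feature outcome of a filtering stage; statuses partition the
    stage's input feature set."""

    status: pd.Series  # feature id -> status string
    thresholds: dict

    @property
    def kept(self) -> list[str]:
        return list(self.status.index[self.status == STATUS_KEPT])

    @property
    def removed(self) -> list[str]:
        return list(self.status.index[self.status != STATUS_KEPT])

    def counts(self) -> pd.Series:
        return self.status.value_counts()


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def qc_cv(fm: FeatureMatrix) -> pd.Series:
    """Coefficient of variation of each feature over QC injections."""
    qc = fm.intensities.loc[fm.qc_mask.to_numpy()]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    cv[(sd == 0)] = 0.0  # zero-variance QC series: CV defined as 0
    return cv


def filter_features(
    fm: FeatureMatrix,
    mz_tol_da: float = 0.005,
    rt_tol_s: float = 40.0,
    qc_cv_max: float | None = 0.20,
    blank_ratio_max: float | None = 0.10,
) -> tuple[FeatureMatrix, FilterReport]:
    """Remove unreliable features; report the first failing rule per feature.

    Rules, in order: detected in blank extracts (mean blank intensity above
    ``blank_ratio_max`` of mean QC intensity), m/z apex spread > mz_tol_da,
    RT apex spread > rt_tol_s, QC intensity CV > qc_cv_max.  A rule whose
    metadata is absent (no blanks injected, no spread columns) is skipped.
    """
    n_qc = int(fm.qc_mask.sum())
    if qc_cv_max is not None and n_qc < 2:
        raise ValueError("QC CV filter requires at least 2 QC samples")
    if blank_ratio_max is not None and "is_blank" not in fm.sample_meta.columns:
        raise ValueError("blank filter enabled but sample_meta has no is_blank flag")

    status = pd.Series(STATUS_KEPT, index=fm.intensities.columns, dtype=object)

    if blank_ratio_max is not None and fm.blank_mask.any():
        blank_mean = fm.intensities.loc[fm.blank_mask.to_numpy()].mean(axis=0)
        ref = fm.intensities.loc[fm.qc_mask.to_numpy()] if n_qc else fm.intensities.loc[fm.bio_mask.to_numpy()]
        ref_mean = ref.mean(axis=0)
        hit = blank_mean > blank_ratio_max * ref_mean
        status[hit & (status == STATUS_KEPT)] = STATUS_BLANK

    if "mz_spread_da" in fm.feature_meta.columns:
        bad = fm.feature_meta["mz_spread_da"] > mz_tol_da
        status[bad & (status == STATUS_KEPT)] = STATUS_MZ
    if "rt_spread_s" in fm.feature_meta.columns:
        bad = fm.feature_meta["rt_spread_s"] > rt_tol_s
        status[bad & (status == STATUS_KEPT)] = STATUS_RT

    if qc_cv_max is not None:
        cv = qc_cv(fm)
        bad = cv > qc_cv_max
        status[bad & (status == STATUS_KEPT)] = STATUS_QC_CV

    report = FilterReport(
        status=status,
        thresholds={
            "mz_tol_da": mz_tol_da,
            "rt_tol_s": rt_tol_s,
            "qc_cv_max": qc_cv_max,
            "blank_ratio_max": blank_ratio_max,
        },
    )
    out = fm.subset_features(report.kept)
    logger.info("filter_features: %d/%d features kept", len(report.kept), len(status))
    return out, report


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def _drift_curve(x_qc: np.ndarray, logy_qc: np.ndarray, x_all: np.ndarray) -> np.ndarray:
    """Smooth log-intensity trend over injection index fitted on QCs."""
    order = np.argsort(x_qc, kind="stable")  # deterministic under row shuffles
    x_qc, logy_qc = x_qc[order], logy_qc[order]
    if len(x_qc) >= 5:
        from sklearn.svm import SVR

        sd = logy_qc.std()
        scale = x_qc.std() or 1.0
        svr = SVR(kernel="rbf", C=max(1.0, 3.0 * sd), gamma="scale",
                  epsilon=0.1 * (sd if sd > 0 else 1.0))
        svr.fit((x_qc / scale).reshape(-1, 1), logy_qc)
        return svr.predict((x_all / scale).reshape(-1, 1))
    # few QCs: local (lowess) regression fallback
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(logy_qc, x_qc, frac=0.9, return_sorted=True)
    return np.interp(x_all, fitted[:, 0], fitted[:, 1])  # flat extrapolation


def correct_drift(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide intensities by a per-feature smooth QC trend (mean scaled to 1).

    A support-vector smoother (radial kernel) is fit to log QC intensity
    against injection index; with fewer than 5 QCs a local regression is
    used instead.  Features whose QC CV would increase after correction, or
    with all-zero QC intensities, are flagged and left unchanged.
    """
    if "injection_index" not in fm.sample_meta.columns:
        raise ValueError("correct_drift requires sample_meta.injection_index")
    qc = fm.qc_mask.to_numpy()
    if qc.sum() < 2:
        raise ValueError("correct_drift requires at least 2 QC samples")
    x_all = fm.sample_meta["injection_index"].to_numpy(dtype=float)
    x_qc = x_all[qc]

    I = fm.intensities.to_numpy(dtype=float).copy()
    flagged: list[str] = []
    cols = list(fm.intensities.columns)
    for j, feat in enumerate(cols):
        y_qc = I[qc, j]
        if not (y_qc > 0).all():
            flagged.append(feat)
            continue
        logy = np.log(y_qc)
        pred = _drift_curve(x_qc, logy, x_all)
        curve = np.exp(pred)
        curve = curve / curve.mean()
        corrected = I[:, j] / curve
        pre_cv = y_qc.std(ddof=1) / y_qc.mean() if y_qc.mean() > 0 else np.inf
        post_qc = corrected[qc]
        post_cv = post_qc.std(ddof=1) / post_qc.mean() if post_qc.mean() > 0 else np.inf
        if post_cv <= pre_cv + 1e-12:
            I[:, j] = corrected
        else:
            flagged.append(feat)

    out = replace(fm, intensities=pd.DataFrame(I, index=fm.intensities.index, columns=cols),
                  flags=dict(fm.flags))
    out.flags["drift_uncorrected"] = flagged
    if flagged:
        logger.warning("correct_drift: %d features left unchanged", len(flagged))
    return out


# ---------------------------------------------------------------------------
# spatial adjustment
# ---------------------------------------------------------------------------

def _median_polish(values: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                   n_rows: int, n_cols: int, max_iter: int = 10,
                   tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Row+column effects of an incomplete two-way table by median polish."""
    resid = values.astype(float).copy()
    resid -= np.median(resid)
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    for _ in range(max_iter):
        delta = 0.0
        for r in range(n_rows):
            m = rows == r
            if m.any():
                med = np.median(resid[m])
                row_eff[r] += med
                resid[m] -= med
                delta = max(delta, abs(med))
        for c in range(n_cols):
            m = cols == c
            if m.any():
                med = np.median(resid[m])
                col_eff[c] += med
                resid[m] -= med
                delta = max(delta, abs(med))
        if delta < tol:
            break
    return row_eff, col_eff


def adjust_spatial(fm: FeatureMatrix) -> FeatureMatrix:
    """Remove additive row+column field effects estimated on control plots.

    Per feature, log intensities of replicated control hybrids (genotype
    medians removed first) are median-polished into row and column effects;
    the predicted surface is subtracted from every field plot on log scale.
    Rows or columns never sampled by a control carry a zero effect.  Control
    plots are discarded from the output.
    """
    meta = fm.sample_meta
    for col in ("row", "col"):
        if col not in meta.columns:
            raise ValueError(f"adjust_spatial requires sample_meta.{col}")
    ctrl = fm.control_mask.to_numpy()
    if "control_id" not in meta.columns or meta.loc[ctrl, "control_id"].nunique() < 2:
        raise ValueError("adjust_spatial requires >=2 replicated control genotypes")

    field = meta["row"].notna().to_numpy() & meta["col"].notna().to_numpy()
    rows_all = pd.factorize(meta["row"])[0]
    # factorize row/col labels on their own axes
    row_codes, row_labels = pd.factorize(meta["row"], use_na_sentinel=True)
    col_codes, col_labels = pd.factorize(meta["col"], use_na_sentinel=True)
    n_rows, n_cols = len(row_labels), len(col_labels)
    del rows_all

    ctrl_idx = np.where(ctrl & field)[0]
    ctrl_ids = meta["control_id"].to_numpy(dtype=object)[ctrl_idx]
    r_ctrl = row_codes[ctrl_idx]
    c_ctrl = col_codes[ctrl_idx]

    uncovered_rows = sorted(set(range(n_rows)) - set(r_ctrl.tolist()))
    uncovered_cols = sorted(set(range(n_cols)) - set(c_ctrl.tolist()))
    if uncovered_rows or uncovered_cols:
        logger.warning(
            "adjust_spatial: %d rows and %d columns without control plots get zero effect",
            len(uncovered_rows), len(uncovered_cols))

    I = fm.intensities.to_numpy(dtype=float)
    if not (I > 0).all():
        raise ValueError("adjust_spatial requires strictly positive intensities")
    logI = np.log(I)
    out = logI.copy()
    for j in range(logI.shape[1]):
        vals = logI[ctrl_idx, j].copy()
        # remove control-genotype medians so only the field surface remains
        for cid in np.unique(ctrl_ids):
            m = ctrl_ids == cid
            vals[m] -= np.median(vals[m])
        row_eff, col_eff = _median_polish(vals, r_ctrl, c_ctrl, n_rows, n_cols)
        surface = np.zeros(len(meta))
        ok = field
        surface[ok] = row_eff[row_codes[ok]] + col_eff[col_codes[ok]]
        out[:, j] = logI[:, j] - surface

    adjusted = pd.DataFrame(np.exp(out), index=fm.intensities.index,
                            columns=fm.intensities.columns)
    keep = ~ctrl
    result = replace(
        fm,
        intensities=adjusted.loc[keep],
        sample_meta=meta.loc[keep],
        flags=dict(fm.flags),
    )
    result.flags["spatial_uncovered"] = {
        "rows": [row_labels[r] for r in uncovered_rows],
        "cols": [col_labels[c] for c in uncovered_cols],
    }
    return result


# ---------------------------------------------------------------------------
# redundancy collapse
# ---------------------------------------------------------------------------

def collapse_redundancy(
    fm: FeatureMatrix,
    delta_catalogue: dict[str, float] | None = None,
    rt_window_s: float = 2.0,
    corr_min: float = 0.9,
    ppm_tol: float = 5.0,
) -> tuple[FeatureMatrix, FilterReport]:
    """Cluster isotope/adduct duplicates and keep one representative each.

    Two features are linked when they elute within ``rt_window_s`` of each
    other, their m/z difference matches a catalogue delta within ``ppm_tol``
    ppm, and their intensity profiles correlate at >= ``corr_min`` over
    non-blank samples.  Clusters are the transitive closure of links; the
    most intense member (highest mean intensity) is retained.
    """
    if delta_catalogue is None:
        delta_catalogue = dict(DEFAULT_DELTA_CATALOGUE)
    if not delta_catalogue:
        raise ValueError("empty delta catalogue")
    deltas = np.array(sorted({abs(v) for v in delta_catalogue.values()}))

    feats = list(fm.intensities.columns)
    mz = fm.feature_meta.loc[feats, "mz"].to_numpy(dtype=float)
    rt = fm.feature_meta.loc[feats, "rt"].to_numpy(dtype=float)
    use = (~fm.blank_mask).to_numpy()
    X = fm.intensities.loc[use].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))

    order = np.argsort(rt, kind="stable")
    from .genostruct import _UnionFind  # same tiny helper

    uf = _UnionFind(len(feats))
    lo = 0
    for a in range(len(order)):
        i = order[a]
        while rt[i] - rt[order[lo]] > rt_window_s:
            lo += 1
        for b in range(lo, a):
            j = order[b]
            dmz = abs(mz[i] - mz[j])
            tol = ppm_tol * 1e-6 * max(mz[i], mz[j])
            if not (np.abs(deltas - dmz) <= tol).any():
                continue
            if norms[i] == 0 or norms[j] == 0:
                continue
            r = float(Xc[:, i] @ Xc[:, j] / (norms[i] * norms[j]))
            if r >= corr_min:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(feats)):
        groups.setdefault(uf.find(i), []).append(i)

    mean_int = X.mean(axis=0)
    status = pd.Series(STATUS_KEPT, index=feats, dtype=object)
    for idxs in groups.values():
        if len(idxs) == 1:
            continue
        rep = max(idxs, key=lambda k: (mean_int[k], feats[k]))
        for k in idxs:
            if k != rep:
                status.iloc[k] = STATUS_REDUNDANT

    report = FilterReport(
        status=status,
        thresholds={"rt_window_s": rt_window_s, "corr_min": corr_min,
                    "ppm_tol": ppm_tol, "deltas": dict(delta_catalogue)},
    )
    out = fm.subset_features(report.kept)
    logger.info("collapse_redundancy: removed %d of %d features",
                len(report.removed), len(feats))
    return out, report


# ---------------------------------------------------------------------------
# mass normalization and PCA
# ---------------------------------------------------------------------------

def normalize_mass(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide each sample's intensities by its dry mass (mg).

    QC and blank injections (pooled extract / solvent, no powder mass) are
    left unchanged.  Refuses to run twice on the same matrix.
    """
    if fm.mass_normalized:
        raise ValueError("feature matrix is already mass-normalized")
    if "dry_mass_mg" not in fm.sample_meta.columns:
        raise ValueError("normalize_mass requires sample_meta.dry_mass_mg")
    mass = fm.sample_meta["dry_mass_mg"]
    needs = ~(fm.qc_mask | fm.blank_mask)
    if mass[needs].isna().any() or (mass[needs] <= 0).any():
        bad = mass.index[needs & (mass.isna() | (mass <= 0))].tolist()
        raise ValueError(f"missing/invalid dry mass for samples: {bad[:5]}")
    divisor = mass.where(needs, 1.0).to_numpy(dtype=float)
    out = replace(
        fm,
        intensities=fm.intensities.div(divisor, axis=0),
        mass_normalized=True,
        flags=dict(fm.flags),
    )
    return out


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def run_pca(fm: FeatureMatrix, n_components: int = 10) -> PcaResult:
    """PCA of unit-scaled, mean-centered biological-sample intensities."""
    bio = fm.bio_mask.to_numpy()
    X = fm.intensities.loc[bio].to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples and 2 features")
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    feats = np.array(fm.intensities.columns)
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant features before PCA")
        X = X[:, ~const]
        feats = feats[~const]
        sd = sd[~const]
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total = float((s**2).sum())
    k = min(n_components, len(s))
    evr = (s[:k] ** 2) / total
    idx = fm.intensities.index[bio]
    comp = [f"PC{i+1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(U[:, :k] * s[:k], index=idx, columns=comp),
        loadings=pd.DataFrame(Vt[:k].T, index=feats, columns=comp),
        explained_variance_ratio=evr,
    )
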