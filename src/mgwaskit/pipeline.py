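"""End-to-end orchestration with deterministic seeds and run manifests.

Stage order: metabolome curation (spatial -> drift -> filters -> redundancy
collapse -> mass normalization) -> genotype structure -> mixed-model GWAS
-> LD expansion and QTL co-localization -> gene mapping / hot spots.  Every
stage logs its input/output counts into a manifest (written even on
failure) and all thresholds are surfaced in a single config with the
pipeline defaults: m/z 0.005 Da, RT 40 s, QC CV 0.20, MAF 0.1, 20 forward
steps, 50 kb co-localization window, 5 Mb / 1 Mb / 0.075 / 10 hot spots.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import genemap as genemap_mod
from . import genostruct, io, metabolome, mlm, sim

logger = logging.getLogger(__name__)
__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    # synthetic scene (used when no external inputs are given)
    sim: sim.SimConfig = field(default_factory=lambda: sim.SimConfig(
        n_hybrids=200, n_chromosomes=5, n_blocks_per_chr=20, n_features=200))
    # metabolome thresholds
    mz_tol_da: float = 0.005
    rt_tol_s: float = 40.0
    qc_cv_max: float = 0.20
    blank_ratio_max: float = 0.10
    corr_min: float = 0.9
    rt_window_s: float = 2.0
    ppm_tol: float = 5.0
    # genotype thresholds
    maf_min: float = 0.1
    r2_tol: float = 1e-9
    # association
    max_steps: int = 20
    gamma: float | None = None
    # co-localization / hot spots
    window_bp: int = 50_000
    hotspot_window_bp: int = 5_000_000
    hotspot_step_bp: int = 1_000_000
    hotspot_freq_min: float = 0.075
    hotspot_count_min: int = 10
    # stage toggles
    run_spatial: bool = True
    run_drift: bool = True
    run_filters: bool = True
    run_collapse: bool = True
    run_mass_norm: bool = True
    run_coloc: bool = True
    run_genemap: bool = True
    # io
    seed: int = 0
    outdir: str | None = None

    _RANGES = {
        "mz_tol_da": (0.0, 1.0), "rt_tol_s": (0.0, 3600.0),
        "qc_cv_max": (0.0, 1.0), "blank_ratio_max": (0.0, 1.0),
        "corr_min": (0.0, 1.0), "maf_min": (0.0, 0.5),
        "hotspot_freq_min": (0.0, 1.0),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in raw:
            sim_known = {f.name for f in dataclasses.fields(sim.SimConfig)}
            sim_unknown = set(raw["sim"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            raw["sim"] = sim.SimConfig(**raw["sim"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class StageRecord:
    name: str
    counts: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256


@dataclass
class RunManifest:
    version: str
    seed: int
    parameters: dict
    stages: list[StageRecord] = field(default_factory=list)
    failed_stage: str | None = None

    def add(self, name: str, counts: dict, outputs: dict[str, Path] | None = None) -> None:
        hashes = {}
        for key, p in (outputs or {}).items():
            p = Path(p)
            hashes[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
        self.stages.append(StageRecord(name=name, counts=counts, outputs=hashes))

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "parameters": self.parameters,
            "failed_stage": self.failed_stage,
            "stages": [dataclasses.asdict(s) for s in self.stages],
        }


@dataclass
class PipelineResult:
    manifest: RunManifest
    features: metabolome.FeatureMatrix
    genotypes: genostruct.GenotypeData
    sets: genostruct.CoInheritedSets
    kinship: genostruct.KinshipPair
    gwas: mlm.GwasResult
    coloc: coloc_mod.ColocResult | None
    backprop: coloc_mod.BackpropResult | None
    regions: genemap_mod.RegionAssignment | None
    hotspots: list[genemap_mod.HotSpot] | None
    truth: sim.SimTruth | None
    summary: dict


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: RunConfig,
    features: metabolome.FeatureMatrix | None = None,
    genotypes: genostruct.GenotypeData | None = None,
    qtl_catalogue: coloc_mod.QtlCatalogue | None = None,
    annotation: genemap_mod.GeneAnnotation | None = None,
    truth: sim.SimTruth | None = None,
) -> PipelineResult:
    """Run all stages in order; abort with the failing stage named.

    With no explicit inputs the synthetic scene defined by ``config.sim``
    (seeded from ``config.seed``) supplies features, genotypes and — for the
    co-localization and gene stages — a planted QTL catalogue and toy gene
    annotation over the causal blocks.
    """
    manifest = RunManifest(version=__version__, seed=config.seed,
                           parameters=io._jsonable(dataclasses.asdict(config)))
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if features is None or genotypes is None:
            stage = "simulate"
            cfg = dataclasses.replace(config.sim, seed=config.seed)
            scene = sim.simulate_scene(cfg)
            features = features or scene.features
            genotypes = genotypes or scene.genotypes
            truth = scene.truth
            manifest.add(stage, {
                "hybrids": genotypes.n_hybrids, "snps": genotypes.n_snps,
                "features": features.intensities.shape[1],
                "samples": features.intensities.shape[0]})

        fm = features
        if config.run_spatial and fm.control_mask.any():
            stage = "metab.spatial"
            fm = metabolome.adjust_spatial(fm)
            manifest.add(stage, {"features": fm.intensities.shape[1],
                                 "samples": fm.intensities.shape[0]})
        if config.run_drift and fm.qc_mask.sum() >= 2:
            stage = "metab.drift"
            fm = metabolome.correct_drift(fm)
            manifest.add(stage, {"features": fm.intensities.shape[1]})
        if config.run_filters:
            stage = "metab.filters"
            fm, report = metabolome.filter_features(
                fm, mz_tol_da=config.mz_tol_da, rt_tol_s=config.rt_tol_s,
                qc_cv_max=config.qc_cv_max if fm.qc_mask.sum() >= 2 else None,
                blank_ratio_max=config.blank_ratio_max if "is_blank" in fm.sample_meta else None)
            manifest.add(stage, {"features": fm.intensities.shape[1],
                                 **{f"removed_{k}": int(v)
                                    for k, v in report.counts().items()
                                    if k != metabolome.STATUS_KEPT}})
        if config.run_collapse:
            stage = "metab.collapse"
            fm, creport = metabolome.collapse_redundancy(
                fm, rt_window_s=config.rt_window_s, corr_min=config.corr_min,
                ppm_tol=config.ppm_tol)
            manifest.add(stage, {"features": fm.intensities.shape[1],
                                 "removed_redundant": len(creport.removed)})
        if config.run_mass_norm:
            stage = "metab.mass_norm"
            fm = metabolome.normalize_mass(fm)
            manifest.add(stage, {"features": fm.intensities.shape[1]})

        stage = "genostruct"
        sets = genostruct.build_coinherited_sets(genotypes, r2_tol=config.r2_tol)
        refs = genostruct.filter_reference_snps(genotypes, sets, maf_min=config.maf_min)
        designs = genostruct.encode_designs(genotypes, snps=refs)
        kin = genostruct.compute_ais_kinship(genotypes)
        manifest.add(stage, {"snps": genotypes.n_snps, "sets": sets.n_sets,
                             "reference_snps": len(refs)})

        stage = "gwas"
        bio = fm.bio_mask
        pheno = fm.intensities.loc[bio.to_numpy()]
        pheno = pheno.loc[pheno.index.intersection(genotypes.G.index)]
        gwas = mlm.run_gwas(pheno, kin, designs, snp_map=genotypes.snp_map,
                            max_steps=config.max_steps, gamma=config.gamma)
        manifest.add(stage, {
            "features_tested": int(pheno.shape[1]),
            "features_associated": int(gwas.associations["feature"].nunique()),
            "associations": int(len(gwas.associations)),
        })

        coloc_res = backprop = None
        if config.run_coloc:
            stage = "coloc"
            if qtl_catalogue is None:
                if truth is None:
                    raise ValueError("co-localization stage needs a QTL catalogue")
                # plant QTLs over the causal blocks (decoys only if none)
                targets = sorted(set(truth.block_reference.values()))
                qtl_catalogue = sim.simulate_qtl_catalogue(
                    genotypes.snp_map, targets,
                    rng=np.random.default_rng(config.seed + 1))
            assoc_refs = sorted(pd.unique(gwas.associations["reference_snp"]))
            expanded = coloc_mod.expand_to_members(assoc_refs, sets)
            coloc_res = coloc_mod.colocalize(expanded, genotypes.snp_map,
                                             qtl_catalogue, window_bp=config.window_bp)
            backprop = coloc_mod.backpropagate(coloc_res, sets, gwas.associations)
            manifest.add(stage, {
                "expanded_snps": int(expanded["member_snp"].nunique()),
                "colocalizing_snps": len(coloc_res.colocalizing_members),
                "qtls_hit": len(coloc_res.qtls_hit),
                "features_implicated": int(backprop.feature_qtls["feature"].nunique())
                if len(backprop.feature_qtls) else 0,
            })

        regions = hotspots = None
        if config.run_genemap:
            stage = "genemap"
            if annotation is None:
                if truth is None:
                    raise ValueError("gene-mapping stage needs a GFF3 annotation")
                exonic = sorted(pd.unique(gwas.associations["reference_snp"]))[:20]
                annotation = sim.simulate_gene_annotation(
                    genotypes.snp_map, exonic,
                    rng=np.random.default_rng(config.seed + 2))
            assoc_refs = sorted(pd.unique(gwas.associations["reference_snp"]))
            expanded_all = coloc_mod.expand_to_members(assoc_refs, sets)
            snp_df = genotypes.snp_map.loc[pd.unique(expanded_all["member_snp"])]
            regions = genemap_mod.map_snps_to_genes(
                snp_df, annotation, reference_of=sets.reference_of,
                associations=gwas.associations)
            met_genes = set(regions.gene_features["gene"]) if len(regions.gene_features) else set()
            hotspots = genemap_mod.detect_hotspots(
                annotation, met_genes, window_bp=config.hotspot_window_bp,
                step_bp=config.hotspot_step_bp, freq_min=config.hotspot_freq_min,
                count_min=config.hotspot_count_min)
            manifest.add(stage, {
                "snps_mapped": int(len(regions.regions)),
                "exonic_snps": int((regions.regions == genemap_mod.REGION_EXON).sum()),
                "genes": int(regions.gene_features["gene"].nunique())
                if len(regions.gene_features) else 0,
                "hotspots": len(hotspots),
            })

        stage = "summarize"
        summary = summarize(gwas, fm, sets, coloc_res, backprop, regions, hotspots)
        manifest.add(stage, {"keys": len(summary)})
    except Exception:
        manifest.failed_stage = stage
        if outdir:
            io.write_json(manifest.to_dict(), outdir / "manifest.json")
        logger.exception("pipeline failed at stage %s", stage)
        raise

    if outdir:
        _write_outputs(outdir, fm, genotypes, sets, kin, gwas, coloc_res,
                       backprop, regions, hotspots, summary, manifest)
    return PipelineResult(manifest=manifest, features=fm, genotypes=genotypes,
                          sets=sets, kinship=kin, gwas=gwas, coloc=coloc_res,
                          backprop=backprop, regions=regions, hotspots=hotspots,
                          truth=truth, summary=summary)


def _write_outputs(outdir, fm, genotypes, sets, kin, gwas, coloc_res, backprop,
                   regions, hotspots, summary, manifest) -> None:
    outdir = Path(outdir)
    io.write_feature_matrix(fm, outdir, prefix="curated")
    io.write_genotypes_tsv(genotypes, outdir)
    io.write_sets_tsv(sets, outdir / "coinherited_sets.tsv")
    io.write_kinship(kin, outdir)
    gwas.associations.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    gwas.h2g.rename("h2g").to_csv(outdir / "h2g.tsv", sep="\t", index_label="feature")
    if coloc_res is not None:
        coloc_res.hits.to_csv(outdir / "coloc_hits.tsv", sep="\t", index=False)
    if backprop is not None and len(backprop.feature_qtls):
        backprop.feature_qtls.to_csv(outdir / "coloc_features.tsv", sep="\t", index=False)
    if regions is not None:
        regions.regions.rename("region").to_csv(outdir / "snp_regions.tsv",
                                                sep="\t", index_label="snp")
        regions.gene_features.to_csv(outdir / "gene_features.tsv", sep="\t", index=False)
    if hotspots:
        pd.DataFrame([dataclasses.asdict(h) for h in hotspots]).to_csv(
            outdir / "hotspots.tsv", sep="\t", index=False)
    io.write_json(summary, outdir / "summary.json")
    io.write_json(manifest.to_dict(), outdir / "manifest.json")


# ---------------------------------------------------------------------------
# bookkeeping
# ---------------------------------------------------------------------------

def _sig3(x: float) -> float:
    """Round to 3 significant digits (the reporting convention for counts
    ratios, e.g. 955/2557 -> 37.3%)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + 2)


def bookkeeping_ratios(totals: dict) -> dict:
    """Derived bookkeeping quantities from raw association counts.

    Expects (any subset of): n_features, n_associated_features,
    n_associations, n_unique_reference_snps, n_expanded_associations,
    n_expanded_unique_snps, n_exonic_snps, n_genes, n_high_h2_features.
    Ratios are returned unrounded (percentages on the 0-100 scale);
    reporting sites round to their display precision.
    """
    t = totals

    def ratio(num, den, scale=1.0):
        if num in t and t.get(den):
            return scale * t[num] / t[den]
        return 0.0 if num in t and den in t else None

    candidates = {
        "mean_snps_per_feature": ratio("n_associations", "n_associated_features"),
        "associated_feature_pct": ratio("n_associated_features", "n_features", 100.0),
        "exonic_snp_pct": ratio("n_exonic_snps", "n_expanded_unique_snps", 100.0),
        "mean_associations_per_gene": ratio("n_exonic_snps", "n_genes"),
        "mean_expanded_associations_per_feature":
            ratio("n_expanded_associations", "n_associated_features"),
        "high_h2_feature_pct": ratio("n_high_h2_features",
                                     "n_associated_features", 100.0),
    }
    return {k: v for k, v in candidates.items() if v is not None}


def summarize(gwas, fm, sets, coloc_res=None, backprop=None, regions=None,
              hotspots=None) -> dict:
    """Reproduce the study-style bookkeeping from pipeline outputs."""
    assoc = gwas.associations
    n_features = int(fm.intensities.shape[1])
    n_assoc_feat = int(assoc["feature"].nunique()) if len(assoc) else 0
    h2 = gwas.h2g
    assoc_h2 = h2.loc[h2.index.intersection(assoc["feature"].unique())] if len(assoc) else h2.iloc[:0]

    totals = {
        "n_features": n_features,
        "n_associated_features": n_assoc_feat,
        "n_associations": int(len(assoc)),
        "n_unique_reference_snps": int(assoc["reference_snp"].nunique()) if len(assoc) else 0,
        "n_high_h2_features": int((assoc_h2 > 0.5).sum()),
    }
    if len(assoc):
        expanded_per_feat = assoc.groupby("feature")["reference_snp"].apply(
            lambda refs: sum(len(sets.members(r)) for r in refs))
        totals["n_expanded_associations"] = int(expanded_per_feat.sum())
        expanded_snps = set()
        for r in pd.unique(assoc["reference_snp"]):
            expanded_snps.update(sets.members(r))
        totals["n_expanded_unique_snps"] = len(expanded_snps)
    else:
        totals["n_expanded_associations"] = 0
        totals["n_expanded_unique_snps"] = 0
    if regions is not None:
        totals["n_exonic_snps"] = int((regions.regions == "exon").sum())
        totals["n_genes"] = int(regions.gene_features["gene"].nunique()) \
            if len(regions.gene_features) else 0

    summary = {
        "totals": totals,
        "ratios": {k: _sig3(v) for k, v in bookkeeping_ratios(totals).items()},
        "h2g_mean": float(h2.mean()) if len(h2) else float("nan"),
        "h2g_mean_associated": float(assoc_h2.mean()) if len(assoc_h2) else float("nan"),
    }
    if coloc_res is not None:
        summary["coloc"] = {
            "colocalizing_snps": len(coloc_res.colocalizing_members),
            "qtls_hit": len(coloc_res.qtls_hit),
        }
    if backprop is not None:
        summary["coloc_per_class"] = {
            cls: {"features": len(rep.features),
                  "reference_snps": len(rep.reference_snps),
                  "ld_snps": len(rep.ld_snps)}
            for cls, rep in backprop.per_class.items()}
        summary["multi_qtl_features"] = len(backprop.multi)
    if hotspots is not None:
        summary["hotspots"] = [
            {"chrom": h.chrom, "start": h.start, "end": h.end,
             "genes": h.gene_count, "metabolite_genes": h.metabolite_gene_count,
             "frequency": _sig3(h.frequency)} for h in hotspots]
    return summary
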