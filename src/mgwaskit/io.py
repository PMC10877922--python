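"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV except genotypes (TSV and minimal VCF), gene models
(GFF3), and the truth/manifest documents (YAML/JSON).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genostruct import CoInheritedSets, GenotypeData, KinshipPair
from .metabolome import FeatureMatrix


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def write_feature_matrix(fm: FeatureMatrix, outdir, prefix: str = "features") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": outdir / f"{prefix}_intensities.tsv",
        "feature_meta": outdir / f"{prefix}_meta.tsv",
        "sample_meta": outdir / f"{prefix}_samples.tsv",
    }
    fm.intensities.to_csv(paths["intensities"], sep="\t", index_label="sample")
    fm.feature_meta.to_csv(paths["feature_meta"], sep="\t", index_label="feature_id")
    fm.sample_meta.to_csv(paths["sample_meta"], sep="\t", index_label="sample")
    return paths


def read_feature_matrix(outdir, prefix: str = "features") -> FeatureMatrix:
    outdir = Path(outdir)
    intensities = pd.read_csv(outdir / f"{prefix}_intensities.tsv", sep="\t",
                              index_col="sample")
    feature_meta = pd.read_csv(outdir / f"{prefix}_meta.tsv", sep="\t",
                               index_col="feature_id")
    sample_meta = pd.read_csv(outdir / f"{prefix}_samples.tsv", sep="\t",
                              index_col="sample")
    for col in ("is_qc", "is_blank", "is_control"):
        if col in sample_meta.columns:
            sample_meta[col] = sample_meta[col].astype(bool)
    return FeatureMatrix(intensities=intensities, feature_meta=feature_meta,
                         sample_meta=sample_meta)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotypes_tsv(g: GenotypeData, outdir, prefix: str = "genotypes") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}.tsv",
        "snp_map": outdir / f"{prefix}_snp_map.tsv",
    }
    g.G.to_csv(paths["matrix"], sep="\t", index_label="hybrid")
    g.snp_map.to_csv(paths["snp_map"], sep="\t", index_label="snp_id")
    if g.parent_of is not None:
        paths["parents"] = outdir / f"{prefix}_parents.tsv"
        g.parent_of.to_csv(paths["parents"], sep="\t", index_label="hybrid")
    if g.panel_presence is not None:
        paths["panel"] = outdir / f"{prefix}_panel.tsv"
        g.panel_presence.rename("panel_presence").to_csv(paths["panel"], sep="\t",
                                                         index_label="snp_id")
    return paths


def read_genotypes_tsv(outdir, prefix: str = "genotypes") -> GenotypeData:
    outdir = Path(outdir)
    G = pd.read_csv(outdir / f"{prefix}.tsv", sep="\t", index_col="hybrid")
    snp_map = pd.read_csv(outdir / f"{prefix}_snp_map.tsv", sep="\t", index_col="snp_id")
    parent_of = None
    panel = None
    pfile = outdir / f"{prefix}_parents.tsv"
    if pfile.exists():
        parent_of = pd.read_csv(pfile, sep="\t", index_col="hybrid")
    pp = outdir / f"{prefix}_panel.tsv"
    if pp.exists():
        panel = pd.read_csv(pp, sep="\t", index_col="snp_id")["panel_presence"]
    return GenotypeData(G=G, snp_map=snp_map, parent_of=parent_of, panel_presence=panel)


def write_vcf(g: GenotypeData, path) -> Path:
    """Minimal uncompressed VCF with GT fields (0/0, 0/1, 1/1; ./.)."""
    path = Path(path)
    order = g.snp_map.loc[g.G.columns].sort_values(["chrom", "pos"]).index
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.snp_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.G.index) + "\n")
        for snp in order:
            chrom = g.snp_map.at[snp, "chrom"]
            pos = int(g.snp_map.at[snp, "pos"])
            calls = "\t".join(
                gt_code.get(v, "./.") if not np.isnan(v) else "./."
                for v in g.G[snp].to_numpy(dtype=float))
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")
    return path


def read_vcf(path) -> GenotypeData:
    """Read a VCF (plain or bgzipped) into 0/1/2 codes via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols = {}
    chroms, poss, ids = [], [], []
    for var in vcf:
        snp = var.ID or f"{var.CHROM}_p{var.POS}"
        codes = var.gt_types.astype(float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        out = np.full(len(samples), np.nan)
        out[codes == 0] = 0.0
        out[codes == 1] = 1.0
        out[codes == 3] = 2.0
        cols[snp] = out
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(snp)
    G = pd.DataFrame(cols, index=samples)
    snp_map = pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)
    return GenotypeData(G=G, snp_map=snp_map)


def read_genome_fasta(path):
    """Indexed FASTA accessor (pyfaidx) usable as the ``genome`` argument of
    :func:`mgwaskit.genemap.classify_variant_effect`."""
    from pyfaidx import Fasta

    return Fasta(str(path))


# ---------------------------------------------------------------------------
# sets, kinships, small tables
# ---------------------------------------------------------------------------

def write_sets_tsv(sets: CoInheritedSets, path) -> Path:
    path = Path(path)
    sets.reference_of.rename("reference_snp").to_csv(path, sep="\t",
                                                     index_label="member_snp")
    return path


def read_sets_tsv(path) -> CoInheritedSets:
    ref_of = pd.read_csv(path, sep="\t", index_col="member_snp")["reference_snp"]
    grouped: dict[str, list[str]] = {}
    for member, ref in ref_of.items():
        grouped.setdefault(ref, []).append(member)
    return CoInheritedSets(sets={r: sorted(m) for r, m in grouped.items()},
                           reference_of=ref_of)


def write_kinship(kin: KinshipPair, outdir, prefix: str = "kinship") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"K_a": outdir / f"{prefix}_additive.tsv",
             "K_d": outdir / f"{prefix}_dominance.tsv"}
    kin.K_a.to_csv(paths["K_a"], sep="\t", index_label="hybrid")
    kin.K_d.to_csv(paths["K_d"], sep="\t", index_label="hybrid")
    return paths


def read_kinship(outdir, prefix: str = "kinship") -> KinshipPair:
    outdir = Path(outdir)
    return KinshipPair(
        K_a=pd.read_csv(outdir / f"{prefix}_additive.tsv", sep="\t", index_col="hybrid"),
        K_d=pd.read_csv(outdir / f"{prefix}_dominance.tsv", sep="\t", index_col="hybrid"),
    )


# ---------------------------------------------------------------------------
# documents
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_yaml(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(obj), fh, sort_keys=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
    return path
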