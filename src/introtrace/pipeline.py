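"""End-to-end run orchestration: simulate -> classify -> annotate ->
summarize -> DE -> ASE, with input validation and a consolidated
summary JSON.

Every threshold is surfaced in the config and echoed into the report;
a fixed seed and config give byte-identical outputs (floats are written
to 6 significant digits).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pyfaidx
import yaml

import introtrace
from introtrace import ase_markers, expression, gene_regions, inheritance
from introtrace import trio_classify
from introtrace.simulate import StudyConfig, simulate_study
from introtrace.simulate.counts import GENOTYPES

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Either ``simulate`` is true (inputs are generated under
    ``outdir/sim``) or all five real-data paths must be given.
    """

    outdir: str = "introtrace_run"
    seed: int = 0
    simulate: bool = True
    sim: StudyConfig = field(default_factory=StudyConfig)
    vcf: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    counts: str | None = None
    design: str | None = None
    role_map: dict[str, str] = field(default_factory=lambda: {
        "offspring": "offspring", "donor": "donor", "recurrent": "recurrent"})
    upstream_len: int = 1000
    indel_min: int = 1
    indel_max: int = 99
    alpha: float = 0.05
    tpm_min: float = 10.0
    het_policy: str = "ambiguous"
    min_evidence: int = 1
    make_figures: bool = False

    def __post_init__(self) -> None:
        for name in ("upstream_len", "indel_max", "alpha", "tpm_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.simulate:
            missing = [k for k in ("vcf", "gff3", "fasta", "counts", "design")
                       if getattr(self, k) is None]
            if missing:
                raise ValueError(f"real-data run missing paths: {missing}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "sim" in data and isinstance(data["sim"], dict):
            data["sim"] = StudyConfig(**data["sim"])
        return cls(**data)


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sig6(x):
    """Round floats to 6 significant digits for stable JSON output."""
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _sig6(v) for k, v in x.items()}
    if isinstance(x, list):
        return [_sig6(v) for v in x]
    return x


def validate_inputs(config: RunConfig) -> dict[str, list[str]]:
    """Parse and cross-check all declared inputs.

    Returns {'errors': [...], 'warnings': [...]}; chromosome-name
    discord between VCF, GFF3 and FASTA is a hard error.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    if config.simulate:
        return {"errors": errors, "warnings": warnings_}
    chrom_sets = {}
    try:
        fasta = pyfaidx.Fasta(config.fasta)
        chrom_sets["fasta"] = set(fasta.keys())
    except Exception as exc:
        errors.append(f"FASTA parse error: {exc}")
    try:
        sites = trio_classify.read_trio_vcf(config.vcf, config.role_map)
        chrom_sets["vcf"] = {s.chrom for s in sites}
    except Exception as exc:
        errors.append(f"VCF parse error: {exc}")
    try:
        gff = pd.read_csv(config.gff3, sep="\t", comment="#", header=None,
                          usecols=[0], names=["seqid"])
        chrom_sets["gff3"] = set(gff["seqid"])
    except Exception as exc:
        errors.append(f"GFF3 parse error: {exc}")
    if "fasta" in chrom_sets:
        for name, chroms in chrom_sets.items():
            extra = chroms - chrom_sets["fasta"]
            if extra:
                errors.append(f"chromosome names in {name} absent from FASTA: "
                              f"{sorted(extra)}")
    try:
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        design = pd.read_csv(config.design, sep="\t")
        missing = set(counts.columns) - set(design["sample"])
        if missing:
            errors.append(f"samples missing from design: {sorted(missing)}")
        for col in ("sample", "genotype", "treatment", "replicate"):
            if col not in design.columns:
                errors.append(f"design table missing column {col}")
    except Exception as exc:
        errors.append(f"counts/design parse error: {exc}")
    return {"errors": errors, "warnings": warnings_}


def gene_lengths(genes: dict[str, gene_regions.GeneModel]) -> pd.Series:
    """Summed exon length per gene (bp), for TPM normalization."""
    return pd.Series({gid: sum(e - s + 1 for s, e in g.exons) or (g.end - g.start + 1)
                      for gid, g in genes.items()})


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write per-stage TSVs plus summary.json."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": introtrace.__version__,
        "seed": config.seed,
        "thresholds": {
            "upstream_len": config.upstream_len,
            "indel_min": config.indel_min,
            "indel_max": config.indel_max,
            "alpha": config.alpha,
            "tpm_min": config.tpm_min,
            "min_evidence": config.min_evidence,
            "het_policy": config.het_policy,
        },
    }

    if config.simulate:
        truth = simulate_study(config.sim, outdir / "sim", seed=config.seed)
        paths = truth.paths
        config = dataclasses.replace(
            config, vcf=paths["vcf"], gff3=paths["gff3"], fasta=paths["fasta"],
            counts=paths["counts"], design=paths["design"])
        summary["simulated"] = True
        summary["truth"] = {
            "gene_weighted_donor_fraction_pct":
                truth.gene_weighted_donor_fraction_pct,
            "diploid_donor_fraction": truth.diploid_donor_fraction,
            "cis_gene_id": truth.cis_gene_id,
        }
    else:
        report = validate_inputs(config)
        if report["errors"]:
            raise ValueError("input validation failed: "
                             + "; ".join(report["errors"]))
        summary["simulated"] = False
    summary["input_md5"] = {k: _md5(getattr(config, k))
                            for k in ("vcf", "gff3", "fasta", "counts", "design")}

    # --- classify ---------------------------------------------------------
    sites = trio_classify.read_trio_vcf(config.vcf, config.role_map)
    sites = trio_classify.filter_indel_length(sites, config.indel_min,
                                              config.indel_max)
    origins = trio_classify.classify_sites(sites, het_policy=config.het_policy)
    site_df = trio_classify.sites_to_frame(sites, origins)
    site_df.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    summary["site_label_counts"] = {
        k: int(v) for k, v in sorted(site_df["origin"].value_counts().items())}
    summary["n_sites"] = len(site_df)

    # --- annotate ---------------------------------------------------------
    fasta = pyfaidx.Fasta(config.fasta)
    chrom_lengths = {name: len(fasta[name]) for name in fasta.keys()}
    index = gene_regions.build_gene_index(config.gff3, chrom_lengths,
                                          upstream_len=config.upstream_len)
    annotated = gene_regions.annotate_sites(sites, origins, index, fasta)
    annotated.to_csv(outdir / "annotated.tsv", sep="\t", index=False)

    # --- summarize --------------------------------------------------------
    kept_genes = gene_regions.gene_filter(list(index.genes.values()))
    kept_ids = {g.gene_id for g in kept_genes}
    summary["n_genes_total"] = len(index.genes)
    summary["n_genes_after_filter"] = len(kept_ids)
    filtered_annot = annotated[annotated["gene_id"].isin(kept_ids)]
    calls = inheritance.assign_gene_origin(filtered_annot, sorted(kept_ids),
                                           min_evidence=config.min_evidence)
    calls.to_csv(outdir / "gene_origin.tsv", sep="\t")
    counts_by_verdict = inheritance.verdict_counts(calls)
    summary["gene_verdict_counts"] = counts_by_verdict
    summary["donor_fraction_pct"] = inheritance.donor_fraction(
        counts_by_verdict["DONOR"], counts_by_verdict["RECURRENT"])
    gene_chrom = {g.gene_id: g.chrom for g in kept_genes}
    table = inheritance.per_chromosome_table(calls, gene_chrom)
    table.to_csv(outdir / "per_chromosome.tsv", sep="\t", index=False)
    summary["per_chromosome"] = table.to_dict(orient="records")
    segments = inheritance.donor_segments(site_df)
    inheritance.write_bed(segments, outdir / "donor_segments.bed")

    # --- differential expression -----------------------------------------
    counts = pd.read_csv(config.counts, sep="\t", index_col=0)
    design = pd.read_csv(config.design, sep="\t")
    lengths = gene_lengths(index.genes).reindex(counts.index)
    lengths = lengths.fillna(1000.0)  # genes absent from annotation
    tpm = expression.tpm_normalize(counts, lengths)
    keep = expression.filter_low_expression(tpm, threshold=config.tpm_min)
    summary["n_genes_expressed"] = len(keep)
    de_results = {}
    for genotype in GENOTYPES:
        res = expression.nb_de_test(counts.loc[keep], design, genotype,
                                    alpha=config.alpha)
        res.to_csv(outdir / f"de_{genotype}.tsv", sep="\t")
        de_results[genotype] = res
    summary["deg_counts"] = {
        g: int((de_results[g]["status"] != "NS").sum()) for g in GENOTYPES}
    patterns = expression.classify_patterns(de_results)
    patterns.to_csv(outdir / "patterns.tsv", sep="\t")
    summary["venn_up_counts"] = expression.venn_counts(patterns)
    summary["n_donor_like_genes"] = int(patterns["donor_like_only"].sum())
    zmat, _ = expression.zscore_matrix(tpm.loc[keep], design)
    zmat.to_csv(outdir / "zscore.tsv", sep="\t")
    if config.make_figures:
        _heatmap(zmat, outdir / "zscore_heatmap.png")

    # --- ASE markers ------------------------------------------------------
    candidates = ase_markers.intersect_patterns_with_origin(
        patterns, calls, filtered_annot)
    candidates.to_csv(outdir / "ase_candidates.tsv", sep="\t", index=False)
    reports = {}
    for row in candidates.itertuples():
        rep = ase_markers.annotate_cis_variants(
            row.gene_id, filtered_annot, index.genes[row.gene_id])
        reports[row.gene_id] = rep.to_dict(orient="records")
        if config.make_figures:
            ase_markers.write_gene_schematic_svg(
                index.genes[row.gene_id], rep,
                str(outdir / f"ase_{row.gene_id}.svg"),
                upstream_len=config.upstream_len)
    with open(outdir / "ase_reports.json", "w") as fh:
        json.dump(_sig6(reports), fh, indent=2, default=str)
    summary["ase_candidates"] = [
        {"gene_id": row.gene_id, "cis_flag": bool(row.cis_flag),
         "promoter_indel_length": None if pd.isna(row.promoter_indel_length)
         else int(row.promoter_indel_length)}
        for row in candidates.itertuples()]

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_sig6(summary), fh, indent=2, sort_keys=True)
    return summary


def _heatmap(zmat: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(zmat.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(zmat.columns)))
    ax.set_xticklabels(zmat.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
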