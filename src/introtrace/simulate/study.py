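"""End-to-end synthetic study: genome, pedigree, trio VCF, counts.

``simulate_study`` wires the generators together and writes every
standard-format input the analysis pipeline consumes, plus plain-TSV
truth sidecars and a JSON truth summary.  The derived line is
conditioned on retaining at least one fully donor-origin protein-coding
gene (re-drawing the pedigree if necessary): the real line was bred and
kept *because* it expresses a donor-derived trait, so a pedigree with
no donor gene would not correspond to the study material.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from introtrace.gene_regions import GeneModel
from introtrace.simulate import genome as genome_mod
from introtrace.simulate.counts import ExpressionSimConfig, simulate_counts
from introtrace.simulate.meiosis import (
    DONOR, ChromosomeSpec, Haplotype, PedigreeConfig, collapse_homozygous,
    default_genome, donor_bp_fraction, haplotype_donor_fraction,
    interval_label, simulate_pedigree,
)
from introtrace.simulate.variants import VariantPlacementConfig, emit_trio_vcf


@dataclass(frozen=True)
class StudyConfig:
    """Desk-scale defaults: 7 chromosomes of 1 Mb / 100 cM, ~200 genes,
    a BC5F4 pedigree and a 9-bp donor-only promoter insertion marker."""

    n_chromosomes: int = 7
    chrom_length_bp: int = 1_000_000
    chrom_length_cM: float = 100.0
    n_genes: int = 196
    te_fraction: float = 0.1
    unknown_fraction: float = 0.1
    upstream_len: int = 1000
    pedigree: PedigreeConfig = field(default_factory=PedigreeConfig)
    placement: VariantPlacementConfig = field(default_factory=VariantPlacementConfig)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    cis_insertion_len: int = 9
    max_pedigree_draws: int = 64


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    specs: list[ChromosomeSpec]
    genes: list[GeneModel]
    sequences: dict[str, bytearray]
    genotype_mosaic: dict[str, Haplotype]
    diploid_donor_fraction: float
    genotype_donor_fraction: float
    gene_origins: dict[str, str]
    gene_weighted_donor_fraction_pct: float
    cis_gene_id: str
    variant_truth: pd.DataFrame
    counts_truth: pd.DataFrame
    design: pd.DataFrame
    paths: dict[str, str] = field(default_factory=dict)


def _cis_eligible(gene: GeneModel, upstream_len: int, chrom_length: int,
                  offset: int = 100) -> bool:
    """A promoter insertion ``offset`` bp 5' of the gene span must land
    inside the upstream window (anchored at the ORF start) and on the
    chromosome; genes whose 5'UTR/intron distance eats the whole window
    cannot host it."""
    pos = gene.start - offset if gene.strand == "+" else gene.end + offset
    win = gene.upstream_window(upstream_len, chrom_length)
    return win is not None and win[0] <= pos <= win[1]


def gene_truth_origin(mosaic: dict[str, Haplotype], gene: GeneModel,
                      upstream_len: int, chrom_length: int) -> str:
    """True origin of a gene's footprint: DONOR / RECURRENT / MIXED."""
    lo, hi = gene.footprint(upstream_len, chrom_length)
    return interval_label(mosaic[gene.chrom], lo - 1, hi)


def gene_weighted_fraction_pct(origins: dict[str, str]) -> float:
    n_d = sum(v == "DONOR" for v in origins.values())
    n_r = sum(v == "RECURRENT" for v in origins.values())
    return 100.0 * n_d / (n_d + n_r)


def simulate_study(config: StudyConfig, outdir: str | Path,
                   seed: int) -> SimTruth:
    """Generate and write a complete synthetic study under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    specs = default_genome(config.n_chromosomes, config.chrom_length_bp,
                           config.chrom_length_cM)
    chrom_len = {sp.name: sp.length_bp for sp in specs}
    genes, sequences = genome_mod.generate_annotation(
        specs, config.n_genes, rng, te_fraction=config.te_fraction,
        unknown_fraction=config.unknown_fraction,
        upstream_len=config.upstream_len)
    coding = [g for g in genes if not (g.mobile_element or g.unknown_protein)]

    # condition on >= 1 fully donor-origin coding gene (see module docstring)
    for _ in range(config.max_pedigree_draws):
        ped = simulate_pedigree(config.pedigree, specs, rng)
        mosaic = collapse_homozygous(ped.offspring, rng)
        origins = {g.gene_id: gene_truth_origin(mosaic, g, config.upstream_len,
                                                chrom_len[g.chrom])
                   for g in genes}
        donor_pure = [g for g in coding if origins[g.gene_id] == DONOR
                      and _cis_eligible(g, config.upstream_len,
                                        chrom_len[g.chrom])]
        if donor_pure:
            break
    else:
        raise RuntimeError("no pedigree draw retained a donor-origin gene; "
                           "increase max_pedigree_draws or donor fraction")
    cis_gene = donor_pure[int(rng.integers(len(donor_pure)))]

    paths = {
        "fasta": str(outdir / "reference.fa"),
        "gff3": str(outdir / "annotation.gff3"),
        "vcf": str(outdir / "trio.vcf"),
        "variant_truth": str(outdir / "trio.truth.tsv"),
        "counts": str(outdir / "counts.tsv"),
        "design": str(outdir / "design.tsv"),
        "counts_truth": str(outdir / "counts.truth.tsv"),
        "gene_truth": str(outdir / "genes.truth.tsv"),
        "truth_json": str(outdir / "sim_truth.json"),
    }
    genome_mod.write_fasta(sequences, paths["fasta"])
    genome_mod.write_gff3(genes, specs, paths["gff3"])

    variant_truth = emit_trio_vcf(
        mosaic, specs, sequences, config.placement, rng,
        vcf_path=paths["vcf"], truth_path=paths["variant_truth"],
        genes=coding, upstream_len=config.upstream_len,
        cis_gene=cis_gene, cis_insertion_len=config.cis_insertion_len)

    gene_ids = [g.gene_id for g in genes]
    counts, design, counts_truth = simulate_counts(
        config.expression, gene_ids, cis_gene.gene_id, rng)
    counts.to_csv(paths["counts"], sep="\t")
    design.to_csv(paths["design"], sep="\t", index=False)
    counts_truth.to_csv(paths["counts_truth"], sep="\t", index=False)

    gene_truth = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": [g.chrom for g in genes],
        "filtered_out": [g.mobile_element or g.unknown_protein for g in genes],
        "true_origin": [origins[g] for g in gene_ids],
    })
    gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)

    truth = SimTruth(
        specs=specs,
        genes=genes,
        sequences=sequences,
        genotype_mosaic=mosaic,
        diploid_donor_fraction=donor_bp_fraction(ped.offspring),
        genotype_donor_fraction=float(np.average(
            [haplotype_donor_fraction(mosaic[sp.name]) for sp in specs],
            weights=[sp.length_bp for sp in specs])),
        gene_origins=origins,
        gene_weighted_donor_fraction_pct=gene_weighted_fraction_pct(
            {g.gene_id: origins[g.gene_id] for g in coding}),
        cis_gene_id=cis_gene.gene_id,
        variant_truth=variant_truth,
        counts_truth=counts_truth,
        design=design,
        paths=paths,
    )
    with open(paths["truth_json"], "w") as fh:
        json.dump({
            "seed": seed,
            "config": {
                "pedigree": asdict(config.pedigree),
                "n_genes": config.n_genes,
                "cis_insertion_len": config.cis_insertion_len,
            },
            "diploid_donor_fraction": truth.diploid_donor_fraction,
            "genotype_donor_fraction": truth.genotype_donor_fraction,
            "gene_weighted_donor_fraction_pct":
                truth.gene_weighted_donor_fraction_pct,
            "cis_gene_id": truth.cis_gene_id,
        }, fh, indent=2)
    return truth
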