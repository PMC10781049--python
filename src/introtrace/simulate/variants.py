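"""Trio variant placement and VCF emission.

Variants are placed relative to a third-party reference (as in real
resequencing, where neither parent is the reference line): each site's
ALT allele is carried by the donor parent, the recurrent parent, or
both, and the offspring genotype follows the parental-origin mosaic at
that position.  A plain-TSV truth sidecar records each site's expected
parental-origin label, computed directly from the carrier and the
mosaic segment -- independently of the classifier under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from introtrace.gene_regions import GeneModel
from introtrace.simulate.meiosis import (
    DONOR, RECURRENT, ChromosomeSpec, Haplotype, label_at,
)
from introtrace.trio_classify import (
    AMBIGUOUS, NON_POLYMORPHIC,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class VariantPlacementConfig:
    """Density and composition of simulated variant sites.

    ``ensure_gene_markers`` places a guaranteed parent-distinguishing
    SNV at both ends of every gene footprint (dense-marker mode), which
    makes gene-level origin calls exact; the sparse default relies on
    the background rates alone.  ``indel_max_len`` defaults above the
    99-bp analysis filter so the filter is exercised.
    """

    snv_rate: float = 1 / 500
    indel_rate: float = 1 / 5000
    indel_max_len: int = 120
    p_donor_alt: float = 0.45
    p_recurrent_alt: float = 0.35
    p_shared_alt: float = 0.20
    ensure_gene_markers: bool = False
    het_fraction: float = 0.0
    sample_names: dict[str, str] = field(default_factory=lambda: {
        "offspring": "offspring", "donor": "donor", "recurrent": "recurrent"})

    def __post_init__(self) -> None:
        if min(self.snv_rate, self.indel_rate) < 0:
            raise ValueError("variant rates must be >= 0")
        if self.indel_max_len < 1:
            raise ValueError("indel_max_len must be >= 1")
        total = self.p_donor_alt + self.p_recurrent_alt + self.p_shared_alt
        if abs(total - 1.0) > 1e-9:
            raise ValueError("carrier probabilities must sum to 1")


def _intersects_cds(gene: GeneModel | None, chrom: str, lo: int, hi: int) -> bool:
    if gene is None or gene.chrom != chrom:
        return False
    return any(s <= hi and lo <= e for s, e in gene.cds)


def emit_trio_vcf(genotype_mosaic: dict[str, Haplotype],
                  specs: list[ChromosomeSpec],
                  sequences: dict[str, bytearray],
                  cfg: VariantPlacementConfig,
                  rng: np.random.Generator,
                  vcf_path: str,
                  truth_path: str | None = None,
                  genes: list[GeneModel] | None = None,
                  upstream_len: int = 1000,
                  cis_gene: GeneModel | None = None,
                  cis_insertion_len: int = 9,
                  cis_offset: int = 100) -> pd.DataFrame:
    """Place variants, write a 3-sample VCF and return the truth table.

    When ``cis_gene`` is given, a donor-only insertion of
    ``cis_insertion_len`` bp is planted in the putative promoter --
    ``cis_offset`` bp 5' of the gene span, inside the upstream window --
    and the gene's coding intervals are kept free of any other variant
    so its protein-coding sequence is identical across the trio.
    """
    chrom_len = {sp.name: sp.length_bp for sp in specs}
    planned: dict[tuple[str, int], dict] = {}

    def plan(chrom, pos, vclass, length, carrier, role):
        key = (chrom, pos)
        if key in planned or pos < 1 or pos > chrom_len[chrom]:
            return
        if vclass == "DELETION" and pos + length > chrom_len[chrom]:
            return
        lo = pos
        hi = pos + (length if vclass == "DELETION" else 0)
        if role != "cis" and _intersects_cds(cis_gene, chrom, lo, hi):
            return
        planned[key] = dict(chrom=chrom, pos=pos, vclass=vclass,
                            length=length, carrier=carrier, role=role)

    if cis_gene is not None:
        pos = (cis_gene.start - cis_offset if cis_gene.strand == "+"
               else cis_gene.end + cis_offset)
        win = cis_gene.upstream_window(upstream_len, chrom_len[cis_gene.chrom])
        if win is None or not win[0] <= pos <= win[1]:
            raise ValueError(
                f"cis gene {cis_gene.gene_id}: promoter position {pos} falls "
                f"outside its upstream window {win}")
        plan(cis_gene.chrom, pos, "INSERTION", cis_insertion_len,
             "donor", "cis")

    if cfg.ensure_gene_markers and genes:
        for g in genes:
            lo, hi = g.footprint(upstream_len, chrom_len[g.chrom])
            for p in (lo, hi):
                plan(g.chrom, p, "SNV", 0, "donor", "marker")

    carriers = ["donor", "recurrent", "both"]
    probs = [cfg.p_donor_alt, cfg.p_recurrent_alt, cfg.p_shared_alt]
    for sp in specs:
        n_snv = rng.poisson(cfg.snv_rate * sp.length_bp)
        for pos in rng.integers(1, sp.length_bp + 1, size=n_snv):
            plan(sp.name, int(pos), "SNV", 0,
                 carriers[rng.choice(3, p=probs)], "background")
        n_indel = rng.poisson(cfg.indel_rate * sp.length_bp)
        for pos in rng.integers(1, sp.length_bp + 1, size=n_indel):
            vclass = "INSERTION" if rng.integers(2) else "DELETION"
            length = int(rng.integers(1, cfg.indel_max_len + 1))
            plan(sp.name, int(pos), vclass, length,
                 carriers[rng.choice(3, p=probs)], "background")

    rows = []
    for key in sorted(planned):
        v = planned[key]
        chrom, pos = v["chrom"], v["pos"]
        seq = sequences[chrom]
        anchor_base = chr(seq[pos - 1])
        if v["vclass"] == "SNV":
            ref = anchor_base
            alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
        elif v["vclass"] == "INSERTION":
            ref = anchor_base
            ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=v["length"]))
            alt = ref + ins
        else:
            ref = bytes(seq[pos - 1:pos + v["length"]]).decode()
            alt = ref[0]
        donor_gt = "ALT" if v["carrier"] in ("donor", "both") else "REF"
        rec_gt = "ALT" if v["carrier"] in ("recurrent", "both") else "REF"
        segment = label_at(genotype_mosaic[chrom], pos - 1)
        off_gt = donor_gt if segment == DONOR else rec_gt
        if cfg.het_fraction > 0 and rng.random() < cfg.het_fraction:
            off_gt = "HET"
        if v["carrier"] == "both":
            expected = NON_POLYMORPHIC
        elif off_gt == "HET":
            expected = AMBIGUOUS
        else:
            expected = DONOR if segment == DONOR else RECURRENT
        rows.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         variant_class=v["vclass"], indel_length=v["length"],
                         carrier=v["carrier"], role=v["role"],
                         donor_gt=donor_gt, recurrent_gt=rec_gt,
                         offspring_gt=off_gt, segment_origin=segment,
                         expected_label=expected))
    truth = pd.DataFrame(rows)

    _write_vcf(truth, specs, cfg, vcf_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


_GT = {"REF": "0/0", "ALT": "1/1", "HET": "0/1"}


def _write_vcf(truth: pd.DataFrame, specs: list[ChromosomeSpec],
               cfg: VariantPlacementConfig, path: str) -> None:
    names = cfg.sample_names
    order = ["offspring", "donor", "recurrent"]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introtrace_sim\n")
        for sp in specs:
            fh.write(f"##contig=<ID={sp.name},length={sp.length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names[r] for r in order) + "\n")
        for row in truth.itertuples():
            gts = [_GT[row.offspring_gt], _GT[row.donor_gt], _GT[row.recurrent_gt]]
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
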