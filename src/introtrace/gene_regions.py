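"""Gene-structure assignment of variants and coding-effect calls.

Variants are assigned to gene structural parts -- the putative promoter
window upstream of the ORF (default 1000 bp), 5'/3' UTRs, introns and
coding exons -- and exonic SNVs/indels are classified as synonymous,
non-synonymous, in-frame or frameshift.  Genes flagged as mobile
elements or encoding unknown proteins can be filtered out before any
inheritance bookkeeping.

Coordinates are GFF/VCF style 1-based inclusive throughout; conversion
to 0-based half-open happens only inside the interval index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from introtrace.trio_classify import DELETION, SNV, TrioSite

logger = logging.getLogger(__name__)

UPSTREAM = "UPSTREAM"
UTR5 = "UTR5"
UTR3 = "UTR3"
EXON = "EXON"
INTRON = "INTRON"
INTERGENIC = "INTERGENIC"

SYNONYMOUS = "SYNONYMOUS"
NONSYNONYMOUS = "NONSYNONYMOUS"
INFRAME_INDEL = "INFRAME_INDEL"
FRAMESHIFT = "FRAMESHIFT"
NONCODING = "NONCODING"

CODING_ALTERING = frozenset({NONSYNONYMOUS, INFRAME_INDEL, FRAMESHIFT})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

Interval = tuple[int, int]  # 1-based inclusive


@dataclass
class GeneModel:
    """Strand-aware gene with exon/CDS/UTR intervals and annotation flags.

    All intervals are 1-based inclusive and sorted by genomic start.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    mobile_element: bool = False
    unknown_protein: bool = False
    malformed: bool = False

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_start(self) -> int:
        """First coding base in transcript orientation (the ORF start)."""
        if not self.cds:
            raise ValueError(f"gene {self.gene_id} has no CDS")
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1]

    def upstream_window(self, length: int, chrom_length: int) -> Interval | None:
        """1000 bp (by default) 5' of the ORF start, clipped at contig ends."""
        anchor = self.cds_start() if self.cds else (
            self.start if self.strand == "+" else self.end)
        if self.strand == "+":
            lo, hi = max(1, anchor - length), anchor - 1
        else:
            lo, hi = anchor + 1, min(chrom_length, anchor + length)
        if hi < lo:
            return None
        return (lo, hi)

    def footprint(self, upstream_len: int, chrom_length: int) -> Interval:
        """Gene span united with the upstream window."""
        win = self.upstream_window(upstream_len, chrom_length)
        lo, hi = self.start, self.end
        if win is not None:
            lo, hi = min(lo, win[0]), max(hi, win[1])
        return (lo, hi)


def _in_intervals(pos: int, intervals: list[Interval]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def transcript_order(intervals: list[Interval], strand: str) -> list[Interval]:
    """CDS/exon intervals in transcript (5'->3') order."""
    return list(intervals) if strand == "+" else list(reversed(intervals))


def genomic_to_cds_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position within the spliced CDS."""
    off = 0
    for s, e in transcript_order(gene.cds, gene.strand):
        if s <= pos <= e:
            return off + (pos - s if gene.strand == "+" else e - pos)
        off += e - s + 1
    raise ValueError(f"position {pos} not in CDS of {gene.gene_id}")


def cds_offset_to_genomic(gene: GeneModel, offset: int) -> int:
    off = offset
    for s, e in transcript_order(gene.cds, gene.strand):
        n = e - s + 1
        if off < n:
            return s + off if gene.strand == "+" else e - off
        off -= n
    raise ValueError(f"CDS offset {offset} beyond CDS of {gene.gene_id}")


class GeneIndex:
    """Interval index over gene footprints (span + upstream window)."""

    def __init__(self, genes: list[GeneModel], chrom_lengths: dict[str, int],
                 upstream_len: int = 1000):
        self.genes: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self.chrom_lengths = dict(chrom_lengths)
        self.upstream_len = upstream_len
        self._trees: dict[str, IntervalTree] = {}
        self._windows: dict[str, Interval | None] = {}
        for g in genes:
            clen = chrom_lengths.get(g.chrom)
            if clen is None:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            self._windows[g.gene_id] = g.upstream_window(upstream_len, clen)
            lo, hi = g.footprint(upstream_len, clen)
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(lo, hi + 1, g.gene_id)  # to 0-based half-open-ish query space

    def upstream_of(self, gene_id: str) -> Interval | None:
        return self._windows[gene_id]

    def query(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.at(pos))
        return [self.genes[g] for g in hits]


def _flag(attrs, key: str) -> bool:
    vals = attrs.get(key, [])
    return bool(vals) and str(vals[0]).lower() in {"true", "1", "yes"}


def build_gene_index(gff3_path: str, chrom_lengths: dict[str, int],
                     upstream_len: int = 1000) -> GeneIndex:
    """Parse a GFF3 into :class:`GeneModel` records and index them.

    One transcript per gene is assumed (the first mRNA child).  Genes
    whose total CDS length is not divisible by 3 are flagged malformed
    with a warning and excluded from coding-effect calls.
    """
    db = gffutils.create_db(str(gff3_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        model = GeneModel(
            gene_id=g.id,
            chrom=g.seqid,
            strand=g.strand,
            start=g.start,
            end=g.end,
            mobile_element=_flag(g.attributes, "mobile_element"),
            unknown_protein=_flag(g.attributes, "unknown_protein"),
        )
        mrnas = list(db.children(g, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else g
        for ft, dest in (("exon", model.exons), ("CDS", model.cds),
                         ("five_prime_UTR", model.utr5),
                         ("three_prime_UTR", model.utr3)):
            for child in db.children(parent, featuretype=ft, order_by="start"):
                dest.append((child.start, child.end))
        if model.cds and model.cds_length % 3 != 0:
            logger.warning("gene %s: CDS length %d not divisible by 3; "
                           "excluded from coding-effect calls",
                           model.gene_id, model.cds_length)
            model.malformed = True
        genes.append(model)
    return GeneIndex(genes, chrom_lengths, upstream_len=upstream_len)


def region_in_gene(gene: GeneModel, pos: int,
                   upstream: Interval | None) -> str | None:
    """Primary structural label of a position within one gene's footprint.

    Precedence: coding exon > UTR > intron > upstream window; the most
    specific functional context wins.
    """
    if gene.start <= pos <= gene.end:
        if _in_intervals(pos, gene.cds):
            return EXON
        if _in_intervals(pos, gene.utr5):
            return UTR5
        if _in_intervals(pos, gene.utr3):
            return UTR3
        if _in_intervals(pos, gene.exons):
            return EXON
        return INTRON
    if upstream is not None and upstream[0] <= pos <= upstream[1]:
        return UPSTREAM
    return None


def effective_position(site: TrioSite) -> int:
    """Reference base used for region assignment.

    Deletions are assigned by their leftmost deleted base (the VCF
    anchor base is shared); SNVs and insertions by the anchor itself.
    """
    return site.pos + 1 if site.variant_class == DELETION else site.pos


def assign_region(site: TrioSite, index: GeneIndex) -> list[tuple[str | None, str]]:
    """All (gene_id, region) labels for a site; [(None, INTERGENIC)] if none."""
    pos = effective_position(site)
    out = []
    for gene in index.query(site.chrom, pos):
        region = region_in_gene(gene, pos, index.upstream_of(gene.gene_id))
        if region is not None:
            out.append((gene.gene_id, region))
    return out or [(None, INTERGENIC)]


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice of the reference (pyfaidx.Fasta or dict of str)."""
    if isinstance(reference, dict):
        return reference[chrom][start - 1:end]
    return str(reference[chrom][start - 1:end]).upper()


def coding_effect(site: TrioSite, gene: GeneModel, reference) -> str:
    """Coding consequence of a variant falling in a coding exon.

    SNVs mutate the affected codon (strand-aware, standard genetic code)
    and the translations are compared; indels are in-frame iff their
    length is a multiple of 3.  Exonic non-CDS positions are NONCODING.
    """
    pos = effective_position(site)
    if gene.malformed or not _in_intervals(pos, gene.cds):
        return NONCODING
    if site.variant_class != SNV:
        return INFRAME_INDEL if site.indel_length % 3 == 0 else FRAMESHIFT
    ref_base = _fetch(reference, site.chrom, site.pos, site.pos)
    if ref_base != site.ref:
        raise ValueError(
            f"reference mismatch at {site.chrom}:{site.pos}: "
            f"FASTA has {ref_base!r}, VCF REF is {site.ref!r}")
    offset = genomic_to_cds_offset(gene, pos)
    codon_idx, within = divmod(offset, 3)
    codon_positions = [cds_offset_to_genomic(gene, codon_idx * 3 + k) for k in range(3)]
    bases = [_fetch(reference, site.chrom, p, p) for p in codon_positions]
    if gene.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        alt_base = site.alt.translate(_COMPLEMENT)
    else:
        alt_base = site.alt
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return SYNONYMOUS if ref_aa == alt_aa else NONSYNONYMOUS


def gene_filter(genes: list[GeneModel]) -> list[GeneModel]:
    """Drop mobile-element and unknown-protein genes."""
    kept = [g for g in genes
            if not (g.mobile_element or g.unknown_protein)]
    n_te = sum(g.mobile_element for g in genes)
    n_unk = sum(g.unknown_protein and not g.mobile_element for g in genes)
    logger.info("gene_filter: removed %d mobile-element and %d unknown-protein "
                "genes, kept %d of %d", n_te, n_unk, len(kept), len(genes))
    return kept


def annotate_sites(sites: list[TrioSite], origins: list[str], index: GeneIndex,
                   reference) -> pd.DataFrame:
    """Long per-(site, gene) annotation table.

    One row per (variant, overlapping gene) pair -- a site in two
    overlapping gene footprints yields two rows -- plus one INTERGENIC
    row for sites outside every footprint.
    """
    rows = []
    for site, origin in zip(sites, origins):
        for gene_id, region in assign_region(site, index):
            effect = NONCODING
            if region == EXON and gene_id is not None:
                effect = coding_effect(site, index.genes[gene_id], reference)
            rows.append({
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "variant_class": site.variant_class,
                "indel_length": site.indel_length,
                "origin": origin,
                "gene_id": gene_id,
                "region": region,
                "coding_effect": effect,
            })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "variant_class", "indel_length", "origin",
                                       "gene_id", "region", "coding_effect"])
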