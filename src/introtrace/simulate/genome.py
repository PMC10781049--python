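"""Synthetic gene annotation and reference sequence.

Generates strand-aware multi-exon gene models (5'UTR, CDS with valid
start/stop and length divisible by 3, 3'UTR) laid out without
overlapping footprints, plus a random reference sequence whose CDS
regions are rewritten with sense codons so coding-effect calls behave
like they would on real sequence.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from introtrace.gene_regions import GeneModel, cds_offset_to_genomic
from introtrace.simulate.meiosis import ChromosomeSpec

_SENSE_CODONS = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
                 if str(Seq(c).translate()) != "*"]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _transcript_to_genomic(exons: list[tuple[int, int]], strand: str,
                           t0: int, t1: int) -> list[tuple[int, int]]:
    """Genomic intervals (1-based inclusive) of transcript slice [t0, t1)."""
    out = []
    off = 0
    order = exons if strand == "+" else list(reversed(exons))
    for s, e in order:
        n = e - s + 1
        a, b = max(t0, off), min(t1, off + n)
        if a < b:
            if strand == "+":
                out.append((s + (a - off), s + (b - off) - 1))
            else:
                out.append((e - (b - off) + 1, e - (a - off)))
        off += n
    return sorted(out)


def _make_gene(gene_id: str, chrom: str, start: int,
               rng: np.random.Generator) -> GeneModel:
    strand = "+" if rng.integers(2) else "-"
    u5 = int(rng.integers(80, 250))
    u3 = int(rng.integers(80, 250))
    n_codons = int(rng.integers(40, 160))
    cds_len = 3 * n_codons
    t_len = u5 + cds_len + u3
    n_exons = int(rng.integers(1, 4))
    # exon transcript lengths: minimum 60 bp each, remainder multinomial
    base = 60
    extra = rng.multinomial(t_len - base * n_exons, [1 / n_exons] * n_exons)
    exon_lens = [base + int(x) for x in extra]
    exons = []
    g = start
    for i, ln in enumerate(exon_lens):
        exons.append((g, g + ln - 1))
        g += ln
        if i < n_exons - 1:
            g += int(rng.integers(120, 600))  # intron
    gene = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     start=exons[0][0], end=exons[-1][1], exons=exons)
    gene.utr5 = _transcript_to_genomic(exons, strand, 0, u5)
    gene.cds = _transcript_to_genomic(exons, strand, u5, u5 + cds_len)
    gene.utr3 = _transcript_to_genomic(exons, strand, u5 + cds_len, t_len)
    flat = sorted(gene.cds)
    for (s1, e1), (s2, e2) in zip(flat[:-1], flat[1:]):
        if s2 <= e1:
            raise ValueError(f"gene {gene_id}: overlapping CDS intervals")
    assert gene.cds_length % 3 == 0
    return gene


def generate_annotation(specs: list[ChromosomeSpec], n_genes: int,
                        rng: np.random.Generator, te_fraction: float = 0.1,
                        unknown_fraction: float = 0.1,
                        upstream_len: int = 1000,
                        ) -> tuple[list[GeneModel], dict[str, bytearray]]:
    """Generate gene models and a consistent reference sequence.

    Genes are laid out round-robin across chromosomes with intergenic
    gaps large enough that footprints (span + upstream window) never
    overlap.  ``te_fraction`` and ``unknown_fraction`` of genes are
    flagged as mobile elements / unknown proteins (disjoint sets).
    """
    sequences: dict[str, bytearray] = {}
    for sp in specs:
        codes = rng.integers(0, 4, size=sp.length_bp, dtype=np.uint8)
        sequences[sp.name] = bytearray(_BASE_LUT[codes].tobytes())

    genes: list[GeneModel] = []
    cursors = {sp.name: upstream_len + 500 for sp in specs}
    spec_cycle = itertools.cycle(specs)
    gid = 0
    while gid < n_genes:
        sp = next(spec_cycle)
        gene = _make_gene(f"gene{gid + 1:04d}", sp.name, cursors[sp.name], rng)
        if gene.end + upstream_len + 500 > sp.length_bp:
            raise ValueError(
                f"chromosome {sp.name} too short for requested gene count")
        cursors[sp.name] = gene.end + upstream_len + int(rng.integers(600, 3000))
        genes.append(gene)
        gid += 1

    order = rng.permutation(len(genes))
    n_te = int(round(te_fraction * len(genes)))
    n_unk = int(round(unknown_fraction * len(genes)))
    for i in order[:n_te]:
        genes[i].mobile_element = True
    for i in order[n_te:n_te + n_unk]:
        genes[i].unknown_protein = True

    for gene in genes:
        _write_cds_sequence(gene, sequences[gene.chrom], rng)
    return genes, sequences


def _write_cds_sequence(gene: GeneModel, seq: bytearray,
                        rng: np.random.Generator) -> None:
    n_codons = gene.cds_length // 3
    middle = rng.choice(len(_SENSE_CODONS), size=max(n_codons - 2, 0))
    spliced = "ATG" + "".join(_SENSE_CODONS[i] for i in middle) + "TAA"
    spliced = spliced[:gene.cds_length]
    for off, base in enumerate(spliced):
        pos = cds_offset_to_genomic(gene, off)  # 1-based
        if gene.strand == "-":
            base = base.translate(_COMPLEMENT)
        seq[pos - 1] = ord(base)


def _gff3_attrs(**kv) -> str:
    return ";".join(f"{k}={v}" for k, v in kv.items())


def write_gff3(genes: list[GeneModel], specs: list[ChromosomeSpec],
               path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sp in specs:
            fh.write(f"##sequence-region {sp.name} 1 {sp.length_bp}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            tid = f"{g.gene_id}.t1"
            fh.write("\t".join([g.chrom, "introtrace_sim", "gene", str(g.start),
                                str(g.end), ".", g.strand, ".",
                                _gff3_attrs(ID=g.gene_id,
                                            mobile_element=str(g.mobile_element).lower(),
                                            unknown_protein=str(g.unknown_protein).lower())])
                     + "\n")
            fh.write("\t".join([g.chrom, "introtrace_sim", "mRNA", str(g.start),
                                str(g.end), ".", g.strand, ".",
                                _gff3_attrs(ID=tid, Parent=g.gene_id)]) + "\n")
            for s, e in g.exons:
                fh.write("\t".join([g.chrom, "introtrace_sim", "exon", str(s),
                                    str(e), ".", g.strand, ".",
                                    _gff3_attrs(Parent=tid)]) + "\n")
            phase = 0
            order = g.cds if g.strand == "+" else list(reversed(g.cds))
            for s, e in order:
                fh.write("\t".join([g.chrom, "introtrace_sim", "CDS", str(s),
                                    str(e), ".", g.strand, str(phase),
                                    _gff3_attrs(Parent=tid)]) + "\n")
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for ft, ivs in (("five_prime_UTR", g.utr5), ("three_prime_UTR", g.utr3)):
                for s, e in ivs:
                    fh.write("\t".join([g.chrom, "introtrace_sim", ft, str(s),
                                        str(e), ".", g.strand, ".",
                                        _gff3_attrs(Parent=tid)]) + "\n")


def write_fasta(sequences: dict[str, bytearray], path: str) -> None:
    records = [SeqRecord(Seq(bytes(seq).decode()), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
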