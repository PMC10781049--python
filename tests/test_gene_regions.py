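"""Region assignment, upstream windows and coding-effect calls."""

import itertools

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from introtrace.gene_regions import (
    EXON, FRAMESHIFT, INFRAME_INDEL, INTRON, NONCODING, NONSYNONYMOUS,
    SYNONYMOUS, UPSTREAM, UTR3, UTR5, GeneIndex, GeneModel, assign_region,
    coding_effect, region_in_gene,
)
from introtrace.trio_classify import TrioSite


def _plus_gene():
    # exon1 [1000..1199]: UTR5 1000..1099, CDS starts 1100
    # exon2 [1500..1999]: CDS 1500..1899, UTR3 1900..1999
    return GeneModel(
        gene_id="gP", chrom="chr1", strand="+", start=1000, end=1999,
        exons=[(1000, 1199), (1500, 1999)],
        cds=[(1100, 1199), (1500, 1899)],
        utr5=[(1000, 1099)], utr3=[(1900, 1999)])


def test_upstream_window_plus_strand():
    g = _plus_gene()
    # ORF starts at 1100 -> window is the 1000 bp immediately 5' of it
    assert g.upstream_window(1000, 100_000) == (100, 1099)


def test_upstream_window_minus_strand():
    g = GeneModel(gene_id="gM", chrom="chr1", strand="-", start=5000, end=6000,
                  exons=[(5000, 6000)], cds=[(5100, 5899)],
                  utr5=[(5900, 6000)], utr3=[(5000, 5099)])
    # ORF start is the CDS end on the minus strand
    assert g.upstream_window(1000, 100_000) == (5900, 6899)


def test_upstream_window_clipped_at_contig_edges():
    g = GeneModel(gene_id="g", chrom="chr1", strand="+", start=400, end=900,
                  exons=[(400, 900)], cds=[(400, 900)])
    assert g.upstream_window(1000, 100_000) == (1, 399)
    gm = GeneModel(gene_id="g2", chrom="chr1", strand="-", start=99_500,
                   end=99_900, exons=[(99_500, 99_900)], cds=[(99_500, 99_900)])
    assert gm.upstream_window(1000, 100_000) == (99_901, 100_000)


def test_region_precedence_within_one_gene():
    g = _plus_gene()
    win = g.upstream_window(1000, 100_000)
    assert region_in_gene(g, 1150, win) == EXON
    assert region_in_gene(g, 1050, win) == UTR5
    assert region_in_gene(g, 1950, win) == UTR3
    assert region_in_gene(g, 1300, win) == INTRON
    assert region_in_gene(g, 500, win) == UPSTREAM
    assert region_in_gene(g, 50, win) is None


def test_intergenic_and_multi_gene_assignment():
    g1 = _plus_gene()
    # a downstream + strand gene whose upstream window reaches back over
    # g1's 3'UTR
    g2 = GeneModel(gene_id="gQ", chrom="chr1", strand="+", start=2600,
                   end=3400, exons=[(2600, 3400)], cds=[(2700, 3399)])
    index = GeneIndex([g1, g2], {"chr1": 100_000})
    hits = assign_region(TrioSite("chr1", 1950, "A", "G"), index)
    assert set(hits) == {("gP", UTR3), ("gQ", UPSTREAM)}
    assert assign_region(TrioSite("chr1", 99_000, "A", "G"), index) == \
        [(None, "INTERGENIC")]


def test_region_counts_match_quadratic_scan_oracle(default_study):
    """Interval-index assignment agrees with a brute-force scan over
    every (site, gene) pair on a simulated annotation."""
    genes = default_study.genes[:40]
    chrom_len = {sp.name: sp.length_bp for sp in default_study.specs}
    index = GeneIndex(genes, chrom_len)
    rng = np.random.default_rng(9)
    chroms = sorted({g.chrom for g in genes})
    sites = [TrioSite(c, int(p), "A", "G")
             for c in chroms
             for p in rng.integers(1, chrom_len[c], size=400)]
    for site in sites:
        got = set(assign_region(site, index))
        expected = set()
        for g in genes:  # quadratic scan, precedence re-derived inline
            if g.chrom != site.chrom:
                continue
            win = g.upstream_window(1000, chrom_len[g.chrom])
            pos = site.pos
            if g.start <= pos <= g.end:
                if any(s <= pos <= e for s, e in g.cds):
                    expected.add((g.gene_id, EXON))
                elif any(s <= pos <= e for s, e in g.utr5):
                    expected.add((g.gene_id, UTR5))
                elif any(s <= pos <= e for s, e in g.utr3):
                    expected.add((g.gene_id, UTR3))
                else:
                    expected.add((g.gene_id, INTRON))
            elif win and win[0] <= pos <= win[1]:
                expected.add((g.gene_id, UPSTREAM))
        if not expected:
            expected = {(None, "INTERGENIC")}
        assert got == expected


def _codon_gene(strand):
    """Gene whose spliced CDS is the concatenation of all 64 codons."""
    codons = ["".join(t) for t in itertools.product("ACGT", repeat=3)]
    spliced = "".join(codons)
    if strand == "+":
        seq = "N" * 100 + spliced + "N" * 100
        cds = [(101, 100 + len(spliced))]
    else:
        comp = str.maketrans("ACGT", "TGCA")
        seq = "N" * 100 + spliced.translate(comp)[::-1] + "N" * 100
        cds = [(101, 100 + len(spliced))]
    gene = GeneModel(gene_id="g64", chrom="chrT", strand=strand, start=101,
                     end=100 + len(spliced), exons=list(cds), cds=list(cds))
    return gene, {"chrT": seq}, codons


def _aa(codon):
    # independent oracle: direct standard-table lookup
    return standard_dna_table.forward_table.get(codon, "*")


@pytest.mark.parametrize("strand", ["+", "-"])
def test_all_576_codon_substitutions_match_table_oracle(strand):
    gene, ref, codons = _codon_gene(strand)
    comp = str.maketrans("ACGT", "TGCA")
    n_checked = 0
    for ci, codon in enumerate(codons):
        for within in range(3):
            for alt in "ACGT":
                if alt == codon[within]:
                    continue
                mutated = codon[:within] + alt + codon[within + 1:]
                expected = (SYNONYMOUS if _aa(codon) == _aa(mutated)
                            else NONSYNONYMOUS)
                t_off = ci * 3 + within
                if strand == "+":
                    pos = 101 + t_off
                    ref_base, alt_base = codon[within], alt
                else:
                    pos = gene.end - t_off
                    ref_base = codon[within].translate(comp)
                    alt_base = alt.translate(comp)
                site = TrioSite("chrT", pos, ref_base, alt_base)
                assert coding_effect(site, gene, ref) == expected, \
                    (codon, within, alt, strand)
                n_checked += 1
    assert n_checked == 576


def test_indel_mod3_rule():
    gene, ref, _ = _codon_gene("+")
    nine = TrioSite("chrT", 110, ref["chrT"][109:119], ref["chrT"][109])
    eight = TrioSite("chrT", 110, ref["chrT"][109:118], ref["chrT"][109])
    assert nine.indel_length == 9
    assert coding_effect(nine, gene, ref) == INFRAME_INDEL
    assert coding_effect(eight, gene, ref) == FRAMESHIFT


def test_exonic_noncoding_and_reference_mismatch():
    g = _plus_gene()
    ref = {"chr1": "A" * 10_000}
    utr_site = TrioSite("chr1", 1050, "A", "G")
    assert coding_effect(utr_site, g, ref) == NONCODING
    bad = TrioSite("chr1", 1150, "C", "G")  # FASTA has A at every position
    with pytest.raises(ValueError, match="chr1:1150"):
        coding_effect(bad, g, ref)


def test_malformed_cds_excluded_from_coding_calls():
    g = _plus_gene()
    g.malformed = True
    site = TrioSite("chr1", 1150, "A", "G")
    assert coding_effect(site, g, {"chr1": "A" * 10_000}) == NONCODING
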