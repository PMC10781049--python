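"""Allele-specific-expression marker discovery.

Intersects donor-like response patterns (up-regulated in the offspring
and the donor parent, unchanged in the recurrent parent) with gene-level
donor-origin calls: a candidate marker gene tracks the donor promoter
haplotype.  The cis flag requires regulatory-region donor variants with
an untouched protein-coding sequence -- a promoter insertion with
identical CDS across genotypes is the canonical hit.
"""

from __future__ import annotations

import logging

import pandas as pd

from introtrace.gene_regions import CODING_ALTERING, GeneModel

logger = logging.getLogger(__name__)

REGULATORY_REGIONS = ("UPSTREAM", "UTR5", "UTR3")


def intersect_patterns_with_origin(patterns: pd.DataFrame,
                                   origins: pd.DataFrame,
                                   annotated: pd.DataFrame) -> pd.DataFrame:
    """Nominate ASE candidate genes.

    A candidate is donor-like in expression and DONOR by gene origin (or
    MIXED with at least one donor regulatory variant).  ``cis_flag`` is
    set when the gene has a donor variant in the upstream window or a
    UTR and *no* donor-origin coding-altering variant;
    ``promoter_indel_length`` reports the longest donor upstream indel.
    Candidates are ranked by offspring adjusted p-value.
    """
    donor_variants = annotated[(annotated["origin"] == "DONOR")
                               & annotated["gene_id"].notna()]
    rows = []
    for gene_id in patterns.index[patterns["donor_like_only"]]:
        if gene_id not in origins.index:
            continue
        verdict = origins.loc[gene_id, "verdict"]
        gv = donor_variants[donor_variants["gene_id"] == gene_id]
        if gv.empty:  # no donor-origin evidence, whatever the verdict claims
            continue
        regulatory = gv[gv["region"].isin(REGULATORY_REGIONS)]
        if verdict == "DONOR":
            pass
        elif verdict == "MIXED" and len(regulatory):
            pass
        else:
            continue
        coding_altering = gv["coding_effect"].isin(CODING_ALTERING).any()
        cis_flag = bool(len(regulatory)) and not coding_altering
        upstream_indels = gv[(gv["region"] == "UPSTREAM")
                             & (gv["variant_class"] != "SNV")]
        promoter_indel_length = (int(upstream_indels["indel_length"].max())
                                 if len(upstream_indels) else None)
        rows.append({
            "gene_id": gene_id,
            "verdict": verdict,
            "status_offspring": patterns.loc[gene_id, "status_offspring"],
            "status_donor": patterns.loc[gene_id, "status_donor"],
            "status_recurrent": patterns.loc[gene_id, "status_recurrent"],
            "log2_fold_change_offspring":
                patterns.loc[gene_id, "log2_fold_change_offspring"],
            "adjusted_p_offspring": patterns.loc[gene_id, "adjusted_p_offspring"],
            "n_donor_variants": len(gv),
            "cis_flag": cis_flag,
            "promoter_indel_length": promoter_indel_length,
        })
    if not rows:
        logger.info("intersect_patterns_with_origin: empty intersection")
    out = pd.DataFrame(rows, columns=[
        "gene_id", "verdict", "status_offspring", "status_donor",
        "status_recurrent", "log2_fold_change_offspring",
        "adjusted_p_offspring", "n_donor_variants", "cis_flag",
        "promoter_indel_length"])
    return out.sort_values(["adjusted_p_offspring", "gene_id"],
                           na_position="last").reset_index(drop=True)


def annotate_cis_variants(gene_id: str, annotated: pd.DataFrame,
                          gene: GeneModel) -> pd.DataFrame:
    """Per-variant report for one candidate's donor-origin variants.

    Distances are to the ORF start, strand-aware: negative values lie
    upstream of the CDS in transcript orientation.
    """
    gv = annotated[(annotated["gene_id"] == gene_id)
                   & (annotated["origin"] == "DONOR")].copy()
    cds_start = gene.cds_start()
    if gene.strand == "+":
        gv["distance_to_cds_start"] = gv["pos"] - cds_start
    else:
        gv["distance_to_cds_start"] = cds_start - gv["pos"]
    cols = ["chrom", "pos", "ref", "alt", "variant_class", "indel_length",
            "region", "coding_effect", "distance_to_cds_start"]
    return gv[cols].sort_values("pos").reset_index(drop=True)


def write_gene_schematic_svg(gene: GeneModel, variants: pd.DataFrame,
                             path: str, upstream_len: int = 1000) -> None:
    """Minimal gene diagram (UTRs, CDS, introns, promoter variants) as SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 1.8))
    span_lo = gene.start - (upstream_len if gene.strand == "+" else 0)
    span_hi = gene.end + (upstream_len if gene.strand == "-" else 0)
    ax.hlines(0.5, span_lo, span_hi, color="0.6", lw=1)
    for s, e in gene.exons:
        ax.add_patch(plt.Rectangle((s, 0.35), e - s + 1, 0.3, color="0.75"))
    for s, e in gene.cds:
        ax.add_patch(plt.Rectangle((s, 0.3), e - s + 1, 0.4, color="0.3"))
    for row in variants.itertuples():
        ax.plot([row.pos, row.pos], [0.75, 0.95], color="crimson", lw=1.5)
        ax.text(row.pos, 0.97, f"{row.variant_class.lower()} {row.indel_length}bp"
                if row.variant_class != "SNV" else "snv",
                rotation=45, fontsize=6, ha="left")
    ax.set_xlim(span_lo, span_hi)
    ax.set_ylim(0, 1.4)
    ax.set_yticks([])
    ax.set_title(f"{gene.gene_id} ({gene.strand})", fontsize=8)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
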