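"""Gene-level parental-origin calls and the donor-inherited fraction.

Variant-level origin labels are aggregated per gene: a gene with only
donor-origin evidence is DONOR, only recurrent-origin evidence is
RECURRENT, both is MIXED, neither is NON_POLYMORPHIC.  The headline
statistic is the donor-inherited gene fraction
100 * N_donor / (N_donor + N_recurrent); MIXED genes are reported but
excluded from both terms, matching the two-term formula.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

VERDICTS = ("DONOR", "RECURRENT", "MIXED", "NON_POLYMORPHIC")


def assign_gene_origin(annotated: pd.DataFrame,
                       gene_ids: list[str] | None = None,
                       min_evidence: int = 1) -> pd.DataFrame:
    """Per-gene origin verdicts from an annotated variant table.

    ``annotated`` needs columns gene_id, origin, variant_class.  NOVEL,
    AMBIGUOUS and NON_POLYMORPHIC variants carry no origin evidence.
    ``gene_ids`` optionally supplies the full gene universe so genes
    without any informative variant appear as NON_POLYMORPHIC.
    ``min_evidence`` is the minimum concordant variant count required
    for a DONOR/RECURRENT verdict (default 1).
    """
    df = annotated[annotated["gene_id"].notna()]
    rows = {}
    for gene_id, sub in df.groupby("gene_id"):
        donor = sub[sub["origin"] == "DONOR"]
        rec = sub[sub["origin"] == "RECURRENT"]
        n_d, n_r = len(donor), len(rec)
        if n_d >= min_evidence and n_r == 0:
            verdict = "DONOR"
        elif n_r >= min_evidence and n_d == 0:
            verdict = "RECURRENT"
        elif n_d >= 1 and n_r >= 1:
            verdict = "MIXED"
        else:
            verdict = "NON_POLYMORPHIC"
        rows[gene_id] = {
            "verdict": verdict,
            "n_donor_variants": n_d,
            "n_recurrent_variants": n_r,
            "n_donor_snv": int((donor["variant_class"] == "SNV").sum()),
            "n_donor_indel": int((donor["variant_class"] != "SNV").sum()),
            "n_recurrent_snv": int((rec["variant_class"] == "SNV").sum()),
            "n_recurrent_indel": int((rec["variant_class"] != "SNV").sum()),
        }
    if gene_ids is not None:
        for g in gene_ids:
            rows.setdefault(g, {
                "verdict": "NON_POLYMORPHIC",
                "n_donor_variants": 0, "n_recurrent_variants": 0,
                "n_donor_snv": 0, "n_donor_indel": 0,
                "n_recurrent_snv": 0, "n_recurrent_indel": 0,
            })
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "gene_id"
    return out


def donor_fraction(n_donor: int, n_recurrent: int) -> float:
    """Donor-inherited gene percentage, 100*N_D/(N_D+N_R), to one decimal."""
    if n_donor < 0 or n_recurrent < 0:
        raise ValueError("counts must be non-negative")
    if n_donor + n_recurrent == 0:
        raise ZeroDivisionError("no donor or recurrent genes: fraction undefined")
    return round(100.0 * n_donor / (n_donor + n_recurrent), 1)


def verdict_counts(calls: pd.DataFrame) -> dict[str, int]:
    counts = calls["verdict"].value_counts().to_dict()
    return {v: int(counts.get(v, 0)) for v in VERDICTS}


def per_chromosome_table(calls: pd.DataFrame,
                         gene_chrom: dict[str, str]) -> pd.DataFrame:
    """Per-chromosome donor-gene counts and whole-percent shares.

    Genes mapping to a chromosome absent from ``gene_chrom`` are counted
    under 'unplaced' with a warning.
    """
    rows: dict[str, dict[str, int]] = {}
    for gene_id, row in calls.iterrows():
        chrom = gene_chrom.get(gene_id)
        if chrom is None:
            logger.warning("gene %s on unknown chromosome; counted as unplaced",
                           gene_id)
            chrom = "unplaced"
        r = rows.setdefault(chrom, {"n_genes": 0, "n_donor_genes": 0})
        r["n_genes"] += 1
        r["n_donor_genes"] += row["verdict"] == "DONOR"
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "chromosome"
    table["pct_of_chromosome_genes"] = (
        100.0 * table["n_donor_genes"] / table["n_genes"]).round().astype(int)
    return table.reset_index()


def expected_backcross_fraction(n_backcrosses: int) -> float:
    """Expected donor-genome percentage after ``n_backcrosses`` backcrosses,
    by the halving-per-backcross model 100 * (1/2)**b.

    Note this model counts halvings from the donor parent itself, so
    b=0 gives 100%; the standard pedigree expectation for a BC_b line
    (which starts from an F1 at 50%) is 100 * (1/2)**(b+1).
    """
    if n_backcrosses < 0:
        raise ValueError("n_backcrosses must be >= 0")
    return 100.0 * 0.5 ** n_backcrosses


def donor_segments(sites: pd.DataFrame) -> pd.DataFrame:
    """Graphical genotype: merge runs of consecutive donor-origin variants
    into per-chromosome segments (BED-style, 0-based half-open)."""
    informative = sites[sites["origin"].isin(["DONOR", "RECURRENT"])]
    segs = []
    for chrom, sub in informative.groupby("chrom"):
        sub = sub.sort_values("pos")
        run_start = None
        last = None
        for row in sub.itertuples():
            if row.origin == "DONOR":
                if run_start is None:
                    run_start = row.pos
                last = row.pos
            elif run_start is not None:
                segs.append((chrom, run_start - 1, last, "DONOR"))
                run_start = None
        if run_start is not None:
            segs.append((chrom, run_start - 1, last, "DONOR"))
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "name"])


def write_bed(segments: pd.DataFrame, path: str) -> None:
    segments.to_csv(path, sep="\t", header=False, index=False)
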