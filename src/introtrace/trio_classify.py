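"""Parental-origin classification of trio variant sites.

Each biallelic site carries homozygous-collapsed genotypes for the
offspring, the donor parent and the recurrent parent.  A site is
donor-origin when the offspring shares the donor's allele and the donor
differs from the recurrent parent; recurrent-origin symmetrically; a
site where all three agree is non-polymorphic, and an offspring allele
seen in neither parent is novel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

REF = "REF"
ALT = "ALT"
HET = "HET"
MISSING = "MISSING"

SNV = "SNV"
INSERTION = "INSERTION"
DELETION = "DELETION"

DONOR = "DONOR"
RECURRENT = "RECURRENT"
NON_POLYMORPHIC = "NON_POLYMORPHIC"
NOVEL = "NOVEL"
AMBIGUOUS = "AMBIGUOUS"

ROLES = ("offspring", "donor", "recurrent")


@dataclass(frozen=True)
class TrioSite:
    """One biallelic variant locus with genotypes for the three roles."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    offspring: str = MISSING
    donor: str = MISSING
    recurrent: str = MISSING

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNV
        return INSERTION if len(self.alt) > len(self.ref) else DELETION

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))


def _collapse_het(gt: str, het_policy: str) -> str:
    if gt != HET:
        return gt
    if het_policy == "major-allele":
        # 0/1 dosage ties break toward the non-reference allele
        return ALT
    return MISSING


def classify_trio_site(site: TrioSite, het_policy: str = "ambiguous") -> str:
    """Label one site by parental origin.

    Any missing genotype (or heterozygous call under the default
    policy) makes the site AMBIGUOUS; otherwise the label follows the
    shared-with-donor / different-from-recurrent rule.
    """
    off = _collapse_het(site.offspring, het_policy)
    don = _collapse_het(site.donor, het_policy)
    rec = _collapse_het(site.recurrent, het_policy)
    if MISSING in (off, don, rec):
        return AMBIGUOUS
    if don == rec:
        return NON_POLYMORPHIC if off == don else NOVEL
    return DONOR if off == don else RECURRENT


def _sample_genotype(rec, sample: str, alt_index: int) -> str:
    gt = rec.samples[sample].get("GT")
    if gt is None or any(a is None for a in gt):
        return MISSING
    alleles = set(gt)
    if alleles == {0}:
        return REF
    if alleles == {alt_index}:
        return ALT
    if alleles <= {0, alt_index}:
        return HET
    return MISSING  # carries another split allele at this site


def read_trio_vcf(path: str, role_map: dict[str, str]) -> list[TrioSite]:
    """Read a trio VCF into an ordered list of biallelic :class:`TrioSite`.

    ``role_map`` maps VCF sample names to the roles ``offspring``,
    ``donor`` and ``recurrent``; the sample-column order in the file is
    irrelevant.  Multi-allelic records are split into biallelic sites
    against the same REF; symbolic alternate alleles are skipped.
    """
    roles = {role: sample for sample, role in role_map.items()}
    if set(roles) != set(ROLES):
        raise ValueError(f"role_map must cover roles {ROLES}, got {sorted(roles)}")
    if len(set(role_map)) != len(role_map):
        raise ValueError("role_map must be injective")
    sites: list[TrioSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = set(vcf.header.samples)
        missing = [s for s in roles.values() if s not in header_samples]
        if missing:
            raise ValueError(f"samples absent from VCF header: {missing}")
        last: tuple[str, int] | None = None
        for rec in vcf:
            if last is not None and rec.chrom == last[0] and rec.pos < last[1]:
                raise ValueError(
                    f"VCF not positionally sorted at {rec.chrom}:{rec.pos}")
            last = (rec.chrom, rec.pos)
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                if alt is None or not set(alt.upper()) <= set("ACGTN"):
                    continue
                sites.append(TrioSite(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    offspring=_sample_genotype(rec, roles["offspring"], alt_index),
                    donor=_sample_genotype(rec, roles["donor"], alt_index),
                    recurrent=_sample_genotype(rec, roles["recurrent"], alt_index),
                ))
    sites.sort(key=lambda s: (s.chrom, s.pos, s.ref, s.alt))
    return sites


def filter_indel_length(sites: list[TrioSite], min_len: int = 1,
                        max_len: int = 99) -> list[TrioSite]:
    """Keep SNVs plus indels whose length is within [min_len, max_len] bp."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [s for s in sites
            if s.variant_class == SNV or min_len <= s.indel_length <= max_len]
    logger.info("filter_indel_length: removed %d of %d sites outside "
                "[%d, %d] bp", len(sites) - len(kept), len(sites), min_len, max_len)
    return kept


def classify_sites(sites: list[TrioSite], het_policy: str = "ambiguous") -> list[str]:
    return [classify_trio_site(s, het_policy=het_policy) for s in sites]


def sites_to_frame(sites: list[TrioSite], origins: list[str] | None = None) -> pd.DataFrame:
    """Per-site table (chrom, pos, ref, alt, class, indel_length[, origin])."""
    df = pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "ref": [s.ref for s in sites],
        "alt": [s.alt for s in sites],
        "variant_class": [s.variant_class for s in sites],
        "indel_length": [s.indel_length for s in sites],
    })
    if origins is not None:
        df["origin"] = origins
    return df
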