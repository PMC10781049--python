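"""Meiosis and pedigree simulation for backcross breeding.

Chromosomes are mosaics of half-open ``[start, end)`` bp segments
labelled by parental origin (donor vs recurrent parent).  Recombination
follows Haldane's model: the crossover count per chromosome is Poisson
with mean equal to the genetic length in Morgans, crossover positions
are uniform in physical coordinates, and there is no interference.

A diploid individual is a mapping ``chromosome name -> (homolog0,
homolog1)`` where each homolog is a sorted segment list tiling
``[0, length_bp)`` with adjacent segments of different labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DONOR = "DONOR"
RECURRENT = "RECURRENT"

# One haplotype: sorted, non-overlapping, gap-free [(start, end, label), ...]
Haplotype = list[tuple[int, int, str]]
Individual = dict[str, tuple[Haplotype, Haplotype]]


@dataclass(frozen=True)
class ChromosomeSpec:
    """Physical and genetic length of one chromosome."""

    name: str
    length_bp: int
    length_cM: float

    def __post_init__(self) -> None:
        if self.length_bp < 10_000:
            raise ValueError(
                f"chromosome {self.name}: length_bp must be >= 10000, got {self.length_bp}"
            )
        if self.length_cM <= 0:
            raise ValueError(f"chromosome {self.name}: length_cM must be > 0")


@dataclass(frozen=True)
class PedigreeConfig:
    """Breeding scheme: F1, then backcrosses to the recurrent parent, then selfing.

    Defaults mirror a BC5F4 line: five backcrosses followed by four
    generations of selfing, one unselected offspring carried forward per
    generation.
    """

    n_backcrosses: int = 5
    n_selfings: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_backcrosses < 0 or self.n_selfings < 0:
            raise ValueError("n_backcrosses and n_selfings must be >= 0")


def default_genome(n_chromosomes: int = 7, length_bp: int = 1_000_000,
                   length_cM: float = 100.0) -> list[ChromosomeSpec]:
    """Desk-scale genome: 7 chromosomes of 1 Mb / 100 cM each."""
    return [ChromosomeSpec(f"chr{i + 1}", length_bp, length_cM)
            for i in range(n_chromosomes)]


def _merge(segments: Haplotype) -> Haplotype:
    out: Haplotype = []
    for s, e, lab in segments:
        if e <= s:
            continue
        if out and out[-1][2] == lab and out[-1][1] == s:
            out[-1] = (out[-1][0], e, lab)
        else:
            out.append((s, e, lab))
    return out


def _slice(hap: Haplotype, a: int, b: int) -> Haplotype:
    """Restrict a haplotype to [a, b)."""
    return [(max(s, a), min(e, b), lab) for s, e, lab in hap if e > a and s < b]


def pure_haplotype(spec: ChromosomeSpec, label: str) -> Haplotype:
    return [(0, spec.length_bp, label)]


def founder(specs: list[ChromosomeSpec], label: str) -> Individual:
    """Fully inbred founder: both homologs carry a single label everywhere."""
    return {sp.name: (pure_haplotype(sp, label), pure_haplotype(sp, label))
            for sp in specs}


def simulate_gamete(pair: tuple[Haplotype, Haplotype], spec: ChromosomeSpec,
                    rng: np.random.Generator) -> Haplotype:
    """Draw one recombinant gamete haplotype from a homolog pair.

    Crossover count ~ Poisson(length_cM / 100); positions uniform in bp;
    the starting homolog is chosen by fair coin and the source homolog
    alternates at each crossover.
    """
    if spec.length_bp <= 0:
        raise ValueError("chromosome length must be positive")
    n_xo = int(rng.poisson(spec.length_cM / 100.0))
    # coincident crossovers cancel; with uniform positions duplicates are
    # measure-zero, deduping keeps the alternation well defined
    cuts = sorted({int(p) for p in rng.integers(1, spec.length_bp, size=n_xo)})
    current = int(rng.integers(2))
    out: Haplotype = []
    prev = 0
    for cut in [*cuts, spec.length_bp]:
        out.extend(_slice(pair[current], prev, cut))
        prev = cut
        current = 1 - current
    return _merge(out)


def cross(mother: Individual, father: Individual, specs: list[ChromosomeSpec],
          rng: np.random.Generator) -> Individual:
    return {
        sp.name: (
            simulate_gamete(mother[sp.name], sp, rng),
            simulate_gamete(father[sp.name], sp, rng),
        )
        for sp in specs
    }


@dataclass
class PedigreeResult:
    """Final offspring of the breeding scheme plus its parents."""

    offspring: Individual
    donor: Individual
    recurrent: Individual
    config: PedigreeConfig
    specs: list[ChromosomeSpec] = field(default_factory=list)


def simulate_pedigree(config: PedigreeConfig, specs: list[ChromosomeSpec],
                      rng: np.random.Generator | None = None) -> PedigreeResult:
    """Simulate donor x recurrent F1, ``n_backcrosses`` backcrosses to the
    recurrent parent, then ``n_selfings`` selfing generations.

    One random offspring is carried forward per generation; there is no
    selection.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    donor = founder(specs, DONOR)
    recurrent = founder(specs, RECURRENT)
    individual = cross(donor, recurrent, specs, rng)  # F1
    for _ in range(config.n_backcrosses):
        individual = cross(individual, recurrent, specs, rng)
    for _ in range(config.n_selfings):
        individual = cross(individual, individual, specs, rng)
    return PedigreeResult(offspring=individual, donor=donor,
                          recurrent=recurrent, config=config, specs=list(specs))


def donor_bp_fraction(individual: Individual) -> float:
    """Diploid bp-weighted donor genome fraction (both homologs)."""
    donor_bp = 0
    total_bp = 0
    for haps in individual.values():
        for hap in haps:
            for s, e, lab in hap:
                total_bp += e - s
                if lab == DONOR:
                    donor_bp += e - s
    return donor_bp / total_bp


def collapse_homozygous(individual: Individual,
                        rng: np.random.Generator) -> dict[str, Haplotype]:
    """Collapse a diploid mosaic to a single homozygous genotype mosaic.

    Where the two homologs agree the shared label is kept.  Residual
    heterozygous intervals (rare after repeated selfing) are resolved by
    a fair coin per maximal disagreeing interval, modelling continued
    inbreeding to fixation.
    """
    out: dict[str, Haplotype] = {}
    for chrom, (h0, h1) in individual.items():
        bounds = sorted({p for s, e, _ in h0 + h1 for p in (s, e)})
        atoms: list[tuple[int, int, str | None]] = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            l0 = label_at(h0, a)
            l1 = label_at(h1, a)
            atoms.append((a, b, l0 if l0 == l1 else None))
        resolved: Haplotype = []
        i = 0
        while i < len(atoms):
            a, b, lab = atoms[i]
            if lab is not None:
                resolved.append((a, b, lab))
                i += 1
                continue
            j = i
            while j < len(atoms) and atoms[j][2] is None:
                j += 1
            lab = DONOR if rng.integers(2) else RECURRENT
            resolved.append((a, atoms[j - 1][1], lab))
            i = j
        out[chrom] = _merge(resolved)
    return out


def label_at(hap: Haplotype, pos: int) -> str:
    """Origin label of the segment containing 0-based position ``pos``."""
    for s, e, lab in hap:
        if s <= pos < e:
            return lab
    raise ValueError(f"position {pos} outside haplotype extent")


def interval_label(hap: Haplotype, start: int, end: int) -> str:
    """Label of [start, end): DONOR / RECURRENT if pure, else 'MIXED'."""
    labels = {lab for _, _, lab in _slice(hap, start, end)}
    if not labels:
        raise ValueError(f"interval [{start}, {end}) outside haplotype extent")
    if len(labels) == 1:
        return labels.pop()
    return "MIXED"


def haplotype_donor_fraction(hap: Haplotype) -> float:
    total = sum(e - s for s, e, _ in hap)
    donor = sum(e - s for s, e, lab in hap if lab == DONOR)
    return donor / total
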