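"""Negative-binomial count simulation for the inoculation experiment.

Emulates a 3 genotypes x {control, inoculated} x 3 replicates design:
a configurable set of genes responds to inoculation in every genotype,
while one planted cis-marker gene is induced only in the genotypes
carrying the donor promoter allele (the offspring and the donor
parent), mimicking a promoter-driven allele-specific response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOTYPES = ("offspring", "donor", "recurrent")
TREATMENTS = ("control", "inoculated")
DONOR_ALLELE_GENOTYPES = frozenset({"offspring", "donor"})


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Parameters of the count generator.

    Baseline means are log-normal; counts are NB with a common
    dispersion; responsive genes are scaled by 2**lfc under inoculation
    in all genotypes; the cis gene by ``cis_lfc`` only in donor-allele
    genotypes.  ``cis_floor_mean`` keeps the planted marker expressed
    well above the low-expression filter.
    """

    n_replicates: int = 3
    dispersion: float = 0.1
    baseline_log_mean: float = float(np.log(150.0))
    baseline_log_sd: float = 1.0
    n_responsive: int = 6
    responsive_floor_mean: float = 30.0
    lfc_min: float = 1.5
    lfc_max: float = 4.0
    frac_up: float = 0.7
    cis_lfc: float = 5.0
    cis_floor_mean: float = 50.0
    libsize_log_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(cfg: ExpressionSimConfig, gene_ids: list[str],
                    cis_gene_id: str | None,
                    rng: np.random.Generator,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Return (counts genes x samples, design table, per-gene truth)."""
    if cis_gene_id is not None and cis_gene_id not in gene_ids:
        raise ValueError(f"cis gene {cis_gene_id} not among gene_ids")
    n_genes = len(gene_ids)
    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                                 size=n_genes))
    lfc = np.zeros(n_genes)
    candidates = [i for i, g in enumerate(gene_ids) if g != cis_gene_id]
    responsive = rng.choice(candidates, size=min(cfg.n_responsive, len(candidates)),
                            replace=False)
    magnitudes = rng.uniform(cfg.lfc_min, cfg.lfc_max, size=len(responsive))
    signs = np.where(rng.random(len(responsive)) < cfg.frac_up, 1.0, -1.0)
    lfc[responsive] = signs * magnitudes
    # responsive genes are, by selection, detectably expressed
    baseline[responsive] = np.maximum(baseline[responsive],
                                      cfg.responsive_floor_mean)
    cis_idx = gene_ids.index(cis_gene_id) if cis_gene_id is not None else None
    if cis_idx is not None:
        baseline[cis_idx] = max(baseline[cis_idx], cfg.cis_floor_mean)

    design_rows = []
    columns = {}
    for genotype in GENOTYPES:
        for treatment in TREATMENTS:
            for rep in range(1, cfg.n_replicates + 1):
                sample = f"{genotype}_{treatment}_{rep}"
                design_rows.append(dict(sample=sample, genotype=genotype,
                                        treatment=treatment, replicate=rep))
                sf = float(np.exp(rng.normal(0.0, cfg.libsize_log_sd)))
                mean = baseline * sf
                if treatment == "inoculated":
                    mean = mean * np.exp2(lfc)
                    if cis_idx is not None and genotype in DONOR_ALLELE_GENOTYPES:
                        mean = mean.copy()
                        mean[cis_idx] = baseline[cis_idx] * sf * 2.0 ** cfg.cis_lfc
                columns[sample] = _nb_draw(rng, mean, cfg.dispersion)

    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    design = pd.DataFrame(design_rows)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "baseline_mean": baseline,
        "lfc": lfc,
        "responsive": lfc != 0,
        "is_cis": [g == cis_gene_id for g in gene_ids],
    })
    return counts, design, truth
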