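"""Count normalization, NB differential expression and response patterns.

Differential expression uses an in-repo negative-binomial Wald test:
size factors by median-of-ratios, per-gene dispersion by method of
moments, a two-group NB GLM (log link, size-factor offset) fit per
gene, and Benjamini-Hochberg correction within each genotype contrast.
This is a deliberately simple engine whose contract is calibration on
synthetic truth (type-I error and power), not numeric parity with any
particular reference tool.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

UP = "UP"
DOWN = "DOWN"
NS = "NS"

_DISPERSION_FLOOR = 1e-8


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: TPM_g = 1e6 * (c_g/L_g) / sum_h(c_h/L_h).

    ``lengths`` are gene lengths in bp, indexed like ``counts``.  Every
    sample column of the result sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {zero.index.tolist()}")
    return rate.div(colsum, axis=1) * 1e6


def filter_low_expression(tpm: pd.DataFrame, threshold: float = 10.0) -> pd.Index:
    """Genes reaching ``threshold`` TPM in at least one sample.

    A gene below the threshold in *every* sample is removed; expression
    in a single sample suffices to keep it, so condition-specific genes
    survive the filter.
    """
    keep = tpm.index[(tpm >= threshold).any(axis=1)]
    logger.info("filter_low_expression: kept %d of %d genes (TPM >= %g in "
                ">=1 sample)", len(keep), len(tpm), threshold)
    return keep


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference over genes
    with all-positive counts)."""
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has positive counts in every sample")
    log_geo = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0))


def _mom_dispersion(norm: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion from normalized counts.

    Within each group, Var = mu + alpha * mu^2 gives
    alpha = (Var - mu) / mu^2; group estimates are averaged.
    """
    estimates = []
    for g in np.unique(groups):
        x = norm[groups == g]
        mu = x.mean()
        if mu > 0:
            estimates.append((x.var(ddof=1) - mu) / mu ** 2)
    if not estimates:
        return _DISPERSION_FLOOR
    return max(float(np.mean(estimates)), _DISPERSION_FLOOR)


def _moderate_dispersions(alphas: np.ndarray) -> np.ndarray:
    """Conservative sharing across genes: each gene uses the larger of its
    own method-of-moments estimate and the across-gene median.

    With a handful of replicates the per-gene estimate is noisy and its
    underestimates inflate Wald statistics; taking the maximum against
    the common value restores type-I calibration while leaving genes
    with genuinely high dispersion conservative.
    """
    informative = alphas[alphas > _DISPERSION_FLOOR]
    common = float(np.median(informative)) if len(informative) else _DISPERSION_FLOOR
    return np.maximum(alphas, common)


def _fit_gene(y: np.ndarray, treat: np.ndarray, offset: np.ndarray,
              alpha_hat: float) -> tuple[float, float]:
    """NB GLM Wald fit for one gene; returns (ln fold change, SE)."""
    exog = sm.add_constant(treat.astype(float))
    model = sm.GLM(y, exog, family=sm.families.NegativeBinomial(alpha=alpha_hat),
                   offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    return float(res.params[1]), float(res.bse[1])


def nb_de_test(counts: pd.DataFrame, design: pd.DataFrame, genotype: str,
               alpha: float = 0.05) -> pd.DataFrame:
    """Inoculated-vs-control NB Wald test within one genotype.

    Returns a per-gene frame with log2_fold_change, p_value, adjusted_p
    (Benjamini-Hochberg across the genes tested in this genotype) and
    status UP/DOWN/NS at FDR ``alpha``.  Dispersions are per-gene
    method-of-moments estimates moderated against the across-gene
    median (see :func:`_moderate_dispersions`); Wald p-values are
    two-sided normal.
    """
    sub = design[design["genotype"] == genotype]
    samples = sub["sample"].tolist()
    treat = (sub["treatment"].to_numpy() == "inoculated")
    for grp in (True, False):
        if (treat == grp).sum() < 2:
            raise ValueError(
                f"genotype {genotype}: fewer than 2 replicates per group")
    mat = counts[samples]
    sf = size_factors(mat)
    offset = np.log(sf.to_numpy())
    norm = mat.to_numpy() / sf.to_numpy()

    raw_alphas = np.array([_mom_dispersion(norm[i], treat)
                           for i in range(len(mat))])
    alphas = _moderate_dispersions(raw_alphas)

    records = []
    for i, gene in enumerate(mat.index):
        y = mat.iloc[i].to_numpy()
        mean_c = norm[i][~treat].mean()
        mean_i = norm[i][treat].mean()
        if y.sum() == 0:
            records.append((gene, 0.0, np.nan))
            continue
        try:
            beta, se = _fit_gene(y, treat, offset, alphas[i])
            if not np.isfinite(beta) or not np.isfinite(se) or se <= 0 or se > 50:
                raise ValueError("unstable fit")
            lfc = beta / np.log(2.0)
            p = 2.0 * stats.norm.sf(abs(beta / se))
        except Exception:
            lfc = float(np.log2((mean_i + 0.5) / (mean_c + 0.5)))
            p = np.nan
        records.append((gene, lfc, p))

    out = pd.DataFrame(records, columns=["gene_id", "log2_fold_change",
                                         "p_value"]).set_index("gene_id")
    out["genotype"] = genotype
    out["adjusted_p"] = np.nan
    tested = out["p_value"].notna()
    if tested.any():
        out.loc[tested, "adjusted_p"] = multipletests(
            out.loc[tested, "p_value"], method="fdr_bh")[1]
    sig = out["adjusted_p"] < alpha
    out["status"] = NS
    out.loc[sig & (out["log2_fold_change"] > 0), "status"] = UP
    out.loc[sig & (out["log2_fold_change"] < 0), "status"] = DOWN
    return out


def nb_genotype_contrast(counts: pd.DataFrame, design: pd.DataFrame,
                         treatment: str, genotype_a: str, genotype_b: str,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Genotype-vs-genotype NB Wald test within one treatment.

    Used for condition-restricted allele-specific expression (e.g.
    genes differing between lines already under control conditions);
    log2 fold changes are ``genotype_b`` over ``genotype_a``.
    """
    sub = design[(design["treatment"] == treatment)
                 & design["genotype"].isin([genotype_a, genotype_b])]
    relabelled = pd.DataFrame({
        "sample": sub["sample"],
        "genotype": "contrast",
        "treatment": np.where(sub["genotype"] == genotype_b,
                              "inoculated", "control"),
        "replicate": sub["replicate"],
    })
    out = nb_de_test(counts, relabelled, "contrast", alpha=alpha)
    return out.assign(genotype=f"{genotype_b}_vs_{genotype_a}:{treatment}")


def classify_patterns(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-genotype response patterns from three per-genotype DE tables.

    ``results`` maps the roles offspring/donor/recurrent to
    :func:`nb_de_test` outputs over the same gene universe.  Adds the
    Venn region of the UP sets and the donor-like flag (UP in offspring
    and donor, NS in the recurrent parent).
    """
    roles = ("offspring", "donor", "recurrent")
    if set(results) != set(roles):
        raise ValueError(f"results must be keyed by roles {roles}")
    common = None
    for role in roles:
        idx = results[role].index
        common = idx if common is None else common.intersection(idx)
    for role in roles:
        dropped = results[role].index.difference(common)
        if len(dropped):
            logger.warning("classify_patterns: %d genes missing from some "
                           "genotype, excluded", len(dropped))
    out = pd.DataFrame(index=common.sort_values())
    out.index.name = "gene_id"
    for role in roles:
        sub = results[role].loc[out.index]
        out[f"status_{role}"] = sub["status"]
        out[f"log2_fold_change_{role}"] = sub["log2_fold_change"]
        out[f"adjusted_p_{role}"] = sub["adjusted_p"]
    up = {role: out[f"status_{role}"] == UP for role in roles}
    out["venn_region"] = [
        "+".join(r for r in roles if up[r].iloc[i]) for i in range(len(out))]
    out["donor_like_only"] = (up["offspring"] & up["donor"]
                              & (out["status_recurrent"] == NS))
    return out


def venn_counts(patterns: pd.DataFrame) -> dict[str, int]:
    """Sizes of the 7 non-empty intersections of the per-genotype UP sets."""
    counts = patterns.loc[patterns["venn_region"] != "", "venn_region"] \
        .value_counts().to_dict()
    return {k: int(v) for k, v in sorted(counts.items())}


def zscore_matrix(tpm: pd.DataFrame, design: pd.DataFrame,
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Replicate-averaged, per-gene z-scored log2 expression matrix.

    log2(TPM+1) values are averaged over replicates per (genotype,
    treatment) group, then each gene row is centered and scaled to mean
    0 / sd 1.  Zero-variance rows are set to 0 and returned as flagged.
    """
    log = np.log2(tpm + 1.0)
    groups = design.groupby(["genotype", "treatment"])["sample"].apply(list)
    avg = pd.DataFrame({f"{g}:{t}": log[samps].mean(axis=1)
                        for (g, t), samps in groups.items()})
    mean = avg.mean(axis=1)
    sd = avg.std(axis=1, ddof=1)
    flagged = avg.index[sd == 0].tolist()
    z = avg.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)
    z.loc[flagged] = 0.0
    if flagged:
        logger.warning("zscore_matrix: %d constant rows set to zero", len(flagged))
    return z, flagged


def ddct_relative_expression(ct_target_treat: float, ct_ref_treat: float,
                             ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression by the 2**(-ddCt) method."""
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** -ddct)
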