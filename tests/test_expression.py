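"""TPM normalization, low-expression filter, NB Wald DE and patterns."""

import numpy as np
import pandas as pd
import pytest

from introtrace.expression import (
    classify_patterns, ddct_relative_expression, filter_low_expression,
    nb_de_test, size_factors, tpm_normalize, venn_counts, zscore_matrix,
)


@pytest.fixture
def design_one_genotype():
    samples = [f"g_{t}_{r}" for t in ("control", "inoculated") for r in (1, 2, 3)]
    return pd.DataFrame({
        "sample": samples, "genotype": "g",
        "treatment": [s.split("_")[1] for s in samples],
        "replicate": [1, 2, 3, 1, 2, 3]})


def test_tpm_equal_counts_equal_lengths():
    counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
    lengths = pd.Series({"a": 500, "b": 500})
    tpm = tpm_normalize(counts, lengths)
    assert tpm["s1"].tolist() == [500_000.0, 500_000.0]


def test_tpm_scale_invariance_and_column_sum(rng):
    counts = pd.DataFrame(rng.integers(0, 500, size=(50, 12)),
                          index=[f"g{i}" for i in range(50)],
                          columns=[f"s{j}" for j in range(12)])
    counts.iloc[0] += 1  # avoid an all-zero column
    lengths = pd.Series(rng.integers(200, 5000, size=50),
                        index=counts.index, dtype=float)
    tpm = tpm_normalize(counts, lengths)
    assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)
    doubled = tpm_normalize(counts * 2, lengths)
    assert np.allclose(tpm.to_numpy(), doubled.to_numpy())


def test_tpm_rejects_all_zero_sample():
    counts = pd.DataFrame({"ok": [1, 2], "bad": [0, 0]}, index=["a", "b"])
    with pytest.raises(ValueError, match="bad"):
        tpm_normalize(counts, pd.Series({"a": 100, "b": 100}))


def test_low_expression_filter_max_rule():
    tpm = pd.DataFrame({
        "s1": [9.9, 10.0, 0.0],
        "s2": [9.9, 0.0, 500.0],
    }, index=["below_everywhere", "boundary_in_one", "high_in_one"])
    kept = filter_low_expression(tpm, threshold=10)
    assert list(kept) == ["boundary_in_one", "high_in_one"]


def test_low_expression_filter_matches_recount(rng):
    tpm = pd.DataFrame(rng.uniform(0, 30, size=(200, 6)),
                       index=[f"g{i}" for i in range(200)])
    kept = filter_low_expression(tpm, threshold=10)
    assert set(kept) == set(tpm.index[tpm.max(axis=1) >= 10])


def test_identical_groups_give_zero_lfc_ns(design_one_genotype):
    counts = pd.DataFrame(
        {s: [100, 50, 200] for s in design_one_genotype["sample"]},
        index=["a", "b", "c"])
    res = nb_de_test(counts, design_one_genotype, "g")
    assert np.allclose(res["log2_fold_change"], 0.0, atol=1e-6)
    assert (res["status"] == "NS").all()


def test_all_zero_gene_flagged_ns_with_undefined_p(design_one_genotype):
    counts = pd.DataFrame(
        {s: [0, 100] for s in design_one_genotype["sample"]}, index=["z", "ok"])
    res = nb_de_test(counts, design_one_genotype, "g")
    assert res.loc["z", "status"] == "NS"
    assert np.isnan(res.loc["z", "p_value"])


def test_insufficient_replicates_rejected(design_one_genotype):
    design = design_one_genotype.iloc[[0, 3, 4]]  # 1 control vs 2 inoculated
    counts = pd.DataFrame({s: [10] for s in design["sample"]}, index=["a"])
    with pytest.raises(ValueError, match="replicates"):
        nb_de_test(counts, design, "g")


def test_bh_adjustment_matches_brute_force_step_up(rng):
    """statsmodels' BH (used internally) vs the textbook step-up
    procedure implemented from scratch, on 100 random p-vectors."""
    from statsmodels.stats.multitest import multipletests

    def brute_force_bh(p):
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, p[i] * m / rank_from_top)
            adj[i] = running
        return adj

    for _ in range(100):
        p = rng.uniform(0, 1, size=rng.integers(1, 40))
        assert np.allclose(multipletests(p, method="fdr_bh")[1],
                           brute_force_bh(p))


def test_bh_all_ones(design_one_genotype):
    from statsmodels.stats.multitest import multipletests
    assert (multipletests(np.ones(10), method="fdr_bh")[1] == 1.0).all()


def test_status_consistent_with_padj_and_sign(design_one_genotype, rng):
    counts = pd.DataFrame(
        {s: rng.integers(0, 400, size=80) for s in design_one_genotype["sample"]},
        index=[f"g{i}" for i in range(80)])
    res = nb_de_test(counts, design_one_genotype, "g", alpha=0.5)
    sig = res["adjusted_p"] < 0.5
    assert (res.loc[sig & (res["log2_fold_change"] > 0), "status"] == "UP").all()
    assert (res.loc[sig & (res["log2_fold_change"] < 0), "status"] == "DOWN").all()
    assert (res.loc[~sig.fillna(False), "status"] == "NS").all()


def _patterns_fixture():
    def de(statuses):
        return pd.DataFrame({
            "status": statuses,
            "log2_fold_change": [1.0] * len(statuses),
            "adjusted_p": [0.01] * len(statuses),
        }, index=[f"g{i}" for i in range(len(statuses))])
    return {
        "offspring": de(["UP", "UP", "NS", "UP", "DOWN"]),
        "donor": de(["UP", "UP", "UP", "NS", "NS"]),
        "recurrent": de(["UP", "NS", "NS", "NS", "NS"]),
    }


def test_pattern_venn_and_donor_like_flag():
    patterns = classify_patterns(_patterns_fixture())
    assert patterns.loc["g0", "venn_region"] == "offspring+donor+recurrent"
    assert not patterns.loc["g0", "donor_like_only"]
    assert patterns.loc["g1", "venn_region"] == "offspring+donor"
    assert patterns.loc["g1", "donor_like_only"]
    assert patterns.loc["g4", "venn_region"] == ""


def test_venn_regions_partition_union_of_up_sets():
    patterns = classify_patterns(_patterns_fixture())
    n_up_union = (patterns[[f"status_{r}" for r in
                            ("offspring", "donor", "recurrent")]] == "UP") \
        .any(axis=1).sum()
    assert sum(venn_counts(patterns).values()) == n_up_union


def test_zscore_rows_standardized_and_constant_rows_flagged():
    samples = [f"{g}_{t}_{r}" for g in ("a", "b") for t in ("control", "inoculated")
               for r in (1, 2)]
    design = pd.DataFrame({
        "sample": samples,
        "genotype": [s.split("_")[0] for s in samples],
        "treatment": [s.split("_")[1] for s in samples],
        "replicate": [int(s.split("_")[2]) for s in samples]})
    rng = np.random.default_rng(3)
    tpm = pd.DataFrame(rng.uniform(1, 100, size=(5, len(samples))),
                       index=[f"g{i}" for i in range(5)], columns=samples)
    tpm.loc["g0"] = 42.0  # constant row
    z, flagged = zscore_matrix(tpm, design)
    assert flagged == ["g0"]
    assert (z.loc["g0"] == 0).all()
    rest = z.drop(index="g0")
    assert np.allclose(rest.mean(axis=1), 0, atol=1e-9)
    assert np.allclose(rest.std(axis=1, ddof=1), 1, atol=1e-9)


def test_zscore_two_gene_hand_computation():
    samples = ["a_control_1", "a_inoculated_1"]
    design = pd.DataFrame({"sample": samples, "genotype": "a",
                           "treatment": ["control", "inoculated"],
                           "replicate": [1, 1]})
    tpm = pd.DataFrame({"a_control_1": [1.0, 3.0], "a_inoculated_1": [3.0, 1.0]},
                       index=["g1", "g2"])
    z, _ = zscore_matrix(tpm, design)
    # log2(1+1)=1, log2(3+1)=2 -> z = (-1/sqrt2, +1/sqrt2) * sqrt2 ... sd=1/sqrt(2)
    expected = (np.array([1.0, 2.0]) - 1.5) / np.std([1.0, 2.0], ddof=1)
    assert np.allclose(z.loc["g1"], expected)
    assert np.allclose(z.loc["g2"], expected[::-1])


@pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
def test_ddct_relative_expression(ddct, expected):
    # arrange Ct values so that ddCt comes out as requested
    assert ddct_relative_expression(20 + ddct, 20, 20, 20) == expected


def test_genotype_contrast_detects_between_line_difference(rng):
    from introtrace.expression import nb_genotype_contrast
    samples = [f"{g}_control_{r}" for g in ("lineA", "lineB") for r in (1, 2, 3)]
    design = pd.DataFrame({
        "sample": samples,
        "genotype": [s.split("_")[0] for s in samples],
        "treatment": "control",
        "replicate": [1, 2, 3, 1, 2, 3]})
    n = 20.0  # 1/dispersion
    mu = np.full(200, 200.0)
    counts = pd.DataFrame(
        {s: rng.negative_binomial(
            n, n / (n + mu * (8.0 if s.startswith("lineB") and False else 1.0)))
         for s in samples},
        index=[f"g{i}" for i in range(200)])
    # plant one gene 8x higher in lineB
    for s in samples:
        if s.startswith("lineB"):
            counts.loc["g0", s] = rng.negative_binomial(n, n / (n + 1600.0))
    res = nb_genotype_contrast(counts, design, "control", "lineA", "lineB")
    assert res.loc["g0", "status"] == "UP"
    assert res.loc["g0", "log2_fold_change"] == pytest.approx(3.0, abs=0.8)
    assert (res.drop(index="g0")["status"] == "NS").mean() > 0.95


def test_size_factors_recover_library_scaling(rng):
    base = rng.integers(50, 500, size=(300, 1))
    scales = np.array([0.5, 1.0, 2.0])
    counts = pd.DataFrame(
        (base * scales).astype(int), columns=["lo", "mid", "hi"])
    sf = size_factors(counts)
    ratios = sf / sf["mid"]
    assert np.allclose(ratios[["lo", "mid", "hi"]], scales, rtol=0.02)
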