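import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster

from mirmethyl.annotation import fixture_as_results, load_table_fixture
from mirmethyl.diffmeth import (
    DifferentialMethylationSelector,
    MethylationDataset,
    beta_to_m,
    bh_adjust,
    differential_methylation,
    m_to_beta,
    pca_covariate_check,
    rank_top,
    sample_correlation_and_clustering,
    volcano_filter,
    volcano_thresholds,
)
from mirmethyl.diffmeth import test_probe as probe_group_test  # alias: avoid pytest collection
from mirmethyl.simulate import SimulationConfig, generate_methylation_dataset


def bh_stepup_bruteforce(p):
    """Literal Benjamini-Hochberg step-up, enforcing monotonicity from the largest p down."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def test_m_transform_fixed_points_and_inverse():
    assert beta_to_m(0.5) == pytest.approx(0.0)
    assert beta_to_m(0.8) == pytest.approx(2.0)
    for x in (0.1, 0.37, 0.92):
        assert m_to_beta(beta_to_m(x)) == pytest.approx(x, abs=1e-12)
    assert beta_to_m(np.array([0.2, 0.7])) == pytest.approx([-2.0, beta_to_m(0.7)])
    with pytest.raises(ValueError):
        beta_to_m(1.2)
    with pytest.raises(ValueError):
        beta_to_m(-0.1)


def test_probe_degenerate_and_shift_cases():
    assert probe_group_test([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)
    control = np.array([0.1, 0.5, -0.2, 0.4])
    coeff, p = probe_group_test(control + 2.0, control)
    assert coeff == pytest.approx(2.0)
    assert p < 0.01
    with pytest.raises(ValueError):
        probe_group_test([1.0], [0.0, 0.0])


def test_probe_ols_path_matches_welch_coefficient():
    rng = np.random.default_rng(5)
    case, control = rng.normal(1, 1, 8), rng.normal(0, 1, 7)
    coeff_w, p_w = probe_group_test(case, control)
    # OLS on group alone reproduces the Welch coefficient exactly
    coeff_o, _ = probe_group_test(case, control, covariates=np.empty((15, 0)))
    assert coeff_o == pytest.approx(coeff_w, abs=1e-12)
    # equal group variances: OLS p agrees with Welch within 10%
    case2, control2 = rng.normal(1.0, 1.0, 9), rng.normal(0.0, 1.0, 9)
    _, p_w2 = probe_group_test(case2, control2)
    _, p_o2 = probe_group_test(case2, control2, covariates=np.empty((18, 0)))
    assert p_o2 == pytest.approx(p_w2, rel=0.1)


def test_bh_adjust_worked_examples():
    assert bh_adjust([0.05]) == pytest.approx([0.05])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=100))
def test_bh_adjust_matches_stepup_bruteforce(p_values):
    got = bh_adjust(p_values)
    expected = bh_stepup_bruteforce(p_values)
    assert got == pytest.approx(expected, abs=1e-12)
    assert (got >= np.asarray(p_values) - 1e-12).all()


def _results_frame(coeffs, p_values):
    ids = [f"cg{i:04d}" for i in range(len(coeffs))]
    return pd.DataFrame(
        {
            "probe_id": ids,
            "mirna_gene": "none",
            "coeff": coeffs,
            "log2_fc": coeffs,
            "p_value": p_values,
            "q_value": bh_adjust(p_values),
        }
    ).set_index("probe_id", drop=False)


def test_volcano_strict_boundaries():
    res = _results_frame([0.5, 0.379, 0.378, -0.5], [0.05, 0.01, 0.01, 0.01])
    out, counts = volcano_filter(res)
    # p exactly at the cutoff is excluded; fold change 1.2999 < 1.3 is excluded
    assert list(out["direction"]) == ["ns", "hyper", "ns", "hypo"]
    assert counts == (2, 1, 1)


def test_volcano_counts_partition_planted():
    coeffs = [3.0] * 50 + [-3.0] * 10 + [0.01] * 40
    ps = [1e-8] * 60 + [0.9] * 40
    _, counts = volcano_filter(_results_frame(coeffs, ps))
    assert counts == (60, 50, 10)
    assert counts.hyper + counts.hypo == counts.total


def test_volcano_threshold_lines():
    lines = volcano_thresholds(0.05, 1.3)
    assert lines["neg_log10_p"] == pytest.approx(1.30103, abs=5e-6)
    assert lines["log2_fc"] == pytest.approx(np.log2(1.3))


def test_rank_top_published_ordering():
    # the published ranking carries directions already; no p-based filtering needed
    res = fixture_as_results(load_table_fixture("mirna_top20"))
    top = rank_top(res, k=20)
    assert top.iloc[0]["mirna_gene"] == "miR-199B"
    assert top.iloc[0]["coeff"] == pytest.approx(2.3595)
    # hyper block ends with the weakest hypermethylated gene, then the hypo block
    assert top.iloc[17]["mirna_gene"] == "miR-320D1"
    assert top.iloc[17]["coeff"] == pytest.approx(1.2870)
    assert list(top.iloc[18:]["mirna_gene"]) == ["miR-1182", "miR-193A"]
    assert rank_top(res, k=1).iloc[0]["mirna_gene"] == "miR-199B"
    assert rank_top(res, k=1, direction="hypo").iloc[0]["coeff"] == pytest.approx(-3.0805)


def test_rank_top_flags_short_selection():
    res, _ = volcano_filter(_results_frame([2.0, 0.0], [1e-4, 0.9]))
    with pytest.warns(UserWarning, match="only 1"):
        out = rank_top(res, k=5)
    assert len(out) == 1
    empty, _ = volcano_filter(_results_frame([0.0], [0.9]))
    with pytest.warns(UserWarning, match="no selected"):
        assert rank_top(empty, k=3).empty


def _tiny_dataset(beta, groups, **meta):
    samples = [f"s{i}" for i in range(beta.shape[1])]
    metadata = pd.DataFrame({"group": groups, **meta}, index=pd.Index(samples, name="sample_id"))
    return MethylationDataset(
        beta=pd.DataFrame(beta, index=[f"cg{i}" for i in range(beta.shape[0])], columns=samples),
        metadata=metadata,
    )


def test_clustering_joins_duplicated_samples_first():
    rng = np.random.default_rng(0)
    base = rng.uniform(0.1, 0.9, (50, 4))
    base[:, 3] = base[:, 0]  # s3 duplicates s0
    ds = _tiny_dataset(base, ["FECD", "FECD", "control", "control"])
    corr, Z = sample_correlation_and_clustering(ds)
    assert corr.iloc[0, 3] == pytest.approx(1.0)
    assert sorted(Z[0, :2]) == [0, 3]


def test_clustering_rejects_constant_sample():
    beta = np.random.default_rng(1).uniform(0.2, 0.8, (30, 4))
    beta[:, 2] = 0.4
    ds = _tiny_dataset(beta, ["FECD", "FECD", "control", "control"])
    with pytest.raises(ValueError, match="s2"):
        sample_correlation_and_clustering(ds)


def test_clustering_separates_groups_and_is_order_invariant():
    cfg = SimulationConfig(
        n_probes=300, n_mirna_genes=60, frac_hyper=0.5, frac_hypo=0.0,
        effect_size=4.0, noise_sd=0.3, host_probes_per_gene=0, seed=3,
    )
    ds, _ = generate_methylation_dataset(cfg)
    corr, Z = sample_correlation_and_clustering(ds)
    cut = fcluster(Z, 2, criterion="maxclust")
    groups = ds.metadata["group"].to_numpy()
    assert len(set(zip(cut, groups))) == 2  # the 2-way cut matches the case/control split

    perm = np.random.default_rng(4).permutation(ds.beta.shape[1])
    ds_perm = MethylationDataset(
        beta=ds.beta.iloc[:, perm], metadata=ds.metadata.iloc[perm], annotation=ds.annotation
    )
    _, Zp = sample_correlation_and_clustering(ds_perm)
    cut_p = fcluster(Zp, 2, criterion="maxclust")
    groups_p = ds_perm.metadata["group"].to_numpy()
    assert len(set(zip(cut_p, groups_p))) == 2


def test_pca_finds_planted_group_effect_and_handles_degenerate_covariates():
    cfg = SimulationConfig(
        n_probes=400, n_mirna_genes=80, frac_hyper=0.5, frac_hypo=0.0,
        effect_size=4.0, noise_sd=0.3, host_probes_per_gene=0, seed=5,
    )
    ds, _ = generate_methylation_dataset(cfg)
    ds.metadata["guttata_grade"] = 2  # constant covariate: association undefined
    pvals = pca_covariate_check(ds, n_components=3)
    assert pvals.loc["PC1", "group"] < 0.01
    assert np.isnan(pvals.loc["PC1", "guttata_grade"])
    with pytest.raises(ValueError, match="n_components"):
        pca_covariate_check(ds, n_components=50)


def test_pca_null_covariate_associations_are_uniformish():
    hits = 0
    n_sims = 60
    for i in range(n_sims):
        cfg = SimulationConfig(
            n_probes=60, n_mirna_genes=12, frac_hyper=0.0, frac_hypo=0.0,
            noise_sd=0.5, host_probes_per_gene=0, seed=100 + i,
        )
        ds, _ = generate_methylation_dataset(cfg)
        pvals = pca_covariate_check(ds, n_components=1)
        hits += pvals.loc["PC1", "age"] < 0.05
    assert hits / n_sims <= 0.15  # ~5% expected; generous Monte-Carlo bound


def test_differential_methylation_frame_contract(small_cohort):
    ds, _ = small_cohort
    res = differential_methylation(ds)
    assert (res["q_value"] >= res["p_value"] - 1e-12).all()
    assert res["coeff"].equals(res["log2_fc"])
    assert res.index.equals(ds.beta.index)


def test_selector_estimator_roundtrip(small_cohort):
    ds, gt = small_cohort
    X = ds.beta.to_numpy().T
    y = ds.metadata["group"].to_numpy()
    sel = DifferentialMethylationSelector(case_label="FECD").fit(X, y)
    reduced = sel.transform(X)
    assert reduced.shape == (X.shape[0], sel.get_support().sum())
    assert sel.counts_.total == (sel.results_["direction"] != "ns").sum()
    # the selector agrees with the functional path
    res, counts = volcano_filter(differential_methylation(ds))
    assert sel.counts_ == counts
    params = sel.get_params()
    assert params["p_threshold"] == 0.05 and params["fc_threshold"] == 1.3
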