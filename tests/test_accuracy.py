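"""Empirical accuracy statistics: correlations, error rates, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imputeqc as iq
from imputeqc.accuracy import (
    allelic_error_rates,
    compute_stats,
    concordance,
    empirical_r,
    maf_summary,
    segregation_errors,
    window_summary,
)
from tests.conftest import brute_force_pearson

# --- empirical r ---------------------------------------------------------


def test_empirical_r_worked_example():
    """Truth [0,1,2,1] vs best-guess [0,1,1,1]: r = 1/sqrt(1.5)."""
    res = empirical_r([0, 1, 2, 1], [0, 1, 1, 1], mode="gt")
    assert res.estimable
    assert res.r == pytest.approx(0.816496580927726, abs=1e-12)
    assert res.rsq == pytest.approx(2.0 / 3.0, abs=1e-12)


def test_empirical_r_identity_and_zero_variance():
    assert empirical_r([0, 1, 2, 1], [0, 1, 2, 1]).r == pytest.approx(1.0)
    res = empirical_r([0, 0, 0, 0], [0, 1, 2, 1])
    assert not res.estimable and res.reason == "zero_truth_variance"
    res = empirical_r([0, 1, 2, 1], [1, 1, 1, 1], mode="gt")
    assert not res.estimable and "zero_imputed_variance" in res.reason


def test_empirical_r_ds_mode_needs_truth_variance_only_when_ds_varies():
    res = empirical_r([0, 1, 2, 1], [0.1, 0.9, 1.8, 1.1], mode="ds")
    assert res.estimable
    res = empirical_r([0, 0, 0, 0], [0.1, 0.9, 1.8, 1.1], mode="ds")
    assert not res.estimable


def test_empirical_r_too_few_pairs():
    res = empirical_r([0, -1, -1, -1], [1, 1, 1, 1], mode="gt")
    assert not res.estimable and res.reason == "fewer_than_2_pairs"


@settings(max_examples=250, derandomize=True)
@given(
    st.lists(st.integers(0, 2), min_size=2, max_size=40),
    st.data(),
)
def test_empirical_r_matches_brute_force(truth, data):
    """Library Pearson agrees with an explicit-sum oracle to 1e-12."""
    imp = data.draw(st.lists(st.integers(0, 2), min_size=len(truth), max_size=len(truth)))
    expect = brute_force_pearson(truth, imp)
    res = empirical_r(truth, imp, mode="gt")
    if expect is None:
        assert not res.estimable
    else:
        assert res.r == pytest.approx(expect, abs=1e-12)


def test_empirical_r_many_random_vectors_vs_scipy(rng):
    """Cross-check against scipy.stats.pearsonr on 1,000 random vectors."""
    from scipy import stats as sps

    for _ in range(1000):
        n = rng.integers(3, 30)
        t = rng.integers(0, 3, size=n)
        x = rng.random(n) * 2
        res = empirical_r(t, x, mode="ds")
        if res.estimable:
            assert res.r == pytest.approx(sps.pearsonr(t, x).statistic, abs=1e-12)


# --- allele-level error rates -------------------------------------------


def test_allelic_error_rates_worked_example():
    """[0,1,2,1] vs [0,1,1,1]: one lost alt allele -> FNR 25%, AER 12.5%."""
    e = allelic_error_rates([0, 1, 2, 1], [0, 1, 1, 1])
    assert (e.fp_alleles, e.fn_alleles) == (0, 1)
    assert e.fnr == pytest.approx(25.0)
    assert e.fpr == pytest.approx(0.0)
    assert e.aer == pytest.approx(12.5)


def test_allelic_error_rates_undefined_denominator():
    """All-reference truth has no alt alleles: FNR undefined, never 0."""
    e = allelic_error_rates([0, 0], [2, 1])
    assert e.fp_alleles == 3
    assert e.fpr == pytest.approx(75.0)
    assert np.isnan(e.fnr)
    assert e.aer == pytest.approx(75.0)


def test_allelic_error_rates_perfect():
    e = allelic_error_rates([0, 1, 2], [0, 1, 2])
    assert (e.fpr, e.fnr, e.aer) == (0.0, 0.0, 0.0)


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=50))
def test_allele_conservation_identity(pairs):
    """FP + FN allele counts equal AER/100 * 2n for every input."""
    t = [p[0] for p in pairs]
    x = [p[1] for p in pairs]
    e = allelic_error_rates(t, x)
    assert e.fp_alleles + e.fn_alleles == pytest.approx(e.aer / 100 * 2 * e.n_pairs)
    if not np.isnan(e.fpr) and not np.isnan(e.fnr):
        lhs = e.fpr / 100 * e.n_ref_alleles + e.fnr / 100 * e.n_alt_alleles
        assert lhs == pytest.approx(e.aer / 100 * 2 * e.n_pairs)
    # aer == 0 exactly when concordance is 100
    conc = concordance(t, x)
    assert (e.aer == 0) == (conc == 100.0)


def test_concordance_worked_examples():
    assert concordance([0, 1, 2, 1], [0, 1, 1, 1]) == pytest.approx(75.0)
    assert concordance([0, 1], [0, 1]) == 100.0
    assert concordance([0, 1], [1, 0]) == 0.0


# --- vectorised stats agree with scalar functions ------------------------


def test_compute_stats_matches_scalar_path(small_sim):
    _, truth, imputed = small_sim
    stats = compute_stats(truth, imputed)
    idx = np.linspace(0, truth.n_variants - 1, 40).astype(int)
    for i in idx:
        t, g, d = truth.g[i], imputed.gt[i], imputed.ds[i]
        r_gt = empirical_r(t, g, mode="gt")
        r_ds = empirical_r(t, d.astype(float), mode="ds")
        row = stats.iloc[i]
        if r_gt.estimable:
            assert row["r_gt"] == pytest.approx(r_gt.r, abs=1e-12)
        else:
            assert np.isnan(row["r_gt"]) and not row["estimable_gt"]
        if r_ds.estimable:
            assert row["r_ds"] == pytest.approx(r_ds.r, abs=1e-12)
        e = allelic_error_rates(t, g)
        assert row["aer"] == pytest.approx(e.aer, abs=1e-12)
        assert row["concordance"] == pytest.approx(concordance(t, g), abs=1e-12)


def test_compute_stats_permutation_invariant(small_sim, rng):
    """Reordering samples leaves every per-variant statistic unchanged."""
    _, truth, imputed = small_sim
    perm = rng.permutation(truth.n_samples)
    stats_a = compute_stats(truth, imputed)
    stats_b = compute_stats(truth.subset_samples(perm), imputed.subset_samples(perm))
    for col in ("r_gt", "r_ds", "aer", "fpr", "fnr", "concordance"):
        np.testing.assert_allclose(
            stats_a[col].to_numpy(), stats_b[col].to_numpy(), atol=1e-9, equal_nan=True
        )


def test_compute_stats_pairwise_missing_handling():
    """A missing cell on either side drops only that pair."""
    keys = [iq.VariantKey("1", 10, "A", "T")]
    truth = iq.TruthMatrix(
        keys=keys,
        samples=["a", "b", "c", "d"],
        g=np.array([[0, 1, 2, -1]], dtype=np.int16),
        region=np.array(["AUTOSOME"], dtype=object),
        af_ref=np.array([0.4]),
        mac_ref=np.array([4]),
    )
    imputed = iq.ImputedCallSet(
        keys=keys,
        samples=["a", "b", "c", "d"],
        gt=np.array([[0, -1, 2, 1]], dtype=np.int16),
        ds=np.array([[0.0, 1.0, 2.0, 1.0]]),
        gp=None,
        rsq_soft=np.array([0.9]),
    )
    stats = compute_stats(truth, imputed)
    assert stats["n_pairs"][0] == 2  # pairs (a, c) only for GT
    assert stats["concordance"][0] == 100.0


# --- overlap sets and segregation ----------------------------------------


def test_common_estimable_set_intersection():
    def table(keys, est):
        return pd.DataFrame(
            {
                "chrom": ["1"] * len(keys),
                "pos": keys,
                "ref": ["A"] * len(keys),
                "alt": ["T"] * len(keys),
                "estimable_gt": est,
            }
        )

    t1 = table([1, 2, 3], [True, True, True])
    t2 = table([2, 3], [True, True])
    t3 = table([2, 3, 4], [True, True, True])
    got = iq.common_estimable_set([t1, t2, t3])
    assert got == {("1", 2, "A", "T"), ("1", 3, "A", "T")}
    # single collection: its own estimable keys
    assert iq.common_estimable_set([t1]) == {("1", p, "A", "T") for p in (1, 2, 3)}
    # disjoint: empty set, not an error
    assert iq.common_estimable_set([table([1], [True]), table([2], [True])]) == set()


def test_segregation_errors_counts():
    rng = np.random.default_rng(5)
    n, s = 200, 40
    g = rng.integers(0, 3, size=(n, s)).astype(np.int16)
    g[:10] = 0  # 10 monomorphic truth variants
    truth = iq.TruthMatrix(
        keys=[iq.VariantKey("1", i + 1, "A", "T") for i in range(n)],
        samples=[f"S{i}" for i in range(s)],
        g=g,
        region=np.array(["AUTOSOME"] * n, dtype=object),
        af_ref=np.full(n, 0.3),
        mac_ref=np.full(n, 5),
    )
    imp_gt = g.copy()
    imp_gt[10:13] = 0  # 3 segregating variants imputed monomorphic
    imp_gt[0] = 1  # 1 monomorphic variant imputed segregating
    res = segregation_errors(truth, imp_gt)
    assert res.n_seg_truth == 190 and res.n_seg_as_mono == 3
    assert res.pct_seg_as_mono == pytest.approx(100 * 3 / 190)
    assert res.n_mono_truth == 10 and res.n_mono_as_seg == 1
    assert res.pct_mono_as_seg == pytest.approx(10.0)
    # perfect imputation
    perfect = segregation_errors(truth, g)
    assert perfect.pct_seg_as_mono == 0.0 and perfect.pct_mono_as_seg == 0.0


def test_segregation_errors_all_monomorphic_truth():
    truth = iq.TruthMatrix(
        keys=[iq.VariantKey("1", 1, "A", "T")],
        samples=["a", "b"],
        g=np.zeros((1, 2), dtype=np.int16),
        region=np.array(["AUTOSOME"], dtype=object),
        af_ref=np.array([0.0]),
        mac_ref=np.array([0]),
    )
    res = segregation_errors(truth, truth.g)
    assert np.isnan(res.pct_seg_as_mono)
    assert res.reason == "no_segregating_truth_variants"


# --- summaries ------------------------------------------------------------


def _stats_frame(pos, vals, chrom="10", maf=None):
    n = len(pos)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": pos,
            "maf_ref": maf if maf is not None else [0.2] * n,
            "rsq_emp_ds": vals,
        }
    )


def test_window_summary_worked_example():
    """Variants at 0.2/0.8/1.5 Mb with 1 Mb windows: means 0.8 and 0.5."""
    df = _stats_frame([200_000, 800_000, 1_500_000], [0.9, 0.7, 0.5])
    out = window_summary(df, window_bp=1_000_000)
    assert out["n_variants"].tolist() == [2, 1]
    assert out["mean_rsq_emp_ds"].tolist() == pytest.approx([0.8, 0.5])


def test_window_summary_reports_empty_windows():
    df = _stats_frame([100, 2_500_000], [0.4, 0.6])
    out = window_summary(df, window_bp=1_000_000)
    assert out["n_variants"].tolist() == [1, 0, 1]
    assert np.isnan(out["mean_rsq_emp_ds"][1])


def test_maf_summary_bin_assignment():
    """Half-open (lo, hi] bins; 0.05 goes to the (0.025, 0.05] bin and the
    two-group split puts it with the less-common group."""
    df = _stats_frame(
        [1, 2, 3, 4], [0.5, 0.9, 0.7, 0.6], maf=[0.01, 0.3, 0.4, 0.05]
    )
    bins, groups = maf_summary(df)
    by_edge = {(round(r.maf_lo, 3), round(r.maf_hi, 3)): r for r in bins.itertuples()}
    assert by_edge[(0.005, 0.01)].n_variants == 1
    assert by_edge[(0.005, 0.01)].mean_rsq_emp_ds == pytest.approx(0.5)
    assert by_edge[(0.2, 0.3)].mean_rsq_emp_ds == pytest.approx(0.9)
    assert by_edge[(0.3, 0.4)].mean_rsq_emp_ds == pytest.approx(0.7)
    assert by_edge[(0.025, 0.05)].n_variants == 1  # the 0.05 variant
    g = {r.group: r.n_variants for r in groups.itertuples()}
    assert g == {"common": 2, "less_common": 2}


def test_maf_summary_rejects_out_of_range():
    df = _stats_frame([1], [0.5], maf=[0.7])
    with pytest.raises(ValueError, match="maf"):
        maf_summary(df)
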