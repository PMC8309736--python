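"""Normality screen, paired t-curves, RFT thresholds and SnPM inference,
each against an independent oracle (brute-force enumeration, closed form,
or Monte-Carlo simulation)."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.signal import fftconvolve

from gaitspm.stats import (
    choose_test,
    estimate_fwhm,
    ks_normality,
    rft_threshold,
    scalar_paired_test,
    snpm_paired,
    spm_paired_rft,
    spm_paired_t,
)

# ------------------------------------------------------------------ helpers


def smooth_gaussian_curves(rng, n, n_nodes=100, fwhm=15.0, sd=1.0):
    """Zero-mean curves with Gaussian autocorrelation of the given FWHM."""
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    pad = int(4 * sigma) + 1
    white = rng.normal(size=(n, n_nodes + 2 * pad))
    k = np.exp(-0.5 * (np.arange(-pad, pad + 1) / sigma) ** 2)
    k /= np.sqrt((k**2).sum())
    return sd * fftconvolve(white, k[None, :], mode="valid")[:, :n_nodes]


# ----------------------------------------------------------- paired t curve


def test_paired_t_zero_diffs():
    assert np.all(spm_paired_t(np.zeros((6, 100))) == 0.0)


def test_paired_t_constant_nonzero_is_infinite():
    d = np.ones((4, 10))
    t = spm_paired_t(d)
    assert np.all(np.isinf(t)) and np.all(t > 0)


def test_paired_t_matches_first_principles(rng):
    """Node-wise agreement with an explicit loop computation to 1e-10."""
    d = rng.normal(size=(9, 100))
    t = spm_paired_t(d)
    for q in range(100):
        col = d[:, q]
        mean = sum(col) / 9
        var = sum((v - mean) ** 2 for v in col) / 8
        expected = mean / math.sqrt(var / 9)
        assert t[q] == pytest.approx(expected, abs=1e-10)


# ------------------------------------------------------------- KS normality


def test_ks_reject_rate_on_normal_draws_lilliefors(rng):
    """With the estimated-parameter correction the screen is calibrated:
    about 5% of normal-sample nodes reject."""
    x = rng.normal(size=(1000, 400))
    report = ks_normality(x, alpha=0.05, lilliefors=True)
    assert report.fraction_non_normal == pytest.approx(0.05, abs=0.02)


def test_ks_default_screen_is_conservative(rng):
    """Z-scoring before the plain KS test underestimates departures, so the
    uncorrected default rejects (well) below the nominal rate."""
    x = rng.normal(size=(1000, 100))
    report = ks_normality(x, alpha=0.05)
    assert report.fraction_non_normal <= 0.05


def test_ks_rejects_gross_violation(rng):
    bimodal = np.concatenate([rng.normal(-4, 0.3, 500), rng.normal(4, 0.3, 500)])
    report = ks_normality(bimodal[:, None], alpha=0.05)
    assert bool(report.reject[0])


def test_ks_constant_sample_flagged():
    x = np.ones((10, 3))
    x[:, 1] = np.arange(10)
    report = ks_normality(x)
    assert not report.testable[0] and bool(report.reject[0])
    assert report.testable[1]


def test_choose_test_rules():
    base = dict(p_values=np.full(100, 0.5), testable=np.ones(100, bool), alpha=0.05)
    from gaitspm.stats import NormalityReport

    all_normal = NormalityReport(reject=np.zeros(100, bool), **base)
    assert choose_test(all_normal) == "parametric"
    one_reject = NormalityReport(reject=np.eye(1, 100, 5, dtype=bool)[0], **base)
    assert choose_test(one_reject) == "nonparametric"
    assert choose_test(one_reject, max_reject_fraction=0.05) == "parametric"


# ---------------------------------------------------------------------- RFT


def test_rft_threshold_monotone_in_alpha():
    t1 = rft_threshold(alpha=0.05, df=15, fwhm=12.0)
    t2 = rft_threshold(alpha=0.01, df=15, fwhm=12.0)
    assert t2 > t1


def test_rft_threshold_monotone_in_fwhm():
    t10 = rft_threshold(alpha=0.05, df=15, fwhm=10.0)
    t20 = rft_threshold(alpha=0.05, df=15, fwhm=20.0)
    assert t10 > t20


def test_rft_threshold_approaches_pointwise():
    t_point = sps.t.isf(0.05, 15)
    t_smooth = rft_threshold(alpha=0.05, df=15, fwhm=1e9)
    assert t_smooth == pytest.approx(t_point, rel=1e-3)
    assert rft_threshold(alpha=0.05, df=15, fwhm=20.0) > t_point


def test_rft_threshold_matches_simulation():
    """Within 5% of the Monte-Carlo 95th percentile of max|t| over smooth
    Gaussian fields with known FWHM (two-tailed -> alpha/2)."""
    rng = np.random.default_rng(99)
    for fwhm in (10.0, 18.0):
        max_t = []
        for _ in range(2500):
            d = smooth_gaussian_curves(rng, 16, fwhm=fwhm)
            max_t.append(np.abs(spm_paired_t(d)).max())
        emp = float(np.quantile(max_t, 0.95))
        thr = rft_threshold(alpha=0.025, df=15, fwhm=fwhm, n_nodes=100)
        assert thr == pytest.approx(emp, rel=0.05)


def test_rft_threshold_requires_df():
    with pytest.raises(ValueError, match="df"):
        rft_threshold(alpha=0.05, df=1, fwhm=10.0)


def test_estimate_fwhm_recovers_generation_smoothness(rng):
    est = []
    for _ in range(100):
        d = smooth_gaussian_curves(rng, 16, fwhm=12.0)
        est.append(estimate_fwhm(d - d.mean(axis=0)))
    assert np.mean(est) == pytest.approx(12.0, rel=0.15)


# --------------------------------------------------------------------- SnPM


def brute_force_snpm(d, alpha=0.05):
    """Plain-loop exhaustive sign-flip inference, independent of the
    vectorized implementation."""
    n, Q = d.shape
    t_obs = [sps.ttest_1samp(d[:, q], 0.0).statistic for q in range(Q)]
    max_ts, run_lengths = [], []
    all_signs = list(itertools.product([1.0, -1.0], repeat=n))
    for signs in all_signs:
        sd = np.array(signs)[:, None] * d
        t = [sps.ttest_1samp(sd[:, q], 0.0).statistic for q in range(Q)]
        max_ts.append(max(abs(v) for v in t))
    max_ts_sorted = sorted(max_ts)
    # smallest value with at least (1 - alpha) of the distribution at or below
    idx = math.ceil((1 - alpha) * (len(max_ts_sorted) - 1))
    t_star = max_ts_sorted[idx]
    # observed clusters by scanning
    clusters = []
    q = 0
    while q < Q:
        if abs(t_obs[q]) >= t_star:
            start = q
            while q < Q and abs(t_obs[q]) >= t_star:
                q += 1
            clusters.append((start, q - 1))
        else:
            q += 1
    # permutation max run lengths at the same threshold
    for signs in all_signs:
        sd = np.array(signs)[:, None] * d
        t = [sps.ttest_1samp(sd[:, q], 0.0).statistic for q in range(Q)]
        best = cur = 0
        for v in t:
            cur = cur + 1 if abs(v) >= t_star else 0
            best = max(best, cur)
        run_lengths.append(best)
    out = []
    for s, e in clusters:
        extent = e - s + 1
        p = sum(1 for r in run_lengths if r >= extent) / len(all_signs)
        out.append((s, e, max(p, 1 / len(all_signs))))
    return t_star, out


def test_snpm_exhaustive_matches_brute_force(rng):
    """n=8 exhaustive mode reproduces the 256-flip enumeration exactly:
    threshold, cluster boundaries and cluster p-values."""
    d = smooth_gaussian_curves(rng, 8, n_nodes=60, fwhm=10.0) + 1.1
    res = snpm_paired(d, alpha=0.05, n_permutations=300)
    assert res.exhaustive and res.n_permutations == 256
    t_star, clusters = brute_force_snpm(d)
    assert res.critical_threshold == pytest.approx(t_star, abs=1e-10)
    assert [(c.start_node, c.end_node) for c in res.clusters] == [(s, e) for s, e, _ in clusters]
    for c, (_, _, p) in zip(res.clusters, clusters):
        assert c.p_value == pytest.approx(p, abs=1e-12)


def test_snpm_zero_diffs_no_clusters():
    res = snpm_paired(np.zeros((8, 100)), n_permutations=256)
    assert res.clusters == []


def test_snpm_subject_order_invariance(rng):
    d = smooth_gaussian_curves(rng, 8, fwhm=12.0) + 0.8
    r1 = snpm_paired(d, n_permutations=256)
    r2 = snpm_paired(d[::-1], n_permutations=256)
    assert r1.critical_threshold == pytest.approx(r2.critical_threshold)
    assert [(c.start_node, c.end_node, c.p_value) for c in r1.clusters] == [
        (c.start_node, c.end_node, c.p_value) for c in r2.clusters
    ]


def test_snpm_global_sign_flip_symmetry(rng):
    """Two-tailed: negating all curves keeps clusters, reverses signs."""
    d = smooth_gaussian_curves(rng, 8, fwhm=12.0) + 0.8
    r1 = snpm_paired(d, n_permutations=256)
    r2 = snpm_paired(-d, n_permutations=256)
    assert r1.critical_threshold == pytest.approx(r2.critical_threshold)
    assert [(c.start_node, c.end_node, c.p_value, -c.sign) for c in r1.clusters] == [
        (c.start_node, c.end_node, c.p_value, c.sign) for c in r2.clusters
    ]


def test_snpm_exhaustive_and_random_agree_when_budget_covers(rng):
    d = smooth_gaussian_curves(rng, 6, fwhm=12.0) + 0.5
    r1 = snpm_paired(d, n_permutations=100, seed=1)
    r2 = snpm_paired(d, n_permutations=5000, seed=2)
    assert r1.exhaustive and r2.exhaustive
    assert r1.critical_threshold == r2.critical_threshold
    assert [c.to_dict() for c in r1.clusters] == [c.to_dict() for c in r2.clusters]


def test_snpm_requires_enough_permutations(rng):
    with pytest.raises(ValueError, match="at least 100"):
        snpm_paired(rng.normal(size=(8, 50)), n_permutations=50)


def test_snpm_warns_on_tiny_n(rng):
    with pytest.warns(UserWarning, match="coarse"):
        snpm_paired(rng.normal(size=(4, 50)), n_permutations=256)


def test_snpm_detects_windowed_effect_with_high_power():
    """A 3-degree effect over a 40-node window with 2-degree between-subject
    SD at n=16 is detected (overlapping cluster) in >= 90% of replicates."""
    rng = np.random.default_rng(2024)
    window = np.arange(30, 70)
    hits = 0
    reps = 25
    for r in range(reps):
        d = smooth_gaussian_curves(rng, 16, fwhm=15.0, sd=2.0)
        d[:, window] += 3.0
        res = snpm_paired(d, n_permutations=10000, seed=int(rng.integers(2**31 - 1)))
        hits += any(
            len(set(range(c.start_node, c.end_node + 1)) & set(window.tolist())) > 0 and c.sign > 0
            for c in res.clusters
        )
    assert hits / reps >= 0.9


def test_parametric_rft_branch_runs(rng):
    d = smooth_gaussian_curves(rng, 16, fwhm=15.0)
    d[:, 40:60] += 2.0
    res = spm_paired_rft(d, alpha=0.05)
    assert res.method == "parametric_rft"
    assert res.critical_threshold > sps.t.isf(0.025, 15)
    assert res.clusters  # a 2-sigma-scale shift over 20 nodes is found


# ------------------------------------------------------------- scalar tests


def test_scalar_equal_pairs_degenerate():
    x = np.arange(8, dtype=float)
    stat, p, name = scalar_paired_test(x, x)
    assert (p, name) == (1.0, "degenerate")


def test_scalar_wilcoxon_matches_enumeration():
    """n=6 signed-rank p equals the exhaustive 2^6 null enumeration."""
    wr = np.array([10.0, 12.0, 11.0, 14.0, 9.0, 13.0])
    tr = wr + np.array([0.9, -0.4, 1.6, 0.3, 2.2, -1.1])
    d = tr - wr
    ranks = sps.rankdata(np.abs(d))
    w_plus_obs = ranks[d > 0].sum()
    dist = [sum(r for r, s in zip(ranks, signs) if s > 0)
            for signs in itertools.product([1, -1], repeat=6)]
    n_tot = len(dist)
    p_low = sum(1 for w in dist if w <= w_plus_obs) / n_tot
    p_high = sum(1 for w in dist if w >= w_plus_obs) / n_tot
    p_enum = min(1.0, 2 * min(p_low, p_high))
    res = sps.wilcoxon(tr, wr, zero_method="wilcox", method="exact")
    assert res.pvalue == pytest.approx(p_enum, abs=1e-12)
    # and the screen-dispatched path returns a valid test on these pairs
    stat, p, name = scalar_paired_test(wr, tr)
    assert name in ("wilcoxon", "paired_t") and 0 < p <= 1


def test_scalar_strong_shift_significant(rng):
    wr = rng.normal(0.0, 1.0, 16)
    tr = wr + 5.0 + rng.normal(0.0, 1.0, 16)
    _, p, _ = scalar_paired_test(wr, tr)
    assert p < 0.001


def test_scalar_requires_min_pairs():
    with pytest.raises(ValueError, match="at least 5"):
        scalar_paired_test(np.arange(4.0), np.arange(4.0) + 1)
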