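"""Node-wise normality screening and paired 1D statistical mapping.

The paired unit is one difference curve per subject (TR median minus WR
median, 100 nodes).  Inference over the whole curve controls the
familywise error across nodes either parametrically (random field theory
for smooth 1D t-fields) or non-parametrically (sign permutation of whole
subject curves with the max-|t| statistic, "SnPM").  Clusters are maximal
runs of nodes at or above the critical threshold; each cluster receives a
p-value from the permutation distribution of maximal suprathreshold run
length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Normality screening
# --------------------------------------------------------------------------


@dataclass
class NormalityReport:
    """Per-node Kolmogorov-Smirnov normality screen."""

    p_values: np.ndarray  # (Q,), NaN where not testable
    reject: np.ndarray  # (Q,) bool; non-testable nodes count as non-normal
    testable: np.ndarray  # (Q,) bool
    alpha: float

    @property
    def fraction_non_normal(self) -> float:
        return float(np.mean(self.reject))


def ks_normality(
    node_samples: np.ndarray,
    alpha: float = 0.05,
    standardize: bool = True,
    lilliefors: bool = False,
) -> NormalityReport:
    """One-sample KS test against the normal distribution at every node.

    ``node_samples`` is (n_obs, Q).  By default each node's sample is
    z-scored and compared with the standard normal CDF using the asymptotic
    p-value; because the null parameters are then estimated from the same
    sample, this screen is conservative.  ``lilliefors=True`` applies the
    estimated-parameter correction (Monte-Carlo/table-based p), giving a
    calibrated test.  Zero-variance nodes are flagged non-testable and
    counted as non-normal.
    """
    x = np.atleast_2d(np.asarray(node_samples, dtype=float))
    n, Q = x.shape
    if n < 4:
        raise ValueError("need at least 4 observations per node")
    p = np.full(Q, np.nan)
    testable = np.ones(Q, dtype=bool)
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf
    for q in range(Q):
        col = x[:, q]
        sd = np.std(col, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            testable[q] = False
            continue
        if lilliefors:
            _, p[q] = _lf(col, dist="norm", pvalmethod="table")
        else:
            z = (col - col.mean()) / sd if standardize else col
            p[q] = sps.kstest(z, "norm").pvalue
    reject = ~testable | (np.nan_to_num(p, nan=0.0) < alpha)
    if (~testable).any():
        logger.warning("%d node(s) had zero variance; flagged non-testable", int((~testable).sum()))
    return NormalityReport(p_values=p, reject=reject, testable=testable, alpha=alpha)


def choose_test(report: NormalityReport, max_reject_fraction: float = 0.0) -> str:
    """``"nonparametric"`` if the rejecting-node fraction exceeds the
    allowance (default: any rejecting node), else ``"parametric"``."""
    decision = "nonparametric" if report.fraction_non_normal > max_reject_fraction else "parametric"
    logger.info("normality screen: %.1f%% nodes non-normal -> %s test",
                100 * report.fraction_non_normal, decision)
    return decision


# --------------------------------------------------------------------------
# Paired t curve
# --------------------------------------------------------------------------


def spm_paired_t(diffs: np.ndarray) -> np.ndarray:
    """Node-wise one-sample t statistic of the paired differences.

    ``diffs`` is (n, Q).  Sample SD uses the n-1 denominator.  Nodes with
    zero SD yield a signed-infinity sentinel (0 when the mean is also 0).
    """
    d = np.atleast_2d(np.asarray(diffs, dtype=float))
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning("%d node(s) with zero SD; t set to signed infinity", int(zero_sd.sum()))
        with np.errstate(invalid="ignore"):
            t[zero_sd] = np.where(mean[zero_sd] == 0, 0.0, np.sign(mean[zero_sd]) * np.inf)
    return t


# --------------------------------------------------------------------------
# Random field theory (parametric branch)
# --------------------------------------------------------------------------


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Smoothness (FWHM, in nodes) of a set of residual curves.

    Gradient-based estimator: the residual field is normalized node-wise,
    the mean squared gradient of the normalized field gives the variance of
    the derivative process, and FWHM = sqrt(4 ln 2 / <grad^2>) under a
    Gaussian autocorrelation model.
    """
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    ssq = (R**2).sum(axis=0)
    good = ssq > 0
    if good.sum() < 2:
        raise ValueError("residuals are degenerate; cannot estimate smoothness")
    rpn = R[:, good] / np.sqrt(ssq[good])
    grad = np.diff(rpn, axis=1)
    v = float((grad**2).sum(axis=0).mean())
    if v <= 0:
        return float("inf")
    return float(np.sqrt(4 * np.log(2) / v))


def _ec_density_t(u: float, df: int, resels: float) -> float:
    """Expected Euler characteristic of a 1D t-field excursion set."""
    rho0 = sps.t.sf(u, df)
    rho1 = resels * np.sqrt(4 * np.log(2)) / (2 * np.pi) * (1 + u**2 / df) ** (-(df - 1) / 2.0)
    return float(rho0 + rho1)


def rft_threshold(
    residuals: np.ndarray | None = None,
    alpha: float = 0.05,
    df: int | None = None,
    fwhm: float | None = None,
    n_nodes: int = 100,
) -> float:
    """Critical t for a smooth 1D t-field at familywise level ``alpha``.

    The threshold t* solves ``E[EC](t*) = alpha`` with the expected Euler
    characteristic of the excursion set over a field of ``n_nodes - 1``
    inter-node intervals and the given smoothness.  The smoothness (FWHM in
    nodes) is estimated from the residual curves unless passed directly.
    As FWHM grows the threshold falls to the pointwise critical t; finite
    smoothness always gives a strictly larger value.
    """
    if df is None or df < 2:
        raise ValueError("df must be an integer >= 2")
    if fwhm is None:
        if residuals is None:
            raise ValueError("provide residual curves or an explicit FWHM")
        fwhm = estimate_fwhm(residuals)
    if not fwhm > 0:
        raise ValueError("FWHM must be positive")
    resels = (n_nodes - 1) / fwhm
    t_point = sps.t.isf(alpha, df)

    def excess(u: float) -> float:
        return _ec_density_t(u, df, resels) - alpha

    from scipy.optimize import brentq

    hi = t_point
    while excess(hi) > 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - pathological smoothness
            return t_point
    return float(brentq(excess, t_point, hi, xtol=1e-10))


# --------------------------------------------------------------------------
# SnPM: sign-permutation inference
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Cluster:
    start_node: int
    end_node: int  # inclusive
    p_value: float
    sign: int

    @property
    def extent(self) -> int:
        return self.end_node - self.start_node + 1

    def nodes(self) -> np.ndarray:
        return np.arange(self.start_node, self.end_node + 1)

    def to_dict(self) -> dict:
        return {
            "start_node": self.start_node,
            "end_node": self.end_node,
            "p_value": self.p_value,
            "sign": self.sign,
        }


@dataclass
class SPMResult:
    """Outcome of a 1D paired test over a 100-node field."""

    t_curve: np.ndarray
    critical_threshold: float
    clusters: list[Cluster]
    method: str  # "parametric_rft" | "nonparametric_perm"
    alpha: float
    n_permutations: int | None = None
    seed: int | None = None
    exhaustive: bool | None = None
    fwhm: float | None = None
    df: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.clusters)

    def cluster_nodes(self, sign: int | None = None) -> np.ndarray:
        nodes = [c.nodes() for c in self.clusters if sign is None or c.sign == sign]
        return np.concatenate(nodes) if nodes else np.empty(0, dtype=int)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "critical_threshold": float(self.critical_threshold),
            "t_curve": [float(v) for v in self.t_curve],
            "clusters": [c.to_dict() for c in self.clusters],
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
            "fwhm": self.fwhm,
            "df": self.df,
            **({"meta": self.meta} if self.meta else {}),
        }


def _suprathreshold_clusters(t_curve: np.ndarray, t_star: float) -> list[tuple[int, int, int]]:
    """(start, end, sign) of maximal runs with |t| >= t_star."""
    above = np.abs(t_curve) >= t_star
    out = []
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for s, e in zip(starts, ends):
        sign = 1 if np.nanmean(t_curve[s: e + 1]) >= 0 else -1
        out.append((int(s), int(e), sign))
    return out


def _max_run_lengths(above: np.ndarray) -> np.ndarray:
    """Per-row maximal run length of True in a (P, Q) boolean matrix."""
    c = np.cumsum(above, axis=1)
    floor = np.maximum.accumulate(np.where(above, 0, c), axis=1)
    return (c - floor).max(axis=1)


def _sign_matrix(n: int, n_permutations: int, seed: int | None) -> tuple[np.ndarray, bool]:
    if 2**n <= n_permutations:
        bits = np.arange(2**n, dtype=np.int64)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
        return signs.astype(float), True
    if seed is None:
        raise ValueError("a seed is required for random sign permutations")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    signs[0] = 1.0  # always include the identity relabelling
    return signs, False


def snpm_paired(
    diffs: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> SPMResult:
    """Non-parametric paired test over curves by sign permutation.

    The null distribution flips the sign of each subject's whole difference
    curve, preserving within-curve correlation: exhaustively over all 2^n
    sign vectors when that is within the permutation budget, otherwise over
    ``n_permutations`` seeded uniform sign vectors (identity included).
    The critical threshold t* is the (1 - alpha) quantile of the permuted
    max-|t| distribution (two-tailed).  Each observed cluster's p-value is
    the fraction of permutations whose maximal suprathreshold run (at the
    same t*) is at least as long, floored at 1/n_permutations.
    """
    d = np.atleast_2d(np.asarray(diffs, dtype=float))
    n, Q = d.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    if n < 5:
        warnings.warn(f"only {n} subjects: at most {2**n} sign permutations; p resolution is coarse")

    signs, exhaustive = _sign_matrix(n, n_permutations, seed)
    P = signs.shape[0]

    ssq = (d**2).sum(axis=0)  # invariant under sign flips
    mean_p = signs @ d / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var_p = (ssq[None, :] - n * mean_p**2) / (n - 1)
        var_p = np.maximum(var_p, 0.0)
        t_perm = mean_p / np.sqrt(var_p / n)
    bad = ~np.isfinite(t_perm)
    if bad.any():
        t_perm[bad] = np.where(mean_p[bad] == 0, 0.0, np.inf)
    abs_t = np.abs(t_perm)
    max_t = abs_t.max(axis=1)

    t_star = float(np.quantile(max_t, 1.0 - alpha, method="higher"))
    t_obs = spm_paired_t(d)

    clusters: list[Cluster] = []
    # a zero threshold means the field is degenerate (all permuted t vanish);
    # no meaningful excursion sets exist
    raw = _suprathreshold_clusters(t_obs, t_star) if t_star > 0 else []
    if raw:
        perm_max_run = _max_run_lengths(abs_t >= t_star)
        for s, e, sign in raw:
            extent = e - s + 1
            p = float(np.mean(perm_max_run >= extent))
            clusters.append(Cluster(s, e, max(p, 1.0 / P), sign))

    return SPMResult(
        t_curve=t_obs,
        critical_threshold=t_star,
        clusters=clusters,
        method="nonparametric_perm",
        alpha=alpha,
        n_permutations=P,
        seed=seed,
        exhaustive=exhaustive,
    )


def spm_paired_rft(diffs: np.ndarray, alpha: float = 0.05) -> SPMResult:
    """Parametric paired test over curves with an RFT critical threshold.

    Smoothness is estimated from the subject difference curves residualized
    about the node-wise mean.  Cluster p-values are not computed in this
    branch (clusters are reported at the height threshold with p set to the
    field-level alpha bound)."""
    d = np.atleast_2d(np.asarray(diffs, dtype=float))
    n, Q = d.shape
    t_obs = spm_paired_t(d)
    resid = d - d.mean(axis=0, keepdims=True)
    fwhm = estimate_fwhm(resid)
    # two-tailed inference over |t|: alpha/2 in each tail
    t_star = rft_threshold(alpha=alpha / 2.0, df=n - 1, fwhm=fwhm, n_nodes=Q)
    clusters = [Cluster(s, e, alpha, sign) for s, e, sign in _suprathreshold_clusters(t_obs, t_star)]
    return SPMResult(
        t_curve=t_obs,
        critical_threshold=t_star,
        clusters=clusters,
        method="parametric_rft",
        alpha=alpha,
        fwhm=fwhm,
        df=n - 1,
    )


# --------------------------------------------------------------------------
# Scalar paired tests
# --------------------------------------------------------------------------


def scalar_paired_test(
    x_wr: np.ndarray,
    x_tr: np.ndarray,
    alpha_normality: float = 0.05,
    lilliefors: bool = False,
) -> tuple[float, float, str]:
    """Paired scalar comparison with KS-screened test choice.

    Normality of the paired differences is screened by the same KS rule as
    the curve analysis; a Wilcoxon matched-pairs test (exact null for small
    n, zero differences dropped, mid-rank ties) is used when rejected, a
    paired t-test otherwise.  Returns (statistic, p, test_name).
    """
    x_wr = np.asarray(x_wr, dtype=float)
    x_tr = np.asarray(x_tr, dtype=float)
    if x_wr.shape != x_tr.shape or x_wr.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    n = x_wr.size
    if n < 5:
        raise ValueError("need at least 5 pairs")
    d = x_tr - x_wr
    if np.all(d == 0):
        return 0.0, 1.0, "degenerate"
    report = ks_normality(d[:, None], alpha=alpha_normality, lilliefors=lilliefors)
    if report.reject[0]:
        nz = d[d != 0]
        method = "exact" if (nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size) else "auto"
        res = sps.wilcoxon(x_tr, x_wr, zero_method="wilcox", method=method)
        return float(res.statistic), float(res.pvalue), "wilcoxon"
    res = sps.ttest_rel(x_tr, x_wr)
    return float(res.statistic), float(res.pvalue), "paired_t"
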