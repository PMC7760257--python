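"""Survival, rank and categorical statistics implemented from first principles.

Everything a TMA biomarker study needs downstream of quantification:
paired tumor-vs-normal comparisons, ROC-Youden and median cutpoints,
the Kaplan-Meier product-limit estimator, the two-group log-rank test,
Cox proportional-hazards regression (Efron tie handling, Newton-Raphson),
rank-based group associations (Mann-Whitney, Kruskal-Wallis), chi-square /
Fisher contingency tests, combined two-marker protein profiles, age
tertiles and one-decimal percentage summaries.

The nonparametric tests use exact null distributions (dynamic-programming
enumeration) at small sample sizes and tie-corrected normal / chi-square
approximations otherwise.  scipy supplies only distribution functions and
the classical parametric variants (t tests, one-way ANOVA, Shapiro-Wilk).
All tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "CutoffModel",
    "KMCurve",
    "SurvivalFitResult",
    "paired_compare",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "kruskal_wallis",
    "group_assoc",
    "fisher_exact_2x2",
    "chi_square_test",
    "categorical_assoc",
    "roc_cutoff",
    "median_cutoff",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "combine_profile",
    "combine_profiles",
    "tertile_split",
    "percent_summary",
    "benjamini_hochberg",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    degenerate: bool = False


@dataclass
class CutoffModel:
    """High/low decision rule for one marker and compartment.

    The stratification rule is ``value > cutoff -> "high"`` (ties go low).
    ``auc`` (and training sensitivity/specificity for predicting death at
    the chosen cutoff) are present only for the ROC-Youden method.
    """

    marker: str
    compartment: str
    method: str  # "roc_youden" | "median"
    cutoff: float
    auc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    degenerate: bool = False

    def stratify(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return np.where(values > self.cutoff, "high", "low")


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve.

    ``event_times`` are the distinct observed event times in ascending
    order, ``survival`` the estimator just after each of them, ``at_risk``
    the risk-set size just before, and ``n_events`` the deaths at each.
    ``censor_times`` mark censored follow-up for plotting tick marks.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S(t)=1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalFitResult:
    hazard_ratio: float
    ci95: tuple[float, float]
    p_value: float
    coefficients: dict[str, dict[str, float]]
    method: str  # "cox_univariate" | "cox_adjusted"
    n: int
    n_events: int
    converged: bool = True
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# paired and rank tests


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by DP enumeration.

    Mid-ranks are doubled to integers; the distribution of W+ over all 2^n
    equiprobable sign assignments is built by polynomial convolution.
    """
    scaled = np.round(2.0 * ranks).astype(int)
    total = int(scaled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for s in scaled:
        shifted = np.zeros_like(counts)
        shifted[s:] = counts[: total + 1 - s]
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(2.0 * w_plus))
    cdf = counts[: w + 1].sum()
    sf = counts[w:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 25) -> TestResult:
    """Wilcoxon signed-rank test (two-sided) on paired data or differences.

    Zero differences are dropped; ties in |d| receive mid-ranks.  The null
    distribution is enumerated exactly for n <= ``exact_max_n`` remaining
    pairs, otherwise a tie-corrected normal approximation (no continuity
    correction) is used.  The reported statistic is W+, the positive-rank
    sum.  All-zero differences give p = 1 with the degenerate flag set.
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    n_input = d.size
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", n_input, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _signed_rank_exact_p(ranks, w_plus)
        return TestResult(w_plus, p, "wilcoxon_signed_rank_exact", n)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, "wilcoxon_signed_rank", n, degenerate=True)
    z = (w_plus - mean) / np.sqrt(var)
    return TestResult(w_plus, float(min(1.0, 2.0 * sps.norm.sf(abs(z)))),
                      "wilcoxon_signed_rank", n)


def paired_compare(tumor, normal, method: str = "auto") -> TestResult:
    """Paired tumor-vs-normal comparison.

    ``method="t"`` runs a paired t test on the differences, ``"wilcoxon"``
    the signed-rank test, and ``"auto"`` chooses by a Shapiro-Wilk
    normality test on the differences at alpha = 0.05.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape:
        raise ValueError("tumor and normal must be matched, equal-length vectors")
    if tumor.size < 3:
        raise ValueError("need at least 3 pairs")
    d = tumor - normal
    if np.all(d == 0):
        return TestResult(0.0, 1.0, "paired_degenerate", tumor.size, degenerate=True)
    if method == "auto":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            method = "t" if sps.shapiro(d).pvalue >= 0.05 else "wilcoxon"
    if method == "t":
        res = sps.ttest_rel(tumor, normal)
        return TestResult(float(res.statistic), float(res.pvalue), "paired_t", tumor.size)
    if method == "wilcoxon":
        return wilcoxon_signed_rank(tumor, normal)
    raise ValueError(f"unknown method {method!r}")


def _rank_sum_exact_p(n1: int, n2: int, u1: float) -> float:
    """Exact two-sided p for Mann-Whitney U (no ties) by DP over rank subsets.

    Counts, for each achievable U, the number of ways to pick n1 of the N
    ranks; classic partition-count recursion.
    """
    max_u = n1 * n2
    # f[k][u] = number of rank subsets of size k with U statistic u;
    # choosing rank i as the k-th smallest member adds (i - k) to U
    f = np.zeros((n1 + 1, max_u + 1))
    f[0, 0] = 1.0
    N = n1 + n2
    for i in range(1, N + 1):
        for k in range(min(i, n1), 0, -1):
            # choosing item i as the k-th smallest adds (i - k) to U
            add = i - k
            if add > max_u:
                continue
            f[k, add:] += f[k - 1, : max_u + 1 - add]
    dist = f[n1]
    dist /= dist.sum()
    u = int(round(u1))
    cdf = dist[: u + 1].sum()
    sf = dist[u:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def mann_whitney_u(x, y, exact_max_n: int = 8) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact DP enumeration when there are no ties and both groups have at
    most ``exact_max_n`` observations; otherwise the tie-corrected normal
    approximation without continuity correction.  The statistic is U for
    the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and max(n1, n2) <= exact_max_n:
        p = _rank_sum_exact_p(n1, n2, u1)
        return TestResult(u1, p, "mann_whitney_exact", n1 + n2)
    N = n1 + n2
    mean = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return TestResult(u1, 1.0, "mann_whitney", N, degenerate=True)
    z = (u1 - mean) / np.sqrt(var)
    return TestResult(u1, float(min(1.0, 2.0 * sps.norm.sf(abs(z)))), "mann_whitney", N)


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal-Wallis H test with tie correction; p from chi-square (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    combined = np.concatenate(groups)
    N = combined.size
    ranks = sps.rankdata(combined)
    h = 0.0
    offset = 0
    for g in groups:
        r = ranks[offset : offset + g.size]
        h += r.sum() ** 2 / g.size
        offset += g.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, tie_counts = np.unique(combined, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (N**3 - N)
    if correction <= 0:
        return TestResult(0.0, 1.0, "kruskal_wallis", N, degenerate=True)
    h /= correction
    p = float(sps.chi2.sf(h, len(groups) - 1))
    return TestResult(float(h), p, "kruskal_wallis", N)


def group_assoc(values, labels, kind: str = "auto", parametric: bool = False) -> TestResult:
    """Association between a quantitative variable and a grouping.

    Two groups: Mann-Whitney (or t test when ``parametric``); three or
    more: Kruskal-Wallis (or one-way ANOVA).  ``kind`` may force
    ``"two_group"`` / ``"multi_group"``; ``"auto"`` infers from the labels.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    levels = np.unique(labels)
    if levels.size < 2:
        raise ValueError("need >= 2 groups")
    groups = [values[labels == lv] for lv in levels]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if kind == "two_group" and levels.size != 2:
        raise ValueError("two_group requested but labels have != 2 levels")
    two = levels.size == 2 if kind == "auto" else kind == "two_group"
    if two:
        if parametric:
            res = sps.ttest_ind(groups[0], groups[1])
            return TestResult(float(res.statistic), float(res.pvalue), "t_test", values.size)
        return mann_whitney_u(groups[0], groups[1])
    if parametric:
        res = sps.f_oneway(*groups)
        return TestResult(float(res.statistic), float(res.pvalue), "anova", values.size)
    return kruskal_wallis(groups)


# ---------------------------------------------------------------------------
# contingency tables


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table.

    Sums, over the hypergeometric distribution of the (0, 0) cell with
    fixed margins, the probabilities of all tables no more likely than the
    observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    a = t[0, 0]
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[:, 0].sum()
    n = t.sum()
    if n == 0:
        return TestResult(0.0, 1.0, "fisher_exact", 0, degenerate=True)
    support = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    p = float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-9)].sum()))
    odds = np.inf if t[0, 1] * t[1, 0] == 0 else (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return TestResult(float(odds), p, "fisher_exact", int(n))


def _drop_zero_margins(t: np.ndarray) -> np.ndarray:
    rows = t.sum(axis=1) > 0
    cols = t.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table",
                      stacklevel=3)
    return t[np.ix_(rows, cols)]


def chi_square_test(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D nonnegative array")
    t = _drop_zero_margins(t)
    if t.shape[0] < 2 or t.shape[1] < 2:
        return TestResult(0.0, 1.0, "chi_square", int(t.sum()), degenerate=True)
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return TestResult(stat, float(sps.chi2.sf(stat, dof)), "chi_square", int(n))


def categorical_assoc(table) -> TestResult:
    """Chi-square test, switching to Fisher's exact automatically for 2x2
    tables with any expected count below 5."""
    t = np.asarray(table)
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("contingency table must hold integer counts")
        t = np.round(t).astype(int)
    t = _drop_zero_margins(t)
    if t.shape == (2, 2):
        n = t.sum()
        if n > 0:
            expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
            if expected.min() < 5:
                return fisher_exact_2x2(t)
    return chi_square_test(t)


# ---------------------------------------------------------------------------
# cutpoints


def roc_cutoff(values, death_events, marker: str = "", compartment: str = "") -> CutoffModel:
    """ROC-derived cutpoint for predicting death from a marker value.

    Orientation is "low value predicts death": the AUC is the rank
    (Mann-Whitney) probability that a death case has a lower value than a
    survivor (ties counted half).  The cutoff maximizes Youden's
    J = sensitivity + specificity - 1 over the midpoints between adjacent
    sorted unique values, classifying value <= cutoff as predicted death;
    ties in J break toward the lower cutoff.  The resulting high/low rule
    (value > cutoff -> high) therefore puts predicted deaths in the low
    stratum.
    """
    values = np.asarray(values, dtype=float)
    events = np.asarray(death_events, dtype=bool)
    if values.shape != events.shape:
        raise ValueError("values and death_events must align")
    n_pos = int(events.sum())
    n_neg = int((~events).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: both outcome classes must be present")

    # AUC for score = -value via mid-ranks
    ranks = sps.rankdata(-values)
    auc = (ranks[events].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    uniq = np.unique(values)
    if uniq.size < 2:
        return CutoffModel(marker, compartment, "roc_youden", float(uniq[0]),
                           auc=float(auc), degenerate=True)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_j, best = -np.inf, None
    for c in candidates:
        sens = float((values[events] <= c).mean())
        spec = float((values[~events] > c).mean())
        j = sens + spec - 1.0
        if j > best_j:  # strict: first (lowest) cutoff wins ties
            best_j, best = j, (c, sens, spec)
    cutoff, sens, spec = best
    return CutoffModel(marker, compartment, "roc_youden", float(cutoff),
                       auc=float(auc), sensitivity=sens, specificity=spec)


def median_cutoff(values, marker: str = "", compartment: str = "") -> CutoffModel:
    """Median-split cutpoint; values equal to the median stratify low."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    cutoff = float(np.median(values))
    degenerate = bool(np.all(values == values[0]))
    return CutoffModel(marker, compartment, "median", cutoff, degenerate=degenerate)


# ---------------------------------------------------------------------------
# survival


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape or (times < 0).any():
        raise ValueError("times must be nonnegative and aligned with events")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events])
    at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    surv = np.empty(event_times.size)
    s = 1.0
    for i, t in enumerate(event_times):
        n_i = int((times >= t).sum())
        d_i = int((events & (times == t)).sum())
        s *= 1.0 - d_i / n_i
        at_risk[i], n_events[i], surv[i] = n_i, d_i, s
    return KMCurve(event_times, surv, at_risk, n_events,
                   censor_times=np.sort(times[~events]), n=times.size)


def logrank_test(times, events, group_labels) -> TestResult:
    """Standard two-group log-rank test.

    U = sum over event times of (observed - expected) deaths in group 1,
    V the hypergeometric variance; chi2 = U^2 / V on 1 df.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(group_labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError("log-rank requires exactly 2 non-empty groups")
    g1 = labels == levels[0]
    u = 0.0
    v = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int((events & (times == t)).sum())
        d1 = int((events & (times == t) & g1).sum())
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v <= 0:
        return TestResult(0.0, 1.0, "logrank", times.size, degenerate=True)
    chi2 = u * u / v
    return TestResult(float(chi2), float(sps.chi2.sf(chi2, 1)), "logrank", times.size)


def _cox_loglik(beta, times, events, x):
    """Efron partial log-likelihood with gradient and information matrix."""
    eta = x @ beta
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # descending time
    times_o, events_o, x_o, w_o = times[order], events[order], x[order], w[order]
    p = x.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    s0, s1, s2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    n = times_o.size
    while i < n:
        t = times_o[i]
        j = i
        while j < n and times_o[j] == t:
            s0 += w_o[j]
            s1 += w_o[j] * x_o[j]
            s2 += w_o[j] * np.outer(x_o[j], x_o[j])
            j += 1
        tied = np.flatnonzero(events_o[i:j]) + i
        d = tied.size
        if d:
            t0 = w_o[tied].sum()
            t1 = (w_o[tied, None] * x_o[tied]).sum(axis=0)
            t2 = np.einsum("i,ij,ik->jk", w_o[tied], x_o[tied], x_o[tied])
            ll += (x_o[tied] @ beta).sum()
            for ell in range(d):
                f = ell / d
                c0 = s0 - f * t0
                c1 = s1 - f * t1
                c2 = s2 - f * t2
                ll -= np.log(c0)
                grad_term = c1 / c0
                grad -= grad_term
                info += c2 / c0 - np.outer(grad_term, grad_term)
            grad += x_o[tied].sum(axis=0)
        i = j
    return ll, grad, info


def cox_fit(
    times,
    events,
    covariates,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
    focus: str | None = None,
) -> SurvivalFitResult:
    """Cox proportional-hazards fit by Newton-Raphson with Efron ties.

    ``covariates`` is a DataFrame or 2-D array (one column per covariate).
    Reported ``hazard_ratio`` / ``ci95`` / ``p_value`` refer to ``focus``
    (default: the first column), with Wald confidence intervals
    exp(beta +/- 1.96 se).  Non-convergence raises; runaway coefficients
    (complete separation) are flagged via ``warnings`` with
    ``converged=False``.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    if events.sum() < 1:
        raise ValueError("need at least one event")
    if any(np.ptp(x[:, k]) == 0 for k in range(x.shape[1])):
        raise ValueError("constant covariate")

    center = x.mean(axis=0)
    xc = x - center  # centering improves conditioning, leaves beta unchanged
    beta = np.zeros(x.shape[1])
    ll, grad, info = _cox_loglik(beta, times, events, xc)
    fit_warnings: list[str] = []
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            fit_warnings.append("singular information matrix")
            break
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_loglik(new_beta, times, events, xc)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_loglik(new_beta, times, events, xc)
            halvings += 1
        beta, grad, info = new_beta, new_grad, new_info
        if np.abs(beta).max() > 20.0:
            fit_warnings.append("divergent beta: possible complete separation")
            break
        if abs(new_ll - ll) < tol and np.abs(grad).max() < np.sqrt(tol):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged and not fit_warnings:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
    coefficients = {}
    _exp = lambda v: float(np.exp(np.clip(v, -700.0, 700.0)))  # noqa: E731
    for k, name in enumerate(names):
        b, s = float(beta[k]), float(se[k])
        z = b / s if s > 0 else np.nan
        coefficients[name] = {
            "beta": b,
            "se": s,
            "hr": _exp(b),
            "ci_low": _exp(b - 1.96 * s),
            "ci_high": _exp(b + 1.96 * s),
            "p": float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        }
    focus = focus if focus is not None else names[0]
    c = coefficients[focus]
    return SurvivalFitResult(
        hazard_ratio=c["hr"],
        ci95=(c["ci_low"], c["ci_high"]),
        p_value=c["p"],
        coefficients=coefficients,
        method="cox_univariate" if len(names) == 1 else "cox_adjusted",
        n=times.size,
        n_events=int(events.sum()),
        converged=converged,
        warnings=fit_warnings,
    )


# ---------------------------------------------------------------------------
# profiles, tertiles, percentages


def combine_profile(group_marker1: str, group_marker2: str) -> str | None:
    """Combine two high/low labels into a protein profile.

    Concordant labels give ``"high/high"`` or ``"low/low"``; discordant
    pairs are ``"mixed"`` (excluded from two-group profile comparisons);
    a missing label gives ``None``.
    """
    if group_marker1 not in ("high", "low") or group_marker2 not in ("high", "low"):
        return None
    if group_marker1 == group_marker2:
        return f"{group_marker1}/{group_marker1}"
    return "mixed"


def combine_profiles(groups1, groups2) -> np.ndarray:
    return np.array(
        [combine_profile(a, b) for a, b in zip(groups1, groups2)], dtype=object
    )


def tertile_split(ages) -> tuple[np.ndarray, bool]:
    """Split into tertile groups 0/1/2 at the 1/3 and 2/3 empirical
    quantiles; ties go to the lower group.  Returns (labels, degenerate)."""
    ages = np.asarray(ages, dtype=float)
    if ages.size < 3:
        raise ValueError("need at least 3 values")
    q1, q2 = np.quantile(ages, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(ages <= q1, 0, np.where(ages <= q2, 1, 2))
    return labels, bool(np.all(ages == ages[0]))


def percent_summary(count, total) -> float | np.ndarray:
    """100 * count / total, rounded half-up to one decimal."""
    from decimal import ROUND_HALF_UP, Decimal

    counts = np.atleast_1d(np.asarray(count))
    if total <= 0:
        raise ValueError("total must be positive")
    if (counts < 0).any() or (counts > total).any():
        raise ValueError("counts must lie in [0, total]")
    out = np.array(
        [
            float(
                (Decimal(int(c)) * 100 / Decimal(int(total))).quantize(
                    Decimal("0.1"), rounding=ROUND_HALF_UP
                )
            )
            for c in counts
        ]
    )
    return float(out[0]) if np.isscalar(count) or np.asarray(count).ndim == 0 else out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out
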