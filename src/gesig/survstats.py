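"""Survival and rank statistics: Kaplan-Meier, log-rank, two-group Cox HR,
Harrell's C-index, per-gene univariate Cox screens, Spearman and Wilcoxon.

All estimators are implemented directly from their defining formulas (Breslow
tie handling throughout) so that every downstream analysis number is
traceable to an explicit computation; mainstream survival libraries serve as
independent cross-checks in the test suite, not as the implementation.

Conventions: at a tied time, events precede censorings (a subject censored at
t is still at risk for the events at t); Wald 95% intervals use
z = 1.959964; all p-values are two-sided.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .cohort import Cohort, _check_endpoint

_Z95 = 1.959964


class StatisticsError(ValueError):
    """Raised when a statistic's preconditions are violated."""


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit estimate of a survival function.

    ``times`` holds the distinct event times; ``survival[k]`` is S(t) just
    after ``times[k]``.  ``censor_times`` records censoring marks for
    plotting.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censor_times: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        k = np.searchsorted(self.times, t, side="right")
        return 1.0 if k == 0 else float(self.survival[k - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def kaplan_meier(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise StatisticsError("empty sample")
    if (t <= 0).any():
        raise StatisticsError("times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in uniq], dtype=int)
    d = np.array([((t == u) & (e == 1)).sum() for u in uniq], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(
        times=uniq,
        survival=surv,
        at_risk=at_risk,
        events=d,
        censor_times=np.sort(t[e == 0]),
        n=int(t.size),
    )


# ---------------------------------------------------------------------------
# log-rank


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    variance: float


def logrank_test(time_a, event_a, time_b, event_b) -> LogRankResult:
    """Two-group unweighted (Mantel-Haenszel) log-rank test, 1 df."""
    ta, ea = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, int)
    if ta.size == 0 or tb.size == 0:
        raise StatisticsError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise StatisticsError("log-rank requires at least one event")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    uniq = np.unique(t[e == 1])
    o_a = e_a_exp = var = 0.0
    for u in uniq:
        at_risk = t >= u
        n_tot = at_risk.sum()
        n_a = (at_risk & (g == 0)).sum()
        d = ((t == u) & (e == 1)).sum()
        d_a = ((t == u) & (e == 1) & (g == 0)).sum()
        o_a += d_a
        e_a_exp += d * n_a / n_tot
        if n_tot > 1:
            var += d * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d) / (n_tot - 1)
    o_total = float(ea.sum() + eb.sum())
    if var == 0:
        chi2 = 0.0
    else:
        chi2 = (o_a - e_a_exp) ** 2 / var
    p = float(_st.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return LogRankResult(
        chi_square=float(chi2),
        p_value=p,
        observed=(float(o_a), o_total - float(o_a)),
        expected=(float(e_a_exp), o_total - float(e_a_exp)),
        variance=float(var),
    )


# ---------------------------------------------------------------------------
# one-covariate Cox (Breslow)


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    log_hr: float
    se: float | None
    n_per_group: dict[str, int] | None = None
    events_per_group: dict[str, int] | None = None
    diverged: bool = False


def _cox1_loglik_parts(beta: float, x, t, e):
    """Breslow log partial likelihood, score and information for one covariate."""
    order = np.argsort(t, kind="stable")
    x, t, e = x[order], t[order], e[order]
    w = np.exp(beta * x)
    uniq = np.unique(t[e == 1])
    ll = score = info = 0.0
    for u in uniq:
        risk = t >= u
        s0 = w[risk].sum()
        s1 = (w[risk] * x[risk]).sum()
        s2 = (w[risk] * x[risk] ** 2).sum()
        ev = (t == u) & (e == 1)
        d = ev.sum()
        ll += beta * x[ev].sum() - d * math.log(s0)
        score += x[ev].sum() - d * s1 / s0
        info += d * (s2 / s0 - (s1 / s0) ** 2)
    return ll, score, info


def _cox_newton_1d(x, t, e, max_iter: int = 60, tol: float = 1e-10):
    """Newton-Raphson MLE of a single-covariate Breslow Cox model.

    Returns (beta, se, loglik, diverged).  Monotone likelihood (the score
    never vanishes on any finite beta) is reported via the diverged flag.
    """
    x = np.asarray(x, float)
    t = np.asarray(t, float)
    e = np.asarray(e, int)
    if e.sum() == 0:
        raise StatisticsError("Cox model requires at least one event")
    if np.ptp(x) == 0:
        raise StatisticsError("covariate has zero variance")
    beta = 0.0
    for _ in range(max_iter):
        ll, score, info = _cox1_loglik_parts(beta, x, t, e)
        if info <= 1e-12:
            return beta, None, ll, True
        step = score / info
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(beta) > 15.0:
            return beta, None, ll, True
        if abs(step) < tol:
            break
    ll, score, info = _cox1_loglik_parts(beta, x, t, e)
    se = 1.0 / math.sqrt(info) if info > 0 else None
    return beta, se, ll, se is None


def cox_hr_two_group(group, time, event) -> HazardRatioResult:
    """Unstratified two-group Cox hazard ratio with Wald 95% CI and p-value.

    ``group`` is a boolean/0-1 array or label array with exactly two levels;
    the hazard ratio is for the second (True / "high") level versus the
    first.
    """
    g = np.asarray(group)
    if g.dtype.kind in "b":
        x = g.astype(float)
        labels = ("low", "high")
    elif g.dtype.kind in "iuf":
        levels = np.unique(g)
        if levels.size != 2:
            raise StatisticsError("group must have exactly two levels")
        x = (g == levels[1]).astype(float)
        labels = (str(levels[0]), str(levels[1]))
    else:
        levels = sorted(set(map(str, g)))
        if len(levels) != 2:
            raise StatisticsError("group must have exactly two levels")
        # conventional ordering: "low" is reference when present
        if set(levels) == {"high", "low"}:
            levels = ["low", "high"]
        x = (np.asarray([str(v) for v in g]) == levels[1]).astype(float)
        labels = (levels[0], levels[1])
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if x.sum() == 0 or x.sum() == x.size:
        raise StatisticsError("both groups must be non-empty")
    beta, se, _, diverged = _cox_newton_1d(x, t, e)
    n_per = {labels[0]: int((x == 0).sum()), labels[1]: int((x == 1).sum())}
    ev_per = {
        labels[0]: int(e[x == 0].sum()),
        labels[1]: int(e[x == 1].sum()),
    }
    if diverged or se is None:
        return HazardRatioResult(
            hr=float(np.exp(beta)), ci_low=None, ci_high=None, p_value=None,
            log_hr=float(beta), se=None, n_per_group=n_per,
            events_per_group=ev_per, diverged=True,
        )
    z = beta / se
    return HazardRatioResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        p_value=float(2 * _st.norm.sf(abs(z))),
        log_hr=float(beta),
        se=float(se),
        n_per_group=n_per,
        events_per_group=ev_per,
        diverged=False,
    )


def cox_hr_continuous(x, time, event) -> HazardRatioResult:
    """One-covariate Cox fit for a continuous predictor (HR per unit)."""
    x = np.asarray(x, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    beta, se, _, diverged = _cox_newton_1d(x, t, e)
    if diverged or se is None:
        return HazardRatioResult(
            hr=float(np.exp(beta)), ci_low=None, ci_high=None, p_value=None,
            log_hr=float(beta), se=None, diverged=True,
        )
    z = beta / se
    return HazardRatioResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        p_value=float(2 * _st.norm.sf(abs(z))),
        log_hr=float(beta),
        se=float(se),
        diverged=False,
    )


# ---------------------------------------------------------------------------
# concordance


def concordance_index(linear_predictor, time, event) -> float:
    """Harrell's C over usable pairs (the earlier time is an observed event).

    A pair (i, j) with t_i < t_j and event_i = 1 is usable; it is concordant
    when the subject with the shorter time carries the higher risk predictor.
    Predictor ties count 0.5.  Pairs tied on time are not used.
    """
    lp = np.asarray(linear_predictor, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if t.size < 2:
        raise StatisticsError("need at least two subjects")
    dt = t[:, None] < t[None, :]
    usable = dt & (e[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise StatisticsError("no usable pairs under censoring")
    higher = lp[:, None] > lp[None, :]
    tied = lp[:, None] == lp[None, :]
    conc = (usable & higher).sum() + 0.5 * (usable & tied).sum()
    return float(conc / n_usable)


# ---------------------------------------------------------------------------
# univariate gene screen


def univariate_gene_screen(
    cohort: Cohort, endpoint: str, mode: str = "median_split", min_samples: int = 10
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene one-covariate Cox screen against one endpoint.

    ``median_split`` dichotomizes each gene at its median (> median = high)
    and reports the high-vs-low hazard ratio; ``continuous`` fits the
    standardized expression directly.  Zero-variance genes are skipped and
    listed.  Returns (table, skipped_genes).
    """
    _check_endpoint(endpoint)
    if mode not in ("continuous", "median_split"):
        raise ValueError(f"unknown screen mode {mode!r}")
    mask, t, e = cohort.clinical.endpoint_arrays(endpoint)
    if mask.sum() < min_samples:
        raise StatisticsError(
            f"endpoint {endpoint} available for only {int(mask.sum())} samples"
        )
    values = cohort.expression.values[:, mask]
    rows = []
    skipped: list[str] = []
    for i, gene in enumerate(cohort.expression.gene_ids):
        x = values[i]
        if np.ptp(x) == 0:
            skipped.append(gene)
            continue
        try:
            if mode == "median_split":
                high = x > np.median(x)
                if high.all() or not high.any():
                    skipped.append(gene)
                    continue
                res = cox_hr_two_group(high, t, e)
            else:
                xs = (x - x.mean()) / x.std()
                res = cox_hr_continuous(xs, t, e)
        except StatisticsError:
            skipped.append(gene)
            continue
        rows.append(
            {
                "gene_id": gene,
                "mode": mode,
                "hr": res.hr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "n": int(mask.sum()),
                "events": int(e.sum()),
                "diverged": res.diverged,
            }
        )
    if skipped:
        warnings.warn(
            f"univariate screen skipped {len(skipped)} gene(s) with no usable split",
            stacklevel=2,
        )
    return pd.DataFrame(rows), skipped


# ---------------------------------------------------------------------------
# rank statistics


def spearman_correlation(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman's rho as Pearson correlation of mid-ranks.

    The p-value uses exact permutation enumeration for n <= ``exact_max_n``
    and the t approximation on n - 2 df otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n != y.size or n < 3:
        raise StatisticsError("need paired samples with n >= 3")
    rx = _st.rankdata(x)
    ry = _st.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # permutation null of the rank pairing
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        obs = abs(np.dot(rx_c, ry_c))
        count = total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(np.dot(rx_c, ry_c[list(perm)]))
            count += stat >= obs - 1e-12 * denom
            total += 1
        p = count / total
    else:
        tstat = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho ** 2))
        p = float(2 * _st.t.sf(abs(tstat), df=n - 2))
    return rho, min(1.0, float(p))


def wilcoxon_rank_sum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (rank-sum of ``x`` using mid-ranks, two-sided p).  ``exact``
    enumerates all group assignments of the observed ranks (symmetric null);
    ``normal`` uses the tie-corrected normal approximation with continuity
    correction.  ``auto`` picks exact when n_x + n_y <= 12 without ties.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise StatisticsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n = nx + ny
    ranks = _st.rankdata(pooled)
    w = float(ranks[:nx].sum())
    has_ties = np.unique(pooled).size < n
    if method == "auto":
        method = "exact" if (n <= 12 and not has_ties) else "normal"
    if method == "exact":
        mu = nx * (n + 1) / 2.0
        obs_dev = abs(w - mu)
        count = total = 0
        for combo in itertools.combinations(range(n), nx):
            ws = ranks[list(combo)].sum()
            count += abs(ws - mu) >= obs_dev - 1e-12
            total += 1
        p = count / total
    elif method == "normal":
        mu = nx * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return w, 1.0
        dev = abs(w - mu)
        z = max(0.0, dev - 0.5) / math.sqrt(var)
        p = float(2 * _st.norm.sf(z))
    else:
        raise ValueError(f"unknown method {method!r}")
    return w, min(1.0, float(p))
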