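"""Pre-specified trial statistics.

Rank-based comparison of the primary endpoint (Mann-Whitney U with a
Hodges-Lehmann shift estimate and test-inversion CI), count-rate
comparison of consult frequencies (Poisson log-linear regression with a
negative-binomial fallback under overdispersion), time-to-event analysis
of OMT (Cox partial likelihood with Breslow ties, cumulative incidence),
2x2 chi-square safety counts, subgroup/interaction analysis, net promoter
score classification, and the design-stage noncentral-t power and sample
size calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, EstimationError

__all__ = [
    "EffectEstimate",
    "SubgroupResult",
    "NPSummary",
    "RateRatioResult",
    "HazardRatioResult",
    "mann_whitney",
    "hodges_lehmann",
    "rank_sum_effect",
    "chi_square_2x2",
    "consult_rate_test",
    "cox_time_to_omt",
    "cumulative_incidence",
    "subgroup_analysis",
    "interaction_test",
    "nps_summary",
    "power_two_group_t",
    "sample_size_two_group_t",
    "mc_power_two_group_t",
    "enrollment_with_dropout",
    "percent",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class EffectEstimate:
    """Two-group rank analysis of one endpoint.

    ``shift`` is the Hodges-Lehmann estimate of the treatment-minus-control
    location shift (the median of all pairwise differences), with a CI from
    inverting the Wilcoxon rank-sum test; it is generally not equal to the
    difference of the group medians, which is exposed separately.
    """

    median_a: float
    iqr_a: tuple
    median_b: float
    iqr_b: tuple
    shift: float
    ci_low: float
    ci_high: float
    p_value: float
    n_a: int
    n_b: int

    @property
    def median_difference(self) -> float:
        return self.median_b - self.median_a

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.shift <= self.ci_high):
            raise EstimationError("CI must contain the point estimate")
        if not 0.0 <= self.p_value <= 1.0:
            raise EstimationError("p-value outside [0, 1]")


@dataclass(frozen=True)
class SubgroupResult:
    label: str
    effect_in: EffectEstimate
    effect_out: EffectEstimate
    se_in: float
    se_out: float
    interaction_t: float
    interaction_p: float


@dataclass(frozen=True)
class NPSummary:
    promoters: int
    passives: int
    detractors: int
    nps: float  # percentage points in [-100, 100]
    mean_score: float

    @property
    def n(self) -> int:
        return self.promoters + self.passives + self.detractors


@dataclass(frozen=True)
class RateRatioResult:
    rate_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    model_used: str  # "poisson" | "negative_binomial"
    dispersion: float  # Pearson chi2 / df of the Poisson fit


@dataclass(frozen=True)
class HazardRatioResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    log_hr: float
    se: float
    n_events: int


# ---------------------------------------------------------------------------
# Mann-Whitney / Hodges-Lehmann

#: largest n_x * n_y for which the exact null distribution is used
EXACT_LIMIT = 400


def _u_null_pmf(n: int, m: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic for sample sizes n, m.

    Counts, for each u, the number of ways u can arise as the number of
    (x, y) pairs with y < x under random labelling (partitions of u into
    at most m parts each <= n), normalized by C(n+m, m).
    """
    # Gaussian binomial [n+m, m]_q = prod_{j=1..m} (1 - q^{n+j}) / (1 - q^j)
    size = n * m + 1
    counts = np.zeros(size)
    counts[0] = 1.0
    for j in range(1, m + 1):
        new = counts.copy()
        if n + j < size:  # multiply by (1 - q^{n+j})
            new[n + j :] -= counts[: size - n - j]
        for u in range(j, size):  # divide by (1 - q^j)
            new[u] += new[u - j]
        counts = new
    return counts / counts.sum()


def _tie_corrected_sigma(n: int, m: int, combined: np.ndarray) -> float:
    nn = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n * m / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
    return math.sqrt(max(var, 0.0))


def mann_whitney(x: Sequence, y: Sequence, method: str = "auto") -> tuple:
    """Two-sided Mann-Whitney U test; returns ``(U, p)``.

    ``U`` counts pairs ``(x_i, y_j)`` with ``x_i > y_j`` (+1/2 per tie),
    i.e. the statistic of the first sample.  ``method`` is ``"exact"``
    (enumeration of the null distribution; requires no ties),
    ``"asymptotic"`` (normal approximation with tie correction and
    continuity correction), or ``"auto"``: exact when
    ``n_x * n_y <= 400`` and the data are tie-free, else asymptotic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EstimationError("both samples must be non-empty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    diff = x[:, None] - y[None, :]
    u = float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))

    if method == "auto":
        method = "exact" if (n * m <= EXACT_LIMIT and not has_ties) else "asymptotic"
    if method == "exact":
        if has_ties:
            raise EstimationError("exact method requires tie-free data")
        pmf = _u_null_pmf(n, m)
        k = int(round(u))
        # two-sided: double the smaller tail (symmetric null)
        tail = min(pmf[: k + 1].sum(), pmf[k:].sum())
        return u, float(min(1.0, 2.0 * tail))
    if method != "asymptotic":
        raise ConfigError(f"unknown method {method!r}")
    sigma = _tie_corrected_sigma(n, m, combined)
    if sigma == 0.0:  # every value identical
        return u, 1.0
    mean = n * m / 2.0
    z = (abs(u - mean) - 0.5) / sigma  # continuity corrected, toward the null
    z = max(z, 0.0)
    return u, float(min(1.0, 2.0 * sps.norm.sf(z)))


def hodges_lehmann(x: Sequence, y: Sequence, alpha: float = 0.05) -> tuple:
    """Hodges-Lehmann shift of ``y`` relative to ``x`` with a rank-sum CI.

    Returns ``(shift, ci_low, ci_high)``: the median of all pairwise
    differences ``y_j - x_i`` and the confidence interval obtained by
    inverting the Wilcoxon rank-sum test at level ``alpha`` (exact null
    distribution when ``n*m <= 400``, normal approximation otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EstimationError("both samples must be non-empty")
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must be in (0, 1)")
    n, m = x.size, y.size
    diffs = np.sort((y[None, :] - x[:, None]).ravel())
    nm = n * m
    shift = float(np.median(diffs))
    # invert the size-(2 P(U <= c)) test "reject iff U <= c or U >= nm - c":
    # the non-rejection set in the shift is [D_(c+1), D_(nm-c)] (1-based)
    if nm <= EXACT_LIMIT:
        cdf = np.cumsum(_u_null_pmf(n, m))
        # largest c with P(U <= c) <= alpha/2
        c = int(np.searchsorted(cdf, alpha / 2.0, side="right")) - 1
    else:
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        sigma = math.sqrt(nm * (n + m + 1) / 12.0)
        c = int(math.floor(nm / 2.0 - z * sigma - 0.5))  # continuity corrected
    if c < 0:  # too few pairs to reject at this level: CI is the full span
        return shift, float(diffs[0]), float(diffs[-1])
    lo_idx = min(c, nm - 1)
    hi_idx = max(nm - c - 1, 0)
    if lo_idx > hi_idx:
        lo_idx, hi_idx = hi_idx, lo_idx
    return shift, float(diffs[lo_idx]), float(diffs[hi_idx])


def _iqr(v: np.ndarray) -> tuple:
    return (float(np.percentile(v, 25)), float(np.percentile(v, 75)))


def rank_sum_effect(control: Sequence, treatment: Sequence,
                    alpha: float = 0.05, method: str = "auto") -> EffectEstimate:
    """Full rank analysis of one endpoint: medians/IQRs, HL shift + CI, p."""
    control = np.asarray(control, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    _, p = mann_whitney(treatment, control, method=method)
    shift, lo, hi = hodges_lehmann(control, treatment, alpha=alpha)
    # inversion CI and the midrank point estimate can disagree by a grid
    # step in tiny samples; clamp so the interval always brackets the point
    lo, hi = min(lo, shift), max(hi, shift)
    return EffectEstimate(
        median_a=float(np.median(control)), iqr_a=_iqr(control),
        median_b=float(np.median(treatment)), iqr_b=_iqr(treatment),
        shift=shift, ci_low=lo, ci_high=hi, p_value=p,
        n_a=int(control.size), n_b=int(treatment.size),
    )


# ---------------------------------------------------------------------------
# counts and rates


def chi_square_2x2(a: int, b: int, c: int, d: int,
                   continuity: bool = False) -> tuple:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]]; returns (stat, p).

    No continuity correction by default; set ``continuity=True`` for Yates.
    """
    if min(a, b, c, d) < 0:
        raise EstimationError("cell counts must be >= 0")
    n = a + b + c + d
    if n == 0:
        raise EstimationError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise EstimationError("zero margin: chi-square undefined")
    num = abs(a * d - b * c)
    if continuity:
        num = max(0.0, num - n / 2.0)
    stat = n * num**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(stat), float(sps.chi2.sf(stat, df=1))


#: Pearson dispersion (chi2/df) above which the negative binomial is used
OVERDISPERSION_THRESHOLD = 1.5


def consult_rate_test(counts_a: Sequence, counts_b: Sequence,
                      alpha: float = 0.05,
                      dispersion_threshold: float = OVERDISPERSION_THRESHOLD,
                      ) -> RateRatioResult:
    """Between-arm comparison of per-patient event counts.

    Fits a Poisson log-linear model with an arm indicator (b vs a); if the
    Pearson dispersion statistic per degree of freedom exceeds
    ``dispersion_threshold``, refits a negative binomial model (dispersion
    estimated by maximum likelihood) and reports that instead.
    """
    import statsmodels.api as sm

    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.size == 0 or counts_b.size == 0:
        raise EstimationError("both arms must be non-empty")
    if np.any(counts_a < 0) or np.any(counts_b < 0):
        raise EstimationError("counts must be non-negative")
    if counts_a.sum() == 0 and counts_b.sum() == 0:
        raise EstimationError("all counts zero: rate ratio degenerate")
    yv = np.concatenate([counts_a, counts_b])
    X = sm.add_constant(
        np.concatenate([np.zeros(counts_a.size), np.ones(counts_b.size)])
    )
    pois = sm.GLM(yv, X, family=sm.families.Poisson()).fit()
    dispersion = float(pois.pearson_chi2 / pois.df_resid)
    if dispersion > dispersion_threshold:
        nb = sm.NegativeBinomial(yv, X).fit(disp=False, maxiter=200)
        beta, se = float(nb.params[1]), float(nb.bse[1])
        p = float(nb.pvalues[1])
        model = "negative_binomial"
    else:
        beta, se = float(pois.params[1]), float(pois.bse[1])
        p = float(pois.pvalues[1])
        model = "poisson"
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    return RateRatioResult(
        rate_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=p, model_used=model, dispersion=dispersion,
    )


# ---------------------------------------------------------------------------
# time to event


def cox_time_to_omt(times: Sequence, events: Sequence, arm: Sequence,
                    alpha: float = 0.05, max_iter: int = 50,
                    tol: float = 1e-10) -> HazardRatioResult:
    """Cox proportional-hazards fit for a single binary covariate.

    Maximizes the Breslow partial likelihood by Newton-Raphson and returns
    the hazard ratio (arm = 1 vs 0) with Wald CI and p-value.  Degenerate
    configurations (no events, or events confined to one arm, which makes
    the likelihood monotone) raise :class:`EstimationError`.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    z = np.asarray(arm, dtype=float)
    if not np.all((z == 0) | (z == 1)):
        raise EstimationError("arm must be binary 0/1")
    if np.any(t <= 0):
        raise EstimationError("event/censoring times must be > 0")
    if e.sum() == 0:
        raise EstimationError("no events: hazard ratio not estimable")
    if e[z == 1].sum() == 0 or e[z == 0].sum() == 0:
        raise EstimationError(
            "all events in one arm: monotone partial likelihood, no finite MLE"
        )

    event_times = np.unique(t[e])
    # per event time: number of events d, covariate sum s, risk-set sizes
    d = np.empty(event_times.size)
    s = np.empty(event_times.size)
    r1 = np.empty(event_times.size)  # arm-1 subjects at risk
    r0 = np.empty(event_times.size)
    for i, et in enumerate(event_times):
        at_event = e & (t == et)
        at_risk = t >= et
        d[i] = at_event.sum()
        s[i] = z[at_event].sum()
        r1[i] = z[at_risk].sum()
        r0[i] = (1.0 - z[at_risk]).sum()

    beta = 0.0
    for _ in range(max_iter):
        w = r1 * math.exp(beta)
        denom = w + r0
        mu = w / denom
        grad = float(np.sum(s - d * mu))
        hess = float(-np.sum(d * mu * (1.0 - mu)))
        if hess == 0.0:
            raise EstimationError("flat partial likelihood")
        step = grad / hess
        beta -= step
        if abs(beta) > 50:
            raise EstimationError("Cox estimate diverged (monotone likelihood)")
        if abs(step) < tol:
            break
    w = r1 * math.exp(beta)
    mu = w / (w + r0)
    info = float(np.sum(d * mu * (1.0 - mu)))
    if info <= 0:
        raise EstimationError("singular information")
    se = 1.0 / math.sqrt(info)
    zcrit = sps.norm.ppf(1.0 - alpha / 2.0)
    return HazardRatioResult(
        hazard_ratio=float(math.exp(beta)),
        ci_low=float(math.exp(beta - zcrit * se)),
        ci_high=float(math.exp(beta + zcrit * se)),
        p_value=float(2.0 * sps.norm.sf(abs(beta) / se)),
        log_hr=float(beta), se=se, n_events=int(e.sum()),
    )


def cumulative_incidence(times: Sequence, events: Sequence,
                         alpha: float = 0.05) -> pd.DataFrame:
    """1 - Kaplan-Meier with Greenwood-based pointwise CIs.

    Returns a step-function table with columns ``time``, ``incidence``,
    ``ci_low``, ``ci_high``; incidence is non-decreasing in time.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    km = KaplanMeierFitter(alpha=alpha)
    km.fit(t, event_observed=e)
    surv = km.survival_function_.iloc[:, 0]
    ci = km.confidence_interval_survival_function_
    out = pd.DataFrame({
        "time": surv.index.to_numpy(dtype=float),
        "incidence": 1.0 - surv.to_numpy(),
        "ci_low": 1.0 - ci.iloc[:, 1].to_numpy(),
        "ci_high": 1.0 - ci.iloc[:, 0].to_numpy(),
    })
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# subgroups


def interaction_test(effect1: float, se1: float,
                     effect2: float, se2: float) -> tuple:
    """t statistic for effect heterogeneity against pooled standard errors.

    ``t = (effect1 - effect2) / sqrt(se1^2 + se2^2)``; the two-sided p-value
    uses the large-sample normal reference.
    """
    if se1 <= 0 or se2 <= 0:
        raise EstimationError("standard errors must be > 0")
    tstat = (effect1 - effect2) / math.sqrt(se1**2 + se2**2)
    return float(tstat), float(2.0 * sps.norm.sf(abs(tstat)))


def _bootstrap_hl_se(control: np.ndarray, treatment: np.ndarray,
                     n_boot: int, rng: np.random.Generator) -> float:
    reps = np.empty(n_boot)
    for b in range(n_boot):
        cb = rng.choice(control, size=control.size, replace=True)
        tb = rng.choice(treatment, size=treatment.size, replace=True)
        reps[b] = np.median((tb[None, :] - cb[:, None]).ravel())
    return float(reps.std(ddof=1))


def subgroup_analysis(data: pd.DataFrame, endpoint: str, arm: str,
                      splits: dict, n_boot: int = 1000,
                      seed: Optional[int] = None,
                      alpha: float = 0.05) -> list:
    """Effect-in vs effect-out analysis for each binary covariate split.

    ``splits`` maps a label to a boolean column (or boolean array aligned
    with ``data``); patients where the split is True form the "in" group.
    The effect per subgroup is the Hodges-Lehmann shift; its SE comes from
    a seeded nonparametric bootstrap; heterogeneity is assessed with
    :func:`interaction_test`.  Subgroups with fewer than two patients per
    arm in either half are skipped.
    """
    rng = np.random.default_rng(seed)
    arms = data[arm].to_numpy()
    y = data[endpoint].to_numpy(dtype=float)
    treat = arms == "DC"
    results = []
    for label, split in splits.items():
        mask = (data[split].to_numpy(dtype=bool) if isinstance(split, str)
                else np.asarray(split, dtype=bool))
        halves = {}
        ok = True
        for name, sel in (("in", mask), ("out", ~mask)):
            c = y[sel & ~treat]
            tr = y[sel & treat]
            if c.size < 2 or tr.size < 2:
                ok = False
                break
            eff = rank_sum_effect(c, tr, alpha=alpha)
            se = _bootstrap_hl_se(c, tr, n_boot, rng)
            halves[name] = (eff, se)
        if not ok:
            continue
        (eff_in, se_in), (eff_out, se_out) = halves["in"], halves["out"]
        try:
            tstat, p = interaction_test(eff_in.shift, se_in, eff_out.shift, se_out)
        except EstimationError:  # degenerate endpoint: zero bootstrap SE
            tstat, p = float("nan"), float("nan")
        results.append(SubgroupResult(
            label=label, effect_in=eff_in, effect_out=eff_out,
            se_in=se_in, se_out=se_out,
            interaction_t=tstat, interaction_p=p,
        ))
    return results


# ---------------------------------------------------------------------------
# NPS


def nps_summary(scores: Sequence) -> NPSummary:
    """Classify 1-10 ratings: promoters 9-10, passives 7-8, detractors <= 6."""
    scores = np.asarray(scores, dtype=int)
    if scores.size == 0:
        raise EstimationError("empty score list")
    if np.any((scores < 1) | (scores > 10)):
        raise EstimationError("scores must be integers in 1..10")
    promoters = int(np.sum(scores >= 9))
    passives = int(np.sum((scores >= 7) & (scores <= 8)))
    detractors = int(np.sum(scores <= 6))
    n = scores.size
    return NPSummary(
        promoters=promoters, passives=passives, detractors=detractors,
        nps=100.0 * (promoters - detractors) / n,
        mean_score=float(scores.mean()),
    )


# ---------------------------------------------------------------------------
# design: power and sample size


def power_two_group_t(n_per_arm: int, delta: float, sd: float,
                      alpha: float = 0.05) -> float:
    """Exact power of the two-sided equal-n two-sample t-test (noncentral t)."""
    if n_per_arm < 2:
        raise EstimationError("need at least 2 per arm to fit a t-test")
    if sd <= 0 or delta == 0:
        raise ConfigError("sd must be > 0 and delta nonzero")
    df = 2 * n_per_arm - 2
    nc = abs(delta) / (sd * math.sqrt(2.0 / n_per_arm))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_two_group_t(delta: float, sd: float, power: float = 0.8,
                            alpha: float = 0.05, n_max: int = 1_000_000) -> int:
    """Smallest equal n per arm at which the two-sided t-test attains ``power``."""
    if delta <= 0 or sd <= 0:
        raise ConfigError("delta and sd must be > 0")
    if not 0.0 < power < 1.0:
        raise ConfigError("power must be in (0, 1)")
    # normal-approximation head start, then exact noncentral-t search
    z = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(power)
    n = max(2, int(math.floor(2.0 * (z * sd / delta) ** 2)) - 2)
    while n <= n_max:
        if power_two_group_t(n, delta, sd, alpha) >= power:
            while n > 2 and power_two_group_t(n - 1, delta, sd, alpha) >= power:
                n -= 1
            return n
        n += 1
    raise EstimationError(f"no n <= {n_max} attains power {power}")


def mc_power_two_group_t(n_per_arm: int, delta: float, sd: float,
                         alpha: float = 0.05, n_reps: int = 5000,
                         seed: Optional[int] = None) -> float:
    """Monte-Carlo rejection fraction of the two-sample t-test under the
    design alternative (two normal samples, means ``delta`` apart)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(n_reps, n_per_arm))
    b = rng.normal(delta, sd, size=(n_reps, n_per_arm))
    res = sps.ttest_ind(a, b, axis=1)
    return float(np.mean(res.pvalue < alpha))


def enrollment_with_dropout(n_per_arm: int, dropout_fraction: float) -> int:
    """Total enrolment covering ``n_per_arm`` evaluable per arm after dropout.

    Ceiling of ``2 n / (1 - dropout)``, rounded up to the next even integer
    so the 1:1 allocation stays balanced.
    """
    if not 0.0 <= dropout_fraction < 1.0:
        raise ConfigError("dropout fraction must be in [0, 1)")
    total = math.ceil(2 * n_per_arm / (1.0 - dropout_fraction))
    return total + (total % 2)


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage as printed in trial tables (one decimal by default)."""
    if total <= 0:
        raise EstimationError("total must be > 0")
    return round(100.0 * count / total, decimals)
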