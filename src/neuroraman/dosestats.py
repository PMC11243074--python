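"""Calcium-trace and dose-response statistics.

Covers the read-outs used alongside the spectral classification:

* ΔF/F analysis of calcium-indicator traces against the pre-stimulus
  baseline, and the "responder" rule (a cell responds if its post-stimulus
  fluorescence exceeds 1.5-fold of baseline, strict inequality);
* Student's (pooled-variance) two-sample t-test and classical one-way
  ANOVA;
* a Williams-type step-down trend test of ordered dose groups against the
  zero-dose control, built on isotonic (pooled-adjacent-violators) mean
  estimates with Monte-Carlo critical values;
* Tukey's HSD, delegated to :func:`scipy.stats.tukey_hsd` behind the same
  report interface.

The Williams statistic for dose i is ``t̄ᵢ = (μ̂ᵢ − ȳ₀) / sqrt(s²(1/nᵢ +
1/n₀))`` with μ̂ᵢ the isotonic estimate of the i-th treatment mean and s²
the ANOVA within-group variance.  Critical values are obtained by
simulating the null (equal normal means, the same n-structure, the same
isotonic procedure) rather than from printed tables, which cover only a few
(k, n) combinations; the simulation is seeded and the per-dose rejection
rate is calibrated to alpha by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from neuroraman.exceptions import InvalidParameterError

__all__ = [
    "CalciumTrace",
    "DeltaFResult",
    "DoseGroups",
    "WilliamsTrendResults",
    "delta_f_over_f",
    "responder_fraction",
    "two_sample_t",
    "one_way_anova",
    "pava",
    "williams_critical_values",
    "williams_trend_test",
    "tukey_hsd",
]


@dataclass
class CalciumTrace:
    """One calcium-indicator fluorescence time series.

    ``baseline_window`` holds the frame indices used as the pre-stimulus
    baseline; by default, every frame strictly before ``stim_time_s``.
    """

    time_s: np.ndarray
    fluorescence_au: np.ndarray
    stim_time_s: float
    baseline_window: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence_au = np.asarray(self.fluorescence_au, dtype=float)
        if self.time_s.shape != self.fluorescence_au.shape or self.time_s.ndim != 1:
            raise InvalidParameterError("time and fluorescence must be matching 1-D arrays")
        if np.any(np.diff(self.time_s) <= 0):
            raise InvalidParameterError("time axis must be strictly increasing")
        if not self.time_s[0] <= self.stim_time_s <= self.time_s[-1]:
            raise InvalidParameterError("stimulation time must lie inside the record")
        if np.any(self.fluorescence_au <= 0):
            raise InvalidParameterError("fluorescence must be positive")
        if self.baseline_window is None:
            self.baseline_window = np.flatnonzero(self.time_s < self.stim_time_s)
        else:
            self.baseline_window = np.asarray(self.baseline_window, dtype=int)
        if len(self.baseline_window) == 0:
            raise InvalidParameterError("baseline window is empty")


@dataclass
class DeltaFResult:
    """Per-frame ΔF/F of one trace plus its scalar summaries."""

    dff: np.ndarray             # (F(t) − F) / F per frame
    baseline_f: float           # F: mean fluorescence over the baseline window
    peak_fold: float            # max post-stimulus F(t) / F
    peak_dff: float             # max post-stimulus ΔF/F (= peak_fold − 1)
    mean_post_ratio: float      # mean post-stimulus F(t) / F


def delta_f_over_f(trace: CalciumTrace) -> DeltaFResult:
    """Relative fluorescence change against the pre-stimulus baseline.

    F is the mean fluorescence over the baseline window; ΔF(t) = F(t) − F.
    The summary fold is the maximum post-stimulus F(t)/F.
    """
    f0 = float(np.mean(trace.fluorescence_au[trace.baseline_window]))
    if f0 <= 0:
        raise InvalidParameterError("baseline fluorescence must be positive")
    dff = (trace.fluorescence_au - f0) / f0
    post = trace.time_s >= trace.stim_time_s
    ratios = trace.fluorescence_au[post] / f0
    return DeltaFResult(dff=dff, baseline_f=f0,
                        peak_fold=float(np.max(ratios)),
                        peak_dff=float(np.max(ratios) - 1.0),
                        mean_post_ratio=float(np.mean(ratios)))


def responder_fraction(traces, fold_threshold: float = 1.5) -> float:
    """Percentage of cells whose post-stimulus fold exceeds the threshold.

    Strict inequality: a fold of exactly 1.5 does not count as a response.
    """
    traces = list(traces)
    if not traces:
        raise InvalidParameterError("need at least one trace")
    n_resp = sum(delta_f_over_f(t).peak_fold > fold_threshold for t in traces)
    return 100.0 * n_resp / len(traces)


# ---------------------------------------------------------------------------
# classical tests


def two_sample_t(group_a, group_b) -> dict:
    """Student's pooled-variance two-sided t-test.

    Returns ``{"t", "p", "df"}``.  Degenerate inputs (zero pooled variance)
    yield p = 1 for equal means and p = 0 (flagged) for unequal means
    rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("both groups need n >= 2")
    df = len(a) + len(b) - 2
    pooled = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
    if pooled == 0.0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0, "df": df, "degenerate": True}
        return {"t": np.inf if a.mean() > b.mean() else -np.inf, "p": 0.0,
                "df": df, "degenerate": True}
    res = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": df}


def one_way_anova(groups) -> dict:
    """Classical one-way ANOVA over >= 2 groups.

    Returns ``{"F", "p", "df_between", "df_within", "ss_between",
    "ss_within"}``.  If every group has zero internal variance the result
    is flagged degenerate (F is 0 or infinite).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise InvalidParameterError("need >= 2 groups with n >= 2 each")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    df_between = len(arrays) - 1
    df_within = len(all_values) - len(arrays)
    out = {"df_between": df_between, "df_within": df_within,
           "ss_between": float(ss_between), "ss_within": float(ss_within)}
    if ss_within == 0.0:
        out.update(F=0.0 if ss_between == 0.0 else np.inf,
                   p=1.0 if ss_between == 0.0 else 0.0, degenerate=True)
        return out
    f_stat, p = stats.f_oneway(*arrays)
    out.update(F=float(f_stat), p=float(p))
    return out


def tukey_hsd(groups) -> pd.DataFrame:
    """All-pairs Tukey HSD (delegated to scipy), as a tidy table."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InvalidParameterError("need >= 2 groups")
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append({"group_a": i, "group_b": j,
                         "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                         "p": float(res.pvalue[i, j])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Williams-type trend test


@dataclass
class DoseGroups:
    """Ordered dose groups with the zero-dose control first."""

    doses_um: np.ndarray
    values: list

    def __post_init__(self) -> None:
        self.doses_um = np.asarray(self.doses_um, dtype=float)
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if len(self.doses_um) != len(self.values):
            raise InvalidParameterError("one value array per dose required")
        if len(self.values) < 2:
            raise InvalidParameterError("need a control and >= 1 dose group")
        if np.any(np.diff(self.doses_um) <= 0):
            raise InvalidParameterError("doses must be strictly ascending")
        if self.doses_um[0] != 0.0:
            raise InvalidParameterError("first group must be the 0-dose control")
        if any(len(v) < 2 for v in self.values):
            raise InvalidParameterError("every group needs n >= 2")

    @property
    def ns(self) -> np.ndarray:
        return np.array([len(v) for v in self.values])


def pava(means, weights=None) -> np.ndarray:
    """Weighted pooled-adjacent-violators: the monotone non-decreasing
    sequence closest (weighted least squares) to ``means``.

    E.g. means (1, 3, 2) with equal weights → (1, 2.5, 2.5).  Preserves the
    weighted grand mean.
    """
    means = np.asarray(means, dtype=float)
    weights = (np.ones_like(means) if weights is None
               else np.asarray(weights, dtype=float))
    # blocks of (value, weight); merge while an adjacent violation exists
    vals: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for m, w in zip(means, weights):
        vals.append(m)
        wts.append(w)
        counts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            w_new = wts[-2] + wts[-1]
            v_new = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / w_new
            vals[-2:] = [v_new]
            wts[-2:] = [w_new]
            counts[-2:] = [counts[-2] + counts[-1]]
        # merged blocks may now violate further left; loop handles it
    return np.repeat(vals, counts)


def _williams_statistics(group_means, ns, s2) -> np.ndarray:
    """t̄ᵢ for treatment groups i = 1..k−1 (control is index 0)."""
    mu_hat = pava(group_means[1:], ns[1:])
    se = np.sqrt(s2 * (1.0 / ns[1:] + 1.0 / ns[0]))
    return (mu_hat - group_means[0]) / se


def williams_critical_values(ns, alpha: float = 0.05, n_null: int = 10000,
                             rng=None) -> np.ndarray:
    """Monte-Carlo (1 − alpha) critical values of the Williams statistic.

    Simulates the null — equal normal means, the given per-group sizes,
    pooled variance drawn from its chi-square law — and applies the same
    isotonic procedure, so the critical values match the statistic exactly.
    """
    ns = np.asarray(ns, dtype=int)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    df = int(ns.sum() - len(ns))
    k = len(ns) - 1
    stats_null = np.empty((n_null, k))
    means = rng.standard_normal((n_null, len(ns))) / np.sqrt(ns)
    s2s = rng.chisquare(df, size=n_null) / df
    for r in range(n_null):
        stats_null[r] = _williams_statistics(means[r], ns, s2s[r])
    return np.quantile(stats_null, 1.0 - alpha, axis=0)


@dataclass
class WilliamsTrendResults:
    """Step-down trend-test report: one row per non-control dose."""

    table: pd.DataFrame
    alpha: float
    s2: float
    df: int
    anova: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Williams-type step-down trend test vs 0-dose control",
            f"alpha = {self.alpha:g}; pooled within-group variance s2 = "
            f"{self.s2:.6g} on {self.df} df",
            "(critical values by seeded Monte-Carlo simulation of the null;",
            " significance at a dose requires significance at all higher doses)",
            "",
            self.table.to_string(index=False),
        ]
        return "\n".join(lines)


def williams_trend_test(groups: DoseGroups, alpha: float = 0.05,
                        n_null: int = 10000, rng=None,
                        critical_values=None) -> WilliamsTrendResults:
    """Williams-type monotone-trend test of each dose against control.

    Isotonic (PAVA, weighted by group size) estimates of the treatment
    means feed the statistic ``t̄ᵢ = (μ̂ᵢ − ȳ₀)/sqrt(s²(1/nᵢ + 1/n₀))``;
    per-dose critical values come from :func:`williams_critical_values`
    (pass ``critical_values`` to reuse precomputed ones).  Significance is
    assigned step-down from the highest dose: a dose is significant only if
    every higher dose is.
    """
    ns = groups.ns
    anova = one_way_anova(groups.values)
    s2 = anova["ss_within"] / anova["df_within"]
    if s2 <= 0:
        raise InvalidParameterError("zero within-group variance; trend test undefined")
    group_means = np.array([v.mean() for v in groups.values])
    t_bar = _williams_statistics(group_means, ns, s2)
    if critical_values is None:
        critical_values = williams_critical_values(ns, alpha=alpha,
                                                   n_null=n_null, rng=rng)
    critical_values = np.asarray(critical_values, dtype=float)
    exceeds = t_bar > critical_values
    significant = np.logical_and.accumulate(exceeds[::-1])[::-1]
    mu_hat = pava(group_means[1:], ns[1:])
    table = pd.DataFrame({
        "dose_um": groups.doses_um[1:],
        "n": ns[1:],
        "mean": group_means[1:],
        "isotonic_mean": mu_hat,
        "statistic": t_bar,
        "critical_value": critical_values,
        "significant": significant,
    })
    return WilliamsTrendResults(table=table, alpha=alpha, s2=float(s2),
                                df=anova["df_within"], anova=anova)
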