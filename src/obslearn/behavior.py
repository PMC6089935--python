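"""Go/NoGo behavioral statistics: dPesc, the z-test, and learning criteria.

Trials are partitioned into non-overlapping bins (default 100 trials).
Per bin, the true-positive rate P_T is the escape probability on puffed
trials and the false-positive rate P_F the escape probability on unpuffed
trials; the single performance measure is their difference,
dPesc = P_T - P_F.  Whether a bin shows significant discrimination is
decided by a z-test of independent proportions,

    Z = (|P_T - P_F| - c) / sigma,
    sigma = sqrt(p q (n_T + n_F) / (n_T n_F)),   p pooled, q = 1 - p,

with two continuity-correction variants for c: the form used operationally
in this pipeline, c = (n_T - n_F) / (2 n_T n_F) (``correction="printed"``,
the default — note it vanishes for balanced bins), and the textbook Yates
term c = (1/n_T + 1/n_F) / 2 (``correction="yates"``), kept for
calibration cross-checks.  The two-sided p-value is 2(1 - Phi(Z)); a bin
is significant at p < 0.01.

Learning criteria:

* fine (post-hoc) — slide a window of 8 consecutive 100-trial bins and
  stop at the first window with >= 7 significant bins; the criterion bin
  is the last bin of that window, and trials-to-criterion counts all
  trials up to and including it (lower bound: 800).  Robustness variants
  (4/4 bins, 200-trial bins) are plain parameter changes.
* coarse (online) — a whole day's trials form one bin; the phase switches
  on the second of the first two consecutive days with dPesc
  significantly greater than zero.

The module also covers call-rate statistics (delay-period minus
stimulus-period call probability, paired sign-rank over trials) and
rank-sum group comparisons, plus a model/results wrapper,
:class:`GoNogoDiscrimination`, that runs the whole per-bird pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinStats",
    "CriterionReport",
    "UndefinedStatisticError",
    "bin_trials",
    "bin_stats",
    "proportion_ztest",
    "criterion_scan",
    "daily_criterion",
    "cumulative_escape_curves",
    "call_rate_stats",
    "group_compare",
    "GoNogoDiscrimination",
    "DiscriminationResults",
    "load_trials",
    "load_calls",
]

TRIAL_COLUMNS = ["index", "stimulus_id", "class", "escape", "day"]


class UndefinedStatisticError(ValueError):
    """A bin lacks trials of one class, so P_T or P_F is undefined."""


@dataclass(frozen=True)
class BinStats:
    """Per-bin escape rates and the significance test."""

    bin_index: int
    n_T: int
    n_F: int
    P_T: float
    P_F: float
    dPesc: float
    z_stat: float
    p_value: float
    significant: bool
    partial: bool = False


@dataclass(frozen=True)
class CriterionReport:
    """Outcome of the sliding-window learning-criterion scan."""

    reached: bool
    criterion_bin: int | None
    trials_to_criterion: int | None
    bin_size: int
    window: int
    required: int
    alpha: float


# ------------------------------------------------------------------ I/O


def load_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial log CSV: index,stimulus_id,class,escape,day[,escape_latency_s]."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    df["escape"] = df["escape"].astype(bool)
    return df


def load_calls(path: str | Path) -> pd.DataFrame:
    """Read a call log CSV: trial,class,stim_call,delay_call[,stimulus_id]."""
    df = pd.read_csv(path)
    for col in ("stim_call", "delay_call"):
        df[col] = df[col].astype(bool)
    return df


# ------------------------------------------------------------ statistics


def bin_trials(
    records: pd.DataFrame, bin_size: int = 100
) -> list[tuple[pd.DataFrame, bool]]:
    """Partition trials into consecutive non-overlapping bins.

    Returns (bin, partial) pairs in order; a trailing bin with fewer than
    ``bin_size`` trials is included but flagged partial (criterion scans
    exclude it).  Bin k covers trials (k-1)*bin_size+1 .. k*bin_size.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    n = len(records)
    out = []
    for start in range(0, n, bin_size):
        chunk = records.iloc[start : start + bin_size]
        out.append((chunk, len(chunk) < bin_size))
    return out


def proportion_ztest(
    k_T: int, n_T: int, k_F: int, n_F: int, correction: str = "printed"
) -> tuple[float, float]:
    """Two-proportion z-test with a continuity correction; returns (Z, p).

    ``correction="printed"`` uses c = (n_T - n_F)/(2 n_T n_F);
    ``correction="yates"`` uses the textbook c = (1/n_T + 1/n_F)/2;
    ``correction="none"`` omits it.  The corrected numerator is clipped at
    zero, so Z >= 0 and the two-sided p-value is 2(1 - Phi(Z)).  A
    degenerate pooled proportion (sigma = 0) yields (0, 1).
    """
    if n_T < 1 or n_F < 1:
        raise UndefinedStatisticError(
            f"both classes need trials (n_T={n_T}, n_F={n_F})"
        )
    P_T, P_F = k_T / n_T, k_F / n_F
    p = (k_T + k_F) / (n_T + n_F)
    q = 1.0 - p
    sigma = np.sqrt(p * q * (n_T + n_F) / (n_T * n_F))
    if sigma == 0.0:
        return 0.0, 1.0
    if correction == "printed":
        c = (n_T - n_F) / (2.0 * n_T * n_F)
    elif correction == "yates":
        c = 0.5 * (1.0 / n_T + 1.0 / n_F)
    elif correction == "none":
        c = 0.0
    else:
        raise ValueError(f"unknown correction {correction!r}")
    z = max(abs(P_T - P_F) - c, 0.0) / sigma
    p_value = 2.0 * stats.norm.sf(z)
    return float(z), float(min(p_value, 1.0))


def bin_stats(
    bin_records: pd.DataFrame,
    bin_index: int = 1,
    alpha: float = 0.01,
    correction: str = "printed",
    partial: bool = False,
) -> BinStats:
    """Escape rates, dPesc and the significance test for one bin.

    Raises :class:`UndefinedStatisticError` when either class is absent
    from the bin (the statistic is reported as undefined, never silently
    skipped).
    """
    cls = bin_records["class"].to_numpy()
    esc = bin_records["escape"].to_numpy().astype(bool)
    puffed = cls == "puffed"
    n_T, n_F = int(puffed.sum()), int((~puffed).sum())
    if n_T == 0 or n_F == 0:
        raise UndefinedStatisticError(
            f"bin {bin_index}: n_T={n_T}, n_F={n_F}; escape rates undefined"
        )
    k_T = int(esc[puffed].sum())
    k_F = int(esc[~puffed].sum())
    z, p_value = proportion_ztest(k_T, n_T, k_F, n_F, correction=correction)
    P_T, P_F = k_T / n_T, k_F / n_F
    return BinStats(
        bin_index=bin_index,
        n_T=n_T,
        n_F=n_F,
        P_T=P_T,
        P_F=P_F,
        dPesc=P_T - P_F,
        z_stat=z,
        p_value=p_value,
        significant=bool(p_value < alpha),
        partial=partial,
    )


def criterion_scan(
    bins: list[BinStats],
    window: int = 8,
    required: int = 7,
    bin_size: int = 100,
    alpha: float = 0.01,
) -> CriterionReport:
    """Sliding-window learning criterion over full bins.

    The criterion is met at the first window of ``window`` consecutive
    full bins containing at least ``required`` significant bins; the
    criterion bin is the last bin of that window and trials-to-criterion
    is ``bin_size * criterion_bin`` (1-based bins).  Partial bins are
    excluded.  Fewer than ``window`` full bins -> not reached.
    """
    flags = [b.significant for b in bins if not b.partial]
    for start in range(0, len(flags) - window + 1):
        if sum(flags[start : start + window]) >= required:
            crit_bin = start + window  # 1-based index of the window's last bin
            return CriterionReport(
                True, crit_bin, bin_size * crit_bin, bin_size, window, required, alpha
            )
    return CriterionReport(False, None, None, bin_size, window, required, alpha)


def daily_criterion(
    records: pd.DataFrame, alpha: float = 0.01, correction: str = "printed"
) -> int | None:
    """Coarse phase-switch criterion: whole days as bins.

    Returns the second day of the first pair of consecutive days on which
    dPesc is significantly greater than zero (significant bin and
    dPesc > 0), or None.  Days missing one class count as not significant.
    """
    sig_days = []
    for day, day_records in records.groupby("day", sort=True):
        try:
            s = bin_stats(day_records, bin_index=int(day), alpha=alpha,
                          correction=correction)
        except UndefinedStatisticError:
            continue
        if s.significant and s.dPesc > 0:
            sig_days.append(int(day))
    for a, b in zip(sig_days, sig_days[1:]):
        if b == a + 1:
            return b
    return None


def cumulative_escape_curves(
    records: pd.DataFrame, latency_col: str = "escape_latency_s"
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class cumulative escape probability versus within-trial time.

    Requires an escape-latency column on escape trials.  For each class
    the curve is the fraction of that class's trials with an escape at or
    before time t; the end-of-trial values equal the per-class escape
    rates P_T and P_F.
    """
    if latency_col not in records.columns:
        raise ValueError(f"escape latencies ({latency_col!r}) unavailable")
    out = {}
    for cls, sub in records.groupby("class"):
        lat = sub.loc[sub["escape"].astype(bool), latency_col].to_numpy(dtype=float)
        if np.isnan(lat).any():
            raise ValueError(f"missing latency on escape trials of class {cls!r}")
        times = np.sort(lat)
        cum = np.arange(1, len(times) + 1) / len(sub)
        out[str(cls)] = (times, cum)
    return out


@dataclass(frozen=True)
class CallRateStats:
    """Per-class delay-minus-stimulus call-probability differences."""

    per_class: pd.DataFrame      # class, p_stim, p_delay, difference, p_value, n
    per_stimulus: pd.DataFrame | None


def call_rate_stats(call_records: pd.DataFrame) -> CallRateStats:
    """Delay-period minus stimulus-period call probabilities by class.

    Call probability is the probability of observing at least one call in
    the period.  The per-class difference is tested with a two-sided
    paired sign-rank over the per-trial (delay - stim) flag differences
    (zero differences dropped); all-zero differences yield p = 1.  A
    per-stimulus breakdown is included when a ``stimulus_id`` column is
    present.
    """
    rows = []
    for cls, sub in call_records.groupby("class"):
        if len(sub) < 1:
            continue
        stim = sub["stim_call"].to_numpy(dtype=float)
        delay = sub["delay_call"].to_numpy(dtype=float)
        diff = delay - stim
        if np.any(diff != 0):
            _, p_value = stats.wilcoxon(diff, zero_method="wilcox", method="approx")
        else:
            p_value = 1.0
        rows.append(
            {
                "class": cls,
                "p_stim": stim.mean(),
                "p_delay": delay.mean(),
                "difference": delay.mean() - stim.mean(),
                "p_value": float(p_value),
                "n": len(sub),
            }
        )
    per_class = pd.DataFrame(rows)
    per_stim = None
    if "stimulus_id" in call_records.columns:
        per_stim = (
            call_records.assign(
                diff=call_records["delay_call"].astype(float)
                - call_records["stim_call"].astype(float)
            )
            .groupby(["stimulus_id", "class"], as_index=False)["diff"]
            .agg(difference="mean", n="count")
        )
    return CallRateStats(per_class=per_class, per_stimulus=per_stim)


@dataclass(frozen=True)
class GroupComparison:
    """Rank-sum comparison of two groups of per-bird scalars."""

    median_difference: float
    statistic: float
    p_value: float
    exact: bool
    alternative: str


def group_compare(
    values_a, values_b, alternative: str = "two-sided"
) -> GroupComparison:
    """Wilcoxon rank-sum (Mann-Whitney) comparison of two bird groups.

    The p-value is exact when the samples contain no ties; with ties the
    normal approximation is used and the result is flagged not exact.
    ``median_difference`` is median(a) - median(b).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("group comparisons need at least 3 values per group")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupComparison(
        median_difference=float(np.median(a) - np.median(b)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        exact=not has_ties,
        alternative=alternative,
    )


# ----------------------------------------------------- model/results API


class GoNogoDiscrimination:
    """Discrimination-learning analysis of one bird's trial log.

    Statsmodels-style entry point: construct from a trial DataFrame (or
    CSV via :meth:`from_csv`), then :meth:`fit` to obtain per-bin
    statistics, both learning criteria and a summary table.

    Parameters
    ----------
    trials : DataFrame
        Columns ``index, stimulus_id, class, escape, day`` (and optionally
        ``escape_latency_s``), sorted by trial index.
    bin_size, window, required, alpha : criterion parameters
        Defaults 100-trial bins, 7/8 significant bins, p < 0.01; the
        robustness variants (4/4, 200-trial bins) are parameter changes.
    correction : {"printed", "yates", "none"}
        Continuity-correction variant for the z-test.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        bin_size: int = 100,
        window: int = 8,
        required: int = 7,
        alpha: float = 0.01,
        correction: str = "printed",
    ):
        if not trials["index"].is_monotonic_increasing:
            raise ValueError("trial indices must be strictly increasing")
        self.trials = trials.reset_index(drop=True)
        self.bin_size = bin_size
        self.window = window
        self.required = required
        self.alpha = alpha
        self.correction = correction

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "GoNogoDiscrimination":
        return cls(load_trials(path), **kwargs)

    def fit(self) -> "DiscriminationResults":
        stats_list = []
        for i, (chunk, partial) in enumerate(
            bin_trials(self.trials, self.bin_size), start=1
        ):
            try:
                stats_list.append(
                    bin_stats(chunk, bin_index=i, alpha=self.alpha,
                              correction=self.correction, partial=partial)
                )
            except UndefinedStatisticError:
                # single-class bin: report a null placeholder, never significant
                stats_list.append(
                    BinStats(i, int((chunk["class"] == "puffed").sum()),
                             int((chunk["class"] == "unpuffed").sum()),
                             np.nan, np.nan, np.nan, np.nan, 1.0, False, partial)
                )
        report = criterion_scan(
            stats_list, self.window, self.required, self.bin_size, self.alpha
        )
        daily = daily_criterion(self.trials, self.alpha, self.correction)
        return DiscriminationResults(self, stats_list, report, daily)


class DiscriminationResults:
    """Fitted per-bird discrimination statistics."""

    def __init__(self, model, bin_stats_list, criterion, daily_criterion_day):
        self.model = model
        self.bin_stats_list = bin_stats_list
        self.criterion = criterion
        self.daily_criterion_day = daily_criterion_day

    @property
    def bins(self) -> pd.DataFrame:
        """Per-bin statistics as a DataFrame."""
        return pd.DataFrame([vars(b) for b in self.bin_stats_list])

    @property
    def trials_to_criterion(self) -> int | None:
        return self.criterion.trials_to_criterion

    def dpesc_at_criterion(self, n_blocks: int = 3) -> float | None:
        """Mean dPesc over the last ``n_blocks`` bins up to the criterion bin."""
        if not self.criterion.reached:
            return None
        k = self.criterion.criterion_bin
        vals = [b.dPesc for b in self.bin_stats_list[max(0, k - n_blocks) : k]]
        return float(np.nanmean(vals))

    def summary(self) -> str:
        df = self.bins
        n_sig = int(df["significant"].sum())
        lines = [
            "Go/NoGo discrimination analysis",
            "===============================",
            f"trials:               {len(self.model.trials)}",
            f"bins ({self.model.bin_size}-trial):      "
            f"{len(df)} ({n_sig} significant at p < {self.model.alpha})",
            f"criterion:            {self.model.required}/{self.model.window} "
            f"significant bins",
            f"criterion reached:    {self.criterion.reached}",
            f"trials to criterion:  {self.criterion.trials_to_criterion}",
            f"dPesc at criterion:   "
            + (f"{self.dpesc_at_criterion():.3f}" if self.criterion.reached else "n/a"),
            f"daily criterion day:  {self.daily_criterion_day}",
        ]
        return "\n".join(lines)
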