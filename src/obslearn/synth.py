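"""Synthetic behavioral trial streams, cohorts and call-event tables.

These generators produce trial logs with the statistical structure the
analysis pipeline assumes — class-dependent escape probabilities that
evolve over training — so binning, the z-test, the learning criteria and
the group comparisons can all be exercised and calibrated end to end
without any recorded data.

A bird's discrimination follows a logistic curve in trial number: the
instantaneous dPesc rises from ~0 toward ``asymptote_dPesc`` with
half-asymptote at ``learning_rate`` trials, and the per-class escape
probabilities sit symmetrically around ``baseline_escape``:

    p_puffed(t)   = baseline + d(t)/2
    p_unpuffed(t) = baseline - d(t)/2,      d(t) programmed dPesc,

both clipped to [0, 1].  This is a deliberately minimal monotone
saturating model with interpretable parameters, not a mechanistic account
of avoidance learning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

__all__ = [
    "BirdProfile",
    "CohortSpec",
    "GROUP_PRESETS",
    "simulate_bird",
    "simulate_cohort",
    "simulate_calls",
    "perfect_discriminator_log",
]

#: logistic steepness: slope scale as a fraction of the half-asymptote trial
RAMP_SHARPNESS = 4.0


@dataclass(frozen=True)
class BirdProfile:
    """Generative parameters of one synthetic bird.

    Parameters
    ----------
    baseline_escape : float
        Escape probability shared by both classes at trial 1.
    asymptote_dPesc : float
        Programmed discrimination at convergence.
    learning_rate : float
        Trials to half-asymptote (the logistic midpoint); 0 means an
        instant learner at full asymptote from trial 1.
    n_trials : int
    seed : int or None
    balanced_blocks : bool
        If True, classes alternate in shuffled 100-trial blocks with
        exactly 50 trials per class (for deterministic bin tests);
        otherwise classes are i.i.d. uniform.
    daily_trials : float
        Mean trials per day (Poisson) for day labelling.
    with_latencies : bool
        Attach escape latencies (puffed escapes biased late) to exercise
        the cumulative escape curves.
    """

    baseline_escape: float = 0.30
    asymptote_dPesc: float = 0.35
    learning_rate: float = 1000.0
    n_trials: int = 5000
    seed: int | None = None
    class_sequence: np.ndarray | None = field(default=None, repr=False)
    balanced_blocks: bool = False
    daily_trials: float = 700.0
    with_latencies: bool = False

    def __post_init__(self):
        if not (0.0 <= self.baseline_escape <= 1.0):
            raise ValueError("baseline_escape must lie in [0, 1]")
        if not (-1.0 <= self.asymptote_dPesc <= 1.0):
            raise ValueError("asymptote_dPesc must lie in [-1, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")

    def dpesc_at(self, t) -> np.ndarray:
        """Programmed instantaneous dPesc at trial number(s) t (1-based)."""
        t = np.asarray(t, dtype=float)
        if self.learning_rate == 0:
            return np.full_like(t, self.asymptote_dPesc)
        slope = self.learning_rate / RAMP_SHARPNESS
        return self.asymptote_dPesc / (1.0 + np.exp(-(t - self.learning_rate) / slope))

    def escape_probabilities(self, t) -> tuple[np.ndarray, np.ndarray]:
        """(p_puffed, p_unpuffed) at trial number(s) t, clipped to [0, 1]."""
        d = self.dpesc_at(t)
        p_puffed = np.clip(self.baseline_escape + d / 2.0, 0.0, 1.0)
        p_unpuffed = np.clip(self.baseline_escape - d / 2.0, 0.0, 1.0)
        return p_puffed, p_unpuffed


def _class_draws(profile: BirdProfile, rng: np.random.Generator) -> np.ndarray:
    n = profile.n_trials
    if profile.class_sequence is not None:
        seq = np.asarray(profile.class_sequence, dtype=bool)
        if len(seq) != n:
            raise ValueError("class_sequence length must equal n_trials")
        return seq
    if profile.balanced_blocks:
        out = np.empty(n, dtype=bool)
        block = 100
        for start in range(0, n, block):
            size = min(block, n - start)
            half = size // 2
            chunk = np.r_[np.ones(half, bool), np.zeros(size - half, bool)]
            out[start : start + size] = rng.permutation(chunk)
        return out
    return rng.random(n) < 0.5


def simulate_bird(profile: BirdProfile) -> pd.DataFrame:
    """Generate one bird's trial log as a DataFrame.

    Columns: ``index`` (1-based), ``stimulus_id`` (S_6..S_10 for puffed,
    S_1..S_5 for unpuffed, uniform within class), ``class``, ``escape``,
    ``day`` and, when requested, ``escape_latency_s``.
    """
    rng = np.random.default_rng(profile.seed)
    n = profile.n_trials
    t = np.arange(1, n + 1)
    puffed = _class_draws(profile, rng)
    p_puffed, p_unpuffed = profile.escape_probabilities(t)
    p = np.where(puffed, p_puffed, p_unpuffed)
    escape = rng.random(n) < p

    # stimulus ids: long-puffed contingency, uniform within class
    stim_num = np.where(
        puffed, rng.integers(6, 11, size=n), rng.integers(1, 6, size=n)
    )
    # day labels from Poisson daily trial counts
    day = np.empty(n, dtype=int)
    filled, d = 0, 1
    while filled < n:
        count = max(1, int(rng.poisson(profile.daily_trials)))
        day[filled : filled + count] = d
        filled += count
        d += 1

    df = pd.DataFrame(
        {
            "index": t,
            "stimulus_id": [f"S_{k}" for k in stim_num],
            "class": np.where(puffed, "puffed", "unpuffed"),
            "escape": escape,
            "day": day,
        }
    )
    if profile.with_latencies:
        # escapes happen within a ~6 s trial; puffed escapes biased late
        lat = np.where(
            puffed, rng.uniform(1.0, 6.0, size=n), rng.uniform(0.0, 6.0, size=n)
        )
        df["escape_latency_s"] = np.where(escape, np.round(lat, 4), np.nan)
    return df


def perfect_discriminator_log(
    n_trials: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """A bird that discriminates perfectly from trial 1.

    Escapes on every puffed trial, stays on every unpuffed trial, classes
    balanced within each 100-trial block; the sliding-window criterion on
    such a log returns its lower bound of 800 trials.
    """
    profile = BirdProfile(
        baseline_escape=0.5,
        asymptote_dPesc=1.0,
        learning_rate=0.0,
        n_trials=n_trials,
        seed=seed,
        balanced_blocks=True,
    )
    return simulate_bird(profile)


#: per-group profile targets; discrimination asymptotes follow the
#: reported group medians at criterion, learning midpoints are set to
#: roughly half the reported median trials-to-criterion
GROUP_PRESETS: dict[str, dict] = {
    "EXP": {"asymptote_dPesc": 0.35, "learning_rate": 2400.0},
    "OBS": {"asymptote_dPesc": 0.46, "learning_rate": 450.0},
    "GENEXP": {"asymptote_dPesc": 0.50, "learning_rate": 3000.0},
    "GENOBS": {"asymptote_dPesc": 0.45, "learning_rate": 900.0},
    "PL": {"asymptote_dPesc": 0.33, "learning_rate": 2100.0},
    "VL": {"asymptote_dPesc": 0.26, "learning_rate": 3400.0},
    "-TCOM": {"asymptote_dPesc": 0.45, "learning_rate": 400.0},
}


@dataclass(frozen=True)
class CohortSpec:
    """A group of synthetic birds drawn around shared profile targets.

    ``group`` selects a preset (EXP, OBS, GENEXP, GENOBS, PL, VL, -TCOM);
    per-bird profiles jitter the preset multiplicatively (lognormal on the
    learning midpoint, Gaussian on the asymptote) so group medians land
    near the targets while birds differ.
    """

    group: str = "EXP"
    n_birds: int = 10
    seed: int | None = None
    n_trials: int = 8000
    spread: float = 0.25
    base_profile: BirdProfile = field(default_factory=BirdProfile)

    def __post_init__(self):
        if self.n_birds < 1:
            raise ValueError("n_birds must be >= 1")
        if self.group not in GROUP_PRESETS:
            raise ValueError(
                f"unknown group {self.group!r}; known: {sorted(GROUP_PRESETS)}"
            )


def simulate_cohort(spec: CohortSpec) -> list[pd.DataFrame]:
    """Independent trial logs for all birds of a cohort."""
    rng = np.random.default_rng(spec.seed)
    preset = GROUP_PRESETS[spec.group]
    logs = []
    for _ in range(spec.n_birds):
        asym = np.clip(
            rng.normal(preset["asymptote_dPesc"], spec.spread * 0.2), 0.02, 1.0
        )
        lr = preset["learning_rate"] * rng.lognormal(0.0, spec.spread)
        profile = replace(
            spec.base_profile,
            asymptote_dPesc=float(asym),
            learning_rate=float(lr),
            n_trials=spec.n_trials,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        logs.append(simulate_bird(profile))
    return logs


def simulate_calls(
    n_trials: int,
    p_stim_call: dict[str, float],
    p_delay_call: dict[str, float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Bernoulli call-event table per trial and period.

    ``p_stim_call`` and ``p_delay_call`` map class ("puffed"/"unpuffed")
    to the probability of observing at least one call in the stimulus and
    delay periods respectively.  Classes are i.i.d. uniform; a
    ``stimulus_id`` column supports the per-stimulus breakdown.
    """
    for d in (p_stim_call, p_delay_call):
        for cls, p in d.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"call probability for {cls!r} out of [0, 1]: {p}")
    rng = np.random.default_rng(seed)
    puffed = rng.random(n_trials) < 0.5
    cls = np.where(puffed, "puffed", "unpuffed")
    ps = np.where(puffed, p_stim_call["puffed"], p_stim_call["unpuffed"])
    pd_ = np.where(puffed, p_delay_call["puffed"], p_delay_call["unpuffed"])
    stim_num = np.where(
        puffed, rng.integers(6, 11, size=n_trials), rng.integers(1, 6, size=n_trials)
    )
    return pd.DataFrame(
        {
            "trial": np.arange(1, n_trials + 1),
            "class": cls,
            "stim_call": rng.random(n_trials) < ps,
            "delay_call": rng.random(n_trials) < pd_,
            "stimulus_id": [f"S_{k}" for k in stim_num],
        }
    )
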