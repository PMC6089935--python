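"""Synthetic auditory stimulus sets for Go/NoGo discrimination modelling.

A stimulus is a string of six syllable renditions.  Each rendition is
described by a feature vector of length ``n = 22 + nr``:

* features 1-20 — generic acoustic summary features (SAP-style: Wiener
  entropy, pitch goodness, frequency modulation, ...), emulated here as
  unit-variance Gaussians whose class means differ by a small per-feature
  offset drawn once per set, so that each nuisance feature is by chance
  slightly informative about the stimulus class;
* feature 21 — syllable duration in milliseconds, the one feature that
  cleanly separates the two classes (durations are graded monotonically
  across the ten stimuli, with the short class formed by S_1..S_5 and the
  long class by S_6..S_10);
* feature 22 — a constant 1, the bias channel;
* features 23..22+nr — frozen Gaussian noise: drawn once per rendition and
  held fixed on every presentation, modelling uninformative but stable
  sensory channels.

Ten stimuli, five per class; which duration class is punished ("puffed")
is set by the contingency flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSet",
    "generate_training_set",
    "generate_generalization_set",
    "N_STIMULI",
    "N_RENDITIONS",
    "N_ACOUSTIC",
    "DURATION_INDEX",
    "BIAS_INDEX",
]

N_STIMULI = 10
N_RENDITIONS = 6
N_ACOUSTIC = 21          # features 1..21, duration last
DURATION_INDEX = 20      # 0-based index of the duration feature (feature 21)
BIAS_INDEX = 21          # 0-based index of the bias channel (feature 22)

#: default generator settings; `nuisance_offset_scale` controls how much
#: incidental class information the 20 generic acoustic features carry.
DEFAULT_DURATION_RANGE = (80.0, 260.0)   # ms, spans short zebra-finch syllables
DEFAULT_RENDITION_JITTER_FRAC = 0.01     # of the inter-stimulus duration step
DEFAULT_OFFSET_SCALE = 0.05              # sd of per-feature class-mean offsets
DEFAULT_DAY_JITTER = 0.5                 # sd of day-to-day acoustic drift


@dataclass(frozen=True)
class StimulusSet:
    """Ten stimuli x six syllable renditions with class labels.

    Parameters
    ----------
    features : ndarray, shape (10, 6, n)
        Feature vectors per stimulus and rendition, ``n = 22 + nr``.
    puffed : ndarray of bool, shape (10,)
        True where the stimulus class is followed by the air-puff.
    ids : tuple of str
        Stimulus labels, ``S_1``..``S_10`` (training) or primed
        (generalization).
    variant : {"training", "generalization"}
    contingency : {"long-puffed", "short-puffed"}
    nr : int
        Number of frozen-noise channels.
    seed : int or None
        Seed the set was generated with (None for hand-built sets).
    """

    features: np.ndarray
    puffed: np.ndarray
    ids: tuple
    variant: str
    contingency: str
    nr: int
    seed: int | None = None
    duration_means: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        f = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "puffed", np.asarray(self.puffed, dtype=bool))
        if f.shape[:2] != (N_STIMULI, N_RENDITIONS):
            raise ValueError(
                f"expected ({N_STIMULI}, {N_RENDITIONS}, n) features, got {f.shape}"
            )
        if f.shape[2] != BIAS_INDEX + 1 + self.nr:
            raise ValueError("feature dimensionality inconsistent with nr")
        if self.puffed.sum() != N_STIMULI // 2:
            raise ValueError("expected exactly 5 stimuli per class")

    @property
    def n_features(self) -> int:
        """Total feature dimensionality n = 22 + nr."""
        return self.features.shape[2]

    @property
    def durations(self) -> np.ndarray:
        """Syllable durations, shape (10, 6), in ms."""
        return self.features[:, :, DURATION_INDEX]

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        if not np.all(self.features[:, :, BIAS_INDEX] == 1.0):
            raise ValueError("bias channel must be exactly 1 for every rendition")
        d = self.durations
        if not np.all(d[1:].min(axis=1) > d[:-1].max(axis=1)):
            raise ValueError("duration grading not monotone across stimuli")

    def rendition_matrix(self) -> np.ndarray:
        """All 60 renditions stacked, shape (60, n)."""
        return self.features.reshape(-1, self.n_features)

    def rendition_labels(self) -> np.ndarray:
        """Puffed flag per stacked rendition, shape (60,)."""
        return np.repeat(self.puffed, N_RENDITIONS)

    # ---------------------------------------------------------------- I/O

    def to_csv(self, directory: str | Path, stem: str | None = None) -> Path:
        """Write the set as a CSV (one row per rendition) + JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or f"stimuli_{self.variant}"
        n = self.n_features
        rows = []
        for s in range(N_STIMULI):
            for r in range(N_RENDITIONS):
                rows.append(
                    [self.ids[s], "puffed" if self.puffed[s] else "unpuffed", r + 1]
                    + list(self.features[s, r])
                )
        cols = ["stimulus_id", "class", "rendition"] + [f"f{j+1}" for j in range(n)]
        path = directory / f"{stem}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        meta = {
            "variant": self.variant,
            "contingency": self.contingency,
            "nr": self.nr,
            "seed": self.seed,
        }
        (directory / f"{stem}.json").write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def from_csv(cls, csv_path: str | Path) -> "StimulusSet":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        feat_cols = [c for c in df.columns if c.startswith("f")]
        ids = list(dict.fromkeys(df["stimulus_id"]))
        features = np.empty((len(ids), N_RENDITIONS, len(feat_cols)))
        puffed = np.empty(len(ids), dtype=bool)
        for s, sid in enumerate(ids):
            sub = df[df["stimulus_id"] == sid].sort_values("rendition")
            features[s] = sub[feat_cols].to_numpy()
            puffed[s] = sub["class"].iloc[0] == "puffed"
        return cls(
            features=features,
            puffed=puffed,
            ids=tuple(ids),
            variant=meta["variant"],
            contingency=meta["contingency"],
            nr=int(meta["nr"]),
            seed=meta["seed"],
        )


def _graded_durations(
    rng: np.random.Generator,
    duration_range: tuple[float, float],
    jitter_frac: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Stimulus-level mean durations plus per-rendition jitter.

    Jitter is clipped at 0.45 of the inter-stimulus step so the monotone
    grading (every rendition of S_i longer than every rendition of S_{i-1})
    holds with certainty, not just with high probability.
    """
    lo, hi = duration_range
    means = np.linspace(lo, hi, N_STIMULI)
    step = (hi - lo) / (N_STIMULI - 1)
    jitter = rng.normal(0.0, jitter_frac * step, size=(N_STIMULI, N_RENDITIONS))
    jitter = np.clip(jitter, -0.45 * step, 0.45 * step)
    return means[:, None] + jitter, means, step


def generate_training_set(
    nr: int = 20,
    contingency: str = "long-puffed",
    seed: int | None = None,
    *,
    duration_range: tuple[float, float] = DEFAULT_DURATION_RANGE,
    rendition_jitter_frac: float = DEFAULT_RENDITION_JITTER_FRAC,
    offset_scale: float = DEFAULT_OFFSET_SCALE,
) -> StimulusSet:
    """Generate the training stimulus set S_1..S_10.

    Parameters
    ----------
    nr : int
        Number of frozen-noise channels appended after the bias channel;
        total dimensionality is ``22 + nr``.
    contingency : {"long-puffed", "short-puffed"}
        Which duration class is followed by the air-puff.
    seed : int, optional
        Seed for all random draws; identical arguments reproduce the set
        bit-exactly.
    duration_range : (float, float)
        Range in ms spanned by the ten stimulus-level mean durations.
    rendition_jitter_frac : float
        Rendition-to-rendition duration jitter, as a fraction of the
        inter-stimulus duration step.
    offset_scale : float
        Standard deviation of the once-per-set class-mean offsets applied
        to the 20 generic acoustic features.
    """
    if nr < 0:
        raise ValueError(f"nr must be non-negative, got {nr}")
    if contingency not in ("long-puffed", "short-puffed"):
        raise ValueError(f"unknown contingency {contingency!r}")
    rng = np.random.default_rng(seed)
    n = BIAS_INDEX + 1 + nr
    features = np.empty((N_STIMULI, N_RENDITIONS, n))

    durations, means, _ = _graded_durations(rng, duration_range, rendition_jitter_frac)
    features[:, :, DURATION_INDEX] = durations
    features[:, :, BIAS_INDEX] = 1.0

    # long class = S_6..S_10; class sign -1 for short, +1 for long
    long_class = np.arange(N_STIMULI) >= N_STIMULI // 2
    class_sign = np.where(long_class, 1.0, -1.0)

    # nuisance features: unit Gaussians + a fixed per-feature class offset
    offsets = rng.normal(0.0, offset_scale, size=DURATION_INDEX)
    features[:, :, :DURATION_INDEX] = (
        class_sign[:, None, None] * offsets[None, None, :] / 2.0
        + rng.standard_normal((N_STIMULI, N_RENDITIONS, DURATION_INDEX))
    )

    if nr:
        features[:, :, BIAS_INDEX + 1 :] = rng.standard_normal(
            (N_STIMULI, N_RENDITIONS, nr)
        )

    puffed = long_class if contingency == "long-puffed" else ~long_class
    out = StimulusSet(
        features=features,
        puffed=puffed,
        ids=tuple(f"S_{i+1}" for i in range(N_STIMULI)),
        variant="training",
        contingency=contingency,
        nr=nr,
        seed=seed,
        duration_means=means,
    )
    out.validate()
    return out


def generate_generalization_set(
    train: StimulusSet,
    jitter_scale: float = DEFAULT_DAY_JITTER,
    seed: int | None = None,
    *,
    redraw_noise: bool = True,
) -> StimulusSet:
    """Generate the generalization set S'_1..S'_10 from a training set.

    Models renditions of the same syllables recorded on the next day: each
    generic acoustic feature receives an additive day-to-day offset of
    scale ``jitter_scale``; durations drift by the same relative amount
    (scaled to the rendition jitter, and clipped so the monotone grading
    survives); frozen noise is redrawn because new renditions carry new
    frozen values (``redraw_noise=False`` reuses the training noise, for
    ablation).
    """
    if jitter_scale < 0:
        raise ValueError(f"jitter_scale must be non-negative, got {jitter_scale}")
    if train.variant != "training":
        raise ValueError("generalization sets are derived from a training set")
    rng = np.random.default_rng(seed)
    features = train.features.copy()

    features[:, :, :DURATION_INDEX] += rng.normal(
        0.0, 1.0, size=(N_STIMULI, N_RENDITIONS, DURATION_INDEX)
    ) * jitter_scale

    # duration drift: same relative magnitude as the rendition jitter,
    # clipped so grading cannot break (training jitter is clipped at 0.45
    # of the step, so +-0.04 step of drift keeps every gap positive)
    if train.duration_means is not None:
        step = float(train.duration_means[1] - train.duration_means[0])
    else:
        step = float(np.diff(train.durations.mean(axis=1)).mean())
    drift = rng.normal(
        0.0,
        DEFAULT_RENDITION_JITTER_FRAC * step,
        size=(N_STIMULI, N_RENDITIONS),
    ) * jitter_scale
    features[:, :, DURATION_INDEX] += np.clip(drift, -0.04 * step, 0.04 * step)

    if train.nr:
        if redraw_noise:
            features[:, :, BIAS_INDEX + 1 :] = rng.standard_normal(
                (N_STIMULI, N_RENDITIONS, train.nr)
            )
        # else: frozen noise shared with the training renditions

    out = replace(
        train,
        features=features,
        ids=tuple(i.replace("S_", "S'_") for i in train.ids),
        variant="generalization",
        seed=seed,
    )
    out.validate()
    return out
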