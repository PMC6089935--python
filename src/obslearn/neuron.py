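"""Online logistic neuron with reward-modulated L1 regularization.

The model classifies ten auditory stimuli (six syllable renditions each)
into puffed/unpuffed by a logistic response to z-scored feature vectors.
Per trial t, for each rendition i of the presented stimulus:

    z_i = (X_i - m_{t-1}) / sqrt(v_{t-1})          (bias channel exempt)
    f(z_i) = 1 / (1 + exp(-W . z_i))

and the bird escapes iff sum_i f(z_i) > 3 (majority vote over the six
renditions).  The weights follow gradient ascent on the log-likelihood of
the learning cue u,

    dW = eta * sum_i (u - f(z_i)) z_i

with, in the "experimenter" (regularized) variant, a subtractive L1 shrink
W -> W - sign(W) * lambda applied on successful trials to every weight of
magnitude above lambda, and a penalty that tracks reward prediction error:

    lambda_t = max(0, lambda_{t-1} + alpha * (r_t - rbar_{t-1}))
    rbar_t   = gamma * rbar_{t-1} + (1 - gamma) * r_t

where r_t = +1 on correct decisions and -1 otherwise.  Running feature
statistics are refreshed after every trial:

    m_t = (1 - eps) m_{t-1} + eps <X_i>
    v_t = (1 - eps) v_{t-1} + eps <(X_i - m_t)^2>

The within-trial order is fixed: standardize -> decide -> cue -> gradient
update -> (if regularized and successful) L1 shrink -> lambda and rbar
updates -> running-stat update.  The decision therefore depends only on
pre-trial state, and the lambda update uses the previous trial's reward
average exactly as written above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .stimuli import BIAS_INDEX, N_RENDITIONS, StimulusSet

__all__ = [
    "SimConfig",
    "NeuronState",
    "TrialOutcome",
    "z_transform",
    "update_running_stats",
    "logistic_response",
    "decide",
    "weight_update_observer",
    "l1_shrink",
    "update_reward_average",
    "update_lambda",
    "run_trial",
    "log_p_correct",
    "initial_state",
]

VARIANCE_FLOOR = 1e-8


@dataclass
class SimConfig:
    """Simulation settings and the model's learning constants.

    The four learning constants default to the values used throughout:
    integration rate ``epsilon`` = 0.01, learning rate ``eta`` = 0.007,
    penalty learning rate ``alpha`` = 0.00025 with reward-average decay
    ``gamma`` = 0.99 and initial penalty ``lambda0`` = 0.0005.

    ``cue_mode`` selects the learning-cue hypothesis: ``"airpuff"`` takes
    u directly from the stimulus class; ``"noisy_action"`` models a cue
    read off another bird's actions, flipping u on a pre-drawn random
    ``cue_error_rate`` fraction of trials.

    ``variance_update`` selects the running-variance rule:
    ``"sq-mean-dev"`` (default) squares the rendition-averaged deviation,
    so v tracks the variance of the within-trial mean — for channels that
    vary independently across the six renditions this runs about 6x below
    the per-rendition variance and amplifies their z-scores accordingly;
    ``"mean-sq-dev"`` averages squared deviations (a plain variance).

    ``init_stats`` sets the running statistics at trial 1: ``"cold"``
    (default) starts from m = 0, v = 1 with no knowledge of the feature
    distribution; ``"warm"`` seeds m and v from a silent pass over the
    training set.
    """

    epsilon: float = 0.01
    eta: float = 0.007
    alpha: float = 0.00025
    gamma: float = 0.99
    lambda0: float = 0.0005
    regularized: bool = False
    cue_mode: str = "airpuff"
    cue_error_rate: float = 0.30
    nr: int = 20
    n_trials: int = 10_000
    seed: int | None = None
    snapshot_every: int = 100
    variance_update: str = "sq-mean-dev"
    init_stats: str = "cold"
    shrink_bias: bool = True
    variance_floor: float = VARIANCE_FLOOR

    def __post_init__(self):
        for name in ("epsilon", "eta", "alpha", "gamma"):
            val = getattr(self, name)
            if not (0.0 < val < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {val}")
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be non-negative")
        if not (0.0 <= self.cue_error_rate <= 1.0):
            raise ValueError("cue_error_rate must lie in [0, 1]")
        if self.cue_mode not in ("airpuff", "noisy_action"):
            raise ValueError(f"unknown cue_mode {self.cue_mode!r}")
        if self.variance_update not in ("mean-sq-dev", "sq-mean-dev"):
            raise ValueError(f"unknown variance_update {self.variance_update!r}")
        if self.init_stats not in ("cold", "warm"):
            raise ValueError(f"unknown init_stats {self.init_stats!r}")
        if self.nr < 0:
            raise ValueError("nr must be non-negative")

    def save(self, path: str | Path) -> None:
        """Write the config as YAML (or JSON for a .json path)."""
        import yaml

        path = Path(path)
        payload = asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        """Read a config written by :meth:`save` (field names mirror
        the dataclass)."""
        import yaml

        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**payload)


@dataclass
class NeuronState:
    """Mutable per-trial state of the neuron.

    Attributes
    ----------
    W : ndarray, shape (n,)
        Synaptic weight vector.
    m, v : ndarray, shape (n,)
        Running feature mean and variance (the bias channel is carried
        as m=0, v=1 but never used).
    lam : float
        Current L1 penalty, always >= 0.
    r_bar : float
        Running reward average, in [-1, 1].
    t : int
        Trials completed.
    """

    W: np.ndarray
    m: np.ndarray
    v: np.ndarray
    lam: float = 0.0
    r_bar: float = 0.0
    t: int = 0

    def copy(self) -> "NeuronState":
        return NeuronState(
            self.W.copy(), self.m.copy(), self.v.copy(), self.lam, self.r_bar, self.t
        )

    def to_json(self, path: str | Path, config: SimConfig | None = None) -> None:
        """Checkpoint the state (and, optionally, a config hash) as JSON."""
        payload = {
            "W": self.W.tolist(),
            "m": self.m.tolist(),
            "v": self.v.tolist(),
            "lam": self.lam,
            "r_bar": self.r_bar,
            "t": self.t,
        }
        if config is not None:
            payload["config_hash"] = hash(json.dumps(asdict(config), sort_keys=True))
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NeuronState":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["W"]), np.asarray(d["m"]), np.asarray(d["v"]),
            d["lam"], d["r_bar"], d["t"],
        )


@dataclass(frozen=True)
class TrialOutcome:
    """Outcome of one trial: decision, correctness, reward, responses."""

    escape: bool
    correct: bool
    reward: int
    f_values: np.ndarray = field(repr=False)
    cue: int = 0


# ------------------------------------------------------------- primitives


def z_transform(
    X: np.ndarray,
    m: np.ndarray,
    v: np.ndarray,
    bias_index: int | None = BIAS_INDEX,
    floor: float = VARIANCE_FLOOR,
) -> np.ndarray:
    """Standardize feature vector(s) by running mean and variance.

    ``X`` may be a single vector or a (k, n) stack.  The bias channel is
    exempt and emitted as exactly 1 (a constant has zero variance, so the
    plain z-score would be undefined there).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != m.shape[0] or m.shape != v.shape:
        raise ValueError(
            f"dimension mismatch: X {X.shape}, m {m.shape}, v {v.shape}"
        )
    z = (X - m) / np.sqrt(np.maximum(v, floor))
    if bias_index is not None:
        z[..., bias_index] = 1.0
    return z


def update_running_stats(
    m: np.ndarray,
    v: np.ndarray,
    renditions: np.ndarray,
    epsilon: float,
    mode: str = "mean-sq-dev",
    bias_index: int | None = BIAS_INDEX,
    floor: float = VARIANCE_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential update of running mean and variance from one trial.

    ``renditions`` must hold exactly six feature vectors.  The mean update
    uses the within-trial average <X_i>; the variance update averages
    squared deviations from the *updated* mean (``mode="mean-sq-dev"``) or
    squares the averaged deviation (``mode="sq-mean-dev"``).  The bias
    channel keeps m=0, v=1.
    """
    renditions = np.asarray(renditions, dtype=float)
    if renditions.shape != (N_RENDITIONS, m.shape[0]):
        raise ValueError(
            f"expected ({N_RENDITIONS}, {m.shape[0]}) renditions, got {renditions.shape}"
        )
    xbar = renditions.mean(axis=0)
    m_new = (1.0 - epsilon) * m + epsilon * xbar
    dev = renditions - m_new
    if mode == "mean-sq-dev":
        spread = (dev ** 2).mean(axis=0)
    elif mode == "sq-mean-dev":
        spread = dev.mean(axis=0) ** 2
    else:
        raise ValueError(f"unknown variance-update mode {mode!r}")
    v_new = (1.0 - epsilon) * v + epsilon * spread
    v_new = np.maximum(v_new, floor)
    if bias_index is not None:
        m_new[bias_index] = 0.0
        v_new[bias_index] = 1.0
    return m_new, v_new


def logistic_response(W: np.ndarray, z: np.ndarray) -> np.ndarray | float:
    """f(z) = 1 / (1 + exp(-W.z)), overflow-safe; vectorized over rows."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != W.shape[0]:
        raise ValueError(f"dimension mismatch: W {W.shape}, z {z.shape}")
    a = z @ W
    out = np.empty_like(a, dtype=float) if a.ndim else None
    with np.errstate(over="ignore"):
        if a.ndim == 0:
            return float(1.0 / (1.0 + np.exp(-a))) if a >= 0 else float(
                np.exp(a) / (1.0 + np.exp(a))
            )
        pos = a >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
        ea = np.exp(a[~pos])
        out[~pos] = ea / (1.0 + ea)
    return out


def decide(f_values: np.ndarray) -> bool:
    """Majority vote: escape iff the six responses sum strictly above 3."""
    f_values = np.asarray(f_values, dtype=float)
    if f_values.shape != (N_RENDITIONS,):
        raise ValueError(f"expected {N_RENDITIONS} responses, got {f_values.shape}")
    return bool(f_values.sum() > N_RENDITIONS / 2.0)


def weight_update_observer(
    W: np.ndarray, renditions_z: np.ndarray, u: int, eta: float
) -> np.ndarray:
    """Maximum-likelihood gradient step: W + eta * sum_i (u - f(z_i)) z_i.

    ``f`` is evaluated at the pre-update weights; this is the gradient of
    log P_correct = sum_i log f^u (1-f)^(1-u).
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    renditions_z = np.asarray(renditions_z, dtype=float)
    f = logistic_response(W, renditions_z)
    return W + eta * ((u - f) @ renditions_z)


def l1_shrink(W: np.ndarray, lam: float, shrink_bias: bool = True) -> np.ndarray:
    """Subtract sign(W)*lam from every weight with |W| > lam.

    The magnitude guard prevents small weights from changing sign; weights
    with |W| <= lam are left untouched (not zeroed).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    out = W.copy()
    mask = np.abs(W) > lam
    if not shrink_bias:
        mask[BIAS_INDEX] = False
    out[mask] -= np.sign(W[mask]) * lam
    return out


def update_reward_average(r_bar: float, r: int, gamma: float) -> float:
    """rbar_t = gamma * rbar_{t-1} + (1 - gamma) * r_t."""
    return gamma * r_bar + (1.0 - gamma) * r


def update_lambda(lam: float, r: int, r_bar_prev: float, alpha: float) -> float:
    """lambda_t = max(0, lambda_{t-1} + alpha * (r_t - rbar_{t-1}))."""
    return max(0.0, lam + alpha * (r - r_bar_prev))


def log_p_correct(W: np.ndarray, renditions_z: np.ndarray, u: int) -> float:
    """Log-likelihood that all six renditions predict the cue correctly.

    P_correct = prod_i f(z_i)^u (1 - f(z_i))^(1-u); used as the
    finite-difference oracle for the gradient rule.
    """
    a = np.asarray(renditions_z, dtype=float) @ W
    # log f = -log(1+exp(-a)); log(1-f) = -log(1+exp(a)) — stable via logaddexp
    if u == 1:
        return float(-np.logaddexp(0.0, -a).sum())
    return float(-np.logaddexp(0.0, a).sum())


# ------------------------------------------------------------- trial step


def initial_state(train_set: StimulusSet, config: SimConfig) -> NeuronState:
    """Zero weights; running statistics per ``config.init_stats``.

    Cold start (default) sets m = 0, v = 1: the neuron knows nothing about
    the feature distribution, so channels with large raw offsets (notably
    syllable duration, in ms) are not discriminative until the running
    mean has converged.  Warm start seeds m and v with the mean and
    population variance of all 60 training renditions (a silent pass, no
    learning and no decisions).  r_bar starts at 0; lambda at ``lambda0``
    when regularized, else pinned at 0.
    """
    n = train_set.n_features
    if config.init_stats == "warm":
        X = train_set.rendition_matrix()
        m = X.mean(axis=0)
        v = np.maximum(X.var(axis=0), config.variance_floor)
    else:
        m = np.zeros(n)
        v = np.ones(n)
    m[BIAS_INDEX] = 0.0
    v[BIAS_INDEX] = 1.0
    lam = config.lambda0 if config.regularized else 0.0
    return NeuronState(W=np.zeros(n), m=m, v=v, lam=lam, r_bar=0.0, t=0)


def run_trial(
    state: NeuronState,
    renditions: np.ndarray,
    puffed: bool,
    config: SimConfig,
    flip_cue: bool = False,
) -> tuple[NeuronState, TrialOutcome]:
    """Execute one trial and return the post-trial state and outcome.

    ``renditions`` are the six raw feature vectors of the presented
    stimulus; ``flip_cue`` inverts the learning cue u (used by the
    noisy-action cue hypothesis on its pre-drawn 30% of trials).
    """
    renditions = np.asarray(renditions, dtype=float)
    z = z_transform(renditions, state.m, state.v, floor=config.variance_floor)
    f = logistic_response(state.W, z)
    escape = decide(f)
    correct = escape == bool(puffed)
    r = 1 if correct else -1

    u = int(puffed)
    if flip_cue:
        u = 1 - u

    W = weight_update_observer(state.W, z, u, config.eta)
    lam, r_bar = state.lam, state.r_bar
    if config.regularized:
        if correct:
            W = l1_shrink(W, lam, shrink_bias=config.shrink_bias)
        lam = update_lambda(lam, r, state.r_bar, config.alpha)
        r_bar = update_reward_average(state.r_bar, r, config.gamma)

    m, v = update_running_stats(
        state.m, state.v, renditions, config.epsilon,
        mode=config.variance_update, floor=config.variance_floor,
    )
    new_state = NeuronState(W=W, m=m, v=v, lam=lam, r_bar=r_bar, t=state.t + 1)
    return new_state, TrialOutcome(
        escape=escape, correct=correct, reward=r, f_values=f, cue=u
    )
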