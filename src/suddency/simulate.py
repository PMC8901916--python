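"""Seeded generators for APD observations and EEG-like two-class cohorts.

The cohort generator plants exactly the statistical structure the
analysis pipeline assumes: for a channel with class parameters
(alpha, beta), sample values are drawn from the closed-form value law

    G(v) = A + B * v**(1/alpha) * exp(beta * v),   v in (1, Lmax),

which is the push-forward of the action potential distribution through
the channel's own Lehmer transform.  The pointwise suddency moments of
such a sample, taken with respect to the sample itself, therefore follow
the APD with the generating parameters — an inverse-transform
construction rather than a biophysical EEG simulation.  Gaussian
observation noise and an mV-scale affine decoration are applied
afterwards (the decoration is undone exactly by the pipeline's
positivization step, which only depends on relative sample positions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .apd import ActionPotentialDistribution, APDParams, normalization_constants, _lmax
from .signal import PositiveSignal

__all__ = [
    "CHANNELS_10_20",
    "EXPERIMENTS",
    "MISSING_RATES_HUSM",
    "SyntheticConfig",
    "ExperimentMatrix",
    "Cohort",
    "generate_apd_observations",
    "sample_value_law",
    "generate_cohort",
    "inject_missing",
]

#: the 19 scalp electrodes of the international 10-20 system
CHANNELS_10_20 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: recording conditions: eyes closed, eyes open, task performance
EXPERIMENTS = ("EC", "EO", "TASK")

#: realistic per-group, per-experiment missing-experiment rates observed in
#: a clinical MDD EEG study (fractions of subject-experiments absent)
MISSING_RATES_HUSM = {
    ("H", "EC"): 0.067, ("H", "EO"): 0.033, ("H", "TASK"): 0.067,
    ("MDD", "EC"): 0.118, ("MDD", "EO"): 0.059, ("MDD", "TASK"): 0.029,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a clinical EEG protocol: 19 channels sampled at
    256 Hz over three conditions, ~32 subjects per class.  ``class_params``
    maps class label to the (alpha, beta) of its action potential
    distribution (one pair broadcast to all channels, or a per-channel
    list).  ``noise_sd`` is the additive Gaussian observation noise; the
    default ``None`` means 1% of the constructed signal range.
    """

    n_per_class: int = 32
    channels: int = 19
    experiments: int = 3
    sampling_rate: float = 256.0
    duration_s: float = 10.0
    class_params: dict = field(
        default_factory=lambda: {"H": (0.8, 1.0), "MDD": (0.45, 2.5)}
    )
    noise_sd: float | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1 or self.channels < 1 or self.experiments < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        for label, p in self.class_params.items():
            for pair in np.atleast_2d(np.asarray(p, dtype=float)):
                APDParams(*pair)  # validates domains

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration_s))


@dataclass
class ExperimentMatrix:
    """One subject-experiment recording: rows = time samples (mV), columns = channels."""

    values: np.ndarray
    subject_id: str
    experiment_id: str
    channel_labels: tuple
    sampling_rate: float = 256.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_labels):
            raise ValueError("values must be I x J with one column per channel label")

    @property
    def missing_channels(self) -> np.ndarray:
        """Boolean mask of entirely-absent (all-NaN) channels."""
        return np.all(np.isnan(self.values), axis=0)


@dataclass
class Cohort:
    """A synthetic dataset: experiment matrices plus per-subject class labels."""

    matrices: list
    labels: dict
    config: SyntheticConfig


def generate_apd_observations(params: APDParams, fixture_signal, n: int, seed=None) -> np.ndarray:
    """Draw n suddency-moment observations from the APD on a fixture signal.

    Thin delegation to the distribution's inverse-CDF sampler; suitable as
    input to :func:`suddency.apd.fit_apd_mle`.
    """
    dist = ActionPotentialDistribution(fixture_signal, params)
    return dist.sample(n, seed)


def sample_value_law(params: APDParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample the closed-form value law G(v) = A + B v^(1/alpha) e^(beta v).

    This is the distribution of L(S) for S following the APD — i.e. of the
    signal values themselves — supported on (1, Lmax).  Inversion is by
    monotone grid interpolation with Newton polish on the closed form.
    """
    a, b = params.alpha, params.beta
    _, A, B = normalization_constants(params)
    lmax = _lmax(params)
    u = rng.uniform(1e-12, 1 - 1e-12, size=n)
    grid = np.linspace(1.0, lmax, 2049)
    G = A + B * grid ** (1.0 / a) * np.exp(b * grid)
    v = np.interp(u, G, grid)
    for _ in range(6):
        Gv = A + B * v ** (1.0 / a) * np.exp(b * v)
        g = B * np.exp(b * v) * ((1.0 / a) * v ** (1.0 / a - 1.0) + b * v ** (1.0 / a))
        v = np.clip(v - (Gv - u) / np.maximum(g, 1e-300), 1.0, lmax)
    return v


def _params_for(config: SyntheticConfig, label: str, channel_index: int) -> APDParams:
    p = np.atleast_2d(np.asarray(config.class_params[label], dtype=float))
    pair = p[channel_index % p.shape[0]]
    return APDParams(float(pair[0]), float(pair[1]))


def generate_cohort(config: SyntheticConfig = SyntheticConfig()) -> Cohort:
    """Generate a seeded two-class multichannel cohort.

    Per subject, experiment and channel a signal is drawn from the class's
    value law (so its own pointwise suddency moments follow the class APD),
    noise is added, and the trace is affinely decorated to an mV-like
    scale.  Whole subject-experiments are dropped at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    channels = tuple(CHANNELS_10_20[: config.channels]) if config.channels <= 19 else tuple(
        f"ch{i}" for i in range(config.channels)
    )
    experiments = tuple(EXPERIMENTS[: config.experiments]) if config.experiments <= 3 else tuple(
        f"exp{i}" for i in range(config.experiments)
    )
    matrices, labels = [], {}
    for label in config.class_params:
        for k in range(config.n_per_class):
            sid = f"{label}{k:03d}"
            labels[sid] = label
            for exp in experiments:
                if config.missing_rate > 0 and rng.uniform() < config.missing_rate:
                    continue
                cols = []
                for j in range(config.channels):
                    params = _params_for(config, label, j)
                    v = sample_value_law(params, n, rng)
                    sd = config.noise_sd
                    if sd is None:
                        sd = 0.01 * (v.max() - v.min())
                    if sd > 0:
                        v = v + rng.normal(0.0, sd, size=n)
                    # affine decoration to an EEG-like mV scale; undone
                    # exactly by downstream positivization
                    cols.append(0.05 * (v - v.mean()))
                matrices.append(
                    ExperimentMatrix(
                        np.column_stack(cols), sid, exp, channels, config.sampling_rate
                    )
                )
    return Cohort(matrices, labels, config)


def inject_missing(cohort: Cohort, rates, seed=None) -> Cohort:
    """Drop whole subject-experiments according to a rate table.

    ``rates`` is either a scalar in [0, 1) or a mapping
    ``(group_label, experiment_id) -> rate`` (see
    :data:`MISSING_RATES_HUSM`).  Subjects losing every experiment are
    excluded with a warning.
    """
    rng = np.random.default_rng(seed)

    def rate_for(sid, exp):
        if np.isscalar(rates):
            return float(rates)
        return float(rates.get((cohort.labels[sid], exp), 0.0))

    kept = []
    for m in cohort.matrices:
        r = rate_for(m.subject_id, m.experiment_id)
        if not (0 <= r <= 1):
            raise ValueError(f"rate {r} outside [0, 1]")
        if rng.uniform() >= r:
            kept.append(m)
    surviving = {m.subject_id for m in kept}
    labels = {}
    for sid, lab in cohort.labels.items():
        if sid in surviving:
            labels[sid] = lab
        else:
            warnings.warn(f"subject {sid!r} lost all experiments and is excluded")
    return Cohort(kept, labels, cohort.config)
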