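"""Five-statistic channel featurization and entropy heatmaps.

Each EEG channel is summarized by fitting an action potential
distribution to its pointwise suddency moments and computing five
functionals of the fitted density f and distribution function F:

    int_{-inf}^{m1} f log f ds,   int_{m1}^{m2} f log f ds,
    int_{m2}^{+inf} f log f ds,   F(m1),   1 - F(m2),

where m1 = argmax_{s<=1} f and m2 = argmax_{s>=1} f are the constrained
modes of the fitted density on either side of the arithmetic-mean moment
s = 1.  The three integrals are stored with the printed (non-negated)
sign; standard differential entropy is their negated sum and drives the
scalp heatmaps.  A cohort of N subjects, M experiments and J channels
assembles into 5*M*J features per subject (285 at M=3, J=19).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .apd import (
    ActionPotentialDistribution,
    APDParams,
    fit_apd_mle,
    signal_to_smoments,
)
from .signal import DomainError, preprocess_to_positive

__all__ = [
    "FeatureConfig",
    "ChannelFeatures",
    "SubjectFeatureVector",
    "FEATURE_NAMES",
    "find_modes",
    "channel_features",
    "differential_entropy",
    "assemble_features",
    "features_to_frame",
    "entropy_heatmap",
]

#: the five per-channel statistics, in printed order
FEATURE_NAMES = ("e_left", "e_mid", "e_right", "tail_left", "tail_right")


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of the channel pipeline.

    target_range : positivization range for raw traces (unitless)
    clip : bound on pointwise suddency moments fed to the MLE
    quad_clip : integration bracket half-width for the density integrals
    mode_halfwidth : search half-width for the constrained modes
    mode_step : grid step of the coarse mode scan before refinement
    fit_init, n_starts, fit_maxiter, seed : MLE settings
    """

    target_range: tuple[float, float] = (1.0, 2.0)
    clip: float = 20.0
    quad_clip: float = 50.0
    mode_halfwidth: float = 50.0
    mode_step: float = 0.01
    fit_init: APDParams = field(default_factory=lambda: APDParams(0.5, 1.0))
    n_starts: int = 2
    fit_maxiter: int = 300
    seed: int = 0


def find_modes(
    dist: ActionPotentialDistribution,
    search_halfwidth: float = 50.0,
    step: float = 0.01,
) -> tuple[float, float]:
    """Constrained modes of the density either side of s = 1.

    ``m1`` maximizes f on ``[-search_halfwidth, 1]`` and ``m2`` on
    ``[1, search_halfwidth]``; a coarse grid scan (ties broken toward the
    boundary value 1) is refined by bounded golden-section search.
    """
    hw = float(search_halfwidth)

    def argmax_on(lo: float, hi: float) -> float:
        grid = np.arange(lo, hi + step / 2, step)
        vals = dist.pdf(grid)
        if not np.all(np.isfinite(vals)):
            raise FloatingPointError("non-finite density values in mode search")
        best = vals.max()
        ties = np.flatnonzero(vals >= best * (1 - 1e-12))
        i = ties[np.argmin(np.abs(grid[ties] - 1.0))]
        a = max(lo, grid[i] - 2 * step)
        b = min(hi, grid[i] + 2 * step)
        res = minimize_scalar(lambda s: -float(dist.pdf(s)[0]), bounds=(a, b), method="bounded")
        return float(res.x) if -res.fun >= best else float(grid[i])

    m1 = argmax_on(-hw, 1.0)
    m2 = argmax_on(1.0, hw)
    return min(m1, 1.0), max(m2, 1.0)


@dataclass(frozen=True)
class ChannelFeatures:
    """The five per-channel statistics plus fit metadata.

    ``e_left/e_mid/e_right`` are the segment integrals of f log f (printed
    sign, i.e. *not* negated); ``tail_left = F(m1)``,
    ``tail_right = 1 - F(m2)``.
    """

    e_left: float
    e_mid: float
    e_right: float
    tail_left: float
    tail_right: float
    m1: float
    m2: float
    params: APDParams | None = None
    loglik: float = np.nan

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.e_left, self.e_mid, self.e_right, self.tail_left, self.tail_right]
        )

    @property
    def entropy(self) -> float:
        """Differential entropy of the fitted density, -int f log f."""
        return -(self.e_left + self.e_mid + self.e_right)


def _flogf_integral(dist: ActionPotentialDistribution, lo: float, hi: float) -> float:
    def integrand(s):
        lp = float(dist.logpdf(s)[0])
        return 0.0 if lp < -700 else np.exp(lp) * lp

    val, _ = quad(integrand, lo, hi, limit=200)
    return val


def channel_features(signal_column, config: FeatureConfig = FeatureConfig()) -> ChannelFeatures | None:
    """Run the full channel pipeline: positivize, invert to suddency
    moments, fit the APD by maximum likelihood, locate the constrained
    modes, and integrate the five statistics.

    Returns ``None`` for a missing channel (constant or insufficient
    data); MLE failures propagate.
    """
    col = np.asarray(signal_column, dtype=float).ravel()
    col = col[np.isfinite(col)]
    if col.size < 2 or np.unique(col).size < 2:
        return None
    pos, _ = preprocess_to_positive(col, *config.target_range)
    smom = signal_to_smoments(pos, clip=config.clip)
    fit = fit_apd_mle(
        smom,
        pos,
        init=config.fit_init,
        n_starts=config.n_starts,
        seed=config.seed,
        maxiter=config.fit_maxiter,
    )
    dist = ActionPotentialDistribution(pos, fit.params)
    m1, m2 = find_modes(dist, config.mode_halfwidth, config.mode_step)
    qc = config.quad_clip
    e_left = _flogf_integral(dist, -qc, m1)
    e_mid = _flogf_integral(dist, m1, m2)
    e_right = _flogf_integral(dist, m2, qc)
    tail_left = float(dist.cdf(m1)[0])
    tail_right = 1.0 - float(dist.cdf(m2)[0])
    return ChannelFeatures(
        e_left=e_left,
        e_mid=e_mid,
        e_right=e_right,
        tail_left=tail_left,
        tail_right=tail_right,
        m1=m1,
        m2=m2,
        params=fit.params,
        loglik=fit.loglik,
    )


def differential_entropy(dist: ActionPotentialDistribution, quad_clip: float = 50.0) -> float:
    """Differential entropy -int f log f of an APD, by adaptive quadrature."""
    return -_flogf_integral(dist, -quad_clip, quad_clip)


@dataclass
class SubjectFeatureVector:
    """Assembled per-subject feature vector of length 5 * M * J.

    ``mask`` flags entries that were imputed (missing channel or
    experiment); ``label`` is the class label if known.
    """

    subject_id: str
    values: np.ndarray
    mask: np.ndarray
    names: list[str]
    label: str | None = None


def _feature_names(experiments, channels) -> list[str]:
    return [
        f"{exp}_{ch}_{feat}"
        for exp in experiments
        for ch in channels
        for feat in FEATURE_NAMES
    ]


def assemble_features(
    dataset,
    config: FeatureConfig = FeatureConfig(),
    impute: bool = True,
) -> list[SubjectFeatureVector]:
    """Extract and assemble per-subject feature vectors from a cohort.

    ``dataset`` is an iterable of :class:`suddency.simulate.ExperimentMatrix`
    (or any object with ``subject_id``, ``experiment_id``, ``values``,
    ``channel_labels``).  Ordering is experiment-major, then channel, then
    the five statistics.  Missing channels/experiments are masked and, if
    ``impute`` is set, filled with the per-feature median over subjects
    that have the entry.  Subjects with every experiment missing are
    excluded with a warning.
    """
    dataset = list(dataset)
    experiments = sorted({m.experiment_id for m in dataset}, key=_experiment_order)
    channels = None
    for m in dataset:
        if channels is None:
            channels = list(m.channel_labels)
        elif list(m.channel_labels) != channels:
            raise ValueError("inconsistent channel labels across experiment matrices")
    names = _feature_names(experiments, channels)
    width = len(names)
    subjects = sorted({m.subject_id for m in dataset})
    by_key = {(m.subject_id, m.experiment_id): m for m in dataset}

    vectors = []
    for sid in subjects:
        vals = np.full(width, np.nan)
        mask = np.ones(width, dtype=bool)
        have_any = False
        pos = 0
        for exp in experiments:
            mat = by_key.get((sid, exp))
            for j, _ch in enumerate(channels):
                if mat is not None:
                    feats = channel_features(mat.values[:, j], config)
                    if feats is not None:
                        vals[pos : pos + 5] = feats.as_array()
                        mask[pos : pos + 5] = False
                        have_any = True
                pos += 5
        if not have_any:
            warnings.warn(f"subject {sid!r} has no usable experiments; excluded")
            continue
        vectors.append(SubjectFeatureVector(sid, vals, mask, names))
    if impute and vectors:
        stack = np.vstack([v.values for v in vectors])
        medians = np.nanmedian(stack, axis=0)
        medians = np.where(np.isfinite(medians), medians, 0.0)
        for v in vectors:
            v.values = np.where(v.mask, medians, v.values)
    return vectors


def _experiment_order(exp):
    canonical = {"EC": 0, "EO": 1, "TASK": 2}
    return (canonical.get(exp, 99), exp)


def features_to_frame(vectors: list[SubjectFeatureVector], labels=None) -> pd.DataFrame:
    """Feature table, one row per subject, one named column per feature."""
    df = pd.DataFrame(
        [v.values for v in vectors],
        index=[v.subject_id for v in vectors],
        columns=vectors[0].names if vectors else [],
    )
    df.index.name = "subject_id"
    if labels is not None:
        df.insert(0, "label", [labels.get(v.subject_id) for v in vectors])
    return df


def entropy_heatmap(vectors: list[SubjectFeatureVector], group_labels: dict) -> dict[str, pd.DataFrame]:
    """Per-group mean differential-entropy maps (electrode x experiment).

    Entropy per channel is the negated sum of the three segment integrals;
    masked (missing) channels are ignored in the group mean.
    """
    if not vectors:
        raise ValueError("no feature vectors supplied")
    names = vectors[0].names
    experiments, channels = [], []
    parsed = [nm.rsplit("_", 2)[0] for nm in names[::5]]  # "EXP_CH"
    for p in parsed:
        exp, ch = p.split("_", 1)
        if exp not in experiments:
            experiments.append(exp)
        if ch not in channels:
            channels.append(ch)
    out = {}
    groups = sorted(set(group_labels.values()))
    for g in groups:
        members = [v for v in vectors if group_labels.get(v.subject_id) == g]
        if not members:
            raise ValueError(f"group {g!r} has no subjects")
        heat = np.full((len(channels), len(experiments)), np.nan)
        for ci, ch in enumerate(channels):
            for ei, exp in enumerate(experiments):
                base = (ei * len(channels) + ci) * 5
                vals = []
                for v in members:
                    if not v.mask[base]:
                        vals.append(-(v.values[base] + v.values[base + 1] + v.values[base + 2]))
                if vals:
                    heat[ci, ei] = float(np.mean(vals))
        out[g] = pd.DataFrame(heat, index=channels, columns=experiments)
    return out
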