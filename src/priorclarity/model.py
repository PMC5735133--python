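"""Hierarchical Bayesian ideal-observer model of degraded-speech clarity.

The listener combines a prior expectation about upcoming speech content
(set up by a written cue) with degraded sensory input.  Subjective
clarity is modelled as a function of the precision of the resulting
posterior percept:

* sensory precision ``s_c`` at each vocoder-channel level ``c`` is fixed
  per subject from 4AFC identification accuracy, as the proportion
  correct above chance: ``s_c = max(0, (acc_c - 0.25) / 0.75)``;
* posterior precision multiplies sensory precision by a weighted
  function of prior precision, ``P = s * (1 + w / sigma_prior**2)``,
  with congruency weighting ``w = 0.5`` for a matching cue (the cue is
  valid on half the trials) and ``w = 0`` for mismatching or
  uninformative cues, so that ``P`` reduces exactly to ``s`` when the
  prior carries no weight;
* clarity: posterior precision at or below a perceptual threshold
  ``theta`` is rated 1 (completely unclear); above threshold the height
  is mapped linearly onto the remainder of the 1-4 scale, anchored so
  the subject's highest-precision condition reaches 4 (participants are
  instructed to use the full range of the scale).

Two free parameters per subject — the prior standard deviation
``sigma_prior`` and the threshold ``theta`` — are fitted by global
least squares against the six condition-mean ratings.  A *complex*
variant additionally frees the matching-cue weighting for 16-channel
speech (approximating psychometric-function saturation at high sensory
detail); variants are compared with the small-sample-corrected Akaike
information criterion (AICc).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .design import CHANNEL_LEVELS

CHANCE_4AFC = 0.25
W_MATCH = 0.5
W_MISMATCH = 0.0
W_NEUTRAL = 0.0

SIGMA_BOUNDS = (1e-3, 1e3)
THETA_BOUNDS = (0.0, 1.0)
W16_BOUNDS = (0.0, 1.0)

#: canonical condition order used throughout fitting
CONDITION_ORDER: tuple[tuple[str, int], ...] = tuple(
    (cong, ch) for cong in ("match", "mismatch") for ch in CHANNEL_LEVELS
)


class DegenerateMappingError(ValueError):
    """All posterior precisions lie at or below threshold: no rating range."""


def sensory_precision_from_accuracy(accuracy: float, chance: float = CHANCE_4AFC) -> float:
    """Proportion-above-chance identification accuracy, floored at zero."""
    accuracy = float(accuracy)
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must lie in [0, 1], got {accuracy}")
    return max(0.0, (accuracy - chance) / (1.0 - chance))


def posterior_precision(s, sigma_prior, w):
    """Precision of the combined percept, ``s * (1 + w / sigma_prior**2)``.

    Monotone increasing in the congruency weighting ``w`` and in prior
    precision ``1/sigma_prior**2``; equals the sensory precision when the
    prior carries no weight.  Accepts scalars or arrays.
    """
    s = np.asarray(s, dtype=float)
    sigma = np.asarray(sigma_prior, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma_prior must be positive")
    if np.any(s < 0):
        raise ValueError("sensory precision must be non-negative")
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weighting must lie in [0, 1]")
    out = s * (1.0 + w / sigma**2)
    return float(out) if out.ndim == 0 else out


def predict_clarity(precisions, threshold: float, p_ref: float | None = None):
    """Map posterior precisions to predicted mean ratings on the 1-4 scale.

    ``p_ref`` anchors the top of the scale; by default it is the maximum
    of the supplied condition precisions (the subject's clearest
    condition rates 4).
    """
    p = np.asarray(precisions, dtype=float)
    theta = float(threshold)
    if theta < 0:
        raise ValueError("threshold must be non-negative")
    ref = float(np.max(p)) if p_ref is None else float(p_ref)
    if ref <= theta:
        raise DegenerateMappingError(
            "all posterior precisions are at or below threshold; every condition "
            "would be rated 1 (all-unclear subject)"
        )
    rating = 1.0 + 3.0 * (p - theta) / (ref - theta)
    rating = np.clip(rating, 1.0, 4.0)
    rating = np.where(p <= theta, 1.0, rating)
    return rating


@dataclass(frozen=True)
class PerceptualParameters:
    sigma_prior: float
    threshold: float
    w_match_16: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_prior <= 0:
            raise ValueError("sigma_prior must be positive")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


@dataclass
class ModelFitResult:
    variant: str
    parameters: PerceptualParameters
    rss: float
    n_points: int
    k: int
    aicc: float
    variance_explained_pct: float
    data_hash: str
    boundary_warning: bool = False
    predicted: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "sigma_prior": self.parameters.sigma_prior,
            "threshold": self.parameters.threshold,
            "w_match_16": self.parameters.w_match_16,
            "rss": self.rss,
            "n_points": self.n_points,
            "k": self.k,
            "aicc": self.aicc,
            "variance_explained_pct": self.variance_explained_pct,
            "boundary_warning": self.boundary_warning,
        }


def aicc(rss: float, n: int, k: int) -> float:
    """Akaike information criterion corrected for small samples.

    ``n ln(rss/n) + 2k + 2k(k+1)/(n - k - 1)`` under the Gaussian
    least-squares likelihood; the correction is undefined for
    ``n - k - 1 < 1``.
    """
    if n - k - 1 < 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n - k - 1 < 1)")
    if rss <= 0:
        rss = np.finfo(float).tiny
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def variance_explained(predicted, observed) -> float:
    """Percentage of observed variance captured: 100 * (1 - SS_res / SS_tot)."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def _condition_arrays(s_table: Mapping[int, float]):
    """Per-condition sensory precision and match indicator, in canonical order."""
    missing = [c for c in CHANNEL_LEVELS if c not in s_table]
    if missing:
        raise ValueError(f"sensory precision table missing channel levels {missing}")
    s = np.array([s_table[ch] for _, ch in CONDITION_ORDER], dtype=float)
    is_match = np.array([cong == "match" for cong, _ in CONDITION_ORDER])
    is_match16 = np.array(
        [cong == "match" and ch == 16 for cong, ch in CONDITION_ORDER]
    )
    return s, is_match, is_match16


def predict_condition_means(
    s_table: Mapping[int, float],
    sigma_prior: float,
    threshold: float,
    w_match_16: float | None = None,
) -> np.ndarray:
    """Predicted mean rating for the six match/mismatch x channels conditions.

    Returns all-ones (degenerate, everything unclear) if no condition
    precision exceeds the threshold.
    """
    s, is_match, is_match16 = _condition_arrays(s_table)
    w = np.where(is_match, W_MATCH, W_MISMATCH)
    if w_match_16 is not None:
        w = np.where(is_match16, w_match_16, w)
    p = posterior_precision(s, sigma_prior, w)
    try:
        return predict_clarity(p, threshold)
    except DegenerateMappingError:
        return np.ones_like(p)


def observed_vector(observed: Mapping[tuple[str, int], float]) -> np.ndarray:
    obs = np.array([observed[c] for c in CONDITION_ORDER], dtype=float)
    if np.any((obs < 1.0) | (obs > 4.0)):
        raise ValueError("condition-mean ratings must lie in [1, 4]")
    return obs


def data_hash(observed: Mapping[tuple[str, int], float]) -> str:
    payload = json.dumps(
        {f"{c[0]}/{c[1]}": round(float(observed[c]), 12) for c in CONDITION_ORDER}
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def rss_surface(
    observed: Mapping[tuple[str, int], float],
    s_table: Mapping[int, float],
    sigma_grid: np.ndarray,
    theta_grid: np.ndarray,
) -> np.ndarray:
    """Residual sum of squares of the simple model on a (sigma, theta) grid.

    Vectorised over the grid; used as an independent check on the global
    optimiser and useful for visualising the fit landscape.
    """
    obs = observed_vector(observed)
    s, is_match, _ = _condition_arrays(s_table)
    w = np.where(is_match, W_MATCH, W_MISMATCH)
    sig = np.asarray(sigma_grid, dtype=float)[:, None, None]
    th = np.asarray(theta_grid, dtype=float)[None, :, None]
    p = s[None, None, :] * (1.0 + w[None, None, :] / sig**2)
    ref = p.max(axis=2, keepdims=True)
    span = ref - th
    with np.errstate(divide="ignore", invalid="ignore"):
        rating = 1.0 + 3.0 * (p - th) / span
    rating = np.clip(rating, 1.0, 4.0)
    rating = np.where(p <= th, 1.0, rating)
    rating = np.where(span <= 0, 1.0, rating)  # degenerate: all unclear
    return np.sum((rating - obs[None, None, :]) ** 2, axis=2)


def fit_subject(
    observed: Mapping[tuple[str, int], float],
    s_table: Mapping[int, float],
    variant: str = "simple",
    n_starts: int = 32,
    seed: int = 0,
) -> ModelFitResult:
    """Fit (sigma_prior, threshold[, w_match_16]) by global least squares.

    A seeded Latin-hypercube multi-start over bounded parameter space
    (sigma on a log10 scale) with L-BFGS-B local refinement emulates
    global minimisation of squared residuals deterministically.
    """
    if variant not in ("simple", "complex"):
        raise ValueError("variant must be 'simple' or 'complex'")
    obs = observed_vector(observed)
    zero_variance = bool(np.allclose(obs, obs[0]))
    if zero_variance:
        warnings.warn(
            "observed condition means have zero variance; fit will sit on a "
            "parameter boundary",
            RuntimeWarning,
            stacklevel=2,
        )
    k = 2 if variant == "simple" else 3

    log_sig_bounds = (np.log10(SIGMA_BOUNDS[0]), np.log10(SIGMA_BOUNDS[1]))
    bounds = [log_sig_bounds, THETA_BOUNDS] + ([W16_BOUNDS] if k == 3 else [])
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(x: np.ndarray) -> float:
        sigma = 10.0 ** x[0]
        w16 = x[2] if k == 3 else None
        pred = predict_condition_means(s_table, sigma, x[1], w16)
        return float(np.sum((pred - obs) ** 2))

    sampler = qmc.LatinHypercube(d=len(bounds), seed=int(seed))
    starts = lo + sampler.random(n=n_starts) * (hi - lo)

    best_x, best_rss = None, np.inf
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_rss:
            best_rss, best_x = float(res.fun), res.x
    assert best_x is not None

    sigma_hat = float(10.0 ** best_x[0])
    theta_hat = float(best_x[1])
    w16_hat = float(best_x[2]) if k == 3 else None
    params = PerceptualParameters(sigma_hat, theta_hat, w16_hat)
    pred = predict_condition_means(s_table, sigma_hat, theta_hat, w16_hat)

    on_boundary = bool(
        np.any(np.isclose(best_x, lo, atol=1e-9)) or np.any(np.isclose(best_x, hi, atol=1e-9))
    )
    ve = np.nan if zero_variance else variance_explained(pred, obs)
    return ModelFitResult(
        variant=variant,
        parameters=params,
        rss=best_rss,
        n_points=len(obs),
        k=k,
        aicc=aicc(best_rss, len(obs), k),
        variance_explained_pct=ve,
        data_hash=data_hash(observed),
        boundary_warning=on_boundary or zero_variance,
        predicted=pred,
    )


@dataclass(frozen=True)
class VariantPreference:
    winner: str
    delta_aicc: float


def compare_variants(
    fit_simple: ModelFitResult, fit_complex: ModelFitResult
) -> VariantPreference:
    """AICc preference between the 2- and 3-parameter variants; ties favour parsimony."""
    if fit_simple.variant != "simple" or fit_complex.variant != "complex":
        raise ValueError("arguments must be the simple and complex fits, in that order")
    if fit_simple.data_hash != fit_complex.data_hash:
        raise ValueError("fits were obtained on different observed data")
    if fit_complex.aicc < fit_simple.aicc:
        return VariantPreference("complex", fit_simple.aicc - fit_complex.aicc)
    return VariantPreference("simple", fit_complex.aicc - fit_simple.aicc)
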