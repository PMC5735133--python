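"""Ground-truth synthetic data: behaviour, coupled oscillatory sources,
implanted time-frequency contrasts, and a toy noise vocoder.

The behavioural generator runs the perceptual model *forwards* from known
parameters, so that the fitting machinery can be validated by parameter
recovery.  A cohort defaults to the study conditions: 11 subjects per
group, where the simulated patient group draws more precise prior
expectations (smaller prior SD) than controls, 108 Experiment 1 trials
per condition and the 90-trial identification block.

Neural generators provide a two-region (frontal/temporal) test bed with
known directed beta-band coupling for the connectivity statistics, and
time-frequency map pairs whose congruency-contrast latency is implanted
exactly, for closed-loop validation of the t80 statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import expit

from . import model
from .design import (
    CHANNEL_LEVELS,
    Exp1Schedule,
    Exp1Trial,
    Exp2Trial,
    build_exp1_schedule,
    build_exp2_schedule,
    default_response_sets,
    default_word_pool,
)
from .neural import SFREQ, DEFAULT_FREQS, ANALYSIS_WINDOW_S, TimeFrequencyMap

# Exp2 accuracy model defaults: logit slope per doubling of channels above 4,
# and penalty per phonological neighbour in the response array.
B_CHANNELS = 1.0
B_NEIGHBOURS = 0.5

#: neighbour-count distribution over the 30 trials at each channel level
#: (cases 1/2/3/4 have 2/1/1/0 neighbours with counts 10/5/5/10)
_EXP2_NEIGHBOUR_WEIGHTS = {2: 10 / 30, 1: 10 / 30, 0: 10 / 30}


@dataclass(frozen=True)
class TruePerceptualParameters:
    """Generating parameters for one simulated subject."""

    sigma_prior: float
    threshold: float
    rating_noise_sd: float = 0.3
    identification_ability: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_prior <= 0:
            raise ValueError("sigma_prior must be positive")
        if self.threshold < 0 or self.rating_noise_sd < 0:
            raise ValueError("threshold and rating_noise_sd must be non-negative")


def accuracy_model(
    ability: float, channels: int, n_neighbours: int,
    b_channels: float = B_CHANNELS, b_neighbours: float = B_NEIGHBOURS,
) -> float:
    """4AFC accuracy with a chance floor: 0.25 + 0.75 * logistic(...)."""
    logit = ability + b_channels * np.log2(channels / 4.0) - b_neighbours * n_neighbours
    return float(0.25 + 0.75 * expit(logit))


def expected_accuracy_by_channels(params: TruePerceptualParameters) -> dict[int, float]:
    """Expected identification accuracy per channel level, averaged over the
    neighbour-count mix of the 4AFC design."""
    return {
        ch: sum(
            w * accuracy_model(params.identification_ability, ch, n)
            for n, w in _EXP2_NEIGHBOUR_WEIGHTS.items()
        )
        for ch in CHANNEL_LEVELS
    }


def true_sensory_precision(params: TruePerceptualParameters) -> dict[int, float]:
    acc = expected_accuracy_by_channels(params)
    return {ch: model.sensory_precision_from_accuracy(a) for ch, a in acc.items()}


@dataclass
class SubjectDataset:
    """Observable data for one subject plus derived sensory-precision tables."""

    exp1: pd.DataFrame  # block, congruency, channels, rating
    exp2: pd.DataFrame  # channels, n_neighbours, case_label, correct
    sensory_precision_measured: dict[int, float]
    sensory_precision_true: dict[int, float] | None = None

    def condition_means(self) -> dict[tuple[str, int], float]:
        g = self.exp1.groupby(["congruency", "channels"])["rating"].mean()
        return {(str(c), int(ch)): float(v) for (c, ch), v in g.items()}

    def exp2_accuracy_by_channels(self) -> dict[int, float]:
        g = self.exp2.groupby("channels")["correct"].mean()
        return {int(ch): float(v) for ch, v in g.items()}


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def simulate_subject_behaviour(
    params: TruePerceptualParameters,
    exp1: Exp1Schedule | Sequence[Exp1Trial],
    exp2: Sequence[Exp2Trial],
    seed: int = 0,
) -> SubjectDataset:
    """Forward-simulate clarity ratings and 4AFC outcomes for one subject.

    Ratings are the model's predicted condition mean plus Gaussian noise,
    rounded half-up and clipped to {1,2,3,4}; identification outcomes are
    Bernoulli draws from the logistic accuracy model.
    """
    rng = np.random.default_rng(seed)
    trials = exp1.trials if isinstance(exp1, Exp1Schedule) else list(exp1)
    s_true = true_sensory_precision(params)

    conditions = sorted({(t.condition.congruency, t.condition.channels) for t in trials})
    weights = {"match": model.W_MATCH, "mismatch": model.W_MISMATCH,
               "neutral": model.W_NEUTRAL}
    precisions = {
        c: model.posterior_precision(s_true[c[1]], params.sigma_prior, weights[c[0]])
        for c in conditions
    }
    p_ref = max(precisions.values())
    pred = {
        c: float(model.predict_clarity(np.array([p]), params.threshold, p_ref=p_ref)[0])
        for c, p in precisions.items()
    }

    cong = [t.condition.congruency for t in trials]
    chans = [t.condition.channels for t in trials]
    clean = np.array([pred[(c, ch)] for c, ch in zip(cong, chans)])
    noisy = clean + rng.normal(0.0, params.rating_noise_sd, size=clean.size)
    ratings = np.clip(_round_half_up(noisy), 1, 4).astype(int)
    exp1_df = pd.DataFrame(
        {
            "block": [t.block for t in trials],
            "congruency": cong,
            "channels": chans,
            "rating": ratings,
        }
    )

    acc = np.array(
        [
            accuracy_model(params.identification_ability, t.channels,
                           t.n_neighbours_in_array)
            for t in exp2
        ]
    )
    correct = rng.random(acc.size) < acc
    exp2_df = pd.DataFrame(
        {
            "channels": [t.channels for t in exp2],
            "n_neighbours": [t.n_neighbours_in_array for t in exp2],
            "case_label": [t.case_label for t in exp2],
            "correct": correct.astype(int),
        }
    )
    measured = {
        ch: model.sensory_precision_from_accuracy(a)
        for ch, a in exp2_df.groupby("channels")["correct"].mean().items()
    }
    return SubjectDataset(
        exp1=exp1_df,
        exp2=exp2_df,
        sensory_precision_measured={int(k): float(v) for k, v in measured.items()},
        sensory_precision_true=s_true,
    )


@dataclass(frozen=True)
class GroupParameterDistribution:
    """Log-normal prior-SD and (clipped) normal threshold/ability spreads."""

    sigma_prior_median: float
    sigma_prior_log_sd: float = 0.4
    threshold_mean: float = 0.10
    threshold_sd: float = 0.03
    rating_noise_sd: float = 0.3
    ability_mean: float = 0.5
    ability_sd: float = 0.3

    def draw(self, rng: np.random.Generator) -> TruePerceptualParameters:
        sigma = float(np.exp(rng.normal(np.log(self.sigma_prior_median),
                                        self.sigma_prior_log_sd)))
        theta = float(np.clip(rng.normal(self.threshold_mean, self.threshold_sd),
                              0.0, None))
        ability = float(rng.normal(self.ability_mean, self.ability_sd))
        return TruePerceptualParameters(sigma, theta, self.rating_noise_sd, ability)


#: Study-condition defaults: patients hold more precise (smaller-SD) priors,
#: slightly lower thresholds and slightly weaker identification ability.
DEFAULT_GROUPS: dict[str, GroupParameterDistribution] = {
    "control": GroupParameterDistribution(
        sigma_prior_median=1.0, threshold_mean=0.10, ability_mean=0.5
    ),
    "patient": GroupParameterDistribution(
        sigma_prior_median=0.4, threshold_mean=0.07, ability_mean=0.0
    ),
}


@dataclass
class CohortSpec:
    n_per_group: int = 11
    groups: Mapping[str, GroupParameterDistribution] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    seed: int = 0


def simulate_cohort(
    spec: CohortSpec,
) -> list[tuple[str, SubjectDataset, TruePerceptualParameters]]:
    """Simulate a two-group cohort; returns observables plus hidden truths.

    Every subject receives a freshly seeded Experiment 1 schedule (orders
    A/B counterbalanced within group) and the fixed-design 4AFC block.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 10]))
    pool = default_word_pool(400)
    sets = default_response_sets()
    out = []
    for gi, (group, dist) in enumerate(sorted(spec.groups.items())):
        for i in range(spec.n_per_group):
            params = dist.draw(rng)
            sched_seed = int(spec.seed) * 1009 + gi * 101 + i
            exp1 = build_exp1_schedule(pool, "A" if i % 2 == 0 else "B", sched_seed)
            exp2 = build_exp2_schedule(sets, sched_seed)
            ds = simulate_subject_behaviour(
                params, exp1, exp2, seed=int(rng.integers(2**31))
            )
            out.append((group, ds, params))
    return out


@dataclass
class SourceTrialSet:
    """Per-trial source time series for the frontal and temporal regions."""

    frontal: np.ndarray  # (n_trials, n_samples)
    temporal: np.ndarray
    sfreq: float = SFREQ
    condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frontal.shape != self.temporal.shape:
            raise ValueError("regions must have equal trial counts and lengths")
        expected = int(round(ANALYSIS_WINDOW_S * self.sfreq))
        if self.frontal.shape[1] != expected:
            raise ValueError(
                f"sample count must be {expected} (0-912 ms at {self.sfreq:g} Hz)"
            )
        if self.condition is None:
            self.condition = np.zeros(self.frontal.shape[0], dtype=int)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.frontal.shape[1]) / self.sfreq * 1000.0


@dataclass(frozen=True)
class CouplingSpec:
    direction: str = "frontal_to_temporal"
    band_hz: tuple[float, float] = (13.0, 23.0)
    lag_samples: int = 3
    strength: float = 0.4

    def __post_init__(self) -> None:
        if self.direction not in (
            "frontal_to_temporal", "temporal_to_frontal", "none", "bidirectional"
        ):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.lag_samples < 1:
            raise ValueError("lag must be >= 1 sample (zero-lag coupling carries "
                             "no imaginary coherence)")
        if not 0.0 <= self.strength < 1.0:
            raise ValueError("strength must lie in [0, 1)")


def _band_noise(rng, n_trials, n_samples, band, sfreq, pad):
    sos = signal.butter(4, band, btype="bandpass", fs=sfreq, output="sos")
    x = rng.standard_normal((n_trials, n_samples + 2 * pad))
    x = signal.sosfiltfilt(sos, x, axis=-1)
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


def simulate_coupled_sources(
    spec: CouplingSpec, n_trials: int = 60, seed: int = 0
) -> SourceTrialSet:
    """Two-region trials with directed band-limited coupling.

    The driver carries a band-limited component; the receiver gets a
    lagged copy scaled so that ``strength`` is the fraction of its
    variance attributable to the driver, plus independent noise.  With
    ``direction='none'`` the regions are fully independent.
    """
    n_samples = int(round(ANALYSIS_WINDOW_S * SFREQ))
    rng = np.random.default_rng(seed)
    pad = max(spec.lag_samples, 32)

    def mix(component, noise_level):
        return component + noise_level * rng.standard_normal(component.shape)

    if spec.direction == "none":
        f = _band_noise(rng, n_trials, n_samples, spec.band_hz, SFREQ, pad)[:, pad:-pad]
        t = _band_noise(rng, n_trials, n_samples, spec.band_hz, SFREQ, pad)[:, pad:-pad]
        frontal, temporal = mix(f, 1.0), mix(t, 1.0)
    elif spec.direction == "bidirectional":
        c1 = _band_noise(rng, n_trials, n_samples, spec.band_hz, SFREQ, pad)
        c2 = _band_noise(rng, n_trials, n_samples, spec.band_hz, SFREQ, pad)
        a = np.sqrt(spec.strength)
        b = np.sqrt(1.0 - spec.strength)
        lag = spec.lag_samples
        frontal = (c1[:, pad:-pad]
                   + a * c2[:, pad - lag : -pad - lag]
                   + b * rng.standard_normal((n_trials, n_samples)))
        temporal = (c2[:, pad:-pad]
                    + a * c1[:, pad - lag : -pad - lag]
                    + b * rng.standard_normal((n_trials, n_samples)))
    else:
        comp = _band_noise(rng, n_trials, n_samples, spec.band_hz, SFREQ, pad)
        driver = comp[:, pad:-pad] + rng.standard_normal((n_trials, n_samples))
        lagged = comp[:, pad - spec.lag_samples : -pad - spec.lag_samples]
        receiver = (np.sqrt(spec.strength) * lagged
                    + np.sqrt(1.0 - spec.strength)
                    * rng.standard_normal((n_trials, n_samples)))
        if spec.direction == "frontal_to_temporal":
            frontal, temporal = driver, receiver
        else:
            frontal, temporal = receiver, driver
    return SourceTrialSet(frontal=np.ascontiguousarray(frontal),
                          temporal=np.ascontiguousarray(temporal))


def simulate_tf_contrast(
    latency_ms: float,
    peak_freq_hz: float = 18.0,
    amplitude: float = 1.0,
    seed: int = 0,
    ramp_ms: float = 150.0,
    window_ms: tuple[float, float] = (0.0, 1000.0),
    noise_sd_fraction: float = 1e-3,
) -> tuple[TimeFrequencyMap, TimeFrequencyMap]:
    """Match/mismatch map pair whose 12-24 Hz contrast t80 is implanted.

    The mismatch-minus-match contrast ramps linearly from onset to peak
    so that it first reaches 80% of peak at ``latency_ms`` (up to one
    4 ms sample).  The implant is snapped to the sampling grid, with the
    analogue crossing aimed half a sample early so the small additive
    noise cannot shift the sampled crossing.  Returns (match, mismatch)
    baseline-rescaled maps.
    """
    t0w, t1w = window_ms
    if not (t0w < latency_ms <= t1w):
        raise ValueError(f"latency {latency_ms} ms outside analysis window {window_ms}")
    rng = np.random.default_rng(seed)
    dt = 1000.0 / SFREQ
    times = np.arange(t0w, t1w + 1e-9, dt)
    freqs = DEFAULT_FREQS

    grid_latency = t0w + max(1.0, np.round((latency_ms - t0w) / dt)) * dt
    grid_latency = min(grid_latency, times[-1])
    target = grid_latency - 0.5 * dt  # analogue 80% crossing
    ramp = min(ramp_ms, (target - t0w) / 0.8, (t1w - target) / 0.2)
    onset = target - 0.8 * ramp
    c = np.clip((times - onset) / ramp, 0.0, 1.0) if ramp > 0 else (times >= onset) * 1.0

    g = np.exp(-0.5 * ((freqs - peak_freq_hz) / 4.0) ** 2)
    contrast = amplitude * c[:, None] * g[None, :]
    noise_sd = noise_sd_fraction * abs(amplitude)
    match = rng.normal(0.0, noise_sd, size=contrast.shape) if noise_sd else np.zeros_like(contrast)
    mismatch = contrast + (
        rng.normal(0.0, noise_sd, size=contrast.shape) if noise_sd else 0.0
    )
    kw = dict(times_ms=times, freqs_hz=freqs, rescaled=True)
    return (TimeFrequencyMap(power=match, **kw),
            TimeFrequencyMap(power=mismatch, **kw))


def vocode(
    waveform: np.ndarray,
    sample_rate: float,
    n_channels: int,
    seed: int = 0,
    band_lo_hz: float = 70.0,
    band_hi_hz: float = 5000.0,
    envelope_cutoff_hz: float = 30.0,
) -> np.ndarray:
    """Toy noise vocoder: band envelopes of the input modulate band noise.

    Bands are log-spaced between 70 and 5000 Hz; envelopes are extracted
    by half-wave rectification and 30 Hz low-pass filtering.  More
    channels preserve more spectral detail.  Output matches the input's
    duration and RMS.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1 or not np.all(np.isfinite(x)):
        raise ValueError("waveform must be a finite mono signal")
    hi = min(band_hi_hz, 0.45 * sample_rate)
    edges = np.logspace(np.log10(band_lo_hz), np.log10(hi), n_channels + 1)
    rng = np.random.default_rng(seed)
    env_sos = signal.butter(2, envelope_cutoff_hz, btype="lowpass", fs=sample_rate,
                            output="sos")
    out = np.zeros_like(x)
    for lo, hi_ in zip(edges[:-1], edges[1:]):
        sos = signal.butter(3, (lo, hi_), btype="bandpass", fs=sample_rate,
                            output="sos")
        band = signal.sosfiltfilt(sos, x)
        env = signal.sosfiltfilt(env_sos, np.maximum(band, 0.0))
        env = np.maximum(env, 0.0)
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(x.size))
        out += env * carrier
    rms_in = np.sqrt(np.mean(x**2))
    rms_out = np.sqrt(np.mean(out**2))
    if rms_out > 0:
        out *= rms_in / rms_out
    return out


def band_envelope_correlation(
    original: np.ndarray, processed: np.ndarray, sample_rate: float,
    n_analysis_bands: int = 12,
) -> float:
    """Mean correlation of log-spaced band envelopes between two signals.

    A simple intelligibility proxy used to verify that more vocoder
    channels transmit more spectro-temporal detail.
    """
    edges = np.logspace(np.log10(100.0), np.log10(0.45 * sample_rate / 2),
                        n_analysis_bands + 1)
    env_sos = signal.butter(2, 30.0, btype="lowpass", fs=sample_rate, output="sos")
    cors = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sos = signal.butter(3, (lo, hi), btype="bandpass", fs=sample_rate,
                            output="sos")
        e1 = signal.sosfiltfilt(env_sos, np.abs(signal.sosfiltfilt(sos, original)))
        e2 = signal.sosfiltfilt(env_sos, np.abs(signal.sosfiltfilt(sos, processed)))
        if e1.std() > 0 and e2.std() > 0:
            cors.append(np.corrcoef(e1, e2)[0, 1])
    return float(np.mean(cors)) if cors else np.nan
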