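"""Synthetic resting-EEG cohorts and spatial working-memory trial logs.

The generator produces data with the statistical structure the analysis
assumes, so every downstream stage can be exercised without real recordings.

**EEG signal model.** Each subject-condition has a target power spectral
density (uV^2/Hz)

    psd(f) = offset * f^(-exponent)                (aperiodic 1/f background)
           + sum_b A_b * exp(-(f - c_b)^2 / (2 s_b^2))   (oscillatory bumps)
           + 2 * noise_sd^2 / sfreq                (sensor white-noise floor)

with Gaussian bumps for theta, alpha, beta and gamma. The alpha bump is
centred at the subject's individual alpha peak frequency (IAPF, group means
10.38 Hz young / 9.56 Hz older, between-subject SD 1 Hz) and the theta bump
rides 4.5 Hz below it, so band anchoring has ground truth to recover.
Time series are realised in the frequency domain (random-phase shaping of
the one-sided amplitude spectrum); all channels share one oscillatory
realisation and receive independent 1/f + white backgrounds.

Group and condition effects are encoded in the default amplitudes: lower
IAPF, theta and alpha amplitudes in the older group; eyes-closed alpha
enhancement (eyes-open alpha is a fixed fraction of eyes-closed); higher
eyes-open gamma in the older group. A configurable fraction of older
profiles is generated peakless (zero alpha bump) to emulate the "no clear
alpha peak" exclusions (3 of 27 by default).

**Latent coupling.** A standard-normal latent factor z scales the theta,
alpha and beta bump amplitudes and the aperiodic offset multiplicatively
(exp(lambda*z)), so the first principal component of the EEG features tracks
broadband oscillatory power. The same z lowers the per-choice success
probability of the memory task in the *older group only* — the planted
older-only EEG-behavior coupling.

**Behavior model.** Each recall choice succeeds with probability
p = sigmoid(base_logit[group] - coupling[group]*z + ability_sd*e),
e ~ N(0,1) per subject. A trial ends at the third goal; the sequence of
visits is recorded so that CBE and NET can be scored from the log. The base
logits (1.7096 young, 0.1848 older) solve the closed-form expectations
E[CBE] = E[p + p^2 + p^3] and E[NET] = 10 E[p^3] to balance both against
the study's printed group means (2.19/5.95 young, 1.22/2.46 older).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .memory import Trial, TrialLog
from .spectral import F_MAX, F_MIN, GRID_STEP, PowerSpectrum

__all__ = [
    "CohortSpec",
    "EffectConfig",
    "BehaviorConfig",
    "SubjectProfile",
    "sample_cohort",
    "expected_psd",
    "synthesize_eeg",
    "simulate_spectrum",
    "generate_trial_log",
    "PAD_GRID_SHAPE",
    "pads_adjacent",
]

GROUPS = ("young", "older")
CONDITIONS = ("closed", "open")
BANDS = ("theta", "alpha", "beta", "gamma")

# 18 floor pads on a 3 x 6 grid; adjacency = shared grid edge
PAD_GRID_SHAPE = (3, 6)
N_PADS = 18


@dataclass(frozen=True)
class CohortSpec:
    """Cohort sizes and recording geometry.

    Defaults mirror the study: 21 young / 27 older participants, six 1-min
    baselines alternating eyes-closed and eyes-open (3 segments of 60 s per
    condition) at 512 Hz. The synthetic montage defaults to 8 channels.
    """

    n_young: int = 21
    n_older: int = 27
    n_channels: int = 8
    sfreq: float = 512.0
    segment_len: float = 60.0
    n_segments_per_condition: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_young < 0:
            raise ValueError(f"n_young must be >= 0, got {self.n_young}")
        if self.n_older < 0:
            raise ValueError(f"n_older must be >= 0, got {self.n_older}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.sfreq <= 2 * F_MAX:
            raise ValueError(f"sfreq must exceed {2 * F_MAX} Hz, got {self.sfreq}")
        if self.segment_len < 1.0:
            raise ValueError(f"segment_len must be >= 1 s, got {self.segment_len}")
        if self.n_segments_per_condition < 1:
            raise ValueError("n_segments_per_condition must be >= 1")


def _per_group(young: float, older: float) -> dict[str, float]:
    return {"young": young, "older": older}


@dataclass(frozen=True)
class EffectConfig:
    """Generative group/condition effect parameters.

    Bump amplitudes are peak densities (uV^2/Hz) above the aperiodic
    background; only the IAPF group means are anchored to reported values,
    the remaining magnitudes encode the reported effect *directions*
    (theta/alpha lower in the older group, eyes-open alpha suppression,
    higher older eyes-open gamma) at realistic resting-EEG levels.
    """

    iapf_mean: dict = field(default_factory=lambda: _per_group(10.38, 9.56))
    iapf_sd: float = 1.0
    iapf_open_shift: float = -0.2  # Hz; eyes-open alpha peak is slightly slower
    iapf_range: tuple = (7.3, 12.7)  # keep peaks inside the 7-13 Hz search range

    alpha_amp_mean: dict = field(default_factory=lambda: _per_group(6.0, 4.0))
    alpha_amp_sd: float = 1.5
    alpha_open_ratio: float = 0.45
    theta_amp_mean: dict = field(default_factory=lambda: _per_group(1.6, 1.0))
    theta_amp_sd: float = 0.4
    theta_open_ratio: float = 0.8
    beta_amp_mean: dict = field(default_factory=lambda: _per_group(0.5, 0.5))
    beta_amp_sd: float = 0.12
    beta_open_ratio: dict = field(default_factory=lambda: _per_group(0.85, 1.1))
    gamma_amp_mean: dict = field(default_factory=lambda: _per_group(0.10, 0.12))
    gamma_amp_sd: float = 0.03
    gamma_open_ratio: dict = field(default_factory=lambda: _per_group(1.1, 1.4))

    aperiodic_offset_mean: dict = field(default_factory=lambda: _per_group(25.0, 18.0))
    aperiodic_offset_rel_sd: float = 0.2
    aperiodic_exponent_mean: float = 1.35
    aperiodic_exponent_sd: float = 0.12

    bump_sd: dict = field(
        default_factory=lambda: {"theta": 0.8, "alpha": 0.8, "beta": 2.5, "gamma": 3.5}
    )
    beta_center: float = 20.0
    gamma_center: float = 38.0

    latent_power_scale: float = 0.45  # exp(scale * z) on theta/alpha/beta + offset
    peakless_fraction_older: float = 3.0 / 27.0
    noise_sd: float = 1.0  # uV per-channel white sensor noise
    acquisition_highpass_hz: float = 1.0  # amplifier high-pass rolloff on the 1/f background


@dataclass(frozen=True)
class BehaviorConfig:
    """Per-choice success model for the 10-trial, 3-goals-among-18 task."""

    base_logit: dict = field(default_factory=lambda: _per_group(1.7096, 0.1848))
    latent_coupling: dict = field(default_factory=lambda: _per_group(0.0, 1.3))
    ability_sd: float = 0.4
    max_visits_per_trial: int = 12

    def __post_init__(self):
        for g in GROUPS:
            if g not in self.base_logit or g not in self.latent_coupling:
                raise ValueError(f"behavior config must cover group {g!r}")
        if self.ability_sd < 0:
            raise ValueError("ability_sd must be >= 0")


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters for one synthetic participant."""

    subject_id: str
    group: str
    iapf: dict  # condition -> Hz
    band_amplitudes: dict  # (band, condition) -> uV^2/Hz bump height
    aperiodic_offset: float
    aperiodic_exponent: float
    noise_sd: float
    latent_factor: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for key, amp in self.band_amplitudes.items():
            if amp < 0:
                raise ValueError(f"negative band amplitude for {key}")
        if self.band_amplitudes[("alpha", "closed")] < self.band_amplitudes[("alpha", "open")]:
            raise ValueError("eyes-closed alpha amplitude must be >= eyes-open")

    @property
    def peakless(self) -> bool:
        return self.band_amplitudes[("alpha", "closed")] == 0.0


def _truncated_normal(rng, mean, sd, low, high=np.inf):
    """Rejection-free clipped normal; adequate for mild truncation."""
    return float(np.clip(rng.normal(mean, sd), low, high))


def sample_cohort(spec: CohortSpec, config: EffectConfig | None = None) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles; deterministic given ``spec.seed``.

    A fixed number of older profiles, ``round(peakless_fraction_older *
    n_older)``, is generated with a zero alpha bump ("no clear peak").
    """
    config = config or EffectConfig()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    profiles: list[SubjectProfile] = []
    n_peakless = int(round(config.peakless_fraction_older * spec.n_older))
    peakless_idx = set(rng.choice(spec.n_older, size=n_peakless, replace=False).tolist()) if n_peakless else set()
    counters = {"young": 0, "older": 0}
    for group, n in (("young", spec.n_young), ("older", spec.n_older)):
        for i in range(n):
            z = float(rng.standard_normal())
            scale = math.exp(config.latent_power_scale * z)
            iapf_closed = _truncated_normal(
                rng, config.iapf_mean[group], config.iapf_sd, *config.iapf_range
            )
            iapf_open = float(np.clip(iapf_closed + config.iapf_open_shift, *config.iapf_range))
            amps: dict = {}
            alpha_c = _truncated_normal(rng, config.alpha_amp_mean[group], config.alpha_amp_sd, 0.5)
            theta_c = _truncated_normal(rng, config.theta_amp_mean[group], config.theta_amp_sd, 0.1)
            beta_c = _truncated_normal(rng, config.beta_amp_mean[group], config.beta_amp_sd, 0.05)
            gamma_c = _truncated_normal(rng, config.gamma_amp_mean[group], config.gamma_amp_sd, 0.01)
            peakless = group == "older" and i in peakless_idx
            amps[("alpha", "closed")] = 0.0 if peakless else alpha_c * scale
            amps[("alpha", "open")] = 0.0 if peakless else alpha_c * config.alpha_open_ratio * scale
            amps[("theta", "closed")] = theta_c * scale
            amps[("theta", "open")] = theta_c * config.theta_open_ratio * scale
            amps[("beta", "closed")] = beta_c * scale
            amps[("beta", "open")] = beta_c * config.beta_open_ratio[group] * scale
            amps[("gamma", "closed")] = gamma_c
            amps[("gamma", "open")] = gamma_c * config.gamma_open_ratio[group]
            offset = (
                _truncated_normal(
                    rng,
                    config.aperiodic_offset_mean[group],
                    config.aperiodic_offset_rel_sd * config.aperiodic_offset_mean[group],
                    1.0,
                )
                * scale
            )
            exponent = _truncated_normal(
                rng, config.aperiodic_exponent_mean, config.aperiodic_exponent_sd, 0.5, 2.5
            )
            counters[group] += 1
            profiles.append(
                SubjectProfile(
                    subject_id=f"{group[0]}{counters[group]:03d}",
                    group=group,
                    iapf={"closed": iapf_closed, "open": iapf_open},
                    band_amplitudes=amps,
                    aperiodic_offset=offset,
                    aperiodic_exponent=exponent,
                    noise_sd=config.noise_sd,
                    latent_factor=z,
                )
            )
    return profiles


def _bump_centers(profile: SubjectProfile, condition: str, config: EffectConfig) -> dict[str, float]:
    iapf = profile.iapf[condition]
    return {
        "theta": iapf - 4.5,  # centre of the anchored [iapf-6, iapf-3] theta band
        "alpha": iapf,
        "beta": config.beta_center,
        "gamma": config.gamma_center,
    }


def _background_psd(profile: SubjectProfile, freqs: np.ndarray, config: EffectConfig) -> np.ndarray:
    """Aperiodic 1/f^chi background with the amplifier high-pass rolloff.

    The rolloff (2nd-order Butterworth power response at
    ``acquisition_highpass_hz``) keeps infra-slow drift out of the synthetic
    recordings, as an acquisition chain would.
    """
    f = np.maximum(np.asarray(freqs, dtype=float), 1e-6)
    psd = profile.aperiodic_offset * np.power(f, -profile.aperiodic_exponent)
    fc = config.acquisition_highpass_hz
    if fc > 0:
        psd = psd / (1.0 + (fc / f) ** 4)
    return psd


def expected_psd(
    profile: SubjectProfile,
    condition: str,
    freqs: np.ndarray,
    config: EffectConfig | None = None,
    include_noise_floor: bool = True,
    sfreq: float = 512.0,
) -> np.ndarray:
    """Analytic one-sided target PSD (uV^2/Hz) of the signal model at ``freqs``."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    config = config or EffectConfig()
    f = np.asarray(freqs, dtype=float)
    psd = _background_psd(profile, f, config)
    centers = _bump_centers(profile, condition, config)
    for band in BANDS:
        amp = profile.band_amplitudes[(band, condition)]
        if amp > 0:
            s = config.bump_sd[band]
            psd = psd + amp * np.exp(-0.5 * ((f - centers[band]) / s) ** 2)
    if include_noise_floor:
        psd = psd + 2.0 * profile.noise_sd**2 / sfreq
    return psd


def _shape_noise(rng, psd: np.ndarray, n: int, sfreq: float) -> np.ndarray:
    """Realize a Gaussian series whose expected periodogram equals ``psd``."""
    nf = psd.size
    amp = np.sqrt(psd * sfreq * n / 2.0)
    z = (rng.standard_normal(nf) + 1j * rng.standard_normal(nf)) / math.sqrt(2.0)
    coef = amp * z
    coef[0] = 0.0
    if n % 2 == 0:
        coef[-1] = coef[-1].real * math.sqrt(2.0)
    return np.fft.irfft(coef, n=n)


def synthesize_eeg(
    profile: SubjectProfile,
    condition: str,
    spec: CohortSpec,
    rng: np.random.Generator | int | None = None,
    config: EffectConfig | None = None,
) -> np.ndarray:
    """Multichannel resting EEG (channels x samples, uV) for one condition.

    All channels share one realisation of the oscillatory (bump) component
    and receive independent aperiodic + white-noise backgrounds. The total
    duration is ``n_segments_per_condition * segment_len`` seconds.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    config = config or EffectConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(round(spec.n_segments_per_condition * spec.segment_len * spec.sfreq))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sfreq)
    centers = _bump_centers(profile, condition, config)
    osc_psd = np.zeros_like(freqs)
    for band in BANDS:
        amp = profile.band_amplitudes[(band, condition)]
        if amp > 0:
            s = config.bump_sd[band]
            osc_psd += amp * np.exp(-0.5 * ((freqs - centers[band]) / s) ** 2)
    bg_psd = _background_psd(profile, np.maximum(freqs, freqs[1]), config)
    bg_psd[0] = 0.0
    osc = _shape_noise(rng, osc_psd, n, spec.sfreq)
    data = np.empty((spec.n_channels, n))
    for c in range(spec.n_channels):
        background = _shape_noise(rng, bg_psd, n, spec.sfreq)
        white = rng.normal(0.0, profile.noise_sd, size=n)
        data[c] = osc + background + white
    return data


def simulate_spectrum(
    profile: SubjectProfile,
    condition: str,
    rng: np.random.Generator | int | None = None,
    config: EffectConfig | None = None,
    n_epochs: int = 180,
    sfreq: float = 512.0,
) -> PowerSpectrum:
    """Directly simulate the epoch-averaged scalp spectrum (fast path).

    Emulates averaging ``n_epochs`` periodogram epochs: each 0.5 Hz bin is
    the target density scaled by a Gamma(n_epochs, 1/n_epochs) multiplier
    (the chi-square averaging noise of a mean periodogram). Statistically
    matches the full time-series route at a tiny fraction of its cost; used
    for large simulation studies.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    freqs = np.arange(F_MIN, F_MAX + GRID_STEP / 2, GRID_STEP)
    psd = expected_psd(profile, condition, freqs, config, sfreq=sfreq)
    noisy = psd * rng.gamma(shape=float(n_epochs), scale=1.0 / n_epochs, size=freqs.size)
    return PowerSpectrum(freqs=freqs, power=noisy, n_epochs_used=n_epochs, condition=condition)


# ---------------------------------------------------------------------------
# working-memory trial logs
# ---------------------------------------------------------------------------


def pads_adjacent(a: int, b: int) -> bool:
    """Shared-edge adjacency of pads on the 3 x 6 grid."""
    ra, ca = divmod(a, PAD_GRID_SHAPE[1])
    rb, cb = divmod(b, PAD_GRID_SHAPE[1])
    return abs(ra - rb) + abs(ca - cb) == 1


def _sample_goal_set(rng) -> frozenset:
    while True:
        goals = rng.choice(N_PADS, size=3, replace=False)
        pairs = [(goals[0], goals[1]), (goals[0], goals[2]), (goals[1], goals[2])]
        if not any(pads_adjacent(int(a), int(b)) for a, b in pairs):
            return frozenset(int(g) for g in goals)


def per_choice_success_probability(
    profile: SubjectProfile, config: BehaviorConfig, rng: np.random.Generator
) -> float:
    """Subject-level success probability (draws the ability disturbance)."""
    logit = (
        config.base_logit[profile.group]
        - config.latent_coupling[profile.group] * profile.latent_factor
        + config.ability_sd * float(rng.standard_normal())
    )
    return 1.0 / (1.0 + math.exp(-logit))


def generate_trial_log(
    profile: SubjectProfile,
    config: BehaviorConfig | None = None,
    seed: np.random.Generator | int | None = None,
) -> TrialLog:
    """Simulate the 10-trial task for one subject.

    Each choice is a Bernoulli success (visit an un-found goal pad) with the
    subject's per-choice probability; a failure visits a random non-goal
    pad. The trial's visit sequence ends when all three goals are found or
    after ``max_visits_per_trial`` visits.
    """
    config = config or BehaviorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = per_choice_success_probability(profile, config, rng)
    trials = []
    for _ in range(10):
        goals = _sample_goal_set(rng)
        non_goals = [pad for pad in range(N_PADS) if pad not in goals]
        remaining = sorted(goals)
        visits: list[int] = []
        while remaining and len(visits) < config.max_visits_per_trial:
            if rng.random() < p:
                pick = remaining.pop(int(rng.integers(len(remaining))))
                visits.append(pick)
            else:
                visits.append(int(non_goals[rng.integers(len(non_goals))]))
        trials.append(Trial(goals=goals, visits=tuple(visits)))
    return TrialLog(trials=tuple(trials))
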