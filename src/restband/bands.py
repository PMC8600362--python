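"""Individual-alpha-anchored band definitions and the 30 EEG variables.

Because the dominant alpha rhythm slows with age, the alpha band is not fixed
but anchored per subject *and per eye condition* to the individual alpha peak
frequency (IAPF): alpha spans [peak-3, peak+2] Hz and theta is the adjacent
3 Hz band [peak-6, peak-3]. Beta (14-28 Hz), gamma (30-47 Hz) and the total
analysis band (2-47 Hz) are fixed.

Per band the module computes:

* absolute power: band-integrated density, sum of a(f)*df over the band's
  half-open bin range [f_low, f_high), df = 0.5 Hz (uV^2);
* relative power: absolute power divided by total 2-47 Hz power;
* alpha peak frequency and peak power (the detected spectral maximum);
* theta/beta averaged peak frequency ("center of gravity",
  sum a(f)*f / sum a(f) over the band) and averaged peak power (the density
  at the grid bin nearest to the center of gravity).

Fifteen parameters per condition x two eye conditions = the 30-variable
feature vector entering the multivariate analysis. A subject whose spectrum
shows no clear alpha peak in either condition cannot be band-anchored and is
excluded upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import F_MAX, F_MIN, GRID_STEP, PowerSpectrum

__all__ = [
    "AlphaPeakResult",
    "BandDefinition",
    "NoClearAlphaPeak",
    "detect_alpha_peak",
    "define_bands",
    "band_absolute_power",
    "band_relative_power",
    "center_of_gravity",
    "averaged_peak_power",
    "extract_features",
    "FEATURE_NAMES",
    "CONDITIONS",
    "DEFAULT_SEARCH_RANGE",
    "DEFAULT_PROMINENCE_THRESHOLD",
]

CONDITIONS = ("closed", "open")
DEFAULT_SEARCH_RANGE = (7.0, 13.0)  # Hz, alpha peak search window
DEFAULT_PROMINENCE_THRESHOLD = 1.25  # peak power / aperiodic trend ratio

_PER_CONDITION_FEATURES = (
    "theta_apf",
    "theta_ap_power",
    "theta_abs",
    "theta_rel",
    "alpha_peak_freq",
    "alpha_peak_power",
    "alpha_abs",
    "alpha_rel",
    "beta_apf",
    "beta_ap_power",
    "beta_abs",
    "beta_rel",
    "gamma_abs",
    "gamma_rel",
    "total_power",
)
#: the 30 variable names, `{band}_{param}_{condition}` style
FEATURE_NAMES = tuple(f"{feat}_{cond}" for cond in CONDITIONS for feat in _PER_CONDITION_FEATURES)


class NoClearAlphaPeak(ValueError):
    """Raised when band anchoring is requested for a peakless spectrum."""


@dataclass(frozen=True)
class AlphaPeakResult:
    peak_freq: float
    peak_power: float
    clear_peak: bool
    prominence: float


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not self.f_low < self.f_high:
            raise ValueError(f"band {self.name}: f_low must be < f_high")


def _aperiodic_trend(spectrum: PowerSpectrum, exclude: tuple[float, float]) -> np.ndarray:
    """Log-log linear 1/f fit over the analysis range, alpha region excluded.

    Returns the fitted trend evaluated on the full grid (linear power units).
    """
    f, p = spectrum.freqs, spectrum.power
    fit_mask = (p > 0) & ((f < exclude[0]) | (f > exclude[1]))
    if fit_mask.sum() < 3:
        # degenerate (e.g. near-zero) spectrum: flat trend at the mean level
        level = max(p.mean(), np.finfo(float).tiny)
        return np.full_like(p, level)
    coef = np.polyfit(np.log10(f[fit_mask]), np.log10(p[fit_mask]), 1)
    return 10.0 ** np.polyval(coef, np.log10(f))


def detect_alpha_peak(
    spectrum: PowerSpectrum,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
    prominence_threshold: float = DEFAULT_PROMINENCE_THRESHOLD,
) -> AlphaPeakResult:
    """Find the individual dominant alpha peak, or flag its absence.

    The candidate is the highest strict local maximum of a(f) within the
    search range. Its prominence is the ratio of its power to a log-log
    linear aperiodic fit over 2-47 Hz (excluding a margin around the search
    range); ``clear_peak`` requires prominence >= the threshold. A purely
    monotone 1/f spectrum has no qualifying local maximum and is reported as
    peakless rather than with a fabricated frequency.
    """
    f, p = spectrum.freqs, spectrum.power
    lo, hi = search_range
    if f[0] > lo or f[-1] < hi:
        raise ValueError(f"spectrum grid does not cover the search range {search_range}")
    # strict interior local maxima of the full spectrum
    interior = np.zeros_like(p, dtype=bool)
    interior[1:-1] = (p[1:-1] > p[:-2]) & (p[1:-1] > p[2:])
    in_range = (f >= lo) & (f <= hi)
    candidates = np.flatnonzero(interior & in_range)
    if candidates.size == 0:
        return AlphaPeakResult(peak_freq=np.nan, peak_power=np.nan, clear_peak=False, prominence=0.0)
    best = candidates[np.argmax(p[candidates])]
    trend = _aperiodic_trend(spectrum, exclude=(lo - 1.0, hi + 1.0))
    prominence = float(p[best] / trend[best]) if trend[best] > 0 else np.inf
    return AlphaPeakResult(
        peak_freq=float(f[best]),
        peak_power=float(p[best]),
        clear_peak=prominence >= prominence_threshold,
        prominence=prominence,
    )


def define_bands(alpha_peak: float) -> dict[str, BandDefinition]:
    """Anchor theta/alpha to the alpha peak; beta/gamma/total are fixed.

    alpha = [peak-3, peak+2], theta = [peak-6, peak-3]; the theta lower edge
    is clamped to 2 Hz (with a warning) when the peak is below 8 Hz, to stay
    inside the analysis range.
    """
    theta_low = alpha_peak - 6.0
    if theta_low < F_MIN:
        warnings.warn(
            f"alpha peak {alpha_peak:.2f} Hz puts the theta lower edge at "
            f"{theta_low:.2f} Hz; clamping to {F_MIN} Hz",
            stacklevel=2,
        )
        theta_low = F_MIN
    return {
        "theta": BandDefinition("theta", theta_low, alpha_peak - 3.0),
        "alpha": BandDefinition("alpha", alpha_peak - 3.0, alpha_peak + 2.0),
        "beta": BandDefinition("beta", 14.0, 28.0),
        "gamma": BandDefinition("gamma", 30.0, 47.0),
        "total": BandDefinition("total", F_MIN, F_MAX),
    }


def _band_mask(spectrum: PowerSpectrum, band: BandDefinition) -> np.ndarray:
    f = spectrum.freqs
    if band.f_low < f[0] - 1e-9 or band.f_high > f[-1] + GRID_STEP + 1e-9:
        raise ValueError(f"band {band.name} [{band.f_low}, {band.f_high}) outside the spectral grid")
    # half-open bin membership keeps contiguous bands disjoint
    return (f >= band.f_low - 1e-9) & (f < band.f_high - 1e-9)


def band_absolute_power(spectrum: PowerSpectrum, band: BandDefinition) -> float:
    """Band-integrated power: sum of a(f)*df over bins f_low <= f < f_high (uV^2)."""
    mask = _band_mask(spectrum, band)
    return float(spectrum.power[mask].sum() * GRID_STEP)


def band_relative_power(spectrum: PowerSpectrum, band: BandDefinition) -> float:
    """Band power as a fraction of the total 2-47 Hz power."""
    total = band_absolute_power(spectrum, BandDefinition("total", F_MIN, F_MAX))
    if total <= 0:
        raise ZeroDivisionError("zero total power: relative power undefined")
    return band_absolute_power(spectrum, band) / total


def center_of_gravity(spectrum: PowerSpectrum, band: BandDefinition) -> float:
    """Averaged peak frequency: sum(a(f)*f) / sum(a(f)) over the band's bins."""
    mask = _band_mask(spectrum, band)
    a = spectrum.power[mask]
    total = a.sum()
    if total <= 0:
        raise ZeroDivisionError(f"zero power in band {band.name}: center of gravity undefined")
    return float((a * spectrum.freqs[mask]).sum() / total)


def averaged_peak_power(spectrum: PowerSpectrum, cog_freq: float) -> float:
    """Density at the grid bin nearest the averaged peak frequency.

    Distance ties between two bins resolve toward the lower frequency.
    """
    f = spectrum.freqs
    if cog_freq < f[0] - 1e-9 or cog_freq > f[-1] + 1e-9:
        raise ValueError(f"frequency {cog_freq} Hz outside the spectral grid")
    dist = np.abs(f - cog_freq)
    # argmin returns the first (lower-frequency) index on exact ties
    return float(spectrum.power[np.argmin(dist)])


def _condition_features(
    spectrum: PowerSpectrum,
    search_range: tuple[float, float],
    prominence_threshold: float,
) -> dict[str, float]:
    peak = detect_alpha_peak(spectrum, search_range, prominence_threshold)
    if not peak.clear_peak:
        raise NoClearAlphaPeak(
            f"no clear alpha peak in condition {spectrum.condition!r}; subject must be excluded"
        )
    bands = define_bands(peak.peak_freq)
    out: dict[str, float] = {}
    for name in ("theta", "beta"):
        cog = center_of_gravity(spectrum, bands[name])
        out[f"{name}_apf"] = cog
        out[f"{name}_ap_power"] = averaged_peak_power(spectrum, cog)
        out[f"{name}_abs"] = band_absolute_power(spectrum, bands[name])
        out[f"{name}_rel"] = band_relative_power(spectrum, bands[name])
    out["alpha_peak_freq"] = peak.peak_freq
    out["alpha_peak_power"] = peak.peak_power
    out["alpha_abs"] = band_absolute_power(spectrum, bands["alpha"])
    out["alpha_rel"] = band_relative_power(spectrum, bands["alpha"])
    out["gamma_abs"] = band_absolute_power(spectrum, bands["gamma"])
    out["gamma_rel"] = band_relative_power(spectrum, bands["gamma"])
    out["total_power"] = band_absolute_power(spectrum, bands["total"])
    return out


def extract_features(
    spectra: dict[str, PowerSpectrum],
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
    prominence_threshold: float = DEFAULT_PROMINENCE_THRESHOLD,
) -> dict[str, float]:
    """The 30 named EEG variables for one subject (15 per eye condition).

    ``spectra`` maps condition ('closed', 'open') to that condition's
    scalp-averaged spectrum; bands are re-anchored to each condition's own
    alpha peak. Raises :class:`NoClearAlphaPeak` if either condition lacks
    a clear peak (such subjects are excluded from the final sample).
    """
    missing = [c for c in CONDITIONS if c not in spectra]
    if missing:
        raise ValueError(f"missing condition(s): {missing}")
    features: dict[str, float] = {}
    for cond in CONDITIONS:
        per_cond = _condition_features(spectra[cond], search_range, prominence_threshold)
        for key, value in per_cond.items():
            features[f"{key}_{cond}"] = value
    assert set(features) == set(FEATURE_NAMES)
    return features
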