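"""Spectrum validation and conversion to the fixed 1,600-feature vector.

Each accepted spectrum is interpolated with a cubic spline (natural boundary
conditions) and sampled on the even-wavenumber grid 600, 602, ..., 3798 cm^-1
(1,600 points), then standardized to zero mean and unit population standard
deviation.  Spectra with fewer than 1,626 sampling points, or that do not
cover 600-3,800 cm^-1 inclusive, are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .jcampdx import RawSpectrum

__all__ = [
    "PreprocessConfig",
    "FeatureVector",
    "ValidationVerdict",
    "DegenerateSpectrumError",
    "validate_spectrum",
    "resample_spectrum",
    "standardize",
    "preprocess_spectrum",
    "preprocess_batch",
]

REASON_TOO_FEW_POINTS = "too_few_points"
REASON_RANGE_NOT_COVERED = "range_not_covered"
REASON_DEGENERATE = "degenerate_spectrum"


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum is constant (zero variance): a flat/empty scan."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Validation thresholds and the resampling grid.

    Defaults encode the study rules: at least 1,626 sampling points, full
    coverage of 600-3,800 cm^-1, and a grid of every second wavenumber from
    600 to 3,798 cm^-1 (1,600 features).
    """

    min_points: int = 1626
    required_range_low: float = 600.0
    required_range_high: float = 3800.0
    grid_start: float = 600.0
    grid_stop: float = 3798.0
    grid_step: float = 2.0

    def __post_init__(self) -> None:
        if not self.grid_start < self.grid_stop:
            raise ValueError("grid_start must be < grid_stop")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        n, rem = divmod(self.grid_stop - self.grid_start, self.grid_step)
        if abs(rem) > 1e-9 and abs(rem - self.grid_step) > 1e-9:
            raise ValueError("grid span must be divisible by grid_step")
        if (
            self.required_range_low > self.grid_start
            or self.required_range_high < self.grid_stop
        ):
            raise ValueError("required range must contain the grid")

    @property
    def grid(self) -> np.ndarray:
        """The evaluation grid in cm^-1 (1,600 points under defaults)."""
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    @property
    def n_features(self) -> int:
        return int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1


@dataclass(frozen=True)
class ValidationVerdict:
    accepted: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


@dataclass
class FeatureVector:
    """1,600 standardized absorbance values on the fixed grid."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def validate_spectrum(
    s: RawSpectrum, cfg: PreprocessConfig | None = None
) -> ValidationVerdict:
    """Accept iff the spectrum has >= ``min_points`` samples and its
    wavenumbers cover [600, 3800] cm^-1 including both endpoints."""
    cfg = cfg or PreprocessConfig()
    if s.n_points < cfg.min_points:
        return ValidationVerdict(False, REASON_TOO_FEW_POINTS)
    if (
        s.wavenumbers[0] > cfg.required_range_low
        or s.wavenumbers[-1] < cfg.required_range_high
    ):
        return ValidationVerdict(False, REASON_RANGE_NOT_COVERED)
    return ValidationVerdict(True)


def resample_spectrum(
    s: RawSpectrum, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Fit an interpolating natural cubic spline through all points and
    evaluate it on the fixed grid (raw values, pre-standardization)."""
    cfg = cfg or PreprocessConfig()
    spline = CubicSpline(s.wavenumbers, s.absorbances, bc_type="natural")
    return np.asarray(spline(cfg.grid), dtype=float)


def standardize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Center and scale to zero mean, unit population (divide-by-N) SD.

    Raises :class:`DegenerateSpectrumError` for constant input.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("standardize needs at least 2 values")
    sd = v.std()  # population SD (ddof=0)
    if sd == 0:
        raise DegenerateSpectrumError("constant spectrum (zero variance)")
    return (v - v.mean()) / sd


def preprocess_spectrum(
    s: RawSpectrum, cfg: PreprocessConfig | None = None
) -> FeatureVector:
    """validate -> resample -> standardize for one accepted spectrum."""
    cfg = cfg or PreprocessConfig()
    verdict = validate_spectrum(s, cfg)
    if not verdict:
        raise ValueError(f"{s.sample_id}: rejected ({verdict.reason})")
    return FeatureVector(s.sample_id, standardize(resample_spectrum(s, cfg)))


def preprocess_batch(
    spectra: Iterable[RawSpectrum], cfg: PreprocessConfig | None = None
) -> tuple[list[FeatureVector], list[tuple[str, str]]]:
    """Apply the full chain per spectrum.

    Returns the feature vectors in input order plus a rejection log of
    (sample_id, reason) for spectra that fail validation or are degenerate.
    """
    cfg = cfg or PreprocessConfig()
    features: list[FeatureVector] = []
    rejections: list[tuple[str, str]] = []
    for s in spectra:
        verdict = validate_spectrum(s, cfg)
        if not verdict:
            rejections.append((s.sample_id, verdict.reason or "rejected"))
            continue
        try:
            values = standardize(resample_spectrum(s, cfg))
        except DegenerateSpectrumError:
            rejections.append((s.sample_id, REASON_DEGENERATE))
            continue
        features.append(FeatureVector(s.sample_id, values))
    return features, rejections


def features_to_frame(features: Sequence[FeatureVector], cfg: PreprocessConfig | None = None):
    """Feature matrix as a DataFrame: sample_id index, columns w0600...w3798."""
    import pandas as pd

    cfg = cfg or PreprocessConfig()
    cols = [f"w{int(round(w)):04d}" for w in cfg.grid]
    return pd.DataFrame(
        np.vstack([f.values for f in features]) if features else np.empty((0, cfg.n_features)),
        index=pd.Index([f.sample_id for f in features], name="sample_id"),
        columns=cols,
    )
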