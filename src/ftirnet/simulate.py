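"""Synthetic FTIR mixture simulator with known fentanyl weight fractions.

Street-drug samples are modelled as Beer-Lambert additive mixtures: the
absorbance at wavenumber v is the weight-fraction-weighted sum of pure
component spectra, plus a slowly-varying polynomial baseline and Gaussian
measurement noise.  Pure components are rendered from small libraries of
Gaussian/Lorentzian peaks.  Each simulated sample records its true fentanyl
weight fraction, from which two labels derive:

* ``strip_label`` — the immunoassay-strip analogue, positive whenever the
  fentanyl fraction reaches the strip's very low detection limit (0.05 % by
  weight by default).  This is the reference ("ground truth") label.
* ``ftir_proxy_label`` — a stand-in for a technician reading the FTIR
  spectrum, positive only at or above a 5 % detection-limit analogue (FTIR
  visual interpretation misses fentanyl below roughly 3-10 % by weight).

The peak positions are invented: the simulator targets the statistical
structure of the classification problem, not spectroscopic realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .jcampdx import RawSpectrum, write_jcampdx

__all__ = [
    "PeakSpec",
    "ComponentLibrary",
    "MixtureSpec",
    "SyntheticSample",
    "SimConfig",
    "default_library",
    "render_component",
    "synthesize_spectrum",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class PeakSpec:
    """One absorption band: center (cm^-1), half-width parameter (cm^-1),
    peak height (absorbance) and line shape."""

    center: float
    width: float
    height: float
    shape: Literal["gaussian", "lorentzian"] = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.height < 0:
            raise ValueError("height must be nonnegative")
        if not 600.0 <= self.center <= 3800.0:
            raise ValueError("center must lie in [600, 3800] cm^-1")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class ComponentLibrary:
    """Named pure components, each a list of peaks; one is the fentanyl
    component whose weight fraction drives the labels."""

    components: dict[str, tuple[PeakSpec, ...]]
    fentanyl_component_name: str = "fentanyl"

    def __post_init__(self) -> None:
        if self.fentanyl_component_name not in self.components:
            raise ValueError("fentanyl component missing from library")
        for name, peaks in self.components.items():
            if len(peaks) == 0:
                raise ValueError(f"component {name!r} has no peaks")
        fent = self.components[self.fentanyl_component_name]
        for name, peaks in self.components.items():
            if name != self.fentanyl_component_name and set(peaks) == set(fent):
                raise ValueError(f"component {name!r} duplicates fentanyl's peaks")

    @property
    def cut_names(self) -> list[str]:
        return [n for n in self.components if n != self.fentanyl_component_name]


@dataclass(frozen=True)
class MixtureSpec:
    """Composition of one sample: weight fractions summing to 1, baseline
    polynomial coefficients (lowest order first, absorbance units on a
    normalized abscissa) and Gaussian noise SD in absorbance units."""

    weights: dict[str, float]
    baseline_coeffs: tuple[float, ...] = ()
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {total})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SyntheticSample:
    sample_id: str
    spectrum: RawSpectrum
    fentanyl_fraction: float
    strip_label: int
    ftir_proxy_label: int
    components_present: list[str]

    @property
    def fentanyl_concentration_pct(self) -> float:
        return 100.0 * self.fentanyl_fraction


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the simulated cohort.

    ``positive_fraction`` 0.481 mirrors the observed strip-positive share;
    positives draw their fentanyl weight fraction log-uniformly over
    [0.2 %, 15 %], so a substantial share falls below the 5 % FTIR
    detection-limit analogue.  ``noise_sd`` of 0.001 absorbance units is
    typical RMS noise for a benchtop ATR-FTIR instrument.
    """

    n_samples: int = 2000
    positive_fraction: float = 0.481
    conc_low: float = 0.002   # weight fraction, 0.2 %
    conc_high: float = 0.15   # weight fraction, 15 %
    strip_lod: float = 0.0005  # 0.05 % by weight
    ftir_lod: float = 0.05     # 5 % by weight
    grid_start: float = 600.0
    grid_stop: float = 3800.0
    grid_step: float = 1.0
    noise_sd: float = 0.001
    baseline_max_frac: float = 0.2  # max |baseline| relative to max signal
    max_cuts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if not self.strip_lod < self.ftir_lod:
            raise ValueError("strip_lod must be below ftir_lod")
        if not 0 < self.conc_low < self.conc_high <= 1:
            raise ValueError("need 0 < conc_low < conc_high <= 1")
        grid = self.grid
        if len(grid) < 1626 or grid[0] > 600.0 or grid[-1] < 3800.0:
            raise ValueError("synthesis grid must have >=1626 points covering [600, 3800]")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


def _gaussian(grid: np.ndarray, p: PeakSpec) -> np.ndarray:
    return p.height * np.exp(-(((grid - p.center) / p.width) ** 2))


def _lorentzian(grid: np.ndarray, p: PeakSpec) -> np.ndarray:
    return p.height * p.width**2 / ((grid - p.center) ** 2 + p.width**2)


def render_component(
    peaks: Sequence[PeakSpec], grid: np.ndarray
) -> np.ndarray:
    """Sum of the peak line shapes on the grid; nonnegative by construction."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for p in peaks:
        out += _gaussian(grid, p) if p.shape == "gaussian" else _lorentzian(grid, p)
    return out


def default_library() -> ComponentLibrary:
    """The fixed, versioned component library shipped with the package.

    Fentanyl plus six common cuts/actives.  Fentanyl's bands at 1702 and
    3320 cm^-1 sit >= 30 cm^-1 from every other component's band centers, so
    the fentanyl fingerprint is identifiable in mixtures.
    """
    g, l = "gaussian", "lorentzian"
    comps: dict[str, tuple[PeakSpec, ...]] = {
        "fentanyl": (
            PeakSpec(700, 8, 0.55, l),
            PeakSpec(1142, 10, 0.40, g),
            PeakSpec(1448, 12, 0.50, g),
            PeakSpec(1702, 9, 1.00, l),   # amide C=O, isolated band
            PeakSpec(2940, 20, 0.30, g),
            PeakSpec(3320, 25, 0.45, g),  # isolated N-H stretch analogue
        ),
        "caffeine": (
            PeakSpec(745, 7, 0.35, l),
            PeakSpec(1025, 9, 0.30, g),
            PeakSpec(1240, 10, 0.45, g),
            PeakSpec(1545, 11, 0.60, g),
            PeakSpec(1655, 9, 0.90, l),
            PeakSpec(2955, 22, 0.25, g),
        ),
        "heroin": (
            PeakSpec(770, 8, 0.30, l),
            PeakSpec(1055, 9, 0.35, g),
            PeakSpec(1175, 9, 0.55, g),
            PeakSpec(1365, 10, 0.40, g),
            PeakSpec(1620, 10, 0.35, g),
            PeakSpec(1758, 8, 0.85, l),
            PeakSpec(2920, 24, 0.30, g),
        ),
        "methamphetamine": (
            PeakSpec(698, 6, 0.60, l),
            PeakSpec(748, 6, 0.45, l),
            PeakSpec(1085, 10, 0.25, g),
            PeakSpec(1490, 10, 0.35, g),
            PeakSpec(2800, 30, 0.40, g),
            PeakSpec(3030, 18, 0.30, g),
        ),
        "mannitol": (
            PeakSpec(878, 8, 0.40, g),
            PeakSpec(1018, 9, 0.70, g),
            PeakSpec(1078, 9, 0.65, g),
            PeakSpec(1278, 10, 0.30, g),
            PeakSpec(2900, 25, 0.25, g),
            PeakSpec(3280, 45, 0.55, g),
        ),
        "inositol": (
            PeakSpec(920, 8, 0.35, g),
            PeakSpec(1042, 8, 0.60, g),
            PeakSpec(1122, 9, 0.50, g),
            PeakSpec(1385, 10, 0.25, g),
            PeakSpec(3230, 40, 0.50, g),
        ),
        "lactose": (
            PeakSpec(898, 8, 0.35, g),
            PeakSpec(1032, 9, 0.65, g),
            PeakSpec(1068, 8, 0.55, g),
            PeakSpec(1150, 9, 0.40, g),
            PeakSpec(2895, 25, 0.20, g),
            PeakSpec(3350, 50, 0.50, g),
        ),
    }
    return ComponentLibrary(components=comps, fentanyl_component_name="fentanyl")


def synthesize_spectrum(
    lib: ComponentLibrary,
    mix: MixtureSpec,
    grid: np.ndarray,
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
) -> RawSpectrum:
    """Render one mixture: weighted component sum + baseline + noise.

    With zero noise and no baseline the output is exactly the weighted sum
    of the pure-component renders (Beer-Lambert superposition).
    """
    grid = np.asarray(grid, dtype=float)
    absorb = np.zeros_like(grid)
    for name, w in mix.weights.items():
        if name not in lib.components:
            raise KeyError(f"unknown component {name!r}")
        if w > 0:
            absorb = absorb + w * render_component(lib.components[name], grid)
    if mix.baseline_coeffs:
        # normalized abscissa in [0, 1] keeps coefficients scale-free
        t = (grid - grid[0]) / (grid[-1] - grid[0])
        absorb = absorb + np.polynomial.polynomial.polyval(t, mix.baseline_coeffs)
    if mix.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        absorb = absorb + rng.normal(0.0, mix.noise_sd, size=grid.shape)
    return RawSpectrum(
        sample_id=sample_id, wavenumbers=grid, absorbances=absorb,
        meta={"title": sample_id},
    )


def _max_pure_signal(lib: ComponentLibrary, grid: np.ndarray) -> float:
    return max(
        float(render_component(p, grid).max()) for p in lib.components.values()
    )


def generate_dataset(
    cfg: SimConfig | None = None,
    lib: ComponentLibrary | None = None,
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Simulate a labelled cohort; a pure function of (cfg, lib).

    Exactly ``floor(n * positive_fraction + 0.5)`` samples contain fentanyl
    (deterministic count, so class balance is exact).  Positives draw the
    fentanyl weight fraction log-uniformly from [conc_low, conc_high]; the
    remaining weight is split over 1-3 cuts via a Dirichlet draw.  Negatives
    contain cuts only.  Sample order is then shuffled (seeded).
    """
    cfg = cfg or SimConfig()
    lib = lib or default_library()
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    n_pos = int(np.floor(cfg.n_samples * cfg.positive_fraction + 0.5))
    max_sig = _max_pure_signal(lib, grid)
    b_scale = cfg.baseline_max_frac * max_sig / 3.0  # 3 coeffs, each <= scale

    cuts = lib.cut_names
    samples: list[SyntheticSample] = []
    is_positive = np.zeros(cfg.n_samples, dtype=bool)
    is_positive[:n_pos] = True
    rng.shuffle(is_positive)
    width = len(str(cfg.n_samples - 1))
    for i in range(cfg.n_samples):
        if is_positive[i]:
            log_f = rng.uniform(np.log(cfg.conc_low), np.log(cfg.conc_high))
            fent = float(np.exp(log_f))
        else:
            fent = 0.0
        n_cuts = int(rng.integers(1, cfg.max_cuts + 1))
        chosen = list(rng.choice(cuts, size=n_cuts, replace=False))
        parts = rng.dirichlet(np.ones(n_cuts)) * (1.0 - fent)
        weights = {c: float(p) for c, p in zip(chosen, parts)}
        if fent > 0:
            weights[lib.fentanyl_component_name] = fent
        coeffs = tuple(rng.uniform(-b_scale, b_scale, size=3))
        mix = MixtureSpec(
            weights=weights, baseline_coeffs=coeffs, noise_sd=cfg.noise_sd
        )
        sid = f"sim{i:0{width}d}"
        spec = synthesize_spectrum(lib, mix, grid, rng, sample_id=sid)
        samples.append(
            SyntheticSample(
                sample_id=sid,
                spectrum=spec,
                fentanyl_fraction=fent,
                strip_label=int(fent >= cfg.strip_lod),
                ftir_proxy_label=int(fent >= cfg.ftir_lod),
                components_present=sorted(weights),
            )
        )

    table = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "strip_label": [s.strip_label for s in samples],
            "ftir_proxy_label": [s.ftir_proxy_label for s in samples],
            "fentanyl_concentration_pct": [
                s.fentanyl_concentration_pct for s in samples
            ],
            "components_present": [
                "|".join(s.components_present) for s in samples
            ],
        }
    )
    return samples, table


def write_dataset(
    samples: Sequence[SyntheticSample],
    table: pd.DataFrame,
    out_dir: str | Path,
    cfg: SimConfig | None = None,
) -> None:
    """Persist a simulated cohort: one .jdx per sample, labels.csv, and the
    generating configuration echoed to sim_config.json."""
    out_dir = Path(out_dir)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        write_jcampdx(s.spectrum, spectra_dir / f"{s.sample_id}.jdx")
    table.to_csv(out_dir / "labels.csv", index=False)
    if cfg is not None:
        cfg_dict = asdict(cfg)
        (out_dir / "sim_config.json").write_text(
            json.dumps(cfg_dict, indent=2) + "\n"
        )
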