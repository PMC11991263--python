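"""Synthetic LIBS-like spectrum generation.

Emulates the data regime of a two-origin herb authentication study: 2
classes x 20 pressed tablets x 50 laser shots on a 370-1100 nm grid of 2048
points.  Each spectrum is

    baseline(lambda) + sum_lines  m_cl * j_tl * A_l * exp(-(lambda-c_l)^2 / 2w_l^2) + noise,

clipped at zero: a smooth polynomial continuum, Gaussian emission lines
whose amplitudes carry a per-class multiplier ``m_cl`` (the discriminative
signal) and a per-tablet multiplicative jitter ``j_tl`` shared by all shots
of that tablet (the grouped correlation structure of repeated shots on one
tablet), and i.i.d. Gaussian detector noise.

The Gaussian line profile is a deliberate simplification: real LIBS lines
are Voigt-like and ride on a plasma continuum with self-absorption effects,
none of which are modelled here.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra_io import SpectralDataset

__all__ = ["LineSpec", "SynthConfig", "generate",
           "default_angelica_like_config", "single_line_task_config",
           "CHARACTERISTIC_LINES"]

# Characteristic emission wavelengths (nm) of the elements marked in the
# reference spectra: Ca, Na, N and K.
CHARACTERISTIC_LINES = {"Ca": 616.22, "Na": 589.14, "N": 656.26, "K": 766.49}


@dataclass(frozen=True)
class LineSpec:
    """One emission line: element tag, centre (nm), amplitude, Gaussian sigma (nm)."""

    element: str
    center_nm: float
    base_intensity: float
    width_nm: float

    def __post_init__(self):
        if self.width_nm <= 0:
            raise ValueError(f"line {self.element}: width_nm must be > 0")
        if self.base_intensity < 0:
            raise ValueError(f"line {self.element}: base_intensity must be >= 0")


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the study's acquisition layout."""

    grid_start_nm: float = 370.0
    grid_end_nm: float = 1100.0
    n_points: int = 2048
    lines: tuple = ()
    class_multipliers: np.ndarray = None     # (n_classes, n_lines)
    baseline_coeffs: tuple = (0.0,)          # polynomial in u = (grid pos in [0,1])
    noise_sd: float = 0.0
    n_classes: int = 2
    tablets_per_class: int = 20
    shots_per_tablet: int = 50
    tablet_jitter_sd: float = 0.0
    class_names: tuple = None
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.grid_end_nm <= self.grid_start_nm:
            raise ValueError("grid_end_nm must exceed grid_start_nm")
        self.lines = tuple(self.lines)
        for ln in self.lines:
            if not (self.grid_start_nm <= ln.center_nm <= self.grid_end_nm):
                raise ValueError(f"line {ln.element} at {ln.center_nm} nm "
                                 "lies outside the configured grid")
        if self.class_multipliers is None:
            self.class_multipliers = np.ones((self.n_classes, len(self.lines)))
        self.class_multipliers = np.asarray(self.class_multipliers, dtype=float)
        if self.class_multipliers.shape != (self.n_classes, len(self.lines)):
            raise ValueError(
                f"class_multipliers shape {self.class_multipliers.shape} != "
                f"({self.n_classes}, {len(self.lines)})")
        if np.any(self.class_multipliers < 0):
            raise ValueError("class_multipliers must be >= 0")
        if self.noise_sd < 0 or self.tablet_jitter_sd < 0:
            raise ValueError("noise_sd and tablet_jitter_sd must be >= 0")
        if self.class_names is None:
            self.class_names = tuple(f"class{c}" for c in range(self.n_classes))
        if len(self.class_names) != self.n_classes:
            raise ValueError("one class name per class required")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_start_nm, self.grid_end_nm, self.n_points)

    @property
    def n_spectra(self) -> int:
        return self.n_classes * self.tablets_per_class * self.shots_per_tablet


def generate(cfg: SynthConfig) -> SpectralDataset:
    """Generate the labelled synthetic dataset described by ``cfg``.

    Deterministic under ``cfg.seed``: a root :class:`numpy.random.SeedSequence`
    spawns one child stream per tablet, so per-tablet draws are independent
    of generation order.
    """
    grid = cfg.grid
    u = np.linspace(0.0, 1.0, cfg.n_points)
    baseline = np.polynomial.polynomial.polyval(u, np.asarray(cfg.baseline_coeffs, float))

    centers = np.array([ln.center_nm for ln in cfg.lines])
    amps = np.array([ln.base_intensity for ln in cfg.lines])
    widths = np.array([ln.width_nm for ln in cfg.lines])
    # (n_lines, n_points) unit-amplitude profiles
    profiles = (np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / widths[:, None]) ** 2)
                if len(cfg.lines) else np.zeros((0, cfg.n_points)))

    n_tablets = cfg.n_classes * cfg.tablets_per_class
    streams = np.random.SeedSequence(cfg.seed).spawn(n_tablets)

    n = cfg.n_spectra
    intensities = np.empty((n, cfg.n_points))
    labels = np.empty(n, dtype=int)
    groups = np.empty(n, dtype=object)
    sample_ids: list[str] = []
    shot_indices = np.empty(n, dtype=int)

    row = 0
    for c in range(cfg.n_classes):
        for t in range(cfg.tablets_per_class):
            rng = np.random.default_rng(streams[c * cfg.tablets_per_class + t])
            # per-tablet line jitter shared across this tablet's shots
            jitter = 1.0 + rng.normal(0.0, cfg.tablet_jitter_sd, size=len(cfg.lines))
            jitter = np.clip(jitter, 0.0, None)
            line_amp = amps * cfg.class_multipliers[c] * jitter
            clean = baseline + line_amp @ profiles
            noise = rng.normal(0.0, cfg.noise_sd,
                               size=(cfg.shots_per_tablet, cfg.n_points)) \
                if cfg.noise_sd > 0 else np.zeros((cfg.shots_per_tablet,
                                                   cfg.n_points))
            shots = np.clip(clean[None, :] + noise, 0.0, None)
            tablet_id = f"{cfg.class_names[c]}_t{t:02d}"
            for s in range(cfg.shots_per_tablet):
                intensities[row] = shots[s]
                labels[row] = c
                groups[row] = tablet_id
                sample_ids.append(f"{tablet_id}_s{s:02d}")
                shot_indices[row] = s
                row += 1

    return SpectralDataset(wavelengths=grid, intensities=intensities,
                           labels=labels, class_names=list(cfg.class_names),
                           groups=groups, sample_ids=sample_ids,
                           shot_indices=shot_indices)


def _filler_lines() -> list[LineSpec]:
    # Non-discriminative background lines spread over the grid; amplitudes
    # and widths loosely typical of minor emission features.
    specs = [("X1", 395.3, 420.0, 0.55), ("X2", 422.67, 760.0, 0.60),
             ("X3", 445.5, 310.0, 0.70), ("X4", 500.2, 260.0, 0.80),
             ("X5", 553.1, 350.0, 0.65), ("X6", 703.4, 290.0, 0.75),
             ("X7", 819.5, 330.0, 0.90), ("X8", 868.0, 240.0, 0.85),
             ("X9", 940.3, 210.0, 1.00), ("X10", 1030.8, 180.0, 1.10)]
    return [LineSpec(e, c, a, w) for e, c, a, w in specs]


def default_angelica_like_config(seed: int = 0) -> SynthConfig:
    """Two-origin configuration with the four characteristic element lines.

    The four marked lines (Ca 616.22, Na 589.14, N 656.26, K 766.49 nm) are
    the discriminative subset — their amplitudes differ between the two
    classes — while ten filler lines are shared identically.  Baseline,
    jitter and noise levels are invented (the reference study publishes no
    noise model); they are chosen to look like a clean LIBS acquisition:
    continuum ~15% of the strongest peak, per-tablet amplitude jitter 6%,
    additive noise ~1% of the strongest peak.
    """
    discriminative = [
        LineSpec("Ca", CHARACTERISTIC_LINES["Ca"], 900.0, 0.60),
        LineSpec("Na", CHARACTERISTIC_LINES["Na"], 800.0, 0.50),
        LineSpec("N", CHARACTERISTIC_LINES["N"], 700.0, 0.55),
        LineSpec("K", CHARACTERISTIC_LINES["K"], 1000.0, 0.65),
    ]
    fillers = _filler_lines()
    lines = tuple(discriminative + fillers)
    mult = np.ones((2, len(lines)))
    mult[0, :4] = [1.30, 0.75, 1.20, 0.80]   # class 0 element signature
    mult[1, :4] = [0.75, 1.25, 0.85, 1.20]   # class 1 element signature
    return SynthConfig(
        lines=lines, class_multipliers=mult,
        baseline_coeffs=(60.0, 220.0, -230.0, 90.0),
        noise_sd=10.0, n_classes=2, tablets_per_class=20, shots_per_tablet=50,
        tablet_jitter_sd=0.06, class_names=("Anhui", "Sichuan"), seed=seed)


def single_line_task_config(seed: int = 0, elements: tuple = ("N", "Na")
                            ) -> SynthConfig:
    """A variant with one discriminative emission line per class.

    Class 0 is enhanced (and class 1 suppressed) at the first element's
    line, and vice versa at the second; all other lines are identical.  A
    model separating the classes must attend to these two lines, so the
    class-activation map for class ``k`` should peak at ``elements[k]``.

    Each discriminative line is made the dominant peak of its own class
    (base 1200 x 1.5, above the strongest shared line), so the class
    evidence is also the strongest spectral feature — the regime in which
    gradient-weighted class-activation maps localise sharply.  This task
    should be preprocessed with dataset-level (not per-spectrum) min-max
    normalisation: per-spectrum scaling would anchor the two classes on
    different maxima and smear the class signal over every line.
    """
    cfg = default_angelica_like_config(seed)
    by_element = {ln.element: i for i, ln in enumerate(cfg.lines)}
    if len(elements) != cfg.n_classes:
        raise ValueError("one discriminative element per class required")
    lines = list(cfg.lines)
    mult = np.ones_like(cfg.class_multipliers)
    for k, el in enumerate(elements):
        if el not in by_element:
            raise ValueError(f"no line for element {el!r}")
        i = by_element[el]
        lines[i] = replace(lines[i], base_intensity=1200.0)
        for c in range(cfg.n_classes):
            mult[c, i] = 1.5 if c == k else 0.6
    return replace(cfg, lines=tuple(lines), class_multipliers=mult, seed=seed)
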