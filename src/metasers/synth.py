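"""Seeded synthetic-data generators: SERS spectra and co-registered AFM/SSRM maps.

Everything the toolkit consumes can be generated here with known ground truth:

* dilution-series SERS spectra of a reporter molecule whose 1589 cm^-1 band is
  scaled so the *measured* signal-to-noise ratio follows a linear law in
  concentration (the regime in which a limit of detection is defined);
* exosome-like multi-band spectra with bands inside the packaged assignment
  windows;
* doubly modulated metasurface height maps with exosome bumps (spherical
  caps, 30-150 nm), non-conducting silver-deposition defects, conducting
  fabrication imperfections, and seeded roughness, paired pixel-for-pixel
  with an SSRM current map.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .correlate import CurrentMap, HeightMap
from .plasmon import MetasurfaceSpec, fms_profiles
from .spectra import (
    BAND_CENTER,
    BAND_HALF_WIDTH,
    SNR_SMOOTH_CM1,
    DilutionSeries,
    RamanSpectrum,
)

__all__ = [
    "SpectrumModel",
    "SurfaceModel",
    "DEFAULT_CONCENTRATIONS",
    "default_exosome_bands",
    "gen_spectrum",
    "gen_exosome_spectrum",
    "gen_dilution_series",
    "gen_surface_pair",
]

#: Default 4-mPBA dilution series in uM.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (50.0, 5.0, 0.5, 0.05)

#: Default wavenumber grid: the 600-1700 cm^-1 Stokes range at 0.5 cm^-1
#: (typical dispersion of a CCD spectrograph over this range).
GRID_START, GRID_STOP, GRID_STEP = 600.0, 1700.0, 0.5

_HALF_NORMAL_MEAN = np.sqrt(2.0 / np.pi)  # E|N(0,1)|


def _axis(start=GRID_START, stop=GRID_STOP, step=GRID_STEP) -> np.ndarray:
    return np.arange(start, stop + 0.5 * step, step)


@dataclass
class SpectrumModel:
    """Generative model of a SERS spectrum.

    ``bands`` is a list of ``(center_cm1, amplitude, width_cm1)`` Gaussian
    bands (width = standard deviation); ``baseline`` holds polynomial
    coefficients (highest degree first, numpy convention) evaluated on a
    [-1, 1]-scaled axis; ``noise_sigma`` is the per-sample Gaussian noise in
    counts.
    """

    bands: list[tuple[float, float, float]] = field(default_factory=list)
    baseline: tuple[float, ...] = (0.0,)
    noise_sigma: float = 0.0
    seed: int = 0
    grid: tuple[float, float, float] = (GRID_START, GRID_STOP, GRID_STEP)

    def __post_init__(self) -> None:
        for c, amp, w in self.bands:
            if amp <= 0 or w <= 0:
                raise ValueError("band amplitudes and widths must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def gen_spectrum(model: SpectrumModel) -> RamanSpectrum:
    """Sum of Gaussian bands + polynomial baseline + seeded Gaussian noise."""
    shift = _axis(*model.grid)
    y = np.polyval(model.baseline, (shift - shift.mean()) / (np.ptp(shift) / 2))
    for center, amp, width in model.bands:
        if not shift[0] <= center <= shift[-1]:
            warnings.warn(
                f"band at {center} cm^-1 lies outside the axis; clipped", stacklevel=2
            )
        y = y + amp * np.exp(-0.5 * ((shift - center) / width) ** 2)
    if model.noise_sigma > 0:
        rng = np.random.default_rng(model.seed)
        y = y + rng.normal(0.0, model.noise_sigma, size=shift.size)
    return RamanSpectrum(shift, y, metadata={"seed": model.seed})


def default_exosome_bands(amplitude: float = 100.0) -> list[tuple[float, float, float]]:
    """Nine Gaussian bands, one inside each packaged assignment window.

    Centers follow the major exosome SERS bands (tryptophan/nucleic acids at
    ~725, tyrosine ~820, alpha-helix backbone ~952, protein/lipid C-C ~1045,
    amide III ~1230, nucleic-acid CH2 ~1335, carotenoid ~1510, amide II
    ~1558, aromatic residues ~1600 cm^-1); amplitudes vary around
    ``amplitude`` to mimic relative band strengths.
    """
    centers = [725.0, 820.0, 952.0, 1045.0, 1230.0, 1335.0, 1510.0, 1558.0, 1600.0]
    rel = [1.0, 0.6, 0.7, 0.9, 0.8, 1.0, 0.5, 0.7, 1.2]
    return [(c, amplitude * r, 6.0) for c, r in zip(centers, rel)]


def gen_exosome_spectrum(
    amplitude: float = 100.0,
    noise_sigma: float = 2.0,
    seed: int = 0,
) -> RamanSpectrum:
    """An exosome-like multi-band spectrum on a gentle sloping baseline."""
    model = SpectrumModel(
        bands=default_exosome_bands(amplitude),
        baseline=(10.0, 30.0),
        noise_sigma=noise_sigma,
        seed=seed,
    )
    spec = gen_spectrum(model)
    spec.metadata["label"] = "synthetic exosome"
    return spec


# ---------------------------------------------------------------------------
# dilution series
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _snr_calibration(
    target_snr: float,
    noise_sigma: float,
    band_width: float,
    step: float,
    half_width: float,
    smooth_cm1: float | None,
) -> float:
    """Band amplitude whose *expected measured* S/N equals ``target_snr``.

    The pipeline's band height is the maximum of the (optionally smoothed)
    baseline-subtracted signal over the analysis window, which is upward-
    biased by the noise order statistics when the band is weak; the noise
    estimator averages |residual|, expectation ``sigma * sqrt(2/pi)``.  This
    inverts the expectation of that ratio by a fixed-seed Monte Carlo average
    (4000 window draws), so the generated series is linear in the *measured*
    S/N, matching how a real calibration curve is acquired.
    """
    from scipy.ndimage import gaussian_filter1d

    n_win = int(2 * half_width / step) + 1
    # simulate with margin so the smoothing filter sees realistic neighbours
    pad = int(3 * (smooth_cm1 or 0) / step) + 1
    x = (np.arange(n_win + 2 * pad) - (n_win // 2 + pad)) * step
    g = np.exp(-0.5 * (x / band_width) ** 2)
    rng = np.random.default_rng(987654321)  # calibration draw, independent of data seeds
    Z = rng.normal(0.0, 1.0, size=(4000, x.size))
    noise_mean = _HALF_NORMAL_MEAN * noise_sigma
    core = slice(pad, pad + n_win)

    def expected_snr(amp: float) -> float:
        y = amp * g + noise_sigma * Z
        if smooth_cm1:
            y = gaussian_filter1d(y, smooth_cm1 / step, axis=1)
        return float(np.mean(np.max(y[:, core], axis=1))) / noise_mean

    lo, hi = 0.0, max(10 * target_snr * noise_mean, 10 * noise_sigma)
    if expected_snr(lo) >= target_snr:
        return 0.0
    return float(brentq(lambda a: expected_snr(a) - target_snr, lo, hi, xtol=1e-6))


@lru_cache(maxsize=64)
def _snr_calibration_full(
    target_snr: float,
    noise_sigma: float,
    band_width: float,
    smooth_cm1: float | None,
    n_rep: int = 24,
) -> float:
    """Refine :func:`_snr_calibration` through the full measurement pipeline.

    The fast calibration assumes the baseline is recovered exactly, but the
    penalised baseline estimator absorbs a few percent of weak bands, so the
    amplitude is refined by secant iteration on the Monte-Carlo expectation of
    the *actual* pipeline (baseline estimation, pooled noise, smoothed band
    height) over ``n_rep`` fixed-seed replicate spectra.
    """
    from .spectra import band_intensity, estimate_baseline, noise_amplitude

    shift = _axis()
    rng = np.random.default_rng(424242)  # common random numbers across amplitudes
    noise = rng.normal(0.0, noise_sigma, size=(n_rep, shift.size))
    band = np.exp(-0.5 * ((shift - BAND_CENTER) / band_width) ** 2)

    def measured(amp: float) -> float:
        sigs, noises = [], []
        for k in range(n_rep):
            spec = RamanSpectrum(shift, amp * band + noise[k])
            base = estimate_baseline(spec)
            noises.append(noise_amplitude(spec, base))
            sigs.append(band_intensity(spec, base, smooth_cm1=smooth_cm1))
        return float(np.mean(sigs) / np.mean(noises))

    amp0 = _snr_calibration(
        target_snr, noise_sigma, band_width, GRID_STEP, BAND_HALF_WIDTH, smooth_cm1
    )
    if amp0 == 0 and measured(0.0) >= target_snr:
        return 0.0
    a_prev, f_prev = amp0, measured(amp0) - target_snr
    a_cur = max(amp0 * target_snr / (f_prev + target_snr), 1e-3 * noise_sigma)
    for _ in range(3):
        f_cur = measured(a_cur) - target_snr
        if abs(f_cur) < 5e-3 * max(target_snr, 1.0) or f_cur == f_prev:
            break
        a_next = a_cur - f_cur * (a_cur - a_prev) / (f_cur - f_prev)
        a_prev, f_prev = a_cur, f_cur
        a_cur = max(a_next, 0.0)
    return float(a_cur)


def gen_dilution_series(
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS,
    sn_slope: float = 15.0,
    noise_sigma: float = 5.0,
    seed: int = 0,
    band_width: float = 5.0,
    calibrated: bool = True,
) -> DilutionSeries:
    """Reporter-molecule dilution series with linear expected S/N = sn_slope * c.

    Each spectrum carries a single Gaussian band at 1589 cm^-1 whose amplitude
    is calibrated (see :func:`_snr_calibration`) so the expectation of the
    pipeline's measured S/N equals ``sn_slope * c[uM]``; with the defaults the
    series crosses S/N = 3 at 0.2 uM.  With ``calibrated=False`` the amplitude
    is simply ``sn_slope * c * noise_sigma * sqrt(2/pi)`` (the noise-free
    ideal), which understates weak-band S/N.

    A ``noise_sigma`` of 0 produces noiseless fit-only fixtures (measured S/N
    diverges); the series is flagged in each spectrum's metadata.
    """
    rng = np.random.default_rng(seed)
    spectra = []
    for c in concentrations:
        target = sn_slope * c
        if noise_sigma == 0:
            amp = target  # arbitrary scale; S/N undefined without noise
        elif calibrated:
            amp = _snr_calibration_full(target, noise_sigma, band_width, SNR_SMOOTH_CM1)
        else:
            amp = target * noise_sigma * _HALF_NORMAL_MEAN
        model = SpectrumModel(
            bands=[(BAND_CENTER, amp, band_width)] if amp > 0 else [],
            baseline=(0.0,),
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        spec = gen_spectrum(model)
        spec.metadata.update(
            concentration_uM=c,
            expected_snr=target,
            noiseless="fit-only fixture" if noise_sigma == 0 else None,
        )
        spectra.append(spec)
    return DilutionSeries(np.asarray(concentrations), spectra)


# ---------------------------------------------------------------------------
# surface maps
# ---------------------------------------------------------------------------


@dataclass
class SurfaceModel:
    """Generative model of a doubly modulated metasurface scan pair.

    The lattice is the separable sum of the closed-form film profile along
    both axes, scaled so the map's peak-to-valley equals ``h``.  Objects are
    given in nm from the top-left origin: exosomes and imperfections as
    ``(x, y, diameter, height)`` spherical caps, silver defects as
    ``(x, y, radius)`` current-only footprints.  Defaults follow the
    fabricated surface: L = 400 nm, h = 80 nm, 1024 x 1024 px over a
    10 x 10 um field.
    """

    L: float = 400.0
    h: float = 80.0
    n_pixels: int = 1024
    pixel_size: float = 10000.0 / 1024
    exosomes: list[tuple[float, float, float, float]] = field(default_factory=list)
    silver_defects: list[tuple[float, float, float]] = field(default_factory=list)
    imperfections: list[tuple[float, float, float, float]] = field(default_factory=list)
    roughness_nm: float = 8.0  # white pixel-scale height noise, RMS nm
    amp_disorder: float = 0.10  # fractional lattice-amplitude disorder (corr. ~2L)
    current_noise: float = 0.05
    current_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        gate_lo, gate_hi = 30.0, 150.0
        for x, y, d, hh in self.exosomes:
            if not gate_lo <= d <= gate_hi:
                raise ValueError(
                    f"exosome diameter {d} nm outside the {gate_lo}-{gate_hi} nm gate"
                )
            if hh <= 0:
                raise ValueError("exosome height must be positive")

    @classmethod
    def random(
        cls,
        seed: int = 0,
        n_exosomes: int = 5,
        n_defects: int = 3,
        n_imperfections: int = 3,
        min_separation: float | None = None,
        **kwargs,
    ) -> "SurfaceModel":
        """Place objects at randomly chosen depression centers of the lattice.

        Exosomes settle in depressions (the surface is morphologically
        complementary to them), so all objects are anchored at depression
        centers ``((i + 1/2) L, (j + 1/2) L)`` with a minimum pairwise
        separation (default 3 L) so sites stay individually resolvable.
        """
        model = cls(seed=seed, **kwargs)
        rng = np.random.default_rng(seed)
        field_nm = model.n_pixels * model.pixel_size
        if min_separation is None:
            min_separation = min(3 * model.L, field_nm / 4)
        n_cells = int(field_nm // model.L)
        margin_cells = 1
        placed: list[tuple[float, float]] = []
        need = n_exosomes + n_defects + n_imperfections
        attempts = 0
        while len(placed) < need and attempts < 10000:
            attempts += 1
            i = rng.integers(margin_cells, n_cells - margin_cells)
            j = rng.integers(margin_cells, n_cells - margin_cells)
            x = (i + 0.5) * model.L
            y = (j + 0.5) * model.L
            if all(np.hypot(x - px, y - py) >= min_separation for px, py in placed):
                placed.append((x, y))
        if len(placed) < need:
            raise RuntimeError("could not place all objects with the requested separation")
        k = 0
        for _ in range(n_exosomes):
            x, y = placed[k]
            k += 1
            d = float(rng.uniform(60, 120))
            model.exosomes.append((x, y, d, d * float(rng.uniform(0.3, 0.6))))
        for _ in range(n_defects):
            x, y = placed[k]
            k += 1
            model.silver_defects.append((x, y, float(rng.uniform(30, 80))))
        for _ in range(n_imperfections):
            x, y = placed[k]
            k += 1
            d = float(rng.uniform(60, 120))
            model.imperfections.append((x, y, d, d * float(rng.uniform(0.3, 0.6))))
        return model


def _spherical_cap(X, Y, x0, y0, diameter, height):
    """Spherical-cap bump of base diameter and apex height (nm) at (x0, y0)."""
    R = diameter / 2.0
    Rs = (R**2 + height**2) / (2.0 * height)
    r2 = (X - x0) ** 2 + (Y - y0) ** 2
    inside = r2 < R**2
    cap = np.zeros_like(X)
    cap[inside] = np.sqrt(np.maximum(Rs**2 - r2[inside], 0.0)) - (Rs - height)
    return cap


def gen_surface_pair(
    model: SurfaceModel,
) -> tuple[HeightMap, CurrentMap, pd.DataFrame]:
    """Generate a co-registered (height, current, ground-truth) triple.

    Height map: separable-sum lattice + spherical-cap bumps for exosomes and
    imperfections + seeded correlated roughness.  Current map: unit baseline
    with multiplicative noise, suppressed to ``current_floor`` on exosome and
    silver-defect footprints (vesicles and deposition voids do not conduct)
    and untouched on imperfections.  Objects overlapping the map edge are
    rejected with a warning and excluded from the ground truth.
    """
    n = model.n_pixels
    px = model.pixel_size
    coords = (np.arange(n) + 0.5) * px
    X, Y = np.meshgrid(coords, coords)
    spec = MetasurfaceSpec(model.L, model.h, max(model.h / 4, 1.0))  # d irrelevant to yu
    rng = np.random.default_rng(model.seed)
    if model.h > 0:
        yu_x, _ = fms_profiles(spec, coords)
        height = 0.5 * (yu_x[None, :] + yu_x[:, None])
        if model.amp_disorder > 0:
            # fabrication spread of the modulation amplitude: a smooth
            # multiplicative field with correlation length ~2L
            dis = ndimage.gaussian_filter(
                rng.normal(size=(n, n)), sigma=2 * model.L / px, mode="wrap"
            )
            dis *= model.amp_disorder / dis.std()
            mean = height.mean()
            height = mean + (1.0 + dis) * (height - mean)
    else:
        height = np.zeros((n, n))
    current = np.ones((n, n))
    field_nm = n * px
    truth_rows = []

    def in_bounds(x0, y0, radius):
        return (
            radius <= x0 <= field_nm - radius and radius <= y0 <= field_nm - radius
        )

    for x0, y0, d, hh in model.exosomes:
        if not in_bounds(x0, y0, d / 2):
            warnings.warn(f"exosome at ({x0}, {y0}) overlaps the map edge; rejected")
            continue
        height += _spherical_cap(X, Y, x0, y0, d, hh)
        current[(X - x0) ** 2 + (Y - y0) ** 2 < (d / 2) ** 2] = model.current_floor
        truth_rows.append(dict(x=x0, y=y0, label="exosome", diameter=d, height=hh))
    for x0, y0, r in model.silver_defects:
        if not in_bounds(x0, y0, r):
            warnings.warn(f"silver defect at ({x0}, {y0}) overlaps the map edge; rejected")
            continue
        current[(X - x0) ** 2 + (Y - y0) ** 2 < r**2] = model.current_floor
        truth_rows.append(dict(x=x0, y=y0, label="silver_defect", diameter=2 * r, height=0.0))
    for x0, y0, d, hh in model.imperfections:
        if not in_bounds(x0, y0, d / 2):
            warnings.warn(f"imperfection at ({x0}, {y0}) overlaps the map edge; rejected")
            continue
        height += _spherical_cap(X, Y, x0, y0, d, hh)
        truth_rows.append(dict(x=x0, y=y0, label="imperfection", diameter=d, height=hh))

    if model.roughness_nm > 0:
        height = height + rng.normal(0.0, model.roughness_nm, size=(n, n))
    if model.current_noise > 0:
        current = current * (1.0 + rng.normal(0.0, model.current_noise, size=(n, n)))

    meta = dict(seed=model.seed, L_nm=model.L, h_nm=model.h)
    hmap = HeightMap(height, px, meta=meta)
    cmap = CurrentMap(current, px, meta=meta)
    truth = pd.DataFrame(truth_rows, columns=["x", "y", "label", "diameter", "height"])
    return hmap, cmap, truth
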