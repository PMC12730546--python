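"""Correlative AFM/SSRM identification of single exosomes on a metasurface.

An exosome deposited in a metasurface depression shows up in two co-registered
scanning-probe channels at once: as a 30-150 nm topographic bump in the AFM
height map, and as a spot of vanishing current in the SSRM conductance map
(lipid vesicles do not conduct).  Silver-deposition defects also kill the
current but leave no bump; polymer-matrix imperfections produce bumps that
conduct normally.  Crossing the two channels therefore classifies every
candidate site:

==================  ==========  =================
low conductivity    bump        class
==================  ==========  =================
yes                 yes         exosome
yes                 no          silver_defect
no                  yes         imperfection
no                  no          clean
==================  ==========  =================

The periodic lattice of the metasurface itself dominates the height map and is
removed by Fourier notch filtering before bump detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

__all__ = [
    "HeightMap",
    "CurrentMap",
    "Site",
    "remove_lattice",
    "detect_low_conductivity",
    "detect_bumps",
    "classify_sites",
    "cross_section",
    "estimate_period",
    "PeriodEstimationError",
    "score_classification",
]

#: Default exosome lateral-size gate in nm (typical extracellular-vesicle range).
SIZE_GATE: tuple[float, float] = (30.0, 150.0)


class PeriodEstimationError(RuntimeError):
    """No dominant spatial frequency found in the map spectrum."""


@dataclass
class ScanMap:
    """A rectangular scanning-probe map with physical pixel size in nm."""

    data: np.ndarray
    pixel_size: float  # nm per pixel
    unit: str = ""
    registered: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("map data must be a 2-D matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("map contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (nm)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        return (self.shape[1] * self.pixel_size, self.shape[0] * self.pixel_size)


class HeightMap(ScanMap):
    """AFM topography, heights in nm."""

    def __init__(self, data, pixel_size, **kw):
        kw.setdefault("unit", "nm")
        super().__init__(data, pixel_size, **kw)


class CurrentMap(ScanMap):
    """SSRM conductance map, normalised current (arbitrary units)."""

    def __init__(self, data, pixel_size, **kw):
        kw.setdefault("unit", "norm")
        super().__init__(data, pixel_size, **kw)


@dataclass
class Site:
    """A candidate site in map coordinates (nm from the top-left origin)."""

    x: float
    y: float
    low_conductivity: bool = False
    bump: bool = False
    size: float = np.nan  # lateral FWHM or equivalent diameter, nm
    height: float = np.nan  # bump height, nm
    label: str = "clean"
    cluster: bool = False


def _check_pair(hmap: HeightMap, cmap: CurrentMap) -> None:
    if hmap.shape != cmap.shape or hmap.pixel_size != cmap.pixel_size:
        raise ValueError("maps are not co-registered (shape/pixel_size mismatch)")
    if not (hmap.registered and cmap.registered):
        raise ValueError("maps are not flagged as co-registered")


# ---------------------------------------------------------------------------
# lattice removal and period estimation
# ---------------------------------------------------------------------------


def remove_lattice(hmap: HeightMap, L: float, harmonics: int = 3, notch_half_width: int = 1) -> HeightMap:
    """Suppress the periodic lattice of period ``L`` (nm) by Fourier notch filtering.

    Zeroes the 2-D FFT in bands of +-``notch_half_width`` bins around the
    lattice frequency 1/L and its first ``harmonics - 1`` overtones, along
    both map axes (the doubly modulated surface has its spectral energy on
    the two frequency axes).  The DC component is preserved.
    """
    if L <= 2 * hmap.pixel_size:
        raise ValueError(
            f"period L = {L} nm is not resolvable at pixel size {hmap.pixel_size} nm"
        )
    z = hmap.data
    F = np.fft.fft2(z)
    ny, nx = z.shape
    fy = np.fft.fftfreq(ny, d=hmap.pixel_size)
    fx = np.fft.fftfreq(nx, d=hmap.pixel_size)
    f0 = 1.0 / L
    dfy = abs(fy[1] - fy[0])
    dfx = abs(fx[1] - fx[0])
    mask = np.ones_like(F, dtype=bool)
    for m in range(1, harmonics + 1):
        near_y = np.abs(np.abs(fy) - m * f0) <= notch_half_width * dfy + 1e-12
        near_x = np.abs(np.abs(fx) - m * f0) <= notch_half_width * dfx + 1e-12
        low_y = np.abs(fy) <= notch_half_width * dfy + 1e-12
        low_x = np.abs(fx) <= notch_half_width * dfx + 1e-12
        # lattice energy sits at (+-m f0, ~0) and (~0, +-m f0)
        mask &= ~(np.outer(near_y, low_x))
        mask &= ~(np.outer(low_y, near_x))
        mask &= ~(np.outer(near_y, near_x))  # cross terms of the double modulation
    resid = np.real(np.fft.ifft2(F * mask))
    return HeightMap(resid, hmap.pixel_size, registered=hmap.registered, meta=dict(hmap.meta))


def estimate_period(hmap: HeightMap, min_contrast: float = 8.0) -> float:
    """Dominant lattice period (nm) from the axis-averaged power spectrum.

    Averages the 1-D power spectra of all rows and all columns, excludes
    near-DC bins, and requires the dominant peak to stand ``min_contrast``
    times above the median spectral power.

    Raises
    ------
    PeriodEstimationError
        If no bin dominates (e.g. white-noise or flat maps).
    """
    z = hmap.data - hmap.data.mean()
    ny, nx = z.shape
    if min(ny, nx) < 16:
        raise ValueError("map too small for spectral period estimation")
    spec_rows = np.abs(np.fft.rfft(z, axis=1)) ** 2
    spec_cols = np.abs(np.fft.rfft(z, axis=0)) ** 2
    best = None
    for spec, n in ((spec_rows.mean(axis=0), nx), (spec_cols.mean(axis=1), ny)):
        freqs = np.fft.rfftfreq(n, d=hmap.pixel_size)
        s = spec.copy()
        s[:2] = 0.0  # DC and the first bin (drift)
        i = int(np.argmax(s))
        med = np.median(s[s > 0]) if np.any(s > 0) else 0.0
        if med <= 0 or s[i] < min_contrast * med or freqs[i] == 0:
            continue
        if best is None or s[i] > best[0]:
            best = (s[i], 1.0 / freqs[i])
    if best is None:
        raise PeriodEstimationError("no dominant spatial frequency in the map")
    return float(best[1])


# ---------------------------------------------------------------------------
# site detection
# ---------------------------------------------------------------------------


def detect_low_conductivity(
    cmap: CurrentMap, drop_fraction: float = 0.9, min_area_px: int = 4
) -> list[Site]:
    """Connected regions where the current drops below (1 - drop_fraction) * median.

    Each region is reported with its centroid (nm) and equivalent-disk
    diameter.  ``drop_fraction = 0.9`` means a site must lose at least 90% of
    the median current.
    """
    if not 0 < drop_fraction <= 1:
        raise ValueError("drop_fraction must be in (0, 1]")
    med = float(np.median(cmap.data))
    thresh = (1.0 - drop_fraction) * med
    mask = cmap.data < thresh
    labels, _ = ndimage.label(mask)
    sites = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid
        sites.append(
            Site(
                x=cx * cmap.pixel_size,
                y=cy * cmap.pixel_size,
                low_conductivity=True,
                size=region.equivalent_diameter_area * cmap.pixel_size,
            )
        )
    return sites


def detect_bumps(
    residual: HeightMap,
    min_height: float = 10.0,
    size_gate: tuple[float, float] = SIZE_GATE,
    smooth_px: float = 1.5,
) -> list[Site]:
    """Topographic candidates in a lattice-removed height map.

    Smooths the residual with a Gaussian of ``smooth_px`` pixels (suppressing
    pixel-scale instrument/grain noise while leaving 30-150 nm objects
    essentially intact), thresholds at ``min_height`` (nm), labels connected
    blobs, and keeps those whose lateral full width at half maximum falls
    inside ``size_gate`` (nm).  Blobs containing several distinct local
    maxima are flagged as clusters (an aggregate rather than a single
    vesicle).
    """
    z = residual.data - np.median(residual.data)  # offset-invariant
    if smooth_px > 0:
        z = ndimage.gaussian_filter(z, sigma=smooth_px)
    px = residual.pixel_size
    mask = z > min_height
    labels, n = ndimage.label(mask)
    pad = int(np.ceil(size_gate[1] / px)) + 2
    sites: list[Site] = []
    for region in measure.regionprops(labels, intensity_image=z):
        peak = float(region.intensity_max)
        # half-max footprint measured on the field around the peak, not on the
        # thresholded blob (which would clip bumps peaking just above threshold)
        py, px_i = np.unravel_index(
            np.argmax(np.where(labels[region.slice] == region.label, z[region.slice], -np.inf)),
            z[region.slice].shape,
        )
        ry0, rx0 = region.slice[0].start, region.slice[1].start
        py, px_i = py + ry0, px_i + rx0
        y0, y1 = max(py - pad, 0), min(py + pad + 1, z.shape[0])
        x0, x1 = max(px_i - pad, 0), min(px_i + pad + 1, z.shape[1])
        win = z[y0:y1, x0:x1]
        half_lab, _ = ndimage.label(win > peak / 2.0)
        comp = half_lab[py - y0, px_i - x0]
        half_mask = half_lab == comp
        fwhm = 2.0 * np.sqrt(np.count_nonzero(half_mask) / np.pi) * px
        if not size_gate[0] <= fwhm <= size_gate[1]:
            continue
        # distinct local maxima in the half-max component flag aggregates
        local_max = (
            (win == ndimage.maximum_filter(win, size=5)) & half_mask & (win > 0.6 * peak)
        )
        _, n_max = ndimage.label(local_max)
        # intensity-weighted centroid of the half-max component
        wy, wx = np.nonzero(half_mask)
        weights = win[wy, wx]
        cy = float(np.average(wy + y0, weights=weights))
        cx = float(np.average(wx + x0, weights=weights))
        sites.append(
            Site(
                x=cx * px,
                y=cy * px,
                bump=True,
                size=fwhm,
                height=peak,
                cluster=n_max > 1,
            )
        )
    return sites


def classify_sites(
    ssrm_sites: list[Site],
    afm_sites: list[Site],
    match_radius: float = 200.0,
    registered: bool = True,
) -> pd.DataFrame:
    """Merge SSRM and AFM candidates into a classified site table.

    SSRM low-conductivity sites and AFM bumps within ``match_radius`` (nm,
    default half a 400 nm lattice period) of each other are treated as one
    physical site.  Classes follow the decision table: low conductivity with
    an exosome-like bump -> ``exosome``; low conductivity alone ->
    ``silver_defect``; a conductive bump -> ``imperfection``.
    """
    if not registered:
        raise ValueError("maps must be co-registered before classification")
    used_afm = np.zeros(len(afm_sites), dtype=bool)
    rows = []
    for s in ssrm_sites:
        best_j, best_d = -1, np.inf
        for j, b in enumerate(afm_sites):
            if used_afm[j]:
                continue
            dist = np.hypot(s.x - b.x, s.y - b.y)
            if dist < best_d:
                best_j, best_d = j, dist
        if best_j >= 0 and best_d <= match_radius:
            b = afm_sites[best_j]
            used_afm[best_j] = True
            rows.append(
                dict(
                    x=(s.x + b.x) / 2,
                    y=(s.y + b.y) / 2,
                    low_conductivity=True,
                    bump=True,
                    size=b.size,
                    height=b.height,
                    label="exosome",
                    cluster=b.cluster,
                )
            )
        else:
            rows.append(
                dict(
                    x=s.x,
                    y=s.y,
                    low_conductivity=True,
                    bump=False,
                    size=s.size,
                    height=np.nan,
                    label="silver_defect",
                    cluster=False,
                )
            )
    for j, b in enumerate(afm_sites):
        if not used_afm[j]:
            rows.append(
                dict(
                    x=b.x,
                    y=b.y,
                    low_conductivity=False,
                    bump=True,
                    size=b.size,
                    height=b.height,
                    label="imperfection",
                    cluster=b.cluster,
                )
            )
    cols = ["x", "y", "low_conductivity", "bump", "size", "height", "label", "cluster"]
    return pd.DataFrame(rows, columns=cols)


def identify(
    hmap: HeightMap,
    cmap: CurrentMap,
    L: float = 400.0,
    min_height: float = 15.0,
    drop_fraction: float = 0.9,
    size_gate: tuple[float, float] = SIZE_GATE,
    match_radius: float | None = None,
) -> pd.DataFrame:
    """End-to-end correlative pipeline: lattice removal, both detectors, classifier."""
    _check_pair(hmap, cmap)
    if match_radius is None:
        match_radius = L / 2
    resid = remove_lattice(hmap, L)
    ssrm = detect_low_conductivity(cmap, drop_fraction)
    afm = detect_bumps(resid, min_height=min_height, size_gate=size_gate)
    return classify_sites(ssrm, afm, match_radius=match_radius)


# ---------------------------------------------------------------------------
# cross sections and scoring
# ---------------------------------------------------------------------------


def cross_section(
    hmap: HeightMap, polyline: np.ndarray, samples_per_px: float = 1.0
) -> dict:
    """Interpolated height profile along a polyline, with modulation statistics.

    ``polyline`` is an (n, 2) array of (x, y) vertices in nm.  The profile is
    sampled by bilinear interpolation; per-period peak-to-valley swings are
    measured between consecutive crests and reported as mean/min/max
    modulation.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be an (n>=2, 2) array of (x, y) nm")
    w_nm, h_nm = hmap.extent_nm
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > w_nm) or np.any(
        pts[:, 1] < 0
    ) or np.any(pts[:, 1] > h_nm):
        raise ValueError("polyline extends outside the map")
    segs = []
    dist0 = 0.0
    for p0, p1 in zip(pts, pts[1:]):
        length = float(np.hypot(*(p1 - p0)))
        n = max(int(round(length / hmap.pixel_size * samples_per_px)), 2)
        t = np.linspace(0, 1, n)
        xy = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        segs.append((dist0 + t * length, xy))
        dist0 += length
    dist = np.concatenate([s[0] for s in segs])
    xy = np.concatenate([s[1] for s in segs])
    rows = xy[:, 1] / hmap.pixel_size
    cols = xy[:, 0] / hmap.pixel_size
    prof = ndimage.map_coordinates(hmap.data, [rows, cols], order=1, mode="nearest")
    # per-period swings: peak-to-valley between consecutive crests
    from scipy.signal import find_peaks

    span = float(prof.max() - prof.min())
    swings = []
    if span > 0:
        crests, _ = find_peaks(prof, prominence=0.2 * span)
        for i0, i1 in zip(crests, crests[1:]):
            seg = prof[i0 : i1 + 1]
            swings.append(float(seg.max() - seg.min()))
    swings = np.asarray(swings)
    return {
        "distance_nm": dist,
        "profile_nm": prof,
        "swings_nm": swings,
        "mean_modulation_nm": float(swings.mean()) if swings.size else 0.0,
        "min_modulation_nm": float(swings.min()) if swings.size else 0.0,
        "max_modulation_nm": float(swings.max()) if swings.size else 0.0,
    }


def score_classification(
    predicted: pd.DataFrame, truth: pd.DataFrame, match_radius: float = 200.0
) -> pd.DataFrame:
    """Per-class precision/recall of a site table against a ground-truth table.

    Both tables need columns ``x``, ``y`` (nm) and ``label``.  A prediction
    matches a truth object of the same label within ``match_radius`` nm; each
    truth object can be claimed once.
    """
    classes = sorted(set(truth["label"]).union(predicted["label"]) - {"clean"})
    rows = []
    for cls in classes:
        p = predicted[predicted["label"] == cls]
        t = truth[truth["label"] == cls]
        claimed = np.zeros(len(t), dtype=bool)
        tp = 0
        for _, pr in p.iterrows():
            d = np.hypot(t["x"].to_numpy() - pr["x"], t["y"].to_numpy() - pr["y"])
            d[claimed] = np.inf
            if d.size and d.min() <= match_radius:
                claimed[int(np.argmin(d))] = True
                tp += 1
        rows.append(
            dict(
                label=cls,
                tp=tp,
                n_pred=len(p),
                n_true=len(t),
                precision=tp / len(p) if len(p) else np.nan,
                recall=tp / len(t) if len(t) else np.nan,
            )
        )
    return pd.DataFrame(rows)
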