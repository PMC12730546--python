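"""Quasistatic plasmonics of a modulated thin metal film (flexible metasurface).

The model starts from the plasmon resonance of a hollow metal nanocylinder
(inner radius ``ri``, outer radius ``re``, ratio ``alpha = re/ri``) excited by a
dipole source placed inside the hollow, solved in the quasistatic
approximation.  A conformal map ``z1 = -i log(w - a)`` then carries the annulus
onto a periodically modulated metal film of period ``L``, modulation ``h`` and
crest thickness ``d``, so every closed form derived for the cylinder becomes a
statement about the metasurface: the resonant radius ratio becomes an optimal
film thickness, and the uniform interior field becomes a local field that is
exponentially concentrated in the film depressions, where analytes
(e.g. exosomes) settle.

Conventions
-----------
* Time factor ``exp(-i omega t)``; passive media therefore have
  ``Im(epsilon) >= 0``.  Inputs violating this are rejected, not conjugated.
* All lengths are nanometres.  The model is dimensionless otherwise.
* ``eps_i`` is the permittivity of the half-space in front of the film (the
  hollow interior of the cylinder before mapping), ``eps_m`` the metal and
  ``eps_e`` the substrate side (cylinder exterior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PassivityError",
    "NoResonanceError",
    "ResonanceSingularityError",
    "OpticalMedium",
    "CylinderGeometry",
    "MetasurfaceSpec",
    "PotentialSolution",
    "FieldMap",
    "ResonanceResult",
    "optical_quality",
    "det",
    "alpha_res",
    "det_res_estimate",
    "uniform_internal_field",
    "dipole_amplitude",
    "solve_matching_system",
    "matching_residuals",
    "geometry_from_fms",
    "fms_from_geometry",
    "fms_profiles",
    "field_intensity",
    "field_map",
    "emax_estimate",
    "optimal_thickness",
    "sers_factor",
    "sers_average",
    "resonance_scan",
    "validity_report",
]


class PassivityError(ValueError):
    """Permittivity has Im(eps) < 0, i.e. the wrong time convention (gain)."""


class NoResonanceError(ValueError):
    """The metal is not plasmonic enough for a dipole resonance to exist."""


class ResonanceSingularityError(ArithmeticError):
    """The scattering determinant vanishes; coefficients are singular."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalMedium:
    """A medium characterised by its complex relative permittivity.

    Parameters
    ----------
    epsilon
        Complex relative permittivity, time convention ``exp(-i omega t)``
        so that ``Im(epsilon) >= 0`` for passive media.
    wavelength_nm
        Optional wavelength at which ``epsilon`` was taken (metadata only).
    """

    epsilon: complex
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if np.imag(self.epsilon) < 0:
            raise PassivityError(
                f"Im(epsilon) = {np.imag(self.epsilon)} < 0; passive media "
                "require Im(epsilon) >= 0 under the exp(-i omega t) convention"
            )

    @property
    def quality(self) -> float:
        """Optical quality factor |Re eps| / Im eps."""
        return optical_quality(self)


@dataclass(frozen=True)
class CylinderGeometry:
    """Hollow-nanocylinder geometry plus its three media.

    ``alpha`` is the outer/inner radius ratio ``re/ri`` and ``a`` the
    (dimensionless) off-axis position of the interior dipole source,
    ``0 < a < 1``.  ``media`` is (interior, metal, exterior).
    """

    alpha: float
    a: float
    media: tuple[OpticalMedium, OpticalMedium, OpticalMedium]

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise ValueError(f"alpha = {self.alpha} must exceed 1")
        if not 0 < self.a < 1:
            raise ValueError(f"source offset a = {self.a} must lie in (0, 1)")

    @property
    def eps(self) -> tuple[complex, complex, complex]:
        return tuple(m.epsilon for m in self.media)  # type: ignore[return-value]


@dataclass(frozen=True)
class MetasurfaceSpec:
    """Modulated-film geometry: period ``L``, modulation ``h``, crest thickness ``d`` (nm).

    The equivalent cylinder-frame parameters are ``a = tanh(pi h / L)`` and
    ``alpha = a + (1 - a) exp(2 pi d / L)``; both are derived on construction.
    ``h = 0`` and ``d = 0`` are allowed flat-film limits.
    """

    L: float
    h: float
    d: float
    a: float = field(init=False)
    alpha: float = field(init=False)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("period L must be positive")
        if self.h < 0 or self.d < 0:
            raise ValueError("modulation h and thickness d must be >= 0")
        a, alpha = geometry_from_fms(self.L, self.h, self.d)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "alpha", alpha)

    def profiles(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Upper (illuminated) and lower film surfaces ``yu(x)``, ``yb(x)`` in nm."""
        return fms_profiles(self, x)


@dataclass(frozen=True)
class PotentialSolution:
    """Coefficients of the dipole-harmonic potentials around the cylinder.

    ``A`` multiplies the interior potential ``~ w``, ``B`` and ``C`` the metal
    shell terms ``~ w`` and ``~ 1/w``, and ``D`` the exterior term ``~ 1/w``;
    all are per unit source amplitude ``U0`` and signed so that ``A`` equals
    the closed-form interior dipole amplitude.  ``E0 = U0 * 2 pi / L`` is the
    uniform field the source maps to in the film frame.
    """

    A: complex
    B: complex
    C: complex
    D: complex
    U0: complex = 1.0
    E0: complex | None = None


@dataclass(frozen=True)
class FieldMap:
    """Gridded local-field enhancement above the film surface.

    ``intensity`` is |E/E0|^2 and ``G = intensity**2`` the pointwise SERS
    factor; both are NaN-masked below the metal surface ``y < yu(x)``.
    """

    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray
    G: np.ndarray
    mask: np.ndarray  # True where the point lies above the film surface


@dataclass(frozen=True)
class ResonanceResult:
    """Outcome of a thickness scan for the dipole plasmon resonance."""

    alpha_res: float
    det_at_res: complex
    det_min_numeric: complex
    relative_gap: float
    d_opt: float
    alpha_opt: float


# ---------------------------------------------------------------------------
# resonance closed forms
# ---------------------------------------------------------------------------


def optical_quality(metal: OpticalMedium | complex) -> float:
    """Quality factor Q = |Re eps| / Im eps of a lossy medium.

    Raises
    ------
    PassivityError
        If ``Im(eps) <= 0`` (wrong time convention, or a lossless input for
        which Q is undefined).
    """
    eps = metal.epsilon if isinstance(metal, OpticalMedium) else complex(metal)
    if np.imag(eps) <= 0:
        raise PassivityError(
            "optical quality requires Im(epsilon) > 0 under exp(-i omega t)"
        )
    return abs(np.real(eps)) / np.imag(eps)


def det(alpha, eps_i, eps_m, eps_e):
    """Scattering determinant of the hollow cylinder's dipole harmonic.

    ``Det = alpha^2 (eps_e + eps_m)(eps_i + eps_m) + (eps_m - eps_e)(eps_i - eps_m)``.
    Vectorised over ``alpha``.
    """
    alpha = np.asarray(alpha)
    return (alpha**2) * (eps_e + eps_m) * (eps_i + eps_m) + (eps_m - eps_e) * (
        eps_i - eps_m
    )


def alpha_res(metal_re: float, eps_i: float, eps_e: float) -> float:
    """Resonant radius ratio at which |Det| is minimal (lossless estimate).

    ``alpha_res = sqrt((eps_e - eps_m')(eps_i - eps_m') /
    ((eps_e + eps_m')(eps_i + eps_m')))``, which requires the metal's real
    permittivity to satisfy ``eps_m' < -max(eps_i, eps_e)``.
    """
    ratio = ((eps_e - metal_re) * (eps_i - metal_re)) / (
        (eps_e + metal_re) * (eps_i + metal_re)
    )
    if ratio <= 0:
        raise NoResonanceError(
            f"(eps_e - eps_m')(eps_i - eps_m') / ((eps_e + eps_m')(eps_i + eps_m'))"
            f" = {ratio:.4g} <= 0: metal not plasmonic enough "
            "(need eps_m' < -max(eps_i, eps_e))"
        )
    return float(np.sqrt(ratio))


def det_res_estimate(metal: OpticalMedium, eps_i: float, eps_e: float) -> complex:
    """Large-Q estimate of Det at resonance, ``~ 2i (eps_e + eps_i) eps_m' / Qm``.

    This is an estimate valid for ``Qm >> 1`` and ``|eps_m'| >> 1``; the exact
    value is ``det(alpha_res(...), ...)``.
    """
    q = optical_quality(metal)
    if q < 10:
        warnings.warn(
            f"Qm = {q:.3g} < 10: the large-Q resonance estimate is unreliable",
            stacklevel=2,
        )
    return 2j * (eps_e + eps_i) * np.real(metal.epsilon) / q


def uniform_internal_field(geom: CylinderGeometry) -> complex:
    """Field ratio Ei/E0 inside the hollow under uniform external excitation.

    ``Ei/E0 = 4 alpha^2 eps_e eps_m / Det``; the interior field is uniform.
    """
    eps_i, eps_m, eps_e = geom.eps
    d = det(geom.alpha, eps_i, eps_m, eps_e)
    if d == 0:
        raise ResonanceSingularityError("Det = 0: exact (lossless) resonance")
    return 4 * geom.alpha**2 * eps_e * eps_m / d


def dipole_amplitude(geom: CylinderGeometry, a: float | None = None) -> complex:
    """Interior dipole-field amplitude A excited by an off-axis source.

    ``A = a [alpha^2 (eps_e + eps_m)(eps_i - eps_m)
    - (eps_e - eps_m)(eps_i + eps_m)] / Det`` per unit source amplitude.
    """
    if a is None:
        a = geom.a
    if not 0 <= a < 1:
        raise ValueError(f"source offset a = {a} must lie in [0, 1)")
    eps_i, eps_m, eps_e = geom.eps
    alpha = geom.alpha
    d = det(alpha, eps_i, eps_m, eps_e)
    if d == 0:
        raise ResonanceSingularityError("Det = 0: exact (lossless) resonance")
    num = alpha**2 * (eps_e + eps_m) * (eps_i - eps_m) - (eps_e - eps_m) * (
        eps_i + eps_m
    )
    return a * num / d


def solve_matching_system(
    geom: CylinderGeometry, a: float | None = None, U0: complex = 1.0
) -> PotentialSolution:
    """Solve the 4x4 interface-matching system for the dipole harmonic.

    The source contributes a potential ``-U0 a sin(phi) / r`` inside the
    hollow; each region carries a dipole harmonic ``(p r + q / r) sin(phi)``
    and the four unknown amplitudes are fixed by continuity of the potential
    and of the normal displacement ``eps dphi/dr`` at ``r = 1`` and
    ``r = alpha``.  Returned coefficients are per unit ``U0`` and signed so
    that ``A`` reproduces the closed-form :func:`dipole_amplitude`.
    """
    if a is None:
        a = geom.a
    eps_i, eps_m, eps_e = geom.eps
    alpha = geom.alpha
    s = a  # per unit U0
    # unknowns [A1, B1, C1, D1]: interior A1*r; metal B1*r + C1/r; exterior D1/r
    M = np.array(
        [
            [1, -1, -1, 0],
            [eps_i, -eps_m, eps_m, 0],
            [0, alpha, 1 / alpha, -1 / alpha],
            [0, eps_m, -eps_m / alpha**2, eps_e / alpha**2],
        ],
        dtype=complex,
    )
    rhs = np.array([s, -eps_i * s, 0, 0], dtype=complex)
    try:
        A1, B1, C1, D1 = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - exact resonance only
        raise ResonanceSingularityError("matching system is singular") from exc
    # sign flip so that A matches the closed-form interior dipole amplitude
    return PotentialSolution(A=-A1, B=-B1, C=-C1, D=-D1, U0=U0)


def matching_residuals(
    geom: CylinderGeometry,
    sol: PotentialSolution,
    a: float | None = None,
    n_angles: int = 64,
) -> tuple[float, float]:
    """Max interface residuals (potential, normal displacement) of a solution.

    Evaluates both continuity conditions at ``n_angles`` sampled polar angles
    on each interface and returns the largest absolute mismatch of each kind,
    normalised by the source amplitude.
    """
    if a is None:
        a = geom.a
    eps_i, eps_m, eps_e = geom.eps
    alpha = geom.alpha
    A1, B1, C1, D1 = -sol.A, -sol.B, -sol.C, -sol.D
    phi = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    s = np.sin(phi)

    def amp(p, q, r):
        return p * r + q / r

    def damp(p, q, r):
        return p - q / r**2

    # interface r = 1: interior (A1 r - a / r) vs metal
    pot1 = (amp(A1, -a, 1.0) - amp(B1, C1, 1.0)) * s
    dsp1 = (eps_i * damp(A1, -a, 1.0) - eps_m * damp(B1, C1, 1.0)) * s
    # interface r = alpha: metal vs exterior (D1 / r)
    pot2 = (amp(B1, C1, alpha) - amp(0, D1, alpha)) * s
    dsp2 = (eps_m * damp(B1, C1, alpha) - eps_e * damp(0, D1, alpha)) * s
    pot_res = max(np.abs(pot1).max(), np.abs(pot2).max())
    dsp_res = max(np.abs(dsp1).max(), np.abs(dsp2).max())
    return float(pot_res), float(dsp_res)


# ---------------------------------------------------------------------------
# film geometry (conformal map)
# ---------------------------------------------------------------------------


def geometry_from_fms(L: float, h: float, d: float) -> tuple[float, float]:
    """Map film parameters (L, h, d) to cylinder-frame (a, alpha).

    ``a = tanh(pi h / L)`` and ``alpha = a + (1 - a) exp(2 pi d / L)``.
    """
    if L <= 0 or h < 0 or d < 0:
        raise ValueError("require L > 0, h >= 0, d >= 0")
    a = float(np.tanh(np.pi * h / L))
    alpha = a + (1 - a) * float(np.exp(2 * np.pi * d / L))
    return a, alpha


def fms_from_geometry(L: float, a: float, alpha: float) -> tuple[float, float]:
    """Inverse of :func:`geometry_from_fms`: recover (h, d) from (a, alpha)."""
    if not 0 <= a < 1:
        raise ValueError(f"a = {a} must lie in [0, 1)")
    if alpha < a:
        raise ValueError(f"alpha = {alpha} must be >= a = {a}")
    h = L / np.pi * float(np.arctanh(a))
    d = L / (2 * np.pi) * float(np.log((alpha - a) / (1 - a)))
    return h, d


def fms_profiles(
    spec: MetasurfaceSpec, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Film surfaces: illuminated ``yu(x)`` and substrate-side ``yb(x)`` in nm.

    ``yu = -(L/2pi) ln(sqrt(1 - a^2 sin^2 x1) - a cos x1)`` and ``yb`` the
    same with ``alpha^2`` under the root, ``x1 = 2 pi x / L``.  The crests sit
    at ``x = n L`` and the depressions at ``x = L/2 + n L``.
    """
    x = np.asarray(x, dtype=float)
    a, alpha = spec.a, spec.alpha
    x1 = 2 * np.pi * x / spec.L
    pref = spec.L / (2 * np.pi)
    yu = -pref * np.log(np.sqrt(1 - a**2 * np.sin(x1) ** 2) - a * np.cos(x1))
    yb = -pref * np.log(np.sqrt(alpha**2 - a**2 * np.sin(x1) ** 2) - a * np.cos(x1))
    return yu, yb


def field_intensity(spec: MetasurfaceSpec, A: complex, x, y):
    """Local intensity enhancement |E/E0|^2 = |A|^2 exp(-4 pi y / L) above the film.

    The dipole-term closed form is independent of ``x``; ``x`` enters only
    through the surface mask: points below ``yu(x)`` are returned as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    yu, _ = fms_profiles(spec, x)
    inten = np.abs(A) ** 2 * np.exp(-4 * np.pi * y / spec.L)
    return np.where(y >= yu, inten, np.nan)


def field_map(
    spec: MetasurfaceSpec,
    A: complex,
    x: np.ndarray,
    y: np.ndarray,
) -> FieldMap:
    """Evaluate intensity and SERS-factor maps on the grid ``x`` (cols) × ``y`` (rows)."""
    X, Y = np.meshgrid(np.asarray(x, float), np.asarray(y, float))
    yu, _ = fms_profiles(spec, X)
    mask = Y >= yu
    inten = np.where(mask, np.abs(A) ** 2 * np.exp(-4 * np.pi * Y / spec.L), np.nan)
    return FieldMap(x=X, y=Y, intensity=inten, G=inten**2, mask=mask)


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------


def emax_estimate(
    L: float,
    h: float,
    dy: float,
    eps_i: float,
    eps_e: float,
    Qm: float,
) -> float:
    """Resonant field amplitude at the depression bottom, decayed over height ``dy``.

    ``Emax/E0 = 2 eps_i Qm a / ((a + 1)(eps_e + eps_i)) * exp(-2 pi dy / L)``
    with ``a = tanh(pi h / L)``; ``dy >= 0`` is the distance above the bottom.
    """
    if dy < 0:
        raise ValueError("dy must be >= 0")
    a = float(np.tanh(np.pi * h / L))
    return (
        2 * eps_i * Qm * a / ((a + 1) * (eps_e + eps_i)) * float(np.exp(-2 * np.pi * dy / L))
    )


def optimal_thickness(
    L: float, h: float, eps_i: float, eps_e: float, metal_re: float
) -> tuple[float, float]:
    """Optimal crest thickness ``d_max`` and the corresponding bottom thickness (nm).

    ``d_max ~ (L / 2 pi)(eps_e + eps_i) / ((1 - a) |eps_m'|)`` in the
    ``|eps_m'| >> 1`` regime; the film thins toward the depression bottom by
    the conformal factor, ``d_bottom ~ exp(-2 pi h / L) d_max``.
    """
    if L <= 0 or h < 0:
        raise ValueError("require L > 0 and h >= 0")
    if abs(metal_re) < 5:
        warnings.warn(
            f"|eps_m'| = {abs(metal_re):.3g} < 5: thin-film estimate unreliable",
            stacklevel=2,
        )
    a = float(np.tanh(np.pi * h / L))
    d_max = L / (2 * np.pi) * (eps_e + eps_i) / ((1 - a) * abs(metal_re))
    d_bottom = float(np.exp(-2 * np.pi * h / L)) * d_max
    return d_max, d_bottom


def sers_factor(intensity):
    """Pointwise SERS factor G = (|E/E0|^2)^2 from an intensity enhancement."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity enhancement must be >= 0")
    out = intensity**2
    return float(out) if out.ndim == 0 else out


def sers_average(Qm: float) -> float:
    """Surface-averaged SERS factor estimate G ~ Qm^4 at resonance."""
    if Qm <= 0:
        raise ValueError("Qm must be positive")
    return Qm**4


def resonance_scan(
    L: float,
    h: float,
    metal: OpticalMedium,
    eps_i: float,
    eps_e: float,
    d_range: tuple[float, float] = (1.0, 50.0),
    n_grid: int = 512,
) -> ResonanceResult:
    """Scan the film thickness for the |Det| minimum (dipole resonance).

    Maps each thickness ``d`` in ``d_range`` to ``alpha`` via
    :func:`geometry_from_fms`, evaluates |Det|, and refines the grid minimum
    by golden-section search to relative tolerance 1e-9 (ties broken toward
    smaller ``d``).  The analytic lossless ``alpha_res`` and the Det value
    there are reported alongside for comparison.
    """
    d_lo, d_hi = d_range
    if not 0 < d_lo < d_hi:
        raise ValueError("d_range must be positive and increasing")
    eps_m = metal.epsilon
    a = float(np.tanh(np.pi * h / L))

    def alpha_of(dv):
        return a + (1 - a) * np.exp(2 * np.pi * np.asarray(dv) / L)

    def objective(dv):
        return np.abs(det(alpha_of(dv), eps_i, eps_m, eps_e))

    grid = np.linspace(d_lo, d_hi, n_grid)
    vals = objective(grid)
    i = int(np.argmin(vals))  # argmin takes the first (smallest-d) tie
    if i in (0, n_grid - 1):
        warnings.warn(
            "|Det| minimum at the boundary of d_range; resonance may lie outside",
            stacklevel=2,
        )
        d_opt = float(grid[i])
    else:
        res = minimize_scalar(
            objective,
            bracket=(grid[i - 1], grid[i], grid[i + 1]),
            method="golden",
            options={"xtol": 1e-9},
        )
        d_opt = float(res.x)
    alpha_opt = float(alpha_of(d_opt))
    det_min = complex(det(alpha_opt, eps_i, eps_m, eps_e))
    a_res = alpha_res(float(np.real(eps_m)), eps_i, eps_e)
    det_at_res = complex(det(a_res, eps_i, eps_m, eps_e))
    gap = abs(a_res - alpha_opt) / a_res
    return ResonanceResult(
        alpha_res=a_res,
        det_at_res=det_at_res,
        det_min_numeric=det_min,
        relative_gap=gap,
        d_opt=d_opt,
        alpha_opt=alpha_opt,
    )


def validity_report(
    spec: MetasurfaceSpec, metal: OpticalMedium, wavelength_nm: float
) -> dict:
    """Quasistatic-validity diagnostics: size parameter and a skin-depth proxy.

    The quasistatic closed forms assume the structure is small compared to
    the wavelength and the film thinner than the skin depth.  The report is
    informative only — the model is evaluated regardless — and the skin-depth
    figure is a conventional estimate ``lambda / (2 pi Im sqrt(eps_m))``, not
    a hard validity bound.
    """
    n_metal = np.sqrt(complex(metal.epsilon))
    skin = wavelength_nm / (2 * np.pi * np.imag(n_metal)) if np.imag(n_metal) > 0 else np.inf
    return {
        "L_over_lambda": spec.L / wavelength_nm,
        "quasistatic_ok": spec.L / wavelength_nm < 1.0,
        "skin_depth_nm_estimate": float(skin),
        "d_over_skin_depth": spec.d / skin if np.isfinite(skin) else 0.0,
        "caveat": (
            "skin depth is an order-of-magnitude proxy; the quasistatic model "
            "is evaluated regardless of these ratios"
        ),
    }
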