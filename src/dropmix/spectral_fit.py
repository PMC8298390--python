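"""Fluorescence spectral unmixing and exponential rise-time fitting.

A measured emission spectrum is modelled as a linear combination of four
max-normalised component spectra plus a constant offset,

    f(lambda) = s_d * sc_diode + s_fluo * fl_fluo
              + s_fura- * fl_fura- + s_fura+ * fl_fura+ + c,

fitted by ordinary least squares over the 510-750 nm window. The two
calcium-dependent scale factors (Fluo-5N, lambda_max 515 nm, and
Ca-bound Fura Red, lambda_max 640 nm; the Ca-free Fura Red form peaks at
670 nm) grow with mixing time t as

    s(t) = a * (1 - exp(-t / tau)),

fitted by damped nonlinear least squares to give the fluorescence rise
time tau. Because the residence time of a drop in the detection volume is
inversely proportional to tape speed, raw intensities are rescaled by
speed / reference_speed before unmixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError

COMPONENT_NAMES = ("diode", "fluo", "fura_minus", "fura_plus")
DEFAULT_WINDOW_NM = (510.0, 750.0)
DEFAULT_REFERENCE_SPEED = 100.0  # mm/s, a control tape speed


@dataclass
class Spectrum:
    """Wavelength-resolved fluorescence intensities with acquisition metadata."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    tape_speed_mm_s: float | None = None
    replicates: int = 1
    speed_corrected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.shape != self.intensities.shape:
            raise ValidationError("wavelengths and intensities must be equal length")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing")


@dataclass
class ComponentSet:
    """Max-normalised component spectra on a shared wavelength grid."""

    wavelengths_nm: np.ndarray
    components: dict[str, np.ndarray]
    peaks_nm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        for name in COMPONENT_NAMES:
            if name not in self.components:
                raise ValidationError(f"missing component {name!r}")
        for name, y in self.components.items():
            y = np.asarray(y, dtype=float)
            peak = y.max()
            if not np.isclose(peak, 1.0, rtol=1e-9):
                raise ValidationError(f"component {name!r} must be max-normalised "
                                      f"(max={peak})")
            self.components[name] = y

    def on_grid(self, wavelengths_nm: np.ndarray) -> dict[str, np.ndarray]:
        return {name: np.interp(wavelengths_nm, self.wavelengths_nm, y)
                for name, y in self.components.items()}


@dataclass
class SpectralFitResult:
    s_d: float
    s_fluo: float
    s_fura_minus: float
    s_fura_plus: float
    c: float
    residual_norm: float
    window_nm: tuple[float, float]

    def coefficient(self, name: str) -> float:
        return {"diode": self.s_d, "fluo": self.s_fluo,
                "fura_minus": self.s_fura_minus, "fura_plus": self.s_fura_plus,
                "offset": self.c}[name]


def fit_components(spec: Spectrum, comps: ComponentSet,
                   window: tuple[float, float] = DEFAULT_WINDOW_NM) -> SpectralFitResult:
    """Unconstrained linear least-squares decomposition over the window."""
    lo, hi = window
    if lo >= hi:
        raise ValidationError(f"window {window} must be an increasing interval")
    mask = (spec.wavelengths_nm >= lo) & (spec.wavelengths_nm <= hi)
    if mask.sum() < len(COMPONENT_NAMES) + 1:
        raise ValidationError("too few samples inside the fit window")
    wl = spec.wavelengths_nm[mask]
    y = spec.intensities[mask]
    grid = comps.on_grid(wl)
    A = np.column_stack([grid[n] for n in COMPONENT_NAMES] + [np.ones_like(wl)])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise FitError(f"singular design matrix (rank {rank} < {A.shape[1]}); "
                       "components are degenerate over the window")
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(np.linalg.norm(A @ coef - y))
    return SpectralFitResult(*coef, residual_norm=resid, window_nm=(lo, hi))


def scale_by_tape_speed(spec: Spectrum,
                        reference_speed: float = DEFAULT_REFERENCE_SPEED) -> Spectrum:
    """Correct intensities for the 1/speed residence time of a drop.

    Multiplies by speed / reference_speed; idempotent once
    ``speed_corrected`` is set.
    """
    if spec.speed_corrected:
        return spec
    if spec.tape_speed_mm_s is None or not spec.tape_speed_mm_s > 0:
        raise ValidationError("spectrum lacks positive tape_speed_mm_s metadata")
    if not reference_speed > 0:
        raise ValidationError("reference_speed must be positive")
    factor = spec.tape_speed_mm_s / reference_speed
    return replace(spec, intensities=spec.intensities * factor, speed_corrected=True)


@dataclass(frozen=True)
class RisePoint:
    """One (interaction time, fitted scale factor) measurement."""

    t_s: float
    s: float
    sigma: float | None = None

    def __post_init__(self):
        if not self.t_s > 0:
            raise ValidationError(f"interaction time must be > 0, got {self.t_s}")


@dataclass
class RiseFitResult:
    a: float
    tau_s: float
    covariance: np.ndarray
    unstable: bool = False
    gradient_norm: float = 0.0


def average_fastest_points(points: list[RisePoint], k: int) -> list[RisePoint]:
    """Merge the k earliest time points into their mean (weak-signal pooling)."""
    if k <= 1:
        return list(points)
    pts = sorted(points, key=lambda p: p.t_s)
    head, tail = pts[:k], pts[k:]
    sig = [p.sigma for p in head]
    sigma = (float(np.sqrt(np.sum(np.square(sig))) / k)
             if all(s is not None for s in sig) else None)
    merged = RisePoint(float(np.mean([p.t_s for p in head])),
                       float(np.mean([p.s for p in head])), sigma)
    return [merged] + tail


def fit_rise(points: list[RisePoint], average_fastest: int = 0) -> RiseFitResult:
    """Fit s(t) = a * (1 - exp(-t/tau)) by damped least squares.

    ``average_fastest`` >= 2 pools the earliest k points by mean before
    fitting. Initial tau comes from the time of half-maximum; five starts
    spanning a decade around it guard against local minima. Point sigmas,
    when all present, act as inverse weights. Plateau-only data (no
    curvature) is returned flagged ``unstable`` rather than trusted.
    """
    pts = average_fastest_points(points, average_fastest)
    if len(pts) < 3:
        raise ValidationError(f"need >= 3 points after averaging, got {len(pts)}")
    t = np.array([p.t_s for p in pts])
    s = np.array([p.s for p in pts])
    sig = np.array([p.sigma if p.sigma is not None else np.nan for p in pts])
    w = 1.0 / sig if not np.any(np.isnan(sig)) else np.ones_like(s)

    spread = s.max() - s.min()
    if spread <= 1e-12 * max(abs(s.max()), 1e-300):
        # all scale factors equal: any tau fits equally badly
        return RiseFitResult(float(s.mean()), float(t.min()),
                             np.full((2, 2), np.inf), unstable=True)

    def resid(p):
        a, log_tau = p
        return w * (a * (1.0 - np.exp(-t / np.exp(log_tau))) - s)

    # initial tau from the half-maximum crossing time
    half = s.min() + 0.5 * spread
    i = int(np.argmin(np.abs(s - half)))
    tau0 = max(t[i] / np.log(2.0), 1e-6)
    best = None
    for factor in np.logspace(-0.5, 0.5, 5):
        p0 = np.array([s.max(), np.log(tau0 * factor)])
        try:
            sol = least_squares(resid, p0, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("rise fit failed from every initial guess")
    a_hat = float(best.x[0])
    tau_hat = float(np.exp(best.x[1]))
    J = best.jac
    # delta-method covariance in (a, tau); J columns are (a, log tau)
    dof = max(len(pts) - 2, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov_log = s2 * np.linalg.inv(J.T @ J)
        T = np.diag([1.0, tau_hat])  # d(log tau) -> d(tau)
        cov = T @ cov_log @ T
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.inf)
    grad = float(np.linalg.norm(J.T @ best.fun))
    unstable = (not np.isfinite(cov).all()) or (
        cov[1, 1] > 0 and np.sqrt(cov[1, 1]) > 10.0 * tau_hat)
    if tau_hat <= 0:
        raise FitError(f"non-physical rise time {tau_hat}")
    return RiseFitResult(a_hat, tau_hat, cov, unstable=unstable, gradient_norm=grad)
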