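"""Curve-fit stages: DSF melting point, one-site ITC binding, and
Michaelis-Menten uptake kinetics.

The fit stages follow a statsmodels-like pattern: a model object is built
from the data, ``fit()`` returns a results object carrying estimates,
asymptotic standard errors and a ``summary()`` table.  The melting-point
extraction is a direct measurement (derivative peak), not a parametric
fit, and is exposed as a function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.signal import savgol_filter

log = logging.getLogger(__name__)


class NoTransitionError(ValueError):
    """Melt curve shows no unfolding transition."""


class DegenerateFitError(ValueError):
    """Data carry no information about the fit parameters."""


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge."""


# ---------------------------------------------------------------------------
# DSF


@dataclass
class MeltCurve:
    """Thermal melt curve: fluorescence vs temperature (°C)."""

    temperature: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence must match in length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")


def melting_temperature(curve: MeltCurve, window: int = 5,
                        polyorder: int = 2) -> float:
    """Melting temperature as the peak of the smoothed first derivative.

    The fluorescence is smoothed with a centered Savitzky-Golay filter
    (default window 5 points, quadratic), differentiated numerically, and
    the discrete derivative maximum is refined by parabolic interpolation
    through its two neighbours.  Invariant under affine transforms
    a*F + b (a > 0) of the fluorescence.

    Raises
    ------
    NoTransitionError
        If the derivative is nowhere positive (no unfolding transition).
    """
    T, F = curve.temperature, curve.fluorescence
    if len(T) < 5:
        raise ValueError("need at least 5 points spanning the transition")
    window = min(window, len(T) if len(T) % 2 else len(T) - 1)
    smooth = savgol_filter(F, window_length=window, polyorder=polyorder)
    dFdT = np.gradient(smooth, T)
    i = int(np.argmax(dFdT))
    if dFdT[i] <= 0 or np.ptp(F) == 0:
        raise NoTransitionError("no melting transition: derivative never positive")
    tm = T[i]
    if 0 < i < len(T) - 1:
        y0, y1, y2 = dFdT[i - 1], dFdT[i], dFdT[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            # parabola through the three points; assumes near-uniform grid
            tm = T[i] + 0.5 * (y0 - y2) / denom * (T[i + 1] - T[i])
    return float(tm)


# ---------------------------------------------------------------------------
# ITC


@dataclass
class Thermogram:
    """Integrated per-injection heats, normalized per mole of injectant.

    Concentrations in µM, volumes in µL, heats in the generator's energy
    unit per mole (kcal/mol by convention).
    """

    heats: np.ndarray
    injection_volumes: np.ndarray
    cell_conc: float
    syringe_conc: float
    cell_volume: float

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if len(self.heats) < 2:
            raise ValueError("need at least 2 injections")
        if self.heats.shape != self.injection_volumes.shape:
            raise ValueError("heats and injection_volumes must match")
        if min(self.cell_conc, self.syringe_conc, self.cell_volume) <= 0:
            raise ValueError("concentrations and volumes must be positive")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be positive")


def itc_injection_heats(kd: float, dh: float, n_sites: float,
                        cell_conc: float, syringe_conc: float,
                        injection_volumes: np.ndarray,
                        cell_volume: float) -> np.ndarray:
    """Per-injection heats of a single-site titration (Wiseman isotherm).

    Mass balance per injection with perfusion dilution: injecting a volume
    v into the fixed cell volume V0 displaces mixed solution, so total
    concentrations follow C -> C_in + (C - C_in) exp(-v/V0).  Bound
    complex [MX] solves the quadratic

        [MX] = ((n*M + X + Kd) - sqrt((n*M + X + Kd)^2 - 4 n M X)) / 2,

    and the heat of injection i is dH * V0 * ([MX]_i - [MX]_{i-1}
    exp(-v_i/V0)), normalized per mole of injectant.
    """
    v = np.asarray(injection_volumes, dtype=float)
    M = cell_conc
    X = 0.0
    mx_prev = 0.0
    heats = np.empty(len(v))
    for i, vi in enumerate(v):
        f = np.exp(-vi / cell_volume)
        M = M * f
        X = syringe_conc + (X - syringe_conc) * f
        sites = n_sites * M
        b = sites + X + kd
        mx = 0.5 * (b - np.sqrt(b * b - 4.0 * sites * X))
        heats[i] = dh * cell_volume * (mx - mx_prev * f) / (syringe_conc * vi)
        mx_prev = mx
    return heats


@dataclass
class BindingResults:
    """One-site ITC fit results."""

    kd: float
    dh: float
    n_sites: float
    kd_se: float
    dh_se: float
    n_se: float
    residual_norm: float
    n_obs: int
    model: "OneSiteBindingModel" = field(repr=False, default=None)  # type: ignore

    @property
    def params(self) -> dict:
        return {"kd": self.kd, "dh": self.dh, "n_sites": self.n_sites}

    def summary(self) -> str:
        rows = [
            ("K_D (µM)", self.kd, self.kd_se),
            ("dH (per mol)", self.dh, self.dh_se),
            ("n (sites)", self.n_sites, self.n_se),
        ]
        lines = ["One-site binding fit (Wiseman isotherm)",
                 "-" * 46,
                 f"{'parameter':<14}{'estimate':>12}{'std err':>12}"]
        for name, est, se in rows:
            lines.append(f"{name:<14}{est:>12.4g}{se:>12.3g}")
        lines.append(f"residual norm: {self.residual_norm:.3g} "
                     f"on {self.n_obs} injections")
        return "\n".join(lines)


class OneSiteBindingModel:
    """Single-site binding model for an ITC thermogram.

    Fits (K_D, dH, n) by nonlinear least squares on the per-injection
    heats, optimizing log K_D for conditioning.  Initial K_D is scanned
    over decades around the cell concentration; dH starts from the first
    injection heat.
    """

    def __init__(self, thermogram: Thermogram):
        self.data = thermogram

    def _predict(self, kd: float, dh: float, n: float) -> np.ndarray:
        d = self.data
        return itc_injection_heats(kd, dh, n, d.cell_conc, d.syringe_conc,
                                   d.injection_volumes, d.cell_volume)

    def fit(self) -> BindingResults:
        d = self.data
        scale = float(np.max(np.abs(d.heats)))
        if scale < 1e-12:
            raise DegenerateFitError("total heat is ~0: no binding signal")

        def residuals(theta):
            log_kd, dh, n = theta
            return self._predict(np.exp(log_kd), dh, n) - d.heats

        dh0 = d.heats[0]
        best = None
        for kd0 in [0.01, 0.1, 1.0, 10.0, 100.0]:
            x0 = [np.log(kd0 * d.cell_conc), dh0, 1.0]
            try:
                sol = least_squares(residuals, x0, method="lm", xtol=1e-14,
                                    ftol=1e-14, max_nfev=5000)
            except Exception:  # singular Jacobian at absurd starts
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            raise FitFailureError("one-site ITC fit did not converge; "
                                  f"diagnostics: {getattr(best, 'message', 'n/a')}")
        log_kd, dh, n = best.x
        kd = float(np.exp(log_kd))
        resid_norm = float(np.sqrt(2 * best.cost))
        dof = max(len(d.heats) - 3, 1)
        s2 = 2 * best.cost / dof
        try:
            cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            kd_se = kd * se[0]  # delta method for log-parametrization
            dh_se, n_se = se[1], se[2]
        except np.linalg.LinAlgError:
            kd_se = dh_se = n_se = np.nan
        return BindingResults(kd=kd, dh=float(dh), n_sites=float(n),
                              kd_se=float(kd_se), dh_se=float(dh_se),
                              n_se=float(n_se), residual_norm=resid_norm,
                              n_obs=len(d.heats), model=self)


def fit_one_site_itc(thermogram: Thermogram) -> BindingResults:
    """Functional wrapper around :class:`OneSiteBindingModel`."""
    return OneSiteBindingModel(thermogram).fit()


# ---------------------------------------------------------------------------
# uptake kinetics


@dataclass
class KineticDataset:
    """Whole-cell uptake time courses at several substrate concentrations.

    ``amounts[i]`` is the intracellular amount time course (nmol/mg) at
    ``substrate_concs[i]`` (mM) over the shared ``timepoints`` (min).
    """

    substrate_concs: np.ndarray
    timepoints: np.ndarray
    amounts: np.ndarray

    def __post_init__(self) -> None:
        self.substrate_concs = np.asarray(self.substrate_concs, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.amounts = np.asarray(self.amounts, dtype=float)
        if len(self.substrate_concs) == 0:
            raise ValueError("substrate concentration list is empty")
        if self.amounts.shape != (len(self.substrate_concs),
                                  len(self.timepoints)):
            raise ValueError("amounts must be (n_substrates, n_timepoints)")

    def initial_velocities(self, **kw) -> tuple[np.ndarray, np.ndarray]:
        """Initial uptake velocity and its standard error per substrate."""
        v = np.empty(len(self.substrate_concs))
        se = np.empty_like(v)
        for i in range(len(v)):
            v[i], se[i] = initial_velocity(self.timepoints, self.amounts[i],
                                           **kw)
        return v, se


def initial_velocity(time: np.ndarray, amount: np.ndarray,
                     max_points: int = 4,
                     plateau_fraction: float = 0.5) -> tuple[float, float]:
    """Initial uptake slope by ordinary least squares on the early window.

    The window is the points acquired before ``plateau_fraction`` of the
    final amount is reached, capped at ``max_points`` — whichever is
    smaller — and must contain at least 3 points.  Returns (slope,
    standard error); the intercept is free to absorb any offset.
    """
    time = np.asarray(time, dtype=float)
    amount = np.asarray(amount, dtype=float)
    plateau = amount[-1]
    if plateau > amount[0]:
        below = amount - amount[0] <= plateau_fraction * (plateau - amount[0])
        n_win = int(np.argmin(below)) if not below.all() else len(time)
    else:
        n_win = len(time)
    n_win = min(max(n_win, 3), max_points, len(time))
    if n_win < 3:
        raise ValueError("fewer than 3 points in the initial-velocity window")
    t, a = time[:n_win], amount[:n_win]
    X = np.column_stack([t, np.ones_like(t)])
    coef, res, *_ = np.linalg.lstsq(X, a, rcond=None)
    slope = coef[0]
    dof = n_win - 2
    if dof > 0 and len(res):
        s2 = res[0] / dof
        se = float(np.sqrt(s2 * np.linalg.inv(X.T @ X)[0, 0]))
    else:
        se = 0.0
    return float(slope), se


def michaelis_menten(s, vmax, km):
    """Y = V_max * X / (K_M + X)."""
    return vmax * s / (km + s)


@dataclass
class MichaelisMentenResults:
    """Michaelis-Menten fit: V_max, K_M and asymptotic standard errors."""

    vmax: float
    km: float
    vmax_se: float
    km_se: float
    residual_norm: float
    n_obs: int
    boundary_fit: bool = False

    @property
    def params(self) -> dict:
        return {"vmax": self.vmax, "km": self.km}

    def summary(self) -> str:
        lines = ["Michaelis-Menten fit: Y = Vmax*X/(Km + X)",
                 "-" * 46,
                 f"{'parameter':<26}{'estimate':>10}{'std err':>10}",
                 f"{'V_max (nmol/mg/min)':<26}{self.vmax:>10.4g}"
                 f"{self.vmax_se:>10.3g}",
                 f"{'K_M (mM)':<26}{self.km:>10.4g}{self.km_se:>10.3g}",
                 f"residual norm: {self.residual_norm:.3g} on {self.n_obs} levels"]
        if self.boundary_fit:
            lines.append("warning: K_M at lower boundary (velocities saturated "
                         "at all substrate levels)")
        return "\n".join(lines)


class MichaelisMentenModel:
    """Nonlinear least-squares Michaelis-Menten model for velocity data.

    Unweighted by default; pass per-point standard deviations as ``sigma``
    for inverse-variance weighting.
    """

    _KM_FLOOR = 1e-9  # mM; fits pinned here are flagged as boundary fits

    def __init__(self, substrate: np.ndarray, velocity: np.ndarray,
                 sigma: np.ndarray | None = None):
        self.s = np.asarray(substrate, dtype=float)
        self.v = np.asarray(velocity, dtype=float)
        self.sigma = None if sigma is None else np.asarray(sigma, dtype=float)
        if len(np.unique(self.s)) < 2:
            raise ValueError("need >= 2 distinct substrate concentrations")
        if np.any(self.v < 0):
            raise ValueError("velocities must be non-negative")
        if not np.any(self.v > 0):
            raise ValueError("all velocities are zero: nothing to fit")

    def fit(self) -> MichaelisMentenResults:
        p0 = [1.2 * self.v.max(), np.median(self.s)]
        try:
            popt, pcov = curve_fit(michaelis_menten, self.s, self.v, p0=p0,
                                   sigma=self.sigma,
                                   bounds=([0, self._KM_FLOOR], np.inf),
                                   maxfev=20000)
        except RuntimeError as exc:
            raise FitFailureError(
                f"Michaelis-Menten fit did not converge (start {p0}): {exc}"
            ) from exc
        vmax, km = popt
        se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
        resid = michaelis_menten(self.s, *popt) - self.v
        # K_M far below the lowest substrate level is unidentifiable:
        # the data are saturated everywhere
        boundary = km < 1e-3 * self.s.min()
        if boundary:
            log.warning("K_M pinned at lower boundary: data look saturated")
        return MichaelisMentenResults(
            vmax=float(vmax), km=float(km), vmax_se=float(se[0]),
            km_se=float(se[1]), residual_norm=float(np.linalg.norm(resid)),
            n_obs=len(self.s), boundary_fit=bool(boundary))


def fit_michaelis_menten(substrate, velocity, sigma=None) -> MichaelisMentenResults:
    """Functional wrapper around :class:`MichaelisMentenModel`."""
    return MichaelisMentenModel(substrate, velocity, sigma=sigma).fit()
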