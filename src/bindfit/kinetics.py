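"""1:1 Langmuir biosensor kinetics.

Trace containers, preprocessing (reference subtraction, Savitzky-Golay
smoothing, baseline re-zeroing), single-exponential association and
dissociation fits, the K_obs-vs-concentration line that yields K_on,
the R^2-filtered mean K_off, and the kinetic K_D = K_off/K_on.

Time is in seconds, signal in nm interference shift, concentrations in
nM, so K_on is in nM^-1 s^-1 and K_off in s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import interp1d
from scipy.optimize import curve_fit, least_squares
from scipy.signal import savgol_filter
from scipy.stats import linregress

__all__ = [
    "PHASES",
    "BLITrace",
    "KineticParameters",
    "KobsRecord",
    "KobsLineFit",
    "KoffEstimate",
    "FitError",
    "preprocess_trace",
    "association_model",
    "dissociation_model",
    "fit_kobs",
    "kon_from_kobs",
    "mean_koff",
    "kinetic_kd",
    "fit_association_then_dissociation",
]

PHASES = ("baseline", "association", "dissociation")


class FitError(RuntimeError):
    """A kinetic or equilibrium fit failed or was given degenerate data."""


@dataclass
class BLITrace:
    """One biosensor's time series with phase annotation.

    ``phase`` labels each point as baseline, association or
    dissociation; labels must form contiguous blocks in that order
    (phases may be absent, e.g. an association-only trace).
    ``is_reference`` marks a receptor-free control sensor run in
    parallel for background subtraction.
    """

    time: np.ndarray
    signal: np.ndarray
    phase: np.ndarray
    analyte_conc: float
    sensor_id: str = ""
    is_reference: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (self.time.shape == self.signal.shape == self.phase.shape):
            raise ValueError("time, signal and phase must have identical shape")
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValueError("trace must be a non-empty 1-D series")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"time must be strictly increasing (sensor {self.sensor_id!r})")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"signal contains non-finite values (sensor {self.sensor_id!r})")
        if float(self.analyte_conc) < 0:
            raise ValueError("analyte_conc must be >= 0")
        self.analyte_conc = float(self.analyte_conc)
        self._check_phase_blocks()

    def _check_phase_blocks(self) -> None:
        labels = [str(p) for p in self.phase]
        unknown = set(labels) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels {sorted(unknown)} (sensor {self.sensor_id!r})")
        # contiguous blocks in canonical order
        order = []
        for lab in labels:
            if not order or order[-1] != lab:
                order.append(lab)
        ranks = [PHASES.index(lab) for lab in order]
        if len(set(order)) != len(order) or ranks != sorted(ranks):
            raise ValueError(
                "phase labels must form contiguous baseline -> association -> "
                f"dissociation blocks (sensor {self.sensor_id!r})"
            )

    def has_phase(self, name: str) -> bool:
        return bool(np.any(self.phase == name))

    def segment(self, name: str, rezero_time: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Return (time, signal) of one phase, time re-zeroed to its start."""
        mask = self.phase == name
        if not np.any(mask):
            raise ValueError(f"trace has no {name!r} phase (sensor {self.sensor_id!r})")
        t = self.time[mask]
        y = self.signal[mask]
        if rezero_time:
            t = t - t[0]
        return t, y


@dataclass(frozen=True)
class KineticParameters:
    """Association/dissociation rate constants and the kinetic K_D.

    ``kd_kinetic`` is always ``koff / kon``; SEMs, when available, are
    mean +/- SEM across replicates or fit standard errors.
    """

    kon: float
    koff: float
    kon_sem: float | None = None
    koff_sem: float | None = None

    def __post_init__(self) -> None:
        if not (self.kon > 0 and self.koff > 0):
            raise ValueError("kon and koff must be positive")

    @property
    def kd_kinetic(self) -> float:
        return self.koff / self.kon

    @property
    def kd_sem(self) -> float | None:
        kd, sem = kinetic_kd(self.kon, self.koff, self.kon_sem, self.koff_sem)
        return sem


@dataclass(frozen=True)
class KobsRecord:
    """Observed association rate at one analyte concentration."""

    analyte_conc: float
    kobs: float
    fit_r2: float
    plateau: float

    def __post_init__(self) -> None:
        if self.kobs <= 0:
            raise ValueError("kobs must be positive")
        if not (0.0 <= self.fit_r2 <= 1.0 + 1e-12):
            raise ValueError("fit_r2 must lie in [0, 1]")


@dataclass(frozen=True)
class KobsLineFit:
    """Ordinary least-squares line K_obs = K_on * C + intercept."""

    kon: float
    kon_sem: float
    intercept: float
    intercept_sem: float
    r2: float
    n: int
    concentration_dependent: bool


@dataclass(frozen=True)
class KoffEstimate:
    """R^2-filtered mean dissociation rate constant."""

    koff: float
    sem: float | None
    n_used: int
    n_excluded: int
    per_trace: tuple = field(default=())


def association_model(t, conc: float, kinetics: KineticParameters, bmax: float):
    """1:1 Langmuir association: ``R_eq * (1 - exp(-K_obs t))``.

    ``K_obs = K_on*C + K_off`` and ``R_eq = B_max * C / (C + K_D)``.
    """
    t = np.asarray(t, dtype=float)
    kobs = kinetics.kon * conc + kinetics.koff
    req = bmax * conc / (conc + kinetics.kd_kinetic) if conc > 0 else 0.0
    return req * (1.0 - np.exp(-kobs * t))


def dissociation_model(t, r0: float, koff: float):
    """One-phase exponential decay ``r0 * exp(-K_off t)``."""
    t = np.asarray(t, dtype=float)
    return r0 * np.exp(-koff * t)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum((y - yhat) ** 2))
    if sst == 0.0:
        return 0.0
    return 1.0 - ssr / sst


def preprocess_trace(
    trace: BLITrace,
    reference: BLITrace | None = None,
    smoothing: tuple[int, int] | None = (11, 3),
    baseline_seconds: float = 10.0,
) -> BLITrace:
    """Reference-subtract, smooth, and baseline-zero a trace.

    The receptor-free reference (run in parallel) is interpolated onto
    the trace's time grid and subtracted, removing buffer drift and
    non-specific background.  Savitzky-Golay smoothing (default window
    11 points, polynomial order 3; pass ``None`` to disable) is applied
    next, and finally the mean of the last ``baseline_seconds`` of the
    baseline phase is subtracted so the association starts from zero.
    Phase labels are preserved.
    """
    y = trace.signal.copy()
    if reference is not None:
        t0, t1 = reference.time[0], reference.time[-1]
        if trace.time[0] < t0 - 1e-9 or trace.time[-1] > t1 + 1e-9:
            raise ValueError("reference time grid does not cover the trace")
        ref = interp1d(reference.time, reference.signal, assume_sorted=True)(trace.time)
        y = y - ref
    if smoothing is not None:
        window, order = smoothing
        if window % 2 == 0 or window <= order:
            raise ValueError("smoothing window must be odd and > polynomial order")
        if window > y.size:
            raise ValueError("smoothing window longer than trace")
        y = savgol_filter(y, window, order)
    if trace.has_phase("baseline"):
        mask = trace.phase == "baseline"
        tb, yb = trace.time[mask], y[mask]
        cut = tb[-1] - baseline_seconds
        tail = yb[tb >= cut] if np.any(tb >= cut) else yb
        y = y - float(tail.mean())
    return replace(trace, signal=y)


def fit_kobs(trace: BLITrace) -> KobsRecord:
    """Fit ``plateau * (1 - exp(-kobs t))`` to the association phase.

    Initial values come from a log-linear regression of the early rise;
    a flat or signal-free association raises :class:`FitError`.
    """
    t, y = trace.segment("association")
    if t.size < 5:
        raise FitError("association phase must contain at least 5 points")
    if np.ptp(y) == 0.0 or np.allclose(y, 0.0, atol=1e-300):
        raise FitError("no association signal (constant trace)")

    plateau0 = float(np.mean(y[int(0.95 * y.size):])) if y.size >= 20 else float(y[-1])
    if plateau0 <= 0:
        plateau0 = float(np.max(np.abs(y))) or 1.0
    kobs0 = _loglinear_rate_rise(t, y, plateau0)

    def model(tt, plateau, kobs):
        return plateau * (1.0 - np.exp(-kobs * tt))

    try:
        popt, _ = curve_fit(
            model, t, y, p0=[plateau0, kobs0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"association fit failed to converge: {exc}") from exc
    plateau, kobs = popt
    if kobs <= 0 or plateau <= 0:
        raise FitError("association fit returned non-positive rate or plateau")
    r2 = _r_squared(y, model(t, *popt))
    return KobsRecord(trace.analyte_conc, float(kobs), max(0.0, min(1.0, r2)), float(plateau))


def _loglinear_rate_rise(t: np.ndarray, y: np.ndarray, plateau: float) -> float:
    """Rate guess from -ln(1 - y/plateau) on the early rise."""
    frac = y / plateau
    ok = (frac > 0.02) & (frac < 0.8) & (t > 0)
    if np.count_nonzero(ok) >= 3:
        slope = np.polyfit(t[ok], -np.log1p(-np.clip(frac[ok], None, 0.999999)), 1)[0]
        if slope > 0:
            return float(slope)
    return 1.0 / max(float(t[-1]), 1e-9)


def _loglinear_rate_decay(t: np.ndarray, y: np.ndarray) -> float:
    ok = (y > 0) & (t >= 0)
    if np.count_nonzero(ok) >= 3:
        slope = np.polyfit(t[ok], np.log(y[ok]), 1)[0]
        if slope < 0:
            return float(-slope)
    return 1.0 / max(float(t[-1]), 1e-9)


def _fit_decay(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Fit r0*exp(-koff t); returns (koff, r0, r2)."""
    if t.size < 5:
        raise FitError("dissociation phase must contain at least 5 points")
    r0_0 = float(y[0]) if y[0] > 0 else max(float(np.max(y)), 1e-6)
    koff0 = _loglinear_rate_decay(t, y)
    try:
        popt, _ = curve_fit(
            dissociation_model, t, y, p0=[r0_0, koff0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"dissociation fit failed to converge: {exc}") from exc
    r0, koff = popt
    r2 = _r_squared(y, dissociation_model(t, r0, koff))
    return float(koff), float(r0), r2


def kon_from_kobs(records: Sequence[KobsRecord]) -> KobsLineFit:
    """K_on as the slope of the K_obs vs concentration line (OLS).

    Requires observations at >= 3 distinct concentrations.  The
    intercept is reported for cross-checking against the independently
    fitted K_off but is not constrained to equal it.  A zero (or
    statistically indistinguishable from zero) slope is flagged as
    lacking concentration dependence.
    """
    conc = np.array([r.analyte_conc for r in records], dtype=float)
    kobs = np.array([r.kobs for r in records], dtype=float)
    if np.unique(conc).size < 3:
        raise ValueError("need kobs at >= 3 distinct concentrations")
    res = linregress(conc, kobs)
    slope_sem = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    icpt_sem = float(res.intercept_stderr) if np.isfinite(res.intercept_stderr) else 0.0
    dependent = res.slope > 0 and (slope_sem == 0.0 or res.slope > 2.0 * slope_sem)
    return KobsLineFit(
        kon=float(res.slope),
        kon_sem=slope_sem,
        intercept=float(res.intercept),
        intercept_sem=icpt_sem,
        r2=float(res.rvalue**2),
        n=int(conc.size),
        concentration_dependent=bool(dependent),
    )


def mean_koff(traces: Sequence[BLITrace], r2_threshold: float = 0.8) -> KoffEstimate:
    """Mean K_off over per-trace exponential-decay fits passing an R^2 filter.

    Each dissociation phase is fit to ``r0 * exp(-K_off t)``; fits with
    R^2 <= ``r2_threshold`` (typically the low-concentration, low-signal
    conditions) are excluded, as are fits that fail outright.  Returns
    the mean, the SEM across surviving traces (``None`` for a single
    survivor), and the exclusion count.
    """
    fits, n_excluded = [], 0
    records = []
    for trace in traces:
        try:
            t, y = trace.segment("dissociation")
            koff, r0, r2 = _fit_decay(t, y)
        except FitError:
            n_excluded += 1
            continue
        records.append((trace.sensor_id, koff, r2))
        if r2 > r2_threshold:
            fits.append(koff)
        else:
            n_excluded += 1
    if not fits:
        raise FitError(
            f"no dissociation fit passed the R^2 > {r2_threshold} filter "
            f"({n_excluded} excluded)"
        )
    arr = np.asarray(fits)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else None
    return KoffEstimate(
        koff=float(arr.mean()),
        sem=sem,
        n_used=int(arr.size),
        n_excluded=int(n_excluded),
        per_trace=tuple(records),
    )


def kinetic_kd(
    kon: float,
    koff: float,
    kon_sem: float | None = None,
    koff_sem: float | None = None,
) -> tuple[float, float | None]:
    """Kinetic K_D = K_off / K_on, with SEM propagated in quadrature.

    Relative SEMs of the two rate constants combine as
    ``sqrt((s_on/kon)^2 + (s_off/koff)^2) * K_D``; returns
    ``(kd, None)`` when either SEM is unavailable.
    """
    if kon <= 0:
        raise ValueError("kon must be positive")
    kd = koff / kon
    if kon_sem is None or koff_sem is None:
        return kd, None
    rel = math.sqrt((kon_sem / kon) ** 2 + (koff_sem / koff) ** 2)
    return kd, kd * rel


def fit_association_then_dissociation(trace: BLITrace) -> KineticParameters:
    """Joint two-phase fit sharing kon, koff and B_max.

    For single-concentration experiments: the association and
    dissociation phases are fit simultaneously with the dissociation
    starting amplitude pinned to the association model's value at the
    phase boundary (signal continuity).  SEMs come from the
    least-squares covariance.
    """
    if not (trace.has_phase("association") and trace.has_phase("dissociation")):
        raise FitError("trace must contain both association and dissociation phases")
    conc = trace.analyte_conc
    if conc <= 0:
        raise FitError("analyte concentration must be positive for a kinetic fit")
    ta, ya = trace.segment("association")
    td, yd = trace.segment("dissociation")
    # association time elapsed at the dissociation start (phase boundary)
    t_assoc_end = float(trace.time[trace.phase == "dissociation"][0]
                        - trace.time[trace.phase == "association"][0])

    # sequential initial guesses
    rec = fit_kobs(trace)
    koff0 = _loglinear_rate_decay(td, yd)
    koff0 = min(koff0, 0.95 * rec.kobs) if rec.kobs > koff0 else rec.kobs * 0.5
    kon0 = max((rec.kobs - koff0) / conc, 1e-12)
    kd0 = koff0 / kon0
    bmax0 = rec.plateau * (conc + kd0) / conc

    def residuals(theta):
        lkon, lkoff, lbmax = theta
        kin = KineticParameters(kon=10.0**lkon, koff=10.0**lkoff)
        ra = association_model(ta, conc, kin, 10.0**lbmax)
        r_boundary = association_model(t_assoc_end, conc, kin, 10.0**lbmax)
        rd = dissociation_model(td, float(r_boundary), kin.koff)
        return np.concatenate([ra - ya, rd - yd])

    theta0 = np.log10([kon0, koff0, bmax0])
    sol = least_squares(residuals, theta0, method="lm",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise FitError(f"joint association/dissociation fit failed: {sol.message}")
    kon, koff, _ = 10.0**sol.x
    # covariance of log-params -> SEM of params via delta method
    dof = sol.fun.size - sol.x.size
    kon_sem = koff_sem = None
    if dof > 0:
        ssr = float(np.sum(sol.fun**2))
        try:
            jtj_inv = np.linalg.inv(sol.jac.T @ sol.jac)
            cov = jtj_inv * ssr / dof
            ln10 = math.log(10.0)
            kon_sem = float(math.sqrt(max(cov[0, 0], 0.0)) * ln10 * kon)
            koff_sem = float(math.sqrt(max(cov[1, 1], 0.0)) * ln10 * koff)
        except np.linalg.LinAlgError:
            pass
    return KineticParameters(kon=float(kon), koff=float(koff),
                             kon_sem=kon_sem, koff_sem=koff_sem)
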