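"""Estimation layer: steady-state saturation fits, IC50/displacement
fits, competition-model fits with bootstrap confidence intervals,
normalizations, and nested model comparison.

All fits operate on replicate points jointly (never on replicate means)
and are deterministic given the data; bootstrap resampling is
deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares
from scipy.stats import f as f_dist

from .equilibrium import (
    AffinityShiftParameters,
    CompetitionSystem,
    EquilibriumParameters,
    affinity_shift_competition,
    bound_fraction_no_competitor,
    hill_binding,
    wang_competition_curve,
)
from .kinetics import FitError

__all__ = [
    "EquilibriumFit",
    "CompetitionDataset",
    "CompetitionFitResult",
    "Ic50Fit",
    "ModelComparison",
    "fit_steady_state",
    "normalize_percent_of_reference",
    "normalize_fraction_of_calculated_zero",
    "fit_ic50",
    "fit_competition_model",
    "compare_models",
]

NORMALIZATION_MODES = ("fraction_of_total", "percent_of_zero_competitor")


@dataclass(frozen=True)
class EquilibriumFit:
    """Steady-state Hill fit with uncertainties.

    SEMs are across-replicate when replicates permit per-replicate fits,
    otherwise asymptotic standard errors from the joint-fit covariance.
    ``extrapolated_bmax`` flags datasets whose top concentration does
    not approach saturation (top signal < 60% of fitted B_max).
    """

    params: EquilibriumParameters
    bmax_sem: float | None
    kd_sem: float | None
    hill_sem: float | None
    n_replicates: int
    residual_sd: float
    extrapolated_bmax: bool


@dataclass
class CompetitionDataset:
    """Competitor-concentration grid with replicate measurements.

    ``normalization`` declares the scale of ``value``:
    ``fraction_of_total`` (bound sites / total sites, in [0, 1]) or
    ``percent_of_zero_competitor`` (100 at x = 0 by construction).
    """

    conc: np.ndarray
    value: np.ndarray
    replicate: np.ndarray | None = None
    normalization: str = "fraction_of_total"

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.conc.shape != self.value.shape or self.conc.ndim != 1:
            raise ValueError("conc and value must be 1-D arrays of equal length")
        if np.any(self.conc < 0) or not np.all(np.isfinite(self.conc)):
            raise ValueError("concentrations must be finite and >= 0")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("values must be finite")
        if np.unique(self.conc).size < 2:
            raise ValueError("need >= 2 distinct competitor concentrations")
        if self.normalization not in NORMALIZATION_MODES:
            raise ValueError(f"normalization must be one of {NORMALIZATION_MODES}")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.conc.shape:
                raise ValueError("replicate labels must match data length")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"competitor_nM": self.conc, "value": self.value})
        df.insert(1, "replicate",
                  self.replicate if self.replicate is not None else np.zeros(len(df), int))
        df["normalization"] = self.normalization
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CompetitionDataset":
        norm = "fraction_of_total"
        if "normalization" in df.columns and len(df):
            modes = df["normalization"].unique()
            if len(modes) != 1:
                raise ValueError("mixed normalization modes in one dataset")
            norm = str(modes[0])
        return cls(
            conc=df["competitor_nM"].to_numpy(float),
            value=df["value"].to_numpy(float),
            replicate=df["replicate"].to_numpy() if "replicate" in df.columns else None,
            normalization=norm,
        )


@dataclass(frozen=True)
class CompetitionFitResult:
    """Result of fitting a competition model to displacement data."""

    model: str
    kb: float
    kb_ci: tuple[float, float] | None
    alpha: float | None
    alpha_ci: tuple[float, float] | None
    ssr: float
    n_points: int
    n_parameters: int
    residual_sd: float
    n_boot: int
    seed: int | None
    ci_method: str = "parametric bootstrap (percentile)"

    def __post_init__(self) -> None:
        if self.kb_ci is not None:
            lo, hi = self.kb_ci
            if not (lo < self.kb < hi):
                raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class Ic50Fit:
    """Descending-logistic fit of a displacement curve."""

    ic50: float
    ic50_sem: float | None
    top: float
    bottom: float
    slope: float
    r2: float


@dataclass(frozen=True)
class ModelComparison:
    """Nested comparison of competitive vs affinity-shift fits.

    The fully competitive model is the alpha -> infinity boundary of the
    affinity-shift family, so the extra-sum-of-squares F-test applies
    with one extra parameter; a small-sample-corrected information
    criterion (AICc) is computed as well.  ``verdict`` is the model both
    agree on, or ``"ambiguous"``.
    """

    f_statistic: float
    p_value: float
    aicc_competitive: float
    aicc_shift: float
    verdict: str
    competitive: CompetitionFitResult
    shift: CompetitionFitResult


# ---------------------------------------------------------------------------
# steady-state saturation
# ---------------------------------------------------------------------------

def _as_dose_response(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data.rename(columns={"conc_nM": "conc", "signal_nm": "signal"})
    else:
        conc, signal = data
        df = pd.DataFrame({"conc": conc, "signal": signal, "replicate": 0})
    if "replicate" not in df.columns:
        df = df.assign(replicate=0)
    return df[["conc", "replicate", "signal"]].astype({"conc": float, "signal": float})


def _hill_curve(c, bmax, kd, hill):
    return hill_binding(c, EquilibriumParameters(bmax=bmax, kd=kd, hill=hill))


def _fit_hill_once(conc, signal) -> tuple[np.ndarray, np.ndarray]:
    top = float(np.max(signal))
    if top <= 0:
        raise FitError("no positive signal to fit")
    half = 0.5 * top
    above = conc[signal >= half]
    kd0 = float(above.min()) if above.size else float(np.median(conc[conc > 0]))
    p0 = [1.05 * top, max(kd0, 1e-9), 1.0]
    popt, pcov = curve_fit(
        _hill_curve, conc, signal, p0=p0,
        bounds=([1e-12, 1e-12, 0.05], [np.inf, np.inf, 20.0]), maxfev=20000,
    )
    return popt, pcov


def fit_steady_state(data) -> EquilibriumFit:
    """Fit plateau signals to a one-site model with variable Hill slope.

    ``data`` is a DataFrame with columns ``conc`` (nM), ``replicate``
    and ``signal`` (nm), or a ``(conc, signal)`` pair of arrays.  All
    replicate points are fit jointly for the point estimates; when >= 2
    replicates are present, each replicate is also fit separately and
    the across-replicate SEM of each parameter is reported.
    """
    df = _as_dose_response(data)
    if df["conc"].nunique() < 4:
        raise FitError("need >= 4 distinct concentrations for a Hill fit")
    if np.allclose(df["signal"], 0.0):
        raise FitError("all signals are zero; nothing to fit")

    conc = df["conc"].to_numpy()
    signal = df["signal"].to_numpy()
    try:
        popt, pcov = _fit_hill_once(conc, signal)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"steady-state fit failed to converge: {exc}") from exc
    bmax, kd, hill = (float(v) for v in popt)
    yhat = _hill_curve(conc, *popt)
    dof = max(conc.size - 3, 1)
    residual_sd = float(np.sqrt(np.sum((signal - yhat) ** 2) / dof))

    reps = df["replicate"].unique()
    sems: list[float | None]
    if len(reps) >= 2:
        per_rep = []
        for rep in reps:
            sub = df[df["replicate"] == rep]
            try:
                p_r, _ = _fit_hill_once(sub["conc"].to_numpy(), sub["signal"].to_numpy())
                per_rep.append(p_r)
            except (RuntimeError, ValueError, FitError):
                pass
        if len(per_rep) >= 2:
            arr = np.array(per_rep)
            sems = list(arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0]))
        else:
            sems = [float(np.sqrt(max(pcov[i, i], 0.0))) for i in range(3)]
    else:
        sems = [float(np.sqrt(max(pcov[i, i], 0.0))) for i in range(3)]

    top_signal = df.loc[df["conc"] == df["conc"].max(), "signal"].mean()
    extrapolated = bool(top_signal < 0.6 * bmax)
    return EquilibriumFit(
        params=EquilibriumParameters(bmax=bmax, kd=kd, hill=hill),
        bmax_sem=float(sems[0]),
        kd_sem=float(sems[1]),
        hill_sem=float(sems[2]),
        n_replicates=int(len(reps)),
        residual_sd=residual_sd,
        extrapolated_bmax=extrapolated,
    )


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

def normalize_percent_of_reference(values, reference_value: float) -> np.ndarray:
    """Express values as percent of a reference (e.g. zero-competitor) signal."""
    if not (reference_value > 0):
        raise ValueError("reference value must be positive")
    return 100.0 * np.asarray(values, dtype=float) / float(reference_value)


def normalize_fraction_of_calculated_zero(
    bound_values, system: CompetitionSystem, zero_value: float | None = None
) -> np.ndarray:
    """Rescale bead-only measurements to fraction-of-total units.

    When only bead-bound ligand is quantified (no supernatant), absolute
    fraction bound is unknown; measurements are rescaled so that the
    zero-competitor measurement maps onto the calculated depletion
    isotherm value :func:`bound_fraction_no_competitor`.  ``zero_value``
    defaults to the first element of ``bound_values``.
    """
    values = np.asarray(bound_values, dtype=float)
    f0 = bound_fraction_no_competitor(system)
    if f0 <= 0:
        raise ValueError("calculated zero-competitor bound fraction is zero "
                         "(no receptor); cannot normalize")
    v0 = float(values[0]) if zero_value is None else float(zero_value)
    if v0 <= 0:
        raise ValueError("zero-competitor measurement must be positive")
    return values * (f0 / v0)


# ---------------------------------------------------------------------------
# IC50
# ---------------------------------------------------------------------------

def fit_ic50(
    dataset: CompetitionDataset,
    fix_bottom: bool = True,
    fix_slope: bool = True,
) -> Ic50Fit:
    """Fit a descending logistic to a displacement curve.

    ``y = bottom + (top - bottom) / (1 + (x / IC50)^slope)`` with bottom
    fixed at 0 and slope fixed at 1 by default.  The dataset must span
    the transition: values both above 75% and below 25% of the
    zero-competitor level.
    """
    x = dataset.conc
    y = dataset.value
    zero_level = float(y[x == x.min()].mean())
    if zero_level <= 0:
        raise FitError("non-positive zero-competitor level")
    if not (np.any(y > 0.75 * zero_level) and np.any(y < 0.25 * zero_level)):
        raise FitError("dataset does not span the displacement transition")

    mid = y <= 0.5 * zero_level
    ic50_0 = float(x[mid].min()) if np.any(mid & (x > 0)) else float(np.median(x[x > 0]))

    def model(xx, log_ic50, top, bottom, slope):
        ic50 = 10.0 ** log_ic50
        return bottom + (top - bottom) / (1.0 + (xx / ic50) ** slope)

    p0 = [math.log10(max(ic50_0, 1e-9)), zero_level]
    lo, hi = [-12.0, 0.0], [12.0, np.inf]
    if not fix_bottom:
        p0.append(0.0); lo.append(0.0); hi.append(np.inf)
    if not fix_slope:
        p0.append(1.0); lo.append(0.1); hi.append(10.0)

    def wrapped(xx, *theta):
        i = 2
        bottom = 0.0
        slope = 1.0
        if not fix_bottom:
            bottom = theta[i]; i += 1
        if not fix_slope:
            slope = theta[i]; i += 1
        return model(xx, theta[0], theta[1], bottom, slope)

    try:
        popt, pcov = curve_fit(wrapped, x, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"IC50 fit failed to converge: {exc}") from exc
    ic50 = 10.0 ** popt[0]
    sem = None
    var = pcov[0, 0]
    if np.isfinite(var) and var >= 0:
        sem = float(math.log(10.0) * ic50 * math.sqrt(var))
    i = 2
    bottom = 0.0
    slope = 1.0
    if not fix_bottom:
        bottom = float(popt[i]); i += 1
    if not fix_slope:
        slope = float(popt[i]); i += 1
    yhat = wrapped(x, *popt)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / sst if sst > 0 else 0.0
    return Ic50Fit(ic50=float(ic50), ic50_sem=sem, top=float(popt[1]),
                   bottom=bottom, slope=slope, r2=r2)


# ---------------------------------------------------------------------------
# competition-model fitting
# ---------------------------------------------------------------------------

_KB_BOUNDS = (1e-4, 1e9)  # nM
_ALPHA_BOUNDS = (1.0 + 1e-9, 1e9)


def _predict(
    x: np.ndarray,
    system: CompetitionSystem,
    model: str,
    alpha: float | None,
    normalization: str,
) -> np.ndarray:
    if model == "competitive":
        y = wang_competition_curve(system, x)
    elif model == "affinity_shift":
        y = affinity_shift_competition(AffinityShiftParameters(system, alpha), x)
    else:
        raise ValueError(f"unknown model {model!r}")
    if normalization == "percent_of_zero_competitor":
        y0 = bound_fraction_no_competitor(system)
        y = 100.0 * y / y0
    return np.atleast_1d(y)


def _fit_point(
    dataset: CompetitionDataset,
    system: CompetitionSystem,
    model: str,
    kb_init: float,
    alpha_init: float,
) -> tuple[float, float | None, float]:
    """Least-squares point estimate; returns (kb, alpha, ssr)."""
    x, y = dataset.conc, dataset.value
    lb_kb, ub_kb = np.log10(_KB_BOUNDS)

    if model == "competitive":
        def resid(theta):
            sys_i = replace(system, kb=10.0 ** theta[0])
            return _predict(x, sys_i, model, None, dataset.normalization) - y
        theta0 = [np.clip(math.log10(kb_init), lb_kb, ub_kb)]
        bounds = ([lb_kb], [ub_kb])
    else:
        lb_a, ub_a = np.log10(_ALPHA_BOUNDS)
        def resid(theta):
            sys_i = replace(system, kb=10.0 ** theta[0])
            return _predict(x, sys_i, model, 10.0 ** theta[1],
                            dataset.normalization) - y
        theta0 = [np.clip(math.log10(kb_init), lb_kb, ub_kb),
                  np.clip(math.log10(alpha_init), lb_a + 1e-9, ub_a)]
        bounds = ([lb_kb, lb_a], [ub_kb, ub_a])

    sol = least_squares(resid, theta0, bounds=bounds, xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise FitError(f"competition fit ({model}) failed: {sol.message}")
    kb = 10.0 ** sol.x[0]
    alpha = 10.0 ** sol.x[1] if model == "affinity_shift" else None
    return kb, alpha, float(np.sum(sol.fun ** 2))


def _grid_init(dataset: CompetitionDataset, system: CompetitionSystem,
               model: str) -> tuple[float, float]:
    """Coarse log-grid scan for robust starting values."""
    x, y = dataset.conc, dataset.value
    best = (np.inf, system.kb, 10.0)
    kb_grid = np.logspace(0, 7, 15)
    alpha_grid = [2.0, 5.0, 20.0, 100.0, 1e4] if model == "affinity_shift" else [None]
    for kb in kb_grid:
        for alpha in alpha_grid:
            yhat = _predict(x, replace(system, kb=kb), model, alpha,
                            dataset.normalization)
            ssr = float(np.sum((yhat - y) ** 2))
            if ssr < best[0]:
                best = (ssr, kb, alpha if alpha is not None else 10.0)
    return best[1], best[2]


def fit_competition_model(
    dataset: CompetitionDataset,
    system: CompetitionSystem,
    model: str = "competitive",
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> CompetitionFitResult:
    """Estimate the competitor constant K_B (and alpha) from displacement data.

    ``system`` supplies the known quantities A, R and K_A; its ``kb``
    field serves only as an initial guess (refined by a coarse grid scan
    first).  95% confidence intervals come from a seeded parametric
    bootstrap: residual SD is estimated from the fit, Gaussian noise is
    added to the fitted curve, and each resample is refit; percentile
    bounds are reported.  Set ``n_boot=0`` to skip the bootstrap.

    Raises :class:`FitError` when no displacement is detectable (fitted
    K_B at the upper bound).
    """
    if model not in ("competitive", "affinity_shift"):
        raise ValueError(f"unknown model {model!r}")
    kb0, alpha0 = _grid_init(dataset, system, model)
    kb, alpha, ssr = _fit_point(dataset, system, model, kb0, alpha0)
    if kb >= 0.5 * _KB_BOUNDS[1]:
        raise FitError("fitted K_B is unbounded: no displacement detected")

    n = dataset.conc.size
    k = 1 if model == "competitive" else 2
    dof = max(n - k, 1)
    sd = math.sqrt(ssr / dof)

    kb_ci = alpha_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        sys_hat = replace(system, kb=kb)
        yhat = _predict(dataset.conc, sys_hat, model, alpha, dataset.normalization)
        kbs, alphas = [], []
        for _ in range(n_boot):
            y_star = yhat + rng.normal(0.0, sd, size=n)
            ds_star = CompetitionDataset(
                conc=dataset.conc, value=y_star,
                replicate=dataset.replicate, normalization=dataset.normalization,
            )
            try:
                kb_b, alpha_b, _ = _fit_point(ds_star, system, model, kb,
                                              alpha if alpha else 10.0)
            except FitError:
                continue
            kbs.append(kb_b)
            if alpha_b is not None:
                alphas.append(alpha_b)
        if len(kbs) < max(10, n_boot // 2):
            raise FitError("bootstrap refits failed too often; unstable fit")
        tail = 100.0 * (1.0 - ci_level) / 2.0
        lo, hi = np.percentile(kbs, [tail, 100.0 - tail])
        # percentile CI can exclude the point estimate in pathological
        # resamples; widen minimally so the invariant lo < kb < hi holds
        kb_ci = (min(float(lo), kb * (1 - 1e-9)), max(float(hi), kb * (1 + 1e-9)))
        if alphas:
            lo_a, hi_a = np.percentile(alphas, [tail, 100.0 - tail])
            alpha_ci = (float(lo_a), float(hi_a))

    return CompetitionFitResult(
        model=model, kb=kb, kb_ci=kb_ci, alpha=alpha, alpha_ci=alpha_ci,
        ssr=ssr, n_points=int(n), n_parameters=k, residual_sd=sd,
        n_boot=int(n_boot), seed=seed,
    )


def _aicc(n: int, k: int, ssr: float) -> float:
    """Small-sample-corrected AIC for a Gaussian least-squares fit.

    ``k`` counts model parameters plus the noise variance.
    """
    k = k + 1
    if n - k - 1 <= 0:
        return math.inf
    ssr = max(ssr, 1e-300)
    return n * math.log(ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def compare_models(
    dataset: CompetitionDataset,
    system: CompetitionSystem,
    seed: int | None = None,
    n_boot: int = 0,
) -> ModelComparison:
    """Decide between fully competitive and affinity-shift displacement.

    Fits both models, then runs the extra-sum-of-squares F-test (the
    competitive model is the boundary of the affinity-shift family, one
    fewer parameter) and AICc.  The verdict is ``"affinity_shift"`` when
    the F-test rejects the competitive model (p < 0.05) and AICc agrees,
    ``"competitive"`` when the F-test does not reject and AICc agrees,
    and ``"ambiguous"`` otherwise (including zero-residual ties).
    """
    fit_c = fit_competition_model(dataset, system, "competitive",
                                  n_boot=n_boot, seed=seed)
    fit_s = fit_competition_model(dataset, system, "affinity_shift",
                                  n_boot=n_boot, seed=seed)
    n = dataset.conc.size
    df_extra = fit_s.n_parameters - fit_c.n_parameters
    df_resid = n - fit_s.n_parameters
    if df_resid <= 0:
        raise FitError("too few points for model comparison")

    # numerical tie: both models describe the data equally well to within
    # floating-point resolution, so no comparison is meaningful
    scale = max(1.0, float(np.max(np.abs(dataset.value))))
    tiny = n * (1e-7 * scale) ** 2
    if abs(fit_c.ssr - fit_s.ssr) <= tiny:
        f_stat, p_value = 0.0, 1.0
        verdict = "ambiguous"
    else:
        if fit_s.ssr <= 0:
            f_stat, p_value = math.inf, 0.0
        else:
            f_stat = ((fit_c.ssr - fit_s.ssr) / df_extra) / (fit_s.ssr / df_resid)
            f_stat = max(f_stat, 0.0)
            p_value = float(f_dist.sf(f_stat, df_extra, df_resid))
        aicc_c = _aicc(n, fit_c.n_parameters, fit_c.ssr)
        aicc_s = _aicc(n, fit_s.n_parameters, fit_s.ssr)
        if p_value < 0.05 and aicc_s < aicc_c:
            verdict = "affinity_shift"
        elif p_value >= 0.05 and aicc_c <= aicc_s:
            verdict = "competitive"
        else:
            verdict = "ambiguous"
        return ModelComparison(
            f_statistic=float(f_stat), p_value=float(p_value),
            aicc_competitive=aicc_c, aicc_shift=aicc_s,
            verdict=verdict, competitive=fit_c, shift=fit_s,
        )
    return ModelComparison(
        f_statistic=f_stat, p_value=p_value,
        aicc_competitive=_aicc(n, fit_c.n_parameters, fit_c.ssr),
        aicc_shift=_aicc(n, fit_s.n_parameters, fit_s.ssr),
        verdict=verdict, competitive=fit_c, shift=fit_s,
    )
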