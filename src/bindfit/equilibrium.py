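"""Mass-action equilibrium models for ligand-receptor binding.

This module contains the closed-form and numerically solved equilibrium
models used throughout the package:

* the ligand-depletion quadratic isotherm for a binary interaction at
  concentrations where free != total,
* the exact trigonometric (cubic-root) solution for a fully competitive
  three-species system, as used to fit bead-based displacement data,
* an allosteric ternary-complex model (ATCM) in which a modulator binds
  the ligand and rescales its receptor affinity by a cooperativity
  factor ``alpha``, producing a non-zero displacement plateau,
* the Hill saturation model with variable slope, and
* the Cheng-Prusoff IC50 -> Ki conversion.

All concentrations are expressed in nM throughout; the I/O layer is
responsible for any unit conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CompetitionSystem",
    "EquilibriumParameters",
    "AffinityShiftParameters",
    "dimer_to_sites",
    "bound_fraction_no_competitor",
    "wang_competition_curve",
    "affinity_shift_competition",
    "affinity_shift_plateau",
    "hill_binding",
    "cheng_prusoff_ki",
]

#: tolerance within which an out-of-range arccos argument is treated as
#: floating-point round-off and clamped; larger excursions indicate an
#: invalid parameter set and raise.
_ARCCOS_CLAMP_TOL = 1e-9


def _positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a finite positive number, got {value!r}")
    return value


def _nonnegative(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class CompetitionSystem:
    """Composition of a three-species competition experiment.

    Parameters
    ----------
    a_total
        Total concentration of ligand binding sites (nM).  For a
        disulfide-linked ligand dimer with two independent sites this is
        twice the protein concentration; see :func:`dimer_to_sites`.
    r_total
        Total receptor concentration (nM).
    ka
        Equilibrium dissociation constant of the receptor-ligand
        interaction (nM).
    kb
        Equilibrium dissociation constant of the competitor-ligand
        interaction (nM).
    """

    a_total: float
    r_total: float
    ka: float
    kb: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "a_total", _positive("a_total", self.a_total))
        object.__setattr__(self, "r_total", _nonnegative("r_total", self.r_total))
        object.__setattr__(self, "ka", _positive("ka", self.ka))
        object.__setattr__(self, "kb", _positive("kb", self.kb))


@dataclass(frozen=True)
class EquilibriumParameters:
    """Steady-state saturation parameters: B_max, K_D and Hill slope."""

    bmax: float
    kd: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bmax", _positive("bmax", self.bmax))
        object.__setattr__(self, "kd", _positive("kd", self.kd))
        object.__setattr__(self, "hill", _positive("hill", self.hill))


@dataclass(frozen=True)
class AffinityShiftParameters:
    """Allosteric ternary-complex model parameters.

    ``alpha`` multiplies the receptor-ligand K_D when the competitor is
    bound to the ligand; ``alpha > 1`` encodes negative cooperativity
    (competitor weakens receptor binding without abolishing it) and
    produces a non-zero displacement plateau at saturating competitor.
    """

    system: CompetitionSystem
    alpha: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", _positive("alpha", self.alpha))


def dimer_to_sites(dimer_conc: float) -> float:
    """Convert a dimer protein concentration to a binding-site concentration.

    A disulfide-linked ligand dimer presents two receptor-binding sites,
    so 32 nM dimer corresponds to 64 nM sites.  Sites are assumed
    independent; protomer-level cooperativity is not modelled.
    """
    return 2.0 * _nonnegative("dimer_conc", dimer_conc)


def bound_fraction_no_competitor(system: CompetitionSystem) -> float:
    """Fraction of ligand sites occupied at equilibrium, no competitor.

    Exact ligand-depletion solution of A + R <-> AR with totals ``a_total``
    and ``r_total`` and dissociation constant ``ka``::

        Y0 = (A + K_A + R - sqrt((A + K_A + R)^2 - 4*A*R)) / (2*A)

    The result lies in ``[0, min(1, R/A)]``.
    """
    a, r, ka = system.a_total, system.r_total, system.ka
    s = a + ka + r
    disc = s * s - 4.0 * a * r
    if disc < 0:  # mathematically impossible for valid inputs
        raise ArithmeticError(
            f"negative discriminant {disc} in ligand-depletion solution; "
            "internal consistency failure"
        )
    return (s - math.sqrt(disc)) / (2.0 * a)


def _free_receptor(system: CompetitionSystem, x: np.ndarray) -> np.ndarray:
    """Free receptor concentration in the competitive three-species system.

    Evaluates the trigonometric solution of the cubic that governs the
    system in which ligand sites (total A, constant K_A) and competitor
    (total X, constant K_B) both bind the receptor (total R), then
    polishes the root with vectorized Newton iteration on the
    mass-action balance.  The polish removes the catastrophic
    cancellation the closed form suffers when the free-receptor
    concentration is many orders of magnitude below the totals.
    """
    a, r, ka, kb = system.a_total, system.r_total, system.ka, system.kb
    h = ka + kb + a + x - r
    k = kb * (a - r) + ka * (x - r) + ka * kb
    l = -ka * kb * r

    q = h * h - 3.0 * k
    if np.any(q <= 0):
        raise ArithmeticError("non-positive cubic discriminant; invalid system")
    arg = (-2.0 * h**3 + 9.0 * h * k - 27.0 * l) / (2.0 * np.sqrt(q**3))
    excess = np.abs(arg) - 1.0
    if np.any(excess > _ARCCOS_CLAMP_TOL):
        raise ArithmeticError(
            "arccos argument outside [-1, 1] beyond numerical tolerance; "
            "invalid competition parameters"
        )
    t = np.arccos(np.clip(arg, -1.0, 1.0))
    # free receptor = (2*sqrt(h^2-3k)*cos(t/3) - h) / 3
    p = (2.0 * np.sqrt(q) * np.cos(t / 3.0) - h) / 3.0
    p = np.clip(p, 0.0, r)

    # Newton refinement of p*(1 + A/(K_A+p) + X/(K_B+p)) = R
    for _ in range(100):
        g = p * (1.0 + a / (ka + p) + x / (kb + p)) - r
        dg = 1.0 + a * ka / (ka + p) ** 2 + x * kb / (kb + p) ** 2
        step = g / dg
        p = np.clip(p - step, 0.0, r)
        if np.all(np.abs(step) <= 1e-15 * np.maximum(p, 1e-300) + 1e-300):
            break
    return p


def wang_competition_curve(system: CompetitionSystem, x) -> np.ndarray | float:
    """Fraction of ligand sites receptor-bound vs competitor concentration.

    Exact mass-action equilibrium of the fully competitive three-species
    system, via the classical trigonometric root of the governing cubic::

        h = K_A + K_B + A + X - R
        k = K_B*(A-R) + K_A*(X-R) + K_A*K_B
        l = -K_A*K_B*R
        t = arccos[(-2h^3 + 9hk - 27l) / (2*sqrt((h^2-3k)^3))]
        Y = (2*sqrt(h^2-3k)*cos(t/3) - h) / (3K_A + 2*sqrt(h^2-3k)*cos(t/3) - h)

    ``Y(0)`` equals :func:`bound_fraction_no_competitor`; Y is
    non-increasing in ``x`` and tends to 0 as ``x`` grows.

    Parameters
    ----------
    system
        Totals and dissociation constants (nM).
    x
        Competitor concentration(s), nM; scalar or array-like, >= 0.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x_arr)) or np.any(x_arr < 0):
        raise ValueError("competitor concentrations must be finite and >= 0")
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)

    if system.r_total == 0.0:
        y = np.zeros_like(x_arr)
    else:
        p = _free_receptor(system, x_arr)
        # Y = [AR]/A = p/(K_A + p), identical to the printed closed form
        y = p / (system.ka + p)
    return float(y[0]) if scalar else y


def hill_binding(c, params: EquilibriumParameters) -> np.ndarray | float:
    """Hill saturation curve: ``B_max * c^h / (c^h + K_D^h)``.

    ``K_D`` is the half-saturation concentration for any Hill slope
    ``h``, so ``hill_binding(K_D, params) == B_max / 2`` exactly.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be >= 0")
    scalar = c_arr.ndim == 0
    c_arr = np.atleast_1d(c_arr)
    with np.errstate(divide="ignore"):
        # work in ratio space: (c/K_D)^h, stable for extreme K_D
        ratio = (c_arr / params.kd) ** params.hill
    y = params.bmax * ratio / (1.0 + ratio)
    y = np.where(c_arr == 0.0, 0.0, y)
    return float(y[0]) if scalar else y


def cheng_prusoff_ki(ic50: float, ligand_conc: float, kd: float) -> float:
    """Convert an IC50 into a competitor K_i: ``Ki = IC50 / (1 + L/K_D)``.

    Valid when reactant depletion is negligible; under depletion the
    IC50 is inflated and the conversion overestimates K_i.
    """
    ic50 = _positive("ic50", ic50)
    ligand_conc = _nonnegative("ligand_conc", ligand_conc)
    kd = _positive("kd", kd)
    return ic50 / (1.0 + ligand_conc / kd)


def _ternary_free_species(
    system: CompetitionSystem, alpha: float, x: float, free_l: float
) -> tuple[float, float]:
    """Free receptor and free competitor given free ligand sites.

    With free ligand ``l`` fixed, conservation of receptor reduces to a
    quadratic in free receptor ``p`` (the competitor balance is then
    explicit), solved in closed form with the numerically stable root.
    """
    r, ka, kb = system.r_total, system.ka, system.kb
    d = alpha * ka * kb
    s = 1.0 + free_l / ka
    e = d * (1.0 + free_l / kb)
    if free_l == 0.0:
        p = r / s
        c = x / (1.0 + free_l / kb)
        return p, c
    # s*l*p^2 + (s*e + l*X - R*l)*p - R*e = 0
    qa = s * free_l
    qb = s * e + free_l * x - r * free_l
    qc = -r * e
    disc = qb * qb - 4.0 * qa * qc
    p = (2.0 * -qc) / (qb + math.sqrt(disc))  # stable positive root
    c = x / (1.0 + free_l / kb + free_l * p / d)
    return p, c


def affinity_shift_competition(
    params: AffinityShiftParameters, x, rtol: float = 1e-12
) -> np.ndarray | float:
    """Receptor-bound ligand fraction under the allosteric ternary model.

    Species: free ligand L, binary complexes LR (K_A) and LC (K_B), and
    ternary LRC, with the receptor binding competitor-bound ligand at
    ``alpha * K_A`` (detailed balance then fixes the competitor's
    affinity for LR at ``alpha * K_B``).  ``Y`` counts ligand sites in
    LR or LRC.

    ``Y(0)`` equals :func:`bound_fraction_no_competitor`; as
    ``x -> inf`` the curve plateaus at the depletion isotherm evaluated
    with ``K_A`` replaced by ``alpha * K_A``.  ``alpha == 1`` makes the
    competitor thermodynamically silent for receptor occupancy.

    Solved by bracketed root-finding (Brent) on free ligand, with the
    inner receptor/competitor balances solved in closed form.
    """
    system, alpha = params.system, params.alpha
    x_arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x_arr)) or np.any(x_arr < 0):
        raise ValueError("competitor concentrations must be finite and >= 0")
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)

    a, ka, kb = system.a_total, system.ka, system.kb
    d = alpha * ka * kb
    out = np.empty_like(x_arr)
    for i, xi in enumerate(x_arr):

        def balance(free_l: float, xi=xi) -> float:
            p, c = _ternary_free_species(system, alpha, xi, free_l)
            return free_l * (1.0 + p / ka + c / kb + p * c / d) - a

        if system.r_total == 0.0 and xi == 0.0:
            out[i] = 0.0
            continue
        try:
            free_l = brentq(balance, 0.0, a, rtol=rtol, maxiter=200)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover
            raise ArithmeticError(
                "ternary-complex equilibrium root-finding failed to converge"
            ) from exc
        p, c = _ternary_free_species(system, alpha, xi, free_l)
        out[i] = (free_l * p / ka) * (1.0 + c / (alpha * kb)) / a
    return float(out[0]) if scalar else out


def affinity_shift_plateau(params: AffinityShiftParameters) -> float:
    """Analytic ``x -> inf`` plateau of :func:`affinity_shift_competition`.

    At saturating competitor all ligand is competitor-bound, so receptor
    binding follows the depletion isotherm with ``K_A`` scaled by
    ``alpha``.
    """
    shifted = replace(params.system, ka=params.alpha * params.system.ka)
    return bound_fraction_no_competitor(shifted)
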