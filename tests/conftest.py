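"""Shared fixtures and independent brute-force oracles.

The oracles solve the mass-action systems directly (derivative-free
bisection or generic multidimensional root-finding on the free-species
equations) and never touch the closed-form/Newton code paths they are
used to check.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import brentq, root

from bindfit import CompetitionSystem

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def competitive_oracle(a: float, r: float, ka: float, kb: float, x: float) -> float:
    """Fraction of ligand sites receptor-bound in the competitive system.

    Solves the coupled mass-action equations for the free receptor, free
    ligand sites and free competitor by geometric bisection on the free
    receptor concentration (the receptor balance is strictly monotone).
    """
    if r == 0.0:
        return 0.0

    def balance(p: float) -> float:
        free_sites = a / (1.0 + p / ka)
        free_comp = x / (1.0 + p / kb)
        return p + p * free_sites / ka + p * free_comp / kb - r

    lo, hi = r * 1e-300, r
    if balance(hi) < 0:  # pragma: no cover - cannot happen for valid inputs
        return hi / (ka + hi)
    for _ in range(5000):
        mid = (lo * hi) ** 0.5
        if balance(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-14 * lo:
            break
    p = 0.5 * (lo + hi)
    return p / (ka + p)


def shared_ligand_oracle(a: float, r: float, ka: float, kb: float, x: float) -> float:
    """Receptor-bound fraction when receptor and competitor both bind the ligand.

    This is the alpha -> infinity boundary of the allosteric ternary
    model (no ternary complex).  Bisection on free ligand sites.
    """

    def balance(n: float) -> float:
        free_rec = r / (1.0 + n / ka)
        free_comp = x / (1.0 + n / kb)
        return n + n * free_rec / ka + n * free_comp / kb - a

    n = brentq(balance, a * 1e-300, a, rtol=1e-15, maxiter=1000)
    free_rec = r / (1.0 + n / ka)
    return n * free_rec / ka / a


def ternary_oracle(system: CompetitionSystem, alpha: float, x: float) -> float:
    """Allosteric ternary-complex equilibrium via generic root-finding.

    Solves for log free ligand/receptor/competitor with a Newton-Krylov
    style solver on all three conservation equations simultaneously;
    independent of the quadratic-elimination path in the package.
    """
    a, r, ka, kb = system.a_total, system.r_total, system.ka, system.kb
    d = alpha * ka * kb

    def equations(logv):
        l, p, c = np.exp(logv)
        lr = l * p / ka
        lc = l * c / kb
        lrc = l * p * c / d
        return [
            l + lr + lc + lrc - a,
            p + lr + lrc - r,
            c + lc + lrc - x,
        ]

    x0 = np.log([a * 0.1, max(r, 1e-12) * 0.1, max(x, 1e-12) * 0.1])
    sol = root(equations, x0, method="lm", options={"xtol": 1e-14, "ftol": 1e-14})
    assert sol.success, sol.message
    l, p, c = np.exp(sol.x)
    return (l * p / ka + l * p * c / d) / a


@pytest.fixture
def bead_system() -> CompetitionSystem:
    """The bead-assay design: 64 nM ligand sites, 50 nM receptor, K_A 10.4 nM."""
    return CompetitionSystem(a_total=64.0, r_total=50.0, ka=10.4, kb=200.0)


@pytest.fixture
def competitor_grid() -> np.ndarray:
    """Competitor grid of the displacement experiments, in nM (0-100 uM)."""
    return np.array([0.0, 100.0, 400.0, 1600.0, 25000.0, 100000.0])
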