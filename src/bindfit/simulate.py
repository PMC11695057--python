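"""Seeded synthetic-data generator for every input class the pipeline
consumes: multi-phase biosensor trace families with paired receptor-free
reference sensors, steady-state saturation series on 3.16-fold dilution
ladders, and bead-competition displacement data from either a fully
competitive or an affinity-shift equilibrium.

The generator emulates the statistical structure the analysis assumes:
1:1 Langmuir phases plus additive Gaussian noise and optional linear
baseline drift shared with the reference channel; homoscedastic Gaussian
replicate scatter for endpoint assays (a signal-proportional mode is
available).  Identical design + seed gives bitwise-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import (
    AffinityShiftParameters,
    CompetitionSystem,
    EquilibriumParameters,
    affinity_shift_competition,
    hill_binding,
    wang_competition_curve,
)
from .fitting import CompetitionDataset
from .kinetics import BLITrace, KineticParameters, association_model, dissociation_model

__all__ = [
    "ExperimentDesign",
    "generate_bli_traces",
    "generate_dose_response",
    "generate_competition",
]

#: 3.16-fold (half-log) analyte ladder used for kinetic trace families (nM)
DEFAULT_KINETIC_GRID = (3.2, 10.0, 32.0, 100.0)
#: 3.16-fold ladder spanning the low-nM affinities of the steady-state fits (nM)
DEFAULT_STEADY_STATE_GRID = (0.1, 0.32, 1.0, 3.2, 10.0, 32.0, 100.0)
#: competitor grid of the bead displacement assays: 0-100 uM, in nM
DEFAULT_COMPETITION_GRID = (0.0, 100.0, 400.0, 1600.0, 25000.0, 100000.0)


@dataclass
class ExperimentDesign:
    """Truth parameters, sampling design and noise model for one simulation.

    ``mode`` selects the experiment class; only the matching truth block
    is required.  ``noise_sd`` is an additive Gaussian SD in the assay's
    signal units (nm for traces, signal units for dose-response,
    fraction or percent for competition); ``proportional_noise`` makes
    the SD proportional to the noiseless signal instead.  ``seed`` is
    recorded in all outputs; ``None`` draws one from OS entropy.
    """

    mode: str  # bli_kinetic | steady_state | competition
    # --- truth ---
    kinetics: KineticParameters | None = None
    bmax: float = 0.8  # trace amplitude, nm
    equilibrium: EquilibriumParameters | None = None
    system: CompetitionSystem | None = None
    competition_model: str = "competitive"
    alpha: float = 1.0
    # --- sampling design ---
    concentrations: tuple = ()
    n_replicates: int = 3
    sampling_hz: float = 5.0
    baseline_s: float = 60.0
    association_s: float = 300.0
    dissociation_s: float = 600.0
    # --- noise ---
    noise_sd: float = 0.0
    proportional_noise: bool = False
    drift_rate: float = 0.0  # nm/s, shared by trace and reference
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("bli_kinetic", "steady_state", "competition"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.concentrations:
            self.concentrations = {
                "bli_kinetic": DEFAULT_KINETIC_GRID,
                "steady_state": DEFAULT_STEADY_STATE_GRID,
                "competition": DEFAULT_COMPETITION_GRID,
            }[self.mode]
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0 or np.any(conc < 0):
            raise ValueError("concentration grid must be non-empty and >= 0")
        self.concentrations = tuple(float(c) for c in conc)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.seed is None:
            self.seed = int(np.random.SeedSequence().entropy % (2**31))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_json(self, path: str | Path) -> None:
        """Write a sidecar JSON with the full design (truth + seed)."""
        doc = {
            "mode": self.mode,
            "seed": self.seed,
            "concentrations_nM": list(self.concentrations),
            "n_replicates": self.n_replicates,
            "noise_sd": self.noise_sd,
            "proportional_noise": self.proportional_noise,
            "drift_rate_nm_per_s": self.drift_rate,
        }
        if self.kinetics is not None:
            doc["kinetics"] = {"kon_per_nM_per_s": self.kinetics.kon,
                               "koff_per_s": self.kinetics.koff,
                               "bmax_nm": self.bmax}
            doc["phases_s"] = {"baseline": self.baseline_s,
                               "association": self.association_s,
                               "dissociation": self.dissociation_s}
            doc["sampling_hz"] = self.sampling_hz
        if self.equilibrium is not None:
            doc["equilibrium"] = asdict(self.equilibrium)
        if self.system is not None:
            doc["system"] = asdict(self.system)
            doc["competition_model"] = self.competition_model
            doc["alpha"] = self.alpha
        Path(path).write_text(json.dumps(doc, indent=2))


def _noise(rng: np.random.Generator, design: ExperimentDesign, truth: np.ndarray) -> np.ndarray:
    if design.noise_sd == 0.0:
        return np.zeros_like(truth)
    sd = design.noise_sd * np.abs(truth) if design.proportional_noise else design.noise_sd
    return rng.normal(0.0, 1.0, size=truth.shape) * sd


def generate_bli_traces(design: ExperimentDesign) -> tuple[list[BLITrace], list[BLITrace]]:
    """Simulate a biosensor trace family plus matched reference sensors.

    One trace per concentration in the design grid, with baseline,
    association and dissociation phases generated from the 1:1 Langmuir
    models, plus linear drift and additive noise.  The paired
    receptor-free reference traces carry the same drift statistics and
    noise but no binding signal.  Replicate families are distinguished
    by sensor id.
    """
    if design.mode != "bli_kinetic":
        raise ValueError("design.mode must be 'bli_kinetic'")
    if design.kinetics is None:
        raise ValueError("design.kinetics (truth rate constants) is required")
    rng = design.rng()
    kin, bmax = design.kinetics, design.bmax
    dt = 1.0 / design.sampling_hz
    t_total = design.baseline_s + design.association_s + design.dissociation_s
    time = np.arange(0.0, t_total + 0.5 * dt, dt)
    t_a0 = design.baseline_s
    t_d0 = design.baseline_s + design.association_s
    phase = np.empty(time.shape, dtype=object)
    phase[time < t_a0] = "baseline"
    phase[(time >= t_a0) & (time < t_d0)] = "association"
    phase[time >= t_d0] = "dissociation"

    traces: list[BLITrace] = []
    references: list[BLITrace] = []
    for rep in range(design.n_replicates):
        for conc in design.concentrations:
            clean = np.zeros_like(time)
            am = phase == "association"
            dm = phase == "dissociation"
            clean[am] = association_model(time[am] - t_a0, conc, kin, bmax)
            r_bound = float(association_model(t_d0 - t_a0, conc, kin, bmax))
            clean[dm] = dissociation_model(time[dm] - t_d0, r_bound, kin.koff)
            drift = design.drift_rate * time
            sig = clean + drift + _noise(rng, design, clean)
            ref = drift + _noise(rng, design, np.zeros_like(time))
            sid = f"rep{rep}_c{conc:g}"
            traces.append(BLITrace(time, sig, phase.copy(), conc,
                                   sensor_id=sid, is_reference=False))
            references.append(BLITrace(time, ref, phase.copy(), conc,
                                       sensor_id=f"{sid}_ref", is_reference=True))
    return traces, references


def generate_dose_response(design: ExperimentDesign) -> pd.DataFrame:
    """Simulate steady-state plateau signals on the design's ladder.

    Returns a long-format DataFrame with columns ``conc`` (nM),
    ``replicate`` and ``signal``: Hill-model values plus noise,
    ``n_replicates`` per concentration.
    """
    if design.mode != "steady_state":
        raise ValueError("design.mode must be 'steady_state'")
    if design.equilibrium is None:
        raise ValueError("design.equilibrium (truth Hill parameters) is required")
    rng = design.rng()
    rows = []
    for rep in range(design.n_replicates):
        conc = np.asarray(design.concentrations)
        truth = np.atleast_1d(hill_binding(conc, design.equilibrium))
        sig = truth + _noise(rng, design, truth)
        for c, s in zip(conc, sig):
            rows.append((c, rep, s))
    return pd.DataFrame(rows, columns=["conc", "replicate", "signal"])


def generate_competition(design: ExperimentDesign) -> CompetitionDataset:
    """Simulate replicate bead-competition fraction-bound measurements.

    Noiseless values come from the chosen equilibrium (fully competitive
    closed form, or the allosteric affinity-shift model with the
    design's ``alpha``); Gaussian noise is added per replicate point.
    """
    if design.mode != "competition":
        raise ValueError("design.mode must be 'competition'")
    if design.system is None:
        raise ValueError("design.system (truth competition system) is required")
    rng = design.rng()
    x = np.asarray(design.concentrations)
    if design.competition_model == "competitive":
        truth = np.atleast_1d(wang_competition_curve(design.system, x))
    elif design.competition_model == "affinity_shift":
        params = AffinityShiftParameters(design.system, design.alpha)
        truth = np.atleast_1d(affinity_shift_competition(params, x))
    else:
        raise ValueError(f"unknown competition model {design.competition_model!r}")

    concs, values, reps = [], [], []
    for rep in range(design.n_replicates):
        noisy = truth + _noise(rng, design, truth)
        concs.append(x)
        values.append(noisy)
        reps.append(np.full(x.shape, rep))
    return CompetitionDataset(
        conc=np.concatenate(concs),
        value=np.concatenate(values),
        replicate=np.concatenate(reps),
        normalization="fraction_of_total",
    )
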