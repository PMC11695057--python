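"""File formats and the structured results document.

All tables are strict comma-separated UTF-8 text with "." decimals.
Concentrations are stored in nM and biosensor signal in nm interference
shift; the unit is part of the column name to prevent uM/nM confusion.

Trace tables are long format, one row per time point, with columns
``sensor_id, phase, time_s, signal_nm, analyte_nM, is_reference``.
Dose-response tables carry ``conc_nM, replicate, signal_nm`` and
competition tables ``competitor_nM, replicate, value, normalization``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import __version__
from .fitting import CompetitionDataset
from .kinetics import PHASES, BLITrace

__all__ = [
    "TRACE_COLUMNS",
    "TraceTableError",
    "read_trace_table",
    "write_trace_table",
    "read_dose_response",
    "write_dose_response",
    "read_competition",
    "write_competition",
    "ResultsDocument",
]

TRACE_COLUMNS = ("sensor_id", "phase", "time_s", "signal_nm", "analyte_nM", "is_reference")


class TraceTableError(ValueError):
    """A trace table violated the schema; the message names the offender."""


def write_trace_table(traces: Sequence[BLITrace], path: str | Path) -> None:
    """Write traces to the long-format trace CSV schema."""
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "sensor_id": tr.sensor_id,
            "phase": [str(p) for p in tr.phase],
            "time_s": tr.time,
            "signal_nm": tr.signal,
            "analyte_nM": tr.analyte_conc,
            "is_reference": tr.is_reference,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_table(path: str | Path) -> list[BLITrace]:
    """Read and validate a long-format trace CSV into typed traces.

    Raises :class:`TraceTableError` naming the offending sensor or row
    for missing columns, unknown phase labels, or non-monotone time.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceTableError(f"{path.name}: missing required columns {missing}")
    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        # +2: header line and 0/1-based offset
        rows = (df.index[bad_phase] + 2).tolist()[:5]
        raise TraceTableError(
            f"{path.name}: unknown phase labels at rows {rows} "
            f"(allowed: {list(PHASES)})"
        )
    traces = []
    for sensor_id, sub in df.groupby("sensor_id", sort=False):
        if sub["time_s"].diff().dropna().le(0).any():
            raise TraceTableError(
                f"{path.name}: time not strictly increasing for sensor {sensor_id!r}"
            )
        try:
            traces.append(BLITrace(
                time=sub["time_s"].to_numpy(float),
                signal=sub["signal_nm"].to_numpy(float),
                phase=sub["phase"].to_numpy(object),
                analyte_conc=float(sub["analyte_nM"].iloc[0]),
                sensor_id=str(sensor_id),
                is_reference=bool(sub["is_reference"].iloc[0]),
            ))
        except ValueError as exc:
            raise TraceTableError(f"{path.name}: {exc}") from exc
    return traces


def write_dose_response(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(columns={"conc": "conc_nM", "signal": "signal_nm"})
    out[["conc_nM", "replicate", "signal_nm"]].to_csv(path, index=False)


def read_dose_response(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("conc_nM", "replicate", "signal_nm") if c not in df.columns]
    if missing:
        raise TraceTableError(f"{Path(path).name}: missing required columns {missing}")
    return df.rename(columns={"conc_nM": "conc", "signal_nm": "signal"})


def write_competition(dataset: CompetitionDataset, path: str | Path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


def read_competition(path: str | Path) -> CompetitionDataset:
    df = pd.read_csv(path)
    missing = [c for c in ("competitor_nM", "value") if c not in df.columns]
    if missing:
        raise TraceTableError(f"{Path(path).name}: missing required columns {missing}")
    return CompetitionDataset.from_dataframe(df)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class ResultsDocument:
    """Structured, reproducible record of one analysis run.

    Every estimate carries units in its key name; every stochastic
    result records the seed it was produced with; filters record both
    the threshold and the number of exclusions.
    """

    analysis: str
    parameters: dict[str, Any]
    inputs: dict[str, str] = field(default_factory=dict)
    filters: dict[str, Any] = field(default_factory=dict)
    comparison: dict[str, Any] | None = None
    seed: int | None = None
    version: str = __version__

    @classmethod
    def with_inputs(cls, analysis: str, parameters: dict[str, Any],
                    input_paths: Sequence[str | Path], **kwargs) -> "ResultsDocument":
        digests = {str(p): _sha256(p) for p in input_paths}
        return cls(analysis=analysis, parameters=parameters, inputs=digests, **kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_jsonify))

    @classmethod
    def from_json(cls, path: str | Path) -> "ResultsDocument":
        return cls(**json.loads(Path(path).read_text()))


def _jsonify(obj):
    try:
        import numpy as np
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
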