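"""CSV schemas and fit-report serialisation.

Three long-format tables, all UTF-8, '.' decimal point, no thousands
separators, concentrations in molar and times in minutes:

* trace table: ``well, time_min, tracer_conc_M, competitor_conc_M,
  signal, is_nsb`` — one row per read, one kinetic trace per well;
* dose-response table: ``well, conc_M, raw_signal, reference`` where
  reference is ``none``, ``ref_max`` or ``ref_min`` (reference wells
  define the normalisation anchors);
* stability table: ``time_min, pct_remaining, matrix,
  protein_mg_per_ul``.

Values round-trip as decimal strings with 10 significant digits.  Schema
violations are reported with the offending column (and row where known).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import KineticTrace
from .pk import DepletionSeries

__all__ = [
    "TRACE_COLUMNS",
    "DOSE_RESPONSE_COLUMNS",
    "STABILITY_COLUMNS",
    "SchemaError",
    "write_traces",
    "read_traces",
    "write_dose_response",
    "read_dose_response",
    "write_stability",
    "read_stability",
    "write_report",
    "read_report",
    "subtract_nsb",
]

TRACE_COLUMNS = ["well", "time_min", "tracer_conc_M", "competitor_conc_M", "signal", "is_nsb"]
DOSE_RESPONSE_COLUMNS = ["well", "conc_M", "raw_signal", "reference"]
STABILITY_COLUMNS = ["time_min", "pct_remaining", "matrix", "protein_mg_per_ul"]

_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def write_traces(traces: Sequence[KineticTrace], path) -> None:
    """Write kinetic traces to a long-format trace table CSV."""
    rows = []
    for i, tr in enumerate(traces):
        well = tr.meta.get("well", f"W{i:03d}")
        is_nsb = int(bool(tr.meta.get("is_nsb", False)))
        for t, y in zip(tr.times, tr.signal):
            rows.append((well, t, tr.L, tr.I, y, is_nsb))
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_traces(path, compute_ratio: bool = False) -> list[KineticTrace]:
    """Read a trace table CSV back into KineticTrace objects (one per well).

    With ``compute_ratio`` the table carries raw emissions in ``em_610``
    and ``em_450`` columns instead of ``signal``; the BRET ratio
    (610 nm acceptor over 450 nm donor emission) is computed on read.
    """
    df = pd.read_csv(path)
    if compute_ratio:
        _check_columns(df, [c for c in TRACE_COLUMNS if c != "signal"] + ["em_610", "em_450"], path)
        if np.any(df["em_450"] == 0):
            raise SchemaError(f"{path}: em_450 contains zeros; cannot form BRET ratio")
        df = df.assign(signal=df["em_610"] / df["em_450"])
    _check_columns(df, TRACE_COLUMNS, path)
    for col in ("time_min", "tracer_conc_M", "competitor_conc_M", "signal"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise SchemaError(f"{path}: column {col} is not numeric (first bad row {row})")
    traces = []
    for well, g in df.groupby("well", sort=False):
        g = g.sort_values("time_min")
        L = g["tracer_conc_M"].iloc[0]
        I = g["competitor_conc_M"].iloc[0]
        if g["tracer_conc_M"].nunique() > 1 or g["competitor_conc_M"].nunique() > 1:
            raise SchemaError(f"{path}: well {well} mixes concentrations")
        traces.append(
            KineticTrace(
                times=g["time_min"].to_numpy(),
                signal=g["signal"].to_numpy(),
                L=float(L),
                I=float(I),
                meta={"well": str(well), "is_nsb": bool(g["is_nsb"].iloc[0])},
            )
        )
    return traces


def subtract_nsb(traces: Sequence[KineticTrace]) -> tuple[list[KineticTrace], float]:
    """Subtract the nonspecific-binding floor defined by the plate's NSB wells.

    The NSB level is the mean signal of all wells flagged ``is_nsb``;
    it is subtracted from every non-NSB trace, which are returned as
    specific-binding traces.  Warns (and subtracts nothing) when the
    plate has no NSB well.
    """
    nsb_wells = [tr for tr in traces if tr.meta.get("is_nsb")]
    rest = [tr for tr in traces if not tr.meta.get("is_nsb")]
    if not nsb_wells:
        warnings.warn("plate has no NSB well; signals used as-is", stacklevel=2)
        return list(rest), 0.0
    level = float(np.mean(np.concatenate([tr.signal for tr in nsb_wells])))
    out = [
        KineticTrace(
            times=tr.times, signal=tr.signal - level, L=tr.L, I=tr.I, meta=dict(tr.meta)
        )
        for tr in rest
    ]
    return out, level


def require_control_well(traces: Sequence[KineticTrace]) -> None:
    """Competition fitting requires an I=0 control; refuse otherwise."""
    if not any(tr.I == 0 for tr in traces):
        warnings.warn("plate has no I=0 control well", stacklevel=2)
        raise SchemaError("competition fit refused: no I=0 control well on plate")


def write_dose_response(df: pd.DataFrame, path) -> None:
    _check_columns(df, DOSE_RESPONSE_COLUMNS, path)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_dose_response(path) -> pd.DataFrame:
    """Read a dose-response table; checks reference wells are present."""
    df = pd.read_csv(path)
    _check_columns(df, DOSE_RESPONSE_COLUMNS, path)
    refs = set(df["reference"].astype(str))
    bad = refs - {"none", "ref_max", "ref_min"}
    if bad:
        raise SchemaError(f"{path}: invalid reference value(s): {sorted(bad)}")
    if "ref_max" not in refs or "ref_min" not in refs:
        raise SchemaError(f"{path}: plate needs at least one ref_max and one ref_min row")
    return df


def write_stability(series: DepletionSeries, path) -> None:
    df = pd.DataFrame(
        {
            "time_min": series.times,
            "pct_remaining": series.pct_remaining,
            "matrix": series.matrix,
            "protein_mg_per_ul": series.protein_conc if series.protein_conc is not None else np.nan,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_stability(path) -> DepletionSeries:
    df = pd.read_csv(path)
    _check_columns(df, STABILITY_COLUMNS, path)
    protein = df["protein_mg_per_ul"].iloc[0]
    return DepletionSeries(
        times=df["time_min"].to_numpy(),
        pct_remaining=df["pct_remaining"].to_numpy(),
        matrix=str(df["matrix"].iloc[0]),
        protein_conc=None if pd.isna(protein) else float(protein),
    )


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_report(record: dict, path) -> None:
    """Write a JSON fit report (NaN -> null, inf -> 'inf')."""
    Path(path).write_text(json.dumps(_to_jsonable(record), indent=2) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
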