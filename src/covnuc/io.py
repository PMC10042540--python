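"""CSV/JSON/YAML readers and writers and the analysis configuration schema.

All CSV dialects are UTF-8, comma-separated, dot-decimal, with strict
header-name matching; schema violations are reported with row/column
coordinates. The JSON report schema is versioned and serializes numbers at
full precision alongside a 2–3 significant-figure "printed" rendering for
human comparison against published tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from covnuc.equilibrium import CompetitionAssay
from covnuc.hydrolysis import HydrolysisTimeCourse
from covnuc.kinetics import ProgressCurve
from covnuc.labelling import LabellingTimeCourse

__all__ = [
    "REPORT_SCHEMA_VERSION",
    "CsvSchemaError",
    "AnalysisConfig",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_competition_csv",
    "write_competition_csv",
    "read_progress_curve",
    "read_labelling_course",
    "read_hydrolysis_course",
    "printed",
    "write_report",
    "load_config",
]

REPORT_SCHEMA_VERSION = "1"

COMPETITION_COLUMNS = (
    "analogue_id",
    "analogue_total_uM",
    "t0_pct_gdp",
    "t0_pct_analogue",
    "eq_pct_gdp",
    "eq_pct_analogue",
)


class CsvSchemaError(ValueError):
    """CSV did not match the expected schema; message carries coordinates."""


def read_timeseries_csv(path: str | Path, expected_columns: Sequence[str]) -> pd.DataFrame:
    """Read a CSV with exactly the expected columns (order-insensitive).

    Raises :class:`CsvSchemaError` naming missing/unexpected columns or the
    first non-numeric cell with its row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise CsvSchemaError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in expected_columns if c not in df.columns]
    extra = [c for c in df.columns if c not in expected_columns]
    if missing or extra:
        raise CsvSchemaError(
            f"{path}: column mismatch (missing {missing or 'none'}, "
            f"unexpected {extra or 'none'}; expected {list(expected_columns)})"
        )
    numeric_cols = [c for c in expected_columns if c != "analogue_id"]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CsvSchemaError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at row {row + 2}, "
                f"column {col!r}"
            )
        df[col] = coerced
    return df[list(expected_columns)]


def write_timeseries_csv(path: str | Path, data: dict[str, Sequence[Any]]) -> None:
    pd.DataFrame(data).to_csv(path, index=False)


def read_progress_curve(path: str | Path) -> ProgressCurve:
    df = read_timeseries_csv(path, ("time_s", "signal_au"))
    return ProgressCurve(times=df["time_s"].to_numpy(), signal=df["signal_au"].to_numpy())


def read_labelling_course(path: str | Path) -> LabellingTimeCourse:
    df = read_timeseries_csv(path, ("time_h", "fraction_modified"))
    return LabellingTimeCourse(
        times=df["time_h"].to_numpy(), fraction_modified=df["fraction_modified"].to_numpy()
    )


def read_hydrolysis_course(path: str | Path) -> HydrolysisTimeCourse:
    df = read_timeseries_csv(path, ("time_min", "fraction_gtp"))
    return HydrolysisTimeCourse(
        times=df["time_min"].to_numpy(), fraction_gtp=df["fraction_gtp"].to_numpy()
    )


def read_competition_csv(
    path: str | Path, reference_kd_gdp: float = 2.5, percent_unit: str = "percent"
) -> list[CompetitionAssay]:
    """Read competition assays; ``percent_unit`` is 'percent' (0–100) or
    'fraction' (0–1)."""
    if percent_unit not in ("percent", "fraction"):
        raise ValueError("percent_unit must be 'percent' or 'fraction'")
    scale = 1.0 if percent_unit == "percent" else 100.0
    df = read_timeseries_csv(path, COMPETITION_COLUMNS)
    assays = []
    for _, row in df.iterrows():
        assays.append(
            CompetitionAssay(
                analogue_id=str(row["analogue_id"]),
                analogue_total=float(row["analogue_total_uM"]),
                t0_percent_gdp=scale * float(row["t0_pct_gdp"]),
                t0_percent_analogue=scale * float(row["t0_pct_analogue"]),
                eq_percent_gdp=scale * float(row["eq_pct_gdp"]),
                eq_percent_analogue=scale * float(row["eq_pct_analogue"]),
                reference_kd_gdp=reference_kd_gdp,
            )
        )
    return assays


def write_competition_csv(path: str | Path, assays: Sequence[CompetitionAssay]) -> None:
    rows = {
        "analogue_id": [a.analogue_id for a in assays],
        "analogue_total_uM": [a.analogue_total for a in assays],
        "t0_pct_gdp": [a.t0_percent_gdp for a in assays],
        "t0_pct_analogue": [a.t0_percent_analogue for a in assays],
        "eq_pct_gdp": [a.eq_percent_gdp for a in assays],
        "eq_pct_analogue": [a.eq_percent_analogue for a in assays],
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def printed(value: float, sig: int = 2) -> str:
    """Render a number at 2–3 significant figures, the convention of the
    published tables."""
    if value == 0 or not np.isfinite(value):
        return str(value)
    return float(f"{value:.{sig}g}").__repr__()


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a report dict to JSON (schema-versioned, full precision)."""
    out = {"schema_version": REPORT_SCHEMA_VERSION, **report}

    def default(o: Any):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"unserializable object of type {type(o)}")

    Path(path).write_text(json.dumps(out, indent=2, default=default) + "\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "mode",
    "seed",
    "reference_kd_gdp_pM",
    "percent_unit",
    "ode_rtol",
    "ode_atol",
    "dead_time_s",
    "stages",
    "inputs",
    "outputs",
}


@dataclass
class AnalysisConfig:
    """Validated analysis configuration.

    ``mode`` selects the equilibrium estimator ('paper' tight-binding
    arithmetic vs 'exact' mass-action inversion); ``stages`` lists pipeline
    stages to run; ``inputs``/``outputs`` map stage names to file paths.
    """

    mode: str = "paper"
    seed: int = 0
    reference_kd_gdp_pM: float = 2.5
    percent_unit: str = "percent"
    ode_rtol: float = 1e-8
    ode_atol: float = 1e-12
    dead_time_s: float = 0.0
    stages: list[str] = field(default_factory=list)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "exact"):
            raise ValueError(f"mode must be 'paper' or 'exact', got {self.mode!r}")
        if self.percent_unit not in ("percent", "fraction"):
            raise ValueError("percent_unit must be 'percent' or 'fraction'")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a YAML config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**raw)
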