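"""Validated CSV readers/writers and run manifests.

All files are comma-separated UTF-8 with a mandatory header and ``.``
decimal; Unicode minus signs (as printed in publication tables) are
normalized to ASCII hyphen-minus on ingestion.  Floats round-trip to at
least 10 significant digits; counts round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import StressSeries
from .engine import SimulationTrace
from .panel import MarkerPanel, MarkerSummary

__all__ = [
    "read_panel",
    "write_panel",
    "write_summary",
    "read_trace",
    "write_trace",
    "read_stress",
    "write_stress",
    "RunManifest",
]

_MINUS_VARIANTS = str.maketrans({"−": "-", "–": "-"})

SUMMARY_COLUMNS = [
    "marker",
    "n",
    "mean_pre",
    "sd_pre",
    "mean_post",
    "sd_post",
    "mean_change",
    "sd_change",
    "p",
    "q",
    "d_av",
    "magnitude",
    "test_used",
]


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, encoding="utf-8")
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return frame


def _to_numeric(frame: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        series = frame[col]
        if series.dtype == object:
            series = series.astype(str).str.translate(_MINUS_VARIANTS)
        converted = pd.to_numeric(series, errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            rows = (frame.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric value in {col!r} at line(s) {rows}")
        frame[col] = converted
    return frame


def read_panel(path: str | Path) -> MarkerPanel:
    """Read a long-format paired panel (athlete_id, marker, pre, post)."""
    frame = _read_csv(path, {"athlete_id", "marker", "pre", "post"})
    frame = _to_numeric(frame, ["pre", "post"], path)
    return MarkerPanel.from_long(frame)


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    panel.to_long().to_csv(path, index=False, float_format="%.12g")


def write_summary(summaries: list[MarkerSummary], path: str | Path) -> None:
    """Write per-marker summaries in the published-table column order."""
    frame = pd.DataFrame([s.as_dict() for s in summaries])
    frame[SUMMARY_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def write_trace(trace: SimulationTrace, path: str | Path) -> None:
    trace.frame.to_csv(path, index=False, float_format="%.12g")


def read_trace(path: str | Path) -> SimulationTrace:
    frame = _read_csv(path, {"tick", "cd4", "cd8", "pathogen", "total_immune"})
    return SimulationTrace(frame)


def write_stress(series: StressSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_stress(path: str | Path, ticks_per_day: int = 10) -> StressSeries:
    frame = _read_csv(path, {"tick", "lactate_injection", "glucose_drain"})
    frame = _to_numeric(frame, ["lactate_injection", "glucose_drain"], path)
    return StressSeries.from_frame(frame, ticks_per_day)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one CLI run: command, resolved config, seeds, file digests."""

    command: str
    config: dict
    seed: int | None
    version: str
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""

    @classmethod
    def create(
        cls,
        command: str,
        config: dict,
        seed: int | None,
        inputs: dict[str, str] | None = None,
    ) -> "RunManifest":
        from . import __version__

        manifest = cls(
            command=command,
            config=config,
            seed=seed,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )
        for name, p in (inputs or {}).items():
            manifest.inputs[name] = {"path": str(p), "sha256_16": _digest(Path(p))}
        return manifest

    def add_output(self, name: str, path: str | Path) -> None:
        self.outputs[name] = {"path": str(path), "sha256_16": _digest(Path(path))}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2), encoding="utf-8")
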