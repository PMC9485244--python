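"""Text-format plumbing: traces, step-call tables, histograms, fit reports.

Everything is delimited text or JSON, diffable, and round-trips bit-exactly.
Trace files are long-format TSV (spot_id, frame, photons) with a header row;
step histograms are TSV with a ``# key: value`` metadata header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult, MonteCarloEnvelope, StepHistogram
from .step_counting import PhotobleachTrace

__all__ = [
    "read_traces",
    "write_traces",
    "read_step_calls",
    "write_step_calls",
    "read_step_histogram",
    "write_step_histogram",
    "write_fit_report",
    "read_fit_report",
]


class SchemaError(ValueError):
    """Input file does not match the expected column/header layout."""


def read_traces(path: str | Path, frame_interval: float = 0.1) -> list[PhotobleachTrace]:
    """Read long-format trace TSV into PhotobleachTrace objects.

    Expects columns (spot_id, frame, photons); traces are returned in file
    order, frames sorted within each spot.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"spot_id", "frame", "photons"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"{path}: trace file needs columns {sorted(required)}, got {list(df.columns)}"
        )
    traces = []
    for spot_id, grp in df.groupby("spot_id", sort=False):
        grp = grp.sort_values("frame")
        traces.append(
            PhotobleachTrace(
                intensities=grp["photons"].to_numpy(dtype=float),
                frame_interval=frame_interval,
                spot_id=str(spot_id),
            )
        )
    return traces


def write_traces(traces, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("spot_id\tframe\tphotons\n")
        for trace in traces:
            for f, v in enumerate(trace.intensities):
                fh.write(f"{trace.spot_id}\t{f}\t{v:.6f}\n")


def write_step_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_step_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"spot_id", "n_steps", "censored", "quality"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: step-call file needs columns {sorted(required)}")
    df["n_steps"] = df["n_steps"].astype("Int64")
    return df


def write_step_histogram(hist: StepHistogram, path: str | Path) -> None:
    """TSV with key-value header: censoring and contaminant metadata first."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_censored: {hist.n_censored}\n")
        fh.write(f"# contaminant_estimate: {hist.contaminant_estimate:.6f}\n")
        fh.write(f"# corrected: {str(hist.corrected).lower()}\n")
        fh.write("step_bin\tcount\n")
        for s, c in enumerate(hist.counts, start=1):
            fh.write(f"{s}\t{c:.6f}\n")


def read_step_histogram(path: str | Path) -> StepHistogram:
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    with path.open() as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line.lstrip("# ").split(":", 1)
                except ValueError as exc:
                    raise SchemaError(f"{path}: bad metadata line {line!r}") from exc
                meta[key.strip()] = value.strip()
            elif not header_seen:
                if line.split("\t") != ["step_bin", "count"]:
                    raise SchemaError(
                        f"{path}: expected 'step_bin\\tcount' header, got {line!r}"
                    )
                header_seen = True
            else:
                parts = line.split("\t")
                if len(parts) != 2:
                    raise SchemaError(f"{path}: bad data line {line!r}")
                rows.append((int(parts[0]), float(parts[1])))
    if not rows:
        raise SchemaError(f"{path}: no histogram rows")
    rows.sort()
    bins = [r[0] for r in rows]
    if bins != list(range(1, len(bins) + 1)):
        raise SchemaError(f"{path}: step bins must be contiguous from 1, got {bins}")
    return StepHistogram(
        counts=np.array([r[1] for r in rows]),
        n_censored=int(meta.get("n_censored", 0)),
        contaminant_estimate=float(meta.get("contaminant_estimate", 0.0)),
        corrected=meta.get("corrected", "false").lower() == "true",
    )


def write_fit_report(
    result: FitResult,
    path: str | Path,
    envelope: MonteCarloEnvelope | None = None,
    seed: int | None = None,
    extra: dict | None = None,
) -> None:
    """Machine-readable fit report (JSON): per-m table, selection, settings."""
    doc = {
        "selected_m": result.selected_m,
        "lam": result.lam,
        "fde": result.fde,
        "rmsd": result.rmsd,
        "fit_bins": list(result.fit_bins),
        "convention": result.convention,
        "seed": seed,
        "per_m_table": result.per_m_table.to_dict(orient="records"),
    }
    if envelope is not None:
        doc["monte_carlo"] = {
            "per_bin_sd": [float(x) for x in envelope.per_bin_sd],
            "n_trials": envelope.n_trials,
            "seed": envelope.seed,
        }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_fit_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
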