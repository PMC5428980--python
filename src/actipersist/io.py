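"""CSV readers/writers, inclusion filtering, and run configuration.

All tabular I/O is plain headered CSV.  Two minute-table schemas are
accepted: a tri-axial one with per-minute peak counts for the transverse,
forward and longitudinal axes (summed on read), and a pre-summed one with
a single counts column.  Column names are remappable so reasonable
variants of either schema can be read without editing files.

Inclusion follows the reference protocol for armband recordings: a
participant is analysed only if at least ``min_length`` minutes were
recorded (default 7000), and every included signal is cropped to exactly
that length so all profiles are comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import (
    FAILURE,
    INDETERMINATE,
    SUCCESS,
    GroupSummary,
    PairComparison,
    ParticipantRecord,
    assign_outcome_label,
)
from .persistence import PersistenceDiagram
from .signal import Signal

__all__ = [
    "ValidationError",
    "ConfigError",
    "RunConfig",
    "AXIS_COLUMNS",
    "read_minute_csv",
    "combine_axes",
    "apply_inclusion",
    "read_labels",
    "write_minute_csv",
    "write_labels_csv",
    "write_diagram_csv",
    "write_distance_csv",
    "write_pairs_csv",
    "write_group_summary_csv",
    "write_run_manifest",
]

logger = logging.getLogger(__name__)

AXIS_COLUMNS = ("transverse", "forward", "longitudinal")
LABEL_TOKENS = (SUCCESS, FAILURE, INDETERMINATE)


class ValidationError(Exception):
    """Malformed or inconsistent input data."""


class ConfigError(Exception):
    """Invalid configuration value."""


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration with the reference defaults."""

    window_length: int = 20
    metric: str = "modified_hausdorff"
    q: float = 1.0
    empty_diagram_policy: str = "diagonal"
    ttest_variant: str = "student"
    min_length: int = 7000
    blind_trials: int = 100
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "RunConfig":
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - valid
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        try:
            return cls(**mapping)  # type: ignore[arg-type]
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc


def _require_columns(df: pd.DataFrame, needed: Sequence[str], path: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def read_minute_csv(
    path: str,
    column_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Read and validate a minute-level activity table.

    Expected columns (after applying ``column_map`` renames, which map
    file column names to canonical ones): ``participant_id``,
    ``minute_index`` and either ``counts`` or the three axis columns
    ``transverse``, ``forward``, ``longitudinal``.  Validates numeric,
    nonnegative counts, and per-participant minute indices that start at
    1 and ascend contiguously.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise ValidationError(f"input file not found: {path}") from None
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"{path}: could not parse CSV ({exc})") from exc
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    _require_columns(df, ["participant_id", "minute_index"], path)
    has_axes = all(c in df.columns for c in AXIS_COLUMNS)
    if "counts" not in df.columns and not has_axes:
        raise ValidationError(
            f"{path}: need either a 'counts' column or the axis columns "
            f"{list(AXIS_COLUMNS)}"
        )
    count_cols = list(AXIS_COLUMNS) if has_axes else ["counts"]
    for col in ["minute_index", *count_cols]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value in column '{col}' at data line "
                f"{int(bad[0]) + 2}"
            )
        df[col] = numeric
    if (df[count_cols] < 0).any().any():
        raise ValidationError(f"{path}: negative counts are not allowed")
    dup = df.duplicated(subset=["participant_id", "minute_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate minute {int(row['minute_index'])} for "
            f"participant {row['participant_id']}"
        )
    for pid, sub in df.groupby("participant_id", sort=False):
        idx = sub["minute_index"].to_numpy()
        expected = np.arange(1, len(idx) + 1)
        if not np.array_equal(np.sort(idx), expected):
            raise ValidationError(
                f"{path}: participant {pid}: minute_index must be contiguous "
                "1..n"
            )
    return df.sort_values(["participant_id", "minute_index"], kind="stable")


def combine_axes(table: pd.DataFrame) -> Dict[str, Signal]:
    """Per-participant signals; tri-axial counts are summed each minute."""
    has_axes = all(c in table.columns for c in AXIS_COLUMNS)
    signals: Dict[str, Signal] = {}
    for pid, sub in table.groupby("participant_id", sort=False):
        sub = sub.sort_values("minute_index", kind="stable")
        if has_axes:
            values = sub[list(AXIS_COLUMNS)].to_numpy(dtype=float).sum(axis=1)
        else:
            values = sub["counts"].to_numpy(dtype=float)
        signals[str(pid)] = Signal(values, participant_id=str(pid))
    return signals


def apply_inclusion(
    signals: Mapping[str, Signal], min_length: int = 7000
) -> Tuple[Dict[str, Signal], List[str]]:
    """Drop too-short signals, crop the survivors to exactly ``min_length``.

    Returns (included, excluded_ids).  Exclusions are logged at INFO; an
    empty survivor set is a logged warning, not an error.
    """
    included: Dict[str, Signal] = {}
    excluded: List[str] = []
    for pid, sig in signals.items():
        if len(sig) < min_length:
            excluded.append(pid)
            logger.info(
                "excluding participant %s: %d < %d minutes", pid, len(sig), min_length
            )
        else:
            included[pid] = sig.crop(min_length)
    if not included:
        logger.warning("no participants meet the %d-minute requirement", min_length)
    return included, excluded


def read_labels(path: str) -> Dict[str, str]:
    """Outcome labels per participant, explicit or derived from weights.

    Accepts either (participant_id, label) with label in
    {success, failure, indeterminate}, or (participant_id, w1, w2[, w3])
    phase weights in kg, converted through the outcome rule.  A blank or
    missing w3 means Phase 3 is not yet reached.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise ValidationError(f"labels file not found: {path}") from None
    except Exception as exc:
        raise ValidationError(f"{path}: could not parse CSV ({exc})") from exc
    _require_columns(df, ["participant_id"], path)
    out: Dict[str, str] = {}
    if "label" in df.columns:
        for _, row in df.iterrows():
            pid, label = str(row["participant_id"]), str(row["label"]).strip().lower()
            if label not in LABEL_TOKENS:
                raise ValidationError(
                    f"{path}: unknown label {label!r} for participant {pid}"
                )
            if pid in out and out[pid] != label:
                raise ValidationError(
                    f"{path}: conflicting duplicate labels for participant {pid}"
                )
            out[pid] = label
        return out
    _require_columns(df, ["w1", "w2"], path)
    for _, row in df.iterrows():
        pid = str(row["participant_id"])
        w3 = row.get("w3")
        w3 = None if w3 is None or pd.isna(w3) else float(w3)
        try:
            label = assign_outcome_label(float(row["w1"]), float(row["w2"]), w3)
        except ValueError as exc:
            raise ValidationError(f"{path}: participant {pid}: {exc}") from exc
        if pid in out and out[pid] != label:
            raise ValidationError(
                f"{path}: conflicting duplicate weights for participant {pid}"
            )
        out[pid] = label
    return out


# ---------------------------------------------------------------------------
# writers

def write_minute_csv(records: Sequence[ParticipantRecord], path: str) -> None:
    frames = []
    for rec in records:
        n = len(rec.signal)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": rec.participant_id,
                    "minute_index": np.arange(1, n + 1),
                    "counts": rec.signal.values.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_labels_csv(records: Sequence[ParticipantRecord], path: str) -> None:
    pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "label": [r.label for r in records],
        }
    ).to_csv(path, index=False)


def write_diagram_csv(diagram: PersistenceDiagram, path) -> None:
    r = len(diagram)
    pd.DataFrame(
        {
            "birth": diagram.births,
            "death": diagram.deaths,
            "min_index": diagram.min_indices if diagram.min_indices else [np.nan] * r,
            "max_index": diagram.max_indices if diagram.max_indices else [np.nan] * r,
        }
    ).to_csv(path, index=False)


def write_distance_csv(values: np.ndarray, path) -> None:
    pd.DataFrame(
        {"window_index": np.arange(1, len(values) + 1), "distance": values}
    ).to_csv(path, index=False)


def write_pairs_csv(pairs: Sequence[PairComparison], path) -> None:
    pd.DataFrame(
        {
            "id_a": [p.id_a for p in pairs],
            "id_b": [p.id_b for p in pairs],
            "group": [p.group for p in pairs],
            "value": [p.value for p in pairs],
        }
    ).to_csv(path, index=False)


def write_group_summary_csv(summaries: Mapping[str, GroupSummary], path) -> None:
    rows = [
        {
            "group": s.group,
            "n": s.n,
            "average": s.mean,
            "standard_deviation": s.sd if s.sd is not None else "",
        }
        for s in summaries.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(
    path: str,
    config: RunConfig,
    inputs: Sequence[str] = (),
    extra: Optional[Mapping[str, object]] = None,
) -> None:
    """Machine-readable record of a run: config, versions, input digests."""
    import actipersist

    manifest = {
        "package": "actipersist",
        "version": getattr(actipersist, "__version__", "unknown"),
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
        "inputs": {p: _digest(p) for p in inputs if Path(p).exists()},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
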