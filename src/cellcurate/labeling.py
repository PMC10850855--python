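"""Resumable labeling of cell detections.

The labeling semantics follow the four-button workflow: *Good* (label 1),
*Bad* (label 0), *Questionmark* (label NaN, excluded from training) and
*Return* (step back one record and overwrite a past verdict). The core is a
headless state machine over the feature table, traversed in (frame
ascending, cell_id ascending) order; any front-end (CLI loop, notebook GUI)
is a thin driver over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import StateError, ValidationError

VERDICTS = ("good", "bad", "question")

_LABEL_OF = {"good": 1.0, "bad": 0.0, "question": float("nan")}


@dataclass
class LabelSession:
    """Cursor + per-record verdicts over a sorted feature table."""

    table: pd.DataFrame  # sorted by (frame, cell_id), index reset
    cursor: int = 0
    verdicts: dict[int, str] = field(default_factory=dict)  # row index -> verdict
    dirty: bool = False

    @property
    def n_records(self) -> int:
        return len(self.table)

    @property
    def done(self) -> bool:
        return self.cursor >= self.n_records

    def current_key(self) -> tuple[int, int] | None:
        """(frame, cell_id) at the cursor, or None past the end."""
        if self.done:
            return None
        row = self.table.iloc[self.cursor]
        return int(row["frame"]), int(row["cell_id"])


def start_session(feature_table: pd.DataFrame, resume_at=None) -> LabelSession:
    """Open a labeling session, optionally resuming at a (frame, cell_id).

    Prior labels in the table's ``label`` column are preserved and re-emitted
    by :func:`finalize` unless overwritten during this session.
    """
    if feature_table.empty:
        raise ValidationError("feature table is empty")
    for col in ("frame", "cell_id"):
        if col not in feature_table.columns:
            raise ValidationError(f"feature table lacks required column {col!r}")
    table = (
        feature_table.sort_values(["frame", "cell_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    session = LabelSession(table)
    if resume_at is not None:
        frame, cell_id = int(resume_at[0]), int(resume_at[1])
        match = table.index[(table["frame"] == frame) & (table["cell_id"] == cell_id)]
        if len(match) == 0:
            nearest = _nearest_key(table, frame, cell_id)
            raise ValidationError(
                f"resume point (frame={frame}, cell_id={cell_id}) not found; "
                f"nearest is (frame={nearest[0]}, cell_id={nearest[1]})"
            )
        session.cursor = int(match[0])
    return session


def _nearest_key(table: pd.DataFrame, frame: int, cell_id: int) -> tuple[int, int]:
    keys = table[["frame", "cell_id"]].to_numpy()
    dist = np.abs(keys[:, 0] - frame) * 10**6 + np.abs(keys[:, 1] - cell_id)
    row = keys[int(np.argmin(dist))]
    return int(row[0]), int(row[1])


def assign(session: LabelSession, verdict: str) -> LabelSession:
    """Record a verdict for the current cell and advance the cursor."""
    if verdict not in VERDICTS:
        raise ValidationError(f"verdict must be one of {VERDICTS}, got {verdict!r}")
    if session.done:
        raise StateError("no record at cursor: session is past the last cell")
    session.verdicts[session.cursor] = verdict
    session.cursor += 1
    session.dirty = True
    return session


def undo(session: LabelSession) -> LabelSession:
    """Step back to the previous cell; its verdict stays until overwritten."""
    if session.cursor <= 0:
        raise StateError("nothing to undo: cursor is at the first cell")
    session.cursor -= 1
    session.dirty = True
    return session


def finalize(session: LabelSession) -> tuple[pd.DataFrame, dict]:
    """Labeled table plus a progress report.

    The ``label`` column encodes good -> 1, bad -> 0, question -> NaN;
    records never visited keep their prior label (NaN when there was none).
    """
    table = session.table.copy()
    if "label" not in table.columns:
        table["label"] = np.nan
    table["label"] = table["label"].astype(float)
    for idx, verdict in session.verdicts.items():
        table.loc[idx, "label"] = _LABEL_OF[verdict]
    labels = table["label"]
    report = {
        "cursor": session.cursor,
        "position": session.current_key(),
        "n_records": session.n_records,
        "n_good": int((labels == 1.0).sum()),
        "n_bad": int((labels == 0.0).sum()),
        "n_question": int(
            labels.isna().sum() - (session.n_records - _n_labeled(table, session))
        ),
        "n_unvisited": session.n_records - _n_labeled(table, session),
    }
    return table, report


def _n_labeled(table: pd.DataFrame, session: LabelSession) -> int:
    prior = table.index[table["label"].notna()] if "label" in table else []
    covered = set(session.verdicts) | set(int(i) for i in prior)
    return len(covered)


def save_session(session: LabelSession, path) -> Path:
    """Persist cursor + verdicts (keyed by frame/cell_id) as JSON."""
    path = Path(path)
    payload = {
        "schema": "cellcurate.label_session/1",
        "cursor": session.cursor,
        "verdicts": [
            {
                "frame": int(session.table.iloc[i]["frame"]),
                "cell_id": int(session.table.iloc[i]["cell_id"]),
                "verdict": v,
            }
            for i, v in sorted(session.verdicts.items())
        ],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_session(feature_table: pd.DataFrame, path) -> LabelSession:
    """Rebuild a session saved with :func:`save_session` over the same table."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != "cellcurate.label_session/1":
        raise ValidationError(f"not a label-session file: {path}")
    session = start_session(feature_table)
    lookup = {
        (int(r["frame"]), int(r["cell_id"])): i
        for i, r in session.table[["frame", "cell_id"]].iterrows()
    }
    for entry in payload["verdicts"]:
        key = (entry["frame"], entry["cell_id"])
        if key not in lookup:
            raise ValidationError(f"saved verdict for unknown record {key}")
        session.verdicts[lookup[key]] = entry["verdict"]
    session.cursor = int(payload["cursor"])
    if not 0 <= session.cursor <= session.n_records:
        raise ValidationError("saved cursor out of range")
    return session
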