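"""Session-log serialization (JSONL canonical, CSV export) and manifests.

JSONL is the canonical session format: one record per line with fields
child_id, t, x (array of M reals), intervention, engagement, confidence,
intensity, seed.  Floats are serialized with Python's shortest-round-trip
repr, so a write -> read cycle is bit-exact.  The CSV export flattens the
cue vector into x_0 .. x_{M-1} columns for spreadsheet use.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sessions import Session, SessionRecord

__all__ = ["write_sessions", "read_sessions", "sessions_to_frame",
           "write_manifest", "file_digest"]

_FIELDS = ("child_id", "t", "x", "intervention", "engagement",
           "confidence", "intensity", "seed")


def _record_doc(session: Session, rec: SessionRecord) -> dict:
    return {
        "child_id": session.child_id,
        "t": rec.t,
        "x": [float(v) for v in rec.x],
        "intervention": rec.intervention,
        "engagement": rec.engagement,
        "confidence": rec.confidence,
        "intensity": rec.intensity,
        "seed": session.seed,
    }


def write_sessions(sessions, path, fmt: str = "jsonl") -> None:
    """Write sessions to ``path`` in the canonical JSONL schema (or CSV)."""
    path = Path(path)
    if fmt == "jsonl":
        with path.open("w") as fh:
            for session in sessions:
                for rec in session.records:
                    fh.write(json.dumps(_record_doc(session, rec),
                                        sort_keys=True) + "\n")
    elif fmt == "csv":
        sessions_to_frame(sessions).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def sessions_to_frame(sessions) -> pd.DataFrame:
    """Flat CSV-friendly view: x expanded into x_0 .. x_{M-1} columns."""
    rows = []
    for session in sessions:
        for rec in session.records:
            row = {"child_id": session.child_id, "t": rec.t}
            for j, v in enumerate(rec.x):
                row[f"x_{j}"] = v
            row.update(intervention=rec.intervention, engagement=rec.engagement,
                       confidence=rec.confidence, intensity=rec.intensity,
                       seed=session.seed)
            rows.append(row)
    return pd.DataFrame(rows)


def read_sessions(path, fmt: str = "jsonl"):
    """Read sessions; the inverse of :func:`write_sessions` for JSONL.

    Malformed lines raise an error naming the line number; a cue-vector
    length change within a child is rejected.
    """
    path = Path(path)
    if fmt == "csv":
        return _read_sessions_csv(path)
    if fmt != "jsonl":
        raise ValueError(f"unknown format {fmt!r}")
    per_child: dict = {}
    order = []
    m_per_child: dict = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                doc = json.loads(line)
                if not set(doc) <= set(_FIELDS) or "child_id" not in doc or "t" not in doc:
                    raise ValueError(f"unexpected fields {sorted(doc)}")
                cid = doc["child_id"]
                x = np.asarray(doc["x"], dtype=float)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from None
            if cid in m_per_child and x.shape[0] != m_per_child[cid]:
                raise ValueError(
                    f"{path}:{lineno}: cue length {x.shape[0]} != "
                    f"{m_per_child[cid]} seen earlier for child {cid!r}")
            m_per_child[cid] = x.shape[0]
            if cid not in per_child:
                per_child[cid] = {"records": [], "seed": doc.get("seed")}
                order.append(cid)
            per_child[cid]["records"].append(SessionRecord(
                t=float(doc["t"]), x=x, intervention=doc.get("intervention"),
                engagement=doc.get("engagement"), confidence=doc.get("confidence"),
                intensity=doc.get("intensity")))
    return [Session(child_id=cid, records=per_child[cid]["records"],
                    seed=per_child[cid]["seed"]) for cid in order]


def _read_sessions_csv(path):
    df = pd.read_csv(path)
    xcols = sorted((c for c in df.columns if c.startswith("x_")),
                   key=lambda c: int(c.split("_")[1]))
    sessions = []
    for cid, grp in df.groupby("child_id", sort=False):
        records = []
        for _, row in grp.iterrows():
            records.append(SessionRecord(
                t=float(row["t"]), x=row[xcols].to_numpy(dtype=float),
                intervention=None if pd.isna(row["intervention"]) else row["intervention"],
                engagement=None if pd.isna(row["engagement"]) else float(row["engagement"]),
                confidence=None if pd.isna(row["confidence"]) else float(row["confidence"]),
                intensity=None if pd.isna(row["intensity"]) else float(row["intensity"])))
        seed = grp["seed"].iloc[0]
        sessions.append(Session(child_id=str(cid), records=records,
                                seed=None if pd.isna(seed) else int(seed)))
    return sessions


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, *, command: str, config: dict, seed: int,
                   inputs=(), version: str = None) -> None:
    """Reproducibility manifest: version, effective config, seed, input digests.

    Deliberately timestamp-free so repeated runs are byte-identical.
    """
    from . import __version__
    doc = {
        "tool": "adaptint",
        "version": version or __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "inputs": {str(p): file_digest(p) for p in inputs},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
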