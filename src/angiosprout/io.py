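"""Run-output serialization: TIFF snapshots, CSV tables, JSON summaries.

Every artifact carries the configuration hash and the seed so runs can be
matched back to the exact parameter set that produced them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_label_snapshot(path, lattice, mcs: int, config_hash: str) -> None:
    """Label matrix as 16-bit single-channel TIFF plus a JSON sidecar
    mapping cell id to (kind, genotype)."""
    path = Path(path)
    tifffile.imwrite(path, lattice.labels.astype(np.uint16))
    sidecar = {
        "mcs": mcs,
        "config_hash": config_hash,
        "cells": {str(r.id): {"kind": r.kind, "genotype": r.genotype}
                  for r in lattice.records()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_label_snapshot(path):
    """Label matrix and sidecar metadata written by `write_label_snapshot`."""
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    meta = json.loads(path.with_suffix(".json").read_text())
    return labels, meta


def write_field_snapshot(path, field, mcs: int, config_hash: str) -> None:
    tifffile.imwrite(Path(path), field.c.astype(np.float32))


def write_graph_json(path, graph, sprouts=None, *, mcs=None,
                     config_hash="") -> None:
    """Skeleton-graph dump: nodes (position, kind), edges (endpoints,
    length), and optional sprout records for one sampled frame."""
    data = {
        "mcs": mcs,
        "config_hash": config_hash,
        "nodes": [{"id": int(n), "pos": [float(v) for v in d["pos"]],
                   "kind": d.get("kind")}
                  for n, d in graph.nodes(data=True)],
        "edges": [{"u": int(u), "v": int(v), "length": float(d["length"])}
                  for u, v, d in graph.edges(data=True)],
        "sprouts": [
            {"branch": [float(v) for v in s.branch],
             "end": [float(v) for v in s.end],
             "leader": int(s.leader),
             "members": [int(m) for m in s.members]}
            for s in (sprouts or [])
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def write_tracks(path, tracks: pd.DataFrame, config_hash: str, seed: int) -> None:
    """Track table CSV with a provenance header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        tracks.to_csv(fh, index=False)


def read_tracks(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_events(path, events, config_hash: str, seed: int) -> None:
    rows = [{"sprout_id": e.sprout_id, "mcs": e.mcs,
             "old_leader": e.old_leader, "new_leader": e.new_leader}
            for e in events]
    df = pd.DataFrame(rows, columns=["sprout_id", "mcs", "old_leader", "new_leader"])
    with open(Path(path), "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_summary(path, summary: dict, config_hash: str, seed=None) -> None:
    data = {"config_hash": config_hash, "seed": seed}
    data.update(_jsonable(summary))
    Path(path).write_text(json.dumps(data, indent=1, default=str))
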