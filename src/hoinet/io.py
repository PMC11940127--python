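"""On-disk formats: array container + JSON sidecar for epochs, TSV tables,
JSON search traces.

An epoch set is stored as ``<participant>_<session>.npy`` (channels x time
x trials) next to ``<participant>_<session>.json`` holding the sampling
rate, channel names, group, and session.  Behavior tables and result
grids are plain TSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EpochSet
from .gsa import SearchTrace

__all__ = [
    "save_epochset",
    "load_epochset",
    "load_epoch_dir",
    "save_behavior",
    "load_behavior",
    "trace_to_dict",
    "save_traces",
]

REQUIRED_META = ("fs", "channel_names", "group", "session", "participant")


def save_epochset(epochs: EpochSet, out_dir: str | Path, extra_meta: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{epochs.participant}_{epochs.session}"
    np.save(out_dir / f"{stem}.npy", epochs.data)
    meta = {
        "participant": epochs.participant,
        "group": epochs.group,
        "session": epochs.session,
        "fs": epochs.fs,
        "channel_names": epochs.channel_names,
    }
    if extra_meta:
        meta.update(extra_meta)
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    return out_dir / f"{stem}.npy"


def load_epochset(npy_path: str | Path) -> EpochSet:
    npy_path = Path(npy_path)
    sidecar = npy_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in REQUIRED_META if k not in meta]
    if missing:
        raise ValueError(f"{sidecar}: missing metadata fields {missing}")
    data = np.load(npy_path)
    return EpochSet(
        participant=meta["participant"],
        group=meta["group"],
        session=meta["session"],
        data=data,
        fs=meta["fs"],
        channel_names=meta["channel_names"],
    )


def load_epoch_dir(path: str | Path) -> tuple[dict[tuple[str, str], EpochSet], dict[str, str]]:
    """Load every epoch set in a directory; validate a consistent montage.

    Returns (epochs keyed by (participant, session), participant -> group).
    """
    path = Path(path)
    epochs: dict[tuple[str, str], EpochSet] = {}
    groups: dict[str, str] = {}
    montage: list[str] | None = None
    for npy in sorted(path.glob("*.npy")):
        es = load_epochset(npy)
        if montage is None:
            montage = es.channel_names
        elif es.channel_names != montage:
            raise ValueError(
                f"participant {es.participant}: montage mismatch "
                f"({len(es.channel_names)} vs {len(montage)} channels)"
            )
        epochs[(es.participant, es.session)] = es
        groups[es.participant] = es.group
    if not epochs:
        raise FileNotFoundError(f"no .npy epoch files under {path}")
    return epochs, groups


def save_behavior(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def load_behavior(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def trace_to_dict(trace: SearchTrace, channel_names: list[str] | None = None) -> dict:
    def name(i: int) -> str:
        return channel_names[i] if channel_names else f"ch{i:02d}"

    return {
        "band": trace.band,
        "measure": trace.measure,
        "direction": trace.direction,
        "n_evaluations": trace.n_evaluations,
        "steps": [
            {
                "order": s.order,
                "subset": [name(i) for i in s.subset],
                "subset_indices": list(s.subset),
                "effect": asdict(s.effect),
                "values": s.values,
            }
            for s in trace.steps
        ],
    }


def save_traces(
    traces: list[SearchTrace], path: str | Path, channel_names: list[str] | None = None
) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = [trace_to_dict(t, channel_names) for t in traces]
    Path(path).write_text(json.dumps(payload, indent=1))
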