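"""Pocket event logs, merge/split matrices, the connection matrix gamma,
time-averaged volumes and per-pocket connection distributions.

A pocket tracker watching an MD trajectory emits, per frame, the detected
pockets with their volumes plus "merge" and "split" events between pocket
pairs. Counting those events into the merge matrix alpha and split matrix
beta, the connection matrix is their symmetrized average::

    gamma = 1/2 * (sym(alpha) + sym(beta)),   sym(M) = 1/2 * (M + M.T)

gamma is symmetric with a zero diagonal; each row summarizes one pocket's
dynamic connectivity to the rest of the pocketome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PocketEventLog",
    "MergeSplitMatrices",
    "VolumeSummary",
    "ConnectionDistributions",
    "events_to_matrices",
    "connection_matrix",
    "time_averaged_volumes",
    "connection_distribution",
]


@dataclass
class PocketEventLog:
    """Per-frame pocket volumes and merge/split events.

    ``volumes`` is (n_frames, n_pockets) in A^3 with 0 meaning "not
    detected"; ``merges`` / ``splits`` hold, per frame, the list of ordered
    pocket-name pairs recorded for that frame. Default frame spacing is
    100 ps, the standard pocket-tracking interval.
    """

    pocket_names: tuple[str, ...]
    volumes: np.ndarray
    merges: list[list[tuple[str, str]]]
    splits: list[list[tuple[str, str]]]
    frame_spacing_ps: float = 100.0

    def __post_init__(self) -> None:
        self.pocket_names = tuple(self.pocket_names)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 2 or self.volumes.shape[1] != len(self.pocket_names):
            raise ValueError("volumes must have shape (n_frames, n_pockets)")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")
        n = self.volumes.shape[0]
        if len(self.merges) != n or len(self.splits) != n:
            raise ValueError("merges/splits must have one record per frame")
        known = set(self.pocket_names)
        for frame, events in enumerate(self.merges + self.splits):
            for a, b in events:
                if a == b:
                    raise ValueError(f"self-pair event ({a}, {b}) at frame {frame % n}")
                if a not in known or b not in known:
                    raise ValueError(
                        f"unknown pocket in event ({a}, {b}) at frame {frame % n}"
                    )

    @property
    def n_frames(self) -> int:
        return self.volumes.shape[0]

    def to_json(self, path: str | Path) -> None:
        records = []
        for f in range(self.n_frames):
            vols = {
                name: self.volumes[f, i]
                for i, name in enumerate(self.pocket_names)
                if self.volumes[f, i] > 0
            }
            records.append(
                {
                    "frame": f,
                    "volumes": vols,
                    "merges": [list(p) for p in self.merges[f]],
                    "splits": [list(p) for p in self.splits[f]],
                }
            )
        payload = {
            "pocket_names": list(self.pocket_names),
            "frame_spacing_ps": self.frame_spacing_ps,
            "frames": records,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PocketEventLog":
        payload = json.loads(Path(path).read_text())
        names = tuple(payload["pocket_names"])
        pos = {n: i for i, n in enumerate(names)}
        frames = payload["frames"]
        volumes = np.zeros((len(frames), len(names)))
        merges, splits = [], []
        for rec in frames:
            f = int(rec["frame"])
            for name, v in rec.get("volumes", {}).items():
                volumes[f, pos[name]] = float(v)
            merges.append([tuple(p) for p in rec.get("merges", [])])
            splits.append([tuple(p) for p in rec.get("splits", [])])
        return cls(
            pocket_names=names,
            volumes=volumes,
            merges=merges,
            splits=splits,
            frame_spacing_ps=float(payload.get("frame_spacing_ps", 100.0)),
        )


@dataclass
class MergeSplitMatrices:
    """Ordered-pair merge (alpha) and split (beta) count matrices."""

    alpha: pd.DataFrame
    beta: pd.DataFrame

    def __post_init__(self) -> None:
        for name, m in (("alpha", self.alpha), ("beta", self.beta)):
            if not m.index.equals(m.columns):
                raise ValueError(f"{name} must be square with matching labels")
            arr = m.to_numpy()
            if np.any(arr < 0) or np.any(np.diag(arr) != 0):
                raise ValueError(f"{name} must be non-negative with a zero diagonal")


def events_to_matrices(log: PocketEventLog) -> MergeSplitMatrices:
    """Count merge and split events into the alpha and beta matrices.

    Counts are kept exactly as recorded: an event logged as (i, j) increments
    row i, column j, so the raw matrices may be asymmetric.
    """
    names = log.pocket_names
    pos = {n: i for i, n in enumerate(names)}
    P = len(names)
    alpha = np.zeros((P, P), dtype=int)
    beta = np.zeros((P, P), dtype=int)
    for events, m in ((log.merges, alpha), (log.splits, beta)):
        for frame_events in events:
            for a, b in frame_events:
                m[pos[a], pos[b]] += 1
    idx = pd.Index(names)
    return MergeSplitMatrices(
        alpha=pd.DataFrame(alpha, index=idx, columns=idx),
        beta=pd.DataFrame(beta, index=idx, columns=idx),
    )


def connection_matrix(ms: MergeSplitMatrices, per_ns: bool = False, n_frames: int | None = None,
                      frame_spacing_ps: float = 100.0) -> pd.DataFrame:
    """The connection matrix gamma = 1/2 (sym(alpha) + sym(beta)).

    With ``per_ns=True`` the counts are normalized to events per nanosecond
    of simulated time (requires ``n_frames``), for comparisons across runs
    of unequal length; by default raw counts are kept.
    """
    if not ms.alpha.index.equals(ms.beta.index):
        raise ValueError("alpha and beta must share the same pocket labels")
    a = ms.alpha.to_numpy(dtype=float)
    b = ms.beta.to_numpy(dtype=float)
    if a.shape != b.shape:
        raise ValueError("alpha and beta shapes differ")
    gamma = 0.5 * (0.5 * (a + a.T) + 0.5 * (b + b.T))
    if per_ns:
        if n_frames is None:
            raise ValueError("per_ns normalization requires n_frames")
        gamma = gamma / (n_frames * frame_spacing_ps / 1000.0)
    return pd.DataFrame(gamma, index=ms.alpha.index, columns=ms.alpha.columns)


@dataclass
class VolumeSummary:
    """Per-pocket time-averaged volume (A^3) and detection fraction."""

    table: pd.DataFrame  # columns: mean_volume, detection_fraction

    def __post_init__(self) -> None:
        if not {"mean_volume", "detection_fraction"} <= set(self.table.columns):
            raise ValueError("summary table must have mean_volume and detection_fraction")


def time_averaged_volumes(log: PocketEventLog) -> VolumeSummary:
    """Mean per-frame volume over ALL frames (undetected frames count as 0).

    Averaging over all frames rather than only detected ones keeps a
    never-detected pocket well defined (mean 0) and makes elusive pockets
    show small averages — absence is data.
    """
    mean_vol = log.volumes.mean(axis=0)
    detection = (log.volumes > 0).mean(axis=0)
    table = pd.DataFrame(
        {"mean_volume": mean_vol, "detection_fraction": detection},
        index=pd.Index(log.pocket_names, name="pocket"),
    )
    return VolumeSummary(table=table)


@dataclass
class ConnectionDistributions:
    """Per-pocket, per-class connection samples pooled across systems.

    ``entries[(pocket, label)]`` is the pooled multiset of off-diagonal row
    entries of gamma across that class's systems; ``row_sums`` is a tidy
    table (system, label, pocket, row_sum) of each system's total connection
    weight per pocket — the scalar fed to group comparison.
    """

    entries: dict[tuple[str, str], np.ndarray]
    row_sums: pd.DataFrame


def connection_distribution(
    gammas: Mapping[str, pd.DataFrame], labels: Mapping[str, str]
) -> ConnectionDistributions:
    """Pool gamma row entries and row sums by pocket and activity class.

    All systems must share one pocket name set; a pocket's absence from a
    system would have produced a zero row, and zero entries are retained —
    a silent pocket is evidence, not a missing value.
    """
    systems = list(gammas)
    if not systems:
        raise ValueError("no systems given")
    ref = list(gammas[systems[0]].index)
    for s in systems:
        if list(gammas[s].index) != ref:
            raise ValueError(
                f"system '{s}' pocket names {list(gammas[s].index)} differ from {ref}"
            )
        if s not in labels:
            raise ValueError(f"no label for system '{s}'")

    entries: dict[tuple[str, str], list] = {}
    rows = []
    for s in systems:
        g = gammas[s].to_numpy(dtype=float)
        lab = labels[s]
        for i, pocket in enumerate(ref):
            off = np.delete(g[i], i)
            entries.setdefault((pocket, lab), []).extend(off.tolist())
            rows.append(
                {"system": s, "label": lab, "pocket": pocket, "row_sum": float(off.sum())}
            )
    return ConnectionDistributions(
        entries={k: np.array(v) for k, v in entries.items()},
        row_sums=pd.DataFrame(rows),
    )
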