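"""Mapping kinase residues onto shared MSA columns and matrix assembly.

The panel-wide fluctuation matrix keeps only alignment columns that are
ungapped in every sequence, so every kinase contributes a residue to every
retained column and the matrix is complete by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from kinoflex.trajectory import RMSFProfile

__all__ = [
    "MSA",
    "AlignmentMap",
    "FluctuationMatrix",
    "read_alignment",
    "build_column_map",
    "assemble_matrix",
    "label_from_activity",
]

GAP = "-"


@dataclass
class MSA:
    """A validated multiple sequence alignment (ids + equal-length rows)."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        if self.sequences:
            L = len(self.sequences[0])
            for sid, seq in zip(self.ids, self.sequences):
                if len(seq) != L:
                    raise ValueError(
                        f"ragged alignment: sequence '{sid}' has length {len(seq)}, "
                        f"expected {L}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence(self, sid: str) -> str:
        return self.sequences[self.ids.index(sid)]


@dataclass
class AlignmentMap:
    """Per-kinase (alignment column -> residue_id) maps plus retained columns."""

    column_to_residue: dict[str, dict[int, int]]
    retained_columns: list[int]

    def __post_init__(self) -> None:
        for kid, cmap in self.column_to_residue.items():
            cols = sorted(cmap)
            rids = [cmap[c] for c in cols]
            if any(b <= a for a, b in zip(rids, rids[1:])):
                raise ValueError(
                    f"kinase '{kid}': residue ids must strictly increase with column"
                )

    def to_json(self, path: str | Path) -> None:
        import json

        payload = {
            "retained_columns": self.retained_columns,
            "column_to_residue": {
                k: {str(c): r for c, r in sorted(v.items())}
                for k, v in sorted(self.column_to_residue.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "AlignmentMap":
        import json

        payload = json.loads(Path(path).read_text())
        return cls(
            column_to_residue={
                k: {int(c): int(r) for c, r in v.items()}
                for k, v in payload["column_to_residue"].items()
            },
            retained_columns=[int(c) for c in payload["retained_columns"]],
        )


@dataclass
class FluctuationMatrix:
    """Kinases x alignment-columns RMSF matrix (A) with activity labels.

    ``values`` is a DataFrame (rows = kinase ids, columns = alignment column
    indices); ``labels`` a Series over the same rows with values
    ``active`` / ``inactive``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels index must match the matrix rows")
        if self.values.isna().any().any():
            raise ValueError("fluctuation matrix must have no missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("RMSF values must be non-negative")
        bad = set(self.labels.unique()) - {"active", "inactive"}
        if bad:
            raise ValueError(f"labels must be 'active'/'inactive'; found {sorted(bad)}")

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Binary labels: 1 = active, 0 = inactive."""
        return (self.labels.to_numpy() == "active").astype(int)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out["label"] = self.labels
        out.to_csv(path, index_label="kinase")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FluctuationMatrix":
        df = pd.read_csv(path, index_col="kinase")
        labels = df.pop("label")
        df.columns = [int(c) if str(c).isdigit() else c for c in df.columns]
        return cls(values=df, labels=labels)

    def subset_rows(self, rows: Sequence[str]) -> "FluctuationMatrix":
        return FluctuationMatrix(values=self.values.loc[rows], labels=self.labels.loc[rows])

    def drop_columns(self, cols: Sequence) -> "FluctuationMatrix":
        return FluctuationMatrix(
            values=self.values.drop(columns=list(cols)), labels=self.labels
        )


def read_alignment(path: str | Path, format: str = "fasta") -> MSA:
    """Read a FASTA or Clustal alignment into a validated MSA."""
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        records = list(AlignIO.read(str(path), "clustal"))
    if not records:
        raise ValueError(f"{path}: no sequences found")
    return MSA(ids=[r.id for r in records], sequences=[str(r.seq).upper() for r in records])


def build_column_map(
    msa: MSA, structures: Mapping[str, Sequence[int]]
) -> AlignmentMap:
    """Map alignment columns to residue ids for every kinase.

    ``structures`` gives, per kinase id (matching the MSA ids), the ordered
    residue ids of that kinase's structure; the k-th non-gap character of a
    kinase's aligned sequence corresponds to its k-th residue id. Retained
    columns are those ungapped in every sequence.

    Raises
    ------
    ValueError
        If a kinase's ungapped length differs from its residue list length
        (correspondence error), or a kinase is missing from either input.
    """
    missing = set(msa.ids) - set(structures)
    if missing:
        raise ValueError(f"no residue list for MSA sequences: {sorted(missing)}")

    column_to_residue: dict[str, dict[int, int]] = {}
    ungapped_everywhere = np.ones(msa.length, dtype=bool)
    for sid, seq in zip(msa.ids, msa.sequences):
        resids = list(structures[sid])
        cols = [c for c, ch in enumerate(seq) if ch != GAP]
        if len(cols) != len(resids):
            raise ValueError(
                f"kinase '{sid}': ungapped alignment length {len(cols)} != "
                f"residue list length {len(resids)}"
            )
        column_to_residue[sid] = dict(zip(cols, resids))
        gap_cols = np.ones(msa.length, dtype=bool)
        gap_cols[cols] = False
        ungapped_everywhere &= ~gap_cols

    retained = [int(c) for c in np.nonzero(ungapped_everywhere)[0]]
    return AlignmentMap(column_to_residue=column_to_residue, retained_columns=retained)


def assemble_matrix(
    profiles: Mapping[str, RMSFProfile],
    amap: AlignmentMap,
    labels: Mapping[str, str],
) -> FluctuationMatrix:
    """Assemble the kinases x retained-columns fluctuation matrix.

    Row order follows the iteration order of ``profiles``. Every retained
    column must resolve to a residue present in every kinase's profile;
    otherwise an error lists all failures at once.
    """
    failures = []
    rows = {}
    for kid, profile in profiles.items():
        if kid not in amap.column_to_residue:
            failures.append(f"kinase '{kid}' absent from alignment map")
            continue
        cmap = amap.column_to_residue[kid]
        vals = []
        for col in amap.retained_columns:
            rid = cmap.get(col)
            if rid is None:
                failures.append(f"kinase '{kid}': column {col} unmapped")
                continue
            try:
                vals.append(profile.value_at(rid))
            except KeyError:
                failures.append(
                    f"kinase '{kid}': column {col} maps to residue {rid} "
                    "missing from its RMSF profile"
                )
        if len(vals) == len(amap.retained_columns):
            rows[kid] = vals
    if failures:
        raise ValueError("matrix assembly failed:\n  " + "\n  ".join(failures))

    values = pd.DataFrame.from_dict(rows, orient="index", columns=amap.retained_columns)
    lab = pd.Series({k: labels[k] for k in values.index}, name="label")
    return FluctuationMatrix(values=values, labels=lab.loc[values.index])


def label_from_activity(series: Sequence[float] | np.ndarray, cut: float = 0.5) -> str:
    """Label a kinase from its per-frame activity-probability series.

    The label is ``active`` iff the mean activity over the trajectory is at
    least ``cut`` (default 0.5, the symmetric choice).
    """
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("activity series is empty")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("activity probabilities must lie in [0, 1]")
    return "active" if arr.mean() >= cut else "inactive"
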