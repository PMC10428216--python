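"""Trajectory container, Kabsch superposition and per-residue RMSF.

RMSF protocol
-------------
After discarding an equilibration prefix, every retained frame is
least-squares fit (Kabsch) onto frame 1 over the analysis selection, and the
(fit onto mean -> recompute mean) refinement is iterated to a fixed point,
so the profile does not depend on the arbitrary starting reference. The
per-atom RMSF is the root mean squared displacement from the converged mean
position; per-residue RMSF is the RMS over the residue's selected atoms.
All coordinates are in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "RMSFProfile",
    "kabsch_superpose",
    "compute_rmsf",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "read_coordinate_table",
    "BACKBONE_ATOMS",
]

#: Conventional protein backbone atom names.
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Trajectory:
    """An in-memory trajectory: frames x atoms x 3 coordinates plus metadata.

    ``atom_meta`` is a DataFrame with one row per atom and columns
    ``residue_id``, ``residue_name``, ``atom_name``, ``is_backbone``.
    ``frame_times`` (optional) holds per-frame times in ns.
    """

    coordinates: np.ndarray
    atom_meta: pd.DataFrame
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if len(self.atom_meta) != self.coordinates.shape[1]:
            raise ValueError(
                f"atom_meta has {len(self.atom_meta)} rows but coordinates have "
                f"{self.coordinates.shape[1]} atoms"
            )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != self.n_frames:
                raise ValueError("frame_times length must equal the number of frames")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def atom_mask(self, selection: str | Sequence[str] = "backbone") -> np.ndarray:
        """Boolean mask over atoms for ``'backbone'``, ``'all'`` or a name list."""
        if isinstance(selection, str):
            if selection == "backbone":
                return self.atom_meta["is_backbone"].to_numpy(dtype=bool)
            if selection == "all":
                return np.ones(self.n_atoms, dtype=bool)
            selection = [selection]
        names = set(selection)
        return self.atom_meta["atom_name"].isin(names).to_numpy(dtype=bool)


@dataclass
class RMSFProfile:
    """Per-residue RMSF values (A) with bookkeeping of the frames used."""

    residue_ids: np.ndarray
    rmsf: np.ndarray
    n_frames_used: int
    discard_prefix: int

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if len(self.residue_ids) != len(self.rmsf):
            raise ValueError("residue_ids and rmsf must have equal length")
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf values must be non-negative")

    def value_at(self, residue_id: int) -> float:
        idx = np.nonzero(self.residue_ids == residue_id)[0]
        if len(idx) == 0:
            raise KeyError(f"residue {residue_id} not in profile")
        return float(self.rmsf[idx[0]])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"residue_id": self.residue_ids, "rmsf_A": self.rmsf}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "RMSFProfile":
        df = pd.read_csv(path)
        return cls(
            residue_ids=df["residue_id"].to_numpy(),
            rmsf=df["rmsf_A"].to_numpy(),
            n_frames_used=0,
            discard_prefix=0,
        )


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to ``reference``
    over the masked atoms. The rotation is proper (det = +1).

    Raises
    ------
    ValueError
        If the mask selects fewer than 3 atoms or the selected atoms are
        (numerically) collinear, which leaves the rotation underdetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n_atoms, 3)")
    if mask is None:
        mask = np.ones(len(mobile), dtype=bool)
    mask = np.asarray(mask)
    P = mobile[mask]
    Q = reference[mask]
    if len(P) < 3:
        raise ValueError("superposition requires at least 3 masked atoms")

    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc

    if np.array_equal(P0, Q0):
        # Exact match: return the exact transform so that rigid trajectories
        # produce identically zero displacement, not SVD round-off.
        if np.linalg.matrix_rank(P0, tol=1e-8 * max(np.abs(P0).max(), 1.0)) < 2:
            raise ValueError("masked atoms are collinear; superposition is degenerate")
        return np.eye(3), qc - pc, 0.0

    # Collinear point sets leave rotation about the line free.
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("masked atoms are collinear; superposition is degenerate")

    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc

    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def _fit_frames(coords: np.ndarray, reference: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``reference`` over ``mask``; returns fitted coords."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        R, t, _ = kabsch_superpose(coords[f], reference, mask)
        out[f] = coords[f] @ R.T + t
    return out


def _iterate_fit(
    coords: np.ndarray,
    mask: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit frames to frame 1, then iterate (fit -> recompute mean) to a fixed
    point: the mean structure stops moving, making the RMSF independent of
    the arbitrary starting reference."""
    if np.all(coords == coords[0]):
        # Fully rigid: the mean is a frame itself; avoids the round-off of
        # averaging n identical floats so the RMSF is exactly zero.
        return coords.copy(), coords[0].copy()
    fitted = _fit_frames(coords, coords[0], mask)
    mean = fitted.mean(axis=0)
    for _ in range(max_iter):
        fitted = _fit_frames(fitted, mean, mask)
        new_mean = fitted.mean(axis=0)
        shift = np.abs(new_mean - mean).max()
        mean = new_mean
        if shift < tol:
            break
    return fitted, mean


def _resolve_discard(traj: Trajectory, discard) -> int:
    """Translate the discard policy into a frame count.

    ``discard`` may be an int (frames), a float (ns, requires frame times),
    or ``"auto"``: drop the first 500 ns when frame times exist, else the
    first sixth of the frames (the 500-of-3000-ns proportion typical of the
    runs this analysis targets).
    """
    if discard == "auto":
        if traj.frame_times is not None:
            return int(np.searchsorted(traj.frame_times, traj.frame_times[0] + 500.0))
        return traj.n_frames // 6
    if isinstance(discard, (int, np.integer)):
        return int(discard)
    if isinstance(discard, float):
        if traj.frame_times is None:
            raise ValueError("time-based discard requires frame_times on the trajectory")
        return int(np.searchsorted(traj.frame_times, traj.frame_times[0] + discard))
    raise TypeError(f"unsupported discard policy: {discard!r}")


def compute_rmsf(
    traj: Trajectory,
    selection: str | Sequence[str] = "backbone",
    discard: int | float | str = "auto",
) -> RMSFProfile:
    """Per-residue RMSF of the selected atoms after superposition.

    Parameters
    ----------
    traj : Trajectory
    selection : 'backbone' | 'all' | list of atom names
        Atoms entering both the superposition fit and the RMSF.
    discard : int frames | float ns | 'auto'
        Equilibration prefix to drop before analysis.

    Raises
    ------
    ValueError
        If fewer than 2 frames remain after the discard, or the selection
        matches no atoms.
    """
    n_discard = _resolve_discard(traj, discard)
    if n_discard >= traj.n_frames - 1:
        raise ValueError(
            f"discard of {n_discard} frames leaves fewer than 2 of {traj.n_frames} frames"
        )
    mask = traj.atom_mask(selection)
    if not mask.any():
        raise ValueError(f"selection {selection!r} matches no atoms")

    coords = traj.coordinates[n_discard:]
    fitted, mean = _iterate_fit(coords, mask)

    sq_disp = ((fitted - mean[None, :, :]) ** 2).sum(axis=2).mean(axis=0)  # per atom

    resids = traj.atom_meta["residue_id"].to_numpy()
    residue_ids = np.array(sorted(pd.unique(resids[mask])))
    rmsf = np.empty(len(residue_ids))
    for i, rid in enumerate(residue_ids):
        atoms = mask & (resids == rid)
        rmsf[i] = np.sqrt(sq_disp[atoms].mean())

    return RMSFProfile(
        residue_ids=residue_ids,
        rmsf=rmsf,
        n_frames_used=coords.shape[0],
        discard_prefix=n_discard,
    )


# ---------------------------------------------------------------------------
# IO: multi-model PDB (via biotite) and the plain CSV coordinate table
# ---------------------------------------------------------------------------


def write_pdb_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n_atoms)
    stack.coord = traj.coordinates.astype(np.float32)
    stack.res_id = traj.atom_meta["residue_id"].to_numpy(dtype=int)
    stack.res_name = traj.atom_meta["residue_name"].to_numpy(dtype="U5")
    stack.atom_name = traj.atom_meta["atom_name"].to_numpy(dtype="U6")
    stack.chain_id = np.full(n_atoms, "A", dtype="U4")
    stack.element = np.array(
        [n[:1] for n in traj.atom_meta["atom_name"]], dtype="U2"
    )
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-model PDB file into a Trajectory."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if stack.stack_depth() < 1:
        raise ValueError(f"{path}: no models found")
    atom_names = [str(n) for n in stack.atom_name]
    atom_meta = pd.DataFrame(
        {
            "residue_id": np.asarray(stack.res_id, dtype=int),
            "residue_name": [str(n) for n in stack.res_name],
            "atom_name": atom_names,
            "is_backbone": [n in BACKBONE_ATOMS for n in atom_names],
        }
    )
    return Trajectory(coordinates=np.asarray(stack.coord, dtype=float), atom_meta=atom_meta)


def read_coordinate_table(path: str | Path, atom_meta: pd.DataFrame) -> Trajectory:
    """Read a plain coordinate table (columns frame, atom_index, x, y, z).

    ``atom_meta`` supplies the per-atom metadata the flat table lacks.
    """
    df = pd.read_csv(path)
    required = {"frame", "atom_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns: {sorted(missing)}")
    frames = np.sort(df["frame"].unique())
    n_atoms = len(atom_meta)
    coords = np.full((len(frames), n_atoms, 3), np.nan)
    frame_pos = {f: i for i, f in enumerate(frames)}
    fi = df["frame"].map(frame_pos).to_numpy()
    ai = df["atom_index"].to_numpy(dtype=int)
    coords[fi, ai, 0] = df["x"].to_numpy()
    coords[fi, ai, 1] = df["y"].to_numpy()
    coords[fi, ai, 2] = df["z"].to_numpy()
    if np.isnan(coords).any():
        raise ValueError("coordinate table does not cover every (frame, atom) pair")
    return Trajectory(coordinates=coords, atom_meta=atom_meta)
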