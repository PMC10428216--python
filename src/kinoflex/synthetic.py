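"""Synthetic generators for trajectories, fluctuation panels and pocket event logs.

Every downstream stage of the package (RMSF, stump classification, pocket
networks, clustering) is testable against these generators because each one
plants a known ground truth:

* ``gen_trajectory`` — isotropic Gaussian positional fluctuation per residue,
  so the per-residue RMSF has the closed form sigma * sqrt(3);
* ``gen_fluctuation_panel`` — a kinase panel whose active/inactive classes
  differ only in the fluctuation of one planted signal column (plus an
  optional correlated block mimicking the residues just downstream of the
  DFG motif);
* ``gen_pocket_events`` — pocket presence/volume streams with lognormal
  volumes and Poisson merge/split events at known pair rates.

All three are deterministic given their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from kinoflex.pockets import PocketEventLog
from kinoflex.trajectory import Trajectory

__all__ = [
    "TrajectorySpec",
    "PanelSpec",
    "PocketSimSpec",
    "gen_trajectory",
    "gen_fluctuation_panel",
    "gen_pocket_events",
    "DEFAULT_POCKET_NAMES",
]

#: The canonical seven-pocket panel of the tyrosine-kinase domain:
#: ATP site, allosteric A-site, C-helix/membrane-proximal pockets, etc.
DEFAULT_POCKET_NAMES = ("ATP", "AAS", "CMP", "DRS", "PDIG", "PIF", "MPP")

# Backbone atom template: rough N/CA/C/O geometry (A), non-collinear so that
# rigid-body superposition over a single residue is well posed.
_BACKBONE_NAMES = ("N", "CA", "C", "O")
_BACKBONE_OFFSETS = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.46, 0.0, 0.0],
        [2.0, 1.4, 0.0],
        [1.5, 2.4, 0.8],
    ]
)


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValueError(f"invalid spec field '{field_name}': {message}")


@dataclass(frozen=True)
class TrajectorySpec:
    """Specification of an isotropic-Gaussian synthetic trajectory.

    Parameters
    ----------
    n_frames : int
        Number of frames to generate (>= 1).
    residues : sequence of (residue_id, sigma, mean_position)
        One entry per residue: integer id (strictly increasing), the
        per-coordinate fluctuation standard deviation in A (>= 0), and the
        3-vector mean position of the residue in A.
    backbone_atoms_per_residue : int
        Atoms generated per residue (default 4: N, CA, C, O).
    seed : int
        Seed for the generator; identical spec + seed gives bit-identical
        coordinates.
    """

    n_frames: int
    residues: Sequence[tuple[int, float, Sequence[float]]]
    backbone_atoms_per_residue: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_frames >= 1, "n_frames", "must be >= 1")
        _require(len(self.residues) >= 1, "residues", "must be non-empty")
        _require(
            self.backbone_atoms_per_residue >= 1,
            "backbone_atoms_per_residue",
            "must be >= 1",
        )
        ids = [int(r[0]) for r in self.residues]
        _require(
            all(b > a for a, b in zip(ids, ids[1:])),
            "residues",
            "residue_ids must be unique and strictly increasing",
        )
        for rid, sigma, mean in self.residues:
            _require(float(sigma) >= 0.0, "residues", f"sigma < 0 for residue {rid}")
            _require(
                len(np.asarray(mean, dtype=float).ravel()) == 3,
                "residues",
                f"mean_position of residue {rid} is not a 3-vector",
            )


def gen_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Generate a trajectory with i.i.d. Gaussian atomic displacements.

    Each atom of residue *r* fluctuates independently around its mean
    position with per-coordinate standard deviation ``sigma_r``, so the
    population RMSF of every atom of that residue is ``sigma_r * sqrt(3)``.
    """
    rng = np.random.default_rng(spec.seed)
    n_res = len(spec.residues)
    n_atoms = n_res * spec.backbone_atoms_per_residue

    sigmas = np.empty(n_atoms)
    means = np.empty((n_atoms, 3))
    meta_rows = []
    k = 0
    for rid, sigma, mean in spec.residues:
        base = np.asarray(mean, dtype=float).ravel()
        for a in range(spec.backbone_atoms_per_residue):
            name = _BACKBONE_NAMES[a % 4]
            means[k] = base + _BACKBONE_OFFSETS[a % 4] + np.array([0.0, 0.0, 3.0]) * (a // 4)
            sigmas[k] = float(sigma)
            meta_rows.append(
                {
                    "residue_id": int(rid),
                    "residue_name": "ALA",
                    "atom_name": name,
                    "is_backbone": name in _BACKBONE_NAMES,
                }
            )
            k += 1

    noise = rng.standard_normal((spec.n_frames, n_atoms, 3))
    coords = means[None, :, :] + sigmas[None, :, None] * noise
    atom_meta = pd.DataFrame(meta_rows)
    return Trajectory(coordinates=coords, atom_meta=atom_meta)


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic kinases x columns fluctuation panel.

    The defaults encode the study regime this generator emulates: a panel of
    43 tyrosine kinases over 223 shared alignment columns, where inactive
    kinases are more flexible than active ones at one signal residue
    (class means 1.3 vs 0.6 A, within-class sd 0.18 A) and the three columns
    following the signal column are correlated with it at rho = 0.95, the
    way the residues downstream of the DFG motif co-fluctuate with DFG+3.

    All RMSF draws are truncated at 0 (a fluctuation cannot be negative).
    """

    n_active: int = 20
    n_inactive: int = 23
    n_columns: int = 223
    signal_column: int = 150
    mu_active: float = 0.6
    mu_inactive: float = 1.3
    sigma_within: float = 0.18
    background_mu: float = 1.0
    background_sigma: float = 0.25
    corr_block: tuple[int, ...] = (151, 152, 153)
    rho: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_active >= 0 and self.n_inactive >= 0, "n_active", "counts must be >= 0")
        _require(
            self.n_active + self.n_inactive >= 4,
            "n_active",
            "panel too small to split (need n_active + n_inactive >= 4)",
        )
        _require(self.n_columns >= 1, "n_columns", "must be >= 1")
        _require(
            0 <= self.signal_column < self.n_columns,
            "signal_column",
            f"must lie in [0, {self.n_columns})",
        )
        for c in self.corr_block:
            _require(0 <= c < self.n_columns, "corr_block", f"column {c} out of range")
            _require(c != self.signal_column, "corr_block", "cannot include the signal column")
        _require(0.0 <= self.rho <= 1.0, "rho", "must lie in [0, 1]")
        _require(self.sigma_within >= 0, "sigma_within", "must be >= 0")
        _require(self.background_sigma >= 0, "background_sigma", "must be >= 0")
        # Inactive kinases are the more flexible class; equality is allowed so
        # that null panels (no class signal) can be generated for calibration.
        _require(
            self.mu_inactive >= self.mu_active,
            "mu_inactive",
            "inactive kinases must be at least as flexible (mu_inactive >= mu_active)",
        )


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float, size) -> np.ndarray:
    """Draw from a normal truncated at 0 (RMSF values are non-negative)."""
    if sigma == 0:
        return np.full(size, max(mu, 0.0))
    a = (0.0 - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=size, random_state=rng)


def gen_fluctuation_panel(spec: PanelSpec):
    """Generate a fluctuation matrix and activity labels with a planted rule.

    Returns
    -------
    (FluctuationMatrix, labels)
        The matrix has ``n_active + n_inactive`` rows (actives first) and
        ``n_columns`` columns; ``labels`` is the matrix's label Series
        (values ``active`` / ``inactive``), returned separately as a
        convenience.
    """
    from kinoflex.alignment import FluctuationMatrix

    rng = np.random.default_rng(spec.seed)
    n = spec.n_active + spec.n_inactive
    labels = np.array(["active"] * spec.n_active + ["inactive"] * spec.n_inactive)

    X = _truncated_normal(rng, spec.background_mu, spec.background_sigma, (n, spec.n_columns))

    sig = np.empty(n)
    sig[: spec.n_active] = _truncated_normal(
        rng, spec.mu_active, spec.sigma_within, spec.n_active
    )
    sig[spec.n_active:] = _truncated_normal(
        rng, spec.mu_inactive, spec.sigma_within, spec.n_inactive
    )
    X[:, spec.signal_column] = sig

    if spec.corr_block:
        z = (sig - sig.mean()) / (sig.std() if sig.std() > 0 else 1.0)
        for c in spec.corr_block:
            eps = rng.standard_normal(n)
            mixed = spec.rho * z + np.sqrt(1.0 - spec.rho**2) * eps
            X[:, c] = np.clip(spec.background_mu + spec.background_sigma * mixed, 0.0, None)

    row_ids = [
        f"KIN{i + 1:03d}-1_{'a' if lab == 'active' else 'i'}" for i, lab in enumerate(labels)
    ]
    values = pd.DataFrame(X, index=row_ids, columns=list(range(spec.n_columns)))
    fm = FluctuationMatrix(values=values, labels=pd.Series(labels, index=row_ids, name="label"))
    return fm, fm.labels


@dataclass(frozen=True)
class PocketSimSpec:
    """Specification of a synthetic pocket event stream.

    ``volume_mu`` / ``volume_sigma`` are the log-space parameters of the
    per-pocket lognormal volume (A^3): a pocket present in a frame has volume
    ``exp(Normal(volume_mu, volume_sigma))``. ``presence_prob`` is the
    per-frame detection probability, and ``link_rate[i, j]`` the expected
    number of merge events (and, independently, split events) recorded as the
    ordered pair (i, j) per frame. Defaults place pockets around the
    ~500-600 A^3 scale typical of the kinase ATP site, always-on detection,
    and a uniform low link rate.
    """

    n_frames: int = 5000
    pocket_names: tuple[str, ...] = DEFAULT_POCKET_NAMES
    volume_mu: tuple[float, ...] | float = float(np.log(550.0))
    volume_sigma: tuple[float, ...] | float = 0.4
    presence_prob: tuple[float, ...] | float = 0.9
    link_rate: float | np.ndarray = 0.005
    frame_spacing_ps: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_frames >= 1, "n_frames", "must be >= 1")
        _require(len(self.pocket_names) >= 1, "pocket_names", "must be non-empty")
        _require(
            len(set(self.pocket_names)) == len(self.pocket_names),
            "pocket_names",
            "must be unique",
        )
        p = np.broadcast_to(np.asarray(self.presence_prob, dtype=float), (self.n_pockets,))
        _require(bool(np.all((p >= 0) & (p <= 1))), "presence_prob", "must lie in [0, 1]")
        rates = self.link_rate_matrix()
        _require(bool(np.all(rates >= 0)), "link_rate", "rates must be >= 0")
        sig = np.broadcast_to(np.asarray(self.volume_sigma, dtype=float), (self.n_pockets,))
        _require(bool(np.all(sig >= 0)), "volume_sigma", "must be >= 0")

    @property
    def n_pockets(self) -> int:
        return len(self.pocket_names)

    def link_rate_matrix(self) -> np.ndarray:
        """Per-ordered-pair event rate matrix with a zero diagonal."""
        m = np.broadcast_to(
            np.asarray(self.link_rate, dtype=float), (self.n_pockets, self.n_pockets)
        ).copy()
        np.fill_diagonal(m, 0.0)
        return m


def gen_pocket_events(spec: PocketSimSpec) -> PocketEventLog:
    """Generate a pocket event log with known presence, volume and link rates."""
    rng = np.random.default_rng(spec.seed)
    P = spec.n_pockets
    names = spec.pocket_names

    prob = np.broadcast_to(np.asarray(spec.presence_prob, dtype=float), (P,))
    mu = np.broadcast_to(np.asarray(spec.volume_mu, dtype=float), (P,))
    sig = np.broadcast_to(np.asarray(spec.volume_sigma, dtype=float), (P,))

    present = rng.random((spec.n_frames, P)) < prob[None, :]
    volumes = np.exp(mu[None, :] + sig[None, :] * rng.standard_normal((spec.n_frames, P)))
    volumes = np.where(present, volumes, 0.0)

    rates = spec.link_rate_matrix()
    merge_counts = rng.poisson(rates[None, :, :], size=(spec.n_frames, P, P))
    split_counts = rng.poisson(rates[None, :, :], size=(spec.n_frames, P, P))

    def _events(counts_f: np.ndarray) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        for i, j in zip(*np.nonzero(counts_f)):
            out.extend([(names[i], names[j])] * int(counts_f[i, j]))
        return out

    merges = [_events(merge_counts[f]) for f in range(spec.n_frames)]
    splits = [_events(split_counts[f]) for f in range(spec.n_frames)]

    return PocketEventLog(
        pocket_names=names,
        volumes=volumes,
        merges=merges,
        splits=splits,
        frame_spacing_ps=spec.frame_spacing_ps,
    )
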