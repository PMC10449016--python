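"""Trajectory-analysis operators: MSD, rotational correlation, tail order.

These are the observables used to assign physical origins to the
quasi-elastic modes: the mean-square displacement distinguishes
whole-molecule translation from localized motion (Einstein relation
MSD = 6 D t in 3-D), the first-rank orientational autocorrelation
⟨cos θ(t)⟩ of a named intramolecular vector decays as exp(−2 D_r t) for
isotropic rotational diffusion, and the acyl-tail order parameter
S = ⟨(3 cos²β − 1)/2⟩ tracks the gel → liquid-crystalline transition.

Operators take a :class:`Trajectory` — time-ordered coordinates with
atom labels and named groups — and average over all time origins
(stride configurable).  They work equally on synthetic Brownian
trajectories and on user-supplied unwrapped MD output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Trajectory",
    "VectorSpec",
    "msd",
    "rotational_correlation",
    "tail_order",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "default_lag_grid",
]


@dataclass
class Trajectory:
    """Time-ordered coordinates (Å) with labels, groups and fixed time step.

    ``groups`` maps a name (e.g. ``"P"``, ``"N"``, ``"headgroup-H"``) to
    atom indices, ordered consistently per molecule so that the i-th
    entry of two groups belongs to the same molecule.  ``wrapped`` marks
    coordinates folded into the periodic box; translational observables
    then require ``box`` metadata to unwrap.
    """

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    dt: float  # ps per frame
    labels: list[str]
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    mol_index: np.ndarray | None = None
    box: np.ndarray | None = None  # orthorhombic extents (3,) or None
    wrapped: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n_atoms = self.coords.shape[1]
        if len(self.labels) != n_atoms:
            raise ValueError("one label per atom required")
        for name, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n_atoms):
                raise ValueError(f"group {name!r} references invalid atoms")
            self.groups[name] = idx

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def group(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise KeyError(
                f"unknown group {name!r}; available: {sorted(self.groups)}"
            )
        return self.groups[name]

    def unwrapped_coords(self) -> np.ndarray:
        """Coordinates with periodic jumps removed (minimum-image accumulation)."""
        if not self.wrapped:
            return self.coords
        if self.box is None:
            raise ValueError(
                "coordinates are wrapped but no box metadata is available"
            )
        box = np.asarray(self.box, dtype=float)
        disp = np.diff(self.coords, axis=0)
        disp -= box * np.round(disp / box)
        out = np.empty_like(self.coords)
        out[0] = self.coords[0]
        out[1:] = self.coords[0] + np.cumsum(disp, axis=0)
        return out


@dataclass
class VectorSpec:
    """Intramolecular vector definition: tail group → head group, per molecule.

    The i-th atom of ``tail_group`` pairs with the i-th atom of
    ``head_group`` (e.g. P→N for the headgroup director, N→H for amine
    hydrogens).  Vectors are normalized before any correlation.
    """

    tail_group: str
    head_group: str

    def unit_vectors(self, traj: Trajectory) -> np.ndarray:
        """(n_frames, n_vectors, 3) unit vectors; errors name the offender."""
        tail = traj.group(self.tail_group)
        head = traj.group(self.head_group)
        if tail.size != head.size or tail.size == 0:
            raise ValueError(
                f"groups {self.tail_group!r}/{self.head_group!r} must pair "
                "one atom per molecule"
            )
        v = traj.coords[:, head, :] - traj.coords[:, tail, :]
        norm = np.linalg.norm(v, axis=2)
        bad = np.argwhere(norm == 0.0)
        if bad.size:
            f, m = bad[0]
            raise ValueError(
                f"zero-length {self.tail_group}->{self.head_group} vector "
                f"for molecule {m} at frame {f}"
            )
        return v / norm[:, :, None]


def default_lag_grid(n_frames: int, n_lags: int = 50) -> np.ndarray:
    """Log-spaced lag frames from 1 to n_frames − 1 (unique, sorted)."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    lags = np.unique(
        np.round(np.geomspace(1, n_frames - 1, n_lags)).astype(int)
    )
    return lags


def msd(
    traj: Trajectory,
    group: str,
    lags: np.ndarray | None = None,
    stride: int = 1,
    remove_drift: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-square displacement ⟨|r(t+τ) − r(t)|²⟩ in Å² vs τ in ps.

    Averages over all time origins (with the given stride) and all atoms
    of the group.  Coordinates must be unwrapped; wrapped trajectories
    are unwrapped through their box metadata.  ``remove_drift``
    subtracts the group's centre-of-mass path first (off by default).
    Returns (times_ps, msd) with MSD(0) = 0 prepended.
    """
    if traj.n_frames < 2:
        raise ValueError("MSD needs at least 2 frames")
    coords = traj.unwrapped_coords()[:, traj.group(group), :]
    if remove_drift:
        coords = coords - coords.mean(axis=1, keepdims=True)
    if lags is None:
        lags = default_lag_grid(traj.n_frames)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 1) or np.any(lags >= traj.n_frames):
        raise ValueError("lags must lie in [1, n_frames)")
    out = np.empty(lags.size)
    for i, lag in enumerate(lags):
        d = (coords[lag:] - coords[:-lag])[::stride]
        out[i] = np.mean(np.sum(d * d, axis=2))
    times = np.concatenate([[0.0], lags * traj.dt])
    return times, np.concatenate([[0.0], out])


def rotational_correlation(
    traj: Trajectory,
    spec: VectorSpec,
    lags: np.ndarray | None = None,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """First-rank orientational autocorrelation ⟨cos θ(τ)⟩ vs τ in ps.

    cos θ(τ) is the dot product of the molecule's unit vector at a time
    origin and at lag τ, averaged over molecules and origins.  The value
    at τ = 0 is exactly 1.
    """
    u = spec.unit_vectors(traj)
    if lags is None:
        lags = default_lag_grid(traj.n_frames)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 1) or np.any(lags >= traj.n_frames):
        raise ValueError("lags must lie in [1, n_frames)")
    out = np.empty(lags.size)
    for i, lag in enumerate(lags):
        dots = np.sum(u[lag:] * u[:-lag], axis=2)[::stride]
        out[i] = np.mean(dots)
    times = np.concatenate([[0.0], lags * traj.dt])
    return times, np.concatenate([[1.0], out])


def tail_order(
    traj: Trajectory,
    carbon_groups: list[str],
    normal_axis: np.ndarray | None = None,
    convention: str = "cc",
    hydrogen_groups: list[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Acyl-tail order parameters S = ⟨(3 cos²β − 1)/2⟩ per carbon.

    β is the angle between the chosen tail vector and the bilayer
    normal.  ``convention="cc"`` (default) uses successive-carbon
    vectors C_i → C_{i+1}; ``convention="ch"`` uses C_i → H_i vectors
    (an S_CD-style definition) and then needs ``hydrogen_groups``
    aligned with ``carbon_groups``.  Returns per-carbon S and the chain
    mean.  S = 1 for all-trans chains parallel to the normal (C→C
    convention); S = 0 for isotropic orientations.
    """
    if normal_axis is None:
        raise ValueError("bilayer normal axis must be specified")
    normal = np.asarray(normal_axis, dtype=float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ValueError("bilayer normal axis must be non-zero")
    normal = normal / nn
    if convention not in ("cc", "ch"):
        raise ValueError("convention must be 'cc' or 'ch'")
    if convention == "cc":
        if len(carbon_groups) < 2:
            raise ValueError("C→C convention needs at least two carbon groups")
        pairs = [
            (carbon_groups[i], carbon_groups[i + 1])
            for i in range(len(carbon_groups) - 1)
        ]
    else:
        if hydrogen_groups is None or len(hydrogen_groups) != len(carbon_groups):
            raise ValueError("C–H convention needs one hydrogen group per carbon")
        pairs = list(zip(carbon_groups, hydrogen_groups))
    s_values = np.empty(len(pairs))
    for i, (a, b) in enumerate(pairs):
        u = VectorSpec(a, b).unit_vectors(traj)
        cos_b = u @ normal
        s_values[i] = np.mean(1.5 * cos_b**2 - 0.5)
    return s_values, float(np.mean(s_values))


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write extended-XYZ-style frames; comment line carries time metadata.

    Each atom row is ``label x y z group mol`` so that group assignments
    round-trip through the file.
    """
    path = Path(path)
    # inverse group map: atom index → group name (first group that has it)
    atom_group = ["-"] * traj.n_atoms
    for name, idx in traj.groups.items():
        for a in idx:
            atom_group[int(a)] = name
    mols = (
        traj.mol_index
        if traj.mol_index is not None
        else np.zeros(traj.n_atoms, dtype=int)
    )
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            box = (
                " box=" + ",".join(f"{b:g}" for b in traj.box)
                if traj.box is not None
                else ""
            )
            fh.write(f"time={f * traj.dt:g} dt={traj.dt:g}{box}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a]
                fh.write(
                    f"{traj.labels[a]} {x:.6f} {y:.6f} {z:.6f} "
                    f"{atom_group[a]} {int(mols[a])}\n"
                )


def read_xyz_trajectory(path: str | Path, dt: float | None = None) -> Trajectory:
    """Read the extended-XYZ-style format written by :func:`write_xyz_trajectory`."""
    path = Path(path)
    frames: list[np.ndarray] = []
    labels: list[str] = []
    groups_raw: list[str] = []
    mols: list[int] = []
    box = None
    file_dt = None
    with path.open() as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n_atoms = int(head)
            comment = fh.readline()
            for tok in comment.split():
                if tok.startswith("dt="):
                    file_dt = float(tok[3:])
                elif tok.startswith("box="):
                    box = np.array([float(v) for v in tok[4:].split(",")])
            coords = np.empty((n_atoms, 3))
            first_frame = not frames
            for a in range(n_atoms):
                parts = fh.readline().split()
                coords[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
                if first_frame:
                    labels.append(parts[0])
                    groups_raw.append(parts[4] if len(parts) > 4 else "-")
                    mols.append(int(parts[5]) if len(parts) > 5 else 0)
            frames.append(coords)
    groups: dict[str, list[int]] = {}
    for a, g in enumerate(groups_raw):
        if g != "-":
            groups.setdefault(g, []).append(a)
    return Trajectory(
        coords=np.stack(frames),
        dt=dt if dt is not None else (file_dt or 1.0),
        labels=labels,
        groups={k: np.array(v) for k, v in groups.items()},
        mol_index=np.array(mols),
        box=box,
    )
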