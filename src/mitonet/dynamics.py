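"""Trajectory summary statistics for wild-type vs mutant complex comparison.

Implements the standard least-squares rigid superposition (Kabsch fit with
a proper-rotation constraint), per-frame RMSD against a reference frame,
per-atom RMSF about the iteratively refined average structure, and
essential dynamics — PCA of the atomic positional covariance, whose leading
eigenvectors describe the collective motions.

Trajectories are plain tabular files (frame, atom, x, y, z) in Å; binary MD
formats are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class GeometryError(ValueError):
    """Degenerate configuration: too few or collinear atoms."""


@dataclass(frozen=True)
class Trajectory:
    """frames x atoms x 3 Cartesian coordinates in Å."""

    coordinates: np.ndarray
    frame_times: np.ndarray | None = None
    atom_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        c = self.coordinates
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if not np.isfinite(c).all():
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


def read_trajectory(path) -> Trajectory:
    """Read a (frame, atom, x, y, z) whitespace/CSV table."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"frame", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"trajectory table missing columns: {sorted(required - set(df.columns))}"
        )
    frames = np.sort(df["frame"].unique())
    atoms = np.sort(df["atom"].unique())
    df = df.sort_values(["frame", "atom"])
    coords = df[["x", "y", "z"]].to_numpy(float).reshape(
        len(frames), len(atoms), 3
    )
    return Trajectory(coordinates=coords)


def write_trajectory(traj: Trajectory, path) -> None:
    rows = []
    for f in range(traj.n_frames):
        for a in range(traj.n_atoms):
            x, y, z = traj.coordinates[f, a]
            rows.append((f, a, x, y, z))
    pd.DataFrame(rows, columns=["frame", "atom", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False
    )


def kabsch_superpose(
    reference: np.ndarray, mobile: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid fit of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to the
    reference.  The rotation is proper (det = +1).
    """
    reference = np.asarray(reference, float)
    mobile = np.asarray(mobile, float)
    if reference.shape != mobile.shape or reference.ndim != 2:
        raise GeometryError("structures must share an (atoms, 3) shape")
    n = reference.shape[0]
    if n < 3:
        raise GeometryError("superposition requires at least 3 atoms")
    ref_mean = reference.mean(axis=0)
    mob_mean = mobile.mean(axis=0)
    ref_c = reference - ref_mean
    mob_c = mobile - mob_mean
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise GeometryError("reference atoms are collinear or coincident")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_mean - rotation @ mob_mean
    fitted = mob_c @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_c) ** 2, axis=1))))
    return rotation, translation, rmsd


def rmsd_series(traj: Trajectory, reference_frame: int = 0) -> np.ndarray:
    """Per-frame RMSD (Å) after optimal superposition to a reference frame."""
    if not 0 <= reference_frame < traj.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    ref = traj.coordinates[reference_frame]
    series = np.array(
        [kabsch_superpose(ref, frame)[2] for frame in traj.coordinates]
    )
    series[reference_frame] = 0.0
    return series


def _superpose_to_average(coords: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Superpose all frames onto an iteratively refined average structure."""
    fitted = coords.copy()
    reference = fitted[0]
    for _ in range(n_iter):
        for f in range(fitted.shape[0]):
            rot, trans, _ = kabsch_superpose(reference, fitted[f])
            fitted[f] = fitted[f] @ rot.T + trans
        reference = fitted.mean(axis=0)
    return fitted


def rmsf(traj: Trajectory) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) about the mean structure.

    Frames are first superposed onto the average structure (two refinement
    iterations), removing global rigid motion.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least two frames")
    fitted = _superpose_to_average(traj.coordinates)
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


def essential_dynamics(
    traj: Trajectory, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the 3N-dimensional positional covariance.

    Returns (eigenvalues Å^2, eigenvectors (3N, k), projections (frames, k)).
    Eigenvalues are non-negative, in descending order, and sum to the total
    coordinate variance of the superposed trajectory.
    """
    n3 = 3 * traj.n_atoms
    if not 1 <= n_components <= n3:
        raise ValueError(f"n_components must be in [1, {n3}]")
    if traj.n_frames < 2:
        raise ValueError("PCA requires at least two frames")
    fitted = _superpose_to_average(traj.coordinates)
    flat = fitted.reshape(traj.n_frames, n3)
    centered = flat - flat.mean(axis=0)
    covariance = centered.T @ centered / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(covariance)
    order = np.argsort(evals)[::-1]
    eigenvalues = np.clip(evals[order], 0.0, None)[:n_components]
    eigenvectors = evecs[:, order][:, :n_components]
    projections = centered @ eigenvectors
    return eigenvalues, eigenvectors, projections


def summary_frame(traj: Trajectory, n_components: int = 2) -> dict:
    """RMSD series, RMSF and leading eigenvalues as plain tables."""
    evals, _, projections = essential_dynamics(traj, n_components)
    return {
        "rmsd": pd.DataFrame(
            {"frame": np.arange(traj.n_frames), "rmsd": rmsd_series(traj)}
        ),
        "rmsf": pd.DataFrame(
            {"atom": np.arange(traj.n_atoms), "rmsf": rmsf(traj)}
        ),
        "eigenvalues": pd.DataFrame(
            {"component": np.arange(1, len(evals) + 1), "eigenvalue": evals}
        ),
        "projections": pd.DataFrame(
            projections,
            columns=[f"pc{k + 1}" for k in range(projections.shape[1])],
        ),
    }
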