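"""Essential-dynamics (Cartesian PCA) analysis of protein trajectories.

The 3N x 3N covariance matrix of N selected atom positions (C-alpha by
convention, mass-unweighted) is built from superposed frames and
diagonalised. The leading eigenvectors span the *essential subspace*: the
directions of largest collective positional fluctuation. Frames are
projected onto modes, and per-atom RMSF is computed on the trajectory
filtered through a single mode to localise the collective motion.

All covariances and variances here are population statistics (ddof=0), so
the PCA identities (projection variance = eigenvalue, eigenvalue sum =
covariance trace) hold exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import Frame, Selection, Trajectory

__all__ = [
    "EssentialSubspace",
    "ModeProjection",
    "superpose",
    "build_subspace",
    "project",
    "variance_fraction",
    "rmsf_along_mode",
]


@dataclass
class EssentialSubspace:
    selection: Selection
    mean_structure: np.ndarray  # (3N,) nm
    eigenvectors: np.ndarray  # (3N, 3N), columns are modes, orthonormal
    eigenvalues: np.ndarray  # (3N,) nm^2, descending, >= 0
    total_variance: float  # nm^2 (= trace of the covariance)

    @property
    def n_atoms(self) -> int:
        return len(self.selection)


@dataclass
class ModeProjection:
    """Per-frame scalar coordinates (nm) along chosen modes."""

    coordinates: np.ndarray  # (n_frames, n_modes)
    modes: np.ndarray  # mode indices
    labels: np.ndarray  # per-frame source label (condition/trajectory)


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and centroids aligning mobile onto target.

    Minimises sum |R (x - xc) - (y - yc)|^2 over proper rotations (no
    reflection: det R = +1 enforced).
    """
    xc = mobile.mean(axis=0)
    yc = target.mean(axis=0)
    C = (target - yc).T @ (mobile - xc)
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return R, xc, yc


def superpose(traj: Trajectory, sel: Selection, reference: Frame) -> Trajectory:
    """Rigid-body least-squares fit of every frame onto a reference.

    The rotation/translation is determined on the selection and applied to
    all atoms. Reflections are never applied, so mirror-image conformations
    retain a positive RMSD.
    """
    idx = sel.indices
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    ref = reference.coordinates[idx]
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise ValueError("selected reference atoms are collinear; rotation under-determined")

    new_frames = []
    for f in traj.frames:
        R, xc, yc = _kabsch(f.coordinates[idx], ref)
        coords = (f.coordinates - xc) @ R.T + yc
        new_frames.append(Frame(coordinates=coords, box=None, time=f.time))
    return Trajectory(traj.topology, new_frames, superposed=True)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: largest-|component| made positive."""
    out = vecs.copy()
    for m in range(out.shape[1]):
        col = out[:, m]
        i = int(np.argmax(np.abs(col)))  # argmax returns the lowest index on ties
        if col[i] < 0:
            out[:, m] = -col
    return out


def build_subspace(trajs: list[Trajectory] | Trajectory, sel: Selection) -> EssentialSubspace:
    """Covariance of the concatenated selected coordinates, diagonalised.

    Frames must already be superposed; all trajectories share one topology.
    Eigenvalues are sorted descending and clipped at zero (symmetric
    round-off only).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("no trajectories given")
    top = trajs[0].topology
    for t in trajs[1:]:
        if t.topology is not top and t.topology.n_atoms != top.n_atoms:
            raise ValueError("all trajectories must share the topology")
    X = np.concatenate([t.coordinate_array(sel.indices) for t in trajs])  # (F, N, 3)
    F = X.shape[0]
    if F < 2:
        raise ValueError("covariance needs at least 2 frames")
    X = X.reshape(F, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    C = (Xc.T @ Xc) / F
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    return EssentialSubspace(
        selection=sel,
        mean_structure=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        total_variance=float(np.trace(C)),
    )


def project(
    traj: Trajectory,
    sub: EssentialSubspace,
    modes: list[int] | np.ndarray,
    label: str = "",
) -> ModeProjection:
    """Scalar coordinates of each frame along the chosen modes."""
    modes = np.atleast_1d(np.asarray(modes, dtype=int))
    dim = sub.eigenvectors.shape[1]
    if np.any(modes < 0) or np.any(modes >= dim):
        raise IndexError(f"mode indices must lie in [0, {dim})")
    if not traj.superposed:
        warnings.warn(
            "projecting a trajectory that was not superposed; rigid-body motion "
            "will leak into the mode coordinates",
            stacklevel=2,
        )
    X = traj.coordinate_array(sub.selection.indices).reshape(traj.n_frames, -1)
    coords = (X - sub.mean_structure) @ sub.eigenvectors[:, modes]
    return ModeProjection(
        coordinates=coords,
        modes=modes,
        labels=np.full(traj.n_frames, label, dtype=object),
    )


def variance_fraction(sub: EssentialSubspace, k: int) -> float:
    """Fraction of total positional variance captured by the first k modes."""
    n = sub.eigenvalues.size
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    total = sub.eigenvalues.sum()
    if total == 0:
        return 0.0
    return float(sub.eigenvalues[:k].sum() / total)


def rmsf_along_mode(traj: Trajectory, sub: EssentialSubspace, mode: int) -> np.ndarray:
    """Per-atom RMSF (nm) of the trajectory filtered through one mode.

    The filtered trajectory is x_f(t) = mean + p_m(t) v_m, so each atom's
    fluctuation is std(p_m) times the length of its 3-vector block of v_m.
    """
    p = project(traj, sub, [mode]).coordinates[:, 0]
    v = sub.eigenvectors[:, mode].reshape(-1, 3)
    return float(np.std(p)) * np.linalg.norm(v, axis=1)
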