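"""Convert TLS tensors into explicit structural ensembles.

A TLS group describes rigid-body disorder through three tensors: L (rad^2)
is the covariance of a small rotation ("libration") vector, T (A^2) the
covariance of a translation ("vibration") vector, and S (A*rad) their
cross-covariance.  To draw real-space snapshots the tensors are first
decomposed into independent motional axes:

* libration axes and variances: the eigensystem of L;
* screw pitches ``c_k = S_kk / L_kk`` and libration-axis offset points, read
  off the rows of S expressed in the libration eigenframe;
* vibration axes and variances: the eigensystem of the residual
  ``T - C_lib``, where C_lib is the translation covariance already induced
  by librations about displaced, pitched axes.

Each snapshot then composes three exact finite rotations (one per libration
axis, through its offset point, with its screw translation) with an
independent Gaussian vibration.  In the small-angle limit the per-atom
displacement covariance recovers the closed-form anisotropic displacement
tensor ``U(r) = T + A L A' + A S + S' A'`` (see :func:`uij_from_tls`), which
serves as the oracle for the sampler.

Besides independent sampling, deterministic "parallel"/"antiparallel"
stepping of two groups along their motional axes is provided to model
correlated inter-group motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Ensemble, Model, TLSGroup, UnitCell, validate_tls

__all__ = [
    "RigidBodyDisplacement",
    "TLSSampler",
    "CorrelationMode",
    "decompose_tls",
    "sample_displacement",
    "sample_rigid_motions",
    "generate_ensemble",
    "uij_from_tls",
]

#: residual vibration variances down to this value (A^2) are clamped to zero
VIB_CLAMP = 1e-6

_EPS_L = 1e-14  # rad^2 below which a libration axis is treated as inactive


class NonPhysicalTLSError(ValueError):
    """Raised when sampling is requested for a group failing validate_tls."""


def _skew(d: np.ndarray) -> np.ndarray:
    """Matrix A with A @ omega = omega x d (for the ADP formula)."""
    dx, dy, dz = d
    return np.array([[0.0, dz, -dy],
                     [-dz, 0.0, dx],
                     [dy, -dx, 0.0]])


def uij_from_tls(group: TLSGroup, position: np.ndarray) -> np.ndarray:
    """Closed-form anisotropic displacement tensor U(r) in A^2.

    ``U(r) = T + A L A' + A S + S' A'`` with A the skew matrix of
    ``r - origin``; this is the exact displacement covariance of the TLS
    model in the linear (small-libration) regime.
    """
    d = np.asarray(position, dtype=float) - group.origin
    A = _skew(d)
    U = group.T + A @ group.L @ A.T + A @ group.S + group.S.T @ A.T
    return 0.5 * (U + U.T)


@dataclass
class RigidBodyDisplacement:
    """A proper rigid motion: x' = R (x - center) + center + translation."""

    rotation_vector: np.ndarray  # axis-angle, rad
    rotation_center: np.ndarray  # A
    translation: np.ndarray      # A

    def apply(self, coords: np.ndarray) -> np.ndarray:
        R = Rotation.from_rotvec(self.rotation_vector).as_matrix()
        c = self.rotation_center
        return (np.asarray(coords, float) - c) @ R.T + c + self.translation


@dataclass
class TLSSampler:
    """Decomposed TLS group ready for real-space sampling.

    Axes are stored as rows.  ``axis_offsets[k]`` is a point the k-th
    libration axis passes through; ``screw_pitches[k]`` is the translation
    per radian along that axis.
    """

    group: TLSGroup
    libration_axes: np.ndarray       # (3, 3), orthonormal rows
    libration_variances: np.ndarray  # (3,), rad^2
    screw_pitches: np.ndarray        # (3,), A/rad
    axis_offsets: np.ndarray         # (3, 3), points in A
    vibration_axes: np.ndarray       # (3, 3), orthonormal rows
    vibration_variances: np.ndarray  # (3,), A^2

    def reassemble(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Rebuild (T, L, S) from the decomposition (self-consistency check)."""
        L = np.zeros((3, 3))
        S = np.zeros((3, 3))
        C_lib = np.zeros((3, 3))
        for k in range(3):
            lk = self.libration_axes[k]
            var = self.libration_variances[k]
            a_k = self.screw_pitches[k] * lk - np.cross(lk, self.axis_offsets[k] - self.group.origin)
            L += var * np.outer(lk, lk)
            S += var * np.outer(lk, a_k)
            C_lib += var * np.outer(a_k, a_k)
        V = (self.vibration_axes.T * self.vibration_variances) @ self.vibration_axes
        T = V + C_lib
        return T, L, S


def decompose_tls(group: TLSGroup, vib_clamp: float = VIB_CLAMP) -> TLSSampler:
    """Decompose a physical TLS group into sampling axes.

    Raises :class:`NonPhysicalTLSError` if T or L has a negative eigenvalue
    (run :func:`~tlsdiffuse.structures.validate_tls` first to see details).
    If the libration-induced translation covariance slightly exceeds T, the
    (small) negative residual vibration variances are clamped to zero;
    residuals below ``-vib_clamp`` raise.
    """
    report = validate_tls(group)
    if not report.is_physical:
        raise NonPhysicalTLSError(
            "TLS group is not physical; validate_tls reports: "
            + "; ".join(report.messages))

    l_vals, l_vecs = np.linalg.eigh(group.L)      # ascending
    order = np.argsort(l_vals)[::-1]
    l_vals = np.maximum(l_vals[order], 0.0)
    P = l_vecs[:, order].T                        # rows = libration axes
    if np.linalg.det(P) < 0:
        P[2] = -P[2]

    S_hat = P @ group.S @ P.T
    pitches = np.zeros(3)
    w_hat = np.zeros((3, 3))  # offsets in the eigenframe, zero k-component
    for k in range(3):
        if l_vals[k] > _EPS_L:
            pitches[k] = S_hat[k, k] / l_vals[k]
        elif abs(S_hat[k, k]) > 1e-12:
            warnings.warn(
                f"screw element S_{k}{k} dropped: libration variance is zero",
                stacklevel=2)
    if l_vals[0] > _EPS_L:
        w_hat[0, 1] = -S_hat[0, 2] / l_vals[0]
        w_hat[0, 2] = S_hat[0, 1] / l_vals[0]
    if l_vals[1] > _EPS_L:
        w_hat[1, 0] = S_hat[1, 2] / l_vals[1]
        w_hat[1, 2] = -S_hat[1, 0] / l_vals[1]
    if l_vals[2] > _EPS_L:
        w_hat[2, 0] = -S_hat[2, 1] / l_vals[2]
        w_hat[2, 1] = S_hat[2, 0] / l_vals[2]
    w_lab = w_hat @ P  # each row back to the lab frame

    C_lib = np.zeros((3, 3))
    for k in range(3):
        a_k = pitches[k] * P[k] - np.cross(P[k], w_lab[k])
        C_lib += l_vals[k] * np.outer(a_k, a_k)
    V = group.T - C_lib
    V = 0.5 * (V + V.T)
    v_vals, v_vecs = np.linalg.eigh(V)
    if v_vals.min() < -vib_clamp:
        raise NonPhysicalTLSError(
            f"screw/offset translation covariance exceeds T: residual "
            f"vibration variance {v_vals.min():.3e} A^2")
    v_order = np.argsort(v_vals)[::-1]
    v_vals = np.maximum(v_vals[v_order], 0.0)
    Q = v_vecs[:, v_order].T
    if np.linalg.det(Q) < 0:
        Q[2] = -Q[2]

    return TLSSampler(
        group=group,
        libration_axes=P,
        libration_variances=l_vals,
        screw_pitches=pitches,
        axis_offsets=group.origin + w_lab,
        vibration_axes=Q,
        vibration_variances=v_vals,
    )


def _motions_from_draws(
    sampler: TLSSampler,
    thetas: np.ndarray,       # (n, 3) libration angles, rad
    vib_coords: np.ndarray,   # (n, 3) vibration amplitudes along vibration axes, A
) -> tuple[np.ndarray, np.ndarray]:
    """Compose exact finite screw rotations + vibration into affine maps.

    Returns (R, b) with x' = R @ x + b, shapes (n, 3, 3) and (n, 3).
    Rotations are composed in fixed axis order 3rd..1st; the order only
    affects terms beyond second order in the (small) angles.
    """
    n = thetas.shape[0]
    R_tot = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    b_tot = np.zeros((n, 3))
    for k in range(3):
        lk = sampler.libration_axes[k]
        pk = sampler.axis_offsets[k]
        th = thetas[:, k]
        Rk = Rotation.from_rotvec(np.outer(th, lk)).as_matrix()
        bk = pk - Rk @ pk + np.outer(sampler.screw_pitches[k] * th, lk)
        R_tot = Rk @ R_tot
        b_tot = np.einsum("nij,nj->ni", Rk, b_tot) + bk
    b_tot += vib_coords @ sampler.vibration_axes
    return R_tot, b_tot


def sample_rigid_motions(
    sampler: TLSSampler, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` rigid motions; returns (R, b) with x' = R x + b.

    The six amplitudes (three libration angles, three vibrations) are
    independent zero-mean Gaussians with the decomposed variances.
    """
    thetas = rng.normal(size=(n, 3)) * np.sqrt(sampler.libration_variances)
    vibs = rng.normal(size=(n, 3)) * np.sqrt(sampler.vibration_variances)
    return _motions_from_draws(sampler, thetas, vibs)


def sample_displacement(
    sampler: TLSSampler, rng: np.random.Generator
) -> RigidBodyDisplacement:
    """Draw one rigid-body displacement from the TLS distribution."""
    R, b = sample_rigid_motions(sampler, 1, rng)
    o = sampler.group.origin
    return RigidBodyDisplacement(
        rotation_vector=Rotation.from_matrix(R[0]).as_rotvec(),
        rotation_center=o.copy(),
        translation=b[0] + R[0] @ o - o,
    )


@dataclass
class CorrelationMode:
    """How TLS groups move relative to each other in a generated ensemble.

    ``independent`` draws each group's motion from its own random stream.
    ``parallel`` steps every translation and libration axis of all groups
    deterministically through the same grid of multiples of the per-axis
    standard deviation; ``antiparallel`` additionally negates the translation
    steps of the second group.  With ``n_steps=10, step_size=0.5`` the grid
    is -2.5 sigma, -2.0 sigma, ..., +2.0 sigma.
    """

    mode: Literal["independent", "parallel", "antiparallel"] = "independent"
    n_steps: int = 10
    step_size: float = 0.5  # in units of sigma

    def __post_init__(self) -> None:
        if self.mode not in ("independent", "parallel", "antiparallel"):
            raise ValueError(f"unknown correlation mode {self.mode!r}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not self.step_size > 0:
            raise ValueError("step_size must be > 0")

    def grid(self) -> np.ndarray:
        """Deterministic grid multipliers, centered so the grid spans
        [-n_steps/2, n_steps/2) in units of sigma * step_size."""
        return (np.arange(self.n_steps) - self.n_steps // 2) * self.step_size


def _selection_indices(base: Model, groups: Sequence[TLSGroup]) -> list[np.ndarray]:
    seen: dict[int, int] = {}
    out = []
    for gi, g in enumerate(groups):
        idx = [i for i, a in enumerate(base.atoms) if g.contains(a)]
        for i in idx:
            if i in seen:
                raise ValueError(
                    f"TLS selections overlap: atom {base.atoms[i].key} is in "
                    f"groups {seen[i]} and {gi}")
            seen[i] = gi
        out.append(np.asarray(idx, dtype=int))
    for g, idx in zip(groups, out):
        wanted = {(c, r) for c, r in g.selection}
        present = {(base.atoms[i].chain_id, base.atoms[i].residue_number) for i in idx}
        missing = wanted - present
        if missing:
            raise ValueError(
                f"TLS selection addresses residues absent from the model: "
                f"{sorted(missing)[:3]}...")
    return out


def generate_ensemble(
    base: Model,
    cell: UnitCell,
    groups: Sequence[TLSGroup],
    n_models: int,
    mode: CorrelationMode | str = "independent",
    seed: int = 0,
) -> Ensemble:
    """Build a structural ensemble by repeatedly displacing TLS groups.

    In ``independent`` mode every model receives an independent draw per
    group (random streams are derived from ``seed`` by (model, group)
    counters, so the result is reproducible and order-independent).  In
    ``parallel``/``antiparallel`` mode exactly two groups are stepped
    deterministically along their motional axes and ``n_models`` is ignored
    in favor of ``mode.n_steps``.  Atoms in no group are copied unchanged.
    """
    if isinstance(mode, str):
        mode = CorrelationMode(mode=mode)
    indices = _selection_indices(base, groups)
    samplers = [decompose_tls(g) for g in groups]
    base_xyz = base.positions

    models: list[Model] = []
    if mode.mode == "independent":
        if n_models < 1:
            raise ValueError("n_models must be >= 1")
        for m in range(n_models):
            xyz = base_xyz.copy()
            for gi, (sampler, idx) in enumerate(zip(samplers, indices)):
                if idx.size == 0:
                    continue
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(m, gi)))
                R, b = sample_rigid_motions(sampler, 1, rng)
                xyz[idx] = base_xyz[idx] @ R[0].T + b[0]
            models.append(base.with_positions(xyz, model_id=m + 1))
    else:
        if len(groups) != 2:
            raise ValueError(
                f"{mode.mode} mode requires exactly 2 TLS groups, got {len(groups)}")
        grid = mode.grid()
        for m, gmul in enumerate(grid):
            xyz = base_xyz.copy()
            for gi, (sampler, idx) in enumerate(zip(samplers, indices)):
                if idx.size == 0:
                    continue
                thetas = gmul * np.sqrt(sampler.libration_variances)[None, :]
                vib_sign = -1.0 if (mode.mode == "antiparallel" and gi == 1) else 1.0
                vibs = vib_sign * gmul * np.sqrt(sampler.vibration_variances)[None, :]
                R, b = _motions_from_draws(sampler, thetas, vibs)
                xyz[idx] = base_xyz[idx] @ R[0].T + b[0]
            models.append(base.with_positions(xyz, model_id=m + 1))
    return Ensemble(models, cell)
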