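"""Synthetic structures and TLS groups for testing and demonstration.

Everything here is generated programmatically and deterministically from a
seed; no external data is needed.  Toy structures are random point clouds
(not chemically sensible proteins), organized into chains/residues so that
TLS selections can address contiguous blocks.  Random TLS groups are built
from an explicit axis decomposition, so they are physical by construction:
T and L are non-negative definite, trace(S) = 0, and the vibration residual
in the sampler's decomposition is non-negative.

Default scales emulate modest crystallographic rigid-body disorder:
libration eigenvalues around (1.5-2.5 deg)^2, vibration (residual T)
eigenvalues of 0.01-0.03 A^2, screw pitches below ~1 A/rad and libration
axes displaced by ~1-2 A from the group origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Atom, Model, TLSGroup, UnitCell

__all__ = ["ToySpec", "make_toy_structure", "make_random_tls",
           "make_two_group_benchmark"]

_DEFAULT_ELEMENTS = ("C", "N", "O", "S")


@dataclass
class ToySpec:
    """Parameters of a synthetic test system."""

    n_atoms: int = 40
    elements: tuple[str, ...] = _DEFAULT_ELEMENTS
    cell: UnitCell = field(default_factory=lambda: UnitCell(30.0, 34.0, 38.0,
                                                            90.0, 105.0, 90.0))
    n_groups: int = 2
    amplitude_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if not self.amplitude_scale >= 0:
            raise ValueError("amplitude_scale must be >= 0")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def make_toy_structure(spec: ToySpec) -> tuple[Model, UnitCell]:
    """Random point-cloud structure, one chain per TLS group.

    Atoms are placed uniformly at random strictly inside the cell; one atom
    per residue, residues numbered sequentially within each chain, chains
    split as evenly as possible.
    """
    rng = np.random.default_rng(spec.seed)
    frac = rng.uniform(0.03, 0.97, size=(spec.n_atoms, 3))
    xyz = spec.cell.orthogonalize(frac)
    per_chain = np.array_split(np.arange(spec.n_atoms), spec.n_groups)
    atoms: list[Atom] = []
    for ci, idx in enumerate(per_chain):
        chain = _CHAIN_IDS[ci % len(_CHAIN_IDS)]
        for ri, i in enumerate(idx, start=1):
            el = spec.elements[int(rng.integers(len(spec.elements)))]
            atoms.append(Atom(
                element=el,
                position=xyz[i],
                occupancy=1.0,
                b_iso=float(rng.uniform(10.0, 30.0)),
                chain_id=chain,
                residue_number=ri,
                atom_name=f"{el.upper()}1",
                residue_name="UNK",
            ))
    return Model(atoms, model_id=1), spec.cell


def make_random_tls(
    selection,
    origin,
    amplitude_scale: float = 1.0,
    seed: int = 0,
) -> TLSGroup:
    """A random TLS group that always passes physical validation.

    Built generatively: random orthonormal libration/vibration axes, positive
    eigenvalues scaled by ``amplitude_scale``, random screw pitches chosen so
    trace(S) = 0, and T assembled as (vibration covariance) + (translation
    covariance induced by the displaced, pitched libration axes), which makes
    the decomposition residual non-negative by construction.
    """
    rng = np.random.default_rng(seed)
    origin = np.asarray(origin, dtype=float).reshape(3)
    if amplitude_scale == 0.0:
        z = np.zeros((3, 3))
        return TLSGroup(T=z, L=z, S=z, origin=origin,
                        selection=frozenset(selection))

    P = Rotation.random(rng=rng).as_matrix()      # rows: libration axes
    Q = Rotation.random(rng=rng).as_matrix()      # rows: vibration axes
    lib_var = rng.uniform(0.4, 1.0, 3) * np.deg2rad(2.5) ** 2 * amplitude_scale
    vib_var = rng.uniform(0.3, 1.0, 3) * 0.03 * amplitude_scale
    pitches = np.empty(3)
    pitches[:2] = rng.normal(0.0, 0.8, 2)
    # zero-trace convention: sum_k L_kk * c_k = trace(S) = 0
    pitches[2] = -(lib_var[0] * pitches[0] + lib_var[1] * pitches[1]) / lib_var[2]
    w_hat = rng.normal(0.0, 1.5, (3, 3))
    w_hat[np.arange(3), np.arange(3)] = 0.0       # offsets orthogonal to axis

    L = (P.T * lib_var) @ P
    S = np.zeros((3, 3))
    C_lib = np.zeros((3, 3))
    for k in range(3):
        lk = P[k]
        wk = w_hat[k] @ P
        a_k = pitches[k] * lk - np.cross(lk, wk)
        S += lib_var[k] * np.outer(lk, a_k)
        C_lib += lib_var[k] * np.outer(a_k, a_k)
    T = (Q.T * vib_var) @ Q + C_lib
    return TLSGroup(T=T, L=L, S=S, origin=origin, selection=frozenset(selection))


def make_two_group_benchmark(
    spec: ToySpec,
) -> tuple[Model, UnitCell, list[TLSGroup]]:
    """Two disjoint chains with independent valid TLS groups.

    The groups jointly cover all atoms; origins sit at the chain centroids.
    Suitable for independent vs. parallel vs. antiparallel comparisons.
    """
    if spec.n_groups != 2:
        raise ValueError("two-group benchmark requires n_groups=2")
    model, cell = make_toy_structure(spec)
    groups: list[TLSGroup] = []
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.generate_state(2)
    for gi, chain in enumerate(sorted({a.chain_id for a in model.atoms})):
        atoms = [a for a in model.atoms if a.chain_id == chain]
        sel = {(a.chain_id, a.residue_number) for a in atoms}
        centroid = np.mean([a.position for a in atoms], axis=0)
        groups.append(make_random_tls(sel, centroid,
                                      amplitude_scale=spec.amplitude_scale,
                                      seed=int(child_seeds[gi])))
    return model, cell, groups
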