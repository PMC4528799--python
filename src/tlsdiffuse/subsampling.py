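"""Diffuse intensity between Bragg points via real-space cell expansion.

The molecular transform is continuous; the Bragg lattice merely samples it
at integer Miller indices.  Expanding the unit cell m-fold in real space
(by vacuum padding, or by tiling m^3 copies of the contents) shrinks the
reciprocal lattice spacing m-fold, so integer indices of the expanded cell
correspond to fractional indices h/m on the original lattice.  Vacuum
expansion is exact: F_expanded(m*h, m*k, m*l) = F_original(h, k, l).

A fractional-index map can then be collapsed back onto the Bragg lattice by
averaging all fractional points within the 1x1x1 voxel around each integer
index (nearest-integer assignment, ties rounded half away from zero).

Caveat: cell expansion does not preserve crystallographic symmetry for
space groups with screw axes; a warning is emitted when the source
structure declares one, and comparisons with experimental data are then
unsupported (map-to-map comparisons between simulations remain valid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import gemmi
import numpy as np

from .diffuse_core import DiffuseMap, ReciprocalGrid, build_grid, guinier_diffuse
from .structures import Ensemble, Model

__all__ = [
    "ExpandedSystem",
    "expand_system",
    "fractional_diffuse",
    "collapse_to_bragg",
    "has_screw_axis",
]


def has_screw_axis(spacegroup: str) -> bool:
    """True if the space group contains a screw rotation (e.g. P 21 21 21).

    Detected from the symmetry operations: a proper rotation whose intrinsic
    translation (the component surviving averaging over the rotation's
    cyclic group) is nonzero.
    """
    try:
        sg = gemmi.SpaceGroup(spacegroup)
    except Exception:
        return False
    for op in sg.operations():
        R = np.array(op.rot, dtype=float) / gemmi.Op.DEN
        t = np.array(op.tran, dtype=float) / gemmi.Op.DEN
        if np.allclose(R, np.eye(3)) or not np.isclose(np.linalg.det(R), 1.0):
            continue
        # intrinsic translation: average t over the cyclic group of R
        M = np.eye(3)
        P = np.eye(3)
        order = 1
        while order < 7 and not np.allclose(P @ R, np.eye(3)):
            P = P @ R
            M += P
            order += 1
        intrinsic = M @ t / (order)
        if not np.allclose(intrinsic - np.round(intrinsic), 0.0, atol=1e-6):
            return True
    return False


@dataclass
class ExpandedSystem:
    """An ensemble re-expressed in an m-fold larger cell."""

    ensemble: Ensemble
    factor: int
    mode: Literal["vacuum", "copies"]


def expand_system(
    ensemble: Ensemble,
    factor: int,
    mode: Literal["vacuum", "copies"] = "vacuum",
    assign: Callable[[int, tuple[int, int, int]], int] | None = None,
) -> ExpandedSystem:
    """Expand the unit cell ``factor``-fold in each direction.

    ``vacuum`` keeps the atoms where they are and grows the cell (padding
    with empty space); ``copies`` tiles factor^3 translated copies of the
    contents.  In copies mode ``assign(snapshot_index, (i, j, k))`` may
    choose which ensemble model occupies each copy, enabling cross-cell
    correlation schemes; the default places the same model in every copy.
    """
    if factor < 1:
        raise ValueError("expansion factor must be >= 1")
    if mode not in ("vacuum", "copies"):
        raise ValueError(f"unknown expansion mode {mode!r}")
    if ensemble.spacegroup and has_screw_axis(ensemble.spacegroup):
        warnings.warn(
            f"space group {ensemble.spacegroup!r} contains a screw axis: "
            "cell expansion breaks its symmetry; the subsampled map is not "
            "comparable with experimental data", stacklevel=2)

    big_cell = ensemble.cell.scaled(factor)
    if mode == "vacuum" or factor == 1 and mode == "vacuum":
        models = [Model(m.atoms, m.model_id) for m in ensemble.models]
        expanded = Ensemble(models, big_cell, spacegroup=ensemble.spacegroup)
        return ExpandedSystem(expanded, factor, mode)

    A = ensemble.cell.orth_matrix
    offsets = [(i, j, k) for i in range(factor)
               for j in range(factor) for k in range(factor)]
    shift_vecs = {ijk: A @ np.asarray(ijk, dtype=float) for ijk in offsets}
    models = []
    for n, model in enumerate(ensemble.models):
        atoms = []
        for ijk in offsets:
            src = ensemble.models[assign(n, ijk)] if assign is not None else model
            shift = shift_vecs[ijk]
            xyz = src.positions + shift
            atoms.extend(src.with_positions(xyz).atoms)
        # copies share identifiers; Ensemble roster matching tolerates this
        # only because order is preserved, so renumber residues per copy
        renumbered = []
        n_per_copy = ensemble.n_atoms
        max_res = max(a.residue_number for a in ensemble.models[0].atoms) + 1
        for ci, _ in enumerate(offsets):
            for a in atoms[ci * n_per_copy:(ci + 1) * n_per_copy]:
                a.residue_number = a.residue_number + ci * max_res
                renumbered.append(a)
        models.append(Model(renumbered, model.model_id))
    expanded = Ensemble(models, big_cell, spacegroup=ensemble.spacegroup)
    return ExpandedSystem(expanded, factor, mode)


def fractional_diffuse(
    ensemble: Ensemble,
    factor: int,
    d_min: float,
    mode: Literal["vacuum", "copies"] = "vacuum",
    use_b: bool = False,
) -> DiffuseMap:
    """Diffuse map sampled at 1/factor-spaced fractional indices.

    The Guinier variance is evaluated on the integer grid of the expanded
    cell (honoring ``d_min`` of the original cell) and the indices are
    divided by ``factor`` to express them on the original reciprocal
    lattice.  ``factor=1`` reduces exactly to the standard Bragg-lattice
    calculation.
    """
    exp = expand_system(ensemble, factor, mode=mode)
    grid_exp = build_grid(exp.ensemble.cell, d_min)
    dmap = guinier_diffuse(exp.ensemble, grid_exp, use_b=use_b)
    frac_grid = ReciprocalGrid(cell=ensemble.cell, d_min=d_min,
                               indices=grid_exp.indices / factor)
    return DiffuseMap(grid=frac_grid, intensities=dmap.intensities)


def collapse_to_bragg(frac_map: DiffuseMap, factor: int) -> DiffuseMap:
    """Average fractional intensities into the 1x1x1 voxel of each Bragg index.

    Each fractional index is assigned to its nearest integer triple
    (component-wise, ties rounded half away from zero) and the per-voxel
    arithmetic mean becomes that Bragg peak's diffuse intensity.  Total
    intensity is conserved: sum(frac) = sum(collapsed * voxel_count).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    scaled = frac_map.grid.indices * factor
    if not np.allclose(scaled, np.round(scaled), atol=1e-6 * factor):
        bad = np.argmax(np.abs(scaled - np.round(scaled)).max(axis=1))
        raise ValueError(
            f"index {tuple(frac_map.grid.indices[bad])} is not on a "
            f"1/{factor} grid")
    x = frac_map.grid.indices
    nearest = np.sign(x) * np.floor(np.abs(x) + 0.5)  # half away from zero
    nearest = nearest.astype(int)
    uniq, first, inverse = np.unique(nearest, axis=0, return_index=True,
                                     return_inverse=True)
    # keep voxels in first-appearance order so factor=1 is the identity
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    inverse = rank[inverse]
    uniq = uniq[order]
    sums = np.bincount(inverse, weights=frac_map.intensities,
                       minlength=uniq.shape[0])
    counts = np.bincount(inverse, minlength=uniq.shape[0])
    means = sums / counts
    grid = ReciprocalGrid(cell=frac_map.grid.cell, d_min=frac_map.grid.d_min,
                          indices=uniq.astype(float))
    return DiffuseMap(grid=grid, intensities=means, signed=frac_map.signed)
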