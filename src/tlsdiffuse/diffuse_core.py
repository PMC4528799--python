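"""Direct-summation structure factors and ensemble diffuse intensity.

Diffuse intensity is computed as the variance of the complex structure
factor over an ensemble of unit-cell snapshots:

    I_D(hkl) = < |F_n(hkl)|^2 >_n  -  | < F_n(hkl) >_n |^2

with equal model weights.  The crystal-size prefactor (number of unit
cells) is fixed at 1, so intensities are "per unit cell" in electrons^2;
only relative/correlation comparisons are meaningful across maps anyway.

Structure factors use direct summation (exact at arbitrary, including
fractional, Miller indices) with IT92 4-Gaussian atomic form factors.
Per-atom isotropic B factors are ignored by default so that the diffuse
signal reflects only the spread of the ensemble; pass ``use_b=True`` to
retain them as Debye-Waller factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .structures import Ensemble, Model, UnitCell

__all__ = [
    "ReciprocalGrid",
    "StructureFactorSet",
    "DiffuseMap",
    "build_grid",
    "form_factor",
    "structure_factors",
    "compute_structure_factor_set",
    "guinier_diffuse",
    "mean_bragg_intensity",
    "write_map",
    "read_map",
]

_MAX_Z = 98  # IT92 table coverage


@lru_cache(maxsize=None)
def _it92_coefs(symbol: str) -> tuple[np.ndarray, np.ndarray, float]:
    el = gemmi.Element(symbol)
    if el.atomic_number == 0 or el.atomic_number > _MAX_Z or el.it92 is None:
        known = ", ".join(gemmi.Element(z).name for z in range(1, _MAX_Z + 1))
        raise ValueError(
            f"no form-factor entry for element {symbol!r}; known symbols: {known}")
    c = el.it92
    return np.asarray(c.a, dtype=float), np.asarray(c.b, dtype=float), float(c.c)


def form_factor(element: str, s) -> np.ndarray | float:
    """IT92 atomic scattering factor f(s) in electrons, s = sin(theta)/lambda (A^-1).

    ``f(s) = sum_i a_i exp(-b_i s^2) + c``; f(0) is the electron count of the
    neutral atom to tabulation accuracy.
    """
    a, b, c = _it92_coefs(element.strip().capitalize())
    s2 = np.square(np.asarray(s, dtype=float))
    f = np.exp(-np.multiply.outer(s2, b)) @ a + c
    return float(f) if np.isscalar(s) else f


@dataclass
class ReciprocalGrid:
    """Miller indices (possibly fractional) within a resolution limit."""

    cell: UnitCell
    d_min: float
    indices: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=float).reshape(-1, 3)

    @property
    def n(self) -> int:
        return self.indices.shape[0]

    @property
    def s_norms(self) -> np.ndarray:
        """|s| = 1/d in A^-1 per index."""
        return np.linalg.norm(self.cell.s_vectors(self.indices), axis=-1)

    @property
    def d_spacings(self) -> np.ndarray:
        return 1.0 / self.s_norms

    @property
    def stol(self) -> np.ndarray:
        """sin(theta)/lambda = |s|/2, the form-factor argument."""
        return 0.5 * self.s_norms


def build_grid(cell: UnitCell, d_min: float) -> ReciprocalGrid:
    """All integer hkl with d >= d_min (full +-h,+-k,+-l sphere, origin excluded).

    Content is treated as P1; Friedel symmetry of intensities is then an
    emergent property of real scatterers, not an assumption of the grid.
    """
    if not d_min > 0:
        raise ValueError("d_min must be > 0")
    s_max = 1.0 / d_min
    # |h| = |s . a_vec| <= s_max * |a|, likewise for k, l
    A = cell.orth_matrix
    lims = [int(np.floor(s_max * np.linalg.norm(A[:, i]) + 1e-9)) for i in range(3)]
    h, k, l = np.meshgrid(*(np.arange(-m, m + 1) for m in lims), indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()]).astype(float)
    s = np.linalg.norm(cell.s_vectors(hkl), axis=-1)
    keep = (s > 0) & (s <= s_max * (1.0 + 1e-12))
    return ReciprocalGrid(cell=cell, d_min=d_min, indices=hkl[keep])


def _grouped_by_element(model: Model):
    by_el: dict[str, list[int]] = {}
    for i, a in enumerate(model.atoms):
        by_el.setdefault(a.element, []).append(i)
    return by_el


def structure_factors(
    model: Model,
    grid: ReciprocalGrid,
    use_b: bool = False,
) -> np.ndarray:
    """Complex structure factors F(hkl) in electrons by direct summation.

    ``F(h) = sum_j occ_j f_j(s) D_j(s) exp(2 pi i h . x_j)`` with x_j the
    fractional coordinates; ``D_j = exp(-B_j s^2)`` when ``use_b``, else 1.
    """
    frac = grid.cell.fractionalize(model.positions)
    stol = grid.stol
    stol2 = stol * stol
    F = np.zeros(grid.n, dtype=complex)
    occ = np.array([a.occupancy for a in model.atoms])
    b_iso = np.array([a.b_iso for a in model.atoms])
    for el, idx in _grouped_by_element(model).items():
        idx = np.asarray(idx)
        phases = np.exp(2j * np.pi * (grid.indices @ frac[idx].T))
        if use_b:
            w = occ[idx] * np.exp(-np.multiply.outer(stol2, b_iso[idx]))
            contrib = np.einsum("nj,nj->n", phases, w)
        else:
            contrib = phases @ occ[idx]
        F += form_factor(el, stol) * contrib
    return F


@dataclass
class StructureFactorSet:
    """Per-model complex structure factors on one grid."""

    grid: ReciprocalGrid
    values: np.ndarray  # (n_models, n_hkl) complex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.n:
            raise ValueError("values must have shape (n_models, n_hkl)")


def compute_structure_factor_set(
    ensemble: Ensemble, grid: ReciprocalGrid, use_b: bool = False
) -> StructureFactorSet:
    values = np.stack([structure_factors(m, grid, use_b=use_b)
                       for m in ensemble.models])
    return StructureFactorSet(grid=grid, values=values)


@dataclass
class DiffuseMap:
    """Diffuse intensity (electrons^2 per unit cell) on a reciprocal grid.

    Guinier-variance maps are non-negative; maps produced by isotropic
    subtraction or differencing carry ``signed=True`` and may be negative.
    """

    grid: ReciprocalGrid
    intensities: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        if self.intensities.shape[0] != self.grid.n:
            raise ValueError("one intensity per grid index required")
        if not self.signed and self.intensities.size and self.intensities.min() < 0:
            raise ValueError("negative intensity in an unsigned diffuse map")

    @property
    def n(self) -> int:
        return self.grid.n


def guinier_diffuse(
    ensemble: Ensemble, grid: ReciprocalGrid, use_b: bool = False
) -> DiffuseMap:
    """Diffuse map I_D = <|F|^2> - |<F>|^2 over the ensemble's snapshots.

    Structure factors are accumulated model by model, so arbitrarily large
    ensembles use O(n_hkl) memory.  The result is clamped at zero; a genuine
    negative beyond -1e-9 of the map scale would indicate a numerical bug
    and raises instead.
    """
    n = ensemble.n_models
    sum_F = np.zeros(grid.n, dtype=complex)
    sum_F2 = np.zeros(grid.n, dtype=float)
    for model in ensemble.models:
        F = structure_factors(model, grid, use_b=use_b)
        sum_F += F
        sum_F2 += np.abs(F) ** 2
    mean_F2 = sum_F2 / n
    intensities = mean_F2 - np.abs(sum_F / n) ** 2
    scale = max(float(mean_F2.max(initial=0.0)), 1.0)
    if intensities.size and intensities.min() < -1e-9 * scale:
        raise FloatingPointError(
            f"variance came out negative beyond tolerance: {intensities.min():g}")
    return DiffuseMap(grid=grid, intensities=np.maximum(intensities, 0.0))


def mean_bragg_intensity(
    ensemble: Ensemble, grid: ReciprocalGrid, use_b: bool = False
) -> np.ndarray:
    """|<F_n>|^2 per index -- the Bragg component of the ensemble average.

    Together with the diffuse map it reconstructs the total mean intensity:
    <|F|^2> = I_D + |<F>|^2 exactly.
    """
    n = ensemble.n_models
    sum_F = np.zeros(grid.n, dtype=complex)
    for model in ensemble.models:
        sum_F += structure_factors(model, grid, use_b=use_b)
    return np.abs(sum_F / n) ** 2


# ---------------------------------------------------------------------------
# Interchange text format: two-line header (cell; d_min), then "h k l I"
# ---------------------------------------------------------------------------

def write_map(dmap: DiffuseMap, path: str | Path, fractional: bool = False) -> None:
    """Write a map as whitespace-delimited text, one "h k l intensity" per line."""
    cell = dmap.grid.cell
    with open(path, "w") as fh:
        fh.write(f"# cell {cell.a:.6f} {cell.b:.6f} {cell.c:.6f} "
                 f"{cell.alpha:.6f} {cell.beta:.6f} {cell.gamma:.6f}\n")
        fh.write(f"# d_min {dmap.grid.d_min:.6f}\n")
        for (h, k, l), inten in zip(dmap.grid.indices, dmap.intensities):
            if fractional:
                fh.write(f"{h:.4f} {k:.4f} {l:.4f} {inten:.8e}\n")
            else:
                fh.write(f"{int(round(h))} {int(round(k))} {int(round(l))} "
                         f"{inten:.8e}\n")


def read_map(path: str | Path) -> DiffuseMap:
    """Read a map written by :func:`write_map` (signed values allowed)."""
    path = Path(path)
    with open(path) as fh:
        header1 = fh.readline().split()
        header2 = fh.readline().split()
        if header1[:2] != ["#", "cell"] or header2[:2] != ["#", "d_min"]:
            raise ValueError(f"{path}: not a diffuse-map file (bad header)")
        cell = UnitCell(*(float(x) for x in header1[2:8]))
        d_min = float(header2[2])
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    if data.size == 0:
        data = data.reshape(0, 4)
    grid = ReciprocalGrid(cell=cell, d_min=d_min, indices=data[:, :3])
    return DiffuseMap(grid=grid, intensities=data[:, 3],
                      signed=bool(data.size and data[:, 3].min() < 0))
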