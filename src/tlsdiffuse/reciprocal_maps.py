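"""Analytics on diffuse maps: radial profiles, isotropic subtraction,
Pearson correlations (global and per resolution shell) and difference maps.

Diffuse intensity falls off steeply with resolution, so two maps that share
only that radial falloff already correlate strongly.  Comparisons therefore
operate on "anisotropic" maps -- the map minus its spherical (radial-shell
average) component -- which isolates the directional signal.  Shells are
equal-width bins in |s| = 1/d.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diffuse_core import DiffuseMap, ReciprocalGrid

__all__ = [
    "RadialProfile",
    "BinnedCC",
    "radial_profile",
    "subtract_isotropic",
    "pearson_cc",
    "cc_by_resolution",
    "difference_map",
]

DEFAULT_SUBTRACTION_BINS = 50
DEFAULT_CC_BINS = 10


class GridMismatchError(ValueError):
    pass


class ZeroVarianceError(ValueError):
    """Pearson correlation is undefined for a constant map."""


def _check_same_grid(a: DiffuseMap, b: DiffuseMap) -> None:
    if a.grid.n != b.grid.n:
        raise GridMismatchError(
            f"maps have {a.grid.n} and {b.grid.n} indices")
    mismatch = np.nonzero(~np.all(np.isclose(a.grid.indices, b.grid.indices,
                                             atol=1e-9), axis=1))[0]
    if mismatch.size:
        i = int(mismatch[0])
        raise GridMismatchError(
            f"index sets differ, first mismatch at row {i}: "
            f"{tuple(a.grid.indices[i])} vs {tuple(b.grid.indices[i])}")


def _shell_assignment(s: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bins in |s| over [0, s_max]; returns (bin index, edges)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    s_max = float(s.max()) if s.size else 1.0
    edges = np.linspace(0.0, s_max, n_bins + 1)
    width = edges[1] - edges[0] if n_bins > 0 else 1.0
    which = np.minimum((s / width).astype(int) if width > 0 else
                       np.zeros(s.shape, int), n_bins - 1)
    return which, edges


@dataclass
class RadialProfile:
    """Mean intensity per resolution shell (shells in |s| = 1/d, A^-1)."""

    bin_edges: np.ndarray       # (n_bins + 1,)
    mean_intensity: np.ndarray  # (n_bins,); 0 for empty shells
    counts: np.ndarray          # (n_bins,)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s_min": self.bin_edges[:-1],
            "s_max": self.bin_edges[1:],
            "mean_intensity": self.mean_intensity,
            "count": self.counts,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def radial_profile(dmap: DiffuseMap, n_bins: int = DEFAULT_SUBTRACTION_BINS
                   ) -> RadialProfile:
    """Arithmetic mean intensity in equal-width |s| shells."""
    if dmap.n == 0:
        raise ValueError("empty map")
    which, edges = _shell_assignment(dmap.grid.s_norms, n_bins)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=dmap.intensities, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    return RadialProfile(bin_edges=edges, mean_intensity=means,
                         counts=counts.astype(int))


def subtract_isotropic(dmap: DiffuseMap,
                       n_bins: int = DEFAULT_SUBTRACTION_BINS) -> DiffuseMap:
    """Anisotropic map: each intensity minus its |s|-shell mean.

    The output mean within every shell is zero (idempotent operation); values
    are signed.
    """
    if dmap.n == 0:
        raise ValueError("empty map")
    which, _ = _shell_assignment(dmap.grid.s_norms, n_bins)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=dmap.intensities, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    return DiffuseMap(grid=dmap.grid,
                      intensities=dmap.intensities - means[which],
                      signed=True)


def pearson_cc(map_a: DiffuseMap, map_b: DiffuseMap) -> float:
    """Global Pearson correlation between two maps on the same index set."""
    _check_same_grid(map_a, map_b)
    x, y = map_a.intensities, map_b.intensities
    if x.size < 2:
        raise ZeroVarianceError("need at least 2 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("Pearson CC undefined: zero variance in a map")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class BinnedCC:
    """Pearson correlation per resolution shell plus the global value.

    Shells with fewer than 3 points or zero variance are undefined and
    reported as NaN (never as 0).
    """

    bin_edges: np.ndarray
    cc_per_bin: np.ndarray  # NaN where undefined
    counts: np.ndarray
    global_cc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s_min": self.bin_edges[:-1],
            "s_max": self.bin_edges[1:],
            "cc": self.cc_per_bin,
            "count": self.counts,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def cc_by_resolution(map_a: DiffuseMap, map_b: DiffuseMap,
                     n_bins: int = DEFAULT_CC_BINS) -> BinnedCC:
    """Per-shell and global Pearson correlation between two maps."""
    _check_same_grid(map_a, map_b)
    which, edges = _shell_assignment(map_a.grid.s_norms, n_bins)
    ccs = np.full(n_bins, np.nan)
    counts = np.bincount(which, minlength=n_bins)
    for b in range(n_bins):
        sel = which == b
        if counts[b] < 3:
            continue
        x, y = map_a.intensities[sel], map_b.intensities[sel]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        ccs[b] = np.corrcoef(x, y)[0, 1]
    return BinnedCC(bin_edges=edges, cc_per_bin=ccs,
                    counts=counts.astype(int),
                    global_cc=pearson_cc(map_a, map_b))


def difference_map(map_a: DiffuseMap, map_b: DiffuseMap) -> DiffuseMap:
    """Elementwise a - b with sign preserved."""
    _check_same_grid(map_a, map_b)
    return DiffuseMap(grid=map_a.grid,
                      intensities=map_a.intensities - map_b.intensities,
                      signed=True)
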