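"""Independent brute-force reference implementations used only by tests.

These deliberately take the long way around (explicit sums over atom pairs
and model pairs, dictionary-based voxel assignment) so that they share no
code path with the library.
"""

import collections

import numpy as np

from tlsdiffuse.diffuse_core import form_factor


def brute_force_guinier(ensemble, grid):
    """Diffuse intensity via the all-atom covariance (pair) expansion.

    I_D(h) = sum_j sum_k f_j f_k [ <e^{2 pi i h.(x_j - x_k)}>_n
                                   - <e^{2 pi i h.x_j}>_n <e^{-2 pi i h.x_k}>_n ]
    """
    cell = grid.cell
    stol = grid.stol
    models = ensemble.models
    n = len(models)
    atoms = models[0].atoms
    fj = [a.occupancy * form_factor(a.element, stol) for a in atoms]
    frac = [cell.fractionalize(m.positions) for m in models]
    out = np.zeros(grid.n, dtype=complex)
    for j in range(len(atoms)):
        for k in range(len(atoms)):
            pair_mean = np.zeros(grid.n, dtype=complex)
            for m in range(n):
                diff = frac[m][j] - frac[m][k]
                pair_mean += np.exp(2j * np.pi * (grid.indices @ diff))
            pair_mean /= n
            mean_j = np.zeros(grid.n, dtype=complex)
            mean_k = np.zeros(grid.n, dtype=complex)
            for m in range(n):
                mean_j += np.exp(2j * np.pi * (grid.indices @ frac[m][j]))
                mean_k += np.exp(-2j * np.pi * (grid.indices @ frac[m][k]))
            mean_j /= n
            mean_k /= n
            out += fj[j] * fj[k] * (pair_mean - mean_j * mean_k)
    return out.real


def brute_force_collapse(frac_map):
    """Voxel means via explicit nearest-integer assignment in a dict."""
    voxels = collections.defaultdict(list)
    for hkl, inten in zip(frac_map.grid.indices, frac_map.intensities):
        key = tuple(int(np.sign(x) * np.floor(abs(x) + 0.5)) for x in hkl)
        voxels[key].append(inten)
    return {k: float(np.mean(v)) for k, v in voxels.items()}
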