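"""Domain types and I/O for crystal structures, ensembles and TLS groups.

The central container is the :class:`Ensemble`: an ordered collection of
conformer :class:`Model` snapshots that share one atom roster and one
:class:`UnitCell`.  Rigid-body disorder is parameterized by
:class:`TLSGroup` -- the translation (T, A^2), libration (L, rad^2) and
screw (S, A*rad) tensors about an origin, together with a residue
selection.  PDB files carry L in deg^2 and S in A*deg; everything here is
converted to radians on load and back to degrees on write.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "Atom",
    "Model",
    "Ensemble",
    "TLSGroup",
    "TLSValidationReport",
    "read_pdb_multimodel",
    "write_pdb_multimodel",
    "parse_tls_records",
    "format_tls_records",
    "validate_tls",
]

_DEG2RAD = math.pi / 180.0

#: default tolerance for "non-negative" T/L eigenvalues (A^2 resp. rad^2);
#: absorbs rounding noise of 4-decimal tensors in PDB headers
EIG_TOL = 1e-8

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


def _known_element(symbol: str) -> bool:
    el = gemmi.Element(symbol)
    return el.atomic_number > 0


class PDBFormatError(ValueError):
    """Raised for structurally invalid PDB input (missing CRYST1, bad rosters...)."""


class TLSFormatError(ValueError):
    """Raised for malformed REMARK 3 TLS blocks; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell: edges a, b, c in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cell edge {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180) deg")
        ca, cb, cg = (math.cos(_DEG2RAD * v) for v in (self.alpha, self.beta, self.gamma))
        # positive-definiteness of the metric tensor <=> positive cell volume
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0.0:
            raise ValueError("cell angles do not define a positive-definite metric")

    @cached_property
    def _gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @cached_property
    def orth_matrix(self) -> np.ndarray:
        """Orthogonalization matrix; columns are the cell vectors a, b, c."""
        return np.array(self._gemmi.orth.mat.tolist(), dtype=float)

    @cached_property
    def frac_matrix(self) -> np.ndarray:
        """Fractionalization matrix, inverse of :attr:`orth_matrix`.

        Its rows are the reciprocal-cell vectors a*, b*, c*.
        """
        return np.linalg.inv(self.orth_matrix)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.orth_matrix)))

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        """Orthogonal (A) -> fractional coordinates, for (..., 3) arrays."""
        return np.asarray(xyz, dtype=float) @ self.frac_matrix.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orth_matrix.T

    def s_vectors(self, hkl: np.ndarray) -> np.ndarray:
        """Scattering vectors s = h a* + k b* + l c* (A^-1) for (..., 3) indices."""
        return np.asarray(hkl, dtype=float) @ self.frac_matrix

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d = 1/|s| in A; works for fractional indices too."""
        s = np.linalg.norm(self.s_vectors(hkl), axis=-1)
        with np.errstate(divide="ignore"):
            return np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), np.inf)

    def scaled(self, factor: float) -> "UnitCell":
        """Cell with all edges multiplied by ``factor`` (angles unchanged)."""
        return UnitCell(self.a * factor, self.b * factor, self.c * factor,
                        self.alpha, self.beta, self.gamma)


@dataclass
class Atom:
    element: str
    position: np.ndarray  # orthogonal coordinates, A
    occupancy: float = 1.0
    b_iso: float = 0.0
    chain_id: str = "A"
    residue_number: int = 1
    atom_name: str = "X"
    residue_name: str = "ALA"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.element = self.element.strip().capitalize()
        if not _known_element(self.element):
            raise ValueError(f"unknown element symbol {self.element!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str]:
        """Identifier tuple used to match atoms across models."""
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class Model:
    """One conformer snapshot: an ordered atom list."""

    atoms: list[Atom]
    model_id: int = 1

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_positions(self, xyz: np.ndarray, model_id: int | None = None) -> "Model":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=xyz[i].copy()) for i, a in enumerate(self.atoms)]
        return Model(atoms, self.model_id if model_id is None else model_id)


@dataclass
class Ensemble:
    """Ordered collection of models sharing one atom roster and one cell."""

    models: list[Model]
    cell: UnitCell
    spacegroup: str | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("an Ensemble needs at least one model")
        first = self.models[0]
        n = len(first.atoms)
        for m in self.models[1:]:
            if len(m.atoms) != n:
                raise ValueError(
                    f"model {m.model_id} has {len(m.atoms)} atoms, expected {n}")
            for a, b in zip(first.atoms, m.atoms):
                if a.key != b.key or a.element != b.element or a.occupancy != b.occupancy:
                    raise ValueError(
                        f"model {m.model_id}: atom roster mismatch at {b.key}")

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_atoms(self) -> int:
        return len(self.models[0].atoms)

    def coordinates(self) -> np.ndarray:
        """Stacked coordinates, shape (n_models, n_atoms, 3)."""
        return np.stack([m.positions for m in self.models])


def _symmetrize(m: np.ndarray, name: str, tol: float = 1e-4) -> np.ndarray:
    m = np.asarray(m, dtype=float).reshape(3, 3)
    if np.max(np.abs(m - m.T)) > tol * max(1.0, np.max(np.abs(m))):
        raise ValueError(f"{name} tensor is not symmetric")
    return 0.5 * (m + m.T)


@dataclass
class TLSGroup:
    """T/L/S rigid-body disorder tensors about ``origin`` for a residue selection.

    Internal units: T in A^2, L in rad^2, S in A*rad.  The constructor
    symmetrizes T and L and re-centers S to trace zero (S is only determined
    up to its trace, and the zero-trace convention is assumed everywhere
    downstream).  The S row/column convention is S_ij = <omega_i u_j>
    (libration angle component i with translation component j), matching the
    ADP formula U(r) = T + A L A' + A S + S' A'.
    """

    T: np.ndarray
    L: np.ndarray
    S: np.ndarray
    origin: np.ndarray
    selection: frozenset[tuple[str, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.T = _symmetrize(self.T, "T")
        self.L = _symmetrize(self.L, "L")
        S = np.asarray(self.S, dtype=float).reshape(3, 3).copy()
        S -= np.eye(3) * (np.trace(S) / 3.0)
        self.S = S
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.selection = frozenset((str(c), int(r)) for c, r in self.selection)

    def contains(self, atom: Atom) -> bool:
        return (atom.chain_id, atom.residue_number) in self.selection


@dataclass
class TLSValidationReport:
    t_eigenvalues: tuple[float, float, float]
    l_eigenvalues: tuple[float, float, float]
    is_physical: bool
    messages: list[str]


def validate_tls(group: TLSGroup, tol: float = EIG_TOL) -> TLSValidationReport:
    """Check that T and L have non-negative eigenvalues (within ``tol``).

    A TLS group with a negative T or L eigenvalue implies a negative variance
    of translation or libration and cannot be realized by any real-space
    ensemble; such groups must be rejected before sampling.
    """
    t_eig = tuple(sorted(np.linalg.eigvalsh(group.T), reverse=True))
    l_eig = tuple(sorted(np.linalg.eigvalsh(group.L), reverse=True))
    messages: list[str] = []
    ok = True
    if min(t_eig) < -tol:
        ok = False
        messages.append(f"T has a negative eigenvalue: {min(t_eig):.3e} A^2")
    if min(l_eig) < -tol:
        ok = False
        messages.append(f"L has a negative eigenvalue: {min(l_eig):.3e} rad^2")
    tr_s = float(np.trace(group.S))
    messages.append(f"trace(S) deviation from zero: {tr_s:.3e} A*rad")
    return TLSValidationReport(t_eig, l_eig, ok, messages)


# ---------------------------------------------------------------------------
# PDB coordinate I/O (via gemmi)
# ---------------------------------------------------------------------------

def _atom_from_gemmi(chain_id: str, res: gemmi.Residue, at: gemmi.Atom) -> Atom:
    return Atom(
        element=at.element.name,
        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
        occupancy=float(at.occ),
        b_iso=float(at.b_iso),
        chain_id=chain_id,
        residue_number=res.seqid.num,
        atom_name=at.name,
        residue_name=res.name,
    )


def read_pdb_multimodel(
    path: str | Path,
    keep_waters: bool = False,
    keep_hydrogens: bool = False,
) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    Atom order follows file order of the first model; later models are matched
    by (chain, residue number, atom name).  Waters and hydrogens are dropped by
    default; alternate locations other than blank/'A' are always dropped (the
    ensemble itself is the disorder model).  A CRYST1 record is mandatory.
    """
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    if not any(line.startswith("CRYST1") for line in text.splitlines()):
        raise PDBFormatError(f"{path}: no CRYST1 record; a unit cell is required")

    st = gemmi.read_pdb_string(text)
    cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                    st.cell.alpha, st.cell.beta, st.cell.gamma)
    spacegroup = st.spacegroup_hm or None

    def extract(model: gemmi.Model) -> list[Atom]:
        atoms: list[Atom] = []
        for chain in model:
            for res in chain:
                if not keep_waters and res.name.strip() in _WATER_NAMES:
                    continue
                for at in res:
                    if at.altloc not in ("", "A", "\0"):
                        continue
                    if not keep_hydrogens and at.element.name in ("H", "D"):
                        continue
                    if at.element.atomic_number == 0:
                        raise PDBFormatError(
                            f"{path}: unknown element for atom "
                            f"{chain.name}/{res.seqid.num}/{at.name}")
                    atoms.append(_atom_from_gemmi(chain.name, res, at))
        return atoms

    if len(st) == 0:
        raise PDBFormatError(f"{path}: no models found")

    first = extract(st[0])
    if not first:
        raise PDBFormatError(f"{path}: first model contains no atoms after filtering")
    order = {a.key: i for i, a in enumerate(first)}
    if len(order) != len(first):
        raise PDBFormatError(f"{path}: duplicate atom identifiers in first model")

    models = [Model(first, model_id=1)]
    for mi in range(1, len(st)):
        atoms = extract(st[mi])
        if len(atoms) != len(first):
            raise PDBFormatError(
                f"{path}: model {mi + 1} has {len(atoms)} atoms, "
                f"first model has {len(first)}")
        arranged: list[Atom | None] = [None] * len(first)
        for a in atoms:
            idx = order.get(a.key)
            if idx is None:
                raise PDBFormatError(
                    f"{path}: model {mi + 1}: atom {a.key} absent from first model")
            arranged[idx] = a
        missing = next((first[i].key for i, a in enumerate(arranged) if a is None), None)
        if missing is not None:
            raise PDBFormatError(
                f"{path}: model {mi + 1}: atom {missing} missing")
        models.append(Model(arranged, model_id=mi + 1))  # type: ignore[arg-type]

    return Ensemble(models, cell, spacegroup=spacegroup)


def write_pdb_multimodel(
    ensemble: Ensemble,
    path: str | Path,
    tls_groups: Sequence[TLSGroup] | None = None,
) -> None:
    """Write an ensemble as a multi-model PDB (CRYST1 + MODEL/ENDMDL blocks).

    Coordinates are quantized to 3 decimals by the PDB format.  If
    ``tls_groups`` is given, matching REMARK 3 TLS blocks are emitted before
    the coordinates (L in deg^2, S in A*deg, per PDB convention).
    """
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(ensemble.cell.a, ensemble.cell.b, ensemble.cell.c,
                             ensemble.cell.alpha, ensemble.cell.beta,
                             ensemble.cell.gamma)
    st.spacegroup_hm = ensemble.spacegroup or "P 1"
    for model in ensemble.models:
        gm = gemmi.Model(model.model_id)
        # group atoms by chain then residue, preserving roster order;
        # gemmi's add_chain/add_residue copy, so build bottom-up
        chain_order: list[str] = []
        chain_atoms: dict[str, list[Atom]] = {}
        for atom in model.atoms:
            if atom.chain_id not in chain_atoms:
                chain_atoms[atom.chain_id] = []
                chain_order.append(atom.chain_id)
            chain_atoms[atom.chain_id].append(atom)
        for cid in chain_order:
            ch = gemmi.Chain(cid)
            res: gemmi.Residue | None = None
            rkey: tuple[int, str] | None = None
            for atom in chain_atoms[cid]:
                k = (atom.residue_number, atom.residue_name)
                if res is None or k != rkey:
                    if res is not None:
                        ch.add_residue(res)
                    res = gemmi.Residue()
                    res.name = atom.residue_name
                    res.seqid = gemmi.SeqId(atom.residue_number, " ")
                    rkey = k
                ga = gemmi.Atom()
                ga.name = atom.atom_name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_iso
                res.add_atom(ga)
            if res is not None:
                ch.add_residue(res)
            gm.add_chain(ch)
        st.add_model(gm)
    if tls_groups:
        st.raw_remarks = format_tls_records(tls_groups)
    text = st.make_pdb_string()
    if len(ensemble.models) == 1 and "\nMODEL" not in text:
        # gemmi drops MODEL/ENDMDL for single models; keep the block explicit
        lines = text.splitlines()
        first_atom = next(i for i, ln in enumerate(lines)
                          if ln.startswith(("ATOM", "HETATM")))
        mid = ensemble.models[0].model_id
        lines.insert(first_atom, f"MODEL     {mid:>4}")
        end = next(i for i, ln in enumerate(lines) if ln.startswith("END"))
        lines.insert(end, "ENDMDL")
        text = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# REMARK 3 TLS blocks
# ---------------------------------------------------------------------------

_TENSOR_TAG = re.compile(r"([TLS][123][123])\s*:\s*(\S+)")
_RANGE_RE = re.compile(
    r"RESIDUE RANGE\s*:\s+(\S+)\s+(-?\d+)\s+(\S+)\s+(-?\d+)")
_GROUP_RE = re.compile(r"REMARK   3\s+TLS GROUP\s*:\s*(\d+)")
_ORIGIN_RE = re.compile(r"ORIGIN FOR THE GROUP \(A\):(.*)")
_FLOAT_RE = re.compile(r"-?\d+\.?\d*(?:[eE][-+]?\d+)?")

_T_KEYS = ("T11", "T22", "T33", "T12", "T13", "T23")
_L_KEYS = ("L11", "L22", "L33", "L12", "L13", "L23")
_S_KEYS = ("S11", "S12", "S13", "S21", "S22", "S23", "S31", "S32", "S33")


def _tensor_from_upper(d: dict[str, float], prefix: str) -> np.ndarray:
    g = lambda ij: d[f"{prefix}{ij}"]
    return np.array([[g("11"), g("12"), g("13")],
                     [g("12"), g("22"), g("23")],
                     [g("13"), g("23"), g("33")]])


def parse_tls_records(path: str | Path) -> list[TLSGroup]:
    """Parse REMARK 3 TLS blocks (refmac/phenix PDB dialect) from a file.

    Tensor element lines may appear in any order within a block.  L is
    converted deg^2 -> rad^2 and S A*deg -> A*rad on load; S is re-centered to
    trace zero.  A block with no RESIDUE RANGE lines yields a warning but the
    group is retained (with an empty selection).
    """
    path = Path(path)
    blocks: list[dict] = []
    current: dict | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("REMARK   3"):
                continue
            if _GROUP_RE.match(line):
                current = {"elements": {}, "ranges": [], "origin": None,
                           "start_line": lineno}
                blocks.append(current)
                continue
            if current is None:
                continue
            m = _ORIGIN_RE.search(line)
            if m:
                nums = _FLOAT_RE.findall(m.group(1))
                if len(nums) != 3:
                    raise TLSFormatError("malformed ORIGIN line", lineno)
                current["origin"] = np.array([float(x) for x in nums])
                continue
            m = _RANGE_RE.search(line)
            if m:
                c1, r1, c2, r2 = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
                if c1 != c2:
                    raise TLSFormatError("cross-chain RESIDUE RANGE unsupported", lineno)
                current["ranges"].append((c1, r1, r2))
                continue
            tags = _TENSOR_TAG.findall(line)
            if tags:
                expected = len(re.findall(r"[TLS][123][123]\s*:", line))
                if expected != len(tags):
                    raise TLSFormatError("malformed tensor line", lineno)
                for key, val in tags:
                    try:
                        current["elements"][key] = float(val)
                    except ValueError:
                        raise TLSFormatError(
                            f"bad numeric value {val!r} for {key}", lineno) from None

    groups: list[TLSGroup] = []
    for blk in blocks:
        el = blk["elements"]
        missing = [k for k in (*_T_KEYS, *_L_KEYS, *_S_KEYS) if k not in el]
        if missing:
            raise TLSFormatError(
                f"TLS block starting at line {blk['start_line']} is missing "
                f"tensor elements: {', '.join(missing)}")
        if blk["origin"] is None:
            raise TLSFormatError(
                f"TLS block starting at line {blk['start_line']} has no ORIGIN line")
        T = _tensor_from_upper(el, "T")
        L = _tensor_from_upper(el, "L") * _DEG2RAD ** 2
        S = np.array([[el["S11"], el["S12"], el["S13"]],
                      [el["S21"], el["S22"], el["S23"]],
                      [el["S31"], el["S32"], el["S33"]]]) * _DEG2RAD
        sel: set[tuple[str, int]] = set()
        for chain, lo, hi in blk["ranges"]:
            sel.update((chain, r) for r in range(lo, hi + 1))
        if not sel:
            warnings.warn(
                f"TLS block starting at line {blk['start_line']} has an empty "
                "selection; group retained", stacklevel=2)
        groups.append(TLSGroup(T=T, L=L, S=S, origin=blk["origin"],
                               selection=frozenset(sel)))
    return groups


def _contiguous_ranges(residues: Iterable[int]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for r in sorted(set(residues)):
        if out and r == out[-1][1] + 1:
            out[-1] = (out[-1][0], r)
        else:
            out.append((r, r))
    return out


def format_tls_records(groups: Sequence[TLSGroup]) -> list[str]:
    """Render TLS groups as REMARK 3 lines (inverse of :func:`parse_tls_records`)."""
    lines = ["REMARK   3  TLS DETAILS",
             f"REMARK   3   NUMBER OF TLS GROUPS : {len(groups)}"]
    for i, g in enumerate(groups, start=1):
        lines.append(f"REMARK   3  TLS GROUP : {i}")
        by_chain: dict[str, list[int]] = {}
        for chain, resnum in sorted(g.selection):
            by_chain.setdefault(chain, []).append(resnum)
        for chain in sorted(by_chain):
            for lo, hi in _contiguous_ranges(by_chain[chain]):
                lines.append(
                    f"REMARK   3   RESIDUE RANGE :   {chain:<4}{lo:>6}"
                    f"{'':8}{chain:<4}{hi:>6}")
        ox, oy, oz = g.origin
        lines.append(
            f"REMARK   3   ORIGIN FOR THE GROUP (A): {ox:9.4f} {oy:9.4f} {oz:9.4f}")
        T = g.T
        L = g.L / _DEG2RAD ** 2
        S = g.S / _DEG2RAD
        lines.append("REMARK   3   T TENSOR")
        lines.append(f"REMARK   3     T11: {T[0, 0]:9.4f} T22: {T[1, 1]:9.4f}")
        lines.append(f"REMARK   3     T33: {T[2, 2]:9.4f} T12: {T[0, 1]:9.4f}")
        lines.append(f"REMARK   3     T13: {T[0, 2]:9.4f} T23: {T[1, 2]:9.4f}")
        lines.append("REMARK   3   L TENSOR")
        lines.append(f"REMARK   3     L11: {L[0, 0]:9.4f} L22: {L[1, 1]:9.4f}")
        lines.append(f"REMARK   3     L33: {L[2, 2]:9.4f} L12: {L[0, 1]:9.4f}")
        lines.append(f"REMARK   3     L13: {L[0, 2]:9.4f} L23: {L[1, 2]:9.4f}")
        lines.append("REMARK   3   S TENSOR")
        lines.append(f"REMARK   3     S11: {S[0, 0]:9.4f} S12: {S[0, 1]:9.4f} "
                     f"S13: {S[0, 2]:9.4f}")
        lines.append(f"REMARK   3     S21: {S[1, 0]:9.4f} S22: {S[1, 1]:9.4f} "
                     f"S23: {S[1, 2]:9.4f}")
        lines.append(f"REMARK   3     S31: {S[2, 0]:9.4f} S32: {S[2, 1]:9.4f} "
                     f"S33: {S[2, 2]:9.4f}")
    return lines
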