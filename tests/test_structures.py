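import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from tlsdiffuse import (
    Atom,
    Ensemble,
    Model,
    TLSGroup,
    UnitCell,
    parse_tls_records,
    read_pdb_multimodel,
    validate_tls,
    write_pdb_multimodel,
)
from tlsdiffuse.structures import PDBFormatError, TLSFormatError, format_tls_records


def _atom(x, y, z, **kw):
    defaults = dict(element="C", occupancy=1.0, b_iso=15.0,
                    chain_id="A", residue_number=1, atom_name="C1")
    defaults.update(kw)
    return Atom(position=np.array([x, y, z]), **defaults)


class TestUnitCell:
    @pytest.mark.parametrize("bad", [
        dict(a=-1, b=10, c=10),
        dict(a=10, b=0, c=10),
        dict(a=10, b=10, c=10, alpha=0),
        dict(a=10, b=10, c=10, gamma=180),
        # angle combination violating the metric positivity
        dict(a=10, b=10, c=10, alpha=170, beta=170, gamma=170),
    ])
    def test_invalid_cells_rejected(self, bad):
        with pytest.raises(ValueError):
            UnitCell(**bad)

    def test_orthogonal_metrics(self):
        cell = UnitCell(10, 20, 40)
        assert cell.volume == pytest.approx(8000)
        d = cell.d_spacing(np.array([[1, 0, 0], [0, 2, 0], [1, 1, 1]]))
        assert d[0] == pytest.approx(10)
        assert d[1] == pytest.approx(10)
        assert d[2] == pytest.approx(1 / math.sqrt(0.01 + 0.0025 + 0.000625))

    def test_frac_orth_inverse(self):
        cell = UnitCell(23, 31, 47, 85, 95, 103)
        xyz = np.random.default_rng(0).uniform(-10, 50, (20, 3))
        assert np.allclose(cell.orthogonalize(cell.fractionalize(xyz)), xyz)


class TestPDBRoundTrip:
    def _random_ensemble(self, seed, n_models=3, n_atoms=7):
        rng = np.random.default_rng(seed)
        cell = UnitCell(25, 30, 35, 90, 100, 90)
        base = [
            _atom(*rng.uniform(1, 20, 3),
                  element=["C", "N", "O"][i % 3],
                  occupancy=round(float(rng.uniform(0.2, 1.0)), 2),
                  b_iso=round(float(rng.uniform(5, 60)), 2),
                  chain_id="A" if i < n_atoms // 2 else "B",
                  residue_number=1 + i,
                  atom_name=f"X{i}")
            for i in range(n_atoms)
        ]
        models = []
        for m in range(n_models):
            shift = rng.normal(0, 1, (n_atoms, 3))
            models.append(Model(
                [Atom(a.element, a.position + shift[i], a.occupancy, a.b_iso,
                      a.chain_id, a.residue_number, a.atom_name)
                 for i, a in enumerate(base)], model_id=m + 1))
        return Ensemble(models, cell, spacegroup="P 1")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_positions_quantized(self, seed, tmp_path):
        """Write->read is the identity up to 3-decimal coordinate quantization."""
        ens = self._random_ensemble(seed)
        path = tmp_path / "ens.pdb"
        write_pdb_multimodel(ens, path)
        back = read_pdb_multimodel(path)
        assert back.n_models == ens.n_models
        assert back.n_atoms == ens.n_atoms
        assert np.allclose(back.coordinates(), ens.coordinates(), atol=5.1e-4)
        for a, b in zip(ens.models[0].atoms, back.models[0].atoms):
            assert a.key == b.key
            assert b.occupancy == pytest.approx(a.occupancy, abs=0.005)
            assert b.b_iso == pytest.approx(a.b_iso, abs=0.005)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_models=st.integers(1, 4))
    def test_round_trip_property(self, seed, n_models, tmp_path_factory):
        ens = self._random_ensemble(seed, n_models=n_models)
        path = tmp_path_factory.mktemp("rt") / "e.pdb"
        write_pdb_multimodel(ens, path)
        back = read_pdb_multimodel(path)
        assert np.allclose(back.coordinates(), ens.coordinates(), atol=5.1e-4)

    def test_single_model_block_count(self, tmp_path):
        ens = self._random_ensemble(0, n_models=1)
        path = tmp_path / "one.pdb"
        write_pdb_multimodel(ens, path)
        text = path.read_text()
        assert text.count("MODEL ") == 1 and text.count("ENDMDL") == 1

    def test_missing_cryst1_rejected(self, tmp_path):
        path = tmp_path / "nocell.pdb"
        path.write_text(
            "ATOM      1  C1  UNK A   1       1.000   2.000   3.000"
            "  1.00 10.00           C\nEND\n")
        with pytest.raises(PDBFormatError, match="CRYST1"):
            read_pdb_multimodel(path)

    def test_roster_mismatch_names_offender(self, tmp_path):
        lines = [
            "CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1",
            "MODEL        1",
            "ATOM      1  C1  UNK A   1       1.000   2.000   3.000  1.00 10.00           C",
            "ENDMDL",
            "MODEL        2",
            "ATOM      1  C2  UNK A   1       1.000   2.000   3.000  1.00 10.00           C",
            "ENDMDL",
            "END",
        ]
        path = tmp_path / "bad.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(PDBFormatError, match="C2"):
            read_pdb_multimodel(path)

    def test_water_and_hydrogen_filtering(self, tmp_path):
        lines = [
            "CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1",
            "ATOM      1  C1  UNK A   1       1.000   2.000   3.000  1.00 10.00           C",
            "ATOM      2  H1  UNK A   1       1.500   2.000   3.000  1.00 10.00           H",
            "HETATM    3  O   HOH A   2       9.000   9.000   9.000  1.00 20.00           O",
            "END",
        ]
        path = tmp_path / "filt.pdb"
        path.write_text("\n".join(lines) + "\n")
        assert read_pdb_multimodel(path).n_atoms == 1
        assert read_pdb_multimodel(path, keep_waters=True).n_atoms == 2
        assert read_pdb_multimodel(path, keep_hydrogens=True).n_atoms == 2
        assert read_pdb_multimodel(path, keep_waters=True,
                                   keep_hydrogens=True).n_atoms == 3

    def test_altloc_keeps_a_or_blank(self, tmp_path):
        lines = [
            "CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1",
            "ATOM      1  C1 AUNK A   1       1.000   2.000   3.000  0.60 10.00           C",
            "ATOM      2  C1 BUNK A   1       1.400   2.000   3.000  0.40 10.00           C",
            "ATOM      3  N1  UNK A   2       5.000   5.000   5.000  1.00 10.00           N",
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        ens = read_pdb_multimodel(path)
        assert ens.n_atoms == 2
        assert ens.models[0].atoms[0].occupancy == pytest.approx(0.6)


class TestTLSRecords:
    def _group(self, seed=0):
        from tlsdiffuse import make_random_tls

        return make_random_tls({("A", i) for i in range(1, 8)},
                               origin=[5.0, -3.0, 12.0], seed=seed)

    def test_no_blocks_empty_list(self, tmp_path):
        path = tmp_path / "plain.pdb"
        path.write_text("CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1\nEND\n")
        assert parse_tls_records(path) == []

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_write_parse_round_trip(self, seed, tmp_path):
        """Tensors survive the REMARK 3 dialect within 4-decimal precision."""
        g = self._group(seed)
        path = tmp_path / "tls.pdb"
        path.write_text("\n".join(format_tls_records([g])) + "\n")
        (back,) = parse_tls_records(path)
        assert np.allclose(back.T, g.T, atol=1e-4)
        assert np.allclose(back.L, g.L, atol=1e-4 * np.deg2rad(1) ** 2 * 100)
        assert np.allclose(back.S, g.S, atol=1e-4 * np.deg2rad(1) * 10)
        assert back.selection == g.selection
        assert np.allclose(back.origin, g.origin, atol=1e-4)

    def test_three_blocks_disjoint_selections(self, tmp_path):
        gs = [self._group(i) for i in range(3)]
        sels = [frozenset({("ABC"[i], r) for r in range(1, 5)}) for i in range(3)]
        gs = [TLSGroup(g.T, g.L, g.S, g.origin, sels[i]) for i, g in enumerate(gs)]
        path = tmp_path / "three.pdb"
        path.write_text("\n".join(format_tls_records(gs)) + "\n")
        back = parse_tls_records(path)
        assert len(back) == 3
        for a in range(3):
            for b in range(a + 1, 3):
                assert not (back[a].selection & back[b].selection)

    def test_deg_to_rad_conversion(self, tmp_path):
        lines = format_tls_records([TLSGroup(
            T=np.eye(3) * 0.01,
            L=np.eye(3) * np.deg2rad(2.0) ** 2,  # = 4 deg^2 in the header
            S=np.zeros((3, 3)),
            origin=np.zeros(3),
            selection={("A", 1)})])
        assert any("L11:    4.0000" in ln for ln in lines)
        path = tmp_path / "units.pdb"
        path.write_text("\n".join(lines) + "\n")
        (back,) = parse_tls_records(path)
        assert back.L[0, 0] == pytest.approx(4.0 * (math.pi / 180) ** 2)

    def test_line_reordering_invariance(self, tmp_path):
        g = self._group(4)
        lines = format_tls_records([g])
        tensor = [ln for ln in lines if any(
            f"{p}{i}{j}:" in ln for p in "TLS" for i in "123" for j in "123")]
        other = [ln for ln in lines if ln not in tensor]
        path = tmp_path / "shuf.pdb"
        path.write_text("\n".join(other + tensor[::-1]) + "\n")
        (back,) = parse_tls_records(path)
        assert np.allclose(back.T, g.T, atol=1e-4)
        assert np.allclose(back.S, g.S, atol=1e-3)

    def test_malformed_tensor_line_reports_line_number(self, tmp_path):
        lines = format_tls_records([self._group(0)])
        bad_i = next(i for i, ln in enumerate(lines) if "T11:" in ln)
        lines[bad_i] = lines[bad_i].replace(":", ": oops", 1)
        path = tmp_path / "bad.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TLSFormatError, match=f"line {bad_i + 1}"):
            parse_tls_records(path)

    def test_empty_selection_warns_but_keeps_group(self, tmp_path):
        g = self._group(1)
        lines = [ln for ln in format_tls_records([g]) if "RESIDUE RANGE" not in ln]
        path = tmp_path / "nosel.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.warns(UserWarning, match="empty"):
            (back,) = parse_tls_records(path)
        assert back.selection == frozenset()

    def test_trace_convention_recentered(self):
        g = TLSGroup(T=np.eye(3) * 0.01, L=np.eye(3) * 1e-3,
                     S=np.diag([0.3, 0.0, 0.0]), origin=np.zeros(3),
                     selection=set())
        assert np.trace(g.S) == pytest.approx(0.0, abs=1e-12)
        assert g.S[0, 0] == pytest.approx(0.2)


class TestValidateTLS:
    def test_zero_group_is_physical(self):
        z = np.zeros((3, 3))
        rep = validate_tls(TLSGroup(z, z, z, np.zeros(3), set()))
        assert rep.is_physical
        assert rep.t_eigenvalues == (0, 0, 0)

    def test_diagonal_eigenvalues_sorted_descending(self):
        g = TLSGroup(np.diag([0.01, 0.02, 0.03]), np.zeros((3, 3)),
                     np.zeros((3, 3)), np.zeros(3), set())
        rep = validate_tls(g)
        assert rep.is_physical
        assert np.allclose(rep.t_eigenvalues, (0.03, 0.02, 0.01))

    def test_rotated_negative_eigenvalue_detected(self):
        """An indefinite T hidden by a similarity transform is caught."""
        R = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        T = R @ np.diag([0.05, 0.01, -0.02]) @ R.T
        rep = validate_tls(TLSGroup(T, np.zeros((3, 3)), np.zeros((3, 3)),
                                    np.zeros(3), set()))
        assert not rep.is_physical
        assert rep.t_eigenvalues[2] == pytest.approx(-0.02)

    @pytest.mark.parametrize("seed", range(4))
    def test_physicality_invariant_under_frame_rotation(self, seed):
        from tlsdiffuse import make_random_tls

        g = make_random_tls(set(), np.zeros(3), seed=seed)
        R = Rotation.random(rng=np.random.default_rng(seed + 100)).as_matrix()
        rotated = TLSGroup(R @ g.T @ R.T, R @ g.L @ R.T, R @ g.S @ R.T,
                           R @ g.origin, set())
        assert validate_tls(g).is_physical == validate_tls(rotated).is_physical


class TestEnsembleInvariants:
    def test_mismatched_roster_rejected(self):
        cell = UnitCell(20, 20, 20)
        m1 = Model([_atom(1, 1, 1)], 1)
        m2 = Model([_atom(1, 1, 1, atom_name="C9")], 2)
        with pytest.raises(ValueError, match="roster"):
            Ensemble([m1, m2], cell)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            Ensemble([], UnitCell(20, 20, 20))

    def test_occupancy_bounds(self):
        with pytest.raises(ValueError):
            _atom(0, 0, 0, occupancy=1.5)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="element"):
            _atom(0, 0, 0, element="Xx")
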