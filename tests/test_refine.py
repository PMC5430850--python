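"""Restrained refinement: restraint generation and minimisation."""

import math

import numpy as np
import pytest

from hairpinforge import (MinimizerConfig, NucSequence, build_restraints,
                          build_rna_3d, fold_mfe, minimize, perturb)
from hairpinforge.errors import ConsistencyError
from hairpinforge.nucio import AtomRecord, Model3D, Residue3D
from hairpinforge.refine import RestraintSet, _objective, write_trace
from hairpinforge import chem


@pytest.fixture(scope="module")
def built_1bjh():
    seq = NucSequence("1BJH", "GTACAAAGTAC")
    return build_rna_3d(seq, fold_mfe(seq, closed=True))


class TestBuildRestraints:
    def test_every_linkage_is_a_bond_term(self, built_1bjh):
        rs = build_restraints(built_1bjh)
        flat = built_1bjh.atom_index()
        linkages = [
            (i, j) for i, j in rs.bond_idx
            if flat[i][2] == "O3'" and flat[j][2] == "P"
            and flat[i][0] + 1 == flat[j][0]]
        assert len(linkages) == 10  # n - 1 phosphodiester bonds

    def test_single_residue_bond_count_matches_topology(self):
        seq = NucSequence("x", "A")
        from hairpinforge import SecondaryStructure
        m = build_rna_3d(seq, SecondaryStructure(pair=[0]))
        rs = build_restraints(m)
        want = chem.residue_bonds("A", has_5p_phosphate=False,
                                  is_3p_terminal=True,
                                  is_5p_terminal=True)
        assert len(rs.bond_idx) == len(want)

    def test_counts_report(self, built_1bjh):
        counts = build_restraints(built_1bjh).counts()
        assert counts["planes"] == 11          # one base plane per residue
        assert counts["bonds"] > counts["planes"]
        assert counts["angles"] > counts["bonds"]


class TestObjectiveGradient:
    def test_matches_finite_differences(self, built_1bjh):
        rs = build_restraints(built_1bjh)
        # evaluate at a deformed point so every term is active
        rng = np.random.default_rng(7)
        x = built_1bjh.coords() + rng.normal(0, 0.15,
                                             built_1bjh.coords().shape)
        f, g = _objective(x, rs)
        for _ in range(30):
            i = rng.integers(0, x.shape[0])
            d = rng.integers(0, 3)
            h = 1e-6
            xp = x.copy()
            xp[i, d] += h
            xm = x.copy()
            xm[i, d] -= h
            fd = (_objective(xp, rs, want_grad=False)
                  - _objective(xm, rs, want_grad=False)) / (2 * h)
            assert g[i, d] == pytest.approx(fd, rel=1e-3, abs=1e-5)


def _two_atom_model(distance):
    return Model3D("A", [Residue3D("DA", 1, [
        AtomRecord("C5", "C", np.array([0.0, 0.0, 0.0])),
        AtomRecord("C6", "C", np.array([distance, 0.0, 0.0])),
    ])], "DNA")


class TestMinimize:
    def test_repulsion_separates_close_pair(self):
        model = _two_atom_model(0.8)
        rs = RestraintSet(
            bond_idx=np.empty((0, 2), dtype=int),
            bond_target=np.empty(0),
            angle_idx=np.empty((0, 3), dtype=int),
            angle_target=np.empty(0), plane_groups=[],
            torsion_idx=np.empty((0, 4), dtype=int),
            torsion_target=np.empty(0), exclusions=set())
        out, trace = minimize(model, rs,
                              MinimizerConfig(max_iterations=500))
        seps = []
        cur = model
        for _ in range(8):
            cur, t = minimize(cur, rs,
                              MinimizerConfig(max_iterations=5))
            seps.append(np.linalg.norm(cur.coords()[0] - cur.coords()[1]))
        assert all(seps[i + 1] >= seps[i] - 1e-12
                   for i in range(len(seps) - 1))
        final = np.linalg.norm(out.coords()[0] - out.coords()[1])
        assert final > 0.8

    def test_trace_is_monotone(self, built_1bjh, assert_monotone):
        rs = build_restraints(built_1bjh)
        _, trace = minimize(built_1bjh, rs,
                            MinimizerConfig(max_iterations=300))
        assert assert_monotone(trace)
        assert len(trace) <= 301

    def test_gauss_newton_also_descends(self, built_1bjh,
                                        assert_monotone):
        rs = build_restraints(built_1bjh)
        _, trace = minimize(built_1bjh, rs, MinimizerConfig(
            max_iterations=10, method="gauss_newton"))
        assert assert_monotone(trace)
        assert trace[-1] < trace[0]

    def test_rotation_invariance(self, built_1bjh):
        """Rigidly rotating the input rotates the output identically
        (checked over a window short enough that floating-point path
        bifurcation cannot occur)."""
        rs = build_restraints(built_1bjh)
        cfg = MinimizerConfig(max_iterations=40)
        out_a, trace_a = minimize(built_1bjh, rs, cfg)

        theta = math.radians(37.0)
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0],
                      [0, 0, 1.0]])
        t = np.array([5.0, -3.0, 2.0])
        rotated = built_1bjh.copy()
        rotated.set_coords(built_1bjh.coords() @ R.T + t)
        out_b, trace_b = minimize(rotated, rs, cfg)
        assert trace_b[-1] == pytest.approx(trace_a[-1], rel=1e-6,
                                            abs=1e-9)
        assert np.allclose(out_b.coords(),
                           out_a.coords() @ R.T + t, atol=1e-6)

    def test_atom_identity_preserved(self, built_1bjh):
        rs = build_restraints(built_1bjh)
        out, _ = minimize(built_1bjh, rs,
                          MinimizerConfig(max_iterations=50))
        assert out.atom_index() == built_1bjh.atom_index()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConsistencyError):
            MinimizerConfig(max_iterations=0)
        with pytest.raises(ConsistencyError):
            MinimizerConfig(convergence_tol=0.0)


class TestIdealModelStationarity:
    def test_settled_model_barely_moves(self, ideal_hairpin):
        _, _, ideal, rs = ideal_hairpin
        out, trace = minimize(ideal, rs,
                              MinimizerConfig(max_iterations=300,
                                              convergence_tol=1e-10))
        # already at (numerical) minimum: tiny objective change, tiny
        # coordinate motion
        assert trace[-1] <= trace[0] + 1e-9
        assert trace[0] - trace[-1] < 0.02
        assert np.abs(out.coords() - ideal.coords()).max() < 0.05

    def test_chain_integrity_at_minimum(self, ideal_hairpin):
        _, _, ideal, rs = ideal_hairpin
        for k in range(len(ideal.residues) - 1):
            gap = np.linalg.norm(ideal.residues[k].atom("O3'").xyz
                                 - ideal.residues[k + 1].atom("P").xyz)
            assert gap == pytest.approx(1.60, abs=0.05)


class TestTraceOutput:
    def test_tsv_written(self, tmp_path, built_1bjh):
        rs = build_restraints(built_1bjh)
        _, trace = minimize(built_1bjh, rs,
                            MinimizerConfig(max_iterations=5))
        p = tmp_path / "trace.tsv"
        write_trace(trace, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "iteration\tobjective"
        assert len(lines) == len(trace) + 1
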