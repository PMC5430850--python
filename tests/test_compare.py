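"""Kabsch superposition and backbone RMSD."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation

from hairpinforge import (FixtureSpec, backbone_rmsd, kabsch_superpose,
                          perturb, rmsd_report, synthetic_hairpin)
from hairpinforge.errors import (CorrespondenceError,
                                 DegenerateInputError)


def _rigid(points, angle_deg=37.0, axis=(0, 0, 1), t=(5.0, -3.0, 2.0)):
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.asarray(axis,
                                                                float))
    return R.apply(points) + np.asarray(t)


class TestKabsch:
    def test_identical_sets(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        res = kabsch_superpose(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered_exactly(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(12, 3))
        Q = _rigid(P)
        res = kabsch_superpose(P, Q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.apply(P), Q, atol=1e-9)

    def test_rotation_is_proper(self):
        # a mirrored set must not be matched by a reflection
        rng = np.random.default_rng(1)
        P = rng.normal(size=(6, 3))
        Q = P * np.array([-1.0, 1.0, 1.0])
        res = kabsch_superpose(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0,
                                                            abs=1e-9)
        assert res.rmsd > 0.1

    def test_matches_numeric_optimiser_on_small_sets(self):
        """Independent oracle: direct minimisation over rotation-vector
        parameters must reach the same optimum on <= 6-point sets."""
        rng = np.random.default_rng(2)
        for n in (3, 4, 5, 6):
            P = rng.normal(size=(n, 3)) * 2.0
            Q = _rigid(P, angle_deg=61.0, axis=(1, 2, 0.5)) \
                + rng.normal(0, 0.4, size=(n, 3))

            def cost(x):
                R = Rotation.from_rotvec(x[:3])
                moved = R.apply(P) + x[3:]
                return np.mean(np.sum((moved - Q) ** 2, axis=1))

            best = None
            for k in range(12):
                x0 = np.concatenate([
                    Rotation.random(
                        random_state=100 + k).as_rotvec(),
                    Q.mean(axis=0) - P.mean(axis=0)])
                r = scipy_minimize(cost, x0, method="Nelder-Mead",
                                   options={"xatol": 1e-12,
                                            "fatol": 1e-14,
                                            "maxiter": 20000})
                if best is None or r.fun < best.fun:
                    best = r
            oracle = math.sqrt(best.fun)
            assert kabsch_superpose(P, Q).rmsd == pytest.approx(
                oracle, abs=1e-6)

    def test_errors(self):
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(CorrespondenceError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


@pytest.fixture(scope="module")
def hairpin_model():
    _, _, model = synthetic_hairpin(FixtureSpec(4, 3, seed=5))
    return model


class TestBackboneRmsd:
    def test_self_is_zero(self, hairpin_model):
        assert backbone_rmsd(hairpin_model, hairpin_model) == \
            pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, hairpin_model):
        ref = perturb(hairpin_model, 0.2, seed=9)
        moved = hairpin_model.copy()
        moved.set_coords(_rigid(hairpin_model.coords()))
        a = backbone_rmsd(hairpin_model, ref)
        b = backbone_rmsd(moved, ref)
        assert a == pytest.approx(b, abs=1e-9)

    def test_equals_direct_formula_on_matched_atoms(self, hairpin_model):
        from hairpinforge.compare import _backbone_coords
        other = perturb(hairpin_model, 0.2, seed=3)
        xa, _ = _backbone_coords(hairpin_model, "backbone")
        xb, _ = _backbone_coords(other, "backbone")
        sup = kabsch_superpose(xa, xb)
        direct = math.sqrt(np.mean(np.sum(
            (sup.apply(xa) - xb) ** 2, axis=1)))
        assert backbone_rmsd(hairpin_model, other) == pytest.approx(
            direct, abs=1e-12)

    def test_excludes_base_atoms(self, hairpin_model):
        """Displacing only base atoms leaves the backbone RMSD at 0."""
        from hairpinforge import chem
        moved = hairpin_model.copy()
        for res in moved.residues:
            base = chem.RESIDUE_CODES[res.name][1]
            for a in res.atoms:
                if a.name in chem.BASE_ATOMS[base]:
                    a.xyz = a.xyz + np.array([0.7, 0.0, 0.0])
        assert backbone_rmsd(hairpin_model, moved) == pytest.approx(
            0.0, abs=1e-9)

    def test_length_mismatch_is_error(self, hairpin_model):
        _, _, other = synthetic_hairpin(FixtureSpec(5, 3, seed=5))
        with pytest.raises(CorrespondenceError, match="11.*13|13.*11"):
            backbone_rmsd(hairpin_model, other)

    def test_p_only_selection(self, hairpin_model):
        other = perturb(hairpin_model, 0.2, seed=4)
        r_backbone = backbone_rmsd(hairpin_model, other, "backbone")
        r_p = backbone_rmsd(hairpin_model, other, "p-only")
        assert r_p > 0
        assert r_p != pytest.approx(r_backbone, abs=1e-6)


class TestRmsdReport:
    def test_identical_pair(self, hairpin_model):
        df = rmsd_report([("self", hairpin_model, hairpin_model)])
        assert len(df) == 2  # one row + mean
        assert df.iloc[0]["rmsd"] == pytest.approx(0.0, abs=1e-12)
        assert df.iloc[-1]["label"] == "mean"
        assert df.iloc[-1]["rmsd"] == pytest.approx(0.0, abs=1e-12)

    def test_mean_is_arithmetic_mean(self):
        pairs = []
        for k, (stem, loop) in enumerate([(3, 3), (4, 3), (5, 4),
                                          (6, 3), (4, 5)]):
            _, _, m = synthetic_hairpin(FixtureSpec(stem, loop, seed=k))
            pairs.append((f"p{k}", m, perturb(m, 0.25, seed=k)))
        df = rmsd_report(pairs)
        rows = df[df["label"] != "mean"]
        assert df.iloc[-1]["rmsd"] == pytest.approx(
            rows["rmsd"].mean(), abs=1e-12)
        assert list(rows["chain_length"]) == \
            sorted(rows["chain_length"])

    def test_noise_scaling_orders_rmsd_by_length(self):
        """References perturbed with sigma proportional to length give
        an RMSD column that increases with length (by construction)."""
        pairs = []
        for k, stem in enumerate([2, 4, 6, 8]):
            _, _, m = synthetic_hairpin(FixtureSpec(stem, 3, seed=40))
            sigma = 0.05 * len(m.residues)
            pairs.append((f"L{len(m.residues)}", m,
                          perturb(m, sigma, seed=k)))
        df = rmsd_report(pairs)
        rows = df[df["label"] != "mean"]
        rmsds = list(rows["rmsd"])
        assert rmsds == sorted(rmsds)

    def test_error_names_offending_label(self, hairpin_model):
        _, _, other = synthetic_hairpin(FixtureSpec(5, 3, seed=5))
        with pytest.raises(CorrespondenceError, match="badpair"):
            rmsd_report([("badpair", hairpin_model, other)])
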