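"""Template library and 3D model construction."""

import numpy as np
import pytest

from hairpinforge import (NucSequence, SecondaryStructure, build_rna_3d,
                          fold_mfe, load_templates)
from hairpinforge import chem
from hairpinforge.errors import (ConsistencyError,
                                 TemplateValidationError)


@pytest.fixture(scope="module")
def lib():
    return load_templates("builtin")


class TestTemplates:
    def test_builtin_has_rna_and_dna_residues(self, lib):
        assert {"A", "C", "G", "U"} <= set(lib.residues)
        assert {"DA", "DC", "DG", "DT", "DU"} <= set(lib.residues)

    def test_wc_partner_contacts_in_hbond_range(self, lib):
        flip = np.diag([1.0, -1.0, -1.0])
        for n1, n2 in [("A", "U"), ("G", "C")]:
            t1 = lib.residues[n1].atoms
            t2 = lib.residues[n2].atoms
            for a1, a2, _ in chem.wc_hbonds(chem.RESIDUE_CODES[n1][1],
                                            chem.RESIDUE_CODES[n2][1]):
                d = np.linalg.norm(t1[a1] - flip @ t2[a2])
                assert 2.8 <= d <= 3.0

    def test_corrupted_bond_is_rejected(self, lib, tmp_path):
        import importlib.resources
        text = (importlib.resources.files("hairpinforge.data")
                / "templates_v1.txt").read_text()
        # stretch the adenosine C1'-C2' bond to ~2.5 A
        out = []
        in_a = False
        for line in text.splitlines():
            if line.startswith("[residue A]"):
                in_a = True
            elif line.startswith("["):
                in_a = False
            if in_a and line.startswith("C2' "):
                f = line.split()
                line = (f"{f[0]:5s} {f[1]} {float(f[2]) + 1.0:9.4f} "
                        f"{float(f[3]):9.4f} {float(f[4]):9.4f}")
            out.append(line)
        bad = tmp_path / "bad.txt"
        bad.write_text("\n".join(out) + "\n")
        with pytest.raises(TemplateValidationError, match="C1'-C2'|C2'"):
            load_templates(bad)


class TestBuild:
    def test_single_nucleotide(self):
        seq = NucSequence("x", "G")
        m = build_rna_3d(seq, SecondaryStructure(pair=[0]))
        assert len(m.residues) == 1
        assert m.chemistry == "RNA"
        # 5'-OH + 3'-OH guanosine: 19-1(no H2'')+... full inventory
        assert set(m.residues[0].atom_names) == set(chem.expected_atoms(
            "G", has_5p_phosphate=False, is_3p_terminal=True,
            is_5p_terminal=True))

    def test_t_is_rendered_as_u(self, pipeline_folds):
        seq, ss = pipeline_folds["1BJH"]
        m = build_rna_3d(seq, ss)
        assert set(r.name for r in m.residues) <= {"A", "C", "G", "U"}
        assert m.sequence_letters() == seq.residues.replace("T", "U")

    def test_wc_geometry_of_built_stem(self, pipeline_folds):
        seq, ss = pipeline_folds["1BJH"]
        m = build_rna_3d(seq, ss)
        for i, j in ss.pairs():
            ri, rj = m.residues[i - 1], m.residues[j - 1]
            bi = chem.RESIDUE_CODES[ri.name][1]
            bj = chem.RESIDUE_CODES[rj.name][1]
            for a1, a2, _ in chem.wc_hbonds(bi, bj):
                d = np.linalg.norm(ri.atom(a1).xyz - rj.atom(a2).xyz)
                assert 2.8 <= d <= 3.05

    def test_axial_rise_matches_configured_value(self):
        lib = load_templates("builtin")
        seq = NucSequence("x", "GGGGGGAAACCCCCC")
        pair = [0] * 15
        for k in range(6):
            pair[k] = 15 - k
            pair[14 - k] = k + 1
        m = build_rna_3d(seq, SecondaryStructure(pair=pair))
        c1 = [m.residues[k].atom("C1'").xyz for k in range(6)]
        rises = [c1[k + 1][2] - c1[k][2] for k in range(5)]
        # pair steps advance along the helix axis (z) by the configured
        # rise; fitting it back recovers the parameter within 1%
        for r in rises:
            assert r == pytest.approx(lib.rise, abs=0.05)
        assert np.mean(rises) == pytest.approx(lib.rise, rel=0.01)

    def test_twist_recovered_from_built_stem(self):
        lib = load_templates("builtin")
        seq = NucSequence("x", "GGGGGGAAACCCCCC")
        pair = [0] * 15
        for k in range(6):
            pair[k] = 15 - k
            pair[14 - k] = k + 1
        m = build_rna_3d(seq, SecondaryStructure(pair=pair))
        # project glycosidic N onto the xy plane and measure step twist
        import math
        angles = []
        for k in range(6):
            v = m.residues[k].atom("N9").xyz if \
                m.residues[k].has_atom("N9") else \
                m.residues[k].atom("N1").xyz
            c = m.residues[k].atom("C1'").xyz
            d = v - c
            angles.append(math.degrees(math.atan2(d[1], d[0])))
        twists = [(angles[k + 1] - angles[k]) % 360 for k in range(5)]
        for t in twists:
            assert t == pytest.approx(lib.twist, abs=1.0)

    def test_no_steric_collapse(self, pipeline_folds):
        for name in ("1BJH", "2L5K"):
            seq, ss = pipeline_folds[name]
            m = build_rna_3d(seq, ss)
            coords = [np.array([a.xyz for a in r.atoms])
                      for r in m.residues]
            for i in range(len(coords)):
                for j in range(i + 2, len(coords)):
                    d = np.linalg.norm(coords[i][:, None]
                                       - coords[j][None, :], axis=-1)
                    assert d.min() >= 1.5

    def test_deterministic(self, pipeline_folds):
        seq, ss = pipeline_folds["2M8Y"]
        m1 = build_rna_3d(seq, ss)
        m2 = build_rna_3d(seq, ss)
        assert np.array_equal(m1.coords(), m2.coords())

    def test_atom_inventory_per_position(self, pipeline_folds):
        seq, ss = pipeline_folds["1LA8"]
        m = build_rna_3d(seq, ss)
        n = len(m.residues)
        for k, res in enumerate(m.residues):
            want = chem.expected_atoms(
                res.name, has_5p_phosphate=(k > 0),
                is_3p_terminal=(k == n - 1), is_5p_terminal=(k == 0))
            assert sorted(res.atom_names) == sorted(want)

    def test_length_mismatch_is_error(self):
        seq = NucSequence("x", "GTAC")
        with pytest.raises(ConsistencyError):
            build_rna_3d(seq, SecondaryStructure(pair=[0, 0, 0]))
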