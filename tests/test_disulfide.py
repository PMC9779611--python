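import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sialofold import fixtures
from sialofold.disulfide import (
    NotationError,
    consensus_topology,
    detect_bonds,
    dimer_bridge_scan,
    parse_notation,
    render_dash,
    render_pipe,
)
from sialofold.structmodel import parse_pdb_text


def _random_pairing(rng, n_cys):
    """Random partial pairing of ordinals 1..n_cys."""
    ordinals = list(range(1, n_cys + 1))
    rng.shuffle(ordinals)
    n_bonds = int(rng.integers(0, n_cys // 2 + 1))
    return [
        (min(ordinals[2 * i], ordinals[2 * i + 1]), max(ordinals[2 * i], ordinals[2 * i + 1]))
        for i in range(n_bonds)
    ]


def _model_for(pairs, n_cys, seed=0):
    text = fixtures.make_cys_structure([(a, b, 2.05) for a, b in pairs], n_cys, seed=seed)
    return parse_pdb_text(text, model_id=f"rand{seed}")


class TestDetect:
    def test_pair_below_cutoff(self):
        model = _model_for([(1, 2)], 2)
        topo = detect_bonds(model)
        assert len(topo.bonds) == 1
        assert topo.bonds[0].distance == pytest.approx(2.05, abs=1e-3)
        assert topo.free == []

    def test_pair_above_cutoff(self):
        text = fixtures.make_cys_structure([(1, 2, 3.20)], 2, seed=0)
        topo = detect_bonds(parse_pdb_text(text))
        assert topo.bonds == []
        assert len(topo.free) == 2

    def test_cutoff_boundary_strict(self):
        text = fixtures.make_cys_structure([(1, 2, 3.0)], 2, seed=0)
        topo = detect_bonds(parse_pdb_text(text))
        assert topo.bonds == []  # "smaller than" the cutoff, not equal

    def test_seven_cys_pattern(self, cys7_model):
        topo = detect_bonds(cys7_model)
        assert topo.notation_dash == "C1-C6, C2-C4, C3-C5"
        assert [s.ordinal for s in topo.free] == [7]

    def test_no_cysteines_empty_topology(self):
        model = fixtures.ideal_helix(10)
        topo = detect_bonds(model)
        assert topo.bonds == [] and topo.free == [] and topo.sites == []

    def test_missing_sg_counted_free_with_warning(self, cys7_model):
        cys = [r for c in cys7_model.chains for r in c.residues if r.name == "CYS"]
        cys[6].atoms[:] = [a for a in cys[6].atoms if a.name != "SG"]
        with pytest.warns(UserWarning, match="SG"):
            topo = detect_bonds(cys7_model)
        assert any(not s.has_sg for s in topo.free)
        assert topo.check_conservation()

    def test_rigid_motion_invariance(self, cys7_model):
        before = detect_bonds(cys7_model).bond_keys
        rng = np.random.default_rng(0)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        for chain in cys7_model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    v = R @ np.array([atom.x, atom.y, atom.z]) + np.array([5.0, -3.0, 2.0])
                    atom.x, atom.y, atom.z = map(float, v)
        assert detect_bonds(cys7_model).bond_keys == before

    def test_cutoff_monotonicity(self, cys7_model):
        small = detect_bonds(cys7_model, cutoff_angstrom=2.5)
        large = detect_bonds(cys7_model, cutoff_angstrom=6.0)
        assert len(large.bonds) >= len(small.bonds)

    def test_greedy_conflict_resolution(self):
        # three SGs in a row: 1-2 at 2.0, 2-3 at 2.4 -> only the closer pair bonds
        from sialofold.structmodel import Atom, Chain, Residue, StructureModel

        chain = Chain("A")
        for i, x in enumerate([0.0, 2.0, 4.4]):
            res = Residue("CYS", i + 1)
            res.atoms.append(Atom("CA", "C", x, 5.0, 0.0))
            res.atoms.append(Atom("SG", "S", x, 0.0, 0.0))
            chain.residues.append(res)
        topo = detect_bonds(StructureModel("tri", [chain]))
        assert topo.notation_dash == "C1-C2"
        assert [s.ordinal for s in topo.free] == [3]

    def test_maxweight_mode_matches_greedy_on_clean_geometry(self, cys7_model):
        greedy = detect_bonds(cys7_model, matching="greedy").bond_keys
        exact = detect_bonds(cys7_model, matching="maxweight").bond_keys
        assert greedy == exact

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        n_cys = int(rng.integers(2, 9))
        pairs = _random_pairing(rng, n_cys)
        topo = detect_bonds(_model_for(pairs, n_cys, seed=seed % 100))
        assert topo.check_conservation()
        assert {tuple(sorted((b.site_a.ordinal, b.site_b.ordinal))) for b in topo.bonds} == set(
            pairs
        )


class TestNotation:
    def test_dash_parse(self):
        assert parse_notation("C1-C4, C2-C5, C3-C6") == {(1, 4), (2, 5), (3, 6)}

    def test_endash_parse(self):
        assert parse_notation("C1–C4, C2–C5, C3–C6") == {(1, 4), (2, 5), (3, 6)}

    def test_pipe_parse(self):
        assert parse_notation("|C:1 C:3 |C:2 C:5 |C:4 C:6") == {(1, 3), (2, 5), (4, 6)}

    def test_seven_bond_pattern(self):
        pattern = "C1-C5, C2-C4, C3-C13, C6-C14, C7-C10, C8-C12, C9-C11"
        assert parse_notation(pattern) == {
            (1, 5), (2, 4), (3, 13), (6, 14), (7, 10), (8, 12), (9, 11),
        }

    def test_interchain_parse(self):
        assert parse_notation("A:1|B:8, A:8|B:1") == {
            (("A", 1), ("B", 8)),
            (("A", 8), ("B", 1)),
        }

    def test_ordinal_reuse_errors(self):
        with pytest.raises(NotationError):
            parse_notation("C1-C2, C1-C3")

    @pytest.mark.parametrize("bad", ["", "C1-C2-C3", "Cx-C2", "C1", "C1-C1"])
    def test_malformed(self, bad):
        with pytest.raises(NotationError):
            parse_notation(bad)

    def test_render_roundtrip(self, cys7_model):
        topo = detect_bonds(cys7_model)
        assert parse_notation(render_dash(topo)) == {(1, 6), (2, 4), (3, 5)}
        assert parse_notation(render_pipe(topo)) == {(1, 6), (2, 4), (3, 5)}

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_roundtrip_property(self, seed):
        rng = np.random.default_rng(seed)
        n_cys = int(rng.integers(2, 20))
        pairs = _random_pairing(rng, n_cys)
        if not pairs:
            return
        dash = ", ".join(f"C{a}-C{b}" for a, b in sorted(pairs))
        pipe = " ".join(f"|C:{a} C:{b}" for a, b in sorted(pairs))
        assert parse_notation(dash) == set(pairs)
        assert parse_notation(pipe) == set(pairs)


class TestConsensus:
    def test_identical_topologies(self):
        texts = fixtures.make_family(5, "C1-C4, C2-C5, C3-C6", 0.0, seed=3)
        models = [parse_pdb_text(t, f"m{i}") for i, t in enumerate(texts)]
        consensus, support = consensus_topology(models)
        assert consensus == {
            (("A", 1), ("A", 4)),
            (("A", 2), ("A", 5)),
            (("A", 3), ("A", 6)),
        }
        assert all(f == 1.0 for f in support.values())

    def test_one_broken_bond_support(self):
        texts = fixtures.make_family(10, "C1-C4, C2-C5, C3-C6", 0.0, seed=4)
        models = [parse_pdb_text(t, f"m{i}") for i, t in enumerate(texts)]
        # break C1-C4 in one model by moving its first SG far away
        broken = models[0]
        cys = [r for r in broken.chains[0].residues if r.name == "CYS"]
        sg = cys[0].atom("SG")
        sg.x += 50.0
        consensus, support = consensus_topology(models)
        key = (("A", 1), ("A", 4))
        assert support[key] == pytest.approx(0.9)
        assert key in consensus  # 0.9 >= default threshold 0.8

    def test_jittered_family_recovery(self):
        texts = fixtures.make_family(10, "C1-C4, C2-C5, C3-C6", 0.3, seed=42)
        models = [parse_pdb_text(t, f"m{i}") for i, t in enumerate(texts)]
        consensus, _ = consensus_topology(models)
        assert {(a[1], b[1]) for a, b in consensus} == {(1, 4), (2, 5), (3, 6)}

    def test_needs_two_models(self, cys7_model):
        with pytest.raises(ValueError):
            consensus_topology([cys7_model])

    def test_unequal_ordinal_counts_error(self, cys7_model):
        other = parse_pdb_text(fixtures.make_cys_structure([(1, 2, 2.05)], 2, seed=1))
        with pytest.raises(ValueError, match="ordinal counts"):
            consensus_topology([cys7_model, other])


class TestDimer:
    def test_homodimer_c7_bridge(self, homodimer_model):
        report = dimer_bridge_scan(homodimer_model)
        assert report.notation == "A:7|B:7"
        assert report.symmetric is True
        assert len(report.free) == 12  # C1..C6 of both chains

    def test_reciprocal_bridges(self, reciprocal_dimer_model):
        report = dimer_bridge_scan(reciprocal_dimer_model)
        assert report.notation == "A:1|B:8, A:8|B:1"
        assert report.symmetric is True

    def test_asymmetric_not_flagged(self):
        text = fixtures.make_dimer_structure([(1, 8, 2.05)], n_cys=8, seed=0)
        report = dimer_bridge_scan(parse_pdb_text(text))
        assert report.notation == "A:1|B:8"
        assert report.symmetric is False

    def test_monomer_empty(self, cys7_model):
        report = dimer_bridge_scan(cys7_model)
        assert report.inter_bonds == []
        assert report.symmetric is False

    def test_multimer_conservation(self, homodimer_model):
        topo = detect_bonds(homodimer_model)
        assert topo.check_conservation()
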