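import numpy as np
import pytest

from conftest import toy_structure
from oracles import grid_shortest_path_oracle
from xlmod.sasd import (DistanceFileError, build_solvent_grid, euclidean_distance,
                        mono_link_accessible, parse_distance_file, sas_distance,
                        write_distance_file, _propagate)
from xlmod.structure_model import Atom, AtomSpec, Residue, Structure
from xlmod.synthetic_fixtures import (make_helix, make_hollow_shell, make_slab,
                                      make_two_chain_complex)


def add_probe(structure, coord, seq, chain="A"):
    res = Residue("LYS", seq, "", chain)
    res.atoms = [Atom(name="CB", element="C", res_name="LYS", res_seq=seq,
                      chain_id=chain, coord=np.asarray(coord, dtype=float),
                      vdw_radius=1.70)]
    for ch in structure.chains:
        if ch.id == chain:
            ch.residues.append(res)
            return AtomSpec("LYS", seq, chain, "CB")
    raise KeyError(chain)


class TestSolventGrid:
    def test_empty_structure_is_all_solvent(self):
        st = Structure(id="empty")
        grid = build_solvent_grid(st, spacing=1.0,
                                  region=(np.zeros(3), np.full(3, 5.0)))
        assert grid.n_protein == 0

    def test_single_atom_blocking_radius(self):
        st = toy_structure([(5.0, 5.0, 5.0)])
        grid = build_solvent_grid(st, spacing=1.0, solvent_radius=2.0,
                                  region=(np.zeros(3), np.full(3, 10.0)))
        # PROTEIN iff cell center within vdw (1.7) + solvent (2.0) of the atom
        for idx in np.ndindex(grid.shape):
            d = np.linalg.norm(grid.center(idx) - [5.0, 5.0, 5.0])
            assert grid.protein[idx] == (d <= 3.7)

    def test_slab_labeling_matches_per_cell_oracle(self):
        slab = make_slab(nx=3, ny=3, nz=2)
        grid = build_solvent_grid(slab, spacing=1.5)
        atoms = list(slab.iter_atoms())
        for idx in list(np.ndindex(grid.shape))[::7]:
            c = grid.center(idx)
            expect = any(
                np.linalg.norm(c - a.coord) <= a.vdw_radius + 2.0 for a in atoms)
            assert grid.protein[idx] == expect


class TestSasDistance:
    def test_free_space_close_to_euclidean(self):
        st = toy_structure([(0, 0, 0), (10.0, 0, 0)])
        xl = sas_distance(st, AtomSpec("LYS", 1, "A", "CB"),
                          AtomSpec("LYS", 2, "A", "CB"), spacing=1.0)
        assert xl.euclidean == pytest.approx(10.0)
        assert 10.0 <= xl.sasd <= 10.0 + 3 * 1.0

    @pytest.mark.parametrize("direction", [
        (1, 0, 0), (0.6, 0.8, 0), (0.5, 0.5, 0.7071), (0.3, -0.9, 0.3)])
    def test_free_space_metric_error_bound(self, direction):
        # the 26-neighbor chamfer metric overestimates straight lines by at
        # most ~12.81 % (worst direction), plus endpoint-snapping slack
        d = np.asarray(direction, dtype=float)
        d /= np.linalg.norm(d)
        for length in (10.0, 20.0, 30.0):
            st = toy_structure([(0, 0, 0), tuple(length * d)])
            xl = sas_distance(st, AtomSpec("LYS", 1, "A", "CB"),
                              AtomSpec("LYS", 2, "A", "CB"), spacing=1.0)
            assert xl.sasd <= 1.1281 * xl.euclidean + np.sqrt(3.0) * 1.0
        if tuple(direction) == (1, 0, 0):  # axis-aligned paths are exact
            assert xl.sasd == pytest.approx(xl.euclidean, abs=1e-9)

    def test_slab_detour_exceeds_euclidean(self):
        slab = make_slab(nx=6, ny=6, nz=4)  # 10 x 10 x 6 A block
        s1 = add_probe(slab, (5.0, 5.0, -4.0), 900)
        s2 = add_probe(slab, (5.0, 5.0, 10.0), 901)
        xl = sas_distance(slab, s1, s2, spacing=1.0)
        assert xl.euclidean == pytest.approx(14.0)
        assert xl.sasd > xl.euclidean + 5.0
        assert xl.path is not None and len(xl.path) > 2
        # traced path length telescopes to the reported distance
        steps = np.linalg.norm(np.diff(xl.path, axis=0), axis=1)
        assert steps.sum() == pytest.approx(xl.sasd, abs=1e-9)

    def test_buried_endpoint_is_unreachable(self):
        shell = make_hollow_shell()
        probe_seq = shell.chains[0].residues[-1].seq
        out = add_probe(shell, (20.0, 0.0, 0.0), 999)
        xl = sas_distance(shell, AtomSpec("LYS", probe_seq, "A", "CB"), out)
        assert xl.sasd == -1.0 and xl.path is None

    def test_symmetry_is_exact(self):
        slab = make_slab(nx=6, ny=6, nz=4)
        s1 = add_probe(slab, (2.0, 5.0, -4.0), 900)
        s2 = add_probe(slab, (8.0, 5.0, 10.0), 901)
        a = sas_distance(slab, s1, s2, spacing=1.0).sasd
        b = sas_distance(slab, s2, s1, spacing=1.0).sasd
        assert a == b

    def test_refinement_converges(self):
        slab = make_slab(nx=6, ny=6, nz=4)
        s1 = add_probe(slab, (5.0, 5.0, -4.0), 900)
        s2 = add_probe(slab, (5.0, 5.0, 10.0), 901)
        d1 = sas_distance(slab, s1, s2, spacing=1.0, max_dist=None).sasd
        d05 = sas_distance(slab, s1, s2, spacing=0.5, max_dist=None).sasd
        assert abs(d05 - d1) <= np.sqrt(3.0) * 1.0

    def test_lower_bound_against_euclidean(self, helix):
        rng = np.random.default_rng(0)
        residues = list(helix.iter_residues())
        for _ in range(8):
            i, j = rng.choice(len(residues), size=2, replace=False)
            s1 = AtomSpec("LYS", residues[i].seq, "A", "CB")
            s2 = AtomSpec("LYS", residues[j].seq, "A", "CB")
            xl = sas_distance(helix, s1, s2, spacing=1.0)
            if xl.sasd >= 0:
                assert xl.sasd >= xl.euclidean - 2 * 1.0

    def test_agrees_with_independent_dijkstra(self):
        """Propagated distances equal a scipy graph Dijkstra on the same grid."""
        helix = make_helix(12)
        grid = build_solvent_grid(helix, spacing=1.2)
        free = np.argwhere(~grid.protein)
        rng = np.random.default_rng(1)
        for _ in range(3):
            src = tuple(free[rng.integers(len(free))])
            mine = _propagate(grid.protein, src, 1.2, None)
            oracle = grid_shortest_path_oracle(grid.protein, src, 1.2)
            finite = np.isfinite(mine)
            assert np.array_equal(finite, np.isfinite(oracle))
            np.testing.assert_allclose(mine[finite], oracle[finite], atol=1e-9)

    def test_backbone_mode_strips_linked_side_chains(self, helix):
        # with the NZ atoms of the linked residues removed from labeling, the
        # grid contains strictly fewer protein cells
        s1 = AtomSpec("LYS", 1, "A", "CB")
        s2 = AtomSpec("LYS", 8, "A", "CB")
        xl_bb = sas_distance(helix, s1, s2, backbone_mode=True)
        xl_all = sas_distance(helix, s1, s2, side_chain_handling="all")
        xl_none = sas_distance(helix, s1, s2, side_chain_handling="none")
        for xl in (xl_bb, xl_all, xl_none):
            assert xl.sasd >= 0
        assert xl_all.sasd <= xl_bb.sasd + 1e-9  # fewer obstacles, shorter path
        assert xl_bb.sasd <= xl_none.sasd + 1e-9


class TestEuclideanAndMono:
    def test_pythagorean_pair(self):
        st = toy_structure([(0, 0, 0), (3.0, 4.0, 0)])
        assert euclidean_distance(st, AtomSpec("LYS", 1, "A", "CB"),
                                  AtomSpec("LYS", 2, "A", "CB")) == pytest.approx(5.0)

    def test_same_spec_is_zero(self, helix):
        s = AtomSpec("LYS", 3, "A", "CB")
        assert euclidean_distance(helix, s, s) == 0.0

    def test_helix_pair_matches_norm(self, helix):
        from xlmod.structure_model import resolve_spec
        s1, s2 = AtomSpec("LYS", 1, "A", "CB"), AtomSpec("LYS", 8, "A", "CB")
        expect = float(np.linalg.norm(resolve_spec(helix, s1).coord
                                      - resolve_spec(helix, s2).coord))
        assert euclidean_distance(helix, s1, s2) == pytest.approx(expect)

    def test_surface_site_is_accessible(self):
        slab = make_slab(lys_xy=[(7.0, 7.0)])
        seq = slab.chains[0].residues[-1].seq
        assert mono_link_accessible(slab, AtomSpec("LYS", seq, "A", "CB"))

    def test_enclosed_site_is_buried(self):
        shell = make_hollow_shell()
        seq = shell.chains[0].residues[-1].seq
        assert not mono_link_accessible(shell, AtomSpec("LYS", seq, "A", "CB"))

    def test_site_buried_by_docking(self):
        """A surface lysine becomes inaccessible under a docked partner slab."""
        complex_ = make_two_chain_complex(gap=3.0, lys_a=((7.0, 7.0),), lys_b=())
        seq = complex_.chains[0].residues[-1].seq
        spec = AtomSpec("LYS", seq, "A", "CB")
        alone = complex_.select_chains(["A"])
        assert mono_link_accessible(alone, spec)
        assert not mono_link_accessible(complex_, spec)


class TestDistanceFile:
    def test_tab_delimited_pair_row(self):
        xls = parse_distance_file("1\tprotein.pdb\tLYS-1-C-CB\tLYS-2-C-CB\n")
        assert len(xls) == 1 and not xls[0].is_mono
        assert xls[0].spec1.chain_id == "C" and xls[0].spec2.chain_id == "C"

    def test_three_columns_is_a_mono_link(self):
        xls = parse_distance_file("2\tprotein.pdb\tLYS-9-A\n")
        assert xls[0].is_mono and xls[0].index == 2

    def test_roundtrip(self):
        text = ("1\tprotein.pdb\tLYS-1-C-CB\tLYS-2-C-CB\n"
                "2\tprotein.pdb\tLYS-9-A\n"
                "3\tprotein.pdb\tLYS-3-C-CB\tLYS-7-C-CB\t12.50\t14.75\n")
        xls = parse_distance_file(text)
        assert xls[2].euclidean == 12.50 and xls[2].sasd == 14.75
        assert write_distance_file(xls) == text
        assert parse_distance_file(write_distance_file(xls)) == xls

    @pytest.mark.parametrize("bad, match", [
        ("1\tonly_two\n", "line 1"),
        ("x\tp.pdb\tLYS-1-A\n", "bad index"),
        ("1\tp.pdb\tLYS-1-A\tnot-a-spec\n", "line 1"),
        ("", "no cross-link rows"),
    ])
    def test_malformed_rows(self, bad, match):
        with pytest.raises(DistanceFileError, match=match):
            parse_distance_file(bad)
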