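"""Triangle labelling, geometry, key encoding, bulk generation and file I/O."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tsrkit as tk
from tsrkit.config import BinningConfig
from tsrkit.structure_io import MoleculeSelection, Provenance

from conftest import make_kv, rotate_translate


def small_config(m=5, n_theta=30, n_dist=17, **kwargs):
    return BinningConfig(
        mode="COFACTOR",
        label_map={chr(ord("A") + i): i + 1 for i in range(m)},
        theta_bins=tuple(90.0 * (i + 1) / n_theta for i in range(n_theta)),
        dist_bins=tuple(float(i + 1) for i in range(n_dist)),
        **kwargs,
    )


class TestLabelVertices:
    def test_plain_descending_sort(self):
        labels, order = tk.label_vertices(
            [(2, (0, 0, 0)), (5, (3, 0, 0)), (1, (0, 4, 0))]
        )
        assert labels == (5, 2, 1)
        assert order == (1, 0, 2)

    def test_tie_broken_by_centroid_distance(self):
        # two label-3 vertices; the farther one from the centroid leads
        points = [(3, (4.0, 0.0, 0.0)), (3, (-2.0, 0.0, 0.0)), (1, (0.0, 1.5, 0.0))]
        labels, order = tk.label_vertices(points)
        assert labels == (3, 3, 1)
        assert order[0] == 0  # (4,0,0) is farther from the centroid

    def test_full_tie_preserves_input_order(self):
        side = [(7, (0.0, 0.0, 0.0)), (7, (2.0, 0.0, 0.0)), (7, (1.0, math.sqrt(3.0), 0.0))]
        labels, order = tk.label_vertices(side)
        assert labels == (7, 7, 7)
        assert order == (0, 1, 2)


class TestTriangleGeometry:
    def test_analytic_right_triangle(self):
        maxdist, theta = tk.triangle_geometry([(0, 0, 0), (2, 0, 0), (0, 2, 0)])
        assert maxdist == pytest.approx(2.828, abs=1e-3)
        assert theta == pytest.approx(63.435, abs=1e-3)

    def test_equilateral_median_is_perpendicular(self):
        pts = [(0, 0, 0), (2, 0, 0), (1, math.sqrt(3.0), 0)]
        maxdist, theta = tk.triangle_geometry(pts)
        assert maxdist == pytest.approx(2.0)
        assert theta == pytest.approx(90.0)

    def test_collinear_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            tk.triangle_geometry([(0, 0, 0), (2, 0, 0), (1, 0, 0)])

    def test_coincident_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            tk.triangle_geometry([(0, 0, 0), (0, 0, 0), (1, 1, 0)])


class TestEncodeKey:
    def test_origin_of_code_space(self):
        assert tk.encode_key(1, 1, 1, 1, 1, small_config()) == 0

    def test_matches_enumeration_oracle(self):
        # oracle: the key is the index of the tuple in odometer order over
        # (l1, l2, l3, theta_bin, dist_bin)
        config = small_config(m=5, n_theta=30, n_dist=17)
        ordered = list(
            itertools.product(
                range(1, 6), range(1, 6), range(1, 6), range(1, 31), range(1, 18)
            )
        )
        target = (3, 2, 1, 5, 7)
        assert ordered.index(target) == 28124
        assert tk.encode_key(*target, config) == 28124

    def test_bijective_exhaustively_on_small_space(self):
        config = small_config(m=3, n_theta=4, n_dist=5)
        seen = set()
        for tup in itertools.product(
            range(1, 4), range(1, 4), range(1, 4), range(1, 5), range(1, 6)
        ):
            key = tk.encode_key(*tup, config)
            assert tk.decode_key(key, config) == tup
            seen.add(key)
        assert len(seen) == 3 * 3 * 3 * 4 * 5
        assert seen == set(range(len(seen)))

    @settings(derandomize=True, max_examples=200)
    @given(
        l1=st.integers(1, 5), l2=st.integers(1, 5), l3=st.integers(1, 5),
        tb=st.integers(1, 30), db=st.integers(1, 17),
    )
    def test_decode_inverts_encode(self, l1, l2, l3, tb, db):
        config = small_config()
        key = tk.encode_key(l1, l2, l3, tb, db, config)
        assert tk.decode_key(key, config) == (l1, l2, l3, tb, db)

    def test_out_of_range_rejected(self):
        config = small_config()
        with pytest.raises(ValueError, match="l1"):
            tk.encode_key(6, 1, 1, 1, 1, config)
        with pytest.raises(ValueError, match="dist_bin"):
            tk.encode_key(1, 1, 1, 1, 18, config)
        with pytest.raises(ValueError, match="out of range"):
            tk.decode_key(-1, config)


class TestGenerateKeys:
    def test_four_points_four_triangles(self):
        atoms = [
            tk.AtomRecord(i + 1, f"X{i}", "C", "LIG", 1, "A", xyz)
            for i, xyz in enumerate(
                [(0.0, 0.0, 0.0), (2.0, 0.0, 0.0), (0.0, 2.0, 0.0), (0.3, 0.7, 2.0)]
            )
        ]
        sel = MoleculeSelection(atoms, Provenance("T", "A", "L", "t"), "COFACTOR")
        kv, records = tk.generate_keys(sel, tk.default_config("COFACTOR"))
        assert kv.total() == 4
        assert len(records) == 4

    def test_total_is_n_choose_3(self, toy_cofactor_sel):
        kv, _ = tk.generate_keys(toy_cofactor_sel, tk.default_config("COFACTOR"), records=False)
        assert kv.total() == math.comb(25, 3)

    def test_size_gap_cutoff_drops_long_triangles(self, toy_cofactor_tail_sel):
        config = tk.default_config("COFACTOR")
        kv_all, _ = tk.generate_keys(toy_cofactor_tail_sel, config, records=False)
        kv_cut, _ = tk.generate_keys(
            toy_cofactor_tail_sel, config.with_(size_gap_cutoff=20.0), records=False
        )
        assert kv_cut.total() < kv_all.total()

    def test_fewer_than_three_atoms_errors(self, toy_cofactor_sel):
        sel = MoleculeSelection(
            toy_cofactor_sel.atoms[:2], toy_cofactor_sel.provenance, "COFACTOR"
        )
        with pytest.raises(ValueError, match="at least 3"):
            tk.generate_keys(sel, tk.default_config("COFACTOR"))

    def test_mode_mismatch_errors(self, toy_cofactor_sel):
        with pytest.raises(ValueError, match="mode"):
            tk.generate_keys(toy_cofactor_sel, tk.default_config("CA"))

    @pytest.mark.parametrize("seed", [7, 21])
    def test_rigid_motion_invariance(self, toy_cofactor_tail_sel, seed):
        config = tk.default_config("COFACTOR")
        kv, _ = tk.generate_keys(toy_cofactor_tail_sel, config, records=False)
        moved = toy_cofactor_tail_sel.with_coords(
            rotate_translate(toy_cofactor_tail_sel.coords, seed)
        )
        kv_moved, _ = tk.generate_keys(moved, config, records=False)
        assert kv.counts == kv_moved.counts

    def test_permutation_invariance(self, toy_cofactor_sel):
        config = tk.default_config("COFACTOR")
        kv, _ = tk.generate_keys(toy_cofactor_sel, config, records=False)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(toy_cofactor_sel.atoms))
        shuffled = MoleculeSelection(
            [toy_cofactor_sel.atoms[i] for i in perm],
            toy_cofactor_sel.provenance,
            "COFACTOR",
        )
        kv_shuf, _ = tk.generate_keys(shuffled, config, records=False)
        assert kv.counts == kv_shuf.counts

    def test_grouping_map_merges_labels(self):
        model = tk.read_structure(
            tk.make_toy_protein(9, pattern=("LEU", "ILE", "VAL"))
        )
        sel = tk.select_calpha(model, "A")
        grouped, _ = tk.generate_keys(
            sel, tk.default_config("CA", grouping=True), records=False
        )
        ile_label = tk.AMINO_ACID_LABELS["ILE"]
        for key in grouped.counts:
            l1, l2, l3, _, _ = tk.decode_key(key, tk.default_config("CA", grouping=True))
            assert l1 == l2 == l3 == ile_label

    def test_jitter_stability_versus_unrelated(self, toy_cofactor_sel):
        config = tk.default_config("COFACTOR")
        kv, _ = tk.generate_keys(toy_cofactor_sel, config, records=False)
        jittered = tk.jitter_family(toy_cofactor_sel, 1, sigma=0.02, seed=3)[0]
        kv_j, _ = tk.generate_keys(jittered, config, records=False)
        rng = np.random.default_rng(11)
        unrelated = toy_cofactor_sel.with_coords(
            rng.uniform(-8.0, 8.0, size=toy_cofactor_sel.coords.shape)
        )
        kv_u, _ = tk.generate_keys(unrelated, config, records=False)
        assert tk.generalized_jaccard(kv, kv_j) > tk.generalized_jaccard(kv, kv_u)


class TestKeyAndTripletFiles:
    def test_key_file_roundtrip(self, tmp_path, toy_cofactor_sel):
        config = tk.default_config("COFACTOR")
        kv, _ = tk.generate_keys(toy_cofactor_sel, config, records=False)
        path = tmp_path / "toy.keys.tsv"
        tk.write_key_file(kv, path, config)
        back = tk.read_key_file(path)
        assert back.counts == kv.counts
        assert back.mode == kv.mode
        assert back.config_hash == kv.config_hash
        assert back.provenance.role == kv.provenance.role

    def test_triplet_file_roundtrip_and_row_count(self, tmp_path, toy_cofactor_sel):
        config = tk.default_config("COFACTOR")
        kv, records = tk.generate_keys(toy_cofactor_sel, config)
        path = tmp_path / "toy.triplets.tsv"
        tk.write_triplet_file(records, kv, path, config)
        _, back = tk.read_triplet_file(path)
        assert len(back) == kv.total()
        assert back == records

    def test_empty_key_vector_write_errors(self, tmp_path):
        empty = make_kv({})
        with pytest.raises(ValueError, match="empty"):
            tk.write_key_file(empty, tmp_path / "x.tsv")

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# tsrkit v1\nkey\tfrequency\n12\tnot_a_number\n")
        with pytest.raises(ValueError, match="line 3"):
            tk.read_key_file(path)


class TestKeyToTriangleMapping:
    def _store(self, selections, config):
        store = tk.TripletStore()
        for sel in selections:
            _, records = tk.generate_keys(sel, config)
            store.add_records(records)
        return store

    def test_key_occurring_twice_in_one_molecule(self, toy_cofactor_sel):
        config = tk.default_config("COFACTOR")
        kv, records = tk.generate_keys(toy_cofactor_sel, config)
        key = next(k for k, f in kv.counts.items() if f == 2)
        store = tk.TripletStore()
        store.add_records(records)
        hits = tk.map_key_to_triangles(key, store)
        assert len(hits) == 2
        assert all(h.key == key for h in hits)

    def test_absent_key_gives_empty_list(self, toy_cofactor_sel):
        config = tk.default_config("COFACTOR")
        _, records = tk.generate_keys(toy_cofactor_sel, config)
        store = tk.TripletStore()
        store.add_records(records)
        assert tk.map_key_to_triangles(10**12, store) == []

    def test_provenance_distinguishes_molecules(self, toy_cofactor_sel):
        config = tk.default_config("COFACTOR")
        copies = [
            toy_cofactor_sel.with_coords(
                rotate_translate(toy_cofactor_sel.coords, seed), role=f"copy{seed}"
            )
            for seed in (1, 2, 3)
        ]
        store = self._store(copies, config)
        kv, _ = tk.generate_keys(copies[0], config, records=False)
        key = next(k for k, f in kv.counts.items() if f == 1)
        hits = tk.map_key_to_triangles(key, store)
        assert {h.provenance for h in hits} == {"copy1", "copy2", "copy3"}
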