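"""Mesh geometry invariants and file round trips."""

import numpy as np
import pytest

from longicort import make_icosphere
from longicort.io import (
    Cohort, FormatError, GeneSet, SchemaError, SubjectRecord, UnitError,
    VertexMap, read_cohort_table, read_gene_sets, read_sidecar,
    read_surface, read_vertex_map, write_cohort_table, write_gene_sets,
    write_surface, write_vertex_map,
)


class TestMesh:
    @pytest.mark.parametrize("s,expected_v,expected_f", [(0, 12, 20), (1, 42, 80), (2, 162, 320)])
    def test_icosphere_counts(self, s, expected_v, expected_f):
        m = make_icosphere(s, 100.0)
        assert m.n_vertices == expected_v == 10 * 4**s + 2
        assert m.n_faces == expected_f == 20 * 4**s

    def test_closed_mesh_euler_characteristic(self, small_mesh):
        assert small_mesh.euler_characteristic == 2

    def test_vertex_areas_positive_and_conserved(self, small_mesh):
        assert np.all(small_mesh.vertex_areas > 0)
        assert np.isclose(small_mesh.vertex_areas.sum(), small_mesh.total_area, rtol=1e-9)

    def test_adjacency_symmetric(self, small_mesh):
        a = small_mesh.adjacency
        assert (a != a.T).nnz == 0

    def test_geodesic_ball_connected(self, small_mesh):
        from scipy.sparse.csgraph import connected_components

        ball = small_mesh.geodesic_ball(0, 40.0)
        sub = small_mesh.adjacency[ball][:, ball]
        n_comp, _ = connected_components(sub, directed=False)
        assert n_comp == 1

    def test_negative_subdivisions_rejected(self):
        with pytest.raises(ValueError):
            make_icosphere(-1)


class TestVertexMapIO:
    def test_curv_round_trip_zeros(self, tmp_path, small_mesh):
        vmap = VertexMap(np.zeros(small_mesh.n_vertices), "mm", small_mesh.mesh_id)
        path = tmp_path / "zeros.curv"
        write_vertex_map(vmap, path)
        back = read_vertex_map(path, mesh=small_mesh)
        assert np.array_equal(back.values, vmap.values)

    def test_curv_round_trip_float32_exact(self, tmp_path, small_mesh, rng):
        values = rng.normal(2.5, 0.2, small_mesh.n_vertices).astype(np.float32)
        vmap = VertexMap(values, "mm", small_mesh.mesh_id)
        path = tmp_path / "thick.curv"
        write_vertex_map(vmap, path)
        back = read_vertex_map(path, mesh=small_mesh)
        assert np.array_equal(back.values.astype(np.float32), values)
        assert back.unit == "mm"

    def test_csv_round_trip(self, tmp_path):
        vmap = VertexMap([2.5, -1.25, 3.0], "percent-per-year")
        path = tmp_path / "map.csv"
        write_vertex_map(vmap, path)
        back = read_vertex_map(path)
        assert np.array_equal(back.values, [2.5, -1.25, 3.0])

    def test_gifti_round_trip(self, tmp_path, small_mesh, rng):
        values = rng.normal(size=small_mesh.n_vertices).astype(np.float32)
        path = tmp_path / "map.shape.gii"
        write_vertex_map(VertexMap(values, "t", small_mesh.mesh_id), path, format="gifti-shape")
        back = read_vertex_map(path, format="gifti-shape", mesh=small_mesh)
        assert np.array_equal(back.values.astype(np.float32), values)

    def test_vertex_count_mismatch_names_counts(self, tmp_path, small_mesh):
        vmap = VertexMap(np.zeros(100), "mm")
        path = tmp_path / "short.curv"
        write_vertex_map(vmap, path)
        with pytest.raises(FormatError, match="100.*162|162.*100"):
            read_vertex_map(path, mesh=small_mesh)

    def test_garbage_file_rejected(self, tmp_path):
        path = tmp_path / "junk.curv"
        path.write_bytes(b"\x00\x01")   # truncated: no parseable header
        with pytest.raises(FormatError):
            read_vertex_map(path, unit="mm")

    def test_sidecar_carries_unit_and_provenance(self, tmp_path):
        vmap = VertexMap([1.0, 2.0], "mm", "m0")
        path = tmp_path / "m.csv"
        write_vertex_map(vmap, path, stage="test", parameters={"k": 1}, seed=9)
        side = read_sidecar(path)
        assert side["unit"] == "mm" and side["mesh_id"] == "m0"
        assert side["provenance"]["seed"] == 9

    def test_unit_mismatch_arithmetic_rejected(self):
        a = VertexMap([1.0], "mm")
        b = VertexMap([1.0], "percent-per-year")
        with pytest.raises(UnitError):
            _ = a + b

    def test_nan_values_masked_not_propagated(self):
        vmap = VertexMap([1.0, np.nan, 3.0], "mm")
        assert not np.isnan(vmap.values).any()
        assert list(vmap.valid) == [True, False, True]

    def test_surface_round_trip(self, tmp_path, small_mesh):
        path = tmp_path / "template.surf"
        write_surface(small_mesh, path)
        back = read_surface(path)
        assert np.allclose(back.vertices, small_mesh.vertices)
        assert np.array_equal(back.faces, small_mesh.faces)


def _cohort_csv(tmp_path, rows, items=True):
    cols = ["subject_id", "group", "sex", "age_t1", "isi", "fsiq", "handedness"]
    if items:
        cols += [f"rbsr_t1_{i}" for i in range(1, 44)] + [f"rbsr_t2_{i}" for i in range(1, 44)]
    lines = [",".join(cols)] + [",".join(map(str, r)) for r in rows]
    path = tmp_path / "cohort.csv"
    path.write_text("\n".join(lines))
    return path


class TestCohortTable:
    def test_two_rows_parse(self, tmp_path):
        items = ["0"] * 86
        rows = [["s1", "ASD", "male", 14.0, 2.0, 100, "right"] + items,
                ["s2", "td", "F", 13.0, 2.1, 105, "L"] + items]
        cohort = read_cohort_table(_cohort_csv(tmp_path, rows))
        assert len(cohort) == 2
        assert cohort.subjects[1].group == "TD"       # case-insensitive
        assert cohort.subjects[1].sex == "female"
        assert cohort.subjects[1].handedness == "left"

    def test_three_missing_items_accepted(self, tmp_path):
        items = ["NA", "", "NA"] + ["1"] * 40 + ["0"] * 43
        cohort = read_cohort_table(_cohort_csv(
            tmp_path, [["s1", "ASD", "male", 14.0, 2.0, 100, "right"] + items]))
        assert cohort.subjects[0].n_missing(1) == 3

    def test_four_missing_items_rejected(self, tmp_path):
        items = ["NA"] * 4 + ["1"] * 39 + ["0"] * 43
        with pytest.raises(SchemaError, match="s1"):
            read_cohort_table(_cohort_csv(
                tmp_path, [["s1", "ASD", "male", 14.0, 2.0, 100, "right"] + items]))

    def test_numeric_sentinel_rejected(self):
        with pytest.raises(SchemaError, match="sentinel"):
            SubjectRecord("s1", "ASD", "male", 14.0, 2.0, 100.0,
                          rbsr_items_t1=np.r_[999.0, np.zeros(42)])

    def test_nonpositive_isi_names_subject(self, tmp_path):
        rows = [["bad-subj", "ASD", "male", 14.0, -1.0, 100, "right"] + ["0"] * 86]
        with pytest.raises(SchemaError, match="bad-subj"):
            read_cohort_table(_cohort_csv(tmp_path, rows))

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("subject_id,group,sex\ns1,ASD,male")
        with pytest.raises(SchemaError, match="missing required"):
            read_cohort_table(path)

    def test_write_read_round_trip(self, tmp_path):
        items = np.zeros(43)
        items[0] = np.nan
        subj = SubjectRecord("s1", "ASD", "male", 14.0, 2.0, 100.0,
                             rbsr_items_t1=items, rbsr_items_t2=np.ones(43))
        path = tmp_path / "cohort.csv"
        write_cohort_table(Cohort([subj]), path)
        back = read_cohort_table(path)
        assert back.subjects[0].n_missing(1) == 1
        assert np.array_equal(back.subjects[0].rbsr_items_t2, np.ones(43))


class TestGeneSets:
    def test_gmt_parse(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdown\tA\tB\tC\nS2\tup\tD\n")
        sets = read_gene_sets(path)
        assert [s.name for s in sets] == ["S1", "S2"]
        assert sets[0].members == ("A", "B", "C")
        assert sets[0].annotation == "down"

    def test_duplicates_collapsed_with_warning(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S1\tdown\tA\tA\tB\n")
        with pytest.warns(UserWarning, match="duplicate"):
            sets = read_gene_sets(path)
        assert sets[0].members == ("A", "B")

    def test_empty_set_rejected(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("S1\tdown\t\n")
        with pytest.raises(SchemaError):
            read_gene_sets(path)

    def test_plain_list(self, tmp_path):
        path = tmp_path / "risk.txt"
        path.write_text("GENE1\nGENE2\n")
        sets = read_gene_sets(path)
        assert sets[0].members == ("GENE1", "GENE2")

    def test_round_trip(self, tmp_path):
        gs = GeneSet("S", ("A", "B"), "down")
        path = tmp_path / "out.gmt"
        write_gene_sets([gs], path)
        assert read_gene_sets(path)[0] == gs
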