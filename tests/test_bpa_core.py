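import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from _oracles import permutation_nes_zscores
from bpa.bpa_core import (
    BPAMatrix,
    ExpressionMatrix,
    area_nes,
    bpa_transform,
    select_by_sd,
    signature_from_expression,
)
from bpa.geneset_io import GeneSet, GeneSetCollection, restrict_to_universe


class TestExpressionMatrix:
    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionMatrix(["g1"], ["c1"], np.array([[-1.0]]))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            ExpressionMatrix(["g1"], ["c1"], np.array([[np.nan]]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate gene"):
            ExpressionMatrix(["g1", "g1"], ["c1"], np.ones((2, 1)))

    def test_tsv_roundtrip(self, small_expr, tmp_path):
        p = tmp_path / "expr.tsv"
        small_expr.write_tsv(p)
        back = ExpressionMatrix.read_tsv(p)
        assert back.gene_ids == small_expr.gene_ids
        assert back.cell_ids == small_expr.cell_ids
        np.testing.assert_allclose(back.values, small_expr.values)

    def test_mtx_reader(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        values = csr_matrix(np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 0.0]]))
        mmwrite(str(tmp_path / "m.mtx"), values)
        (tmp_path / "features.tsv").write_text("g1\ng2\ng3\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        expr = ExpressionMatrix.read_mtx(
            tmp_path / "m.mtx", tmp_path / "features.tsv", tmp_path / "barcodes.tsv"
        )
        assert expr.gene_ids == ["g1", "g2", "g3"]
        np.testing.assert_allclose(expr.values, values.toarray())


class TestSignature:
    def test_three_gene_example(self):
        # ranks (3,1,2) -> scaled (0.75, 0.25, 0.50) -> quantiles
        sig = signature_from_expression(np.array([5.0, 1.0, 3.0]))
        expected = norm.ppf([0.75, 0.25, 0.50])
        np.testing.assert_allclose(sig.z, expected, atol=1e-12)
        assert abs(sig.z[0] - 0.6745) < 1e-4

    def test_tie_symmetry(self):
        sig = signature_from_expression(np.array([7.0, 7.0, 1.0]))
        assert sig.z[0] == sig.z[1]

    def test_all_identical_is_flat_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            sig = signature_from_expression(np.array([7.0, 7.0]))
        np.testing.assert_array_equal(sig.z, [0.0, 0.0])

    def test_tie_free_z_sums_to_zero(self, rng):
        sig = signature_from_expression(rng.permutation(np.arange(101.0)))
        assert abs(sig.z.sum()) < 1e-10

    def test_z_bounded_by_extreme_quantile(self, rng):
        n = 57
        sig = signature_from_expression(rng.uniform(size=n))
        assert np.max(np.abs(sig.z)) <= abs(norm.ppf(n / (n + 1.0))) + 1e-12

    @given(
        values=st.lists(
            st.integers(min_value=0, max_value=1000),
            min_size=3,
            max_size=40,
            unique=True,
        ),
        scale=st.floats(min_value=0.1, max_value=5.0),
        shift=st.floats(min_value=0.0, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, values, scale, shift):
        x = np.asarray(values, dtype=float) / 10.0
        a = signature_from_expression(x)
        b = signature_from_expression(np.exp(scale * x / 100.0) + shift)
        np.testing.assert_allclose(a.z, b.z, atol=1e-12)

    def test_needs_two_genes(self):
        with pytest.raises(ValueError):
            signature_from_expression(np.array([1.0]))


class TestAreaNES:
    def tie_free_signature(self, n):
        return signature_from_expression(np.arange(1.0, n + 1.0))

    def test_full_set_gives_zero(self):
        sig = self.tie_free_signature(12)
        gs = GeneSet("all", "d", tuple(sig.gene_ids))
        assert abs(area_nes(sig, gs)) < 1e-10

    def test_single_top_gene(self):
        sig = self.tie_free_signature(9)
        top = sig.gene_ids[int(np.argmax(sig.z))]
        nes = area_nes(sig, GeneSet("top", "d", (top,)))
        assert abs(nes - norm.ppf(0.9)) < 1e-12
        assert abs(nes - 1.2816) < 1e-4

    def test_top_four_genes(self):
        sig = self.tie_free_signature(9)
        order = np.argsort(sig.z)[::-1]
        top4 = tuple(sig.gene_ids[i] for i in order[:4])
        nes = area_nes(sig, GeneSet("top4", "d", top4))
        expected = norm.ppf([0.9, 0.8, 0.7, 0.6]).sum() / 2.0
        assert abs(nes - expected) < 1e-12
        assert abs(nes - 1.4504) < 1e-4

    def test_unrestricted_set_is_contract_violation(self):
        sig = self.tie_free_signature(5)
        with pytest.raises(ValueError, match="restrict"):
            area_nes(sig, GeneSet("bad", "d", ("missing_gene",)))


class TestBPATransform:
    def test_single_cell_full_set_is_zero(self):
        expr = ExpressionMatrix(
            ["g0", "g1", "g2", "g3", "g4"],
            ["c"],
            np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]),
        )
        coll = GeneSetCollection(
            sets=[GeneSet("all", "d", ("g0", "g1", "g2", "g3", "g4"))]
        )
        out = bpa_transform(expr, coll, min_overlap=1)
        assert out.shape == (1, 1)
        assert abs(out.nes[0, 0]) < 1e-10

    def test_per_cell_independence(self, small_expr, small_collection):
        dup = ExpressionMatrix(
            gene_ids=small_expr.gene_ids,
            cell_ids=small_expr.cell_ids + ["c0_dup"],
            values=np.hstack([small_expr.values, small_expr.values[:, [0]]]),
        )
        base = bpa_transform(small_expr, small_collection, min_overlap=1)
        with_dup = bpa_transform(dup, small_collection, min_overlap=1)
        np.testing.assert_array_equal(with_dup.nes[:, :5], base.nes)
        np.testing.assert_array_equal(with_dup.nes[:, 5], base.nes[:, 0])

    def test_matches_per_cell_area_nes(self, small_expr, small_collection):
        out = bpa_transform(small_expr, small_collection, min_overlap=1)
        restricted = restrict_to_universe(
            small_collection, small_expr.gene_ids, min_overlap=1
        )
        for j in range(len(small_expr.cell_ids)):
            sig = signature_from_expression(
                small_expr.values[:, j], gene_ids=small_expr.gene_ids
            )
            for i, s in enumerate(restricted):
                assert abs(out.nes[i, j] - area_nes(sig, s)) < 1e-10

    def test_no_surviving_sets_lists_overlaps(self, small_expr):
        coll = GeneSetCollection(sets=[GeneSet("S", "d", ("absent1", "absent2"))])
        with pytest.raises(ValueError, match="overlap"):
            bpa_transform(small_expr, coll, min_overlap=1)

    def test_rank_invariance_of_transform(self, small_expr, small_collection):
        a = bpa_transform(small_expr, small_collection, min_overlap=1)
        squashed = ExpressionMatrix(
            small_expr.gene_ids,
            small_expr.cell_ids,
            np.log1p(small_expr.values) * 3.7,
        )
        b = bpa_transform(squashed, small_collection, min_overlap=1)
        np.testing.assert_allclose(a.nes, b.nes, atol=1e-10)

    def test_permutation_oracle_small(self, rng):
        n_genes, n_cells = 150, 3
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"c{j}" for j in range(n_cells)],
            rng.uniform(0.01, 8.0, size=(n_genes, n_cells)),
        )
        sets = [
            GeneSet(
                f"S{k}",
                "d",
                tuple(f"g{i}" for i in rng.choice(n_genes, size=30, replace=False)),
            )
            for k in range(8)
        ]
        coll = GeneSetCollection(sets=sets)
        out = bpa_transform(expr, coll, min_overlap=1)
        analytic, empirical = [], []
        gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
        for j in range(n_cells):
            sig = signature_from_expression(expr.values[:, j])
            idx = [np.array([gene_index[g] for g in s.genes]) for s in sets]
            zs = permutation_nes_zscores(sig.z, idx, n_perm=3000, rng=rng)
            empirical.extend(zs)
            analytic.extend(out.nes[:, j])
        r = np.corrcoef(analytic, empirical)[0, 1]
        assert r > 0.99


class TestSelectBySD:
    def make_bpa(self, rows, names):
        return BPAMatrix(
            set_names=names,
            cell_ids=[f"c{i}" for i in range(rows.shape[1])],
            nes=rows,
        )

    def test_keeps_varying_row(self):
        bpa = self.make_bpa(
            np.array([[1.0, 1.0, 1.0], [0.0, 2.0, 4.0]]), ["const", "vary"]
        )
        out = select_by_sd(bpa, 1)
        assert out.set_names == ["vary"]

    def test_full_k_is_identity_up_to_order(self):
        bpa = self.make_bpa(np.array([[0.0, 1.0], [5.0, 5.0]]), ["a", "b"])
        out = select_by_sd(bpa, 2)
        assert sorted(out.set_names) == ["a", "b"]

    def test_ties_broken_by_name(self):
        rows = np.array([[0.0, 0.2], [0.0, 1.0], [1.0, 2.0]])
        bpa = self.make_bpa(rows, ["low", "zz", "aa"])
        out = select_by_sd(bpa, 2)
        assert out.set_names == ["aa", "zz"]

    def test_bad_k(self):
        bpa = self.make_bpa(np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            select_by_sd(bpa, 3)


class TestBPAMatrixIO:
    def test_tsv_roundtrip_with_annotations(self, tmp_path):
        ann = pd.DataFrame(
            {"cell_type": ["t1", "t2"]}, index=pd.Index(["c1", "c2"], name="cell_id")
        )
        bpa = BPAMatrix(
            set_names=["S1", "S2"],
            cell_ids=["c1", "c2"],
            nes=np.array([[0.5, -1.0], [2.0, 0.0]]),
            annotations=ann,
            provenance={"note": "test"},
        )
        p = tmp_path / "bpa.tsv"
        bpa.write_tsv(p)
        back = BPAMatrix.read_tsv(p)
        np.testing.assert_allclose(back.nes, bpa.nes)
        assert back.provenance == {"note": "test"}
        assert list(back.annotations["cell_type"]) == ["t1", "t2"]

    def test_annotations_must_cover_cells(self):
        ann = pd.DataFrame({"x": [1]}, index=pd.Index(["c1"], name="cell_id"))
        with pytest.raises(ValueError, match="missing"):
            BPAMatrix(["S"], ["c1", "c2"], np.zeros((1, 2)), annotations=ann)


def test_null_calibration_quick(rng):
    """NES over random sets of a tie-free signature is ~ N(0, 1)."""
    n_genes = 2000
    sig = signature_from_expression(rng.uniform(size=n_genes))
    nes = []
    for _ in range(300):
        idx = rng.choice(n_genes, size=25, replace=False)
        nes.append(sig.z[idx].sum() / np.sqrt(25))
    nes = np.asarray(nes)
    assert abs(nes.mean()) < 0.15
    assert 0.85 < nes.std(ddof=1) < 1.15
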