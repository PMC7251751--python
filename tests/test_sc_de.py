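"""Normalization, hurdle fitting, LRT, fold change, BH/DE calls, markers
and the cell-type overlap table."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from amygdex.genesets import GeneSet, ValidationError
from amygdex.sc_de import (
    DEResult,
    HurdleModelSpec,
    SnucDataset,
    bh_fdr,
    call_de,
    celltype_overlap,
    de_analysis,
    de_event_counts,
    fit_hurdle,
    fold_change,
    lrt_diagnosis,
    markers,
    normalize,
)
from amygdex.simulate import SimConfig, gen_snuc_dataset


def make_dataset(counts: np.ndarray, meta: pd.DataFrame) -> SnucDataset:
    genes = [f"G{i}" for i in range(counts.shape[0])]
    return SnucDataset(genes=genes, cell_meta=meta, counts=sp.csr_matrix(counts))


def simple_meta(n_cells: int, **overrides) -> pd.DataFrame:
    base = {
        "donor": ["d1"] * n_cells,
        "diagnosis": ["control"] * n_cells,
        "cluster": [1] * n_cells,
        "age": [10.0] * n_cells,
        "sex": ["M"] * n_cells,
        "RIN": [7.0] * n_cells,
        "PMI": [20.0] * n_cells,
    }
    base.update(overrides)
    return pd.DataFrame(base, index=[f"c{i}" for i in range(n_cells)])


class TestNormalize:
    def test_hand_arithmetic(self):
        # one cell with counts (1,1,2), scale 4 -> log2(2), log2(2), log2(3)
        counts = np.array([[1.0], [1.0], [2.0]])
        d = make_dataset(counts, simple_meta(1))
        norm = normalize(d, scale_factor=4)
        vals = np.asarray(norm.values.todense()).ravel()
        assert vals == pytest.approx([np.log2(2), np.log2(2), np.log2(3)])

    def test_zero_stays_zero(self):
        counts = np.array([[0.0, 5.0], [3.0, 0.0]])
        d = make_dataset(counts, simple_meta(2))
        vals = np.asarray(normalize(d).values.todense())
        assert vals[0, 0] == 0.0 and vals[1, 1] == 0.0

    def test_depth_invariance(self):
        counts = np.array([[1.0], [3.0]])
        doubled = counts * 2
        m1 = simple_meta(1)
        v1 = np.asarray(normalize(make_dataset(counts, m1)).values.todense())
        v2 = np.asarray(normalize(make_dataset(doubled, m1)).values.todense())
        assert np.allclose(v1, v2)

    def test_zero_total_cell_dropped(self, caplog):
        counts = np.array([[1.0, 0.0], [2.0, 0.0]])
        d = make_dataset(counts, simple_meta(2))
        norm = normalize(d)
        assert norm.values.shape[1] == 1
        assert len(norm.cell_meta) == 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError, match="counts"):
            make_dataset(np.array([[-1.0]]), simple_meta(1))

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValidationError, match="counts"):
            make_dataset(np.array([[1.5]]), simple_meta(1))


class TestBH:
    def test_hand_example(self):
        # (0.01, 0.02, 0.03, 0.04) -> all 0.04
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))

            # independent oracle: sort, n*p/rank, cumulative min from the tail
            order = np.argsort(p)
            ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
            cummin = np.minimum.accumulate(ranked[::-1])[::-1]
            want = np.empty_like(p)
            want[order] = np.minimum(cummin, 1.0)

            assert np.allclose(bh_fdr(p), want)

    def test_nan_passthrough(self):
        q = bh_fdr(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and np.isfinite(q[0])


@pytest.fixture(scope="module")
def de_meta():
    """10 donors (5 ASD + 5 control), 40 cells each."""
    rng = np.random.default_rng(2)
    n_per = 40
    rows = []
    for i in range(10):
        donor = f"A{i}" if i < 5 else f"C{i}"
        diag = "ASD" if i < 5 else "control"
        for j in range(n_per):
            rows.append((donor, diag, 1, 5.0 + i, "M" if i % 2 else "F",
                         7.0 + 0.1 * i, 15.0 + i))
    return pd.DataFrame(
        rows, columns=["donor", "diagnosis", "cluster", "age", "sex", "RIN", "PMI"],
        index=[f"c{i}" for i in range(10 * n_per)],
    )


class TestFitHurdle:
    def test_label_symmetry_null(self, de_meta):
        rng = np.random.default_rng(4)
        y = np.where(rng.random(len(de_meta)) < 0.8, rng.normal(2.0, 1.0, len(de_meta)), 0.0)
        y = np.maximum(y, 0.0)
        full, reduced = fit_hurdle(y, de_meta)
        assert full.fit_status in ("mixed", "fixed_fallback")
        # diagnosis coefficients near zero in both parts
        i = full.test_col
        assert abs(full.discrete.beta[i]) < 0.6
        assert abs(full.continuous.beta[i]) < 0.4

    def test_continuous_coefficient_recovery(self):
        # planted 1.0 log2 continuous effect, no detection effect
        config = SimConfig(seed=31, n_genes=3, n_clusters=1, n_cells_per_donor=400,
                           dropout_base=0.2, planted_de=(("G000002", 1, 1.0, 0.0),))
        ds = gen_snuc_dataset(config)
        norm = normalize(ds)
        y = norm.gene_vector(1)
        full, _ = fit_hurdle(y, norm.cell_meta)
        assert full.continuous.beta[full.test_col] == pytest.approx(1.0, abs=0.2)

    def test_all_zero_gene_flagged(self, de_meta):
        full, reduced = fit_hurdle(np.zeros(len(de_meta)), de_meta)
        assert full.fit_status == "failed"

    def test_single_donor_group_flagged(self):
        meta = simple_meta(40, donor=["d1"] * 20 + ["d2"] * 20,
                           diagnosis=["ASD"] * 20 + ["control"] * 20)
        y = np.abs(np.random.default_rng(0).normal(2, 1, 40))
        full, _ = fit_hurdle(y, meta)
        assert full.fit_status == "failed"

    def test_all_detected_drops_discrete(self, de_meta):
        rng = np.random.default_rng(5)
        y = np.abs(rng.normal(3.0, 1.0, len(de_meta))) + 0.1
        full, reduced = fit_hurdle(y, de_meta)
        assert full.discrete is None and full.continuous is not None
        stat, df, p = lrt_diagnosis(full, reduced)
        assert df == 1

    def test_forced_fixed_status(self, de_meta):
        rng = np.random.default_rng(6)
        y = np.maximum(np.where(rng.random(len(de_meta)) < 0.8,
                                rng.normal(2.0, 1.0, len(de_meta)), 0.0), 0.0)
        spec = HurdleModelSpec(mixed=False)
        full, reduced = fit_hurdle(y, de_meta, spec)
        assert full.fit_status == "fixed_fallback"


class TestLRT:
    def test_equal_logliks_give_p_one(self, de_meta):
        rng = np.random.default_rng(7)
        y = np.maximum(np.where(rng.random(len(de_meta)) < 0.8,
                                rng.normal(2.0, 1.0, len(de_meta)), 0.0), 0.0)
        full, _ = fit_hurdle(y, de_meta)
        stat, df, p = lrt_diagnosis(full, full)
        assert stat == 0.0 and p == 1.0

    def test_df_two_when_both_parts_present(self, de_meta):
        rng = np.random.default_rng(8)
        y = np.maximum(np.where(rng.random(len(de_meta)) < 0.7,
                                rng.normal(2.0, 1.0, len(de_meta)), 0.0), 0.0)
        full, reduced = fit_hurdle(y, de_meta)
        assert full.discrete is not None and full.continuous is not None
        _, df, _ = lrt_diagnosis(full, reduced)
        assert df == 2

    def test_mismatched_status_rejected(self, de_meta):
        rng = np.random.default_rng(9)
        y = np.maximum(np.where(rng.random(len(de_meta)) < 0.8,
                                rng.normal(2.0, 1.0, len(de_meta)), 0.0), 0.0)
        full_mixed, _ = fit_hurdle(y, de_meta)
        _, reduced_fixed = fit_hurdle(y, de_meta, HurdleModelSpec(mixed=False))
        with pytest.raises(ValidationError, match="status"):
            lrt_diagnosis(full_mixed, reduced_fixed)

    def test_label_permutation_symmetry(self, de_meta):
        rng = np.random.default_rng(10)
        y = np.maximum(np.where(rng.random(len(de_meta)) < 0.8,
                                rng.normal(2.0, 1.0, len(de_meta)), 0.0), 0.0)
        swapped = de_meta.copy()
        swapped["diagnosis"] = np.where(de_meta["diagnosis"] == "ASD", "control", "ASD")
        full_a, red_a = fit_hurdle(y, de_meta)
        full_b, red_b = fit_hurdle(y, swapped)
        fc_a = fold_change(full_a, full_a)
        fc_b = fold_change(full_b, full_b)
        assert fc_a.log2_fc == pytest.approx(-fc_b.log2_fc, abs=0.02)
        _, _, p_a = lrt_diagnosis(full_a, red_a)
        _, _, p_b = lrt_diagnosis(full_b, red_b)
        assert p_a == pytest.approx(p_b, abs=0.02)


class TestFoldChange:
    def test_zero_coefficients_zero_fc(self, de_meta):
        # constant expression: diagnosis coefficients ~0 in both parts
        rng = np.random.default_rng(11)
        y = np.maximum(np.where(rng.random(len(de_meta)) < 0.8, 2.0, 0.0), 0.0)
        full, _ = fit_hurdle(y, de_meta)
        fc = fold_change(full, full)
        assert fc.log2_fc == pytest.approx(0.0, abs=0.15)

    def test_small_fold_fails_gate(self):
        fc_small = type("FC", (), {})()
        from amygdex.sc_de import FoldChange

        fc = FoldChange(log2_fc=np.log2(1.05), pct_change=0.05,
                        log2_fc_simplified=np.log2(1.05), pct_change_simplified=0.05)
        assert not fc.passes_gate(0.10)

    def test_gate_requires_both_models(self):
        from amygdex.sc_de import FoldChange

        fc = FoldChange(log2_fc=0.5, pct_change=0.41,
                        log2_fc_simplified=0.05, pct_change_simplified=0.04)
        assert not fc.passes_gate(0.10)
        fc2 = FoldChange(log2_fc=0.5, pct_change=0.41,
                         log2_fc_simplified=0.4, pct_change_simplified=0.32)
        assert fc2.passes_gate(0.10)


class TestCallDE:
    def _result(self, gene, p, pct, pct_simp=None):
        return DEResult(gene=gene, cluster=1, log2_fc=0.0, pct_change=pct,
                        lrt_stat=0.0, df=2, p_value=p, fdr=np.nan, is_de=False,
                        fit_status="mixed",
                        pct_change_simplified=pct if pct_simp is None else pct_simp)

    def test_conjunction_gate(self):
        results = [self._result("A", 0.0001, 0.05), self._result("B", 0.0001, 0.5)]
        called = call_de(results)
        assert not called[0].is_de and called[1].is_de

    def test_all_p_one_no_events(self):
        called = call_de([self._result(f"G{i}", 1.0, 0.9) for i in range(5)])
        assert not any(r.is_de for r in called)

    def test_is_de_iff_gates(self):
        rng = np.random.default_rng(12)
        results = [
            self._result(f"G{i}", rng.random() ** 3, rng.normal(0, 0.3))
            for i in range(50)
        ]
        called = call_de(results, fdr_cut=0.05, fc_cut=0.10)
        for r in called:
            expected = r.fdr < 0.05 and abs(r.pct_change) >= 0.10
            assert r.is_de == expected

    def test_event_counting(self):
        results = [
            DEResult("A", 1, 0.5, 0.5, 10, 2, 1e-5, 1e-4, True, "mixed", 0.5),
            DEResult("A", 2, 0.5, 0.5, 10, 2, 1e-5, 1e-4, True, "mixed", 0.5),
            DEResult("B", 1, 0.5, 0.5, 10, 2, 1e-5, 1e-4, True, "mixed", 0.5),
        ]
        events, genes = de_event_counts(results)
        assert (events, genes) == (3, 2)
        assert events >= genes


class TestMarkers:
    def test_exclusive_gene_is_top_marker(self):
        config = SimConfig(seed=41, n_genes=10, n_clusters=3, n_cells_per_donor=60,
                           planted_markers=(("G000005", 2, 2.0, 4.0),))
        ds = gen_snuc_dataset(config)
        res = markers(ds, 2)
        by_gene = {r.gene: r for r in res}
        assert by_gene["G000005"].is_marker
        top = max(res, key=lambda r: r.log2_enrichment)
        assert top.gene == "G000005"

    def test_uniform_gene_not_marker(self):
        config = SimConfig(seed=42, n_genes=10, n_clusters=3, n_cells_per_donor=60)
        ds = gen_snuc_dataset(config)
        for cluster in (1, 2, 3):
            res = markers(ds, cluster)
            assert not any(r.is_marker for r in res)

    def test_planted_marker_per_cluster_recovered(self):
        config = SimConfig(
            seed=43, n_genes=12, n_clusters=3, n_cells_per_donor=100,
            planted_markers=(
                ("G000001", 1, 1.5, 3.0),
                ("G000002", 2, 1.5, 3.0),
                ("G000003", 3, 1.5, 3.0),
            ),
        )
        ds = gen_snuc_dataset(config)
        for cluster, gene in ((1, "G000001"), (2, "G000002"), (3, "G000003")):
            res = markers(ds, cluster)
            by_gene = {r.gene: r for r in res}
            assert by_gene[gene].is_marker and by_gene[gene].fdr < 0.05

    def test_empty_cluster_rejected(self, null_snuc):
        with pytest.raises(ValidationError):
            markers(null_snuc, 99)


class TestCelltypeOverlap:
    def _de(self, gene, cluster, is_de=True):
        return DEResult(gene, cluster, 0.5, 0.5, 10, 2, 1e-5, 1e-4, is_de, "mixed", 0.5)

    def test_empty_de_list(self):
        table = celltype_overlap([self._de("X", 1, is_de=False)],
                                 [GeneSet("s", frozenset({"Y"}))])
        assert (table["overlap"] == 0).all()

    def test_full_overlap(self):
        de = [self._de("X", 1), self._de("Y", 1)]
        table = celltype_overlap(de, [GeneSet("s", frozenset({"X", "Y"}))])
        assert table.loc[0, "overlap"] == 2

    def test_toy_enumeration(self):
        # DE = {X, Y}; set = {Y, Z}; universe = 4 -> P(X >= 1) for
        # hypergeometric(N=4, K=2, n=2) = 1 - C(2,2)/C(4,2) = 5/6
        de = [self._de("X", 1), self._de("Y", 1)]
        table = celltype_overlap(de, [GeneSet("s", frozenset({"Y", "Z"}))], universe=4)
        assert table.loc[0, "overlap"] == 1
        assert table.loc[0, "p_value"] == pytest.approx(5 / 6, rel=1e-10)


class TestCalibrationContrast:
    def test_fixed_fallback_over_rejects_on_donor_correlated_data(self):
        """With substantial donor heterogeneity the donor random intercept
        keeps the null rejection rate far below the fixed-effects path,
        which badly over-rejects on the same data.  (The mixed path is
        itself somewhat inflated in this strong-heterogeneity regime —
        few donors, chi-square reference — which is why the calibration
        criterion runs at the milder simulator defaults.)"""
        config = SimConfig(seed=314, n_genes=150, n_clusters=1,
                           n_cells_per_donor=400, donor_sd=0.15, resid_sd=0.8)
        ds = gen_snuc_dataset(config)
        norm = normalize(ds)
        meta = norm.cell_meta

        def rejection(spec):
            from amygdex.sc_de import build_design

            design = build_design(meta, spec)
            ps = []
            for i in range(150):
                full, red = fit_hurdle(norm.gene_vector(i), meta, spec, design=design)
                _, _, p = lrt_diagnosis(full, red)
                ps.append(p)
            return float(np.mean(np.array(ps) < 0.05))

        rej_mixed = rejection(HurdleModelSpec(mixed=True))
        rej_fixed = rejection(HurdleModelSpec(mixed=False))
        assert rej_fixed > 0.30
        assert rej_mixed < rej_fixed - 0.15


class TestDeAnalysis:
    def test_planted_effect_detected_null_mostly_not(self):
        config = SimConfig(
            seed=51, n_genes=30, n_clusters=1, n_cells_per_donor=200,
            dropout_base=0.1, planted_de=(("G000007", 1, 1.5, 0.0),),
        )
        ds = gen_snuc_dataset(config)
        results = de_analysis(ds)
        by_gene = {r.gene: r for r in results}
        assert by_gene["G000007"].is_de
        n_false = sum(r.is_de for r in results if r.gene != "G000007")
        assert n_false <= 2

    def test_mtx_round_trip_counts_mode(self, tmp_path):
        config = SimConfig(seed=52, n_genes=8, n_clusters=2, n_cells_per_donor=30)
        ds = gen_snuc_dataset(config, counts=True)
        ds.to_mtx_dir(tmp_path / "snuc")
        back = SnucDataset.from_mtx_dir(tmp_path / "snuc")
        assert back.genes == ds.genes
        assert np.allclose(
            np.asarray(back.counts.todense()), np.asarray(ds.counts.todense())
        )
        pd.testing.assert_frame_equal(back.cell_meta, ds.cell_meta)

    def test_global_fdr_mode_runs(self, null_snuc):
        results = de_analysis(null_snuc, fdr_scope="global")
        assert len(results) > 0

    def test_gene_subset(self, null_snuc):
        results = de_analysis(null_snuc, genes=["G000001", "G000002"])
        assert {r.gene for r in results} <= {"G000001", "G000002"}
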