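import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from scrhythm.hurdle import (
    compute_cdr,
    find_markers,
    fit_hurdle,
    normalized_log_expression,
    peak_trough_filter,
    timepoint_shift_contrasts,
    wilcoxon_de,
)
from scrhythm.io import CellCountMatrix, PipelineConfig


def _ccm(counts, timepoints=None, cell_types=None, samples=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    cells = pd.DataFrame(
        {
            "barcode": [f"c{i}" for i in range(n_cells)],
            "sample": samples or ["s1"] * n_cells,
            "timepoint_hours": timepoints if timepoints is not None else [0.0] * n_cells,
            "cell_type": cell_types or ["typeA"] * n_cells,
        }
    )
    return CellCountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        cells=cells,
    )


class TestCdr:
    def test_raw_values_and_scaling(self):
        # one cell detects both genes, one detects half
        counts = np.array([[1, 1], [1, 0]])
        ccm = _ccm(counts)
        raw = compute_cdr(ccm, scale=False)
        assert np.allclose(raw, [1.0, 0.5])
        scaled = compute_cdr(ccm)
        assert scaled.mean() == pytest.approx(0.0)
        assert scaled.var() == pytest.approx(1.0)

    def test_zero_variance_fallback_warns(self):
        counts = np.array([[1, 1], [1, 1]])
        with pytest.warns(RuntimeWarning, match="zero variance"):
            cdr = compute_cdr(_ccm(counts))
        assert np.allclose(cdr, 0.0)

    def test_single_cell_error(self):
        with pytest.raises(ValueError, match="single cell"):
            compute_cdr(_ccm(np.array([[1], [0]])))

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.7, size=(30, 40))
        ccm = _ccm(counts)
        ccm_perm = _ccm(counts[rng.permutation(30)])
        assert np.allclose(compute_cdr(ccm), compute_cdr(ccm_perm))


class TestFitHurdle:
    def test_null_coefficients_center_on_zero(self):
        rng = np.random.default_rng(8)
        disc_coefs, cont_coefs = [], []
        for _ in range(60):
            n = 200
            group = (np.arange(n) >= n // 2).astype(float)
            counts = rng.poisson(1.0, size=n)
            X = np.column_stack([np.ones(n), group])
            log_expr = np.log2(1.0 + counts)
            try:
                fit = fit_hurdle(counts, log_expr, X)
            except ValueError:
                continue
            disc_coefs.append(fit.coef_discrete[1])
            cont_coefs.append(fit.coef_continuous[1])
        for coefs in (disc_coefs, cont_coefs):
            coefs = np.asarray(coefs)
            z = coefs.mean() / (coefs.std(ddof=1) / np.sqrt(len(coefs)))
            assert abs(z) < 3.0

    def test_recovers_planted_continuous_shift(self):
        rng = np.random.default_rng(3)
        shifts = []
        for rep in range(20):
            n = 500
            group = (np.arange(n) >= n // 2).astype(float)
            log_expr = rng.normal(2.0 + 1.0 * group, 0.5)
            counts = np.ones(n)  # constant detection
            X = np.column_stack([np.ones(n), group])
            fit = fit_hurdle(counts, log_expr, X)
            shifts.append(fit.coef_continuous[1])
        assert np.mean(shifts) == pytest.approx(1.0, abs=0.05)

    def test_degenerate_constant_expression_flagged(self):
        n = 30
        counts = np.ones(n)
        log_expr = np.full(n, 2.5)
        X = np.column_stack([np.ones(n), (np.arange(n) >= 15).astype(float)])
        fit = fit_hurdle(counts, log_expr, X)
        assert fit.degenerate

    def test_too_few_detected_cells(self):
        counts = np.zeros(50)
        counts[0] = 3
        X = np.ones((50, 1))
        with pytest.raises(ValueError, match="detected cells"):
            fit_hurdle(counts, np.log2(1 + counts), X)


class TestShiftContrasts:
    def test_needs_three_timepoints(self):
        counts = np.random.default_rng(0).poisson(1, size=(5, 40))
        tps = [0.0] * 20 + [12.0] * 20
        with pytest.raises(ValueError, match="3 distinct timepoints"):
            timepoint_shift_contrasts(_ccm(counts, tps))

    def test_balanced_shifts_sum_near_zero(self, standard_sim, standard_calls):
        contrasts, _ = standard_calls
        tested = contrasts[contrasts["tested"]]
        sums = tested.groupby("gene_id")["shift_lfc"].sum()
        spread = tested.groupby("gene_id")["shift_lfc"].apply(
            lambda s: s.abs().max()
        )
        # shifts from a common average: sums are small next to the shifts
        assert np.median(np.abs(sums)) < 0.05
        big = spread > 0.3
        assert (np.abs(sums[big]) < 0.5 * spread[big]).mean() > 0.9

    def test_planted_phase_zero_gene(self, standard_sim, standard_calls):
        _, truth = standard_sim
        contrasts, _ = standard_calls
        gene = truth.genes.query("clock_arm == 'positive'").iloc[0]["gene_id"]
        sub = contrasts[contrasts["gene_id"] == gene].set_index("timepoint")
        assert sub.loc[0.0, "shift_lfc"] > 0
        assert sub.loc[12.0, "shift_lfc"] < 0
        extremes = sub["shift_lfc"].abs().sort_values(ascending=False)
        assert set(extremes.index[:2]) == {0.0, 12.0}

    def test_null_uniformity(self, null_hurdle_contrasts):
        p = null_hurdle_contrasts.loc[
            null_hurdle_contrasts["tested"], "pvalue"
        ].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_null_type_one_error(self, null_hurdle_contrasts):
        p = null_hurdle_contrasts.loc[
            null_hurdle_contrasts["tested"], "pvalue"
        ].to_numpy()
        frac = (p < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(p))

    def test_lrt_nonnegative(self, null_hurdle_contrasts):
        stat = null_hurdle_contrasts.loc[
            null_hurdle_contrasts["tested"], "stat"
        ]
        assert (stat >= 0).all()

    def test_min_pct_screen(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(1.0, size=(3, 120))
        counts[1] = 0
        counts[1, :2] = 1  # ~1.7% detection everywhere
        tps = np.tile([0.0, 6.0, 12.0, 18.0], 30)
        res = timepoint_shift_contrasts(_ccm(counts, list(tps)), PipelineConfig())
        g1 = res[res["gene_id"] == "g1"]
        assert not g1["tested"].any()
        assert (g1["reason"] == "min_pct").all()


class TestPeakTroughFilter:
    def _frame(self, rows):
        base = {
            "tested": True, "reason": "", "stat": 10.0, "df": 2,
            "pvalue": 0.001, "pct_in": 0.5, "pct_out": 0.5,
        }
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_peak_and_trough_assignment(self):
        contrasts = self._frame(
            [
                {"gene_id": "g", "timepoint": 0.0, "shift_lfc": -0.4, "padj": 0.01},
                {"gene_id": "g", "timepoint": 6.0, "shift_lfc": 0.05, "padj": 0.9},
                {"gene_id": "g", "timepoint": 12.0, "shift_lfc": 0.5, "padj": 0.01},
                {"gene_id": "g", "timepoint": 18.0, "shift_lfc": -0.05, "padj": 0.8},
            ]
        )
        calls = peak_trough_filter(contrasts, PipelineConfig())
        row = calls.iloc[0]
        assert row["rhythmic"]
        assert row["peak_timepoint"] == 12.0
        assert row["trough_timepoint"] == 0.0

    def test_single_significant_timepoint_not_rhythmic(self):
        contrasts = self._frame(
            [
                {"gene_id": "g", "timepoint": 0.0, "shift_lfc": 0.5, "padj": 0.01},
                {"gene_id": "g", "timepoint": 12.0, "shift_lfc": -0.3, "padj": 0.2},
            ]
        )
        assert not peak_trough_filter(contrasts).iloc[0]["rhythmic"]

    def test_two_positive_shifts_not_rhythmic(self):
        contrasts = self._frame(
            [
                {"gene_id": "g", "timepoint": 0.0, "shift_lfc": 0.5, "padj": 0.01},
                {"gene_id": "g", "timepoint": 6.0, "shift_lfc": 0.4, "padj": 0.01},
                {"gene_id": "g", "timepoint": 12.0, "shift_lfc": -0.3, "padj": 0.4},
            ]
        )
        assert not peak_trough_filter(contrasts).iloc[0]["rhythmic"]

    def test_small_shift_does_not_count(self):
        # significant p but |shift| below the 0.15 cell-level cutoff
        contrasts = self._frame(
            [
                {"gene_id": "g", "timepoint": 0.0, "shift_lfc": 0.10, "padj": 0.01},
                {"gene_id": "g", "timepoint": 12.0, "shift_lfc": -0.5, "padj": 0.01},
            ]
        )
        assert not peak_trough_filter(contrasts).iloc[0]["rhythmic"]

    def test_subset_property(self, standard_calls):
        contrasts, calls = standard_calls
        assert set(calls.loc[calls["rhythmic"], "gene_id"]) <= set(
            calls.loc[calls["tested"], "gene_id"]
        )
        assert set(calls["gene_id"]) == set(contrasts["gene_id"])

    def test_peak_differs_from_trough(self, standard_calls):
        _, calls = standard_calls
        rhy = calls[calls["rhythmic"]]
        assert (rhy["peak_timepoint"] != rhy["trough_timepoint"]).all()


class TestRecovery:
    def test_recall_and_false_calls(self, standard_sim, standard_calls):
        _, truth = standard_sim
        _, calls = standard_calls
        merged = calls.merge(truth.genes, on="gene_id")
        rhy = merged[merged["is_rhythmic"]]
        non = merged[~merged["is_rhythmic"]]
        assert rhy["rhythmic"].mean() > 0.7
        assert non["rhythmic"].mean() < 0.05

    def test_clock_panel_antiphase(self, standard_sim, standard_calls):
        _, truth = standard_sim
        _, calls = standard_calls
        merged = calls.merge(truth.genes, on="gene_id")
        panel = merged[merged["clock_arm"] != ""]
        assert panel["rhythmic"].all()
        pos = panel[panel["clock_arm"] == "positive"]
        rep = panel[panel["clock_arm"] == "repressor"]
        assert (pos["peak_timepoint"] == 0.0).all()
        assert (pos["trough_timepoint"] == 12.0).all()
        assert (rep["peak_timepoint"] == 12.0).all()
        assert (rep["trough_timepoint"] == 0.0).all()


class TestWilcoxon:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        half = rng.poisson(2.0, size=(10, 15))
        counts = np.hstack([half, half])
        ccm = _ccm(counts)
        res = wilcoxon_de(ccm, np.arange(15), np.arange(15, 30))
        assert np.allclose(res.loc[res["tested"], "log2fc"], 0.0)
        assert (res.loc[res["tested"], "pvalue"] > 0.9).all()

    def test_min_pct_exclusion(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, size=(2, 100))
        counts[1] = 0
        counts[1, [0, 1, 50, 51]] = 1  # 4% in both groups
        ccm = _ccm(counts)
        res = wilcoxon_de(
            ccm, np.arange(50), np.arange(50, 100), min_pct=0.05
        )
        assert not res["tested"].iloc[1]

    def test_exact_p_matches_enumeration(self):
        # n=5 vs 5, distinct values: exact rank-sum p from all 252 splits
        values = np.array([3, 11, 1, 8, 6, 9, 4, 12, 2, 14])
        counts = values[None, :]
        ccm = _ccm(counts)
        res = wilcoxon_de(ccm, np.arange(5), np.arange(5, 10), min_pct=0.0)
        log_expr = normalized_log_expression(ccm)[0]
        xb = log_expr[5:]
        u_obs = sum(
            (b > a) + 0.5 * (b == a)
            for b in xb for a in log_expr[:5]
        )
        center = 25 / 2
        count = 0
        for combo in itertools.combinations(range(10), 5):
            grp_b = log_expr[list(combo)]
            grp_a = log_expr[[i for i in range(10) if i not in combo]]
            u = sum((b > a) + 0.5 * (b == a) for b in grp_b for a in grp_a)
            if abs(u - center) >= abs(u_obs - center) - 1e-12:
                count += 1
        expected = count / 252
        assert res["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_empty_group_rejected(self):
        ccm = _ccm(np.ones((2, 4), dtype=int))
        with pytest.raises(ValueError, match="nonempty"):
            wilcoxon_de(ccm, np.array([], dtype=int), np.arange(4))


class TestMarkers:
    def test_marker_gene_found(self):
        rng = np.random.default_rng(4)
        n_a, n_b = 60, 60
        counts = rng.poisson(1.0, size=(10, n_a + n_b))
        counts[0, :n_a] = rng.poisson(8.0, size=n_a)  # typeA marker
        ccm = _ccm(
            counts,
            cell_types=["typeA"] * n_a + ["typeB"] * n_b,
        )
        markers = find_markers(ccm, PipelineConfig())
        hit = markers[
            (markers["cell_type"] == "typeA") & (markers["gene_id"] == "g0")
        ]
        assert len(hit) == 1
        assert hit["log2fc"].iloc[0] >= 0.405
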