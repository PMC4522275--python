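"""Per-cell quantification, threshold derivation, scoring, image QC."""

import numpy as np
import pandas as pd
import pytest

import spectracell as sc
from spectracell.phenotyping import PHENOTYPES, nearest_rank_percentile
from spectracell.segmentation import CellLabelMap
from spectracell.synthetic import REGION_CODES
from spectracell.unmixing import AbundanceMap


def _amap3(lineage, tet, nuclear):
    data = np.stack([np.asarray(nuclear, float),
                     np.asarray(lineage, float),
                     np.asarray(tet, float)], axis=2)
    return AbundanceMap(
        data=data, residual=np.zeros(data.shape[:2]),
        endmember_names=["nuclear_red", "warp_red", "true_blue"],
        wavelengths_nm=np.array([500.0, 600.0, 700.0]),
    )


def _records(od_lineage, od_tet, region="other"):
    n = len(od_lineage)
    return pd.DataFrame(
        {
            "image_id": "img0",
            "cell_id": np.arange(1, n + 1),
            "y": np.zeros(n),
            "x": np.zeros(n),
            "area_px2": np.full(n, 30),
            "region": region,
            "od_lineage": np.asarray(od_lineage, float),
            "od_tet": np.asarray(od_tet, float),
            "od_nuclear": np.ones(n),
        }
    )


class TestQuantifyCells:
    def test_membrane_mean_is_ring_average(self):
        """Cell ring pixels with tet OD {0.1, 0.3} → mean OD 0.2."""
        labels = np.zeros((9, 9), dtype=np.int32)
        labels[4, 4] = 1
        tet = np.zeros((9, 9))
        # ring (expansion by 1) holds the 4-neighbourhood of the nucleus
        tet[3, 4] = tet[5, 4] = 0.1
        tet[4, 3] = tet[4, 5] = 0.3
        cells = CellLabelMap(
            labels=labels,
            table=pd.DataFrame([{"cell_id": 1, "y": 4.0, "x": 4.0,
                                 "area_px2": 1, "eq_radius_px": 0.56}]),
        )
        amap = _amap3(np.zeros((9, 9)), tet, np.full((9, 9), 0.5))
        regions = np.full((9, 9), REGION_CODES["follicle"], dtype=np.uint8)
        rec = sc.quantify_cells(cells, amap, regions, ring_px=1.0)
        assert rec["od_tet"][0] == pytest.approx(0.2)
        assert rec["od_nuclear"][0] == pytest.approx(0.5)
        assert rec["region"][0] == "follicle"

    def test_zero_cells_give_empty_records(self):
        cells = CellLabelMap(labels=np.zeros((4, 4), np.int32),
                             table=pd.DataFrame(columns=["cell_id", "y", "x",
                                                         "area_px2", "eq_radius_px"]))
        amap = _amap3(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4)))
        rec = sc.quantify_cells(cells, amap, np.zeros((4, 4), np.uint8))
        assert rec.empty

    def test_unknown_channel_rejected(self):
        cells = CellLabelMap(labels=np.zeros((4, 4), np.int32), table=pd.DataFrame())
        amap = _amap3(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(KeyError, match="missing_stain"):
            sc.quantify_cells(cells, amap, np.zeros((4, 4), np.uint8),
                              channel_map={"lineage": "missing_stain",
                                           "tetraspanin": "true_blue",
                                           "nuclear": "nuclear_red"})


class TestThresholds:
    def test_nearest_rank_95th_of_100_values(self):
        """ODs 0.01…1.00, 95th nearest-rank percentile → exactly 0.95."""
        ods = np.arange(1, 101) / 100.0
        assert nearest_rank_percentile(ods, 95) == pytest.approx(0.95)

    def test_derive_thresholds_on_graded_controls(self):
        ods = np.arange(1, 101) / 100.0
        rec = _records(od_lineage=ods, od_tet=ods)
        thr = sc.derive_thresholds(rec)
        assert thr.tet_dim_bright_od == pytest.approx(0.95)
        assert thr.lineage_positivity_od == pytest.approx(0.99)
        assert thr.n_control_cells == 100

    def test_constant_controls_give_constant_threshold(self):
        rec = _records(np.full(60, 0.05), np.full(60, 0.05))
        thr = sc.derive_thresholds(rec)
        assert thr.tet_dim_bright_od == pytest.approx(0.05)

    def test_too_few_controls_rejected_with_counts(self):
        rec = _records(np.ones(10), np.ones(10))
        with pytest.raises(ValueError, match="10"):
            sc.derive_thresholds(rec, min_control_cells=50)

    def test_threshold_monotone_in_percentile(self):
        ods = np.arange(1, 101) / 100.0
        rec = _records(ods, ods)
        t50 = sc.derive_thresholds(rec, percentile_tet=50).tet_dim_bright_od
        t95 = sc.derive_thresholds(rec, percentile_tet=95).tet_dim_bright_od
        assert t50 < t95

    def test_invariant_to_record_order(self):
        rng = np.random.default_rng(3)
        ods = rng.random(80)
        rec = _records(ods, ods)
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = sc.derive_thresholds(rec)
        b = sc.derive_thresholds(shuffled)
        assert a.tet_dim_bright_od == b.tet_dim_bright_od
        assert a.lineage_positivity_od == b.lineage_positivity_od

    def test_callable_selector(self):
        ods = np.arange(1, 101) / 100.0
        rec = _records(ods, ods, region="stroma")
        thr = sc.derive_thresholds(rec, control_selector=lambda r: r["region"] == "stroma")
        assert thr.n_control_cells == 100


class TestScoring:
    def test_four_way_classes(self):
        thr = sc.ScoringThresholds(lineage_positivity_od=0.2, tet_dim_bright_od=0.25)
        rec = _records([0.5, 0.1, 0.5, 0.1], [0.30, 0.1, 0.1, 0.30])
        scored = sc.score_cells(rec, thr)
        assert list(scored["phenotype"]) == [
            "lin_pos_bright", "lin_neg_dim", "lin_pos_dim", "lin_neg_bright",
        ]

    def test_boundary_equality_counts_as_bright(self):
        thr = sc.ScoringThresholds(lineage_positivity_od=0.2, tet_dim_bright_od=0.25)
        scored = sc.score_cells(_records([0.2], [0.25]), thr)
        assert scored["phenotype"][0] == "lin_pos_bright"

    def test_classes_partition_records(self, scored_default):
        scored, _, _ = scored_default
        counts = scored["phenotype"].value_counts()
        assert counts.sum() == len(scored)
        assert set(counts.index) <= set(PHENOTYPES)

    def test_class_fraction_recovery_on_default_scene(self, scored_default):
        """Scored bright/lin+ fractions per region within ±3 points of truth."""
        from scipy.spatial import cKDTree

        scored, _, truth = scored_default
        tree = cKDTree(truth.cells[["y", "x"]].to_numpy())
        d, idx = tree.query(scored[["y", "x"]].to_numpy())
        m = scored[d < 3]
        mt = truth.cells.iloc[idx[d < 3]]
        for region in ("follicle", "t_zone", "stroma"):
            sel = (mt["region"] == region).to_numpy()
            true_bright = (mt["tet_class"][sel] == "bright").mean()
            true_lin = (mt["lineage_class"][sel] == "lin_pos").mean()
            assert m["tet_bright"].to_numpy()[sel].mean() == pytest.approx(
                true_bright, abs=0.03
            ), region
            assert m["lineage_positive"].to_numpy()[sel].mean() == pytest.approx(
                true_lin, abs=0.03
            ), region


class TestImageQC:
    def test_strict_less_than_10_percent_rule(self):
        kept, dropped, qc = sc.qc_filter_images(
            {"a": 0.05, "b": 0.09, "c": 0.10, "d": 0.50}
        )
        assert dropped == ["a", "b"]
        assert kept == ["c", "d"]
        assert [q.passed for q in qc] == [False, False, True, True]

    def test_empty_input(self):
        kept, dropped, qc = sc.qc_filter_images({})
        assert kept == [] and dropped == [] and qc == []

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sc.qc_filter_images({"a": 1.5})


class TestPhenotypeScorer:
    def test_fit_predict_roundtrip(self):
        ods = np.arange(1, 101) / 100.0
        controls = _records(ods, ods)
        scorer = sc.PhenotypeScorer().fit(controls)
        assert scorer.thresholds_.tet_dim_bright_od == pytest.approx(0.95)
        pred = scorer.predict(_records([1.5], [1.5], region="follicle"))
        assert pred[0] == "lin_pos_bright"

    def test_unfitted_scorer_rejects_transform(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            sc.PhenotypeScorer().transform(_records([1.0], [1.0]))

    def test_get_set_params(self):
        scorer = sc.PhenotypeScorer(percentile_tet=90.0)
        assert scorer.get_params()["percentile_tet"] == 90.0
        scorer.set_params(percentile_tet=97.0)
        assert scorer.percentile_tet == 97.0
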