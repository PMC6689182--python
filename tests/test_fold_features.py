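import math

import numpy as np
import pytest

from cisrate.data_model import Dataset
from cisrate.fold_features import (
    DEFAULT_LENGTH_GRID,
    FeatureMatrix,
    FoldFeatureSpec,
    WINDOW_FAMILIES,
    build_fold_matrix,
    dataset_thresholds,
    fold_specs,
    location_features,
    nearest_rank,
    nonoverlap_min_windows,
    rank_features,
    threshold_features,
    whole_feature,
)
from cisrate.folding import FoldWindow, enumerate_windows, fold_window
from cisrate.synthetic_data import plant_hairpin
from conftest import make_record


def _fw(start, dg, L=10, gid="g"):
    return FoldWindow(gid, start, L, dg)


class TestRankFeatures:
    def test_five_values(self):
        ws = [_fw(-5 + i, dg) for i, dg in enumerate([-10, -8, -6, -4, -2])]
        r = rank_features(ws)
        assert r["rank_min"] == -10
        assert r["rank_max"] == -2
        assert r["rank_25"] == -8  # ceil(0.25*5)=2nd smallest
        assert r["rank_10"] == -10  # ceil(0.1*5)=1st
        assert r["rank_75"] == -4
        assert r["rank_90"] == -2

    def test_single_window(self):
        r = rank_features([_fw(-1, -3.5)])
        assert all(v == -3.5 for v in r.values())

    def test_empty_missing(self):
        assert all(math.isnan(v) for v in rank_features([]).values())

    def test_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 40))
            e = np.round(rng.normal(-5, 3, n), 3)
            ws = [_fw(-n + i, float(v)) for i, v in enumerate(e)]
            r = rank_features(ws)
            s = np.sort(e)
            for pct, fam in [(10, "rank_10"), (25, "rank_25"), (75, "rank_75"), (90, "rank_90")]:
                k = max(1, math.ceil(pct / 100 * n))
                assert r[fam] == s[k - 1]
            assert r["rank_min"] == s[0] and r["rank_max"] == s[-1]


class TestLocationFeatures:
    def test_long_utr_all_defined(self, rng):
        rec = make_record(utr5="".join(rng.choice(list("ACGU"), 100)), body="GCU" * 30)
        vals = location_features(rec, 35, windows=enumerate_windows(rec, 35))
        assert all(math.isfinite(v) for v in vals.values())

    def test_short_utr_missing_and_coincident(self, rng):
        rec = make_record(utr5="".join(rng.choice(list("ACGU"), 30)), body="GCU" * 30)
        ws = enumerate_windows(rec, 35)
        vals = location_features(rec, 35, windows=ws)
        assert math.isnan(vals["loc_-65"])
        assert vals["loc_-30"] == vals["loc_5cap"]  # cap at -30

    def test_loc_minus1_span(self, rng):
        rec = make_record(utr5="".join(rng.choice(list("ACGU"), 20)), body="GCU" * 30)
        ws = enumerate_windows(rec, 12)
        direct = fold_window(rec.seq[rec.utr5_len - 1 : rec.utr5_len - 1 + 12])[0]
        vals = location_features(rec, 12, windows=ws)
        assert vals["loc_-1"] == pytest.approx(direct)


class TestThresholdFeatures:
    def _thresholds(self):
        pooled = np.array([-10, -8, -6, -5, -4, -3, -2, -1, -0.5, 0.0])
        return dataset_thresholds(pooled)

    def test_no_qualifying_scores_zero(self):
        th = self._thresholds()
        ws = [_fw(-3, -2.5), _fw(-2, -1.0)]  # all above the 20th pct cutoff (-8)
        vals = threshold_features(ws, th)
        assert vals["pct_le20"] == 0.0
        assert vals["sum_le20"] == 0.0

    def test_all_qualifying(self):
        th = self._thresholds()
        ws = [_fw(-3, -20.0), _fw(-2, -15.0)]
        assert threshold_features(ws, th)["pct_le20"] == 100.0

    def test_brute_force_sums(self, rng):
        pooled = rng.normal(-5, 3, 500)
        th = dataset_thresholds(pooled)
        for _ in range(50):
            e = rng.choice(pooled, size=int(rng.integers(1, 30)))
            ws = [_fw(-len(e) + i, float(v)) for i, v in enumerate(e)]
            vals = threshold_features(ws, th)
            assert vals["sum_le10"] == pytest.approx(e[e <= th[10]].sum())
            assert vals["sum_ge80"] == pytest.approx(e[e >= th[80]].sum())
            assert vals["pct_ge90"] == pytest.approx(100 * np.mean(e >= th[90]))
            assert 0 <= vals["pct_le20"] <= 100

    def test_threshold_permutation_invariance(self, rng):
        pooled = rng.normal(-5, 3, 400)
        assert dataset_thresholds(pooled) == dataset_thresholds(rng.permutation(pooled))


class TestWholeFeature:
    def test_zero_utr_folds_cds_head(self):
        rec = make_record(utr5="", body="GCUUAU" * 10)
        assert whole_feature(rec) == pytest.approx(fold_window(rec.seq[:35])[0])

    def test_unstructured_zero(self):
        rec = make_record(utr5="AAAAAAAAAA", body="AAAAAA" * 5 + "CCC")
        assert whole_feature(rec) == 0.0

    def test_equals_explicit_subsequence(self, rng):
        rec = make_record(utr5="".join(rng.choice(list("ACGU"), 25)), body="GCU" * 20)
        assert whole_feature(rec) == pytest.approx(fold_window(rec.seq[: 25 + 35])[0])


class TestNonoverlapMinWindows:
    def test_short_region_fewer_windows(self, rng):
        rec = make_record(utr5="".join(rng.choice(list("ACGU"), 10)), body="GCU" * 15)
        ws = enumerate_windows(rec, 35)
        chosen = nonoverlap_min_windows(ws, k=2)
        assert len(chosen) == 1  # all 10 windows mutually overlap

    def test_tie_break_5prime(self):
        ws = [_fw(-40, -5.0), _fw(-20, -5.0), _fw(-10, -1.0)]
        chosen = nonoverlap_min_windows(ws, k=2)
        assert chosen[0].start == -40 and chosen[1].start == -20

    def test_planted_hairpins_recovered_in_energy_order(self, rng):
        utr = "".join(rng.choice(list("ACGU"), p=[0.4, 0.1, 0.1, 0.4], size=130))
        for pos, stem in [(5, 10), (50, 8), (95, 6)]:
            arm = "".join(rng.choice(list("GC"), stem))
            utr = utr[:pos] + arm + utr[pos + stem :]
            utr, _ = plant_hairpin(utr, pos, stem, 4)
        rec = make_record(utr5=utr, body="GCU" * 15)
        ws = enumerate_windows(rec, 30)
        chosen = nonoverlap_min_windows(ws, k=3)
        assert len(chosen) == 3
        # greedy energies are non-increasing in selection order
        assert chosen[0].delta_g <= chosen[1].delta_g <= chosen[2].delta_g
        assert chosen[0].delta_g == min(w.delta_g for w in ws)
        # exhaustive oracle over non-overlapping pairs: the planted, well
        # separated hairpins make the greedy pair the optimal pair
        best_sum = min(
            a.delta_g + b.delta_g
            for a in ws
            for b in ws
            if a.start + a.length <= b.start
        )
        assert chosen[0].delta_g + chosen[1].delta_g == pytest.approx(best_sum)


class TestBuildFoldMatrix:
    def test_column_count_formula(self):
        specs = fold_specs(DEFAULT_LENGTH_GRID)
        assert len(specs) == len(DEFAULT_LENGTH_GRID) * len(WINDOW_FAMILIES) + 1

    def test_pombe_constraint_drops_3prime_windows(self):
        specs = fold_specs((35,), pombe_constraint=True)
        names = {s.column for s in specs}
        assert "fold.L35.loc_-1" not in names  # reaches +34
        assert "fold.L35.rank_min" not in names
        assert "fold.L35.loc_-65" in names  # reaches only -31..+?
        assert "fold.whole" not in names

    def test_pombe_boundary_length(self):
        specs = fold_specs((30, 31, 32), pombe_constraint=True)
        names = {s.column for s in specs}
        assert "fold.L31.rank_min" in names  # -1 start reaches +30 exactly
        assert "fold.L32.rank_min" not in names

    def test_matrix_rows_align_and_invariants(self, small_dataset):
        d, _ = small_dataset
        sub = Dataset(list(d)[:25], name="sub")
        fm = build_fold_matrix(sub, lengths=(15, 30))
        assert fm.gene_ids == sub.gene_ids
        assert len(fm.feature_names) == 2 * len(WINDOW_FAMILIES) + 1
        for L in (15, 30):
            rmin = fm.frame[f"fold.L{L}.rank_min"]
            for fam in ("rank_10", "rank_25", "rank_75", "rank_90", "rank_max"):
                other = fm.frame[f"fold.L{L}.{fam}"]
                ok = rmin.notna() & other.notna()
                assert (rmin[ok] <= other[ok] + 1e-9).all()
            pct = fm.frame[f"fold.L{L}.pct_le20"].dropna()
            assert ((0 <= pct) & (pct <= 100)).all()


class TestFeatureMatrix:
    def test_design_imputes_column_mean(self):
        fm = FeatureMatrix.from_dict(["a", "b", "c"], {"x": [1.0, math.nan, 3.0]})
        X = fm.design()
        assert X[1, 0] == pytest.approx(2.0)
        assert fm.mask.loc["b", "x"]

    def test_tsv_round_trip(self, tmp_path):
        fm = FeatureMatrix.from_dict(["a", "b"], {"x": [1.5, math.nan], "y": [0.0, 2.0]})
        path = tmp_path / "m.tsv"
        fm.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        assert back.feature_names == ["x", "y"]
        assert math.isnan(back.frame.loc["b", "x"])
        assert back.frame.loc["b", "y"] == 2.0
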