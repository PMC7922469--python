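import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from soynmr.cohort import KOREA_CHINA_MARKERS, default_design, simulate_cohort
from soynmr.preprocess import aggregate_metabolite_features, normalize
from soynmr.workflow import (
    compare_group_levels,
    grid_search_preprocessing,
    one_vs_rest_models,
    one_vs_rest_report,
    run_preset,
    vip_cutoff_sweep,
)


@pytest.fixture(scope="module")
def korea_china_features(binned_module, library_module):
    nm = normalize(binned_module, "total_area")
    feats = aggregate_metabolite_features(nm, library_module)
    labels = binned_module.metadata["country"].values
    return feats, labels


# session fixtures re-exposed at module granularity for clarity
@pytest.fixture(scope="module")
def binned_module(request):
    return request.getfixturevalue("binned")


@pytest.fixture(scope="module")
def library_module(request):
    return request.getfixturevalue("library")


class TestGridSearch:
    def test_strong_cohort_selects_one_valid_cell(self, binned_module, library_module):
        labels = binned_module.metadata["country"].values
        rows = grid_search_preprocessing(
            binned_module,
            labels,
            family="opls",
            max_components=4,
            n_permutations=25,
            seed=0,
            aggregate=library_module,
        )
        assert len(rows) == 4
        assert all(r.valid for r in rows)
        selected = [r for r in rows if r.selected]
        assert len(selected) == 1
        best_q2 = max(r.q2y for r in rows if r.valid)
        assert selected[0].q2y == best_q2

    def test_single_cell_grid_selected_iff_valid(self, binned_module, library_module):
        labels = binned_module.metadata["country"].values
        rows = grid_search_preprocessing(
            binned_module,
            labels,
            family="opls",
            normalizations=("total_area",),
            scalings=("uv",),
            max_components=3,
            n_permutations=25,
            seed=1,
            aggregate=library_module,
        )
        assert len(rows) == 1
        assert rows[0].selected == (rows[0].valid and rows[0].q2y > 0)

    def test_noise_labels_select_nothing(self, binned_module, library_module):
        rng = np.random.default_rng(0)
        labels = rng.permutation(binned_module.metadata["country"].values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = grid_search_preprocessing(
                binned_module,
                labels,
                family="opls",
                normalizations=("total_area",),
                scalings=("uv", "pareto"),
                max_components=3,
                n_permutations=25,
                seed=0,
                aggregate=library_module,
            )
        assert not any(r.selected for r in rows)


class TestVipSweep:
    def test_zero_cutoff_retains_everything(self, korea_china_features):
        feats, labels = korea_china_features
        y = (labels == "Korea").astype(float)
        rows = vip_cutoff_sweep(
            feats.values,
            y,
            family="opls",
            cutoffs=(0.0, 99.0),
            max_components=3,
            stratify=labels,
        )
        assert rows[0].n_variables == feats.shape[1]
        assert not rows[1].feasible

    def test_cutoff_one_retains_planted_markers(self, korea_china_features, library_module):
        feats, labels = korea_china_features
        y = (labels == "Korea").astype(float)
        rows = vip_cutoff_sweep(
            feats.values,
            y,
            family="opls",
            cutoffs=(1.0,),
            max_components=3,
            stratify=labels,
        )
        kept = {feats.columns[i] for i in rows[0].variables}
        planted = set(KOREA_CHINA_MARKERS)
        assert len(kept & planted) >= 7


class TestOneVsRest:
    def test_report_shape_and_columns(self, cohort):
        conc, meta = cohort
        china = (meta["country"] == "China").values
        labels = meta["region_class"].values[china]
        results = one_vs_rest_models(conc.values[china], labels, seed=0)
        report = one_vs_rest_report(results)
        assert list(report.columns) == ["class", "sensitivity", "specificity", "accuracy"]
        assert len(report) == 3
        assert set(report["class"]) == {
            "NR vs. MR&SR",
            "MR vs. NR&SR",
            "SR vs. NR&MR",
        }

    def test_regional_models_separate_planted_effects(self):
        # spec'd scenario: seed-3 cohort, bin-level features, VIP selection
        report = run_preset("china_regions", seed=3, n_permutations=20)["report"]
        assert (report["accuracy"] >= 90.0).all()

    def test_duplicated_class_profile_drops_to_chance(self, rng):
        X = np.vstack(
            [
                rng.normal(0, 1, size=(8, 6)),
                rng.normal(0, 1, size=(8, 6)),
                rng.normal(8, 1, size=(8, 6)),
            ]
        )
        labels = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
        results = one_vs_rest_models(X, labels, seed=0)
        report = one_vs_rest_report(results).set_index("class")
        # A and B are statistically identical: their models cannot separate
        assert report.loc["A vs. B&C", "accuracy"] < 85.0
        assert report.loc["C vs. A&B", "accuracy"] == 100.0

    def test_two_classes_rejected(self, rng):
        with pytest.raises(ValueError, match="3 classes"):
            one_vs_rest_models(rng.normal(size=(10, 3)), ["A"] * 5 + ["B"] * 5)


class TestCompareGroupLevels:
    def test_identical_groups_flag_nothing(self):
        X = pd.DataFrame({"m1": [1.0] * 8, "m2": [2.0] * 8})
        labels = ["A"] * 4 + ["B"] * 4
        table = compare_group_levels(X, labels)
        assert not table["significant"].any()
        assert table["degenerate"].all()
        assert (table["p_value"] == 1.0).all()

    def test_planted_fold_change_detected_with_power(self):
        # oracle: Monte-Carlo power at 1.3x fold, CV 0.10, n = 32 vs 36
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            sigma = np.sqrt(np.log(1.01))
            a = 1.3 * np.exp(rng.normal(0, sigma, 32))
            b = np.exp(rng.normal(0, sigma, 36))
            X = pd.DataFrame({"marker": np.r_[a, b]})
            labels = ["K"] * 32 + ["C"] * 36
            t = compare_group_levels(X, labels)
            hits += bool(t.loc["marker", "significant"])
        assert hits >= int(0.95 * n_runs)

    def test_group_order_flips_ratio_keeps_pvalue(self, rng):
        a = rng.normal(2, 0.2, 10)
        b = rng.normal(1, 0.2, 12)
        X1 = pd.DataFrame({"m": np.r_[a, b]})
        labels1 = ["A"] * 10 + ["B"] * 12
        X2 = pd.DataFrame({"m": np.r_[b, a]})
        labels2 = ["B"] * 12 + ["A"] * 10
        t1 = compare_group_levels(X1, labels1)
        t2 = compare_group_levels(X2, labels2)
        assert t1.loc["m", "p_value"] == pytest.approx(t2.loc["m", "p_value"])
        assert t1.loc["m", "higher_in"] == "A"
        assert t2.loc["m", "higher_in"] == "A"
        assert t1.loc["m", "mean_ratio"] == pytest.approx(
            1.0 / t2.loc["m", "mean_ratio"]
        )

    def test_more_than_two_groups_rejected(self, cohort):
        conc, meta = cohort
        feats = conc.iloc[:, :3]
        with pytest.raises(ValueError, match="2 groups"):
            compare_group_levels(feats, meta["region_class"].values)


class TestSignRecovery:
    def test_predictive_loading_signs_match_planted_directions(self):
        """Across 50 seeded cohorts, the OPLS predictive weight at each
        marker's dominant uniquely-owned bin carries the planted effect
        direction (markers with no attributable bin are unassessable)."""
        from soynmr.cohort import (
            SPECTROMETER_MHZ,
            multiplet_lines,
            simulate_spectra,
        )
        from soynmr.library import build_metabolite_library
        from soynmr.pls import OPLS
        from soynmr.preprocess import ColumnScaler, bin_spectra

        lib = build_metabolite_library()
        # coarser render grid: bin values are sums, so resolution only
        # rescales them and the 245-bin layout is unchanged
        design = default_design().with_(ppm_step=0.001)
        directions = {
            "alanine": 1, "citrate": 1, "isoleucine": 1, "tartarate": 1,
            "valine": 1, "asparagine": -1, "choline": -1, "galactarate": -1,
            "tryptophan": -1,
        }
        ok = total = 0
        for seed in range(50):
            ss = simulate_spectra(design, seed)
            bm = bin_spectra(ss)
            nm = normalize(bm, "total_area")
            y = (bm.metadata["country"].values == "Korea").astype(float)
            X = ColumnScaler("uv").fit(nm.values.values).transform(nm.values.values)
            w = OPLS(n_orthogonal=2).fit(X, y).x_weights_
            owners: dict[int, set] = {}
            for p in lib.peaks:
                offsets, _ = multiplet_lines(p)
                for off in offsets / SPECTROMETER_MHZ:
                    b = bm.bin_index_of(p.center_shift + off)
                    if b is not None:
                        owners.setdefault(b, set()).add(p.metabolite_name)
            mean_bins = nm.values.values.mean(axis=0)
            for name, direction in directions.items():
                bins = {bm.bin_index_of(p.center_shift) for p in lib.peaks_of(name)}
                clean = [b for b in bins if b is not None and owners.get(b) == {name}]
                if not clean:
                    continue
                dominant = max(clean, key=lambda b: mean_bins[b])
                total += 1
                ok += int(np.sign(w[dominant]) == direction)
        assert total >= 300  # at least 6 assessable markers per seed
        assert ok / total >= 0.95


class TestEndToEnd:
    def test_full_run_is_deterministic(self):
        a = run_preset("korea_china", seed=5, n_permutations=20)
        b = run_preset("korea_china", seed=5, n_permutations=20)
        pd.testing.assert_frame_equal(a["report"], b["report"])
        assert a["permutation"].q2y_intercept == b["permutation"].q2y_intercept
        assert a["auc"] == b["auc"]

    def test_korea_china_recovery_has_high_accuracy(self):
        res = run_preset("korea_china", seed=5, n_permutations=20)
        assert res["report"]["accuracy"].iloc[0] >= 90.0
        assert res["permutation"].valid
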