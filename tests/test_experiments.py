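"""Phase-lag, clustering, class-partition and correlation analyses."""

import numpy as np
import pandas as pd
import pytest

from polya_rhythms import Variant
from polya_rhythms.experiments import (circular_distance, circular_mean,
                                       circular_std, classify_sets,
                                       correlation_comparison,
                                       phase_lag_analysis,
                                       run_class_partition,
                                       run_phase_clustering)
from polya_rhythms.features import Quantity


class TestCircularHelpers:
    def test_mean_handles_wraparound(self):
        assert circular_mean(np.array([23.0, 1.0])) == pytest.approx(0.0, abs=1e-9)

    def test_std_of_tight_cluster_small(self):
        vals = np.array([23.5, 0.5, 23.8, 0.2])
        assert circular_std(vals) < 1.0

    def test_distance_symmetric_and_bounded(self):
        assert circular_distance(1.0, 23.0) == pytest.approx(2.0)
        assert circular_distance(0.0, 12.0) == pytest.approx(12.0)


class TestPhaseLag:
    def test_self_comparison_gives_zero_lag(self):
        df = pd.DataFrame({"phi_deA": np.linspace(0, 23.9, 50)})
        df["phase_ratio"] = df["phi_deA"]       # output phase == input phase
        df["amp_ratio"] = 0.5
        lag = phase_lag_analysis(df, "deA", Quantity.RATIO)
        assert lag.circ_mean == pytest.approx(0.0, abs=1e-9)
        assert lag.circ_std == pytest.approx(0.0, abs=1e-6)
        assert lag.lag_magnitude == pytest.approx(0.0, abs=1e-9)

    def test_signed_mean_reflects_shortest_offset(self):
        df = pd.DataFrame({"phi_deA": np.zeros(10),
                           "phase_ratio": np.full(10, 13.5),
                           "amp_ratio": np.full(10, 0.5)})
        lag = phase_lag_analysis(df, "deA", Quantity.RATIO)
        assert lag.circ_mean == pytest.approx(13.5)
        assert lag.signed_mean == pytest.approx(-10.5)
        assert lag.lag_magnitude == pytest.approx(10.5)

    def test_rhythmic_filter_reduces_n(self, global_sweep_small):
        all_sets = phase_lag_analysis(global_sweep_small, "deA", Quantity.RATIO,
                                      rhythmic_only=False)
        rhythmic = phase_lag_analysis(global_sweep_small, "deA", Quantity.RATIO,
                                      rhythmic_only=True)
        assert rhythmic.n < all_sets.n == len(global_sweep_small)

    def test_empty_selection_raises(self):
        df = pd.DataFrame({"phi_deA": [1.0], "phase_ratio": [np.nan],
                           "amp_ratio": [0.5]})
        with pytest.raises(ValueError):
            phase_lag_analysis(df, "deA", Quantity.RATIO)


class TestClassification:
    def test_full_variant_definitions(self):
        df = pd.DataFrame({
            "amp_total": [0.3, 0.1, 0.25, 0.05],
            "amp_ratio": [0.5, 0.5, 0.1, 0.1],
        })
        labels = classify_sets(df, Variant.FULL).tolist()
        assert labels == ["I", "II", "UNCLASSIFIED", "UNCLASSIFIED"]

    def test_boundary_amplitude_is_inclusive(self):
        df = pd.DataFrame({"amp_total": [0.2], "amp_ratio": [0.2]})
        assert classify_sets(df, Variant.FULL).tolist() == ["I"]

    def test_no_trsc_variant_definitions(self):
        df = pd.DataFrame({"amp_total": [0.1, 0.3], "amp_ratio": [0.4, 0.4]})
        labels = classify_sets(df, Variant.NO_TRSC_RHYTHM).tolist()
        assert labels == ["III", "IV"]

    def test_no_polya_variant_rejected(self):
        df = pd.DataFrame({"amp_total": [0.1], "amp_ratio": [0.4]})
        with pytest.raises(ValueError):
            classify_sets(df, Variant.NO_POLYA)


@pytest.fixture(scope="module")
def full_partition():
    return run_class_partition(Variant.FULL, 15_000, 100)


@pytest.fixture(scope="module")
def no_trsc_partition():
    return run_class_partition(Variant.NO_TRSC_RHYTHM, 15_000, 101)


class TestPartitionBiology:
    def test_class_ii_has_lower_degradation_rate_than_class_i(self, full_partition):
        by = full_partition.groupby("class_label")["k_dgrd"].median()
        assert by["II"] < by["I"]

    def test_class_i_enriched_in_antiphasic_transcription_degradation(
            self, full_partition):
        anti = full_partition["dphi_trsc_dgrd"].abs() >= 6.0
        frac = anti.groupby(full_partition["class_label"]).mean()
        assert frac["I"] > frac["II"] + 0.1

    def test_class_iv_needs_faster_degradation_than_class_iii(
            self, no_trsc_partition):
        by = no_trsc_partition.groupby("class_label")["k_dgrd"].median()
        assert by["IV"] > by["III"]

    def test_class_iv_phase_geometry(self, no_trsc_partition):
        """Class IV: deadenylation near degradation, both opposite polyA."""
        df = no_trsc_partition
        close = (df["dphi_deA_dgrd"].abs() < 6.0)
        far = (df["dphi_deA_polyA"].abs() > 6.0)
        frac_iv = (close & far)[df["class_label"] == "IV"].mean()
        frac_iii = (close & far)[df["class_label"] == "III"].mean()
        assert frac_iv > frac_iii + 0.1


class TestClustering:
    def test_windowed_deadenylation_clusters_output_phases(self):
        strong = run_phase_clustering("iv", 1500, 7)
        control = run_phase_clustering("ii", 1500, 8)
        assert strong.capture_narrow > control.capture_narrow + 0.15
        assert strong.ks_uniform_p < 1e-6
        assert control.ks_uniform_p > 1e-4
        # all three predicted windows populated
        assert min(strong.window_occupancy) > 0.2

    def test_uniform_control_sits_at_baseline(self):
        res = run_phase_clustering("i", 1500, 9)
        assert abs(res.excess_narrow) < 0.08
        assert res.ks_uniform_p > 1e-3


class TestCorrelationComparison:
    def test_deadenylation_phase_shows_spurious_negative_pearson(
            self, global_sweep_small):
        table = correlation_comparison(global_sweep_small)
        row = table[(table.parameter == "phi_deA")
                    & (table.output == "phase_ratio")].iloc[0]
        assert row.pearson_r < -0.2
        assert row.spearman_rho < -0.2

    def test_monotone_noncircular_pair_agrees_across_methods(
            self, global_sweep_small):
        """Deadenylation amplitude drives L/S amplitude monotonically."""
        from scipy import stats
        df = global_sweep_small
        r = stats.pearsonr(df["A_deA"], df["amp_ratio"]).statistic
        rho = stats.spearmanr(df["A_deA"], df["amp_ratio"]).statistic
        assert r > 0.3 and rho > 0.3

    def test_constant_output_yields_nan_with_warning(self):
        df = pd.DataFrame({
            **{f"phi_{p}": np.linspace(0, 23, 30)
               for p in ("trsc", "dgrd", "deA", "polyA")},
            "phase_total": np.full(30, 4.0), "phase_ratio": np.full(30, 4.0),
            "phase_long": np.full(30, 4.0),
        })
        with pytest.warns(UserWarning, match="constant"):
            table = correlation_comparison(df)
        assert table["pearson_r"].isna().all()
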