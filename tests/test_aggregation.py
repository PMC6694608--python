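"""Lane/sample/experiment rollups and dataset comparison."""

import math

import numpy as np
import pytest

from fqstat.aggregation import (
    UnitKey,
    aggregate_experiment,
    aggregate_sample,
    build_metric_table,
    compare_datasets,
    percent_difference,
)
from fqstat.fastq_core import SegmentStats, stats_for_file


def stats(n_reads, length, qual, hq):
    return SegmentStats(
        n_reads=n_reads, n_bases=n_reads * length, len_min=length, len_max=length,
        len_sum=n_reads * length, qual_sum=qual, hq_bases=hq,
    )


class TestSampleLevel:
    def test_read_counts_add(self):
        lanes = {f"L{i}": stats(n, 50, n * 50 * 30, n * 25) for i, n in
                 enumerate([10, 20, 30, 40])}
        assert aggregate_sample(lanes).n_reads == 100

    def test_single_lane_identity(self):
        s = stats(10, 50, 15000, 400)
        assert aggregate_sample({"L1": s}) == s

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            aggregate_sample({})

    def test_merged_mean_quality_is_base_weighted(self, small_manifest):
        """Sample mean quality equals the base-weighted mean of lane means."""
        per_lane = {
            k.lane: stats_for_file(f.path)
            for k, f in small_manifest.entries
            if k.sample == "S1" and k.mate == "R1"
        }
        merged = aggregate_sample(per_lane)
        weighted = sum(s.mean_quality * s.n_bases for s in per_lane.values()) / sum(
            s.n_bases for s in per_lane.values()
        )
        assert merged.mean_quality == pytest.approx(weighted, rel=1e-12)


class TestExperimentLevel:
    def make_units(self):
        # 2 samples x 2 lanes, sample S2's lanes carry 10x the bases of S1's
        units = {}
        for sample, scale, hq_frac in (("S1", 1, 0.9), ("S2", 10, 0.5)):
            for lane in ("L1", "L2"):
                n = 100 * scale
                units[UnitKey("raw", sample, "R1", lane)] = stats(
                    n, 50, n * 50 * 30, int(n * 50 * hq_frac)
                )
        return units

    def test_pooled_tallies_identical_across_resolutions(self):
        units = self.make_units()
        pooled_lane, _ = aggregate_experiment(units, "lane")
        pooled_sample, _ = aggregate_experiment(units, "sample")
        assert pooled_lane == pooled_sample

    def test_unweighted_sample_mean_differs_from_pooled_when_unbalanced(self):
        units = self.make_units()
        pooled, disp = aggregate_experiment(units, "sample")
        # unweighted mean over samples: (90 + 50) / 2 = 70
        assert disp["hq_percent"][0] == pytest.approx(70.0)
        # pooled is dominated by the 10x sample: (0.9*5000 + 0.5*50000) bases hq
        assert pooled.hq_percent == pytest.approx(
            100 * (0.9 * 10000 + 0.5 * 100000) / 110000
        )
        assert disp["hq_percent"][0] != pytest.approx(pooled.hq_percent)

    def test_single_unit_resolutions_coincide(self):
        units = {UnitKey("raw", "S1", "R1", "L1"): stats(10, 50, 15000, 400)}
        a, da = aggregate_experiment(units, "lane")
        b, db = aggregate_experiment(units, "sample")
        assert a == b
        assert da == db
        assert da["hq_percent"][1] == 0.0

    def test_balanced_design_resolution_equivalence(self):
        units = {
            UnitKey("raw", s, "R1", l): stats(100, 50, 100 * 50 * 30, 2500)
            for s in ("S1", "S2") for l in ("L1", "L2")
        }
        _, dl = aggregate_experiment(units, "lane")
        _, ds = aggregate_experiment(units, "sample")
        assert dl["hq_percent"][0] == ds["hq_percent"][0]


class TestPercentDifference:
    def test_relative(self):
        assert percent_difference(90.0, 94.5) == pytest.approx(5.0)

    def test_equal_is_zero(self):
        assert percent_difference(3.7, 3.7) == 0.0

    def test_zero_baseline_undefined(self):
        assert math.isnan(percent_difference(0.0, 5.0))

    def test_absolute_mode(self):
        assert percent_difference(90.0, 94.5, mode="absolute") == pytest.approx(4.5)

    def test_near_antisymmetry_for_small_deltas(self):
        d1 = percent_difference(100.0, 101.0)
        d2 = percent_difference(101.0, 100.0)
        assert d1 == pytest.approx(-d2, rel=0.02)


class TestMetricTable:
    def make_stats(self, dataset):
        shift = 0 if dataset == "raw" else 100
        return {
            UnitKey(dataset, s, m, l): stats(100, 50, 100 * 50 * 30 + shift, 2500)
            for s in ("S1", "S2") for m in ("R1", "R2") for l in ("L1", "L2")
        }

    def test_levels_and_conservation(self):
        table = build_metric_table(self.make_stats("raw"))
        lane = table[table["level"] == "lane"]
        sample = table[table["level"] == "sample"]
        exp = table[table["level"] == "experiment_lane"]
        assert len(lane) == 8 and len(sample) == 4 and len(exp) == 2
        # conservation per mate: lanes -> samples -> experiment
        for mate in ("R1", "R2"):
            n_l = lane[lane["mate"] == mate]["read_count"].sum()
            n_s = sample[sample["mate"] == mate]["read_count"].sum()
            n_e = exp[exp["mate"] == mate]["read_count"].sum()
            assert n_l == n_s == n_e == 400

    def test_mates_never_merged(self):
        table = build_metric_table(self.make_stats("raw"))
        assert set(table["mate"]) == {"R1", "R2"}

    def test_compare_datasets_pairs_and_diffs(self):
        both = {**self.make_stats("raw"), **self.make_stats("trimmed")}
        table = build_metric_table(both)
        comp = compare_datasets(table, "raw", "trimmed")
        lane = comp[comp["level"] == "lane"]
        assert len(lane) == 8
        expected = percent_difference(30.0, (150000 + 100) / 5000)
        assert np.allclose(lane["mean_quality_diff"], expected)

    def test_unmatched_units_excluded_with_warning(self):
        a = self.make_stats("raw")
        b = self.make_stats("trimmed")
        b.pop(UnitKey("trimmed", "S1", "R1", "L1"))
        table = build_metric_table({**a, **b})
        with pytest.warns(UserWarning, match="only one dataset"):
            comp = compare_datasets(table, "raw", "trimmed")
        lane = comp[comp["level"] == "lane"]
        assert len(lane) == 7
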