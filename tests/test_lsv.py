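"""LSV filtering, classification, binning and coordination statistics."""

import numpy as np
import pandas as pd
import pytest

from exondef import (SyntheticConfig, bin_profile, classify_and_quantify,
                     filter_lsvs, generate_binary_event_panel,
                     generate_lsv_tables, intermediate_vs_extreme_test,
                     kd_coordination, quantify_lsvs)


class TestFilters:
    def test_toy_table_keeps_exactly_the_compliant_records(self, lsv_fixture):
        kept, report = filter_lsvs(lsv_fixture, min_reads=10)
        assert sorted(kept["lsv_id"].unique()) == ["A", "B"]
        assert report.dropped["structure"] == 2       # C (2 events), D (no IR)
        assert report.dropped["junction_distance"] == 1   # E
        assert report.dropped["lowest_two_sum"] == 1      # F
        assert report.n_kept == 2

    def test_disabled_thresholds_leave_only_structure_rule(self, lsv_fixture):
        kept, _ = filter_lsvs(lsv_fixture, min_reads=0,
                              min_junction_distance=0.0,
                              min_lowest_two_sum=0.0)
        assert sorted(kept["lsv_id"].unique()) == ["A", "B", "E", "F"]

    def test_survivor_sets_nested_across_read_cutoffs(self, lsv_fixture):
        survivors = []
        for cutoff in (10, 20, 50, 80, 100):
            kept, _ = filter_lsvs(lsv_fixture, min_reads=cutoff)
            survivors.append(set(kept["lsv_id"]))
        for a, b in zip(survivors[1:], survivors[:-1]):
            assert a <= b
        assert survivors[0] == {"A", "B"} and survivors[2] == {"A"}
        assert survivors[-1] == set()

    def test_filters_commute(self):
        cfg = SyntheticConfig(n_events=60, contamination=0.3)
        table, _ = generate_lsv_tables(cfg, seed=13)
        table = table[table.condition == "normal"]
        kept, _ = filter_lsvs(table, min_reads=40)
        # independently applied single filters intersect to the same set
        only = {}
        only["dist"], _ = filter_lsvs(table, min_reads=0, min_lowest_two_sum=0)
        only["low"], _ = filter_lsvs(table, min_reads=0, min_junction_distance=0)
        only["reads"], _ = filter_lsvs(table, min_reads=40,
                                       min_junction_distance=0,
                                       min_lowest_two_sum=0)
        expected = (set(only["dist"].lsv_id) & set(only["low"].lsv_id)
                    & set(only["reads"].lsv_id))
        assert set(kept.lsv_id) == expected

    def test_distance_mode_ends(self, lsv_fixture):
        kept, _ = filter_lsvs(lsv_fixture, min_reads=10, distance_mode="ends")
        assert "A" in set(kept["lsv_id"])


class TestClassifyQuantify:
    def _lsv(self, incl, skip, ir, spans=(400, 1400)):
        return pd.DataFrame({
            "lsv_id": ["x"] * 3,
            "junction_start": [0, 0, 0],
            "junction_end": [spans[0], spans[1], 1],
            "is_ir": [False, False, True],
            "frequency": [incl, skip, ir],
        })

    def test_direct_substitution(self):
        psi, eff = classify_and_quantify(self._lsv(0.5, 0.3, 0.2))
        assert psi == pytest.approx(62.5)
        assert eff == pytest.approx(0.8)

    def test_no_retention_gives_full_efficiency(self):
        _, eff = classify_and_quantify(self._lsv(0.6, 0.4, 0.0))
        assert eff == pytest.approx(1.0)

    def test_equal_productive_frequencies_give_psi_50(self):
        psi, _ = classify_and_quantify(self._lsv(0.4, 0.4, 0.2))
        assert psi == pytest.approx(50.0)

    def test_psi_invariant_to_uniform_rescaling(self):
        a, _ = classify_and_quantify(self._lsv(0.5, 0.3, 0.2))
        b, _ = classify_and_quantify(self._lsv(0.25, 0.15, 0.6))
        assert a == pytest.approx(b)

    def test_efficiency_complements_ir(self):
        lsv = self._lsv(0.45, 0.25, 0.3)
        _, eff = classify_and_quantify(lsv)
        assert eff + 0.3 == pytest.approx(1.0)

    def test_two_ir_events_rejected(self):
        lsv = self._lsv(0.5, 0.3, 0.2)
        lsv.loc[1, "is_ir"] = True
        with pytest.raises(ValueError):
            classify_and_quantify(lsv)

    def test_tied_spans_flagged_and_excluded(self):
        lsv = self._lsv(0.5, 0.3, 0.2, spans=(400, 400))
        with pytest.raises(ValueError):
            classify_and_quantify(lsv)
        assert len(quantify_lsvs(lsv)) == 0


class TestBinProfile:
    def test_constant_efficiency(self):
        events = pd.DataFrame({"psi": np.linspace(1, 99, 50),
                               "efficiency": np.full(50, 0.9)})
        prof = bin_profile(events)
        assert np.allclose(prof.median_efficiency, 0.9)
        assert prof.counts.sum() == 50

    def test_single_event_populates_one_bin(self):
        prof = bin_profile(pd.DataFrame({"psi": [55.0], "efficiency": [0.8]}))
        assert np.nansum(prof.counts) == 1
        assert np.isnan(prof.median_efficiency).sum() == 9

    def test_generated_events_show_interior_minimum(self):
        cfg = SyntheticConfig(n_events=1500)
        table, _ = generate_lsv_tables(cfg, seed=2)
        events = quantify_lsvs(table[table.condition == "normal"])
        prof = bin_profile(events)
        med = prof.median_efficiency
        assert np.nanmin(med[3:7]) < min(med[0], med[9]) - 0.05

    def test_last_bin_closed_at_100(self):
        events = pd.DataFrame({"psi": [100.0], "efficiency": [0.9]})
        prof = bin_profile(events)
        assert prof.counts[-1] == 1


class TestIntermediateVsExtreme:
    @staticmethod
    def _events(rng, n=2000, drop=0.0, sd=0.05):
        psi = rng.uniform(0, 100, n)
        eff = np.where((psi >= 40) & (psi <= 60), 0.9 - drop, 0.9)
        return pd.DataFrame({"psi": psi, "efficiency": eff + rng.normal(0, sd, n)})

    def test_true_drop_detected_and_within_ci(self):
        events = self._events(np.random.default_rng(0), drop=0.10)
        stats = intermediate_vs_extreme_test(events, n_boot=500, seed=1)
        assert stats.significant
        assert stats.ci_low <= -0.10 <= stats.ci_high

    def test_identical_groups_give_zero_difference(self):
        events = pd.DataFrame({"psi": [5.0, 50.0, 95.0] * 20,
                               "efficiency": [0.8] * 60})
        stats = intermediate_vs_extreme_test(events, n_boot=100, seed=0)
        assert stats.difference == 0.0
        assert not stats.significant

    def test_null_calibrated(self):
        sig = 0
        for s in range(10):
            events = self._events(np.random.default_rng(200 + s), drop=0.0)
            sig += intermediate_vs_extreme_test(events, n_boot=200,
                                                seed=s).significant
        assert sig <= 1

    def test_ci_narrows_with_bootstrap_size(self):
        events = self._events(np.random.default_rng(5), drop=0.05)
        # CI endpoints stabilize; spread of replicate medians shrinks ~1/sqrt(B)
        narrow = intermediate_vs_extreme_test(events, n_boot=800, seed=3)
        wide = intermediate_vs_extreme_test(events, n_boot=50, seed=3)
        assert narrow.n_boot > wide.n_boot
        assert abs((narrow.ci_high - narrow.ci_low)
                   - (wide.ci_high - wide.ci_low)) < 0.02

    def test_empty_group_reported(self):
        events = pd.DataFrame({"psi": [50.0] * 5, "efficiency": [0.5] * 5})
        with pytest.raises(ValueError):
            intermediate_vs_extreme_test(events, n_boot=10, seed=0)


class TestKdCoordination:
    def test_no_efficiency_change_gives_zero_fractions(self):
        rows = []
        for cond in ("control", "kd001", "kd002"):
            for e in range(20):
                rows.append((f"ev{e}", cond, 50.0 + (0 if cond == "control" else 10.0), 20.0))
        table = pd.DataFrame(rows, columns=["event_id", "condition", "psi", "pir"])
        out = kd_coordination(table, subset_min_conditions=1)
        frac = out["profile"]["fraction_dse_exceeding"].dropna()
        assert (frac == 0.0).all()

    def test_single_condition_means_zero_dpsi(self):
        cfg = SyntheticConfig()
        table, _ = generate_binary_event_panel(cfg, 30, 1, seed=0)
        with pytest.raises(ValueError):
            kd_coordination(table.assign(condition="kd001"))

    def test_coordinated_events_peak_at_intermediate_dpsi(self):
        cfg = SyntheticConfig()
        table, _ = generate_binary_event_panel(cfg, 400, 40, seed=5)
        out = kd_coordination(table, subset_min_conditions=20)
        prof = out["profile"]
        centers = (prof.dpsi_low + prof.dpsi_high).to_numpy() / 2
        frac = prof["fraction_dse_exceeding"].to_numpy()
        mid = np.nanmean(frac[(np.abs(centers) >= 20) & (np.abs(centers) <= 60)])
        small = np.nanmean(frac[np.abs(centers) < 10])
        assert mid > small + 0.2

    def test_subset_rules_on_constructed_fixture(self):
        rows = []
        for e, (sd_big, ir_rich) in enumerate([(True, True), (True, False),
                                               (False, True)]):
            for c in range(6):
                cond = "control" if c == 0 else f"kd{c:03d}"
                psi = 50.0 + (20.0 * (c % 2) if sd_big else 0.5 * c)
                pir = 10.0 if ir_rich or c < 2 else 0.0
                rows.append((f"ev{e}", cond, psi, pir))
        table = pd.DataFrame(rows, columns=["event_id", "condition", "psi", "pir"])
        out = kd_coordination(table, subset_sd_threshold=5.0,
                              subset_min_conditions=4)
        assert out["subset_event_ids"] == ["ev0"]

    def test_missing_control_condition(self):
        table = pd.DataFrame({"event_id": ["a"], "condition": ["kd001"],
                              "psi": [50.0], "pir": [10.0]})
        with pytest.raises(ValueError):
            kd_coordination(table)
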