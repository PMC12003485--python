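"""Acquisition thresholds, phenotype gating, and enumeration."""

import numpy as np
import pandas as pd
import pytest

from meromix import cytometry as cy
from meromix import synthgen
from meromix.errors import DomainError, MissingChannelError, SchemaError


def make_table(rows, volume=0.05, label=None):
    return cy.EventTable(pd.DataFrame(rows), volume, label)


class TestAcquisitionThresholds:
    @pytest.mark.parametrize("fsch, fl3, kept", [
        (1500.0, 5000.0, False),   # below the FSC-H threshold
        (50000.0, 1000.0, False),  # fails FL3-A > 1100
        (2001.0, 1101.0, True),    # strictly above both
        (2000.0, 2000.0, False),   # boundary is excluded (strict >)
    ])
    def test_strict_threshold_rules(self, fsch, fl3, kept):
        t = make_table([{"FSC-H": fsch, "FSC-A": fsch, "FL3-A": fl3}])
        out = cy.apply_acquisition_thresholds(t)
        assert len(out) == (1 if kept else 0)

    def test_idempotent(self):
        t = synthgen.gen_fcm_events(n=2000, debris_fraction=0.3, seed=5)
        once = cy.apply_acquisition_thresholds(t)
        twice = cy.apply_acquisition_thresholds(once)
        assert len(twice) == len(once)

    def test_volume_unchanged(self):
        t = synthgen.gen_fcm_events(n=500, seed=1)
        out = cy.apply_acquisition_thresholds(t)
        assert out.acquired_volume_ml == t.acquired_volume_ml

    def test_missing_channel_rejected(self):
        t = make_table([{"FSC-A": 1000.0}])
        with pytest.raises(MissingChannelError):
            cy.apply_acquisition_thresholds(t)

    def test_debris_retention_matches_binomial_expectation(self):
        # debris is generated below both thresholds, so retention is the
        # non-debris fraction up to multinomial noise (3 sigma ~ 150/10000)
        frac = 0.5 / 3
        t = synthgen.gen_fcm_events(
            {"gsb": frac, "small_psb": frac, "large_psb": frac},
            n=10_000, debris_fraction=0.5, seed=11)
        out = cy.apply_acquisition_thresholds(t)
        assert len(out) == pytest.approx(5000, abs=150)


class TestClassifyPhenotypes:
    def test_three_cluster_recovery(self):
        t = synthgen.gen_fcm_events(n=3000, debris_fraction=0.0, seed=3)
        labeled = cy.classify_phenotypes(cy.apply_acquisition_thresholds(t))
        counts = labeled.events["label"].value_counts()
        truth = labeled.events["true_label"].value_counts()
        for ph in cy.PHENOTYPES:
            assert abs(int(counts[ph]) - int(truth[ph])) <= 1

    def test_left_closed_cut_convention(self):
        t = make_table([{"FSC-H": 3000.0, "FSC-A": 10.0 ** 4.5,
                         "FL3-A": 2000.0}])
        out = cy.classify_phenotypes(t)
        assert out.events["label"].iloc[0] == "small_psb"

    def test_empty_table_stays_empty(self):
        t = make_table([])
        t.events = pd.DataFrame(columns=["FSC-H", "FSC-A", "FL3-A"])
        out = cy.classify_phenotypes(t)
        assert len(out) == 0
        assert "label" in out.events.columns

    def test_zero_area_events_tallied_not_counted(self):
        t = make_table([
            {"FSC-H": 3000.0, "FSC-A": 0.0, "FL3-A": 2000.0},
            {"FSC-H": 3000.0, "FSC-A": 1e5, "FL3-A": 2000.0},
        ])
        out = cy.classify_phenotypes(t)
        assert len(out) == 1
        assert out.n_unclassifiable == 1

    def test_partition_every_event_gets_one_label(self):
        t = synthgen.gen_fcm_events(n=5000, debris_fraction=0.2, seed=9)
        labeled = cy.classify_phenotypes(cy.apply_acquisition_thresholds(t))
        assert labeled.events["label"].isin(cy.PHENOTYPES).all()

    def test_order_independence(self):
        t = synthgen.gen_fcm_events(n=1000, seed=2)
        t = cy.apply_acquisition_thresholds(t)
        rev = cy.EventTable(t.events.iloc[::-1].reset_index(drop=True),
                            t.acquired_volume_ml, t.sample_label)
        a = cy.classify_phenotypes(t).events["label"].value_counts()
        b = cy.classify_phenotypes(rev).events["label"].value_counts()
        assert a.to_dict() == b.to_dict()

    def test_fraction_recovery_within_two_percent(self):
        fractions = {"gsb": 0.2, "small_psb": 0.5, "large_psb": 0.3}
        t = synthgen.gen_fcm_events(fractions, n=10_000,
                                    debris_fraction=0.0, seed=21)
        labeled = cy.classify_phenotypes(cy.apply_acquisition_thresholds(t))
        counts = labeled.events["label"].value_counts()
        total = counts.sum()
        for ph, want in fractions.items():
            assert counts[ph] / total == pytest.approx(want, abs=0.02)


class TestConcentrationAndSummary:
    def label_table(self, n_by_phenotype, volume, label):
        rows = []
        for ph, n in n_by_phenotype.items():
            rows += [{"FSC-H": 3000.0, "FSC-A": 1e5, "FL3-A": 2000.0,
                      "label": ph}] * n
        t = make_table(rows, volume=volume, label=label)
        return t

    def test_concentration_is_count_over_volume(self):
        t = self.label_table({"gsb": 5000}, 0.05, "bl_top")
        res = cy.concentration_and_summary([t])
        assert res.concentration("bl_top", "gsb") == pytest.approx(100_000)

    def test_bl_summary_mean_and_sample_sd(self):
        tables = [self.label_table({"large_psb": n}, 1.0, pos)
                  for n, pos in zip((100_000, 200_000, 300_000),
                                    cy.BL_POSITIONS)]
        res = cy.concentration_and_summary(tables)
        row = res.bl_summary.set_index("phenotype").loc["large_psb"]
        assert row.mean_cells_per_ml == pytest.approx(2.0e5)
        assert row.sd_cells_per_ml == pytest.approx(1.0e5)

    def test_identical_positions_give_zero_sd(self):
        tables = [self.label_table({"gsb": 1000}, 1.0, pos)
                  for pos in cy.BL_POSITIONS]
        res = cy.concentration_and_summary(tables)
        row = res.bl_summary.set_index("phenotype").loc["gsb"]
        assert row.sd_cells_per_ml == 0.0

    def test_above_below_reported_but_excluded_from_summary(self):
        tables = [self.label_table({"gsb": 1000}, 1.0, pos)
                  for pos in cy.BL_POSITIONS]
        tables.append(self.label_table({"gsb": 9_000_000}, 1.0, "above_1m"))
        res = cy.concentration_and_summary(tables)
        row = res.bl_summary.set_index("phenotype").loc["gsb"]
        assert row.mean_cells_per_ml == pytest.approx(1000.0)
        assert res.concentration("above_1m", "gsb") == pytest.approx(9e6)

    def test_single_position_sd_absent(self):
        res = cy.concentration_and_summary(
            [self.label_table({"gsb": 10}, 1.0, "bl_top")])
        row = res.bl_summary.set_index("phenotype").loc["gsb"]
        assert np.isnan(row.sd_cells_per_ml)
        assert row.mean_cells_per_ml == pytest.approx(10.0)

    def test_unlabeled_table_rejected(self):
        t = make_table([{"FSC-H": 3000.0, "FSC-A": 1e5, "FL3-A": 2000.0}],
                       label="bl_top")
        with pytest.raises(SchemaError):
            cy.concentration_and_summary([t])

    def test_concentration_scaling(self):
        a = cy.concentration_and_summary(
            [self.label_table({"gsb": 1000}, 0.1, "bl_top")])
        b = cy.concentration_and_summary(
            [self.label_table({"gsb": 2000}, 0.1, "bl_top")])
        c = cy.concentration_and_summary(
            [self.label_table({"gsb": 1000}, 0.2, "bl_top")])
        assert b.concentration("bl_top", "gsb") == pytest.approx(
            2 * a.concentration("bl_top", "gsb"))
        assert c.concentration("bl_top", "gsb") == pytest.approx(
            a.concentration("bl_top", "gsb") / 2)


class TestIO:
    def test_delimited_round_trip_with_aliases(self, tmp_path):
        t = synthgen.gen_fcm_events(n=200, seed=4)
        path = tmp_path / "events.csv"
        t.events.rename(columns={"FSC-H": "FSC.H"}).to_csv(path, index=False)
        back = cy.read_event_table(path, 0.05, "bl_top",
                                   channel_aliases={"FSC.H": "FSC-H"})
        assert len(back) == 200
        assert "FSC-H" in back.events.columns

    def test_invalid_gating_config(self):
        with pytest.raises(DomainError):
            cy.GatingConfig(size_cuts=(5.5, 4.5))

    def test_negative_volume_rejected(self):
        with pytest.raises(DomainError):
            make_table([], volume=0.0)
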