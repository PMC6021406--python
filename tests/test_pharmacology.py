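"""Drug-epoch comparison, inhibition tabulation and the chi-square test."""
import math

import numpy as np
import pytest

import spikepatterns as sp
from spikepatterns import (
    assess_drug_effect,
    chi_square_2x2,
    tabulate_inhibition,
)
from spikepatterns.pharmacology import DrugEffect, drug_effect_frame

from conftest import make_train


def uniform_train(pre_count, post_count, unit_id="u0"):
    """600 s control epoch then 600 s drug epoch with the given spike counts
    spread evenly over the last 300 s of each."""
    pre = 300.0 + 300.0 * (np.arange(pre_count) + 0.5) / pre_count
    post = 900.0 + 300.0 * (np.arange(post_count) + 0.5) / post_count
    return make_train(np.concatenate([pre, post]), t_stop=1200.0, unit_id=unit_id)


EPOCHS = (sp.Epoch("control", 0, 600), sp.Epoch("drug", 600, 1200))


class TestAssessDrugEffect:
    @pytest.mark.parametrize(
        "post_count, inhibited",
        [(45, True), (60, True), (63, False)],   # ratios 0.15, 0.20, 0.21
    )
    def test_inhibition_boundary(self, cfg, post_count, inhibited):
        train = uniform_train(300, post_count)
        effect = assess_drug_effect(train, *EPOCHS, cfg)
        assert effect.pre_frequency == pytest.approx(1.0)
        assert effect.inhibited is inhibited

    @pytest.mark.parametrize("factor", [0.25, 1.0, 7.0])
    def test_verdict_invariant_under_time_rescaling(self, cfg, factor):
        train = uniform_train(300, 60)
        scaled = train.rescale(factor)
        epochs = [
            sp.Epoch(e.name, e.start * factor, e.end * factor) for e in EPOCHS
        ]
        cfg_scaled = cfg.with_(analysis_window=cfg.analysis_window * factor)
        effect = assess_drug_effect(scaled, *epochs, cfg_scaled)
        assert effect.inhibited is True
        assert effect.ratio == pytest.approx(0.2)

    def test_silent_control_not_assessable(self, cfg):
        train = uniform_train(0, 100)
        effect = assess_drug_effect(train, *EPOCHS, cfg)
        assert not effect.assessable
        assert effect.inhibited is None
        assert math.isnan(effect.ratio)

    def test_regularisation_detected(self, cfg):
        train = sp.generate_renewal_train(2.0, 1.2, 1200.0, seed=8, unit_id="u1")
        modulated = sp.apply_drug_modulation(
            train, sp.DrugModulation("regularise", onset=600.0, seed=9)
        )
        effect = assess_drug_effect(modulated, *EPOCHS, cfg)
        assert effect.pre_label == "IS"
        assert effect.post_label == "RS"
        assert effect.regularised

    def test_synthetic_inhibition(self, cfg):
        train = sp.generate_renewal_train(1.0, 1.0, 1200.0, seed=10)
        modulated = sp.apply_drug_modulation(
            train, sp.DrugModulation("inhibit", onset=600.0, seed=11)
        )
        effect = assess_drug_effect(modulated, *EPOCHS, cfg)
        assert effect.inhibited is True

    def test_epoch_validation(self, cfg):
        train = uniform_train(300, 60)
        with pytest.raises(ValueError, match="shorter"):
            assess_drug_effect(
                train, sp.Epoch("control", 0, 100), sp.Epoch("drug", 600, 1200),
                cfg,
            )
        with pytest.raises(ValueError, match="before"):
            assess_drug_effect(
                train, sp.Epoch("control", 300, 900), sp.Epoch("drug", 0, 600),
                cfg,
            )


def synthetic_effects(irregular, irregular_inhibited, regular, regular_inhibited):
    """DrugEffect fixtures with the requested inhibition counts."""
    effects = []
    for i in range(irregular):
        effects.append(DrugEffect(
            unit_id=f"i{i}", pre_frequency=1.0, post_frequency=0.1,
            ratio=0.1 if i < irregular_inhibited else 0.9,
            inhibited=i < irregular_inhibited,
            pre_label="IS", post_label="IS", regularised=False,
        ))
    for i in range(regular):
        effects.append(DrugEffect(
            unit_id=f"r{i}", pre_frequency=5.0, post_frequency=4.0,
            ratio=0.1 if i < regular_inhibited else 0.8,
            inhibited=i < regular_inhibited,
            pre_label="RS", post_label="RS", regularised=False,
        ))
    return effects


class TestTabulateInhibition:
    def test_published_synaptic_block_counts(self):
        # 98/108 irregular and 8/45 regular units inhibited
        tab = tabulate_inhibition(synthetic_effects(108, 98, 45, 8))
        assert (tab.table.a, tab.table.b, tab.table.c, tab.table.d) == \
            (98, 10, 8, 37)
        by_group = dict(zip(tab.by_group.group, tab.by_group.percent))
        assert by_group == {"irregular": "90.7%", "regular": "17.7%"}

    def test_all_inhibited(self):
        tab = tabulate_inhibition(synthetic_effects(4, 4, 3, 3))
        assert tab.table.b == 0 and tab.table.d == 0

    def test_row_sums_match_group_sizes(self):
        tab = tabulate_inhibition(synthetic_effects(17, 5, 9, 2))
        assert tab.by_group.total.tolist() == [17, 9]
        assert tab.table.a + tab.table.b == 17
        assert tab.table.c + tab.table.d == 9

    def test_non_assessable_excluded(self):
        effects = synthetic_effects(5, 3, 5, 1)
        effects.append(DrugEffect(
            unit_id="silent", pre_frequency=0.0, post_frequency=0.0,
            ratio=math.nan, inhibited=None, pre_label="IS",
            post_label="INSUFFICIENT", regularised=False, assessable=False,
        ))
        tab = tabulate_inhibition(effects)
        assert tab.table.total == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tabulate_inhibition([])

    def test_report_frame_columns(self):
        frame = drug_effect_frame(synthetic_effects(2, 1, 2, 1))
        assert list(frame.columns) == [
            "unit_id", "pre_hz", "post_hz", "ratio", "inhibited",
            "pre_label", "post_label", "regularised",
        ]


class TestChiSquare:
    def test_published_table_highly_significant(self):
        res = chi_square_2x2(sp.ContingencyTable2x2(98, 10, 8, 37))
        assert res.p_value < 0.0001

    def test_independence(self):
        res = chi_square_2x2(sp.ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # sum((O-E)^2/E) computed by hand: 20*(5*9-5*1)^2/(10*10*6*14)
        res = chi_square_2x2(sp.ContingencyTable2x2(5, 5, 1, 9))
        assert res.statistic == pytest.approx(20 * 40**2 / 8400, rel=1e-9)
        assert res.statistic == pytest.approx(3.810, abs=5e-4)

    def test_matches_textbook_formula_on_random_tables(self, rng):
        checked = 0
        while checked < 100:
            a, b, c, d = rng.integers(0, 60, size=4)
            table = np.array([[a, b], [c, d]], dtype=float)
            if np.any(table.sum(0) == 0) or np.any(table.sum(1) == 0):
                continue
            n = table.sum()
            expected = (
                n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            res = chi_square_2x2(sp.ContingencyTable2x2(a, b, c, d))
            assert res.statistic == pytest.approx(expected, abs=1e-9)
            checked += 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(sp.ContingencyTable2x2(0, 0, 5, 5))
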