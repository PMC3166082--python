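"""Activity calls, bimodality, virtual screening, enrichment, associations."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from fiasma.errors import ValidationError
from fiasma.screening import (
    bimodality_analysis,
    classify_activity,
    group_enrichment,
    logbb_association,
    rof_association,
    virtual_screen,
)
from fiasma.synthetic import GeneratorConfig, generate_experimental_set


class TestClassifyActivity:
    @pytest.mark.parametrize(
        "residual, label, flagged",
        [
            (44.1, 1, True),  # inhibiting, but within replicate error of 50
            (50.0, 1, False),  # threshold inclusive; |50-50| >= sd is False->flag?
            (50.1, 0, True),
            (20.0, 1, False),
            (95.0, 0, False),
        ],
    )
    def test_threshold_and_reliability(self, residual, label, flagged):
        call = classify_activity(residual)
        assert call.label == label
        if residual in (44.1, 50.1):
            assert call.low_reliability is True
        if residual in (20.0, 95.0):
            assert call.low_reliability is False

    def test_idempotent_and_boundary_exact(self):
        assert classify_activity(50.0).label == 1
        assert classify_activity(np.nextafter(50.0, 100)).label == 0

    def test_negative_residual_rejected(self):
        with pytest.raises(ValidationError):
            classify_activity(-0.1)


class TestBimodality:
    def test_single_normal_usually_not_rejected(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(70, 15, 300)
            rep = bimodality_analysis(x)
            if rep.pooled_ks_p > 0.05:
                ok += 1
        assert ok >= 8

    def test_two_mode_mixture_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            lo = np.clip(rng.normal(35, 8, 78), 0, 120)
            hi = np.clip(rng.normal(85, 12, 222), 0, 120)
            rep = bimodality_analysis(np.concatenate([lo, hi]))
            if (
                rep.pooled_ks_p < 0.001
                and abs(rep.component_means[0] - 35) < 3
                and abs(rep.component_means[1] - 85) < 3
            ):
                hits += 1
        assert hits >= 8

    def test_degenerate_identical_values(self):
        with pytest.raises(ValidationError):
            bimodality_analysis(np.full(50, 42.0))

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            bimodality_analysis(np.arange(10.0))


def brute_force_enrichment_p(in_active, in_total, total_active, total) -> float:
    """Exact one-sided over-representation p by hypergeometric enumeration."""
    p = 0.0
    for k in range(in_active, min(in_total, total_active) + 1):
        p += (
            math.comb(total_active, k)
            * math.comb(total - total_active, in_total - k)
            / math.comb(total, in_total)
        )
    return p


class TestEnrichment:
    def test_matches_brute_force_enumeration_small_margins(self):
        rows_checked = 0
        for total in (8, 15, 23, 30):
            for total_active in range(1, total):
                for in_total in range(1, total):
                    for in_active in range(0, min(in_total, total_active) + 1):
                        expected = brute_force_enrichment_p(
                            in_active, in_total, total_active, total
                        )
                        got = float(
                            stats.hypergeom.sf(in_active - 1, total, total_active, in_total)
                        )
                        assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)
                        rows_checked += 1
        assert rows_checked > 1000

    def test_fully_concentrated_group_is_flagged(self):
        calls = {f"c{i}": 1 if i < 10 else 0 for i in range(100)}
        groups = {f"c{i}": ["hot"] if i < 10 else ["cold"] for i in range(100)}
        rows, _ = group_enrichment(calls, groups)
        hot = next(r for r in rows if r.group == "hot")
        assert hot.fisher_p == pytest.approx(1.0 / math.comb(100, 10), rel=1e-9)
        assert hot.enriched

    def test_uniform_actives_not_flagged(self):
        flagged = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            calls = {f"c{i}": int(rng.random() < 0.1) for i in range(400)}
            groups = {f"c{i}": [f"g{rng.integers(0, 10)}"] for i in range(400)}
            rows, _ = group_enrichment(calls, groups)
            flagged += any(r.enriched for r in rows)
        assert flagged <= 2

    def test_group_holding_every_compound_has_p_one(self):
        calls = {f"c{i}": int(i < 5) for i in range(20)}
        groups = {f"c{i}": ["all"] + (["sub"] if i < 3 else []) for i in range(20)}
        rows, _ = group_enrichment(calls, groups)
        assert next(r for r in rows if r.group == "all").fisher_p == pytest.approx(1.0)

    def test_bh_adjustment_monotone_in_raw_p(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            calls = {f"c{i}": int(rng.random() < 0.2) for i in range(200)}
            groups = {f"c{i}": [f"g{rng.integers(0, 8)}"] for i in range(200)}
            rows, _ = group_enrichment(calls, groups)
            by_raw = sorted(rows, key=lambda r: r.fisher_p)
            adj = [r.adjusted_p for r in by_raw]
            assert all(b >= a - 1e-12 for a, b in zip(adj, adj[1:]))
            assert all(r.adjusted_p >= r.fisher_p - 1e-12 for r in rows)


class TestRofAssociation:
    def test_study_table_percentages_and_p(self):
        # 2x2 with 72 actives (35 without / 37 with violation) and 204
        # inactives (145 / 59)
        labels = [1] * 72 + [0] * 204
        violated = [False] * 35 + [True] * 37 + [False] * 145 + [True] * 59
        res = rof_association(labels, violated)
        assert res.violation_pct_active == pytest.approx(51.4, abs=0.05)
        assert res.violation_pct_inactive == pytest.approx(28.9, abs=0.05)
        assert res.p <= 0.005

    def test_identical_rates_give_zero_statistic(self):
        labels = [1] * 40 + [0] * 40
        violated = ([True] * 10 + [False] * 30) * 2
        res = rof_association(labels, violated)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            rof_association([1] * 10 + [0] * 10, [False] * 20)


class TestLogBB:
    def test_default_panel_has_no_violations(self, default_experiment, labeled):
        _, labels = labeled
        logbb = {
            r.id: r.logbb for r in default_experiment.table if r.logbb is not None
        }
        res = logbb_association({cid: int(v) for cid, v in labels.items()}, logbb)
        assert res.n > 0
        assert res.violations == []

    def test_injected_violation_listed(self):
        res = logbb_association({"a": 1, "b": 0}, {"a": -0.5, "b": 1.0})
        assert res.violations == ["a"]

    def test_no_data_warns_and_returns_empty(self):
        res = logbb_association({"a": 1}, {})
        assert res.n == 0 and res.violations == []


class TestVirtualScreen:
    def test_planted_filter_counts_reconcile(self, natural_library, trained_model):
        res = virtual_screen(
            natural_library.table, trained_model, natural_library.structures, "nat"
        )
        assert res.n_input == 800
        assert res.n_excluded_incalculable == 13
        assert res.n_excluded_quaternary == 2
        assert res.n_excluded_duplicates == 17
        assert res.n_screened == 768
        assert (
            res.n_screened
            + res.n_excluded_incalculable
            + res.n_excluded_quaternary
            + res.n_excluded_duplicates
            == res.n_input
        )

    def test_quaternary_and_duplicate_reasons_recorded(self, natural_library, trained_model):
        res = virtual_screen(
            natural_library.table, trained_model, natural_library.structures, "nat"
        )
        reasons = res.predictions["excluded_reason"]
        assert (reasons == "quaternary_nitrogen").sum() == 2
        assert (reasons == "duplicate").sum() == 17
        # each planted (source, copy) pair loses exactly its later member
        flagged = set(reasons[reasons == "duplicate"].index)
        pairs = [
            (rec.name.removeprefix("duplicate-of-"), rec.id)
            for rec in natural_library.table
            if rec.name.startswith("duplicate-of-")
        ]
        assert len(pairs) == 17
        for source, copy in pairs:
            assert (source in flagged) ^ (copy in flagged)

    def test_enrichment_recovers_planted_groups(self, drug_library, trained_model):
        res = virtual_screen(drug_library.table, trained_model, drug_library.structures)
        calls = {cid: int(v) for cid, v in res.predictions["predicted"].dropna().items()}
        rows, global_p = group_enrichment(calls, drug_library.groups)
        assert global_p < 0.001
        assert {r.group for r in rows if r.enriched} == set(
            drug_library.truth["enriched_groups"]
        )


class TestAtcGrouping:
    def test_levels(self):
        from fiasma.io import CompoundRecord, CompoundTable
        from fiasma.screening import groups_from_atc

        table = CompoundTable(
            [
                CompoundRecord(id="a", mw=100.0, atc_codes=["N05AB02", "A03AA07"]),
                CompoundRecord(id="b", mw=100.0, atc_codes=["N05AF01"]),
                CompoundRecord(id="c", mw=100.0),
            ]
        )
        level2 = groups_from_atc(table, level=2)
        assert level2 == {"a": ["A03", "N05"], "b": ["N05"]}
        level1 = groups_from_atc(table, level=1)
        assert level1["a"] == ["A", "N"]

    def test_invalid_level_rejected(self):
        from fiasma.io import CompoundTable
        from fiasma.screening import groups_from_atc

        with pytest.raises(ValidationError):
            groups_from_atc(CompoundTable([]), level=7)


class TestRofCorrectionFlag:
    def test_yates_correction_is_more_conservative(self):
        labels = [1] * 72 + [0] * 204
        violated = [False] * 35 + [True] * 37 + [False] * 145 + [True] * 59
        plain = rof_association(labels, violated)
        yates = rof_association(labels, violated, correction=True)
        assert yates.p >= plain.p
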