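"""Two-stage selection: filters, dedup, zones, quotas, stage B."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from panelforge.core import CandidateVariant
from panelforge.selection import (
    ChromosomePartition,
    SelectionConfig,
    allocate_quota,
    assign_zone,
    dedupe_per_gene,
    design_funnel,
    filter_candidates,
    select_stage_a,
    select_stage_b,
    suggest_partition,
)

from oracles import largest_remainder_quota


def _cv(i, pos=None, missing=0.0, score=0.9, gene=None, chrom="1H"):
    return CandidateVariant(
        id=f"c{i}", chrom=chrom, pos=pos or (100 + i), ref="A", alt="G",
        missing_rate=missing, design_score=score, gene_id=gene,
    )


H1 = ChromosomePartition.from_breakpoints(
    "1H",
    [0, 30_000_000, 60_000_000, 380_000_000, 470_000_000, 560_000_000],
    [40, 7, 3, 18, 66],
)


class TestFilter:
    def test_inclusive_boundaries_retained(self):
        cv = _cv(1, missing=0.20, score=0.60)
        assert filter_candidates([cv], 0.20, 0.6, inclusive=True) == [cv]

    def test_strict_boundaries_dropped(self):
        cv = _cv(1, missing=0.05, score=0.80)
        assert filter_candidates([cv], 0.05, 0.8, inclusive=False) == []

    def test_over_threshold_dropped(self):
        assert filter_candidates([_cv(1, missing=0.21, score=0.99)], 0.20, 0.6) == []

    def test_scoreless_always_dropped(self):
        cv = _cv(1, missing=0.0, score=None)
        cv.design_score = None
        assert filter_candidates([cv], 0.20, 0.6) == []


class TestDedupe:
    def test_cap_one_keeps_best_score(self):
        group = [_cv(1, score=0.9, gene="G"), _cv(2, score=0.8, gene="G"),
                 _cv(3, score=0.7, gene="G")]
        kept = dedupe_per_gene(group, 1)
        assert [c.id for c in kept] == ["c1"]

    def test_cap_two_keeps_top_two(self):
        group = [_cv(1, score=0.7, gene="G"), _cv(2, score=0.9, gene="G"),
                 _cv(3, score=0.8, gene="G")]
        kept = dedupe_per_gene(group, 2)
        assert {c.id for c in kept} == {"c2", "c3"}

    def test_ties_break_by_missing_then_position(self):
        a = _cv(1, pos=500, missing=0.10, score=0.8, gene="G")
        b = _cv(2, pos=400, missing=0.05, score=0.8, gene="G")
        assert dedupe_per_gene([a, b], 1) == [b]
        c = _cv(3, pos=300, missing=0.05, score=0.8, gene="G")
        assert dedupe_per_gene([a, b, c], 1) == [c]

    def test_geneless_always_survive(self):
        kept = dedupe_per_gene([_cv(1), _cv(2)], 1)
        assert len(kept) == 2

    def test_cap_below_one_is_error(self):
        with pytest.raises(ValueError):
            dedupe_per_gene([_cv(1)], 0)


class TestZones:
    def test_published_1h_breakpoints(self):
        assert assign_zone(H1, 15_000_000) == "short_high"
        assert assign_zone(H1, 200_000_000) == "pericentromeric"
        assert assign_zone(H1, 400_000_000) == "long_low"
        assert assign_zone(H1, 500_000_000) == "long_high"

    def test_breakpoint_belongs_to_right_zone_half_open(self):
        assert assign_zone(H1, 30_000_000) == "short_low"

    def test_chromosome_end_is_closed(self):
        assert assign_zone(H1, 560_000_000) == "long_high"

    def test_outside_chromosome_is_error(self):
        with pytest.raises(ValueError):
            assign_zone(H1, 560_000_001)

    def test_partition_must_be_contiguous(self):
        from panelforge.selection import Zone, ZONE_LABELS

        zones = [
            Zone(label, start, end, 1.0)
            for label, (start, end) in zip(
                ZONE_LABELS, [(0, 10), (12, 20), (20, 30), (30, 40), (40, 50)]
            )
        ]
        with pytest.raises(ValueError, match="contiguous"):
            ChromosomePartition(chrom="x", zones=zones)


class TestQuota:
    def test_budget_equal_to_span_sum_returns_spans(self):
        assert allocate_quota(H1, 131) == {
            "short_high": 40, "short_low": 7, "pericentromeric": 0,
            "long_low": 18, "long_high": 66,
        }

    def test_largest_remainder_for_budget_100(self):
        assert allocate_quota(H1, 100) == {
            "short_high": 31, "short_low": 5, "pericentromeric": 0,
            "long_low": 14, "long_high": 50,
        }

    def test_zero_budget(self):
        assert sum(allocate_quota(H1, 0).values()) == 0

    def test_all_zero_spans_is_error(self):
        flat = ChromosomePartition.from_breakpoints(
            "x", [0, 10, 20, 30, 40, 50], [0, 0, 5, 0, 0]
        )
        with pytest.raises(ValueError, match="zero"):
            allocate_quota(flat, 3)

    @given(st.integers(min_value=0, max_value=100_000))
    def test_quota_matches_exact_apportionment(self, budget):
        quotas = allocate_quota(H1, budget)
        spans = [40, 7, 18, 66]
        expected = largest_remainder_quota(spans, budget)
        got = [quotas[z] for z in ("short_high", "short_low", "long_low", "long_high")]
        assert got == expected
        assert sum(quotas.values()) == budget
        assert quotas["pericentromeric"] == 0
        total = sum(spans)
        for g, s in zip(got, spans):
            assert abs(g - budget * Fraction(s, total)) < 1


def _partition(chrom="1H", length=1000, spans=(40, 7, 3, 18, 66)):
    return ChromosomePartition.from_breakpoints(
        chrom, [0, 200, 400, 600, 800, length], spans
    )


class TestStageB:
    def test_supply_shortfall_is_reported_not_filled(self):
        part = _partition(spans=(10, 0, 0, 0, 0))
        cands = [_cv(i, pos=50 + i, score=0.9, missing=0.0) for i in range(3)]
        cfg = SelectionConfig(stage_b_budget=5)
        res = select_stage_b(cands, {"1H": part}, cfg)
        assert len(res.selected) == 3
        assert res.shortfall["1H"] == 2

    def test_5h_short_arm_override_relaxes_thresholds(self):
        part = _partition(chrom="5H")
        cv = _cv(1, pos=50, score=0.7, missing=0.10, chrom="5H")
        cfg = SelectionConfig(stage_b_budget=1)
        res = select_stage_b([cv], {"5H": part}, cfg)
        assert res.selected == [cv]
        cfg_no_override = SelectionConfig(stage_b_budget=1, overrides=[])
        res2 = select_stage_b([cv], {"5H": part}, cfg_no_override)
        assert res2.selected == []

    def test_override_applies_only_to_named_zone(self):
        part = _partition(chrom="5H")
        cv = _cv(1, pos=850, score=0.7, missing=0.10, chrom="5H")  # long_high
        cfg = SelectionConfig(stage_b_budget=1)
        assert select_stage_b([cv], {"5H": part}, cfg).selected == []

    def test_missing_partition_is_error(self):
        with pytest.raises(ValueError, match="partition"):
            select_stage_b([_cv(1)], {}, SelectionConfig(stage_b_budget=1))

    def test_pericentromeric_candidates_never_selected(self):
        part = _partition()
        cv = _cv(1, pos=500, score=0.95, missing=0.0)  # pericentromeric zone
        res = select_stage_b([cv], {"1H": part}, SelectionConfig(stage_b_budget=2))
        assert res.selected == []

    def test_cross_stage_gene_cap(self):
        part = _partition(spans=(10, 0, 0, 0, 0))
        a_pick = _cv(1, pos=10, score=0.95, gene="G")
        extra = [_cv(i, pos=10 + i, score=0.9, gene="G") for i in range(2, 6)]
        cfg = SelectionConfig(stage_b_budget=4)
        res = select_stage_b(extra, {"1H": part}, cfg, stage_a_selected=[a_pick])
        assert len(res.selected) == 1  # cap 2 total, one already used in stage A

    def test_selection_is_deterministic(self, sim_bundle):
        cfg = SelectionConfig(stage_b_budget=15)
        a1 = select_stage_a(sim_bundle.candidates, cfg)
        a2 = select_stage_a(sim_bundle.candidates, cfg)
        assert [c.id for c in a1] == [c.id for c in a2]
        r1 = select_stage_b(sim_bundle.candidates, sim_bundle.partitions, cfg, a1)
        r2 = select_stage_b(sim_bundle.candidates, sim_bundle.partitions, cfg, a2)
        assert [c.id for c in r1.selected] == [c.id for c in r2.selected]

    def test_stages_are_disjoint_and_caps_hold(self, sim_bundle):
        cfg = SelectionConfig(stage_b_budget=15)
        a = select_stage_a(sim_bundle.candidates, cfg)
        res = select_stage_b(sim_bundle.candidates, sim_bundle.partitions, cfg, a)
        ids_a = {c.id for c in a}
        ids_b = {c.id for c in res.selected}
        assert not ids_a & ids_b
        counts = {}
        for c in list(a) + res.selected:
            if c.gene_id:
                counts[c.gene_id] = counts.get(c.gene_id, 0) + 1
        assert max(counts.values()) <= cfg.stage_b.per_gene_cap


class TestFunnel:
    def test_published_redundancy_arithmetic(self):
        report = design_funnel(
            [("gene_coverage", 16957), ("distal_supplement", 26091),
             ("pre_redundancy", 43048)],
            duplicates=732, legacy=6951,
        )
        assert report.derived["new_after_dedup"] == 42316
        assert report.derived["final_design"] == 49267

    def test_filter_stages_are_monotone_on_synthetic_run(self, sim_bundle):
        from panelforge.selection import filter_candidates

        n0 = len(sim_bundle.candidates)
        n1 = len(filter_candidates(sim_bundle.candidates, 0.20, 0.6))
        n2 = len(dedupe_per_gene(filter_candidates(sim_bundle.candidates, 0.20, 0.6), 1))
        assert n0 >= n1 >= n2


def test_suggest_partition_recovers_piecewise_breakpoints():
    """Anchors sampled from a known 5-segment curve give breakpoints near
    the true segment edges."""
    import numpy as np

    edges = [0, 200, 400, 600, 800, 1000]
    slopes = [0.20, 0.035, 0.001, 0.09, 0.33]  # cM per unit
    xs = np.arange(5, 1000, 5, dtype=float)
    ys = []
    for x in xs:
        y, x0 = 0.0, 0.0
        for e, s in zip(edges[1:], slopes):
            step = min(x, e) - x0
            if step <= 0:
                break
            y += s * step
            x0 = min(x, e)
        ys.append(y)
    part = suggest_partition(xs, ys, chrom="t", chrom_length=1000)
    got = [z.phys_start for z in part.zones][1:]
    for got_bp, true_bp in zip(got, edges[1:-1]):
        assert abs(got_bp - true_bp) <= 25
    assert all(z.genetic_span >= 0 for z in part.zones)
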