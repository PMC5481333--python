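"""Splicing index arithmetic, Fisher/BH statistics and the significance call."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltasi.events import CandidateEvent, EventType
from deltasi.junctions import EvidenceTable, JunctionCounts
from deltasi.si import test_event as fisher_p
from deltasi.si import (
    SICounts,
    adjust_fdr,
    call_events,
    compute_delta_si,
    compute_si,
    event_support,
    round_half_away,
)

# ---------------------------------------------------------------------------
# Independent oracles


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric point-probability
    summation over the support, independent of scipy."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def bh_oracle(ps):
    """Naive quadratic BH: q_i = min over thresholds t >= p_i of m*t/#{p<=t}."""
    ps = np.asarray(ps, dtype=float)
    m = ps.size
    cnt = (ps[None, :] <= ps[:, None]).sum(axis=1).astype(float)  # cnt_j at t=p_j
    vals = m * ps / cnt
    mask = ps[None, :] >= ps[:, None]  # row i: thresholds t=p_j >= p_i
    q = np.where(mask, vals[None, :], np.inf).min(axis=1)
    return np.minimum(q, 1.0)


# ---------------------------------------------------------------------------
# Per-type support


def _event(etype, **kw):
    defaults = dict(
        event_id="E", etype=etype, gene_id="G", chrom="chr1", strand="+",
        variant_form=frozenset({("x",)}), canonical_form=frozenset({("y",)}),
        novel=False,
    )
    defaults.update(kw)
    return CandidateEvent(**defaults)


class TestEventSupport:
    def test_ir_averages_boundaries_against_spliced(self):
        coords = ("chr1", 200, 300)
        ev = EvidenceTable()
        rec = ev.record(coords, "s1")
        rec.left_boundary_count, rec.right_boundary_count = 4, 6
        jc = JunctionCounts()
        jc.add(coords, "s1", 15)
        e = _event(EventType.INTRON_RETENTION, intron=coords)
        sc = event_support(e, jc, ev, "s1")
        assert (sc.a, sc.b) == (5, 15)

    def test_skipping_averages_flanking_junctions(self):
        jc = JunctionCounts()
        jc.add(("chr1", 200, 500), "s1", 9)
        jc.add(("chr1", 200, 300), "s1", 10)
        jc.add(("chr1", 400, 500), "s1", 14)
        e = _event(
            EventType.EXON_SKIPPING,
            skip=("chr1", 200, 500), upstream=("chr1", 200, 300),
            downstream=("chr1", 400, 500),
        )
        sc = event_support(e, jc, EvidenceTable(), "s1")
        assert (sc.a, sc.b) == (9, 12)

    def test_afe_pools_other_donors(self):
        jc = JunctionCounts()
        jc.add(("chr1", 100, 500), "s1", 30)
        jc.add(("chr1", 200, 500), "s1", 10)
        jc.add(("chr1", 300, 500), "s1", 20)
        e = _event(
            EventType.ALT_FIRST_EXON,
            variant_j=("chr1", 100, 500),
            other_donors=(("chr1", 200, 500), ("chr1", 300, 500)),
        )
        sc = event_support(e, jc, EvidenceTable(), "s1")
        assert (sc.a, sc.b) == (30, 30)

    def test_alt_ss_uses_both_junctions_directly(self):
        jc = JunctionCounts()
        jc.add(("chr1", 200, 400), "s1", 25)
        jc.add(("chr1", 250, 400), "s1", 5)
        e = _event(
            EventType.ALT_5SS,
            variant_j=("chr1", 250, 400), canonical_j=("chr1", 200, 400),
        )
        sc = event_support(e, jc, EvidenceTable(), "s1")
        assert (sc.a, sc.b) == (5, 25)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(4.5) == 5
        assert round_half_away(4.4) == 4
        assert round_half_away(0.5) == 1


class TestSI:
    def test_basic_ratio(self):
        assert compute_si(SICounts(5, 15)) == pytest.approx(0.25)

    def test_absent_variant_gives_zero(self):
        assert compute_si(SICounts(0, 20)) == 0.0

    def test_below_min_support_undefined(self):
        assert compute_si(SICounts(2, 3), min_support=10) is None

    def test_delta_and_direction(self):
        assert compute_delta_si(0.30, 0.10) == pytest.approx(0.20)
        assert compute_delta_si(0.10, 0.30) == pytest.approx(-0.20)
        assert compute_delta_si(None, 0.3) is None

    @given(a=st.integers(0, 500), b=st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_si_bounds(self, a, b):
        si = compute_si(SICounts(a, b), min_support=1)
        if si is not None:
            assert 0.0 <= si <= 1.0


class TestFisher:
    def test_no_association_gives_one(self):
        assert fisher_p(SICounts(5, 5), SICounts(5, 5)) == 1.0

    def test_perfect_separation(self):
        p = fisher_p(SICounts(0, 10), SICounts(10, 0))
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_degenerate_margin_gives_one(self):
        assert fisher_p(SICounts(3, 7), SICounts(0, 0)) == 1.0

    def test_matches_enumeration_oracle_small_tables(self):
        for total in range(1, 17):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        p = fisher_p(SICounts(c, d), SICounts(a, b))
                        q = fisher_two_sided_oracle(a, b, c, d)
                        assert p == pytest.approx(q, abs=1e-9), (a, b, c, d)

    @given(
        a=st.integers(0, 60), b=st.integers(0, 60),
        c=st.integers(0, 60), d=st.integers(0, 60),
    )
    @settings(max_examples=150, deadline=None)
    def test_symmetry_under_group_swap(self, a, b, c, d):
        p1 = fisher_p(SICounts(a, b), SICounts(c, d))
        p2 = fisher_p(SICounts(c, d), SICounts(a, b))
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestBH:
    def test_worked_example(self):
        q = adjust_fdr([0.001, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.004, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.03]) == pytest.approx([0.03])

    def test_all_ones(self):
        assert adjust_fdr([1.0] * 5) == pytest.approx([1.0] * 5)

    def test_empty(self):
        assert adjust_fdr([]) == []

    def test_order_preserving_with_input(self):
        ps = [0.04, 0.001, 0.03, 0.02]
        qs = adjust_fdr(ps)
        assert qs[1] == pytest.approx(0.004)

    def test_matches_naive_quadratic_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(50):
            m = int(rng.integers(1, 400))
            ps = rng.uniform(1e-6, 1.0, size=m)
            if rng.random() < 0.3:  # inject ties
                ps[: m // 2] = np.round(ps[: m // 2], 2) + 1e-6
            assert np.allclose(adjust_fdr(ps), bh_oracle(ps), atol=1e-12)


class TestCallEvents:
    def _alt_event(self, ec="E1"):
        return _event(
            EventType.ALT_5SS, event_id=ec,
            variant_j=("chr1", 250, 400), canonical_j=("chr1", 200, 400),
        )

    def _counts(self, control, treated):
        jc = JunctionCounts()
        jc.add(("chr1", 250, 400), "ctl", control[0])
        jc.add(("chr1", 200, 400), "ctl", control[1])
        jc.add(("chr1", 250, 400), "trt", treated[0])
        jc.add(("chr1", 200, 400), "trt", treated[1])
        return jc

    def test_passing_both_gates_is_significant(self):
        jc = self._counts((20, 80), (40, 60))
        (call,) = call_events([self._alt_event()], jc, EvidenceTable(), "ctl", "trt")
        assert call.delta_si == pytest.approx(0.20)
        assert call.q_value < 0.01
        assert call.significant and call.direction == "up"

    def test_small_delta_fails_despite_tiny_p(self):
        jc = self._counts((100, 900), (200, 800))
        (call,) = call_events([self._alt_event()], jc, EvidenceTable(), "ctl", "trt")
        assert call.p_value < 1e-6
        assert call.delta_si == pytest.approx(0.10)
        assert not call.significant

    def test_large_delta_fails_without_statistical_support(self):
        jc = self._counts((2, 8), (4, 6))
        (call,) = call_events([self._alt_event()], jc, EvidenceTable(), "ctl", "trt")
        assert call.delta_si == pytest.approx(0.20)
        assert call.q_value >= 0.01
        assert not call.significant

    def test_undefined_si_excluded_from_pool(self):
        jc = self._counts((2, 3), (40, 60))  # control below min_support
        (call,) = call_events([self._alt_event()], jc, EvidenceTable(), "ctl", "trt")
        assert call.si_control is None and call.p_value is None
        assert not call.significant

    def test_missing_control_sample_is_an_error(self):
        jc = self._counts((20, 80), (40, 60))
        with pytest.raises(ValueError, match="control"):
            call_events([self._alt_event()], jc, EvidenceTable(), "nope", "trt")

    def test_swap_negates_delta_keeps_p(self):
        jc = self._counts((20, 80), (40, 60))
        (fwd,) = call_events([self._alt_event()], jc, EvidenceTable(), "ctl", "trt")
        (rev,) = call_events([self._alt_event()], jc, EvidenceTable(), "trt", "ctl")
        assert fwd.delta_si == pytest.approx(-rev.delta_si)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)
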