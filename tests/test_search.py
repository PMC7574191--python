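"""Search engine: cost, windowed lookup, track-type semantics, scoring,
ranking, and agreement with the exhaustive oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from patternscan import (
    CandidateAnchor,
    Pattern,
    PatternTrack,
    Region,
    SearchParams,
    Track,
    apply_negative_filter,
    apply_valid_area,
    exhaustive_search,
    expand_loops,
    matching_cost,
    search_pattern,
    search_single_anchor,
    windowed_nearest,
)
from patternscan.errors import LengthMismatch

from conftest import make_track


def shift_targets(targets, offset):
    out = {}
    for name, t in targets.items():
        nt = Track(name, track_type=t.track_type,
                   negative_distance=t.negative_distance)
        for r in t:
            nt.add(r.translated(offset))
        nt.sort()
        out[name] = nt
    return out


# ---------------------------------------------------------------------------
# Cost
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("q,t,expected", [
    ([0, 100], [500, 600], 0.0),          # pure translation
    ([0, 100], [500, 610], 100.0),        # residuals (0, 10)
    ([0, 100, 300], [1000, 1105, 1295], 50.0),  # residuals (0, 5, -5)
])
def test_matching_cost_hand_values(q, t, expected):
    assert matching_cost(q, t) == expected


def test_matching_cost_rejects_mismatched_lengths():
    with pytest.raises(LengthMismatch):
        matching_cost([0, 1], [0])
    with pytest.raises(LengthMismatch):
        matching_cost([], [])


@settings(derandomize=True, max_examples=100)
@given(q=st.lists(st.integers(0, 10**6), min_size=1, max_size=6),
       t=st.lists(st.integers(0, 10**6), min_size=1, max_size=6),
       shift=st.integers(-10**6, 10**6))
def test_cost_translation_invariance(q, t, shift):
    """Shifting all target centers by a constant leaves the cost unchanged."""
    n = min(len(q), len(t))
    q, t = q[:n], t[:n]
    assert matching_cost(q, [x + shift for x in t]) == matching_cost(q, t)


@settings(derandomize=True, max_examples=100)
@given(q=st.lists(st.integers(0, 10**5), min_size=2, max_size=6, unique=True),
       shift=st.integers(0, 10**5))
def test_zero_cost_iff_distance_preserving(q, shift):
    q = sorted(q)
    assert matching_cost(q, [x + shift for x in q]) == 0.0
    perturbed = list(q)
    perturbed[-1] += 7  # breaks one inter-center distance
    assert matching_cost(q, [x + shift for x in perturbed]) > 0.0


# ---------------------------------------------------------------------------
# Windowed nearest
# ---------------------------------------------------------------------------

def centers_track(centers, half=5):
    return [Region("chr1", c - half, c + half) for c in centers]


def test_windowed_nearest_picks_nearest_within_window():
    regs = centers_track([100, 500, 900])
    assert windowed_nearest(regs, 480, 50).center == 500


def test_windowed_nearest_none_outside_window():
    assert windowed_nearest(centers_track([100, 900]), 500, 50) is None


def test_windowed_nearest_tie_breaks_low():
    assert windowed_nearest(centers_track([400, 600]), 500, 200).center == 400


def test_windowed_nearest_empty_list():
    assert windowed_nearest([], 100, 50) is None


# ---------------------------------------------------------------------------
# Valid area
# ---------------------------------------------------------------------------

def test_valid_area_keeps_overlapping_regions():
    targets = {"A": make_track("A", [(100, 200), (300, 400)])}
    valid = [make_track("V", [(150, 350)])]
    out = apply_valid_area(targets, valid)
    assert [(r.start, r.end) for r in out["A"]] == [(100, 200), (300, 400)]


def test_valid_area_removes_outside_regions():
    targets = {"A": make_track("A", [(500, 600)])}
    out = apply_valid_area(targets, [make_track("V", [(150, 350)])])
    assert len(out["A"]) == 0


def test_valid_area_empty_union_removes_all():
    targets = {"A": make_track("A", [(100, 200)])}
    out = apply_valid_area(targets, [Track("V")])
    assert len(out["A"]) == 0


# ---------------------------------------------------------------------------
# Loops
# ---------------------------------------------------------------------------

def loop_track(a_iv, b_iv, chrom_a="chr1", chrom_b="chr1"):
    t = Track("loops", track_type="loop")
    a = Region(chrom_a, *a_iv)
    b = Region(chrom_b, *b_iv)
    a.mate, b.mate = b, a
    t.add(a)
    t.add(b)
    t.sort()
    return t


def test_loop_copies_translated_region():
    targets = {"A": make_track("A", [(110, 120)])}
    out = expand_loops(targets, loop_track((100, 200), (10000, 10100)))
    copies = [r for r in out["A"] if r.loop_derived]
    assert [(r.start, r.end) for r in copies] == [(10010, 10020)]


def test_loop_ignores_non_overlapping_regions():
    targets = {"A": make_track("A", [(500, 600)])}
    out = expand_loops(targets, loop_track((100, 200), (10000, 10100)))
    assert len(out["A"]) == 1


def test_loop_region_overlapping_both_anchors_copied_both_ways():
    # hand-enumerated: anchors A=[100,200) B=[150,250); region [140,160)
    # overlaps both; A->B offset +50 gives [190,210), B->A offset -50 gives
    # [90,110)
    targets = {"A": make_track("A", [(140, 160)])}
    out = expand_loops(targets, loop_track((100, 200), (150, 250)))
    copies = sorted((r.start, r.end) for r in out["A"] if r.loop_derived)
    assert copies == [(90, 110), (190, 210)]


# ---------------------------------------------------------------------------
# Negative filter
# ---------------------------------------------------------------------------

def _span_matching(span, chrom="chr1"):
    root = Region(chrom, span[0], span[0] + 10)
    from patternscan import Matching
    return Matching(chrom=chrom, assignment={("A", 0): root}, anchor_offset=0,
                    cost=0.0, per_track_scores={"A": 1.0}, score=1.0,
                    span=span, center_span=span, root_region=root)


def test_negative_enclosed_region_rejects():
    m = _span_matching((100, 900))
    neg = make_track("N", [(400, 410)], track_type="negative")
    assert apply_negative_filter([m], [(neg, 0)]) == []


def test_negative_extension_rejects():
    # TSS at 1500 extended by 1000 bp -> [500, 2501) overlaps span 100-900
    m = _span_matching((100, 900))
    neg = make_track("N", [(1500, 1501)], track_type="negative")
    assert apply_negative_filter([m], [(neg, 1000)]) == []


def test_negative_far_site_retained():
    # TSS at 25000 extended by 20000 -> [5000, 45001): no overlap with 100-900
    m = _span_matching((100, 900))
    neg = make_track("N", [(25000, 25001)], track_type="negative")
    assert apply_negative_filter([m], [(neg, 20000)]) == [m]


# ---------------------------------------------------------------------------
# Single anchor + scoring
# ---------------------------------------------------------------------------

def test_exact_plant_scores_one(two_region_pattern):
    targets = {"A": make_track("A", [(495, 505), (595, 605)])}
    anchor = CandidateAnchor(targets["A"].regions_on("chr1")[0], 500)
    m = search_single_anchor(two_region_pattern, targets, anchor)
    assert m.cost == 0.0
    assert m.score == 1.0
    assert m.per_track_scores == {"A": 1.0}


def test_missing_perfect_region_kills_candidate(two_region_pattern):
    targets = {"A": make_track("A", [(495, 505)])}  # nothing near center 600
    anchor = CandidateAnchor(targets["A"].regions_on("chr1")[0], 500)
    assert search_single_anchor(two_region_pattern, targets, anchor) is None


def test_unmatched_partial_halves_score(perfect_partial_pattern):
    targets = {"A": make_track("A", [(95, 105)]), "B": Track("B")}
    anchor = CandidateAnchor(targets["A"].regions_on("chr1")[0], 100)
    m = search_single_anchor(perfect_partial_pattern, targets, anchor)
    assert m is not None
    assert m.per_track_scores["B"] == 0.0
    assert m.score == 0.5
    assert m.assignment[("B", 0)] is None


def test_half_window_residual_gives_three_quarters(perfect_partial_pattern):
    # partial region matched at |residual| = window/2 -> s = 0.5, overall 0.75
    targets = {"A": make_track("A", [(95, 105)]),
               "B": make_track("B", [(545, 555)])}  # expected 500, found 550
    anchor = CandidateAnchor(targets["A"].regions_on("chr1")[0], 100)
    m = search_single_anchor(perfect_partial_pattern, targets, anchor)
    assert m.per_track_scores["B"] == 0.5
    assert m.score == 0.75
    assert m.cost == 50.0 ** 2


def test_attribute_similarity_blend():
    pattern = Pattern(
        tracks=[PatternTrack("A", "A", "perfect", centers=[0],
                             attributes=[{"length": 100.0}])],
        params=SearchParams(window=100, use_attributes=True,
                            attribute_weight=1.0),
    )
    # target region length 50 -> sim = 1 - 50/100 = 0.5; residual 0
    targets = {"A": make_track("A", [(475, 525)])}
    anchor = CandidateAnchor(targets["A"].regions_on("chr1")[0], 500)
    m = search_single_anchor(pattern, targets, anchor)
    assert m.score == pytest.approx(0.5)
    # attributes off: same instance scores 1.0
    pattern.params.use_attributes = False
    m2 = search_single_anchor(pattern, targets, anchor)
    assert m2.score == 1.0


# ---------------------------------------------------------------------------
# Full search
# ---------------------------------------------------------------------------

def planted_instance():
    """Three exact plants of a two-track pattern plus background decoys."""
    pattern = Pattern(
        tracks=[
            PatternTrack("A", "A", "perfect", centers=[0]),
            PatternTrack("B", "B", "perfect", centers=[1000]),
        ],
        params=SearchParams(window=200),
    )
    origins = [10_000, 50_000, 90_000]
    a = make_track("A", [(o - 50, o + 50) for o in origins] + [(30_000, 30_100)])
    b = make_track("B", [(o + 950, o + 1050) for o in origins] + [(70_000, 70_100)])
    return pattern, {"A": a, "B": b}, origins


def test_planted_occurrences_recovered_exactly():
    pattern, targets, origins = planted_instance()
    results = search_pattern(pattern, targets,
                             SearchParams(window=200, min_score=0.9))
    assert len(results) == 3
    assert all(m.score == 1.0 and m.cost == 0.0 for m in results)
    assert sorted(m.root_region.center for m in results) == origins


def test_max_results_truncates_to_top_scores():
    pattern, targets, _ = planted_instance()
    results = search_pattern(pattern, targets,
                             SearchParams(window=200, min_score=0.9,
                                          max_results=2))
    assert len(results) == 2
    assert all(m.score == 1.0 for m in results)


def test_search_translation_invariance():
    """Shifting every target by k preserves scores/costs and shifts spans."""
    pattern, targets, _ = planted_instance()
    base = search_pattern(pattern, targets)
    k = 12_345
    shifted = search_pattern(pattern, shift_targets(targets, k))
    assert len(base) == len(shifted)
    for m0, m1 in zip(base, shifted):
        assert m1.cost == m0.cost
        assert m1.score == m0.score
        assert m1.span == (m0.span[0] + k, m0.span[1] + k)


def test_search_is_deterministic():
    pattern, targets, _ = planted_instance()
    r1 = search_pattern(pattern, targets)
    r2 = search_pattern(pattern, targets)
    assert [(m.span, m.score, m.cost) for m in r1] \
        == [(m.span, m.score, m.cost) for m in r2]


def test_ranking_orders_by_score_then_cost():
    pattern, targets, _ = planted_instance()
    results = search_pattern(pattern, targets)
    keys = [(-m.score, m.cost, m.chrom, m.span[0]) for m in results]
    assert keys == sorted(keys)


def test_empty_targets_warn_and_return_nothing(two_region_pattern):
    with pytest.warns(UserWarning):
        assert search_pattern(two_region_pattern, {"A": Track("A")}) == []


def test_valid_area_restricts_full_search():
    pattern, targets, origins = planted_instance()
    # valid area covering only the first planted occurrence
    targets = dict(targets)
    targets["V"] = make_track("V", [(9_000, 12_500)])
    tracks = list(pattern.tracks) + [PatternTrack("V", "V", "valid_area")]
    pat = Pattern(tracks=tracks, params=pattern.params)
    results = search_pattern(pat, targets, SearchParams(window=200, min_score=0.9))
    assert [m.root_region.center for m in results] == [10_000]


def test_negative_track_removes_matchings_near_sites():
    pattern, targets, origins = planted_instance()
    targets = dict(targets)
    targets["TSS"] = make_track("TSS", [(52_000, 52_001)])
    tracks = list(pattern.tracks) + [
        PatternTrack("TSS", "TSS", "negative", negative_distance=20_000)]
    pat = Pattern(tracks=tracks, params=pattern.params)
    results = search_pattern(pat, targets, SearchParams(window=200, min_score=0.9))
    # plants at 50k (within 20 kb of the site) are gone; 10k and 90k survive
    assert sorted(m.root_region.center for m in results) == [10_000, 90_000]


def test_loop_projection_creates_distal_matchings():
    # pattern needs A and B 1 kb apart; B's only region sits across a loop
    pattern = Pattern(
        tracks=[
            PatternTrack("A", "A", "perfect", centers=[0]),
            PatternTrack("B", "B", "perfect", centers=[1000]),
            PatternTrack("L", "L", "loop"),
        ],
        params=SearchParams(window=100),
    )
    targets = {
        "A": make_track("A", [(950, 1050)]),
        "B": make_track("B", [(101_950, 102_050)]),  # distal, via loop anchor
        "L": loop_track((101_000, 103_000), (1_000, 3_000)),
    }
    results = search_pattern(pattern, targets)
    # the projection works in both directions: one matching at each loop end
    assert len(results) == 2
    assert all(m.score == 1.0 for m in results)
    assert sorted(m.root_region.center for m in results) == [1000, 101_000]
    assert any(m.assignment[("B", 0)].loop_derived for m in results)


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

def test_oracle_degenerate_single_region_pattern():
    pattern = Pattern(tracks=[PatternTrack("A", "A", "perfect", centers=[0])],
                      params=SearchParams(window=100))
    targets = {"A": make_track("A", [(0, 10), (100, 110), (200, 210)])}
    results = exhaustive_search(pattern, targets)
    assert len(results) == 3
    assert all(m.cost == 0.0 and m.score == 1.0 for m in results)


def test_oracle_two_region_pattern_enumeration(two_region_pattern):
    # centers: 100, 180, 220; pattern [0, 100], window 50.
    # anchor@100: second expects 200 -> candidates {180, 220}; best 180 (cost 400)
    # anchor@180: second expects 280 -> candidate {220? |220-280|=60 >50} none -> dead
    # anchor@220: second expects 320 -> none -> dead
    targets = {"A": make_track("A", [(95, 105), (175, 185), (215, 225)])}
    results = exhaustive_search(two_region_pattern, targets)
    assert len(results) == 1
    m = results[0]
    assert m.root_region.center == 100
    assert m.assignment[("A", 1)].center == 180
    assert m.cost == 400.0


def test_oracle_matches_engine_on_planted_instance():
    pattern, targets, _ = planted_instance()
    engine = search_pattern(pattern, targets)
    oracle = exhaustive_search(pattern, targets)
    assert [(m.span, m.score, m.cost) for m in engine] \
        == [(m.span, m.score, m.cost) for m in oracle]


def test_oracle_guard_on_huge_instances():
    from patternscan.errors import InstanceTooLarge
    pattern = Pattern(
        tracks=[PatternTrack("A", "A", "perfect", centers=[0, 100, 200, 300])],
        params=SearchParams(window=10_000))
    targets = {"A": make_track("A", [(i * 10, i * 10 + 5) for i in range(60)])}
    with pytest.raises(InstanceTooLarge):
        exhaustive_search(pattern, targets, max_combinations=1000)
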