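"""Root-anchored windowed pattern search over sorted region tracks.

The model: a query pattern Q is a set of region centers Q_i spread over one
or more tracks; a matching f assigns each pattern region to a target region
(center T_f(i)).  Fixing the root pair — the first region of the first
perfect track against a region of its target track — determines a candidate
translation Δ = T_f(1) − Q_1, and the cost of the matching is the squared
sum of the remaining residual offsets relative to Δ:

    C_f(Q, T) = Σ_i (T_f(i) − Q_i − Δ)²        [bp²]

Cost is translation-invariant: only inter-region distances matter.  The
search enumerates every region of the root target track as an anchor and
resolves each remaining pattern region independently by a windowed binary
search around its expected position Q_i + Δ — O(M log N) per anchor,
O(N_root · M log N) overall.

Scores map residuals into [0, 1] with a linear ramp inside the match
window, s_i = max(0, 1 − |residual_i| / window); unmatched partial regions
score 0.  The overall score is the unweighted mean over pattern regions.
"""

from __future__ import annotations

import itertools
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    MATCHABLE_TYPES,
    Matching,
    Pattern,
    PatternTrack,
    Region,
    SearchParams,
    Track,
    TrackType,
    UNMATCHED,
    region_center,
)
from .errors import InstanceTooLarge, LengthMismatch, MissingMate, NoPerfectTrack

_EPS = 1e-9


@dataclass
class CandidateAnchor:
    """A fixed root pair: one region of the root target track and the
    translation Δ = center(root target) − Q_root it induces."""

    root_target_region: Region
    anchor_offset: int


# ---------------------------------------------------------------------------
# Cost
# ---------------------------------------------------------------------------

def matching_cost(q_centers: Sequence[float], t_centers: Sequence[float]) -> float:
    """Squared sum of residual offsets relative to the root (first) pair.

    ``cost = Σ_i ((t_i − q_i) − (t_0 − q_0))²``; the root residual is zero
    by construction, and a pure translation of the pattern costs 0.
    """
    if len(q_centers) != len(t_centers):
        raise LengthMismatch(
            f"{len(q_centers)} pattern centers vs {len(t_centers)} target centers"
        )
    if not q_centers:
        raise LengthMismatch("need at least one center pair")
    q = np.asarray(q_centers, dtype=float)
    t = np.asarray(t_centers, dtype=float)
    residuals = (t - q) - (t[0] - q[0])
    return float(np.sum(residuals ** 2))


# ---------------------------------------------------------------------------
# Windowed nearest lookup
# ---------------------------------------------------------------------------

def windowed_nearest(regions: Sequence[Region], expected_center: int,
                     window: int) -> Optional[Region]:
    """Region whose center is nearest to ``expected_center`` if within
    ``window`` bp, else ``None``.  Ties break toward the lower coordinate.

    Accepts any region list; lookups are done on a center-sorted view so
    nested regions (whose centers are not monotone in start order) are
    handled correctly.
    """
    if not regions:
        return None
    regions = sorted(regions, key=lambda r: (r.center, r.start))
    i = bisect_left(regions, expected_center, key=region_center)
    best = None
    best_dist = window + 1
    if i > 0:
        left = regions[i - 1]
        d = abs(left.center - expected_center)
        if d < best_dist:
            best, best_dist = left, d
    if i < len(regions):
        right = regions[i]
        d = abs(right.center - expected_center)
        if d < best_dist:  # strict: the lower-coordinate candidate wins ties
            best, best_dist = right, d
    return best if best_dist <= window else None


class _TrackIndex:
    """Per-chromosome center arrays + region lists for fast nearest lookup."""

    def __init__(self, track: Track):
        self.regions: Dict[str, List[Region]] = {}
        self.centers: Dict[str, np.ndarray] = {}
        for chrom in track.chroms():
            regs = sorted(track.regions_on(chrom), key=lambda r: (r.center, r.start))
            self.regions[chrom] = regs
            self.centers[chrom] = np.array([r.center for r in regs], dtype=np.int64)

    def nearest(self, chrom: str, expected: int, window: int) -> Optional[Region]:
        centers = self.centers.get(chrom)
        if centers is None or len(centers) == 0:
            return None
        i = int(np.searchsorted(centers, expected))
        best, best_dist = None, window + 1
        if i > 0 and abs(int(centers[i - 1]) - expected) < best_dist:
            best, best_dist = self.regions[chrom][i - 1], abs(int(centers[i - 1]) - expected)
        if i < len(centers) and abs(int(centers[i]) - expected) < best_dist:
            best, best_dist = self.regions[chrom][i], abs(int(centers[i]) - expected)
        return best if best_dist <= window else None


# ---------------------------------------------------------------------------
# Track-type preprocessing
# ---------------------------------------------------------------------------

def _merged_intervals(regions: Iterable[Region], pad: int = 0) -> List[Tuple[int, int]]:
    ivs = sorted((max(0, r.start - pad), r.end + pad) for r in regions)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _overlaps_merged(merged: List[Tuple[int, int]], start: int, end: int) -> bool:
    """>=1 bp overlap of [start, end) with any of the disjoint sorted intervals."""
    if not merged:
        return False
    starts = [s for s, _ in merged]
    i = bisect_right(starts, end - 1)  # last interval starting before `end`
    return i > 0 and merged[i - 1][1] > start


def apply_valid_area(target_tracks: Mapping[str, Track],
                     valid_tracks: Sequence[Track]) -> Dict[str, Track]:
    """Restrict target tracks to regions overlapping the valid-area union.

    Every region (of every target track) without >=1 bp overlap with the
    union of the valid-area regions is removed.  An empty union removes
    everything.
    """
    union: Dict[str, List[Tuple[int, int]]] = {}
    for vt in valid_tracks:
        for chrom in vt.chroms():
            union.setdefault(chrom, []).extend(
                (r.start, r.end) for r in vt.regions_on(chrom))
    merged = {chrom: _merged_intervals(Region(chrom, s, e) for s, e in ivs)
              for chrom, ivs in union.items()}

    out: Dict[str, Track] = {}
    for name, track in target_tracks.items():
        filtered = Track(track.name, track_type=track.track_type,
                         negative_distance=track.negative_distance)
        for chrom in track.chroms():
            keep = [r for r in track.regions_on(chrom)
                    if _overlaps_merged(merged.get(chrom, []), r.start, r.end)]
            if keep:
                filtered.regions[chrom] = keep
        out[name] = filtered
    return out


def expand_loops(target_tracks: Mapping[str, Track],
                 loop_track: Track) -> Dict[str, Track]:
    """Project regions across loop anchors.

    For each loop pair (A, B) and each target region overlapping anchor A, a
    copy translated by ``B.start − A.start`` (onto B's chromosome) is added
    to the region's track, and symmetrically B → A.  Copies are flagged
    ``loop_derived`` and the tracks re-sorted.
    """
    out = {name: t.copy() for name, t in target_tracks.items()}
    anchors = list(loop_track)  # each pair appears once per direction
    for a in anchors:
        if a.mate is None:
            raise MissingMate(f"loop region {a.chrom}:{a.start}-{a.end} has no mate")
    for name, track in out.items():
        new_regions: List[Region] = []
        for a in anchors:
            offset = a.mate.start - a.start
            for r in track.regions_on(a.chrom):
                if r.loop_derived or not r.overlaps(a.start, a.end):
                    continue
                ns, ne = r.start + offset, r.end + offset
                if ns < 0:
                    continue  # copy would fall off the chromosome start
                new_regions.append(Region(
                    a.mate.chrom, ns, ne, name=r.name,
                    attributes=dict(r.attributes) if r.attributes else None,
                    loop_derived=True,
                ))
        for nr in new_regions:
            track.add(nr)
        track.sort()
    return out


def apply_negative_filter(
    candidates: Sequence[Matching],
    negative_tracks: Sequence[Tuple[Track, int]],
) -> List[Matching]:
    """Drop candidates whose span overlaps an extended negative region.

    ``negative_tracks`` pairs each track with its extension distance; each
    negative region is widened by that many bp on both sides (clamped at 0)
    and any >=1 bp overlap with a candidate's span rejects the candidate.
    """
    merged: Dict[str, List[Tuple[int, int]]] = {}
    for track, dist in negative_tracks:
        for chrom in track.chroms():
            merged.setdefault(chrom, []).extend(
                (max(0, r.start - dist), r.end + dist)
                for r in track.regions_on(chrom))
    merged = {chrom: _merged_intervals(Region(chrom, s, e) for s, e in ivs)
              for chrom, ivs in merged.items()}
    return [m for m in candidates
            if not _overlaps_merged(merged.get(m.chrom, []), *m.span)]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _attribute_similarity(q_attrs: Mapping[str, float], region: Region) -> float:
    sims = []
    for key, aq in q_attrs.items():
        at = region.attribute_value(key)
        if at is None:
            sims.append(0.0)
        else:
            denom = max(abs(aq), abs(at), _EPS)
            sims.append(max(0.0, 1.0 - abs(aq - at) / denom))
    return float(np.mean(sims)) if sims else 1.0


def score_matching(matching: Matching, pattern: Pattern,
                   params: Optional[SearchParams] = None) -> Matching:
    """Fill in per-track and overall scores of a matching (in place).

    Per region: ``s_i = max(0, 1 − |residual_i| / window)`` for matched
    regions, 0 for unmatched; optionally blended with numeric-attribute
    similarity.  Per-track score = mean of its regions; overall score =
    mean over all pattern regions.
    """
    params = params or pattern.params
    window = pattern.resolved_window()
    delta = matching.anchor_offset
    per_track: Dict[str, float] = {}
    all_scores: List[float] = []
    for pt in pattern.matchable_tracks():
        track_scores = []
        for i, q in enumerate(pt.centers):
            region = matching.assignment.get((pt.name, i), UNMATCHED)
            if region is UNMATCHED:
                s = 0.0
            else:
                residual = region.center - (q + delta)
                s = max(0.0, 1.0 - abs(residual) / window)
                if params.use_attributes and pt.attributes and pt.attributes[i]:
                    sim = _attribute_similarity(pt.attributes[i], region)
                    w = params.attribute_weight
                    s = s * (1.0 - w + w * sim)
            track_scores.append(s)
        per_track[pt.name] = float(np.mean(track_scores)) if track_scores else 0.0
        all_scores.extend(track_scores)
    matching.per_track_scores = per_track
    matching.score = float(np.mean(all_scores)) if all_scores else 0.0
    return matching


# ---------------------------------------------------------------------------
# Single-anchor resolution
# ---------------------------------------------------------------------------

def _resolve_targets(pattern: Pattern,
                     targets: Mapping[str, Track] | Sequence[Track],
                     matchable_only: bool = False) -> Dict[str, Track]:
    if not isinstance(targets, Mapping):
        targets = {t.name: t for t in targets}
    wanted = pattern.matchable_tracks() if matchable_only else pattern.tracks
    missing = [pt.target_track_name for pt in wanted
               if pt.target_track_name not in targets]
    if missing:
        from .errors import UnresolvedTarget
        raise UnresolvedTarget(
            "pattern tracks reference unloaded target tracks: " + ", ".join(missing))
    return dict(targets)


def _build_matching(pattern: Pattern, anchor: CandidateAnchor,
                    assignment: Dict[Tuple[str, int], Optional[Region]],
                    params: SearchParams) -> Matching:
    delta = anchor.anchor_offset
    matched = [r for r in assignment.values() if r is not UNMATCHED]
    q_by_key = {(pt.name, i): q for pt in pattern.matchable_tracks()
                for i, q in enumerate(pt.centers)}
    cost = sum((r.center - (q_by_key[k] + delta)) ** 2
               for k, r in assignment.items() if r is not UNMATCHED)
    span = (min(r.start for r in matched), max(r.end for r in matched))
    centers = [r.center for r in matched]
    root_key = (pattern.root_track.name, 0)
    m = Matching(
        chrom=anchor.root_target_region.chrom,
        assignment=assignment,
        anchor_offset=delta,
        cost=float(cost),
        per_track_scores={},
        score=0.0,
        span=span,
        center_span=(min(centers), max(centers)),
        root_region=assignment[root_key],
    )
    return score_matching(m, pattern, params)


def search_single_anchor(
    pattern: Pattern,
    targets: Mapping[str, Track] | Sequence[Track],
    anchor: CandidateAnchor,
    params: Optional[SearchParams] = None,
    _indexes: Optional[Dict[str, _TrackIndex]] = None,
) -> Optional[Matching]:
    """Resolve a matching for one fixed root pair, or ``None``.

    With the anchor translation Δ fixed, every remaining pattern region is
    independently assigned the nearest target region within the window of
    its expected position Q_i + Δ.  Any unmatched perfect-track region
    kills the candidate; partial-track regions may stay unmatched.
    """
    params = params or pattern.params
    if _indexes is None:
        targets = _resolve_targets(pattern, targets, matchable_only=True)
        _indexes = {pt.name: _TrackIndex(targets[pt.target_track_name])
                    for pt in pattern.matchable_tracks()}
    window = pattern.resolved_window()
    delta = anchor.anchor_offset
    chrom = anchor.root_target_region.chrom
    root_name = pattern.root_track.name

    assignment: Dict[Tuple[str, int], Optional[Region]] = {}
    for pt in pattern.matchable_tracks():
        index = _indexes[pt.name]
        for i, q in enumerate(pt.centers):
            if pt.name == root_name and i == 0:
                assignment[(pt.name, i)] = anchor.root_target_region
                continue
            region = index.nearest(chrom, q + delta, window)
            if region is None and pt.track_type is TrackType.PERFECT:
                return None
            assignment[(pt.name, i)] = region
    return _build_matching(pattern, anchor, assignment, params)


# ---------------------------------------------------------------------------
# Full search
# ---------------------------------------------------------------------------

def _split_special_tracks(pattern: Pattern, targets: Mapping[str, Track]):
    valid = [targets[pt.target_track_name] for pt in pattern.tracks
             if pt.track_type is TrackType.VALID_AREA]
    loops = [targets[pt.target_track_name] for pt in pattern.tracks
             if pt.track_type is TrackType.LOOP]
    negatives = []
    for pt in pattern.tracks:
        if pt.track_type is TrackType.NEGATIVE:
            track = targets[pt.target_track_name]
            dist = pt.negative_distance or track.negative_distance
            negatives.append((track, dist))
    return valid, loops, negatives


def _finalize(candidates: List[Matching], negatives, params: SearchParams
              ) -> List[Matching]:
    # deduplicate identical assignments (identical assignment => identical cost)
    unique: Dict[Tuple, Matching] = {}
    for m in candidates:
        sig = m.assignment_signature()
        prev = unique.get(sig)
        if prev is None or m.cost < prev.cost:
            unique[sig] = m
    kept = apply_negative_filter(list(unique.values()), negatives)
    kept = [m for m in kept if m.score > params.min_score or params.min_score == 0.0]
    kept.sort(key=lambda m: (-m.score, m.cost, m.chrom, m.span[0], m.span[1]))
    return kept[: params.max_results]


def search_pattern(
    pattern: Pattern,
    targets: Mapping[str, Track] | Sequence[Track],
    params: Optional[SearchParams] = None,
) -> List[Matching]:
    """Genome-wide pattern search: ranked list of matchings.

    Pipeline: valid-area restriction → loop projection → one candidate per
    root-track target region (anchor) resolved by windowed nearest lookups →
    deduplication → negative filtering → score threshold → ranking by
    (score desc, cost asc, chrom, span) → truncation to ``max_results``.
    Deterministic: no randomness anywhere in the search.
    """
    params = params or pattern.params
    targets = _resolve_targets(pattern, targets)
    valid, loops, negatives = _split_special_tracks(pattern, targets)

    matchable_names = {pt.target_track_name for pt in pattern.matchable_tracks()}
    work = {name: targets[name] for name in matchable_names}
    if valid:
        work = apply_valid_area(work, valid)
    for loop_track in loops:
        work = expand_loops(work, loop_track)

    if all(len(t) == 0 for t in work.values()):
        warnings.warn("all target tracks are empty; no matchings possible",
                      stacklevel=2)
        return []

    indexes = {pt.name: _TrackIndex(work[pt.target_track_name])
               for pt in pattern.matchable_tracks()}
    root_pt = pattern.root_track
    root_track = work[root_pt.target_track_name]
    q_root = pattern.root_center

    candidates: List[Matching] = []
    for chrom in root_track.chroms():
        for region in root_track.regions_on(chrom):
            anchor = CandidateAnchor(region, region.center - q_root)
            m = search_single_anchor(pattern, work, anchor, params,
                                     _indexes=indexes)
            if m is not None:
                candidates.append(m)
    return _finalize(candidates, negatives, params)


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

def exhaustive_search(
    pattern: Pattern,
    targets: Mapping[str, Track] | Sequence[Track],
    params: Optional[SearchParams] = None,
    max_combinations: int = 500_000,
) -> List[Matching]:
    """Brute-force reference search for testing.

    For every anchor it enumerates ALL assignments built from the full
    candidate sets (every target region within the window of each expected
    position, plus UNMATCHED for partial regions) and keeps the assignment
    with maximum score, breaking ties by minimum cost, then lowest
    coordinates.  Filters, scoring and ranking are identical to
    :func:`search_pattern`.  Raises :class:`InstanceTooLarge` beyond
    ``max_combinations`` enumerated assignments.
    """
    params = params or pattern.params
    targets = _resolve_targets(pattern, targets)
    valid, loops, negatives = _split_special_tracks(pattern, targets)
    matchable_names = {pt.target_track_name for pt in pattern.matchable_tracks()}
    work = {name: targets[name] for name in matchable_names}
    if valid:
        work = apply_valid_area(work, valid)
    for loop_track in loops:
        work = expand_loops(work, loop_track)

    window = pattern.resolved_window()
    root_pt = pattern.root_track
    root_track = work[root_pt.target_track_name]
    q_root = pattern.root_center
    keys = pattern.region_ids()
    q_by_key = {(pt.name, i): q for pt in pattern.matchable_tracks()
                for i, q in enumerate(pt.centers)}
    type_by_track = {pt.name: pt.track_type for pt in pattern.matchable_tracks()}
    track_by_ptname = {pt.name: work[pt.target_track_name]
                       for pt in pattern.matchable_tracks()}

    total_combos = 0
    candidates: List[Matching] = []
    for chrom in root_track.chroms():
        for root_region in root_track.regions_on(chrom):
            delta = root_region.center - q_root
            anchor = CandidateAnchor(root_region, delta)
            options: List[List[Optional[Region]]] = []
            dead = False
            for key in keys:
                if key == (root_pt.name, 0):
                    options.append([root_region])
                    continue
                pt_name, i = key
                expected = q_by_key[key] + delta
                track = track_by_ptname[pt_name]
                cands = [r for r in track.regions_on(chrom)
                         if abs(r.center - expected) <= window]
                cands.sort(key=lambda r: (abs(r.center - expected), r.start))
                if type_by_track[pt_name] is TrackType.PARTIAL:
                    cands.append(UNMATCHED)
                elif not cands:
                    dead = True
                    break
                options.append(cands)
            if dead:
                continue
            n_combos = int(np.prod([len(o) for o in options]))
            total_combos += n_combos
            if total_combos > max_combinations:
                raise InstanceTooLarge(
                    f"exhaustive enumeration exceeds {max_combinations} assignments")
            best: Optional[Matching] = None
            for combo in itertools.product(*options):
                assignment = dict(zip(keys, combo))
                m = _build_matching(pattern, anchor, assignment, params)
                if best is None or (m.score, -m.cost) > (best.score, -best.cost):
                    best = m
            if best is not None:
                candidates.append(best)
    return _finalize(candidates, negatives, params)
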