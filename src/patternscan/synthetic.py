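"""Synthetic track generation with planted, jittered pattern occurrences.

Backgrounds are homogeneous-Poisson region sets (count ~ Poisson(density ×
chromosome length / 1 Mbp) per track and chromosome, starts uniform,
lengths uniform in a range).  Planted occurrences put one region per
pattern center at ``origin + Q_i + Uniform(−jitter, +jitter)`` into the
mapped track, with origins kept at least twice the pattern span apart so
recovered matchings map unambiguously back to the truth.  Everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Matching, Pattern, PatternTrack, Region, SearchParams, Track
from .errors import GenomeTooSmall

DEFAULT_GENOME: Dict[str, int] = {"chrS": 10_000_000}


@dataclass
class PlantedOccurrence:
    """Ground truth for one planted pattern occurrence."""

    chrom: str
    origin: int
    span: Tuple[int, int]
    regions: Dict[Tuple[str, int], Region] = field(default_factory=dict)


@dataclass
class PlantSpec:
    """What to plant: pattern, how many occurrences, jitter, where."""

    pattern: Pattern
    n_occurrences: int = 100
    jitter: int = 0
    genome: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    background_density: float = 50.0  # regions per Mbp per track
    region_length: Tuple[int, int] = (200, 1000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.n_occurrences < 0:
            raise ValueError("n_occurrences must be >= 0")


def generate_background(
    genome: Dict[str, int],
    density: float,
    region_length_range: Tuple[int, int] = (200, 1000),
    seed: int = 0,
    track_names: Sequence[str] = ("track",),
) -> Dict[str, Track]:
    """Poisson background tracks, reproducible per seed.

    ``density`` is in regions per Mbp per track; density 0 yields empty
    tracks.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = region_length_range
    tracks: Dict[str, Track] = {}
    for name in track_names:
        track = Track(name)
        for chrom, length in genome.items():
            n = rng.poisson(density * length / 1e6)
            if n == 0:
                continue
            lengths = rng.integers(lo, hi + 1, size=n)
            starts = rng.integers(0, np.maximum(1, length - lengths), size=n)
            for s, l in zip(starts, lengths):
                track.add(Region(chrom, int(s), int(s + l)))
        track.sort()
        tracks[name] = track
    return tracks


def _pattern_extent(pattern: Pattern) -> Tuple[int, int]:
    centers = [c for t in pattern.matchable_tracks() for c in t.centers]
    return min(centers), max(centers)


def plant_occurrences(
    tracks: Dict[str, Track],
    spec: PlantSpec,
) -> Tuple[Dict[str, Track], List[PlantedOccurrence]]:
    """Insert jittered pattern occurrences into (copies of) the tracks.

    Origins are drawn uniformly, rejecting any placement closer than twice
    the pattern span to an already-planted occurrence or to a chromosome
    end.  Returns the augmented tracks and the ground-truth list.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pattern = spec.pattern
    lo_q, hi_q = _pattern_extent(pattern)
    span = max(hi_q - lo_q, 1)
    margin = span + spec.jitter + max(spec.region_length) + 1
    guard = 2 * span  # min distance between planted origins

    out = {name: t.copy() for name, t in tracks.items()}
    for pt in pattern.matchable_tracks():
        out.setdefault(pt.target_track_name, Track(pt.target_track_name))

    chroms = sorted(spec.genome)
    weights = np.array([spec.genome[c] for c in chroms], dtype=float)
    usable = weights - 2 * margin
    if spec.n_occurrences and (usable <= 0).all():
        raise GenomeTooSmall("no chromosome can hold the pattern span")
    weights = np.maximum(usable, 0.0)
    weights /= weights.sum()

    placed: Dict[str, List[int]] = {c: [] for c in chroms}
    truth: List[PlantedOccurrence] = []
    max_tries = 1000 * max(spec.n_occurrences, 1)
    tries = 0
    while len(truth) < spec.n_occurrences:
        tries += 1
        if tries > max_tries:
            raise GenomeTooSmall(
                f"could not place {spec.n_occurrences} non-overlapping "
                f"occurrences after {max_tries} tries")
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = spec.genome[chrom]
        origin = int(rng.integers(margin, length - margin))
        if any(abs(origin - o) < guard + span for o in placed[chrom]):
            continue
        occ = PlantedOccurrence(chrom=chrom, origin=origin,
                                span=(origin + lo_q, origin + hi_q))
        lo_len, hi_len = spec.region_length
        for pt in pattern.matchable_tracks():
            for i, q in enumerate(pt.centers):
                jit = int(rng.integers(-spec.jitter, spec.jitter + 1)) \
                    if spec.jitter else 0
                center = origin + q + jit
                rlen = int(rng.integers(lo_len, hi_len + 1))
                start = max(0, center - rlen // 2)
                region = Region(chrom, start, start + rlen)
                out[pt.target_track_name].add(region)
                occ.regions[(pt.name, i)] = region
        placed[chrom].append(origin)
        truth.append(occ)
    for t in out.values():
        t.sort()
    return out, truth


def generate_instance(spec: PlantSpec) -> Tuple[Dict[str, Track],
                                                List[PlantedOccurrence]]:
    """Background + planted occurrences for every matchable pattern track."""
    names = sorted({pt.target_track_name
                    for pt in spec.pattern.matchable_tracks()})
    tracks = generate_background(spec.genome, spec.background_density,
                                 spec.region_length, spec.seed, names)
    return plant_occurrences(tracks, spec)


def match_truth(results: Sequence[Matching],
                truth: Sequence[PlantedOccurrence],
                min_score: float = 0.5) -> List[bool]:
    """Which planted occurrences are recovered by a result set?

    A planted occurrence counts as recovered when some matching with score
    above ``min_score`` has a span overlapping the occurrence's span.
    Unambiguous because planted spans are far apart by construction.
    """
    spans_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for m in results:
        if m.score > min_score:
            spans_by_chrom.setdefault(m.chrom, []).append(m.span)
    hits = []
    for occ in truth:
        spans = spans_by_chrom.get(occ.chrom, [])
        hits.append(any(s < occ.span[1] and occ.span[0] < e for s, e in spans))
    return hits


def benchmark_pattern(window: Optional[int] = None,
                      max_results: int = 2000,
                      min_score: float = 0.0) -> Pattern:
    """The standard 4-track / 6-region benchmark pattern.

    Two perfect tracks (a 2-region mark plus a 1-region mark) and two
    partial tracks (2 + 1 regions) spanning 8 kb — a stand-in for a
    multi-histone-mark regulatory-element shape.
    """
    return Pattern(
        name="benchmark",
        params=SearchParams(window=window, max_results=max_results,
                            min_score=min_score),
        tracks=[
            PatternTrack("markA", "markA", "perfect", centers=[0, 5000]),
            PatternTrack("markB", "markB", "perfect", centers=[2000]),
            PatternTrack("cofactor1", "cofactor1", "partial", centers=[3500, 8000]),
            PatternTrack("cofactor2", "cofactor2", "partial", centers=[6500]),
        ],
    )


def place_decoy_tss(
    truth: Sequence[PlantedOccurrence],
    genome: Dict[str, int],
    n_sites: int = 20,
    clearance: int = 25_000,
    seed: int = 0,
) -> Track:
    """A decoy TSS track whose sites keep ``clearance`` bp away from every
    planted span, so a negative filter built on it cannot reject true
    occurrences.  Used to exercise negative-track semantics on synthetic
    data."""
    rng = np.random.default_rng(seed + 2)
    spans: Dict[str, List[Tuple[int, int]]] = {}
    for occ in truth:
        spans.setdefault(occ.chrom, []).append(occ.span)
    track = Track("TSS")
    chroms = sorted(genome)
    placed = 0
    tries = 0
    while placed < n_sites and tries < 10_000 * max(n_sites, 1):
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, genome[chrom]))
        if any(s - clearance < pos < e + clearance
               for s, e in spans.get(chrom, [])):
            continue
        track.add(Region(chrom, pos, pos + 1, name=f"gene{placed + 1}"))
        placed += 1
    track.sort()
    return track
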