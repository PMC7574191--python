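"""Domain types and coordinate conventions.

All coordinates are 0-based, half-open (BED convention): a region covers
``[start, end)`` with ``end > start``.  The search model reduces each region
to a single point — its center, ``floor((start + end) / 2)`` — so structural
similarity depends only on inter-region distances, never on absolute genomic
position.  Region lengths, when relevant, travel as the implicit numeric
attribute ``"length"``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Tuple

from .errors import InvalidRegion, MissingMate, NoPerfectTrack

UNMATCHED = None  # sentinel value for a pattern region with no target match


class TrackType(str, enum.Enum):
    """Matching semantics of a pattern track.

    - ``perfect``: regions must be present in every result.
    - ``partial``: regions may be missing; absence lowers the score.
    - ``negative``: results whose span touches these regions (after
      extension by ``negative_distance``) are removed.
    - ``valid_area``: target regions outside the union of these regions
      are discarded before the search.
    - ``loop``: paired regions (e.g. chromatin-contact anchors); regions of
      other tracks overlapping one anchor are mirrored to the other.
    """

    PERFECT = "perfect"
    PARTIAL = "partial"
    NEGATIVE = "negative"
    VALID_AREA = "valid_area"
    LOOP = "loop"


#: track types whose regions participate in the matching/scoring itself
MATCHABLE_TYPES = (TrackType.PERFECT, TrackType.PARTIAL)


@dataclass
class Region:
    """One genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    name : str, optional
        Free-text label (BED column 4): annotation label, gene name(s).
    attributes : dict, optional
        Numeric attributes (e.g. ``{"score": 7.5}``); all values finite.
    mate : Region, optional
        Paired region — loop tracks only.
    loop_derived : bool
        True for copies created by loop projection.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    attributes: Optional[Dict[str, float]] = None
    mate: Optional["Region"] = field(default=None, repr=False)
    loop_derived: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise InvalidRegion(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.attributes:
            for k, v in self.attributes.items():
                if not math.isfinite(v):
                    raise InvalidRegion(f"attribute {k!r} is not finite: {v}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def attribute_value(self, key: str) -> Optional[float]:
        """Look up an attribute; ``"length"`` is implicit for every region."""
        if self.attributes and key in self.attributes:
            return float(self.attributes[key])
        if key == "length":
            return float(self.length)
        return None

    def overlaps(self, start: int, end: int) -> bool:
        """>= 1 bp intersection with half-open [start, end)."""
        return self.start < end and start < self.end

    def translated(self, offset: int) -> "Region":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def sort_key(self) -> Tuple[int, int]:
        return (self.start, self.end)


def region_center(r: Region) -> int:
    """Center point of a region: ``floor((start + end) / 2)``.

    Ties on even lengths break toward the lower coordinate, which keeps the
    center translation-equivariant: ``center(r + k) == center(r) + k``.
    """
    return (r.start + r.end) // 2


class Track:
    """A named, chromosome-partitioned, coordinate-sorted set of regions.

    Regions are held per chromosome, sorted ascending by ``(start, end)``.
    ``track_type`` declares default matching semantics (a pattern may
    override it); ``negative_distance`` is the symmetric extension applied
    to negative regions before overlap rejection.
    """

    def __init__(
        self,
        name: str,
        regions: Optional[Dict[str, List[Region]]] = None,
        track_type: TrackType = TrackType.PERFECT,
        negative_distance: int = 0,
    ):
        if negative_distance < 0:
            raise ValueError("negative_distance must be >= 0")
        self.name = name
        self.track_type = TrackType(track_type)
        self.negative_distance = int(negative_distance)
        self.regions: Dict[str, List[Region]] = {}
        if regions:
            for chrom, regs in regions.items():
                self.regions[chrom] = list(regs)
        self.sort()

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def __iter__(self) -> Iterator[Region]:
        for chrom in sorted(self.regions):
            yield from self.regions[chrom]

    def chroms(self) -> List[str]:
        return sorted(self.regions)

    def regions_on(self, chrom: str) -> List[Region]:
        return self.regions.get(chrom, [])

    def add(self, region: Region) -> None:
        self.regions.setdefault(region.chrom, []).append(region)

    def sort(self) -> None:
        for regs in self.regions.values():
            regs.sort(key=Region.sort_key)

    def copy(self) -> "Track":
        t = Track(self.name, track_type=self.track_type,
                  negative_distance=self.negative_distance)
        for chrom, regs in self.regions.items():
            t.regions[chrom] = list(regs)
        return t


def validate_track(track: Track) -> Track:
    """Sort a track per chromosome and enforce region invariants.

    Idempotent.  Raises :class:`~patternscan.errors.MissingMate` if the track
    is a loop track and any region lacks a mate.  (Empty intervals cannot be
    constructed at all — :class:`Region` rejects them.)
    """
    track.sort()
    if track.track_type is TrackType.LOOP:
        for r in track:
            if r.mate is None:
                raise MissingMate(
                    f"loop track {track.name!r}: region "
                    f"{r.chrom}:{r.start}-{r.end} has no mate"
                )
    return track


@dataclass
class SearchParams:
    """Tunable search parameters.

    window : int or None
        Maximum |residual offset| in bp for a target region to count as
        matched.  ``None`` means derive a default from the pattern:
        ``max(500, 5 * pattern_span / M)``.
    max_results : int
        Keep only this many top-scoring matchings (default 2000).
    min_score : float
        Strict lower bound: matchings with score <= min_score are dropped.
    use_attributes : bool
        Blend numeric attribute similarity into per-region scores.
    attribute_weight : float
        Weight of the attribute term in the blend, in [0, 1].
    """

    window: Optional[int] = None
    max_results: int = 2000
    min_score: float = 0.0
    use_attributes: bool = False
    attribute_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.window is not None and self.window <= 0:
            raise ValueError("window must be > 0")
        if self.max_results < 1:
            raise ValueError("max_results must be >= 1")
        if not 0.0 <= self.min_score <= 1.0:
            raise ValueError("min_score must be in [0, 1]")
        if not 0.0 <= self.attribute_weight <= 1.0:
            raise ValueError("attribute_weight must be in [0, 1]")


@dataclass
class PatternTrack:
    """One track of a query pattern.

    ``centers`` are region center offsets relative to an arbitrary pattern
    origin (strictly increasing); only perfect/partial tracks carry centers
    that are matched.  ``attributes`` optionally gives one numeric-attribute
    map per center, compared against target region attributes when
    ``use_attributes`` is on.
    """

    name: str
    target_track_name: str
    track_type: TrackType = TrackType.PERFECT
    centers: List[int] = field(default_factory=list)
    attributes: Optional[List[Optional[Dict[str, float]]]] = None
    negative_distance: int = 0

    def __post_init__(self) -> None:
        self.track_type = TrackType(self.track_type)
        if any(b <= a for a, b in zip(self.centers, self.centers[1:])):
            raise ValueError(
                f"pattern track {self.name!r}: centers must be strictly increasing"
            )
        if self.attributes is not None and len(self.attributes) != len(self.centers):
            raise ValueError(
                f"pattern track {self.name!r}: one attribute map per center required"
            )
        if self.negative_distance < 0:
            raise ValueError("negative_distance must be >= 0")

    @property
    def is_matchable(self) -> bool:
        return self.track_type in MATCHABLE_TYPES


@dataclass
class Pattern:
    """A query pattern: ordered pattern tracks plus search parameters."""

    tracks: List[PatternTrack]
    params: SearchParams = field(default_factory=SearchParams)
    name: str = "pattern"

    def __post_init__(self) -> None:
        if not any(t.track_type is TrackType.PERFECT for t in self.tracks):
            raise NoPerfectTrack(
                f"pattern {self.name!r} has no perfect-matching track"
            )
        if self.total_regions < 1:
            raise ValueError(f"pattern {self.name!r} has no regions to match")

    @property
    def root_track_index(self) -> int:
        """Index of the first perfect track: its first region is the root."""
        for i, t in enumerate(self.tracks):
            if t.track_type is TrackType.PERFECT:
                return i
        raise NoPerfectTrack(self.name)  # unreachable after __post_init__

    @property
    def root_track(self) -> PatternTrack:
        return self.tracks[self.root_track_index]

    @property
    def root_center(self) -> int:
        return self.root_track.centers[0]

    def matchable_tracks(self) -> List[PatternTrack]:
        return [t for t in self.tracks if t.is_matchable]

    @property
    def total_regions(self) -> int:
        """M — total number of matchable pattern regions."""
        return sum(len(t.centers) for t in self.matchable_tracks())

    @property
    def span(self) -> int:
        centers = [c for t in self.matchable_tracks() for c in t.centers]
        return max(centers) - min(centers) if centers else 0

    def resolved_window(self) -> int:
        """Effective match window: explicit value, else 5*span/M with a 500 bp floor."""
        if self.params.window is not None:
            return self.params.window
        m = max(self.total_regions, 1)
        return max(500, int(round(5 * self.span / m)))

    def region_ids(self) -> List[Tuple[str, int]]:
        """Stable ids (track name, center index) for all matchable regions."""
        return [(t.name, i) for t in self.matchable_tracks()
                for i in range(len(t.centers))]


@dataclass
class Matching:
    """One search result.

    ``assignment`` maps (pattern track name, center index) to the matched
    target :class:`Region`, or ``UNMATCHED`` (``None``) for a partial-track
    region with no target inside the window.  ``anchor_offset`` is the
    translation Δ between pattern and target coordinates fixed by the root
    pair; ``cost`` is the squared sum of residual offsets of matched pairs
    relative to Δ (bp²).  ``span`` covers region edges; ``center_span`` the
    centers of the two most extreme matched regions.
    """

    chrom: str
    assignment: Dict[Tuple[str, int], Optional[Region]]
    anchor_offset: int
    cost: float
    per_track_scores: Dict[str, float]
    score: float
    span: Tuple[int, int]
    center_span: Tuple[int, int]
    root_region: Region
    nearest_gene: Optional[str] = None
    gene_distance: Optional[int] = None

    @property
    def matched_track_names(self) -> Tuple[str, ...]:
        """Sorted names of pattern tracks with >= 1 matched region."""
        names = {tname for (tname, _), r in self.assignment.items()
                 if r is not UNMATCHED}
        return tuple(sorted(names))

    def matched_regions(self) -> List[Region]:
        return [r for r in self.assignment.values() if r is not UNMATCHED]

    def assignment_signature(self) -> Tuple:
        """Hashable identity of the assignment, for deduplication."""
        items = []
        for key in sorted(self.assignment):
            r = self.assignment[key]
            items.append((key, None if r is UNMATCHED else (r.chrom, r.start, r.end)))
        return tuple(items)
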