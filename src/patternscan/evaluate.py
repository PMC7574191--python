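"""Benchmark experiments: oracle agreement, planted recovery, scaling.

These drive the package's self-validation: the windowed engine against the
exhaustive oracle on small random instances, recovery of planted pattern
occurrences from Poisson background at fixed study conditions, and the
near-linearithmic runtime growth of the search.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Pattern, PatternTrack, SearchParams, Track, TrackType
from .search import exhaustive_search, search_pattern
from .synthetic import (
    PlantSpec,
    benchmark_pattern,
    generate_background,
    generate_instance,
    match_truth,
    place_decoy_tss,
)

NEGATIVE_TSS_DISTANCE = 20_000  # bp, distal-pattern convention


# ---------------------------------------------------------------------------
# Oracle agreement
# ---------------------------------------------------------------------------

@dataclass
class OracleReport:
    instances: int = 0
    anchors: int = 0
    agreeing_anchors: int = 0
    discrepancies: int = 0

    @property
    def discrepancy_rate(self) -> float:
        return self.discrepancies / self.anchors if self.anchors else 0.0

    @property
    def agreement_percent(self) -> float:
        return 100.0 * self.agreeing_anchors / self.anchors if self.anchors else 100.0


def random_small_instance(rng: np.random.Generator
                          ) -> Tuple[Pattern, Dict[str, Track]]:
    """A random instance with <= 5 pattern regions and <= 50 regions/track."""
    n_tracks = int(rng.integers(1, 4))
    m_total = int(rng.integers(max(n_tracks, 2), 6))
    sizes = np.ones(n_tracks, dtype=int)
    for _ in range(m_total - n_tracks):
        sizes[int(rng.integers(n_tracks))] += 1
    tracks: List[PatternTrack] = []
    for ti, size in enumerate(sizes):
        centers = np.sort(rng.choice(np.arange(0, 10_000, 50),
                                     size=size, replace=False))
        ttype = TrackType.PERFECT if ti == 0 else (
            TrackType.PERFECT if rng.random() < 0.5 else TrackType.PARTIAL)
        tracks.append(PatternTrack(f"t{ti}", f"t{ti}", ttype,
                                   centers=[int(c) for c in centers]))
    pattern = Pattern(tracks=tracks,
                      params=SearchParams(window=int(rng.integers(300, 1500)),
                                          max_results=10_000))
    genome = {"chrT": 200_000}
    n_per_track = int(rng.integers(5, 51))
    targets = generate_background(
        genome, density=n_per_track / 0.2, region_length_range=(100, 400),
        seed=int(rng.integers(2 ** 31)),
        track_names=[f"t{i}" for i in range(n_tracks)])
    return pattern, targets


def _anchor_key(m) -> Tuple:
    r = m.root_region
    return (r.chrom, r.start, r.end)


def oracle_agreement(n_instances: int = 200, seed: int = 0) -> OracleReport:
    """Compare the windowed engine with the exhaustive oracle per anchor.

    For every anchor the oracle reports, the engine must produce a matching
    with identical cost (the oracle only enumerates within-window options,
    so its optimum is always attainable by the windowed search; residual
    disagreements — e.g. boundary-exact partial matches — are counted as
    discrepancies).
    """
    rng = np.random.default_rng(seed)
    report = OracleReport()
    for _ in range(n_instances):
        pattern, targets = random_small_instance(rng)
        engine = search_pattern(pattern, targets)
        oracle = exhaustive_search(pattern, targets)
        by_anchor = {_anchor_key(m): m for m in engine}
        report.instances += 1
        for om in oracle:
            report.anchors += 1
            em = by_anchor.get(_anchor_key(om))
            if em is not None and abs(em.cost - om.cost) <= 1e-6 and \
                    abs(em.score - om.score) <= 1e-9:
                report.agreeing_anchors += 1
            else:
                report.discrepancies += 1
    return report


# ---------------------------------------------------------------------------
# Planted recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    n_planted: int
    n_recovered: int
    n_results: int
    negative_overlaps: int
    min_score: float
    window: int
    jitter: int

    @property
    def recovery_percent(self) -> float:
        return 100.0 * self.n_recovered / self.n_planted if self.n_planted else 100.0


def recovery_experiment(
    seed: int = 0,
    n_occurrences: int = 100,
    background_density: float = 50.0,
    min_score: float = 0.5,
    jitter_fraction: float = 0.2,
    with_negative_tss: bool = True,
) -> RecoveryReport:
    """Plant benchmark-pattern occurrences and measure recovery.

    Study conditions: 10 Mbp toy genome, 4-track/6-region pattern,
    background 50 regions/Mbp/track, uniform jitter 0.2x the match window,
    and (optionally) a decoy negative TSS track extended by 20,000 bp whose
    sites are placed clear of the planted spans.
    """
    pattern = benchmark_pattern(min_score=min_score)
    window = pattern.resolved_window()
    jitter = int(jitter_fraction * window)
    spec = PlantSpec(pattern=pattern, n_occurrences=n_occurrences,
                     jitter=jitter, background_density=background_density,
                     seed=seed)
    targets, truth = generate_instance(spec)

    search_tracks = list(pattern.tracks)
    if with_negative_tss:
        tss = place_decoy_tss(truth, spec.genome,
                              clearance=NEGATIVE_TSS_DISTANCE + 5_000, seed=seed)
        targets["TSS"] = tss
        search_tracks.append(PatternTrack(
            "TSS", "TSS", TrackType.NEGATIVE,
            negative_distance=NEGATIVE_TSS_DISTANCE))
    search_pat = Pattern(tracks=search_tracks, params=pattern.params,
                         name="benchmark_search")

    results = search_pattern(search_pat, targets)
    hits = match_truth(results, truth, min_score=min_score)

    negative_overlaps = 0
    if with_negative_tss:
        d = NEGATIVE_TSS_DISTANCE
        for m in results:
            for r in targets["TSS"].regions_on(m.chrom):
                if r.start - d < m.span[1] and m.span[0] < r.end + d:
                    negative_overlaps += 1
                    break
    return RecoveryReport(
        n_planted=len(truth), n_recovered=int(sum(hits)),
        n_results=len(results), negative_overlaps=negative_overlaps,
        min_score=min_score, window=window, jitter=jitter)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def scaling_pattern() -> Pattern:
    """5-track / 7-region pattern used for runtime scaling runs."""
    base = benchmark_pattern(min_score=0.5)
    tracks = list(base.tracks) + [
        PatternTrack("cofactor3", "cofactor3", TrackType.PARTIAL, centers=[9500])]
    return Pattern(tracks=tracks, params=base.params, name="scaling")


@dataclass
class ScalingReport:
    sizes: List[int] = field(default_factory=list)
    runtimes: List[float] = field(default_factory=list)

    @property
    def ratios(self) -> List[float]:
        return [b / a for a, b in zip(self.runtimes, self.runtimes[1:])]


def scaling_experiment(sizes: Sequence[int] = (10_000, 20_000, 40_000),
                       seed: int = 0, repeats: int = 3) -> ScalingReport:
    """Time the full search at growing background sizes (fixed pattern).

    The genome grows with N at constant density 1,000 regions/Mbp, so N is
    the expected region count per track; each size is timed ``repeats``
    times and the best run kept.
    """
    pattern = scaling_pattern()
    report = ScalingReport()
    for n in sizes:
        genome = {"chrL": int(n * 1000)}  # 1,000 regions/Mbp
        targets = generate_background(
            genome, density=1000.0, region_length_range=(200, 1000),
            seed=seed, track_names=[pt.target_track_name
                                    for pt in pattern.matchable_tracks()])
        best = float("inf")
        for _ in range(repeats):
            t0 = time.perf_counter()
            search_pattern(pattern, targets)
            best = min(best, time.perf_counter() - t0)
        report.sizes.append(n)
        report.runtimes.append(best)
    return report
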