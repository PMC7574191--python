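"""Post-search annotation of matchings.

Nearest gene (TSS closest to the center of the root region), overlap
summaries against a labelled annotation track (e.g. a ChromHMM chromatin
state segmentation), sub-pattern composition counts, and a local
over-representation test (hypergeometric tail + Benjamini-Hochberg) over a
gene→term mapping file.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import Matching, Pattern, PatternTrack, Region, Track, TrackType
from .errors import EmptyUniverse


class NoGeneOnChromosome(Exception):
    """No TSS available on the matching's chromosome (annotation stays empty)."""


# ---------------------------------------------------------------------------
# Nearest gene
# ---------------------------------------------------------------------------

def nearest_gene(matching: Matching, tss_track: Track) -> Tuple[str, int]:
    """Gene whose TSS is closest to the center of the root region.

    Only the matching's own chromosome is searched.  Ties break toward the
    lower coordinate, then the lexicographically smaller gene name.
    Returns ``(gene_name, distance_bp)``.
    """
    regions = tss_track.regions_on(matching.chrom)
    if not regions:
        raise NoGeneOnChromosome(matching.chrom)
    center = matching.root_region.center
    starts = [r.start for r in regions]
    i = bisect_left(starts, center)
    d = min(abs(regions[j].start - center)
            for j in (i - 1, i) if 0 <= j < len(regions))
    # collect every TSS at exactly distance d (several may tie, including
    # distinct genes at the same collapsed coordinate)
    ties: List[Region] = []
    j = i - 1
    while j >= 0 and center - regions[j].start <= d:
        if center - regions[j].start == d:
            ties.append(regions[j])
        j -= 1
    j = i
    while j < len(regions) and regions[j].start - center <= d:
        if regions[j].start - center == d:
            ties.append(regions[j])
        j += 1
    best = min(ties, key=lambda r: (r.start, r.name or ""))
    return best.name or "", d


def annotate_nearest_genes(results: Sequence[Matching],
                           tss_track: Track) -> List[Matching]:
    """Attach nearest gene + distance to every matching (in place)."""
    for m in results:
        try:
            gene, dist = nearest_gene(m, tss_track)
        except NoGeneOnChromosome:
            gene, dist = None, None
        m.nearest_gene, m.gene_distance = gene, dist
    return list(results)


# ---------------------------------------------------------------------------
# Annotation-track overlap
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSummary:
    """Counts of annotation labels over a result set.

    ``label_counts[label]`` = number of matchings whose span overlaps >= 1
    annotation region carrying that label (a matching may count toward
    several labels); ``covered_region_count`` = distinct annotation regions
    overlapped by >= 1 matching span.
    """

    label_counts: Dict[str, int] = field(default_factory=dict)
    matching_count: int = 0
    covered_region_count: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"label": lab, "matchings": n, "total_matchings": self.matching_count,
                 "fraction": n / self.matching_count if self.matching_count else 0.0}
                for lab, n in sorted(self.label_counts.items(),
                                     key=lambda kv: (-kv[1], kv[0]))]
        return pd.DataFrame(rows, columns=["label", "matchings",
                                           "total_matchings", "fraction"])


def annotation_overlap_summary(results: Sequence[Matching],
                               annotation_track: Track) -> AnnotationSummary:
    """Overlap matchings' spans against a labelled annotation track.

    Overlap means >= 1 bp intersection; labels come from the annotation
    regions' BED name column.
    """
    trees: Dict[str, IntervalTree] = {}
    for chrom in annotation_track.chroms():
        trees[chrom] = IntervalTree.from_tuples(
            (r.start, r.end, (idx, r.name or ""))
            for idx, r in enumerate(annotation_track.regions_on(chrom)))
    summary = AnnotationSummary(matching_count=len(results))
    covered: set = set()
    for m in results:
        tree = trees.get(m.chrom)
        if tree is None:
            continue
        labels = set()
        for iv in tree.overlap(m.span[0], m.span[1]):
            idx, label = iv.data
            covered.add((m.chrom, idx))
            labels.add(label)
        for label in labels:
            summary.label_counts[label] = summary.label_counts.get(label, 0) + 1
    summary.covered_region_count = len(covered)
    return summary


# ---------------------------------------------------------------------------
# Sub-pattern composition
# ---------------------------------------------------------------------------

@dataclass
class CompositionSummary:
    """Counts of matchings per exact set of matched pattern tracks."""

    combo_counts: Dict[Tuple[str, ...], int] = field(default_factory=dict)
    matching_count: int = 0

    def ranked(self) -> List[Tuple[Tuple[str, ...], int]]:
        return sorted(self.combo_counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"tracks": ",".join(combo), "n_tracks": len(combo), "matchings": n}
                for combo, n in self.ranked()]
        return pd.DataFrame(rows, columns=["tracks", "n_tracks", "matchings"])


def subpattern_composition(results: Sequence[Matching],
                           pattern: Optional[Pattern] = None) -> CompositionSummary:
    """Partition matchings by the exact set of tracks with >= 1 matched region."""
    summary = CompositionSummary(matching_count=len(results))
    for m in results:
        combo = m.matched_track_names
        summary.combo_counts[combo] = summary.combo_counts.get(combo, 0) + 1
    return summary


def pattern_from_combo(pattern: Pattern, combo: Iterable[str]) -> Pattern:
    """Export a track combination as a new pattern.

    The selected tracks keep their original center offsets but are all
    promoted to perfect matching, mirroring the interactive "search again
    for this combination" workflow.
    """
    combo = set(combo)
    tracks = [
        PatternTrack(name=t.name, target_track_name=t.target_track_name,
                     track_type=TrackType.PERFECT, centers=list(t.centers),
                     attributes=t.attributes)
        for t in pattern.matchable_tracks() if t.name in combo
    ]
    if not tracks:
        raise ValueError("combo selects no pattern tracks")
    return Pattern(tracks=tracks, params=pattern.params,
                   name=pattern.name + "+" + "_".join(sorted(combo)))


# ---------------------------------------------------------------------------
# Over-representation of gene annotations
# ---------------------------------------------------------------------------

def read_gene_terms(path: str) -> Dict[str, List[str]]:
    """Read a 2-column TSV mapping gene -> term (one pair per line)."""
    mapping: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, term = line.split()[:2]
            mapping.setdefault(gene, []).append(term)
    return mapping


def functional_annotation_stub(
    gene_list: Sequence[str],
    gene_terms: Dict[str, List[str]],
    universe: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Local over-representation test over a gene→term table.

    For each term: ``k`` result genes with the term out of ``n`` result
    genes, against ``K`` universe genes with the term out of ``N``;
    p = hypergeometric upper tail P(X >= k); q = Benjamini-Hochberg.
    The universe defaults to all genes in the mapping.
    """
    if universe is None:
        universe = sorted(gene_terms)
    universe_set = set(universe)
    if not universe_set:
        raise EmptyUniverse("background gene universe is empty")
    genes = sorted({g for g in gene_list if g in universe_set})
    n, N = len(genes), len(universe_set)

    terms = sorted({t for g in universe_set for t in gene_terms.get(g, [])})
    rows = []
    for term in terms:
        carriers = {g for g in universe_set if term in gene_terms.get(g, [])}
        K = len(carriers)
        k = len(carriers.intersection(genes))
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p_value": p})
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p_value"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values(["p_value", "term"]).reset_index(drop=True)
    else:
        df["q_value"] = []
    return df
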