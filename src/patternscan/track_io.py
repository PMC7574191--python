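"""Reading and writing the standard interval formats.

BED is read tolerantly (tabs or runs of spaces, ``track``/``browser``/``#``
header lines skipped) and written with tabs.  GTF/GFF gene models are parsed
with :mod:`gffutils`; 1-based inclusive coordinates are converted to 0-based
half-open.  Pattern definitions are JSON; two presets shaped as
multi-histone-mark chromatin-state patterns ship with the package (their
center offsets are fixture values, not measured claims).
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence

import gffutils
import pandas as pd

from .core import (
    Matching,
    Pattern,
    PatternTrack,
    Region,
    SearchParams,
    Track,
    TrackType,
    validate_track,
)
from .errors import ConfigError, InvalidRegion, NoGenesFound, ParseError


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------

_HEADER_PREFIXES = ("track", "browser", "#")


def _data_lines(path: str):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_HEADER_PREFIXES):
                continue
            yield lineno, line.split()


def read_bed(
    path: str,
    track_type: TrackType | str = TrackType.PERFECT,
    name: Optional[str] = None,
    negative_distance: int = 0,
) -> Track:
    """Read a BED3+ file into a validated :class:`Track`.

    Column 4 becomes the region ``name``; a numeric column 5 is stored as
    attribute ``"score"``.  An empty file yields an empty track with a
    warning, not an error.
    """
    track = Track(name or str(path), track_type=TrackType(track_type),
                  negative_distance=negative_distance)
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"expected >= 3 BED columns, got {len(fields)}",
                             path=str(path), line=lineno)
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"non-integer coordinates: {exc}",
                             path=str(path), line=lineno) from None
        attrs = None
        if len(fields) >= 5:
            try:
                attrs = {"score": float(fields[4])}
            except ValueError:
                attrs = None  # non-numeric score column ('.'): ignore
        rname = fields[3] if len(fields) >= 4 else None
        try:
            track.add(Region(chrom, start, end, name=rname, attributes=attrs))
        except InvalidRegion as exc:
            raise ParseError(str(exc), path=str(path), line=lineno) from None
    if len(track) == 0:
        warnings.warn(f"empty track read from {path}", stacklevel=2)
    return validate_track(track)


def write_bed(track: Track, path: str) -> None:
    """Write a track as BED (3, 4 or 5 columns depending on available fields)."""
    with open(path, "w") as fh:
        for r in track:
            cols = [r.chrom, str(r.start), str(r.end)]
            score = r.attributes.get("score") if r.attributes else None
            if r.name is not None or score is not None:
                cols.append(r.name if r.name is not None else ".")
            if score is not None:
                cols.append(f"{score:g}")
            fh.write("\t".join(cols) + "\n")


def read_bedpe(path: str, name: Optional[str] = None) -> Track:
    """Read paired intervals (chrom1 start1 end1 chrom2 start2 end2) as a loop track.

    Both anchors of each pair are added as regions, each holding a ``mate``
    reference to the other.
    """
    track = Track(name or str(path), track_type=TrackType.LOOP)
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ParseError(f"expected >= 6 BEDPE columns, got {len(fields)}",
                             path=str(path), line=lineno)
        try:
            a = Region(fields[0], int(fields[1]), int(fields[2]))
            b = Region(fields[3], int(fields[4]), int(fields[5]))
        except (ValueError, InvalidRegion) as exc:
            raise ParseError(str(exc), path=str(path), line=lineno) from None
        a.mate, b.mate = b, a
        track.add(a)
        track.add(b)
    return validate_track(track)


# ---------------------------------------------------------------------------
# Gene models -> TSS track
# ---------------------------------------------------------------------------

def extract_tss_track(gtf_path: str, name: str = "TSS",
                      feature_types: Sequence[str] = ("gene", "transcript")) -> Track:
    """Extract transcription start sites from a GTF/GFF gene model.

    The TSS of a ``+`` feature is its first base; of a ``-`` feature its
    last.  Each distinct (chrom, tss) yields one 1-bp region; features
    sharing a TSS are collapsed, keeping all gene names (comma-joined).
    """
    try:
        db = gffutils.create_db(
            str(gtf_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise ParseError(f"could not parse gene model: {exc}",
                         path=str(gtf_path)) from None

    sites: Dict[tuple, List[str]] = {}
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            # gffutils keeps GTF 1-based inclusive coords; convert to 0-based
            tss = feat.start - 1 if feat.strand != "-" else feat.end - 1
            gname = (feat.attributes.get("gene_name")
                     or feat.attributes.get("gene_id") or [feat.id])[0]
            names = sites.setdefault((feat.seqid, tss), [])
            if gname not in names:
                names.append(gname)
    if not sites:
        raise NoGenesFound(f"no gene/transcript features in {gtf_path}")

    track = Track(name)
    for (chrom, tss), names in sites.items():
        track.add(Region(chrom, tss, tss + 1, name=",".join(sorted(names))))
    return validate_track(track)


# ---------------------------------------------------------------------------
# Pattern configuration (JSON)
# ---------------------------------------------------------------------------

def pattern_from_dict(cfg: dict) -> Pattern:
    """Build a validated :class:`Pattern` from a config mapping."""
    if "tracks" not in cfg or not isinstance(cfg["tracks"], list):
        raise ConfigError("pattern config needs a 'tracks' list")
    tracks: List[PatternTrack] = []
    for i, tc in enumerate(cfg["tracks"]):
        try:
            tracks.append(PatternTrack(
                name=tc["name"],
                target_track_name=tc.get("target", tc["name"]),
                track_type=TrackType(tc.get("type", "perfect")),
                centers=[int(c) for c in tc.get("centers", [])],
                attributes=tc.get("attributes"),
                negative_distance=int(tc.get("negative_distance", 0)),
            ))
        except KeyError as exc:
            raise ConfigError(f"tracks[{i}]: missing field {exc}") from None
        except ValueError as exc:
            raise ConfigError(f"tracks[{i}]: {exc}") from None
    pc = cfg.get("params", {})
    try:
        params = SearchParams(
            window=pc.get("window"),
            max_results=int(pc.get("max_results", 2000)),
            min_score=float(pc.get("min_score", 0.0)),
            use_attributes=bool(pc.get("use_attributes", False)),
            attribute_weight=float(pc.get("attribute_weight", 0.5)),
        )
    except ValueError as exc:
        raise ConfigError(f"params: {exc}") from None
    try:
        return Pattern(tracks=tracks, params=params,
                       name=cfg.get("name", "pattern"))
    except Exception as exc:
        raise ConfigError(str(exc)) from None


def read_pattern_config(path: str) -> Pattern:
    """Read a JSON pattern definition file."""
    with open(path) as fh:
        try:
            cfg = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid JSON in {path}: {exc}") from None
    return pattern_from_dict(cfg)


def load_preset(name: str) -> Pattern:
    """Load one of the bundled preset patterns (``strong_enhancer``,
    ``active_promoter``)."""
    try:
        text = (resources.files("patternscan") / "presets" / f"{name}.json").read_text()
    except FileNotFoundError:
        raise ConfigError(f"no preset named {name!r}") from None
    return pattern_from_dict(json.loads(text))


def list_presets() -> List[str]:
    folder = resources.files("patternscan") / "presets"
    return sorted(p.name[:-5] for p in folder.iterdir() if p.name.endswith(".json"))


def pattern_to_dict(pattern: Pattern) -> dict:
    return {
        "name": pattern.name,
        "params": {
            "window": pattern.params.window,
            "max_results": pattern.params.max_results,
            "min_score": pattern.params.min_score,
            "use_attributes": pattern.params.use_attributes,
            "attribute_weight": pattern.params.attribute_weight,
        },
        "tracks": [
            {
                "name": t.name,
                "target": t.target_track_name,
                "type": t.track_type.value,
                "centers": list(t.centers),
                **({"attributes": t.attributes} if t.attributes else {}),
                **({"negative_distance": t.negative_distance}
                   if t.negative_distance else {}),
            }
            for t in pattern.tracks
        ],
    }


def write_pattern_config(pattern: Pattern, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(pattern_to_dict(pattern), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Result output
# ---------------------------------------------------------------------------

def matchings_frame(results: Sequence[Matching],
                    track_names: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Tabulate matchings (one row each, ranking order preserved)."""
    if track_names is None:
        seen = []
        for m in results:
            for tname, _ in m.assignment:
                if tname not in seen:
                    seen.append(tname)
        track_names = seen
    track_names = list(track_names)
    rows = []
    for i, m in enumerate(results, start=1):
        row = {
            "rank": i,
            "chrom": m.chrom,
            "start": m.span[0],
            "end": m.span[1],
            "center_start": m.center_span[0],
            "center_end": m.center_span[1],
            "length": m.span[1] - m.span[0],
            "root_center": m.root_region.center,
            "cost": m.cost,
            "score": m.score,
            "matched_tracks": ",".join(m.matched_track_names),
        }
        for tname in track_names:
            row[f"score_{tname}"] = m.per_track_scores.get(tname, float("nan"))
        row["nearest_gene"] = m.nearest_gene if m.nearest_gene is not None else ""
        row["gene_distance"] = (m.gene_distance
                                if m.gene_distance is not None else "")
        rows.append(row)
    columns = (["rank", "chrom", "start", "end", "center_start", "center_end",
                "length", "root_center", "cost", "score", "matched_tracks"]
               + [f"score_{t}" for t in track_names]
               + ["nearest_gene", "gene_distance"])
    return pd.DataFrame(rows, columns=columns)


def read_matchings_tsv(path: str) -> List[Matching]:
    """Reload a result TSV into (lightweight) :class:`Matching` objects.

    Reconstructs what downstream annotation needs — chromosome, span,
    center span, root-region center, scores and the matched track set; the
    full per-region assignment is not serialized and each matched track is
    represented by a single placeholder region covering the span.
    """
    df = pd.read_csv(path, sep="\t")
    results: List[Matching] = []
    for _, row in df.iterrows():
        chrom = str(row["chrom"])
        span = (int(row["start"]), int(row["end"]))
        matched = [t for t in str(row["matched_tracks"]).split(",") if t] \
            if not pd.isna(row["matched_tracks"]) else []
        placeholder = Region(chrom, span[0], span[1])
        rc = int(row["root_center"])
        per_track = {c[len("score_"):]: float(row[c])
                     for c in df.columns if c.startswith("score_")}
        gene = row.get("nearest_gene")
        dist = row.get("gene_distance")
        results.append(Matching(
            chrom=chrom,
            assignment={(t, 0): placeholder for t in matched},
            anchor_offset=0,
            cost=float(row["cost"]),
            per_track_scores=per_track,
            score=float(row["score"]),
            span=span,
            center_span=(int(row["center_start"]), int(row["center_end"])),
            root_region=Region(chrom, rc, rc + 1),
            nearest_gene=None if pd.isna(gene) or gene == "" else str(gene),
            gene_distance=None if pd.isna(dist) or dist == "" else int(dist),
        ))
    return results


def write_matchings(results: Sequence[Matching], bed_path: str, tsv_path: str,
                    track_names: Optional[Iterable[str]] = None) -> None:
    """Write a result set as a BED6 span track plus a detail TSV.

    The BED score column is ``round(1000 * score)``; rows keep ranking order.
    An empty result list produces a valid empty BED and a header-only TSV.
    """
    with open(bed_path, "w") as fh:
        for i, m in enumerate(results, start=1):
            fh.write("\t".join([
                m.chrom, str(m.span[0]), str(m.span[1]),
                f"m{i}", str(round(1000 * m.score)), ".",
            ]) + "\n")
    matchings_frame(results, track_names).to_csv(tsv_path, sep="\t", index=False)
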