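# patternscan

Genome-wide search and ranking of multi-track genomic region patterns.

Epigenomic features — histone-mark peaks, transcription-factor binding
sites, open-chromatin regions, TSSs — live on interval tracks. Regulatory
elements often show up as a *configuration* of such regions: an H3K4me1
peak with H3K27ac ~300 bp away and no H3K4me3 nearby, or two TFs bound at
a fixed spacing inside a DNase-accessible window. `patternscan` takes such
a configuration as a query pattern and finds every structurally similar
occurrence across whole-genome target tracks, ranked by similarity. It is
aimed at people doing regulatory genomics on processed peak/segmentation
data (BED-level), not on raw signal.

## The model

Each region is reduced to its center point. A pattern Q is a list of
center offsets Q_i spread over one or more tracks; a matching f assigns
each pattern region to a target region with center T_f(i). Fixing the
**root pair** — the first region of the first perfect-matching track —
determines a candidate translation Δ = T_f(1) − Q_1, and the cost of the
matching is

    C_f(Q, T) = Σ_i ( T_f(i) − Q_i − Δ )²    [bp²]

Cost 0 means every inter-region distance of the pattern is exactly
preserved; absolute coordinates never matter. The search enumerates every
region of the root target track as an anchor and resolves each remaining
pattern region by a windowed binary search around its expected position
Q_i + Δ — O(M log N) per anchor for M pattern regions and N target
regions. Residuals map to scores in [0, 1] with a linear ramp inside the
match window (s_i = max(0, 1 − |residual_i|/window)); the overall score is
the mean over pattern regions, so a perfect occurrence scores 1.0 and a
missing optional region drags the score down proportionally.

Pattern tracks carry matching semantics:

| type | meaning |
|---|---|
| `perfect` | regions must be present in every result |
| `partial` | regions may be missing; absence lowers the score |
| `negative` | results whose span touches these regions (extended by a distance, e.g. 20,000 bp from TSSs for distal-element searches) are removed |
| `valid_area` | target regions outside these windows are discarded before the search |
| `loop` | paired contact anchors (e.g. from Hi-C); regions overlapping one anchor are projected to the other, so spatially adjacent elements match as if linearly adjacent |

An exhaustive enumeration oracle (`exhaustive_search`) is part of the
package and is tested against the windowed engine on random instances.

## Worked example

```python
from patternscan import (Pattern, PatternTrack, Region, SearchParams,
                         Track, search_pattern)

def track(name, intervals):
    t = Track(name)
    for s, e in intervals:
        t.add(Region("chr1", s, e))
    t.sort()
    return t

pattern = Pattern(
    tracks=[PatternTrack("A", "A", "perfect", centers=[0]),
            PatternTrack("B", "B", "perfect", centers=[1000])],
    params=SearchParams(window=200),
)
origins = [10_000, 50_000, 90_000]
targets = {
    "A": track("A", [(o - 50, o + 50) for o in origins] + [(120_000, 120_100)]),
    "B": track("B", [(o + 950, o + 1050) for o in origins] + [(121_120, 121_220)]),
}
for m in search_pattern(pattern, targets):
    print(f"chr1:{m.span[0]}-{m.span[1]}  score={m.score:.3f}  cost={m.cost:.0f}")
```

prints

```
chr1:9950-11050  score=1.000  cost=0
chr1:49950-51050  score=1.000  cost=0
chr1:89950-91050  score=1.000  cost=0
chr1:120000-121220  score=0.700  cost=14400
```

The three configurations with the exact 1,000 bp spacing score 1.0 at
three different absolute positions; the fourth pair is spaced 1,120 bp, so
its B-region sits 120 bp off the expected position (cost 120² = 14,400
bp², score 1 − 120/200 averaged with the exact root = 0.70).

More in `examples/`: track-type semantics (`02`), the synthetic
planted-pattern benchmark (`03`), result annotation — nearest gene,
segmentation overlap, sub-pattern composition, over-representation
(`04`) — and the shell workflow via the `patternscan` CLI (`05`).

## Command line

```bash
patternscan simulate --seed 11 --out-dir sim/          # synthetic fixtures
patternscan search --pattern sim/pattern.json \
    --track markA=sim/markA.bed --track markB=sim/markB.bed \
    --track cofactor1=sim/cofactor1.bed --track cofactor2=sim/cofactor2.bed \
    --min-score 0.5 --out-prefix run                   # run.bed / run.tsv / run.log
patternscan annotate --results run --tss genes.gtf --annotation states.bed
patternscan compose --results run                      # matched-track combos
```

By default only the 2,000 top-scoring matchings are returned
(`--max-results`), and `--min-score` filters strictly (score > threshold).
Bundled preset patterns (`patternscan presets`) give editable
multi-histone-mark starting points.

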