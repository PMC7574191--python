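# Methods

## Model

A *track* is a chromosome-partitioned, coordinate-sorted sequence of
genomic regions (0-based, half-open; BED convention). The search model
reduces each region to a single point, its center `floor((start+end)/2)`
(floor division for determinism; ties toward the lower coordinate). A
*pattern* Q is an ordered list of pattern tracks, each carrying center
offsets Q_i relative to an arbitrary origin plus matching semantics; a
*matching* f assigns pattern regions to target regions. With the root pair
fixed — the first region of the first perfect track matched to some region
of its target track — the translation Δ = T_f(1) − Q_1 is determined and
the cost is the squared sum of residual offsets relative to Δ:

    C_f(Q,T) = Σ_i (T_f(i) − Q_i − Δ)²   [bp²]

This is translation-invariant by construction: only inter-region distances
enter. Region lengths and other numeric region attributes can optionally
contribute a (dis)similarity term (below); length is exposed as the
implicit attribute `"length"`.

Within one rigid translation class, the per-region optimum is independent
given Δ, so the engine enumerates anchors only on the designated root
track (first perfect track, first center) and resolves every other
pattern region by a windowed binary search at its expected position
Q_i + Δ. Enumerating roots on every pattern track alternately would
re-derive the same translation classes; the exhaustive-oracle comparison
(below) quantifies what, if anything, this simplification misses.
Complexity is O(M log N) per anchor and O(N_root · M log N) overall; the
scaling study measures ≈2.1–2.2× runtime per doubling of N, consistent
with N log N.

## Track-type semantics

- **perfect** — every region must be matched; an unmatched perfect region
  discards the anchor.
- **partial** — regions may stay unmatched; they contribute score 0 and
  no cost term (the cost is defined over matched pairs only; the penalty
  for absence is realized in the ranking through the score).
- **negative** — each negative region is extended by `negative_distance`
  bp on both sides (clamped at 0); a candidate is removed iff its span has
  ≥1 bp overlap with any extended region. Span overlap (rather than
  strict containment) was chosen as the stricter, simpler reading.
- **valid_area** — before the search, every target-track region without
  ≥1 bp overlap with the union of valid-area regions is removed. An
  empty union removes everything (vacuous restriction).
- **loop** — paired regions (BEDPE input; mates may sit on different
  chromosomes). For each pair (A, B), every target region overlapping A
  is copied, translated by `B.start − A.start` onto B's chromosome, and
  vice versa; copies are flagged `loop_derived` and then behave as
  ordinary regions. All regions of one matching share a chromosome;
  loop projection is how trans-positioned elements can participate.

## Scoring

The cost→score map is a design choice isolated in `score_matching`:
per region, `s_i = max(0, 1 − |residual_i|/window)` — a linear ramp that
anchors 1.0 at a perfect match and 0 at the window edge; unmatched
regions score 0. The per-track score is the mean over that track's
regions, and the overall score the unweighted mean over all pattern
regions, so multi-region tracks weigh proportionally to their region
count and `score = 1 ⟺ cost = 0 with nothing unmatched` (attributes
disabled). With attribute matching on, each shared numeric attribute a
contributes `sim = 1 − |a_q − a_t| / max(|a_q|, |a_t|, ε)` (clamped at 0,
mean across attributes) and blends multiplicatively:
`s_i ← s_i · (1 − w + w·sim)` with `w = attribute_weight`.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `window` | max(500, 5·span/M) | bp | maximum residual for a region to count as matched; the default scales with the pattern's characteristic spacing and keeps a 500 bp floor for compact patterns |
| `max_results` | 2000 | – | only the top-scoring matchings are kept |
| `min_score` | 0.0 | – | strict filter (keep score > threshold; 0 disables). With ≥1 perfect track every matching has score > 0, so the default drops nothing |
| `negative_distance` | 0 | bp | per-track extension of negative regions; 20,000 bp is the usual setting for "distal to any TSS" searches, 1,000 bp for promoter-proximal exclusion |
| `attribute_weight` | 0.5 | – | blend weight when attribute matching is enabled |

Ranking is total and deterministic: (score desc, cost asc, chromosome,
span start, span end). Candidates with identical assignments are
deduplicated (identical assignments imply identical cost); distinct
assignments that share regions are all kept — overlap suppression is
deliberately not performed.

## Exhaustive oracle

`exhaustive_search` is an independent reference path: per anchor it
enumerates the full product of per-region candidate sets (every target
region within the window, via linear scans, plus UNMATCHED for partial
regions) and keeps the assignment with maximum score, then minimum cost.
A guard (`max_combinations`, default 5·10⁵) raises on instances too large
to enumerate. On 200 random instances (≤5 pattern regions, ≤50 regions
per track) engine and oracle agree on >99.9% of anchors; the only
disagreement mode observed is the window-boundary tie, where a partial
region sits at exactly |residual| = window (score 0 either way) and the
oracle prefers leaving it unmatched (lower cost) while the engine matches
it. This is reported as a discrepancy, not hidden.

## Synthetic data

The generator emulates processed peak tracks, not reads: per track and
chromosome the region count is Poisson(density · length / 1 Mbp), starts
uniform, lengths uniform in a range (default 200–1,000 bp). Planted
occurrences insert one region per pattern center at
`origin + Q_i + Uniform(−jitter, +jitter)`; jitter is uniform (not
Gaussian) so the maximum residual is bounded and recovery statements are
sharp. Origins are rejected closer than twice the pattern span to each
other, making truth-to-result matching unambiguous, and the decoy TSS
track used for negative-filter runs places its sites at least
`negative_distance + 5 kb` from every planted span by construction — the
negative filter is being tested for *not firing on* true occurrences, so
the fixture must not put forbidden sites on top of them.

The standard benchmark conditions are: 10 Mbp single-chromosome genome,
background 50 regions/Mbp/track, 100 occurrences of a 4-track/6-region
pattern spanning 8 kb (two perfect tracks with 2+1 regions, two partial
with 2+1), jitter 0.2× the window, negative TSS distance 20,000 bp.
Recovery is ≥99% (measured 100%) at score > 0.5. What passing these
tests does **not** show: real chromatin-mark tracks are correlated,
peak densities are non-uniform along the genome, and peak widths are
mark-dependent — none of which the generator models. The benchmark
validates the search mechanics, not biological discovery performance.

## Numerical choices and degenerate inputs

- Integer coordinates throughout; cost in float64 (exact for residuals
  below 2²⁶ bp).
- Nearest-lookup ties break toward the lower coordinate; nearest-gene
  ties toward lower coordinate, then lexicographic gene name.
- Empty target tracks: warning plus empty result list, not an error.
- A pattern must contain ≥1 perfect track (`NoPerfectTrack` otherwise);
  single-region patterns are legal and match every root-track region with
  cost 0.
- The enrichment stub is the standard over-representation test:
  hypergeometric upper tail with Benjamini–Hochberg adjustment, against a
  local gene→term table and an explicit (or mapping-derived) universe.

## Problem sizes used in the self-validation

Oracle comparison: 200 random instances (one to three tracks, M ≤ 5,
≤50 regions/track on a 200 kb toy chromosome). Recovery: the benchmark
conditions above. Scaling: 5 tracks at N = 10⁴, 2·10⁴ and 4·10⁴ expected
regions per track (genome grown with N at constant density 1,000
regions/Mbp), best of 3 timed runs per size. These sizes were chosen to
exercise the N log N behaviour while staying desk-scale; the method
itself has no intrinsic size limit beyond memory.

## Known limitations

- Matchings are intra-chromosomal; loop projection is the only mechanism
  by which trans-positioned features participate.
- Strand is ignored in the matching model; continuous-signal tracks
  (WIG/bigWig) are out of scope — the center-point model requires
  discrete regions.
- The pattern↔target track mapping is 1:1 by name.
- The windowed engine can differ from the unconstrained optimum when the
  true best partner of a region lies outside the window; the window is
  the user's precision/recall dial.
- Bundled presets are editable multi-histone-mark shapes with fixture
  offsets; they are starting points, not measured distances.
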