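"""Minimal search: find a two-track spacing pattern in toy tracks.

The pattern asks for a region on track A and a region on track B about
1 kb downstream.  Three such configurations are planted at different
absolute positions; the search finds all three because only inter-region
distances matter, plus one imperfect occurrence that is ranked lower.
"""

from patternscan import (
    Pattern, PatternTrack, Region, SearchParams, Track, search_pattern,
)


def track(name, intervals):
    t = Track(name)
    for s, e in intervals:
        t.add(Region("chr1", s, e))
    t.sort()
    return t


pattern = Pattern(
    tracks=[
        PatternTrack("A", "A", "perfect", centers=[0]),
        PatternTrack("B", "B", "perfect", centers=[1000]),
    ],
    params=SearchParams(window=200),
)

origins = [10_000, 50_000, 90_000]
targets = {
    "A": track("A", [(o - 50, o + 50) for o in origins] + [(120_000, 120_100)]),
    "B": track("B", [(o + 950, o + 1050) for o in origins]
               + [(121_120, 121_220)]),  # 1,120 bp spacing: imperfect
}

results = search_pattern(pattern, targets)
print(f"{len(results)} matchings (score 1.0 = exact spacing):")
for m in results:
    print(f"  chr1:{m.span[0]}-{m.span[1]}  score={m.score:.3f}  "
          f"cost={m.cost:.0f} bp^2")
print("The three planted 1,000 bp configurations score 1.0; the 1,120 bp")
print("one scores lower (residual 120 bp inside a 200 bp window).")
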