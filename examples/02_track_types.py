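"""Track-type semantics: partial, negative, valid-area and loop tracks.

One hand-built instance per semantics, each printing what changed and why.
"""

from patternscan import (
    Pattern, PatternTrack, Region, SearchParams, Track, search_pattern,
)


def track(name, intervals, ttype="perfect"):
    t = Track(name, track_type=ttype)
    for s, e in intervals:
        t.add(Region("chr1", s, e))
    t.sort()
    return t


params = SearchParams(window=200)

# --- partial: a missing co-factor lowers the score, not the matching -------
pat = Pattern(tracks=[PatternTrack("A", "A", "perfect", centers=[0]),
                      PatternTrack("cofactor", "cofactor", "partial",
                                   centers=[500])], params=params)
targets = {"A": track("A", [(990, 1010), (4990, 5010)]),
           "cofactor": track("cofactor", [(1490, 1510)])}
for m in search_pattern(pat, targets):
    have = "with" if m.assignment[("cofactor", 0)] else "WITHOUT"
    print(f"partial: matching at {m.span} {have} cofactor, score {m.score:.2f}")

# --- negative: matchings near forbidden sites are removed ------------------
pat = Pattern(tracks=[PatternTrack("A", "A", "perfect", centers=[0]),
                      PatternTrack("TSS", "TSS", "negative",
                                   negative_distance=1000)], params=params)
targets = {"A": track("A", [(990, 1010), (9990, 10010)]),
           "TSS": track("TSS", [(1500, 1501)], "negative")}
kept = search_pattern(pat, targets)
print(f"negative: site at 1,500 extended by 1,000 bp removes the matching "
      f"at 1,000; kept: {[m.span for m in kept]}")

# --- valid area: the search space shrinks to the allowed windows -----------
pat = Pattern(tracks=[PatternTrack("A", "A", "perfect", centers=[0]),
                      PatternTrack("DNase", "DNase", "valid_area")],
              params=params)
targets = {"A": track("A", [(990, 1010), (9990, 10010)]),
           "DNase": track("DNase", [(500, 2000)], "valid_area")}
kept = search_pattern(pat, targets)
print(f"valid area: only regions inside the DNase window survive; "
      f"kept: {[m.span for m in kept]}")

# --- loop: regions are projected across chromatin-contact anchors ----------
loops = Track("L", track_type="loop")
a, b = Region("chr1", 100_500, 102_500), Region("chr1", 500, 2500)
a.mate, b.mate = b, a
loops.add(a)
loops.add(b)
pat = Pattern(tracks=[PatternTrack("A", "A", "perfect", centers=[0]),
                      PatternTrack("B", "B", "perfect", centers=[1000]),
                      PatternTrack("L", "L", "loop")], params=params)
targets = {"A": track("A", [(950, 1050)]),
           "B": track("B", [(101_950, 102_050)]),  # only reachable via loop
           "L": loops}
for m in search_pattern(pat, targets):
    derived = m.assignment[("B", 0)].loop_derived or \
        m.assignment[("A", 0)].loop_derived
    print(f"loop: matching at {m.span}, score {m.score:.2f} "
          f"(uses loop-projected copy: {derived})")
print("Distal regions brought together by a loop match as if adjacent.")
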