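import pytest

from patternscan import Pattern, PatternTrack, Region, SearchParams, Track


def make_track(name, intervals, chrom="chr1", track_type="perfect", **kw):
    """Build a track from (start, end) tuples (or (start, end, name) triples)."""
    t = Track(name, track_type=track_type, **kw)
    for iv in intervals:
        if len(iv) == 3:
            s, e, rname = iv
            t.add(Region(chrom, s, e, name=rname))
        else:
            t.add(Region(chrom, *iv))
    t.sort()
    return t


@pytest.fixture
def two_region_pattern():
    """A minimal 1-track pattern with centers 0 and 100 (window 50)."""
    return Pattern(
        tracks=[PatternTrack("A", "A", "perfect", centers=[0, 100])],
        params=SearchParams(window=50),
    )


@pytest.fixture
def perfect_partial_pattern():
    """Perfect root region at 0 plus a partial region at 400 (window 100)."""
    return Pattern(
        tracks=[
            PatternTrack("A", "A", "perfect", centers=[0]),
            PatternTrack("B", "B", "partial", centers=[400]),
        ],
        params=SearchParams(window=100),
    )
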