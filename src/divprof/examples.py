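"""Small worked examples used in documentation and tests."""

from __future__ import annotations

from .repertoire import ClonalFrequencyDistribution

__all__ = ["intersecting_pair_counts", "intersecting_pair"]

# Two six-clone repertoires whose diversity profiles intersect: repertoire 1
# is the more even (its tail of mid-frequency clones is heavier), repertoire 2
# the more clonally expanded at the top ranks.  Expressed as read counts over
# 100 reads so the clonal frequencies are 0.33, 0.29, 0.28, 0.05, 0.04, 0.01
# and 0.42, 0.30, 0.10, 0.08, 0.05, 0.05.
_PAIR_COUNTS = (
    {"CARDYW": 33, "CAKGTFDYW": 29, "CTRDNW": 28, "CARWGLDYW": 5, "CASSLGW": 4, "CAWSVGQW": 1},
    {"CARNYGMDVW": 42, "CAKDRGYW": 30, "CTTDYFDYW": 10, "CARGGVW": 8, "CASRDGYW": 5, "CAIPTW": 5},
)


def intersecting_pair_counts() -> tuple[dict[str, int], dict[str, int]]:
    """Clone -> read-count tables of the worked intersecting-profile pair."""
    return tuple(dict(c) for c in _PAIR_COUNTS)


def intersecting_pair() -> tuple[ClonalFrequencyDistribution, ClonalFrequencyDistribution]:
    """The worked example as clonal frequency distributions."""
    c1, c2 = intersecting_pair_counts()
    return (
        ClonalFrequencyDistribution.from_counts(c1, sample_id="repertoire_1"),
        ClonalFrequencyDistribution.from_counts(c2, sample_id="repertoire_2"),
    )
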