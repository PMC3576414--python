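import numpy as np
import pandas as pd
import pytest

from fossilrecord.variants import CloneGenotype, FrequencySeries, GenerationScale


def make_series(counts, days, population="p1", totals=None, gens_per_day=6.7):
    """Build a FrequencySeries from {mutation_id: [alt counts]} and a day list."""
    totals = totals or {m: [100] * len(days) for m in counts}
    alt = pd.DataFrame.from_dict(counts, orient="index", columns=days)
    tot = pd.DataFrame.from_dict(totals, orient="index", columns=days)
    return FrequencySeries(population, alt, tot, GenerationScale(gens_per_day))


def clone(cid, muts, pop="p1", ecotype="SS", day=156):
    return CloneGenotype(cid, pop, ecotype, frozenset(muts), day)


@pytest.fixture
def paper_like_ss_clones():
    """Six SS clones across three populations with the sharing structure of
    the study: populations p18 and p20 each have a pair sharing mutations,
    the p19 pair shares nothing (two independent origins)."""
    return [
        clone("18-SS1", {"spoT18", "rbs18", "nadR18"}, pop="p18"),
        clone("18-SS2", {"spoT18", "rbs18", "nadR18", "x18"}, pop="p18"),
        clone("19-SS1", {"spoT19a", "rbs19a", "nadR19a"}, pop="p19"),
        clone("19-SS2", {"spoT19b", "rbs19b", "nadR19b"}, pop="p19"),
        clone("20-SS1", {"spoT20", "rbs20", "nadR20"}, pop="p20"),
        clone("20-SS2", {"spoT20", "rbs20", "nadR20", "mokB/trg20"}, pop="p20"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20130219)
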