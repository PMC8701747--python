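import numpy as np
import pandas as pd
import pytest

from oricycle.fragment_io import FragmentSet, _finalize_frame
from oricycle.synthetic import GenomeLayout, OriginTruth, TimePointSpec


def make_fragments(chrom, starts, lengths, label="test", source=None):
    """Build a FragmentSet directly from start/length arrays."""
    starts = np.asarray(starts, dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    df = pd.DataFrame({"chrom": chrom, "start": starts,
                       "end": starts + lengths})
    if source is not None:
        df["source"] = source
    return FragmentSet(label, _finalize_frame(df))


def make_layout(chrom_len=100_000, dyads=(), origins=(), abf1=(),
                background_rate=0.0, nucleosome_weight=20.0,
                abf1_weight=15.0, chrom="chrS", **kw):
    """Hand-built GenomeLayout: dyads as (pos, fuzz_sd, occupancy) tuples."""
    dyad_df = pd.DataFrame(
        [(chrom, p, sd, occ) for p, sd, occ in dyads],
        columns=["chrom", "position", "fuzziness_sd", "relative_occupancy"])
    layout = GenomeLayout(
        chromosomes=[(chrom, chrom_len)], dyads=dyad_df,
        origins=list(origins), abf1_sites=[(chrom, p) for p in abf1],
        background_rate=background_rate, nucleosome_weight=nucleosome_weight,
        abf1_weight=abf1_weight, disruption_band_bp=kw.pop(
            "disruption_band_bp", 7500.0),
        disrupted_fuzziness_sd=kw.pop("disrupted_fuzziness_sd", 40.0), **kw)
    layout.validate()
    return layout


def make_origin(name="oriX", chrom="chrS", acs=50_000, strand="+",
                cls="G1&G2", efficiency=0.8, activation=None,
                occupancy=None, plus_offsets=None, minus_offset=-129):
    occupancy = occupancy or {"t0": 10.0}
    plus_offsets = plus_offsets or {lab: -minus_offset for lab in occupancy}
    return OriginTruth(name, chrom, acs, strand, cls, efficiency, activation,
                       occupancy, plus_offsets, minus_offset)


def make_tp(label="t0", minutes=0.0, fronts=None):
    return TimePointSpec(label, minutes, fronts or {})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
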