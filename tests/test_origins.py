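"""Origin-level analyses: oriented aggregation, dyad calling, peak averages
and the footprint-efficiency correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oricycle.nucleosome import OccupancyTrack
from oricycle.origins import (OriginAnnotation, call_dyads,
                              efficiency_correlation, footprint_peak_average,
                              load_origins, orient_and_aggregate,
                              oriented_window, save_origins,
                              split_by_efficiency)

from conftest import make_origin


def _gaussian_track(length, peaks, sd=20.0, chrom="chrS"):
    x = np.arange(length, dtype=float)
    v = np.zeros(length)
    for p, h in peaks:
        v += h * np.exp(-0.5 * ((x - p) / sd) ** 2)
    return OccupancyTrack(chrom, v, "nucleosome")


def test_call_dyads_constructed_track():
    """Maxima planted at ACS-80 and ACS+150 give offsets (-80, +150) and
    NFR width 230."""
    acs = 2_000
    track = _gaussian_track(4_000, [(acs - 80, 1.0), (acs + 150, 1.0)])
    origin = make_origin(acs=acs, strand="+")
    profile = oriented_window(track, origin, halfspan=500)
    call = call_dyads(profile, acs_index=500)
    assert (call.minus_one_offset, call.plus_one_offset) == (-80, 150)
    assert call.nfr_width == 230


def test_call_dyads_strand_invariance():
    """Mirroring the track and flipping the strand yields identical offsets."""
    length = 4_000
    acs = 2_000
    plus_track = _gaussian_track(length, [(acs - 80, 1.0), (acs + 150, 0.9)])
    minus_track = OccupancyTrack("chrS", plus_track.values[::-1].copy(),
                                 "nucleosome")
    acs_minus = length - 1 - acs
    o_plus = make_origin(acs=acs, strand="+")
    o_minus = make_origin(acs=acs_minus, strand="-")
    w_plus = oriented_window(plus_track, o_plus, 500)
    w_minus = oriented_window(minus_track, o_minus, 500)
    np.testing.assert_allclose(w_plus, w_minus)
    c1, c2 = call_dyads(w_plus, 500), call_dyads(w_minus, 500)
    assert (c1.minus_one_offset, c1.plus_one_offset) == \
        (c2.minus_one_offset, c2.plus_one_offset)


def test_call_dyads_ties_break_toward_acs():
    profile = np.ones(1_001)   # flat: every position ties
    call = call_dyads(profile, acs_index=500)
    assert call.plus_one_offset == 10 and call.minus_one_offset == -10
    assert call.low_confidence


def test_aggregate_orientation_symmetry():
    """Two mirror-image origins on opposite strands aggregate to either
    oriented profile; a single origin aggregates to its own window."""
    length = 4_000
    acs = 2_000
    t = _gaussian_track(length, [(acs - 80, 1.0), (acs + 150, 0.5)])
    mirrored = OccupancyTrack("chrS", t.values[::-1].copy(), "nucleosome")
    o_plus = make_origin(acs=acs, strand="+")
    o_minus = make_origin(acs=length - 1 - acs, strand="-")
    single, n1 = orient_and_aggregate({"chrS": t}, [o_plus], 500)
    both_a, _ = orient_and_aggregate({"chrS": t}, [o_plus], 500)
    # aggregate over the pair, each seeing its own track
    w2 = oriented_window(mirrored, o_minus, 500)
    pair = np.nanmean([both_a, w2], axis=0)
    np.testing.assert_allclose(pair, single)
    assert n1 == 1


def test_aggregate_skips_origins_near_ends():
    t = _gaussian_track(1_000, [(500, 1.0)])
    near_end = make_origin(acs=100, strand="+")
    ok = make_origin(acs=500, strand="+")
    profile, n = orient_and_aggregate({"chrS": t}, [near_end, ok], 400)
    assert n == 1


def test_footprint_peak_average():
    cols = np.arange(-500, 501)
    constant = pd.DataFrame([np.full(len(cols), 3.0)], index=["t0"],
                            columns=cols)
    assert footprint_peak_average(constant).loc["t0"] == pytest.approx(3.0)
    peaked = pd.DataFrame(
        [np.exp(-0.5 * (cols / 50.0) ** 2), 2 * np.exp(-0.5 * (cols / 50.0) ** 2)],
        index=["t0", "t10"], columns=cols)
    # halfwidth 0: the exact value at the aggregate peak (offset 0)
    at_peak = footprint_peak_average(peaked, halfwidth=0)
    assert at_peak.loc["t0"] == pytest.approx(1.0)
    assert at_peak.loc["t10"] == pytest.approx(2.0)


def test_efficiency_correlation_monotone():
    """Density strictly increasing in efficiency gives rho exactly 1, and the
    log2 transform does not change ranks for positive densities."""
    eff = pd.Series(np.linspace(0.1, 0.9, 20),
                    index=[f"o{i}" for i in range(20)])
    dens = pd.DataFrame({"t0": np.exp(eff * 3).to_numpy()}, index=eff.index)
    out = efficiency_correlation(dens, eff)
    assert out.loc["t0", "rho"] == pytest.approx(1.0)
    assert out.loc["t0", "n"] == 20
    # independent check via rank correlation without the transform
    rho_raw = stats.spearmanr(dens["t0"], eff).statistic
    assert out.loc["t0", "rho"] == pytest.approx(rho_raw)


def test_efficiency_correlation_missing_and_flat():
    eff = pd.Series([0.1, 0.5, np.nan, 0.9], index=list("abcd"))
    dens = pd.DataFrame({"t0": [1.0, 2.0, 3.0, 4.0],
                         "t10": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd"))
    out = efficiency_correlation(dens, eff)
    assert out.loc["t0", "n"] == 3          # pairwise exclusion
    assert out.loc["t10", "flat"]
    assert np.isnan(out.loc["t10", "rho"])


def test_split_by_efficiency():
    origins = [make_origin(name=f"o{i}", efficiency=i / 10, acs=10_000 + i)
               for i in range(10)]
    active, passive = split_by_efficiency(origins, frac=0.2)
    assert {o.name for o in active} == {"o8", "o9"}
    assert {o.name for o in passive} == {"o0", "o1"}


def test_origin_table_roundtrip(tmp_path):
    origins = [
        OriginAnnotation("ARS1623", "chrXVI", 561_000, "+", "G1&G2", 0.85),
        OriginAnnotation("ARS228.5", "chrII", 420_000, "-", "G1only", 0.2),
        OriginAnnotation("ARSX", "chrX", 100_000, "+", None, None),
    ]
    path = tmp_path / "origins.tsv"
    save_origins(origins, path)
    back = load_origins(path)
    assert [(o.name, o.chrom, o.acs_position, o.t_rich_strand,
             o.footprint_class, o.efficiency) for o in back] == \
        [(o.name, o.chrom, o.acs_position, o.t_rich_strand,
          o.footprint_class, o.efficiency) for o in origins]


def test_origin_validation():
    with pytest.raises(ValueError, match="strand"):
        OriginAnnotation("x", "chrI", 100, "fwd")
    with pytest.raises(ValueError, match="efficiency"):
        OriginAnnotation("x", "chrI", 100, "+", None, 1.5)
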