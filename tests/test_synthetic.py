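"""The fragment generator: determinism, planted signals, and bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from oricycle.fragment_io import build_vplot
from oricycle.synthetic import (SimulationConfig, build_layout,
                                build_timepoints, coupled_uniforms,
                                simulate_sample, simulate_timecourse)

from conftest import make_layout, make_origin, make_tp


def small_config(**kw):
    defaults = dict(chromosomes=[["chrS", 100_000]], timepoints_min=[10, 20],
                    n_origins_g1g2=1, n_origins_g1only=1,
                    aggregate_halfspan=500)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_layout_dyad_count_from_spacing():
    """100 kb at 165 bp spacing carries ~600 dyads, minus the cleared NFRs,
    and no dyad sits inside an NFR."""
    config = small_config(n_origins_g1g2=2, n_origins_g1only=0)
    layout = build_layout(config, seed=0)
    n_grid = len(np.arange(165 // 2, 100_000, 165))
    assert n_grid == 606
    # each origin clears < 6 grid dyads around its NFR
    assert 606 - 12 <= len(layout.dyads) < 606
    for o in layout.origins:
        half = abs(o.minus_one_offset)
        inside = layout.dyads[
            (layout.dyads["position"] > o.acs_position - half)
            & (layout.dyads["position"] < o.acs_position + half)]
        assert len(inside) == 0


def test_layout_zero_origins_is_pure_array():
    config = small_config(n_origins_g1g2=0, n_origins_g1only=0,
                          abf1_spacing_bp=10**9)
    layout = build_layout(config, seed=0)
    assert layout.origins == [] and layout.abf1_sites == []
    assert len(layout.dyads) == 606


def test_layout_deterministic():
    a = build_layout(small_config(), seed=3)
    b = build_layout(small_config(), seed=3)
    pd.testing.assert_frame_equal(a.dyads, b.dyads)
    assert [(o.name, o.acs_position, o.efficiency) for o in a.origins] == \
        [(o.name, o.acs_position, o.efficiency) for o in b.origins]


def test_layout_rejects_crowded_origins():
    config = small_config(chromosomes=[["chrS", 10_000]], n_origins_g1g2=4,
                          n_origins_g1only=4, aggregate_halfspan=1000)
    with pytest.raises(ValueError, match="closer than"):
        build_layout(config, seed=0)


def test_simulate_deterministic():
    layout = build_layout(small_config(), seed=1)
    tp = build_timepoints(small_config(), layout)[2]
    a = simulate_sample(layout, tp, 5_000, seed=99)
    b = simulate_sample(layout, tp, 5_000, seed=99)
    pd.testing.assert_frame_equal(a.frags, b.frags)


def test_zero_jitter_midpoints_hit_dyads():
    """With fuzziness 0 and no background every nucleosomal midpoint lands
    exactly on its dyad (away from chromosome ends)."""
    dyads = [(p, 0.0, 1.0) for p in range(1_000, 20_000, 165)]
    layout = make_layout(chrom_len=21_000, dyads=dyads)
    fs = simulate_sample(layout, make_tp(), 3_000, seed=5)
    dyad_pos = np.array([p for p, _, _ in dyads])
    mids = fs.frags["midpoint"].to_numpy()
    nearest = dyad_pos[np.argmin(np.abs(mids[:, None] - dyad_pos[None, :]),
                                 axis=1)]
    assert np.abs(mids - nearest).max() <= 1


def test_footprint_fraction_binomial():
    """Weights set for a 10% footprint share: the sub-120 bp count at depth
    10,000 falls within 3 binomial SDs of 1,000."""
    acs = 25_000
    dyads = [(p, 10.0, 1.0) for p in range(1_000, 50_000, 165)
             if abs(p - acs) > 129 + 82]
    n_dyads = len(dyads)
    # single footprint site carrying 1/9 of the nucleosome weight total
    layout = make_layout(
        chrom_len=51_000, dyads=dyads, nucleosome_weight=20.0,
        origins=[make_origin(acs=acs,
                             occupancy={"t0": (n_dyads + 2) * 20.0 / 9.0})])
    fs = simulate_sample(layout, make_tp(), 10_000, seed=11)
    n_small = int((fs.frags["length"] < 120).sum())
    sd = np.sqrt(10_000 * 0.1 * 0.9)
    assert abs(n_small - 1_000) <= 3 * sd


def test_source_counts_sum_to_depth():
    layout = build_layout(small_config(), seed=1)
    tp = build_timepoints(small_config(), layout)[0]
    fs = simulate_sample(layout, tp, 7_777, seed=2)
    assert len(fs) == 7_777
    counts = fs.frags["source"].value_counts()
    assert counts.sum() == 7_777
    assert set(counts.index) <= {"nucleosome", "footprint", "background"}


def test_replicated_region_doubles_coverage():
    """A region fully behind the fork receives twice the fragments of a
    matched unreplicated region (3-SD Poisson tolerance)."""
    layout = make_layout(chrom_len=100_000, background_rate=1.0,
                         origins=[make_origin(acs=25_000, activation=10.0,
                                              occupancy={"t30": 10.0})])
    tp = make_tp("t30", 30.0, fronts={"oriX": 10_000})
    fs = simulate_sample(layout, tp, 60_000, seed=3)
    mids = fs.frags["midpoint"].to_numpy()
    n_rep = int(((mids >= 17_000) & (mids < 33_000)).sum())    # replicated
    n_un = int(((mids >= 60_000) & (mids < 76_000)).sum())     # matched size
    ratio = n_rep / n_un
    sd = ratio * np.sqrt(1 / n_rep + 1 / n_un)
    assert abs(ratio - 2.0) <= 3 * sd


def test_size_mixture_fraction():
    """The sub-120 bp fraction converges to the footprint share plus the
    sub-120 share of the uniform background."""
    layout = make_layout(chrom_len=100_000, background_rate=1.0,
                         origins=[make_origin(acs=50_000,
                                              occupancy={"t0": 25_000.0})])
    fs = simulate_sample(layout, make_tp(), 40_000, seed=4)
    w_fp = 25_000.0
    w_bg = 100_000.0
    p_small_bg = (119 - 20 + 1) / (250 - 20 + 1)
    # planted -1/+1 dyads contribute nucleosome weight 2 * 20
    w_nuc = 2 * 20.0
    expected = (w_fp + w_bg * p_small_bg) / (w_fp + w_bg + w_nuc)
    frac = (fs.frags["length"] < 120).mean()
    sd = np.sqrt(expected * (1 - expected) / 40_000)
    assert abs(frac - expected) <= 3 * sd


def test_timecourse_cardinality_and_labels():
    config = small_config(timepoints_min=list(range(10, 151, 10)))
    layout = build_layout(config, seed=0)
    tps = build_timepoints(config, layout)
    assert len(tps) == 16                    # alpha + 15 released samples
    sets, truth = simulate_timecourse(layout, tps, 500, 2, master_seed=1)
    assert len(sets) == 32
    keys = {(fs.label, fs.replicate) for fs in sets}
    assert len(keys) == 32
    assert len(truth.seeds) == 32
    # source bookkeeping covers every sample
    assert truth.counts_by_source.groupby(["time", "replicate"])["count"] \
        .sum().eq(500).all()


def test_timecourse_duplicate_labels_rejected():
    layout = build_layout(small_config(), seed=0)
    tp = build_timepoints(small_config(), layout)[0]
    with pytest.raises(ValueError, match="duplicate"):
        simulate_timecourse(layout, [tp, tp], 100, 1)


def test_zero_depth_is_pipeline_safe():
    layout = build_layout(small_config(), seed=0)
    tp = build_timepoints(small_config(), layout)[0]
    fs = simulate_sample(layout, tp, 0, seed=1)
    assert len(fs) == 0
    vp = build_vplot(fs, ("chrS", 0, 1_000))
    assert vp.total() == 0


def test_replication_fronts_monotone():
    config = small_config(timepoints_min=list(range(10, 151, 10)))
    layout = build_layout(config, seed=0)
    tps = build_timepoints(config, layout)
    for o in layout.origins:
        fronts = [tp.replication_front_bp[o.name] for tp in tps]
        assert all(b >= a for a, b in zip(fronts, fronts[1:]))
        if o.activation_time is None:
            assert max(fronts) == 0.0


def test_coupled_uniforms_hit_target_spearman(rng):
    from scipy import stats
    u1, u2 = coupled_uniforms(20_000, 0.6, rng)
    rho = stats.spearmanr(u1, u2).statistic
    assert rho == pytest.approx(0.6, abs=0.02)


def test_truth_tables_roundtrip(tmp_path):
    config = small_config()
    layout = build_layout(config, seed=0)
    tps = build_timepoints(config, layout)
    _, truth = simulate_timecourse(layout, tps, 200, 1, master_seed=0)
    truth.write(tmp_path)
    origins = pd.read_csv(tmp_path / "truth_origins.tsv", sep="\t")
    assert list(origins["name"]) == [o.name for o in layout.origins]
    occ = pd.read_csv(tmp_path / "truth_occupancy.tsv", sep="\t",
                      index_col="time")
    assert occ.shape == (len(tps), len(layout.origins))
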