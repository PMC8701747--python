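"""Reference pileup, 2D kernel fitting, cross-correlation scoring and
copy-number normalization."""

import numpy as np
import pytest

from oricycle.equalize import merge_matched
from oricycle.fragment_io import build_vplot
from oricycle.nucleosome import (CopyNumberTrack, aggregate_reference_pileup,
                                 compute_copy_number, copy_number_track,
                                 fit_kernel, normalize_track,
                                 nucleosome_score_track, score_nucleosomes)

from conftest import make_fragments

W = 100


def _pileup_two_point(pos_var=1600.0, size_var=400.0):
    """Symmetric two-point-mass pileup with exactly the given marginal
    variances: mass at offsets +/-sqrt(pos_var), sizes 166 +/- sqrt(size_var)."""
    pileup = np.zeros((231, 2 * W + 1), dtype=np.int64)
    dp, ds = int(np.sqrt(pos_var)), int(np.sqrt(size_var))
    for off in (-dp, dp):
        for size in (166 - ds, 166 + ds):
            pileup[size - 20, off + W] += 25
    return pileup


def test_pileup_single_fragment_at_dyad():
    fs = make_fragments("chrI", [500 - 83], [166])
    pileup = aggregate_reference_pileup(fs, [("chrI", 500)], halfwidth=W)
    assert pileup.sum() == 1
    assert pileup[166 - 20, W] == 1


def test_pileup_counting_oracle(rng):
    """Pileup totals and entries match a naive double loop."""
    starts = rng.integers(0, 5_000, size=800)
    lengths = rng.integers(20, 251, size=800)
    fs = make_fragments("chrI", starts, lengths)
    dyads = [("chrI", int(p)) for p in rng.integers(200, 4_800, size=5)]
    pileup = aggregate_reference_pileup(fs, dyads, halfwidth=W)
    brute = np.zeros_like(pileup)
    for s, l in zip(starts, lengths):
        mid = s + l // 2
        for _, d in dyads:
            if abs(mid - d) <= W:
                brute[l - 20, mid - d + W] += 1
    np.testing.assert_array_equal(pileup, brute)


def test_pileup_skips_off_chromosome_dyads():
    fs = make_fragments("chrI", [100], [166])
    pileup = aggregate_reference_pileup(
        fs, [("chrI", 183), ("chrI", 999_999)], halfwidth=W,
        chrom_lengths={"chrI": 1_000})
    assert pileup.sum() == 1


def test_kernel_variance_shrinkage():
    """Kernel variances are 1/4 (position) and 1/16 (size) of the pileup's
    marginal variances: 1600 -> 400 and 400 -> 25."""
    kernel = fit_kernel(_pileup_two_point(), halfwidth=W)
    assert kernel.var_pos == pytest.approx(400.0)
    assert kernel.var_size == pytest.approx(25.0)
    assert kernel.mu_pos == pytest.approx(0.0)
    assert kernel.mu_size == pytest.approx(166.0)


def test_kernel_normalized_and_separable():
    kernel = fit_kernel(_pileup_two_point(), halfwidth=W)
    w = kernel.weights
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(w >= 0)
    np.testing.assert_allclose(w, np.outer(kernel.g_size, kernel.f_pos),
                               rtol=1e-12)


def test_kernel_degenerate_pileup_rejected():
    pileup = np.zeros((231, 2 * W + 1), dtype=np.int64)
    pileup[166 - 20, W] = 10      # all mass at one grid point
    with pytest.raises(ValueError, match="degenerate|variance"):
        fit_kernel(pileup, halfwidth=W)
    with pytest.raises(ValueError, match="empty"):
        fit_kernel(np.zeros((231, 2 * W + 1)), halfwidth=W)


@pytest.fixture(scope="module")
def kernel():
    return fit_kernel(_pileup_two_point(), halfwidth=W)


def test_score_empty_vplot(kernel):
    fs = make_fragments("chrI", [], [])
    track = score_nucleosomes(build_vplot(fs, ("chrI", 0, 500)), kernel)
    assert np.all(track.values == 0)


def test_score_single_fragment_peaks_at_midpoint(kernel):
    mid = 600
    size = int(round(kernel.mu_size))
    fs = make_fragments("chrI", [mid - size // 2], [size])
    track = score_nucleosomes(build_vplot(fs, ("chrI", 0, 1200)), kernel)
    assert track.start + int(np.argmax(track.values)) == mid


def test_score_brute_force_oracle(kernel, rng):
    """Cross-correlation equals the naive double loop over fragments at 100
    random positions, to 1e-9 relative tolerance."""
    starts = rng.integers(0, 3_000, size=600)
    lengths = rng.integers(20, 251, size=600)
    fs = make_fragments("chrI", starts, lengths)
    region = ("chrI", 0, 3_300)
    track = score_nucleosomes(build_vplot(fs, region), kernel)
    mids = starts + lengths // 2
    positions = rng.integers(W, 3_300 - W, size=100)
    for p in positions:
        expected = 0.0
        for m, l in zip(mids, lengths):
            d = m - p
            if abs(d) <= W and 20 <= l <= 250:
                expected += kernel.g_size[l - 20] * kernel.f_pos[d + W]
        assert track.values[p] == pytest.approx(expected, rel=1e-9, abs=1e-15)


def test_score_linearity(kernel, rng):
    a = make_fragments("chrI", rng.integers(0, 900, 200),
                       rng.integers(100, 200, 200), label="t0")
    b = make_fragments("chrI", rng.integers(0, 900, 300),
                       rng.integers(100, 200, 300), label="t0")
    region = ("chrI", 0, 1_200)
    merged = merge_matched(a, b)
    sa = score_nucleosomes(build_vplot(a, region), kernel).values
    sb = score_nucleosomes(build_vplot(b, region), kernel).values
    sm = score_nucleosomes(build_vplot(merged, region), kernel).values
    np.testing.assert_allclose(sm, sa + sb, rtol=1e-12)


def test_score_translation_equivariance(kernel, rng):
    starts = rng.integers(300, 900, 150)
    lengths = rng.integers(120, 220, 150)
    delta = 41
    s0 = score_nucleosomes(
        build_vplot(make_fragments("chrI", starts, lengths),
                    ("chrI", 0, 1500)), kernel).values
    s1 = score_nucleosomes(
        build_vplot(make_fragments("chrI", starts + delta, lengths),
                    ("chrI", delta, 1500 + delta)), kernel).values
    np.testing.assert_allclose(s0, s1, rtol=1e-12)


def test_track_matches_region_scoring(kernel, rng):
    """The separable genome-scale path equals region V-plot scoring."""
    fs = make_fragments("chrI", rng.integers(0, 1_900, 400),
                        rng.integers(20, 251, 400))
    whole = score_nucleosomes(build_vplot(fs, ("chrI", 0, 2_000)), kernel)
    fast = nucleosome_score_track(fs, "chrI", 2_000, kernel)
    np.testing.assert_allclose(fast.values, whole.values, rtol=1e-9)


# ---- copy number -----------------------------------------------------------

def test_copy_number_identity():
    fs = make_fragments("chrI", np.arange(100) * 10, [150] * 100, label="a")
    assert compute_copy_number(fs, fs, "chrI", 500) == pytest.approx(1.0)


def test_copy_number_ratio_arithmetic():
    """100/10,000 in the reference window vs 400/20,000 gives ratio 2."""
    half = 500
    ref = make_fragments(
        "chrI",
        np.r_[np.linspace(5_000 - half, 5_000 + half - 1, 100).astype(int),
              np.full(9_900, 50_000)],
        [100] * 10_000, label="ref")
    t = make_fragments(
        "chrI",
        np.r_[np.linspace(5_000 - half, 5_000 + half - 1, 400).astype(int),
              np.full(19_600, 50_000)],
        [100] * 20_000, label="t")
    # midpoints = start + 50, so center the window at 5050
    assert compute_copy_number(t, ref, "chrI", 5_050) == pytest.approx(2.0)


def test_copy_number_missing_reference_window():
    ref = make_fragments("chrI", [50_000], [100], label="ref")
    t = make_fragments("chrI", [5_000], [100], label="t")
    assert np.isnan(compute_copy_number(t, ref, "chrI", 5_050))


def test_copy_number_track_matches_scalar(rng):
    ref = make_fragments("chrI", rng.integers(0, 9_800, 3_000), [100] * 3_000,
                         label="ref")
    t = make_fragments("chrI", rng.integers(0, 9_800, 4_000), [100] * 4_000,
                       label="t")
    track = copy_number_track(t, ref, "chrI", 10_000)
    for p in (600, 5_000, 9_000):
        assert track.values[p] == pytest.approx(
            compute_copy_number(t, ref, "chrI", p), rel=1e-12)


def test_normalize_track():
    from oricycle.nucleosome import OccupancyTrack
    track = OccupancyTrack("chrI", np.array([2.0, 4.0, 6.0]), "nucleosome")
    halved = normalize_track(track, CopyNumberTrack("chrI", np.full(3, 2.0)))
    np.testing.assert_allclose(halved.values, [1.0, 2.0, 3.0])
    ident = normalize_track(track, CopyNumberTrack("chrI", np.ones(3)))
    np.testing.assert_allclose(ident.values, track.values)
    bad = normalize_track(track, CopyNumberTrack("chrI",
                                                 np.array([1.0, 0.0, np.nan])))
    assert np.isnan(bad.values[1]) and np.isnan(bad.values[2])
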