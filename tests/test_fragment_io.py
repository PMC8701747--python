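"""Fragment parsing, exclusion filters and V-plot construction."""

import numpy as np
import pandas as pd
import pytest

from oricycle.fragment_io import (apply_exclusions, build_vplot,
                                  read_fragments, write_bed)

from conftest import make_fragments


def test_bed_record_arithmetic(tmp_path):
    """A 100-266 fragment has length 166 and floor-convention midpoint 183."""
    p = tmp_path / "one.bed"
    p.write_text("chrI\t100\t266\n")
    fs = read_fragments(p)
    assert fs.frags.loc[0, "length"] == 166
    assert fs.frags.loc[0, "midpoint"] == 183


def test_bedpe_equivalent_to_bed(tmp_path, rng):
    """BEDPE pairs collapse to the same records as their BED3 outer spans."""
    starts = rng.integers(0, 10_000, size=20)
    lengths = rng.integers(50, 250, size=20)
    bed = tmp_path / "f.bed"
    bedpe = tmp_path / "f.bedpe"
    with open(bed, "w") as b, open(bedpe, "w") as pe:
        for s, l in zip(starts, lengths):
            b.write(f"chrI\t{s}\t{s + l}\n")
            # read1 covers the left 40 bp, read2 the right 40 bp
            pe.write(f"chrI\t{s}\t{s + 40}\tchrI\t{s + l - 40}\t{s + l}\n")
    fs_bed = read_fragments(bed)
    fs_pe = read_fragments(bedpe)
    pd.testing.assert_frame_equal(fs_bed.frags, fs_pe.frags)


def test_bam_pairs_counted_once(tmp_path):
    """Forward-strand mates of proper pairs yield one fragment each."""
    sam = tmp_path / "f.sam"
    lines = ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:chrI\tLN:20000"]
    for i, (s, l) in enumerate([(100, 166), (500, 80), (900, 200)]):
        mate_start = s + l - 40
        lines.append(f"r{i}\t99\tchrI\t{s + 1}\t60\t40M\t=\t{mate_start + 1}"
                     f"\t{l}\t{'A' * 40}\t{'I' * 40}")
        lines.append(f"r{i}\t147\tchrI\t{mate_start + 1}\t60\t40M\t=\t{s + 1}"
                     f"\t{-l}\t{'A' * 40}\t{'I' * 40}")
    sam.write_text("\n".join(lines) + "\n")
    fs = read_fragments(sam, fmt="bam")
    assert fs.frags[["start", "length"]].values.tolist() == \
        [[100, 166], [500, 80], [900, 200]]


def test_empty_file(tmp_path):
    p = tmp_path / "empty.bed"
    p.write_text("")
    assert len(read_fragments(p)) == 0


def test_malformed_bed_reports_line(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chrI\t100\t266\nchrI\t300\t250\n")
    with pytest.raises(ValueError, match="line 2"):
        read_fragments(p)


def test_roundtrip(tmp_path, rng):
    starts = rng.integers(0, 100_000, size=500)
    lengths = rng.integers(20, 251, size=500)
    fs = make_fragments("chrII", starts, lengths)
    p = tmp_path / "rt.bed"
    write_bed(fs, p)
    back = read_fragments(p)
    pd.testing.assert_frame_equal(fs.frags, back.frags)


@pytest.mark.parametrize("chrom,mid,kept", [
    ("chrM", 5_000, False),          # mitochondrial genome excluded
    ("chrXII", 460_000, False),      # inside the rDNA locus
    ("chrXII", 400_000, True),       # outside the rDNA locus
    ("chrXII", 451_574, False),      # first excluded base (0-based boundary)
    ("chrXII", 451_573, True),       # last base before the locus
    ("chrXII", 489_469, True),       # first base after the half-open end
])
def test_saccer3_exclusions_by_midpoint(chrom, mid, kept):
    fs = make_fragments(chrom, [mid - 75], [150])  # even length: mid = start+75
    out = apply_exclusions(fs)
    assert (len(out) == 1) is kept


def test_exclusions_require_known_genome():
    fs = make_fragments("chr1", [100], [150])
    with pytest.raises(ValueError, match="exclusion"):
        apply_exclusions(fs, genome="hg38")


def test_vplot_counts_and_example():
    fs = make_fragments("chrI", [50 - 83, 50 - 83, 60 - 83], [166, 166, 166])
    vp = build_vplot(fs, ("chrI", 0, 100))
    assert vp.total() == 3
    assert vp.counts[166 - vp.size_min, 50] == 2
    assert vp.counts[166 - vp.size_min, 60] == 1


def test_vplot_empty_region():
    fs = make_fragments("chrI", [5000], [166])
    vp = build_vplot(fs, ("chrI", 0, 100))
    assert vp.total() == 0


def test_vplot_brute_force_oracle(rng):
    """Matrix entries equal a naive per-fragment loop on a random fixture."""
    starts = rng.integers(0, 2_000, size=1000)
    lengths = rng.integers(10, 300, size=1000)  # some outside [20, 250]
    fs = make_fragments("chrI", starts, lengths)
    region = ("chrI", 300, 1300)
    vp = build_vplot(fs, region)
    brute = np.zeros_like(vp.counts)
    for s, l in zip(starts, lengths):
        mid = s + l // 2
        if 300 <= mid < 1300 and 20 <= l <= 250:
            brute[l - 20, mid - 300] += 1
    np.testing.assert_array_equal(vp.counts, brute)


def test_vplot_translation_equivariance(rng):
    starts = rng.integers(200, 700, size=300)
    lengths = rng.integers(20, 251, size=300)
    delta = 57
    vp0 = build_vplot(make_fragments("chrI", starts, lengths),
                      ("chrI", 100, 900))
    vp1 = build_vplot(make_fragments("chrI", starts + delta, lengths),
                      ("chrI", 100 + delta, 900 + delta))
    np.testing.assert_array_equal(vp0.counts, vp1.counts)


def test_inverted_region_rejected():
    fs = make_fragments("chrI", [100], [150])
    with pytest.raises(ValueError, match="region"):
        build_vplot(fs, ("chrI", 500, 400))
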