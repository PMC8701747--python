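"""Per-fragment-size depth equalization across time points.

MNase digestion extent, library preparation and sequencing depth all shift
the fragment-size spectrum between samples.  Before any scoring, each
replicate's time course is equalized size by size: for every fragment length
s in [20, 250] bp, the smallest count of s-length fragments across the time
points is found, and every time point is randomly subsampled to exactly that
count.  Matched time points of the two biological replicates are then merged.

Subsampling happens within a replicate (across its time points) and merging
after, never the other way round.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragment_io import SIZE_MAX, SIZE_MIN, FragmentSet


@dataclass
class SizeDepthTable:
    """Per-size fragment counts by time point and their minimum.

    ``counts`` has one row per fragment size in [size_min, size_max] and one
    column per time-point label; ``minimum`` holds m_s = min_t count(s, t).
    """

    size_min: int
    size_max: int
    counts: pd.DataFrame      # index: size, columns: labels
    minimum: pd.Series        # index: size

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out["minimum"] = self.minimum
        out.to_csv(path, sep="\t", index_label="size")


def compute_depths(fragmentsets: list[FragmentSet],
                   size_min: int = SIZE_MIN,
                   size_max: int = SIZE_MAX) -> SizeDepthTable:
    """Count fragments per size per time point and the per-size minimum."""
    if size_max < size_min:
        raise ValueError("empty size range")
    if not fragmentsets:
        raise ValueError("need at least one FragmentSet")
    sizes = np.arange(size_min, size_max + 1)
    cols = {}
    for fs in fragmentsets:
        if fs.label in cols:
            raise ValueError(f"duplicate time-point label {fs.label!r}")
        length = fs.frags["length"].to_numpy()
        inrange = length[(length >= size_min) & (length <= size_max)]
        cols[fs.label] = np.bincount(inrange - size_min,
                                     minlength=len(sizes)).astype(np.int64)
    counts = pd.DataFrame(cols, index=sizes)
    return SizeDepthTable(size_min, size_max, counts, counts.min(axis=1))


def subsample(fs: FragmentSet, table: SizeDepthTable, seed: int) -> FragmentSet:
    """Subsample to exactly m_s fragments for every size s, uniformly without
    replacement.  Fragments outside the table's size range are dropped.

    One child RNG per fragment size is derived from ``seed`` so per-size draws
    are independent and the whole operation is reproducible.
    """
    length = fs.frags["length"].to_numpy()
    sizes = np.arange(table.size_min, table.size_max + 1)
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    keep_idx: list[np.ndarray] = []
    for s, child in zip(sizes, children):
        m = int(table.minimum.loc[s])
        if m == 0:
            continue
        idx = np.flatnonzero(length == s)
        if m > len(idx):
            raise ValueError(
                f"size {s}: requested {m} fragments but only {len(idx)} present")
        if m == len(idx):
            keep_idx.append(idx)
        else:
            rng = np.random.default_rng(child)
            keep_idx.append(rng.choice(idx, size=m, replace=False))
    if keep_idx:
        keep = np.sort(np.concatenate(keep_idx))
    else:
        keep = np.array([], dtype=np.int64)
    return fs.with_frags(fs.frags.iloc[keep], f"subsample(seed={seed})")


def merge_matched(rep1: FragmentSet, rep2: FragmentSet) -> FragmentSet:
    """Merge the two replicates of one time point (simple concatenation)."""
    if rep1.label != rep2.label:
        raise ValueError(
            f"time-point label mismatch: {rep1.label!r} vs {rep2.label!r}")
    frags = pd.concat([rep1.frags, rep2.frags], ignore_index=True)
    return FragmentSet(
        label=rep1.label,
        frags=frags,
        replicate="merged",
        provenance=rep1.provenance + rep2.provenance + ["merge_matched"],
    )
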