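"""Fragment input/output and the midpoint-by-size occupancy matrix (V-plot).

Paired-end MNase-seq protects DNA in particle-sized footprints: the length of
a sequenced fragment reports the bound factor (~150-180 bp for nucleosomes,
<120 bp for sequence-specific factors such as ORC or Abf1p), and its midpoint
reports where the particle sat.  Everything downstream of alignment therefore
works on (chrom, start, end) fragment intervals.

Coordinates are 0-based half-open throughout; BED is native, BAM is converted
on read, and 1-based genomic citations (e.g. the rDNA locus) are converted at
the boundary.  The midpoint of a fragment uses the floor convention
``start + length // 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fragment-size range retained for scoring and depth equalization (bp).
SIZE_MIN = 20
SIZE_MAX = 250

#: rDNA locus on chrXII, converted from the 1-based inclusive citation
#: 451,575-489,469 to 0-based half-open.
RDNA_EXCLUSION = ("chrXII", 451_574, 489_469)
MITO_CHROM = "chrM"

_COLUMNS = ["chrom", "start", "end", "length", "midpoint"]


def _finalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["length"] = df["end"] - df["start"]
    df["midpoint"] = df["start"] + df["length"] // 2
    return df.reset_index(drop=True)


@dataclass
class FragmentSet:
    """A labeled collection of mapped paired-end fragment intervals.

    Parameters
    ----------
    label
        Sample label, typically the time point (``"alpha"``, ``"t20"`` ...).
    frags
        DataFrame with columns chrom, start, end, length, midpoint (0-based
        half-open).  Extra columns (e.g. a ``source`` column from the
        synthetic generator) are carried along untouched.
    replicate
        Optional replicate identifier.
    provenance
        Free-text trail of source files and filters applied.
    """

    label: str
    frags: pd.DataFrame
    replicate: str | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("FragmentSet label must be nonempty")
        missing = [c for c in _COLUMNS if c not in self.frags.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frags)

    def chromosomes(self) -> list[str]:
        return sorted(self.frags["chrom"].unique().tolist())

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.frags[self.frags["chrom"] == chrom]

    def with_frags(self, frags: pd.DataFrame, note: str | None = None) -> "FragmentSet":
        prov = self.provenance + ([note] if note else [])
        return replace(self, frags=frags.reset_index(drop=True), provenance=prov)

    def size_filtered(self, lo: int = SIZE_MIN, hi: int = SIZE_MAX) -> "FragmentSet":
        """Restrict to fragment lengths in [lo, hi] (inclusive)."""
        keep = self.frags["length"].between(lo, hi)
        return self.with_frags(self.frags[keep], f"size_filter[{lo},{hi}]")


def _read_bed3(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={0: str}, skip_blank_lines=True,
    )
    bad = df.index[(df["end"] <= df["start"]) | df["start"].isna() | df["end"].isna()]
    if len(bad):
        raise ValueError(f"{path}: malformed BED record at line {bad[0] + 1}")
    return df


def _read_bedpe(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3, 4, 5],
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        dtype={0: str, 3: str}, skip_blank_lines=True,
    )
    mism = df.index[df["chrom1"] != df["chrom2"]]
    if len(mism):
        raise ValueError(f"{path}: interchromosomal pair at line {mism[0] + 1}")
    out = pd.DataFrame({
        "chrom": df["chrom1"],
        "start": df[["start1", "start2"]].min(axis=1),
        "end": df[["end1", "end2"]].max(axis=1),
    })
    bad = out.index[out["end"] <= out["start"]]
    if len(bad):
        raise ValueError(f"{path}: malformed BEDPE record at line {bad[0] + 1}")
    return out


def _read_bam(path: Path) -> pd.DataFrame:
    import pysam

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    skipped = 0
    with pysam.AlignmentFile(str(path)) as bam:  # autodetect SAM/BAM
        for read in bam.fetch(until_eof=True):
            # One record per fragment: keep the forward-strand mate of each
            # properly paired read, the fragment being the outer pair span.
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired or not read.is_proper_pair:
                skipped += 1
                continue
            if read.is_reverse or read.template_length <= 0:
                continue
            chroms.append(read.reference_name)
            starts.append(read.reference_start)
            ends.append(read.reference_start + read.template_length)
    if skipped:
        logger.info("%s: skipped %d unpaired/improper reads", path, skipped)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def read_fragments(path: str | Path, fmt: str | None = None,
                   label: str | None = None,
                   replicate: str | None = None) -> FragmentSet:
    """Read fragments from BED3, BEDPE or coordinate-sorted paired-end BAM.

    ``fmt`` is inferred from the file extension when omitted.  BEDPE pairs and
    BAM read pairs collapse to the same fragment record a BED3 line would give
    (outer span, counted once).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".bed": "bed", ".bedpe": "bedpe", ".bam": "bam"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name}; pass fmt=")
    if fmt == "bed":
        try:
            df = _read_bed3(path)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["chrom", "start", "end"])
    elif fmt == "bedpe":
        try:
            df = _read_bedpe(path)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["chrom", "start", "end"])
    elif fmt == "bam":
        df = _read_bam(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return FragmentSet(
        label=label or path.stem,
        frags=_finalize_frame(df),
        replicate=replicate,
        provenance=[f"read:{path}:{fmt}"],
    )


def write_bed(fs: FragmentSet, path: str | Path) -> None:
    """Write fragments as BED3 (tab-separated, 0-based half-open)."""
    fs.frags[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def apply_exclusions(fs: FragmentSet, genome: str = "sacCer3",
                     exclusion_intervals: list[tuple[str, int, int]] | None = None,
                     ) -> FragmentSet:
    """Remove fragments whose *midpoint* lies in an excluded region.

    For sacCer3 the exclusions are the mitochondrial genome (chrM) and the
    rDNA locus on chrXII.  Midpoint membership (not any-overlap) matches the
    midpoint-based scoring downstream.
    """
    if exclusion_intervals is None:
        if genome != "sacCer3":
            raise ValueError(
                f"no built-in exclusion list for genome {genome!r}; "
                "pass exclusion_intervals explicitly")
        exclusion_intervals = [RDNA_EXCLUSION]
        drop_chroms = {MITO_CHROM}
    else:
        drop_chroms = set()

    keep = np.ones(len(fs.frags), dtype=bool)
    if drop_chroms:
        keep &= ~fs.frags["chrom"].isin(drop_chroms).to_numpy()
    mid = fs.frags["midpoint"].to_numpy()
    chrom = fs.frags["chrom"].to_numpy()
    for c, s, e in exclusion_intervals:
        keep &= ~((chrom == c) & (mid >= s) & (mid < e))
    removed = int((~keep).sum())
    return fs.with_frags(fs.frags[keep], f"exclusions:{genome}(-{removed})")


def parse_region(region: str | tuple[str, int, int]) -> tuple[str, int, int]:
    """Accept ``(chrom, start, end)`` or a ``"chrom:start-end"`` string."""
    if isinstance(region, str):
        chrom, _, span = region.partition(":")
        lo, _, hi = span.partition("-")
        region = (chrom, int(lo.replace(",", "")), int(hi.replace(",", "")))
    chrom, start, end = region
    if end <= start:
        raise ValueError(f"inverted or empty region {chrom}:{start}-{end}")
    return chrom, int(start), int(end)


@dataclass
class VPlotMatrix:
    """Fragment counts indexed by (fragment size, fragment-midpoint position).

    The chromatin occupancy profile of a region: ``counts[i, j]`` is the
    number of fragments of length ``sizes[i]`` whose midpoint falls at
    ``start + j``.  Sizes span [20, 250] bp by default.
    """

    chrom: str
    start: int
    end: int
    size_min: int
    size_max: int
    counts: np.ndarray  # shape (size_max - size_min + 1, end - start)
    copy_number_corrected: bool = False

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.size_min, self.size_max + 1)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end)

    def total(self) -> float:
        return float(self.counts.sum())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=self.sizes, columns=self.positions
                     ).to_csv(path, sep="\t")


def build_vplot(fs: FragmentSet, region: str | tuple[str, int, int],
                size_min: int = SIZE_MIN, size_max: int = SIZE_MAX) -> VPlotMatrix:
    """Build the V-plot for a region: midpoint-by-size 2D histogram.

    Fragments with midpoint outside the region or length outside
    [size_min, size_max] are excluded.
    """
    chrom, start, end = parse_region(region)
    sub = fs.on_chrom(chrom)
    mid = sub["midpoint"].to_numpy()
    length = sub["length"].to_numpy()
    keep = (mid >= start) & (mid < end) & (length >= size_min) & (length <= size_max)
    counts = np.zeros((size_max - size_min + 1, end - start), dtype=np.int32)
    np.add.at(counts, (length[keep] - size_min, mid[keep] - start), 1)
    return VPlotMatrix(chrom, start, end, size_min, size_max, counts)
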