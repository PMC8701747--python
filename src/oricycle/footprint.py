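"""Small-fragment footprint occupancy.

Fragments shorter than 120 bp report protection by non-nucleosomal factors —
at replication origins, ORC and the pre-RC/pre-IC assembled on the ACS.  Per
chromosome, the density of sub-120 bp fragment midpoints is estimated with a
Gaussian kernel (bandwidth = kernel SD = 50 bp) at every base, and scaled by
the chromosome length so a uniform background sits at 1.  The track is then
divided by the local replication copy number, and finally calibrated across
samples by the Abf1p rule: the reciprocal of the mean occupancy within
±100 bp of the Abf1p binding sites is applied as a per-sample scale factor,
absorbing sample-to-sample differences in MNase digestion (Abf1p occupancy
is cell-cycle independent).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal, stats

from .nucleosome import CopyNumberTrack, OccupancyTrack, normalize_track

#: Strict size cutoff (bp): fragments of this length or longer never count.
SMALL_FRAGMENT_CUTOFF = 120

#: Gaussian KDE bandwidth = kernel standard deviation, in bp.  Note other
#: tools quote bandwidths as FWHM; here bandwidth is the SD.
KDE_BANDWIDTH = 50.0

#: Aggregation half-width around Abf1p sites (bp).
ABF1_HALFWIDTH = 100


def small_fragment_track(fs, chrom: str, length: int,
                         bandwidth: float = KDE_BANDWIDTH,
                         cutoff: int = SMALL_FRAGMENT_CUTOFF) -> OccupancyTrack:
    """Sub-``cutoff`` fragment midpoint KDE times chromosome length.

    The Gaussian kernel (SD = ``bandwidth``) is evaluated at every base; the
    density integrates to ~1 over the chromosome, so after multiplying by the
    chromosome length the track has mean ~1 away from the edges.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    sub = fs.on_chrom(chrom)
    small = sub[sub["length"] < cutoff]
    mids = small["midpoint"].to_numpy()
    mids = mids[(mids >= 0) & (mids < length)]
    if len(mids) == 0:
        warnings.warn(f"{fs.label}/{chrom}: no fragments below {cutoff} bp; "
                      "footprint track is all zero")
        return OccupancyTrack(chrom, np.zeros(length), "footprint")
    hist = np.bincount(mids, minlength=length).astype(np.float64)
    half = int(np.ceil(6 * bandwidth))
    grid = np.arange(-half, half + 1)
    kern = stats.norm.pdf(grid, scale=bandwidth)
    # FFT convolution can leave ~1e-17 negative residue where density is 0
    density = np.maximum(signal.fftconvolve(hist, kern, mode="same"), 0.0)
    return OccupancyTrack(chrom, density / len(mids) * length, "footprint")


def abf1_scale_factor(tracks: dict[str, OccupancyTrack],
                      sites: list[tuple[str, int]],
                      halfwidth: int = ABF1_HALFWIDTH) -> float:
    """Reciprocal of the mean occupancy within ±halfwidth of the Abf1p sites.

    Aggregation weights every covered base equally (windows clipped at
    chromosome ends contribute their covered part).  ``tracks`` maps
    chromosome name to its footprint track; sites on unscored chromosomes
    are ignored.
    """
    values: list[np.ndarray] = []
    for chrom, pos in sites:
        track = tracks.get(chrom)
        if track is None:
            continue
        lo = max(pos - halfwidth, 0)
        hi = min(pos + halfwidth + 1, len(track.values))
        if hi > lo:
            values.append(track.values[lo:hi])
    if not values:
        raise ValueError("no Abf1p site overlaps a scored chromosome")
    mean = float(np.nanmean(np.concatenate(values)))
    if not np.isfinite(mean) or mean == 0:
        raise ValueError("aggregate Abf1p occupancy is zero; calibration "
                         "impossible")
    return 1.0 / mean


def apply_scale_factor(track: OccupancyTrack, factor: float) -> OccupancyTrack:
    return OccupancyTrack(track.chrom, track.values * factor, track.kind,
                          start=track.start,
                          copy_number_normalized=track.copy_number_normalized,
                          abf1_calibrated=True)


def calibrated_footprint_tracks(tracks: dict[str, OccupancyTrack],
                                sites: list[tuple[str, int]],
                                cn: dict[str, CopyNumberTrack] | None = None,
                                halfwidth: int = ABF1_HALFWIDTH,
                                ) -> tuple[dict[str, OccupancyTrack], float]:
    """Copy-number normalize, then Abf1p-calibrate, one sample's tracks.

    The scale factor is computed on the copy-number-normalized tracks (copy
    number first, calibration second); both corrections are multiplicative,
    so they commute up to the factor's value.
    """
    if cn is not None:
        tracks = {c: normalize_track(t, cn[c]) for c, t in tracks.items()}
    factor = abf1_scale_factor(tracks, sites, halfwidth)
    return {c: apply_scale_factor(t, factor) for c, t in tracks.items()}, factor


def acs_footprint_density(track: OccupancyTrack, acs_position: int) -> float:
    """Footprint occupancy at an origin's ACS (single-base read-out)."""
    idx = acs_position - track.start
    if not (0 <= idx < len(track.values)):
        raise ValueError(f"ACS position {acs_position} outside scored range of "
                         f"{track.chrom}")
    return float(track.values[idx])


def density_table(tracks_by_timepoint: dict[str, dict[str, OccupancyTrack]],
                  origins) -> "pd.DataFrame":
    """Per-origin, per-time-point ACS footprint density (origins x times)."""
    import pandas as pd
    rows = {}
    for origin in origins:
        row = {}
        for label, tracks in tracks_by_timepoint.items():
            track = tracks.get(origin.chrom)
            row[label] = (acs_footprint_density(track, origin.acs_position)
                          if track is not None else np.nan)
        rows[origin.name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
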