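"""Origin-level analyses: oriented aggregation, -1/+1 dyad calling and NFR
width, footprint peak averages, and the footprint-efficiency correlation.

All origin-relative coordinates are oriented by the T-rich strand of the ACS,
so "+1" always means the first nucleosome downstream of the ACS in that
orientation regardless of the origin's genomic strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .nucleosome import OccupancyTrack

FOOTPRINT_CLASSES = ("G1&G2", "G1only")

#: Dyad search window on each side of the ACS (bp): at least 10 bp away
#: (outside the ACS footprint itself), at most 500 bp.
DYAD_SEARCH = (10, 500)


@dataclass
class OriginAnnotation:
    """ACS-anchored replication origin record."""

    name: str
    chrom: str
    acs_position: int
    t_rich_strand: str                # "+" or "-"
    footprint_class: str | None = None  # "G1&G2" | "G1only" | None
    efficiency: float | None = None     # fraction of cycles fired, in [0, 1]

    def __post_init__(self) -> None:
        if self.t_rich_strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        if self.footprint_class not in (None, *FOOTPRINT_CLASSES):
            raise ValueError(f"{self.name}: unknown footprint class "
                             f"{self.footprint_class!r}")
        if self.efficiency is not None and not (0 <= self.efficiency <= 1):
            raise ValueError(f"{self.name}: efficiency must be in [0, 1]")

    @property
    def orientation(self) -> int:
        return 1 if self.t_rich_strand == "+" else -1


def load_origins(path: str | Path) -> list[OriginAnnotation]:
    """Read an origin table (TSV: name, chrom, acs_pos, strand, class,
    efficiency; 0-based positions; empty fields allowed)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        cls = getattr(row, "footprint_class", None)
        if isinstance(cls, float) and np.isnan(cls):
            cls = None
        eff = getattr(row, "efficiency", None)
        if eff is not None and np.isnan(eff):
            eff = None
        out.append(OriginAnnotation(row.name, row.chrom, int(row.acs_pos),
                                    row.strand, cls, eff))
    return out


def save_origins(origins: list[OriginAnnotation], path: str | Path) -> None:
    pd.DataFrame([{
        "name": o.name, "chrom": o.chrom, "acs_pos": o.acs_position,
        "strand": o.t_rich_strand, "footprint_class": o.footprint_class,
        "efficiency": o.efficiency,
    } for o in origins]).to_csv(path, sep="\t", index=False)


def oriented_window(track: OccupancyTrack, origin: OriginAnnotation,
                    halfspan: int) -> np.ndarray | None:
    """Extract track values over ACS +/- halfspan, flipped for minus-strand
    origins so index ``halfspan`` is the ACS and larger indices are
    downstream in T-rich orientation.  None if the window leaves the track.
    """
    lo = origin.acs_position - halfspan - track.start
    hi = origin.acs_position + halfspan + 1 - track.start
    if lo < 0 or hi > len(track.values):
        return None
    window = track.values[lo:hi]
    return window[::-1] if origin.orientation < 0 else window


def orient_and_aggregate(tracks: dict[str, OccupancyTrack],
                         origins: list[OriginAnnotation],
                         halfspan: int) -> tuple[np.ndarray, int]:
    """Mean oriented profile over a set of origins.

    Returns (profile of length 2*halfspan + 1, number of origins used);
    origins too close to a chromosome end are skipped.
    """
    windows = []
    for origin in origins:
        track = tracks.get(origin.chrom)
        if track is None:
            continue
        w = oriented_window(track, origin, halfspan)
        if w is not None:
            windows.append(w)
    if not windows:
        raise ValueError("no origin window fits inside the scored tracks")
    return np.nanmean(np.stack(windows), axis=0), len(windows)


def class_aggregates(tracks_by_timepoint: dict[str, dict[str, OccupancyTrack]],
                     origins: list[OriginAnnotation],
                     halfspan: int) -> dict[str, pd.DataFrame]:
    """Per-footprint-class aggregate profiles, one row per time point."""
    out = {}
    for cls in FOOTPRINT_CLASSES:
        members = [o for o in origins if o.footprint_class == cls]
        if not members:
            continue
        rows = {}
        for label, tracks in tracks_by_timepoint.items():
            profile, _ = orient_and_aggregate(tracks, members, halfspan)
            rows[label] = profile
        out[cls] = pd.DataFrame.from_dict(rows, orient="index")
        out[cls].columns = np.arange(-halfspan, halfspan + 1)
    return out


@dataclass
class DyadCall:
    """-1/+1 nucleosome dyad offsets from the ACS (T-rich orientation)."""

    minus_one_offset: int   # negative
    plus_one_offset: int    # positive
    low_confidence: bool = False

    @property
    def nfr_width(self) -> int:
        return self.plus_one_offset - self.minus_one_offset


def call_dyads(profile: np.ndarray, acs_index: int,
               search: tuple[int, int] = DYAD_SEARCH) -> DyadCall:
    """Call the -1/+1 dyads on an oriented nucleosome score profile.

    The +1 dyad is the position of maximal score in [ACS + lo, ACS + hi],
    the -1 dyad the maximum in [ACS - hi, ACS - lo]; ties break toward the
    ACS (the innermost nucleosome is the one named +1/-1).  A flat window
    yields a low-confidence call at the innermost position.
    """
    lo, hi = search
    plus = np.asarray(profile[acs_index + lo: acs_index + hi + 1], dtype=float)
    minus = np.asarray(profile[acs_index - hi: acs_index - lo + 1], dtype=float)
    if len(plus) == 0 or len(minus) == 0:
        raise ValueError("profile does not cover the dyad search window")
    # np.argmax returns the first maximum; order both windows so the first
    # index is the one nearest the ACS.
    plus_offset = lo + int(np.nanargmax(plus))
    minus_offset = -(lo + int(np.nanargmax(minus[::-1])))
    flat = (np.nanmax(plus) == np.nanmin(plus)) or \
           (np.nanmax(minus) == np.nanmin(minus))
    return DyadCall(minus_offset, plus_offset, low_confidence=bool(flat))


def dyad_table(tracks_by_timepoint: dict[str, dict[str, OccupancyTrack]],
               origins: list[OriginAnnotation],
               search: tuple[int, int] = DYAD_SEARCH) -> pd.DataFrame:
    """Aggregate-profile dyad calls per footprint class per time point."""
    halfspan = search[1]
    rows = []
    for cls, profiles in class_aggregates(tracks_by_timepoint, origins,
                                          halfspan).items():
        for label in profiles.index:
            call = call_dyads(profiles.loc[label].to_numpy(), halfspan, search)
            rows.append({"class": cls, "time": label,
                         "minus_one": call.minus_one_offset,
                         "plus_one": call.plus_one_offset,
                         "nfr_width": call.nfr_width,
                         "low_confidence": call.low_confidence})
    return pd.DataFrame(rows)


def footprint_peak_average(profiles: pd.DataFrame,
                           halfwidth: int = 100) -> pd.Series:
    """Mean footprint occupancy +/-halfwidth around the aggregate peak.

    ``profiles``: time points x oriented positions (columns are offsets from
    the ACS).  The peak is the argmax of the time-averaged profile, fixed
    across time points; the returned series is the per-time-point mean over
    the +/-halfwidth window around it.
    """
    mean_profile = profiles.mean(axis=0)
    peak = mean_profile.idxmax()
    cols = [c for c in profiles.columns if abs(c - peak) <= halfwidth]
    return profiles[cols].mean(axis=1)


def efficiency_correlation(densities: pd.DataFrame,
                           efficiencies: pd.Series,
                           eps: float | None = None) -> pd.DataFrame:
    """Per-time-point Spearman correlation between log2 footprint density at
    the ACS and origin activation efficiency.

    ``densities``: origins x time points; ``efficiencies``: per-origin, may
    have missing values (excluded pairwise).  Densities are log2(d + eps)
    transformed with eps = half the smallest positive density (Spearman is
    rank-based, so the transform only matters through eps on zeros).
    Returns per-time-point rho, n, and a zero-variance flag.
    """
    if eps is None:
        positive = densities.to_numpy()
        positive = positive[np.isfinite(positive) & (positive > 0)]
        eps = 0.5 * positive.min() if positive.size else 1.0
    eff = efficiencies.reindex(densities.index)
    rows = []
    for label in densities.columns:
        d = densities[label]
        ok = d.notna() & eff.notna()
        n = int(ok.sum())
        if n < 3:
            rows.append({"time": label, "rho": np.nan, "n": n, "flat": True})
            continue
        x = np.log2(d[ok].to_numpy() + eps)
        y = eff[ok].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"time": label, "rho": np.nan, "n": n, "flat": True})
            continue
        rho = stats.spearmanr(x, y).statistic
        rows.append({"time": label, "rho": float(rho), "n": n, "flat": False})
    return pd.DataFrame(rows).set_index("time")


def split_by_efficiency(origins: list[OriginAnnotation],
                        frac: float = 0.2
                        ) -> tuple[list[OriginAnnotation], list[OriginAnnotation]]:
    """Top/bottom ``frac`` of footprint origins by activation efficiency
    (the active vs. passively replicated sets for the entropy heatmaps)."""
    scored = [o for o in origins
              if o.efficiency is not None and o.footprint_class is not None]
    scored.sort(key=lambda o: o.efficiency)
    k = max(1, int(round(frac * len(scored))))
    return scored[-k:], scored[:k]
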