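"""Shannon-entropy quantification of nucleosome disorganization.

A genomic window's nucleosome scores, normalized to sum to one, define a
probability distribution of nucleosome positioning over the window:

    P_X(x_i) = nuc_i / sum_j nuc_j,      H(X) = - sum_i P_X(x_i) log P_X(x_i)

with the natural logarithm and 0 * log 0 := 0.  Sharp, well-positioned
nucleosomes concentrate the score into a few bases (low entropy); fuzzy or
disrupted nucleosomes spread it (high entropy, bounded by log n for an n-bp
window).  Entropy is invariant to positive rescaling of the scores, so it
reads out organization, not occupancy.

Around replication origins, entropy is computed in 1 kb windows spanning
30 kb, pooled across origins by distance from the origin, and standardized
into z-scores across each row (distance bin) to expose when in the cell
cycle each distance is most disorganized — the signature of the passing
replication fork.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nucleosome import OccupancyTrack

ENTROPY_WINDOW = 1000
ENTROPY_SPAN = 30000


def shannon_entropy(scores: np.ndarray) -> float:
    """Entropy of a nonnegative score vector; NaN if the total is zero.

    NaN entries (e.g. positions with undefined copy number) are ignored.
    """
    scores = np.asarray(scores, dtype=np.float64)
    finite = scores[np.isfinite(scores)]
    if np.any(finite < 0):
        raise ValueError("nucleosome scores must be nonnegative")
    total = finite.sum()
    if total <= 0 or len(finite) == 0:
        return float("nan")
    p = finite / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


@dataclass
class EntropyWindow:
    chrom: str
    start: int
    end: int
    entropy: float

    @property
    def size(self) -> int:
        return self.end - self.start


def window_entropy(track: OccupancyTrack, start: int, end: int) -> EntropyWindow:
    """Entropy of one genomic window of a nucleosome score track."""
    if end <= start:
        raise ValueError("empty window")
    return EntropyWindow(track.chrom, start, end,
                         shannon_entropy(track.slice(start, end)))


def zscore_rows(mat: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Standardize each row to mean 0, SD 1; zero-variance rows become zero
    and are flagged."""
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    # numerically flat rows (identical values can leave ~1e-16 residue)
    flat = (sd <= 1e-12 * mean.abs().clip(lower=1.0)) | sd.isna()
    z = mat.sub(mean, axis=0).div(sd.where(~flat, 1.0), axis=0)
    z[flat] = 0.0
    return z, flat


@dataclass
class EntropyMatrix:
    """Origin-anchored entropy summaries.

    ``aggregate``: |distance-bin| x time-point mean entropy, pooled across
    origins (rows labeled by the bin-center distance from the origin, bp).
    ``aggregate_z``: the same matrix z-scored across each row.
    ``per_origin``: long-format per-origin, per-window entropies.
    ``flat_rows``: distance bins whose row had zero variance.
    """

    aggregate: pd.DataFrame
    aggregate_z: pd.DataFrame
    per_origin: pd.DataFrame
    flat_rows: pd.Series

    def to_tsv(self, path) -> None:
        self.aggregate_z.to_csv(path, sep="\t", index_label="distance_bp")


def entropy_heatmap(tracks_by_timepoint: dict[str, dict[str, OccupancyTrack]],
                    origins,
                    window: int = ENTROPY_WINDOW,
                    span: int = ENTROPY_SPAN) -> EntropyMatrix:
    """Entropy of nucleosome organization around origins through time.

    For each origin, ``span / window`` windows of ``window`` bp are laid out
    centered on the ACS (15 on each side by default).  Windows are pooled
    across origins by the absolute distance of their center from the ACS;
    the per-bin mean entropy per time point is z-scored across time.

    Requires at least two time points (a z-score needs variance to exist).
    """
    labels = list(tracks_by_timepoint)
    if len(labels) < 2:
        raise ValueError("need at least two time points")
    n_win = span // window
    half_span = span // 2
    records = []
    for origin in origins:
        for k in range(n_win):
            start = origin.acs_position - half_span + k * window
            end = start + window
            center_dist = start + window // 2 - origin.acs_position
            for label in labels:
                track = tracks_by_timepoint[label].get(origin.chrom)
                if track is None or start < track.start or \
                        end > track.start + len(track.values):
                    h = np.nan
                else:
                    h = window_entropy(track, start, end).entropy
                records.append((origin.name, center_dist, label, h))
    per_origin = pd.DataFrame(records,
                              columns=["origin", "distance", "time", "entropy"])
    per_origin["abs_distance"] = per_origin["distance"].abs()
    agg = (per_origin.pivot_table(index="abs_distance", columns="time",
                                  values="entropy", aggfunc="mean")
           .reindex(columns=labels))
    z, flat = zscore_rows(agg)
    return EntropyMatrix(agg, z, per_origin, flat)
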