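"""Synthetic MNase-seq fragment generator with planted truth.

Emulates a cell-cycle time course over a small yeast-like genome so that
every downstream stage (equalization, kernel scoring, footprint density,
entropy, origin summaries) can be tested against known ground truth without
any external data:

* a regular array of nucleosomes (fragment sizes ~ truncated Normal(166, 15),
  midpoints jittered around each dyad by a tunable positional fuzziness);
* replication origins with a nucleosome-free region around the ACS, flanked
  by planted -1/+1 dyads, the +1 repositioning through the cell cycle;
* sub-120 bp footprint fragments at each ACS whose expected occupancy
  follows a cell-cycle curve peaking at the G1/S transition (dampened for
  the "G1only" class), plus constant-occupancy Abf1p-like sites used for
  calibration;
* deterministic bidirectional replication: from each active origin a fork
  moves outward at constant speed, doubling the sampling weight of every
  locus behind it, and transiently raising nucleosome fuzziness in a band
  at the fork (the disorganization the entropy analysis detects);
* uniform background fragments.

Origin activation efficiency can be coupled to the footprint occupancy
amplitude at a configurable population Spearman correlation, which the
correlation analyses then try to recover.

Sampling is multinomial over all fragment sources, so source counts sum to
the requested depth exactly and every draw is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .fragment_io import FragmentSet, _finalize_frame
from .origins import OriginAnnotation


# --------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    """All tunable parameters of the generator (YAML round-trippable).

    Times are minutes after release from alpha-factor arrest; the alpha
    sample itself is pre-release G1 (copy number 1 everywhere, time 0).
    """

    chromosomes: list = field(default_factory=lambda: [["chrS", 300_000]])
    timepoints_min: list = field(
        default_factory=lambda: list(range(10, 151, 10)))
    include_alpha: bool = True

    # nucleosome array
    nucleosome_spacing: int = 165
    baseline_fuzziness_sd: float = 10.0
    nucleosome_weight: float = 20.0

    # origins
    n_origins_g1g2: int = 2
    n_origins_g1only: int = 2
    nfr_halfwidth_g1g2: int = 129
    nfr_halfwidth_g1only: int = 110
    efficiency_range_g1g2: tuple = (0.5, 0.95)
    efficiency_range_g1only: tuple = (0.05, 0.45)
    efficiency_coupling_spearman: float = 0.6
    aggregate_halfspan: int = 1000   # origins closer than twice this rejected

    # footprint occupancy curve: base + bump * m_i * (N(c1, s1) + k2 N(c2, s2))
    footprint_base_weight: float = 6.0
    footprint_bump_weight: float = 25.0
    bump_center_min: float = 20.0
    bump_sd_min: float = 10.0
    second_bump_center_min: float = 95.0
    second_bump_scale: float = 0.5
    g1only_damping: float = 0.3

    # +1 nucleosome repositioning (G1&G2 class only)
    plus_one_shift_bp: float = 25.0
    shift_center_min: float = 20.0
    shift_sd_min: float = 8.0

    # replication
    activation_time_g1g2: float | None = 20.0
    activation_time_g1only: float | None = None   # passive
    fork_speed_bp_per_min: float = 750.0
    max_front_bp: float | None = None             # default: half min spacing
    disruption_band_bp: float = 7500.0
    disrupted_fuzziness_sd: float = 40.0

    # fragment-size model
    nuc_size_mean: float = 166.0
    nuc_size_sd: float = 15.0
    nuc_size_range: tuple = (120, 250)
    footprint_size_range: tuple = (60, 119)
    footprint_jitter_sd: float = 15.0
    background_size_range: tuple = (20, 250)

    # background fragments: weight per bp per sample
    background_rate: float = 0.002

    # Abf1p-like calibration sites
    abf1_spacing_bp: int = 50_000
    abf1_weight: float = 15.0

    def labels(self) -> list[str]:
        labels = (["alpha"] if self.include_alpha else [])
        return labels + [f"t{int(t)}" for t in self.timepoints_min]

    def minutes(self) -> list[float]:
        mins = ([0.0] if self.include_alpha else [])
        return mins + [float(t) for t in self.timepoints_min]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _bump(t: float, center: float, sd: float) -> float:
    return float(np.exp(-0.5 * ((t - center) / sd) ** 2))


def coupled_uniforms(n: int, rho_spearman: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two Uniform(0,1) vectors with the given population Spearman
    correlation, via a Gaussian copula (rho_pearson = 2 sin(pi rho_s / 6))."""
    r = 2.0 * np.sin(np.pi * rho_spearman / 6.0)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return stats.norm.cdf(z1), stats.norm.cdf(z2)


# --------------------------------------------------------------------------
# planted truth containers

@dataclass
class OriginTruth:
    """Ground truth for one planted origin."""

    name: str
    chrom: str
    acs_position: int
    t_rich_strand: str
    footprint_class: str
    efficiency: float
    activation_time: float | None          # minutes; None = passive
    footprint_occupancy_by_time: dict      # label -> sampling weight
    plus_one_offset_by_time: dict          # label -> +1 dyad offset (bp, >0)
    minus_one_offset: int                  # bp, < 0 (static)
    amp_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.efficiency <= 1:
            raise ValueError(f"{self.name}: efficiency outside [0, 1]")
        if any(v < 0 for v in self.footprint_occupancy_by_time.values()):
            raise ValueError(f"{self.name}: negative footprint occupancy")
        if self.minus_one_offset >= 0:
            raise ValueError(f"{self.name}: minus_one_offset must be negative")

    @property
    def orientation(self) -> int:
        return 1 if self.t_rich_strand == "+" else -1

    def as_annotation(self) -> OriginAnnotation:
        return OriginAnnotation(self.name, self.chrom, self.acs_position,
                                self.t_rich_strand, self.footprint_class,
                                self.efficiency)

    def plus_one_position(self, label: str) -> int:
        return self.acs_position + self.orientation * \
            int(self.plus_one_offset_by_time[label])

    def minus_one_position(self) -> int:
        return self.acs_position + self.orientation * self.minus_one_offset


@dataclass
class TimePointSpec:
    """One sampled time point and the per-origin replicated distance.

    ``replication_front_bp`` is the replicated extent on each side of the
    origin (clipped where converging forks merge); ``fork_travel_bp`` is the
    unclipped distance the fork would have travelled, used to place the
    transient disruption band at the fork — once travel exceeds the merge
    point the band has moved off and the chromatin is restored.
    """

    label: str
    minutes: float
    replication_front_bp: dict  # origin name -> bp replicated on each side
    fork_travel_bp: dict | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.replication_front_bp.values()):
            raise ValueError(f"{self.label}: negative replication front")
        if self.fork_travel_bp is None:
            self.fork_travel_bp = dict(self.replication_front_bp)


@dataclass
class GenomeLayout:
    """The simulated genome: chromosomes, nucleosome dyads, origins,
    Abf1p-like sites, and the fragment/background model parameters."""

    chromosomes: list                 # [(name, length)]
    dyads: pd.DataFrame               # chrom, position, fuzziness_sd, occupancy
    origins: list                     # [OriginTruth]
    abf1_sites: list                  # [(chrom, position)]
    background_rate: float
    nucleosome_weight: float
    abf1_weight: float
    disruption_band_bp: float
    disrupted_fuzziness_sd: float
    nuc_size_mean: float = 166.0
    nuc_size_sd: float = 15.0
    nuc_size_range: tuple = (120, 250)
    footprint_size_range: tuple = (60, 119)
    footprint_jitter_sd: float = 15.0
    background_size_range: tuple = (20, 250)

    def chrom_length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def validate(self) -> None:
        lengths = dict(self.chromosomes)
        if (self.dyads["fuzziness_sd"] < 0).any():
            raise ValueError("negative dyad fuzziness")
        for _, row in self.dyads.iterrows():
            if not 0 <= row["position"] < lengths[row["chrom"]]:
                raise ValueError("dyad outside chromosome bounds")
        for o in self.origins:
            if not 0 <= o.acs_position < lengths[o.chrom]:
                raise ValueError(f"{o.name}: ACS outside chromosome bounds")
            half = abs(o.minus_one_offset)
            inside = self.dyads[
                (self.dyads["chrom"] == o.chrom)
                & (self.dyads["position"] > o.acs_position - half)
                & (self.dyads["position"] < o.acs_position + half)]
            if len(inside):
                raise ValueError(f"{o.name}: NFR contains a grid dyad")

    def annotations(self) -> list[OriginAnnotation]:
        return [o.as_annotation() for o in self.origins]

    def dyad_list(self) -> list[tuple[str, int]]:
        return list(zip(self.dyads["chrom"], self.dyads["position"].astype(int)))

    def min_origin_spacing(self) -> float:
        best = np.inf
        for chrom, _ in self.chromosomes:
            pos = sorted(o.acs_position for o in self.origins
                         if o.chrom == chrom)
            if len(pos) >= 2:
                best = min(best, float(np.diff(pos).min()))
        return best


@dataclass
class SyntheticTruth:
    """Everything needed to reproduce and check a simulated time course."""

    layout: GenomeLayout
    timepoints: list
    seeds: pd.DataFrame               # time, replicate, seed
    counts_by_source: pd.DataFrame    # time, replicate, source, count

    def timepoint(self, label: str) -> TimePointSpec:
        for tp in self.timepoints:
            if tp.label == label:
                return tp
        raise KeyError(label)

    def expected_relative_density(self, origin: OriginTruth) -> pd.Series:
        """Planted copy-number-normalized footprint density (relative units):
        occupancy(t) divided by the ACS copy number (2 once the origin's own
        fork has moved off, 1 before)."""
        vals = {}
        for tp in self.timepoints:
            copy = 2.0 if tp.replication_front_bp.get(origin.name, 0) > 0 else 1.0
            vals[tp.label] = origin.footprint_occupancy_by_time[tp.label] / copy
        return pd.Series(vals)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.layout.dyads.to_csv(outdir / "truth_dyads.tsv", sep="\t",
                                 index=False)
        rows = []
        for o in self.layout.origins:
            rows.append({
                "name": o.name, "chrom": o.chrom, "acs_pos": o.acs_position,
                "strand": o.t_rich_strand, "footprint_class": o.footprint_class,
                "efficiency": o.efficiency,
                "activation_time": o.activation_time,
                "minus_one_offset": o.minus_one_offset,
                "amp_multiplier": o.amp_multiplier,
            })
        pd.DataFrame(rows).to_csv(outdir / "truth_origins.tsv", sep="\t",
                                  index=False)
        occ = pd.DataFrame({o.name: o.footprint_occupancy_by_time
                            for o in self.layout.origins})
        occ.to_csv(outdir / "truth_occupancy.tsv", sep="\t", index_label="time")
        plus = pd.DataFrame({o.name: o.plus_one_offset_by_time
                             for o in self.layout.origins})
        plus.to_csv(outdir / "truth_plus_one.tsv", sep="\t", index_label="time")
        fronts = pd.DataFrame({tp.label: tp.replication_front_bp
                               for tp in self.timepoints})
        fronts.to_csv(outdir / "truth_fronts.tsv", sep="\t",
                      index_label="origin")
        self.seeds.to_csv(outdir / "truth_seeds.tsv", sep="\t", index=False)
        self.counts_by_source.to_csv(outdir / "truth_counts.tsv", sep="\t",
                                     index=False)


# --------------------------------------------------------------------------
# layout construction

def _allocate_per_chrom(n: int, lengths: list[int]) -> list[int]:
    total = sum(lengths)
    exact = [n * l / total for l in lengths]
    counts = [int(np.floor(e)) for e in exact]
    rema = sorted(range(len(lengths)), key=lambda i: exact[i] - counts[i],
                  reverse=True)
    for i in rema[: n - sum(counts)]:
        counts[i] += 1
    return counts


def build_layout(config: SimulationConfig, seed: int = 0) -> GenomeLayout:
    """Construct the planted genome from a configuration, deterministically.

    Origins of the two footprint classes are interleaved at even spacing
    along each chromosome (strands alternating), efficiencies drawn within
    each class's range, and the footprint occupancy amplitude coupled to
    efficiency at the configured population Spearman correlation.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [c for c, _ in config.chromosomes]
    chrom_lengths = [int(l) for _, l in config.chromosomes]

    n_total = config.n_origins_g1g2 + config.n_origins_g1only
    classes: list[str] = []
    n1, n2 = config.n_origins_g1g2, config.n_origins_g1only
    while n1 or n2:                     # interleave the two classes
        if n1:
            classes.append("G1&G2"); n1 -= 1
        if n2:
            classes.append("G1only"); n2 -= 1

    labels, minutes = config.labels(), config.minutes()
    u_eff, u_amp = (coupled_uniforms(n_total,
                                     config.efficiency_coupling_spearman, rng)
                    if n_total else (np.array([]), np.array([])))

    origins: list[OriginTruth] = []
    per_chrom = _allocate_per_chrom(n_total, chrom_lengths)
    gidx = 0
    for (chrom, length), n_c in zip(config.chromosomes, per_chrom):
        positions = [int(round(length * (i + 1) / (n_c + 1)))
                     for i in range(n_c)]
        if any(np.diff(positions) < 2 * config.aggregate_halfspan):
            raise ValueError(
                f"{chrom}: origins closer than the aggregate window span "
                f"({2 * config.aggregate_halfspan} bp); enlarge the "
                "chromosome or reduce the origin count")
        for pos in positions:
            cls = classes[gidx]
            lo, hi = (config.efficiency_range_g1g2 if cls == "G1&G2"
                      else config.efficiency_range_g1only)
            eff = float(lo + (hi - lo) * u_eff[gidx])
            m = float(0.25 + 1.5 * u_amp[gidx])
            damp = 1.0 if cls == "G1&G2" else config.g1only_damping
            occ = {}
            for lab, t in zip(labels, minutes):
                curve = (_bump(t, config.bump_center_min, config.bump_sd_min)
                         + config.second_bump_scale
                         * _bump(t, config.second_bump_center_min,
                                 config.bump_sd_min))
                occ[lab] = (config.footprint_base_weight
                            + damp * config.footprint_bump_weight * m * curve)
            nominal = (config.nfr_halfwidth_g1g2 if cls == "G1&G2"
                       else config.nfr_halfwidth_g1only)
            plus = {}
            for lab, t in zip(labels, minutes):
                shift = (config.plus_one_shift_bp
                         * _bump(t, config.shift_center_min,
                                 config.shift_sd_min)
                         if cls == "G1&G2" else 0.0)
                plus[lab] = int(round(nominal + shift))
            act = (config.activation_time_g1g2 if cls == "G1&G2"
                   else config.activation_time_g1only)
            origins.append(OriginTruth(
                name=f"ori{gidx + 1:03d}", chrom=chrom, acs_position=pos,
                t_rich_strand="+" if gidx % 2 == 0 else "-",
                footprint_class=cls, efficiency=eff, activation_time=act,
                footprint_occupancy_by_time=occ,
                plus_one_offset_by_time=plus,
                minus_one_offset=-nominal, amp_multiplier=m))
            gidx += 1

    # nucleosome grid, cleared around each origin's NFR and boundary dyads
    dyad_rows = []
    for chrom, length in config.chromosomes:
        grid = np.arange(config.nucleosome_spacing // 2, length,
                         config.nucleosome_spacing)
        keep = np.ones(len(grid), dtype=bool)
        for o in origins:
            if o.chrom != chrom:
                continue
            clear = abs(o.minus_one_offset) + config.nucleosome_spacing // 2
            keep &= np.abs(grid - o.acs_position) > clear
        for pos in grid[keep]:
            dyad_rows.append((chrom, int(pos), config.baseline_fuzziness_sd,
                              1.0))
    dyads = pd.DataFrame(dyad_rows, columns=["chrom", "position",
                                             "fuzziness_sd",
                                             "relative_occupancy"])

    abf1_sites = []
    for chrom, length in config.chromosomes:
        for pos in range(config.abf1_spacing_bp // 2, length,
                         config.abf1_spacing_bp):
            if all(abs(pos - o.acs_position) > 2000 for o in origins
                   if o.chrom == chrom):
                abf1_sites.append((chrom, int(pos)))

    layout = GenomeLayout(
        chromosomes=[(c, int(l)) for c, l in config.chromosomes],
        dyads=dyads, origins=origins, abf1_sites=abf1_sites,
        background_rate=config.background_rate,
        nucleosome_weight=config.nucleosome_weight,
        abf1_weight=config.abf1_weight,
        disruption_band_bp=config.disruption_band_bp,
        disrupted_fuzziness_sd=config.disrupted_fuzziness_sd,
        nuc_size_mean=config.nuc_size_mean,
        nuc_size_sd=config.nuc_size_sd,
        nuc_size_range=tuple(config.nuc_size_range),
        footprint_size_range=tuple(config.footprint_size_range),
        footprint_jitter_sd=config.footprint_jitter_sd,
        background_size_range=tuple(config.background_size_range),
    )
    layout.validate()
    return layout


def build_timepoints(config: SimulationConfig,
                     layout: GenomeLayout) -> list[TimePointSpec]:
    """Per-time-point replicated distances from each origin.

    Deterministic bidirectional fork: distance = speed * (t - activation),
    clipped at half the minimum origin spacing (where converging forks
    merge) or the configured maximum.
    """
    max_front = config.max_front_bp
    if max_front is None:
        spacing = layout.min_origin_spacing()
        max_front = (spacing / 2.0 if np.isfinite(spacing)
                     else max(l for _, l in layout.chromosomes))
    tps = []
    for lab, t in zip(config.labels(), config.minutes()):
        fronts, travels = {}, {}
        for o in layout.origins:
            if o.activation_time is None or t <= o.activation_time:
                travel = 0.0
            else:
                travel = config.fork_speed_bp_per_min * (t - o.activation_time)
            travels[o.name] = float(travel)
            fronts[o.name] = float(min(travel, max_front))
        tps.append(TimePointSpec(lab, t, fronts, travels))
    return tps


# --------------------------------------------------------------------------
# sampling

def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for lo, hi in iv[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [(lo, hi) for lo, hi in out]


def _replicated_intervals(layout: GenomeLayout, tp: TimePointSpec
                          ) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for o in layout.origins:
        f = tp.replication_front_bp.get(o.name, 0.0)
        if f > 0:
            length = layout.chrom_length(o.chrom)
            by_chrom.setdefault(o.chrom, []).append(
                (max(0, int(o.acs_position - f)),
                 min(length, int(o.acs_position + f))))
    return {c: _merge_intervals(v) for c, v in by_chrom.items()}


def _in_intervals(pos: np.ndarray, intervals: list[tuple[int, int]]
                  ) -> np.ndarray:
    if not intervals:
        return np.zeros(len(pos), dtype=bool)
    starts = np.array([lo for lo, _ in intervals])
    ends = np.array([hi for _, hi in intervals])
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


def _disrupted(pos: np.ndarray, chrom: str, layout: GenomeLayout,
               tp: TimePointSpec) -> np.ndarray:
    """Loci in the fork-disruption band of any active origin: the fork has
    passed within the last ``disruption_band_bp`` of travel."""
    out = np.zeros(len(pos), dtype=bool)
    for o in layout.origins:
        if o.chrom != chrom:
            continue
        f = tp.replication_front_bp.get(o.name, 0.0)
        travel = tp.fork_travel_bp.get(o.name, f)
        if f <= 0:
            continue
        d = np.abs(pos - o.acs_position)
        # band trails the moving fork; once travel passes the merge point
        # the band leaves the replicated extent and chromatin is restored
        out |= (d <= f) & (d > travel - layout.disruption_band_bp)
    return out


def simulate_sample(layout: GenomeLayout, tp: TimePointSpec, depth: int,
                    seed: int, replicate: str | None = None) -> FragmentSet:
    """Draw one sample of ``depth`` fragments for one time point.

    Sampling weights: nucleosome_weight x relative occupancy per dyad,
    the origin's time-dependent footprint occupancy at its ACS, the Abf1p
    weight per calibration site, and background_rate per bp — each doubled
    behind the replication front.  Fragment counts per source are
    multinomial, so they sum to ``depth`` exactly; the per-fragment source
    is recorded in a ``source`` column.
    """
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    rng = np.random.default_rng(seed)
    replicated = _replicated_intervals(layout, tp)

    emit_chrom: list[str] = []
    emit_pos: list[float] = []
    emit_sd: list[float] = []
    emit_weight: list[float] = []
    emit_kind: list[str] = []
    emit_seg: list[tuple[int, int] | None] = []

    def add(chrom, pos, sd, w, kind, seg=None):
        emit_chrom.append(chrom); emit_pos.append(pos); emit_sd.append(sd)
        emit_weight.append(w); emit_kind.append(kind); emit_seg.append(seg)

    # grid dyads
    for chrom, _ in layout.chromosomes:
        sub = layout.dyads[layout.dyads["chrom"] == chrom]
        if not len(sub):
            continue
        pos = sub["position"].to_numpy()
        sd = sub["fuzziness_sd"].to_numpy(dtype=float).copy()
        occ = sub["relative_occupancy"].to_numpy(dtype=float)
        disrupted = _disrupted(pos, chrom, layout, tp)
        sd[disrupted] = np.maximum(sd[disrupted], layout.disrupted_fuzziness_sd)
        copy = np.where(_in_intervals(pos, replicated.get(chrom, [])), 2.0, 1.0)
        for p, s, o, c in zip(pos, sd, occ, copy):
            add(chrom, float(p), float(s), layout.nucleosome_weight * o * c,
                "nucleosome")

    # planted -1/+1 dyads of each origin
    for o in layout.origins:
        iv = replicated.get(o.chrom, [])
        for p in (o.minus_one_position(), o.plus_one_position(tp.label)):
            arr = np.array([p])
            sd = layout.dyads["fuzziness_sd"].iloc[0] if len(layout.dyads) \
                else 10.0
            if _disrupted(arr, o.chrom, layout, tp)[0]:
                sd = max(sd, layout.disrupted_fuzziness_sd)
            c = 2.0 if _in_intervals(arr, iv)[0] else 1.0
            add(o.chrom, float(p), float(sd), layout.nucleosome_weight * c,
                "nucleosome")

    # footprints: origins (time-varying) and Abf1p-like sites (constant)
    for o in layout.origins:
        c = 2.0 if _in_intervals(np.array([o.acs_position]),
                                 replicated.get(o.chrom, []))[0] else 1.0
        add(o.chrom, float(o.acs_position), layout.footprint_jitter_sd,
            o.footprint_occupancy_by_time[tp.label] * c, "footprint")
    for chrom, pos in layout.abf1_sites:
        c = 2.0 if _in_intervals(np.array([pos]),
                                 replicated.get(chrom, []))[0] else 1.0
        add(chrom, float(pos), layout.footprint_jitter_sd,
            layout.abf1_weight * c, "footprint")

    # background segments (uniform within; copy 2 inside replicated spans)
    for chrom, length in layout.chromosomes:
        bounds = [0] + [x for lo, hi in replicated.get(chrom, [])
                        for x in (lo, hi)] + [length]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi <= lo:
                continue
            c = 2.0 if _in_intervals(np.array([lo]),
                                     replicated.get(chrom, []))[0] else 1.0
            add(chrom, 0.0, 0.0, layout.background_rate * (hi - lo) * c,
                "background", seg=(lo, hi))

    weights = np.asarray(emit_weight, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all sampling weights are zero")
    counts = (rng.multinomial(depth, weights / weights.sum()) if depth
              else np.zeros(len(weights), dtype=int))

    size_lo, size_hi = layout.nuc_size_range
    a = (size_lo - layout.nuc_size_mean) / layout.nuc_size_sd
    b = (size_hi - layout.nuc_size_mean) / layout.nuc_size_sd
    fp_lo, fp_hi = layout.footprint_size_range
    bg_lo, bg_hi = layout.background_size_range
    chrom_len = dict(layout.chromosomes)

    recs_chrom: list[np.ndarray] = []
    recs_mid: list[np.ndarray] = []
    recs_size: list[np.ndarray] = []
    recs_src: list[np.ndarray] = []
    for kind in ("nucleosome", "footprint", "background"):
        idx = [i for i, k in enumerate(emit_kind) if k == kind]
        n_by = np.array([counts[i] for i in idx])
        total = int(n_by.sum())
        if total == 0:
            continue
        chroms = np.repeat([emit_chrom[i] for i in idx], n_by)
        if kind == "background":
            los = np.repeat([emit_seg[i][0] for i in idx], n_by)
            his = np.repeat([emit_seg[i][1] for i in idx], n_by)
            mids = los + rng.integers(0, his - los)
            sizes = rng.integers(bg_lo, bg_hi + 1, size=total)
        else:
            pos = np.repeat([emit_pos[i] for i in idx], n_by)
            sds = np.repeat([emit_sd[i] for i in idx], n_by)
            mids = np.rint(pos + rng.standard_normal(total) * sds).astype(np.int64)
            if kind == "nucleosome":
                sizes = np.rint(stats.truncnorm.rvs(
                    a, b, loc=layout.nuc_size_mean, scale=layout.nuc_size_sd,
                    size=total, random_state=rng)).astype(np.int64)
                sizes = np.clip(sizes, size_lo, size_hi)
            else:
                sizes = rng.integers(fp_lo, fp_hi + 1, size=total)
        recs_chrom.append(chroms)
        recs_mid.append(mids)
        recs_size.append(sizes)
        recs_src.append(np.full(total, kind))

    if recs_chrom:
        chroms = np.concatenate(recs_chrom)
        mids = np.concatenate(recs_mid).astype(np.int64)
        sizes = np.concatenate(recs_size).astype(np.int64)
        srcs = np.concatenate(recs_src)
        lengths = np.array([chrom_len[c] for c in chroms])
        starts = np.clip(mids - sizes // 2, 0, lengths - sizes)
        df = pd.DataFrame({"chrom": chroms, "start": starts,
                           "end": starts + sizes, "source": srcs})
    else:
        df = pd.DataFrame(columns=["chrom", "start", "end", "source"])
    fs = FragmentSet(tp.label, _finalize_frame(df), replicate=replicate,
                     provenance=[f"simulate(seed={seed}, depth={depth})"])
    return fs


def simulate_timecourse(layout: GenomeLayout, timepoints: list[TimePointSpec],
                        depth: int, n_replicates: int = 2,
                        master_seed: int = 0
                        ) -> tuple[list[FragmentSet], SyntheticTruth]:
    """One FragmentSet per (time point x replicate), plus the truth record.

    Per-sample seeds are derived from the master seed, so any sample can be
    regenerated in isolation, byte-for-byte.
    """
    labels = [tp.label for tp in timepoints]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate time-point labels")
    if not timepoints:
        raise ValueError("need at least one time point")
    seed_rng = np.random.default_rng(master_seed)
    sample_seeds = seed_rng.integers(0, 2**31 - 1,
                                     size=len(timepoints) * n_replicates)
    sets: list[FragmentSet] = []
    seed_rows, count_rows = [], []
    i = 0
    for rep in range(1, n_replicates + 1):
        for tp in timepoints:
            s = int(sample_seeds[i]); i += 1
            fs = simulate_sample(layout, tp, depth, s, replicate=f"rep{rep}")
            sets.append(fs)
            seed_rows.append({"time": tp.label, "replicate": f"rep{rep}",
                              "seed": s})
            vc = (fs.frags["source"].value_counts() if len(fs)
                  else pd.Series(dtype=int))
            for src in ("nucleosome", "footprint", "background"):
                count_rows.append({"time": tp.label, "replicate": f"rep{rep}",
                                   "source": src, "count": int(vc.get(src, 0))})
    truth = SyntheticTruth(layout, timepoints, pd.DataFrame(seed_rows),
                           pd.DataFrame(count_rows))
    return sets, truth
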