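"""Synthetic-data benchmarks: plant a known signal, run the pipeline, and
measure how well it is recovered.

Each function builds its own inputs from a seed, executes the relevant
stage(s), and returns the measured quantities.  They are the package's
self-checks: dyad-position recovery by the kernel score, exactness of the
per-size depth equalization, copy-number ratio recovery behind a planted
replication fork, mass conservation of the footprint KDE, recovery of a
planted footprint-efficiency correlation, and the cell-cycle orderings
(footprint peak timing, correlation peak timing, fork-coupled entropy lag)
from a full end-to-end run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import equalize as eq
from .entropy import shannon_entropy
from .footprint import acs_footprint_density, small_fragment_track
from .nucleosome import (aggregate_reference_pileup, compute_copy_number,
                         copy_number_track, fit_kernel, normalize_track,
                         nucleosome_score_track)
from .origins import efficiency_correlation
from .pipeline import RunConfig, run_all
from .synthetic import (SimulationConfig, build_layout, build_timepoints,
                        simulate_sample)


def _seed_stream(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------

def dyad_recovery(seed: int, n_nucleosomes: int = 50, fuzziness: float = 10.0,
                  fragments_per_nucleosome: int = 30) -> dict:
    """Plant an array of nucleosomes, score it with a kernel fitted to its
    own dyad pileup, and measure the fraction of per-nucleosome score maxima
    within 15 bp of the planted dyads."""
    from .synthetic import GenomeLayout
    spacing = 165
    margin = 1_000
    length = n_nucleosomes * spacing + 2 * margin
    positions = margin + spacing // 2 + spacing * np.arange(n_nucleosomes)
    dyads = pd.DataFrame({"chrom": "chrS", "position": positions,
                          "fuzziness_sd": fuzziness,
                          "relative_occupancy": 1.0})
    layout = GenomeLayout(chromosomes=[("chrS", length)], dyads=dyads,
                          origins=[], abf1_sites=[], background_rate=0.0,
                          nucleosome_weight=1.0, abf1_weight=0.0,
                          disruption_band_bp=0.0, disrupted_fuzziness_sd=0.0)
    from .synthetic import TimePointSpec
    tp = TimePointSpec("t0", 0.0, {})
    depth = n_nucleosomes * fragments_per_nucleosome
    fs = simulate_sample(layout, tp, depth, seed)
    pileup = aggregate_reference_pileup(fs, layout.dyad_list(), halfwidth=100)
    kernel = fit_kernel(pileup)
    track = nucleosome_score_track(fs, "chrS", length, kernel)
    half = spacing // 2
    hits = 0
    for p in positions:
        window = track.values[p - half: p + half + 1]
        offset = int(np.argmax(window)) - half
        hits += abs(offset) <= 15
    return {"recovered_frac": hits / n_nucleosomes, "n": n_nucleosomes}


def equalization_exactness(seed: int, total_fragments: int = 100_000,
                           n_timepoints: int = 4) -> dict:
    """Random fragment sets; after per-size subsampling every size must have
    identical counts across time points and be a subset of its input."""
    rng = np.random.default_rng(seed)
    per = total_fragments // n_timepoints
    sets = []
    for i in range(n_timepoints):
        starts = rng.integers(0, 10**7, size=per)
        lengths = rng.integers(20, 251, size=per)
        df = pd.DataFrame({"chrom": "chrS", "start": starts,
                           "end": starts + lengths})
        from .fragment_io import FragmentSet, _finalize_frame
        sets.append(FragmentSet(f"t{i}", _finalize_frame(df)))
    table = eq.compute_depths(sets)
    subset_ok = True
    sub_seeds = _seed_stream(seed, n_timepoints)
    hists = []
    for fs, s in zip(sets, sub_seeds):
        sub = eq.subsample(fs, table, seed=s)
        lens = sub.frags["length"].to_numpy()
        hists.append(np.bincount(lens - 20, minlength=231))
        orig = set(map(tuple, fs.frags[["start", "end"]].to_numpy()))
        kept = set(map(tuple, sub.frags[["start", "end"]].to_numpy()))
        subset_ok &= kept <= orig
    hists = np.stack(hists)
    spreads = (hists.max(axis=0) - hists.min(axis=0)).max()
    return {"max_count_spread": int(spreads),
            "subset_ok": bool(subset_ok), "n": total_fragments}


def entropy_closed_forms() -> dict:
    """Uniform, point-mass and rescaled windows against the closed forms."""
    uniform = shannon_entropy(np.ones(1000))
    point = np.zeros(1000)
    point[500] = 3.0
    rng_scores = np.linspace(0.1, 5.0, 1000)
    scale_err = abs(shannon_entropy(rng_scores)
                    - shannon_entropy(1e3 * rng_scores))
    return {"uniform_entropy": uniform,
            "point_mass_entropy": shannon_entropy(point),
            "scale_invariance_error": scale_err, "n": 1000}


def copy_number_recovery(seed: int, depth: int = 1_000_000) -> dict:
    """A replicated ACS-centered window versus the G1 reference.

    A small chromosome carries one active origin whose footprint source
    holds ~1% of the genome-wide sampling weight, so the 1001 bp window
    around the ACS collects ~10^4 fragments; a large unreplicated chromosome
    carries the rest.  The expected RPKM ratio is 2 (up to the ~1% of newly
    replicated weight entering the sample total)."""
    from .synthetic import GenomeLayout, OriginTruth, TimePointSpec
    big_positions = np.arange(82, 200_000, 165)
    dyads = pd.DataFrame({"chrom": "chrB", "position": big_positions,
                          "fuzziness_sd": 10.0, "relative_occupancy": 1.0})
    w_rest = len(big_positions) * 20.0
    w_site = w_rest / 99.0
    origin = OriginTruth("oriA", "chrA", 5_000, "+", "G1&G2", 0.8, 10.0,
                         {"alpha": w_site, "t30": w_site},
                         {"alpha": 129, "t30": 129}, -129)
    layout = GenomeLayout(chromosomes=[("chrA", 10_000), ("chrB", 200_000)],
                          dyads=dyads, origins=[origin], abf1_sites=[],
                          background_rate=0.0, nucleosome_weight=20.0,
                          abf1_weight=0.0, disruption_band_bp=0.0,
                          disrupted_fuzziness_sd=0.0)
    s1, s2 = _seed_stream(seed, 2)
    ref = simulate_sample(layout, TimePointSpec("alpha", 0.0, {"oriA": 0.0}),
                          depth, s1)
    samp = simulate_sample(layout,
                           TimePointSpec("t30", 30.0, {"oriA": 2_000.0}),
                           depth, s2)
    ratio = compute_copy_number(samp, ref, "chrA", 5_000)
    mids_r = ref.on_chrom("chrA")["midpoint"].to_numpy()
    mids_t = samp.on_chrom("chrA")["midpoint"].to_numpy()
    c_ref = int(((mids_r >= 4_500) & (mids_r < 5_501)).sum())
    c_t = int(((mids_t >= 4_500) & (mids_t < 5_501)).sum())
    sd = ratio * np.sqrt(1.0 / c_ref + 1.0 / c_t)
    return {"ratio": float(ratio), "sd": float(sd),
            "window_fragments": c_ref, "n": depth}


def normalized_score_parity(seed: int, depth: int = 300_000) -> dict:
    """Identical nucleosome arrays inside and outside a replication front:
    after copy-number normalization their mean kernel scores should agree."""
    from .synthetic import GenomeLayout, OriginTruth, TimePointSpec
    length = 200_000
    positions = np.arange(82, length, 165)
    keep = np.abs(positions - 50_000) > 211
    dyads = pd.DataFrame({"chrom": "chrS", "position": positions[keep],
                          "fuzziness_sd": 10.0, "relative_occupancy": 1.0})
    origin = OriginTruth("oriA", "chrS", 50_000, "+", "G1&G2", 0.8, 10.0,
                         {"alpha": 0.0, "t30": 0.0},
                         {"alpha": 129, "t30": 129}, -129)
    layout = GenomeLayout(chromosomes=[("chrS", length)], dyads=dyads,
                          origins=[origin], abf1_sites=[],
                          background_rate=0.0, nucleosome_weight=20.0,
                          abf1_weight=0.0, disruption_band_bp=0.0,
                          disrupted_fuzziness_sd=0.0)
    s1, s2 = _seed_stream(seed, 2)
    ref = simulate_sample(layout, TimePointSpec("alpha", 0.0, {"oriA": 0.0}),
                          depth, s1)
    samp = simulate_sample(layout,
                           TimePointSpec("t30", 30.0, {"oriA": 30_000.0}),
                           depth, s2)
    pileup = aggregate_reference_pileup(ref, layout.dyad_list(), halfwidth=100)
    kernel = fit_kernel(pileup)
    cn = copy_number_track(samp, ref, "chrS", length)
    track = normalize_track(
        nucleosome_score_track(samp, "chrS", length, kernel), cn)
    pos = dyads["position"].to_numpy()
    replicated = pos[(pos > 25_000) & (pos < 75_000)]
    control = pos[(pos > 120_000) & (pos < 170_000)]
    mean_rep = float(np.nanmean(track.values[replicated]))
    mean_un = float(np.nanmean(track.values[control]))
    return {"score_ratio": mean_rep / mean_un,
            "n": len(replicated) + len(control)}


def kde_mass_conservation(seed: int, n_fragments: int = 10_000,
                          length: int = 100_000) -> dict:
    """Uniform sub-120 bp midpoints: interior mean of the KDE track vs 1."""
    from .fragment_io import FragmentSet, _finalize_frame
    rng = np.random.default_rng(seed)
    mids = rng.integers(0, length, size=n_fragments)
    df = pd.DataFrame({"chrom": "chrS", "start": mids - 40,
                       "end": mids + 40})
    fs = FragmentSet("t0", _finalize_frame(df))
    track = small_fragment_track(fs, "chrS", length, bandwidth=50)
    margin = 150
    return {"interior_mean": float(track.values[margin:length - margin].mean()),
            "n": n_fragments}


def correlation_recovery(seed: int, n_origins: int = 300,
                         depth: int = 600_000,
                         target_rho: float = 0.6,
                         n_permutations: int = 100) -> dict:
    """Plant a footprint-occupancy/efficiency coupling at population Spearman
    0.6 across 300 origins, measure the recovered correlation at the
    occupancy peak, and the null distribution under permuted efficiencies."""
    config = SimulationConfig(
        chromosomes=[["chrS", 4_020 * (n_origins + 1)]],
        timepoints_min=[20], n_origins_g1g2=n_origins, n_origins_g1only=0,
        efficiency_range_g1g2=(0.0, 1.0),
        efficiency_coupling_spearman=target_rho, aggregate_halfspan=500)
    s_layout, s_sim = _seed_stream(seed, 2)
    layout = build_layout(config, seed=s_layout)
    tp = build_timepoints(config, layout)[1]       # the t20 occupancy peak
    fs = simulate_sample(layout, tp, depth, s_sim)
    length = layout.chrom_length("chrS")
    track = small_fragment_track(fs, "chrS", length)
    dens = pd.DataFrame({
        "t20": [acs_footprint_density(track, o.acs_position)
                for o in layout.origins]},
        index=[o.name for o in layout.origins])
    eff = pd.Series({o.name: o.efficiency for o in layout.origins})
    rho = float(efficiency_correlation(dens, eff).loc["t20", "rho"])
    rng = np.random.default_rng(seed + 1)
    null_ok = 0
    x = np.log2(dens["t20"].to_numpy() + 1e-9)
    for _ in range(n_permutations):
        r = stats.spearmanr(x, rng.permutation(eff.to_numpy())).statistic
        null_ok += abs(r) < 0.15
    return {"rho": rho, "null_frac_below_0.15": null_ok / n_permutations,
            "n": n_origins}


# ---------------------------------------------------------------------------

def end_to_end_config(outdir: str, seed: int, n_per_class: int = 20,
                      depth: int = 60_000) -> RunConfig:
    """The study-condition synthetic time course: 16 time points (alpha +
    every 10 min to 150 min), two replicates, origins of both footprint
    classes with planted occupancy peak at 20 min, fork-coupled nucleosome
    disruption, and efficiency-coupled footprint amplitudes."""
    n = 2 * n_per_class
    return RunConfig(
        outdir=outdir, master_seed=seed, depth=depth, n_replicates=2,
        synthetic=dict(
            chromosomes=[["chrS", 36_000 * (n + 1)]],
            timepoints_min=list(range(10, 151, 10)),
            n_origins_g1g2=n_per_class, n_origins_g1only=n_per_class,
        ),
        write_fragments=False)


def end_to_end_orderings(outdir: str, seed: int, **kw) -> dict:
    """Run the full pipeline on the study-condition course and extract the
    cell-cycle orderings and origin-architecture summaries."""
    res = run_all(end_to_end_config(outdir, seed, **kw))
    truth = res.truth

    def minutes(label: str) -> float:
        return truth.timepoint(label).minutes

    # planted expectation for the footprint curve: occupancy / ACS copy number
    g1g2 = [o for o in truth.layout.origins if o.footprint_class == "G1&G2"]
    planted = pd.concat([truth.expected_relative_density(o) for o in g1g2],
                        axis=1).mean(axis=1)
    planted_peak = minutes(planted.idxmax())
    measured_peak = minutes(res.peak_average.loc["G1&G2"].idxmax())

    rho = res.rho["rho"]
    rho_minutes = np.array([minutes(lab) for lab in rho.index])
    rho_peak = minutes(rho.idxmax())
    # first cell cycle only (the planted coupling repeats, dampened, in the
    # second cycle, where loss-of-synchrony noise can shift the global max)
    first_cycle = rho[rho_minutes <= 70]
    rho_peak_first_cycle = minutes(first_cycle.idxmax())

    z = res.entropy_active.aggregate_z
    proximal_peak = minutes(z.iloc[0].idxmax())
    distal_peak = minutes(z.iloc[-1].idxmax())

    widths = res.dyads.groupby("class")["nfr_width"].median()

    # modal fragment size from a deep alpha-sample draw of the same layout;
    # a 3 bp moving average tames bin noise at the distribution's flat top
    alpha_tp = truth.timepoints[0]
    fs = simulate_sample(truth.layout, alpha_tp, 1_000_000,
                         _seed_stream(seed, 3)[2])
    hist = np.bincount(fs.frags["length"].to_numpy(), minlength=251)
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    mode_size = int(np.argmax(smooth))

    return {
        "planted_footprint_peak_min": planted_peak,
        "measured_footprint_peak_min": measured_peak,
        "rho_peak_min": rho_peak,
        "rho_peak_first_cycle_min": rho_peak_first_cycle,
        "rho_at_peak": float(res.rho["rho"].max()),
        "entropy_proximal_peak_min": proximal_peak,
        "entropy_distal_peak_min": distal_peak,
        "nfr_width_g1g2": float(widths["G1&G2"]),
        "nfr_width_g1only": float(widths["G1only"]),
        "modal_fragment_size": mode_size,
        "n_origins": len(truth.layout.origins),
        "result": res,
    }
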