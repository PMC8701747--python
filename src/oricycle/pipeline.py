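"""End-to-end orchestration: simulate (optional) -> equalize -> nucleosome
scoring -> footprint density -> entropy -> origin summaries.

``run_all`` executes the stages on either a synthetic time course (the
generator's planted genome) or user-supplied fragment files, writes all
intermediate tables as plain text, and records a manifest (parameters,
per-sample seeds, SHA-256 checksums of every output) sufficient to verify a
re-run reproduces the same results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import equalize as eq
from . import footprint as fp
from . import nucleosome as nuc
from . import origins as ori
from . import synthetic as syn
from .entropy import EntropyMatrix, entropy_heatmap
from .fragment_io import FragmentSet, apply_exclusions, read_fragments, write_bed


@dataclass
class RunConfig:
    """One auditable home for every pipeline constant and input path."""

    outdir: str = "oricycle_run"
    master_seed: int = 0

    # synthetic mode: generator parameters (SimulationConfig fields)
    synthetic: dict | None = field(default_factory=dict)
    depth: int = 40_000
    n_replicates: int = 2

    # real-data mode: {"fragments": {label: {rep: path}}, "origins": path,
    # "dyads": path, "abf1": path, "chromosomes": [[name, length]]}
    inputs: dict | None = None
    apply_saccer3_exclusions: bool = False

    # scoring constants
    kernel_halfwidth: int = 100
    small_fragment_cutoff: int = 120
    kde_bandwidth: float = 50.0
    cn_window: int = 1001
    shrink_size: float = 1.0 / 16.0
    shrink_pos: float = 1.0 / 4.0
    entropy_window: int = 1000
    entropy_span: int = 30_000
    dyad_search: tuple = (10, 500)
    top_fraction: float = 0.2
    footprint_peak_halfwidth: int = 100
    write_fragments: bool = True

    def __post_init__(self) -> None:
        if self.synthetic is None and self.inputs is None:
            raise ValueError("config needs either 'synthetic' or 'inputs'")
        if self.inputs is not None:
            for key in ("fragments", "origins", "chromosomes"):
                if key not in self.inputs:
                    raise ValueError(f"inputs missing required field {key!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunResult:
    """In-memory results of a pipeline run (the files hold the same data)."""

    manifest: dict
    origins: list
    density: pd.DataFrame                 # origins x time points (calibrated)
    rho: pd.DataFrame                     # per-time-point Spearman
    dyads: pd.DataFrame                   # aggregate dyad calls / NFR widths
    peak_average: pd.DataFrame            # class x time footprint averages
    entropy_active: EntropyMatrix | None
    entropy_passive: EntropyMatrix | None
    nucleosome_tracks: dict               # label -> chrom -> OccupancyTrack
    footprint_tracks: dict
    truth: "syn.SyntheticTruth | None" = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_real_inputs(config: RunConfig):
    inputs = config.inputs
    chromosomes = [(c, int(l)) for c, l in inputs["chromosomes"]]
    origin_list = ori.load_origins(inputs["origins"])
    by_rep: dict[str, list[FragmentSet]] = {}
    for label, reps in inputs["fragments"].items():
        for rep, path in reps.items():
            fs = read_fragments(path, label=label, replicate=rep)
            if config.apply_saccer3_exclusions:
                fs = apply_exclusions(fs)
            by_rep.setdefault(rep, []).append(fs)
    dyads = []
    if inputs.get("dyads"):
        bed = pd.read_csv(inputs["dyads"], sep="\t", header=None,
                          usecols=[0, 1], names=["chrom", "pos"])
        dyads = list(zip(bed["chrom"], bed["pos"].astype(int)))
    abf1 = []
    if inputs.get("abf1"):
        bed = pd.read_csv(inputs["abf1"], sep="\t", header=None,
                          usecols=[0, 1], names=["chrom", "pos"])
        abf1 = list(zip(bed["chrom"], bed["pos"].astype(int)))
    labels = list(inputs["fragments"])
    return chromosomes, origin_list, dyads, abf1, by_rep, labels, None


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline; see the module docstring.

    Deterministic: rerunning with the same configuration (including
    ``master_seed``) reproduces identical output checksums.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_root = np.random.default_rng(config.master_seed)
    stage_seeds = {name: int(s) for name, s in zip(
        ("simulate", "equalize"),
        seed_root.integers(0, 2**31 - 1, size=2))}
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **kw)
        written.append(path)

    truth = None
    if config.inputs is not None:
        (chromosomes, origin_list, dyad_list, abf1_sites, by_rep, labels,
         truth) = _load_real_inputs(config)
    else:
        sim_config = syn.SimulationConfig(**(config.synthetic or {}))
        layout = syn.build_layout(sim_config, seed=stage_seeds["simulate"])
        timepoints = syn.build_timepoints(sim_config, layout)
        sets, truth = syn.simulate_timecourse(
            layout, timepoints, config.depth, config.n_replicates,
            master_seed=stage_seeds["simulate"])
        truth.write(outdir / "truth")
        written.extend(sorted((outdir / "truth").glob("*.tsv")))
        if config.write_fragments:
            frag_dir = outdir / "fragments"
            frag_dir.mkdir(exist_ok=True)
            for fs in sets:
                p = frag_dir / f"{fs.label}_{fs.replicate}.bed"
                write_bed(fs, p)
                written.append(p)
        chromosomes = layout.chromosomes
        origin_list = layout.annotations()
        dyad_list = layout.dyad_list()
        abf1_sites = layout.abf1_sites
        labels = [tp.label for tp in timepoints]
        by_rep = {}
        for fs in sets:
            by_rep.setdefault(fs.replicate, []).append(fs)

    # ---- equalize within each replicate, then merge matched time points
    eq_rng = np.random.default_rng(stage_seeds["equalize"])
    merged: dict[str, FragmentSet] = {}
    for rep in sorted(by_rep):
        sets_r = by_rep[rep]
        table = eq.compute_depths(sets_r)
        save(table.counts.assign(minimum=table.minimum),
             f"depth_table_{rep}.tsv", index_label="size")
        for fs in sets_r:
            sub = eq.subsample(fs, table,
                               seed=int(eq_rng.integers(0, 2**31 - 1)))
            merged[fs.label] = (sub if fs.label not in merged
                                else eq.merge_matched(merged[fs.label], sub))

    ref_label = "alpha" if "alpha" in merged else labels[0]
    ref_fs = merged[ref_label]

    # ---- nucleosome kernel from the reference sample's dyad pileup
    pileup = nuc.aggregate_reference_pileup(
        ref_fs, dyad_list, halfwidth=config.kernel_halfwidth,
        chrom_lengths=dict(chromosomes))
    kernel = nuc.fit_kernel(pileup, halfwidth=config.kernel_halfwidth,
                            shrink_size=config.shrink_size,
                            shrink_pos=config.shrink_pos)
    kernel.to_files(outdir / "kernel.tsv", outdir / "kernel.json")
    written += [outdir / "kernel.tsv", outdir / "kernel.json"]

    # ---- per-time-point tracks
    nuc_tracks: dict[str, dict] = {}
    fp_tracks: dict[str, dict] = {}
    for label in labels:
        fs = merged[label]
        cn = {c: nuc.copy_number_track(fs, ref_fs, c, l, config.cn_window)
              for c, l in chromosomes}
        nuc_tracks[label] = {
            c: nuc.normalize_track(
                nuc.nucleosome_score_track(fs, c, l, kernel), cn[c])
            for c, l in chromosomes}
        raw_fp = {c: fp.small_fragment_track(
            fs, c, l, config.kde_bandwidth, config.small_fragment_cutoff)
            for c, l in chromosomes}
        fp_tracks[label], _ = fp.calibrated_footprint_tracks(
            raw_fp, abf1_sites, cn=cn)

    # ---- origin-level summaries
    density = fp.density_table(fp_tracks, origin_list)
    density = density.reindex(columns=labels)
    save(density, "density.tsv", index_label="origin")

    efficiencies = pd.Series({o.name: o.efficiency for o in origin_list})
    rho = ori.efficiency_correlation(density, efficiencies)
    save(rho, "rho.tsv")

    dyad_calls = ori.dyad_table(nuc_tracks, origin_list,
                                search=tuple(config.dyad_search))
    save(dyad_calls, "dyad_calls.tsv", index=False)

    fp_aggs = ori.class_aggregates(fp_tracks, origin_list,
                                   halfspan=config.dyad_search[1])
    peak_rows = {cls: ori.footprint_peak_average(
        profiles, config.footprint_peak_halfwidth)
        for cls, profiles in fp_aggs.items()}
    peak_average = pd.DataFrame(peak_rows).T.reindex(columns=labels)
    save(peak_average, "footprint_peak_average.tsv", index_label="class")

    entropy_active = entropy_passive = None
    if len(labels) >= 2:
        active, passive = ori.split_by_efficiency(origin_list,
                                                  config.top_fraction)
        if active:
            entropy_active = entropy_heatmap(
                nuc_tracks, active, config.entropy_window, config.entropy_span)
            entropy_active.to_tsv(outdir / "entropy_active.tsv")
            written.append(outdir / "entropy_active.tsv")
        if passive:
            entropy_passive = entropy_heatmap(
                nuc_tracks, passive, config.entropy_window,
                config.entropy_span)
            entropy_passive.to_tsv(outdir / "entropy_passive.tsv")
            written.append(outdir / "entropy_passive.tsv")

    ori.save_origins(origin_list, outdir / "origins.tsv")
    written.append(outdir / "origins.tsv")

    manifest = {
        "master_seed": config.master_seed,
        "stage_seeds": stage_seeds,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("inputs",)},
        "time_points": labels,
        "reference": ref_label,
        "checksums": {str(p.relative_to(outdir)): _sha256(p)
                      for p in sorted(set(written))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return RunResult(manifest, origin_list, density, rho, dyad_calls,
                     peak_average, entropy_active, entropy_passive,
                     nuc_tracks, fp_tracks, truth)
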