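"""End-to-end orchestration: simulate → count → enrich → fit → meta-analysis.

A single YAML config drives a full two-condition run on synthetic data; every
stage output lands in the run directory and is recorded in a manifest with
its SHA-256, the config hash and the seed, so a rerun with the same config
and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from replitime import io as rio
from replitime import simulate as sim
from replitime.binning import BinnedGenome, compute_at_ratio
from replitime.enrichment import EnrichmentTrack, enrichment_chain
from replitime.gel import dotblot_ratio, fraction_below, intensity_to_fractions
from replitime.origins import (
    classify_regions,
    designate_tracks,
    detect_origins,
    overlay_tracks,
    select_deviant_late,
)
from replitime.timing import (
    ReplicationTimingModel,
    compare_conditions,
    global_curve_from_dotblot,
    local_extent,
    profile_at_matched_g,
)

DEFAULT_THRESHOLDS = {
    "min_input_count": 5,
    "min_at": 0.05,
    "half_window_bins": 8,
    "min_prominence_frac": 0.25,
    "min_separation_kb": 9.0,
    "shoulder_min_kb": 15.0,
    "k_sd": 2.0,
}

THRESHOLD_RANGES = {
    "min_input_count": (0, 1000),
    "min_at": (0.0, 1.0),
    "half_window_bins": (0, 100),
    "min_prominence_frac": (0.0, 10.0),
    "min_separation_kb": (0.0, 1000.0),
    "shoulder_min_kb": (0.0, 1000.0),
    "k_sd": (0.0, 100.0),
}


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    bin_width: int = 300
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: list(sim.DEMO_CHROMOSOMES)
    )
    conditions: dict[str, dict] = field(
        default_factory=lambda: {
            "control": {"fork_speed_kb_min": 1.0},
            "mutant": {"fork_speed_kb_min": 0.8},
        }
    )
    timepoints: list[float] = field(default_factory=lambda: list(sim.DEMO_TIMEPOINTS))
    fit_timepoints: list[float] = field(
        default_factory=lambda: list(sim.DEMO_FIT_TIMEPOINTS)
    )
    ip_depth: float = 100.0
    input_depth: float = 100.0
    at_bias: bool = True
    hu_arrest_kb: float = 20.0  # forks keep elongating slowly under HU
    dotblot_noise_sd: float = 0.0
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    compare_g: float = 0.5
    overlay_g: float = 0.3  # early-S overlays keep tracks inside the ±15 kb window
    gel: dict = field(
        default_factory=lambda: {
            "fragment_mean_kb": {"control": 4.0, "mutant": 2.0},
            "n_fragments": 200_000,
            "band_sd_px": 2.0,
        }
    )
    reference_condition: str | None = None

    def __post_init__(self) -> None:
        missing = set(self.fit_timepoints) - set(self.timepoints)
        if missing:
            raise ValueError(f"fit timepoints not in timepoints: {sorted(missing)}")
        if len(self.fit_timepoints) < 3:
            raise ValueError("need at least 3 fit timepoints")
        thr = dict(DEFAULT_THRESHOLDS)
        thr.update(self.thresholds)
        for k, v in thr.items():
            lo, hi = THRESHOLD_RANGES[k]
            if not (lo <= v <= hi):
                raise ValueError(f"threshold {k}={v} outside [{lo}, {hi}]")
        self.thresholds = thr
        if self.reference_condition is None:
            self.reference_condition = next(iter(self.conditions))
        if self.reference_condition not in self.conditions:
            raise ValueError("reference_condition not among conditions")
        self.chromosomes = [(str(n), int(l)) for n, l in self.chromosomes]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "chromosomes" in raw:
            raw = dict(raw)
            raw["chromosomes"] = [tuple(c) for c in raw["chromosomes"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "bin_width": self.bin_width,
            "chromosomes": [[n, l] for n, l in self.chromosomes],
            "conditions": self.conditions,
            "timepoints": list(map(float, self.timepoints)),
            "fit_timepoints": list(map(float, self.fit_timepoints)),
            "ip_depth": self.ip_depth,
            "input_depth": self.input_depth,
            "at_bias": self.at_bias,
            "hu_arrest_kb": self.hu_arrest_kb,
            "dotblot_noise_sd": self.dotblot_noise_sd,
            "thresholds": self.thresholds,
            "compare_g": self.compare_g,
            "overlay_g": self.overlay_g,
            "gel": self.gel,
            "reference_condition": self.reference_condition,
        }

    def sim_config(self, condition: str, origins) -> sim.SimulationConfig:
        params = self.conditions[condition]
        return sim.SimulationConfig(
            chromosomes=list(self.chromosomes),
            origins=origins,
            timepoints=list(self.timepoints),
            bin_width=self.bin_width,
            fork_speed_kb_min=float(params.get("fork_speed_kb_min", 1.0)),
            ip_depth=self.ip_depth,
            input_depth=self.input_depth,
            at_bias=self.at_bias,
            hu_arrest_kb=self.hu_arrest_kb,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    files: list[Path] = []

    def save(path: Path) -> Path:
        files.append(path)
        return path

    cfg_path = save(out / "config.yaml")
    cfg_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    # shared origins and reference genome: fork speed is the only contrast
    origins = sim.demo_origins(config.seed, config.chromosomes)
    ref_cfg = config.sim_config(config.reference_condition, origins)
    seqs = sim.synthetic_genome_sequences(ref_cfg)
    rio.write_fasta(seqs, str(save(out / "genome.fa")))
    genome = BinnedGenome(list(config.chromosomes), config.bin_width)
    at = compute_at_ratio(seqs, genome)
    rio.write_track_tsv(
        EnrichmentTrack(genome, at, stage="at"), str(save(out / "at_ratio.tsv"))
    )

    results = {}
    summary: dict = {"conditions": {}}
    for cond in config.conditions:
        cdir = out / cond
        cdir.mkdir(exist_ok=True)
        scfg = config.sim_config(cond, origins)
        truth = sim.compute_truth(scfg)
        truth_df = genome.bins_dataframe()
        truth_df["half_rep_g"] = truth.half_rep_g
        for i, t in enumerate(truth.timepoints):
            truth_df[f"R_{t:g}"] = truth.r[i]
        truth_df.to_csv(save(cdir / "truth.tsv"), sep="\t", index=False)

        tracks_by_t, input_track = sim.emit_count_tracks(scfg, truth, at)
        rio.write_count_tsv(input_track, str(save(cdir / "input_counts.tsv")))
        for t, tr in tracks_by_t.items():
            rio.write_count_tsv(tr, str(save(cdir / f"ip_counts_t{t:g}.tsv")))
        curve, blot = sim.emit_global_curve(
            truth, scfg, noise_sd=config.dotblot_noise_sd
        )
        blot.to_csv(save(cdir / "dotblot.csv"), index=False)
        curve = global_curve_from_dotblot(str(cdir / "dotblot.csv"))

        eprime = {
            t: enrichment_chain(
                tr, input_track, at,
                min_input_count=thr["min_input_count"],
                min_at=thr["min_at"],
                half_window_bins=thr["half_window_bins"],
            )
            for t, tr in tracks_by_t.items()
        }
        series = local_extent(eprime, curve, t_last=float(config.timepoints[-1]))
        model = ReplicationTimingModel(series, curve, config.fit_timepoints)
        res = model.fit()
        results[cond] = {"res": res, "curve": curve, "eprime": eprime, "scfg": scfg}
        res.to_frame().to_csv(save(cdir / "model.tsv"), sep="\t", index=False, na_rep="NA")
        f = res.evaluate_extent([0.25, 0.5, 0.75])
        for gv, row in zip((25, 50, 75), f):
            rio.write_bedgraph(
                EnrichmentTrack(genome, row, stage=f"F{gv}"),
                str(save(cdir / f"F{gv}.bedgraph")),
            )
        summary["conditions"][cond] = {
            "fork_speed_kb_min": scfg.fork_speed_kb_min,
            "G_at_fit_timepoints": dict(
                zip(map(str, config.fit_timepoints),
                    [curve.g_at(t) for t in config.fit_timepoints])
            ),
            "n_converged": int((res.status == 0).sum()),
            "n_fallback": int((res.status == 1).sum()),
            "n_masked": int((res.status == 2).sum()),
        }

    # origin meta-analysis on the reference condition's HU sample
    ref = results[config.reference_condition]
    hu_track, hu_truth_bins = sim.emit_hu_sample(ref["scfg"], at)
    rio.write_count_tsv(hu_track, str(save(out / "hu_counts.tsv")))
    hu_profile = enrichment_chain(
        hu_track,
        _hu_input(ref["scfg"], genome),
        at,
        min_input_count=thr["min_input_count"],
        min_at=thr["min_at"],
        half_window_bins=thr["half_window_bins"],
    )
    origin_set = detect_origins(
        hu_profile,
        min_prominence_frac=thr["min_prominence_frac"],
        min_separation_kb=thr["min_separation_kb"],
    )
    origin_set.table.to_csv(save(out / "origins.tsv"), sep="\t", index=False)
    origin_set.to_bed(str(save(out / "origins.bed")))
    rep_tracks = designate_tracks(
        origin_set, hu_profile, shoulder_min_kb=thr["shoulder_min_kb"]
    )
    pd.DataFrame(
        [
            {
                "chrom": t.chrom,
                "peak_pos": t.peak_pos,
                "left_shoulder_bp": t.left_shoulder_bp,
                "right_shoulder_bp": t.right_shoulder_bp,
                "span_start_bin": t.span_bins[0],
                "span_end_bin": t.span_bins[1],
            }
            for t in rep_tracks
        ]
    ).to_csv(save(out / "tracks.tsv"), sep="\t", index=False)

    # peak-normalised overlays at matched global extent
    overlay_fwhm = {}
    if rep_tracks:
        for cond, r in results.items():
            prof = profile_at_matched_g(r["eprime"], r["curve"], config.overlay_g)
            ov = overlay_tracks(rep_tracks, prof)
            pd.DataFrame(
                {"offset_bp": ov["offsets_bp"], "average": ov["average"]}
            ).to_csv(save(out / f"overlay_{cond}.tsv"), sep="\t", index=False)
            overlay_fwhm[cond] = {"G": config.overlay_g, "fwhm_bp": ov["fwhm_bp"]}
    summary["overlay"] = overlay_fwhm

    # condition comparison on early/late classes
    conds = list(config.conditions)
    if len(conds) >= 2 and rep_tracks:
        ra = results[conds[0]]["res"]
        rb = results[conds[1]]["res"]
        classes = classify_regions(rep_tracks, genome, results=ra)
        comp = compare_conditions(
            ra, rb, classes, g=config.compare_g, alternative="greater"
        )
        rio.write_bedgraph(
            EnrichmentTrack(genome, comp["delta"], stage="deltaF"),
            str(save(out / "deltaF.bedgraph")),
        )
        deviants = select_deviant_late(ra, rb, classes, g=config.compare_g,
                                       k_sd=thr["k_sd"])
        rio.write_bed_bins(genome, deviants, str(save(out / "deviant_late.bed")),
                           name="deviant_late")
        comp_out = {k: v for k, v in comp.items() if k != "delta"}
        comp_out["n_deviant_late"] = int(deviants.size)
        # lateness (rank of 1 - F_control(0.75)) vs timing change: later loci
        # should show the larger slow-fork delay
        from scipy.stats import spearmanr

        f75 = results[conds[0]]["res"].evaluate_extent([0.75])[0]
        ok = ~np.isnan(f75) & ~np.isnan(comp["delta"])
        comp_out["lateness_vs_delta_spearman"] = float(
            spearmanr(-f75[ok], comp["delta"][ok]).statistic
        )
        rio.write_json(comp_out, str(save(out / "compare.json")))
        summary["compare"] = comp_out

    # S1 gel lanes per condition + gap dot-blot quantification
    ladder = sim.default_ladder()
    ladder.markers.to_csv(save(out / "ladder.csv"), index=False)
    gel_summary = {}
    means = config.gel["fragment_mean_kb"]
    for cond in config.conditions:
        lane = sim.emit_s1_lane(
            float(means[cond]),
            int(config.gel["n_fragments"]),
            ladder,
            band_sd_px=float(config.gel["band_sd_px"]),
            seed=config.seed,
            label=cond,
        )
        pd.DataFrame({"pixel": lane.pixel, "intensity": lane.intensity}).to_csv(
            save(out / f"gel_{cond}.csv"), index=False
        )
        dist = intensity_to_fractions(lane, ladder)
        dist.to_frame().to_csv(save(out / f"gel_fractions_{cond}.tsv"), sep="\t",
                               index=False)
        gel_summary[cond] = {
            "fragment_mean_kb": float(means[cond]),
            "fraction_below_1kb": fraction_below(dist, 1.0),
        }
    summary["gel"] = gel_summary

    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(int(sim.Stream.DOTBLOT), 1))
    )
    rows = []
    for rep in range(1, 4):
        for cond in config.conditions:
            gap_density = 1.0 / float(means[cond])  # gaps per kb sets label uptake
            rows.append(
                {
                    "sample": cond,
                    "replicate": rep,
                    "intensity": 100.0 * gap_density * float(np.exp(rng.normal(0, 0.1))),
                }
            )
    blot_df = pd.DataFrame(rows)
    blot_df.to_csv(save(out / "gap_dotblot.csv"), index=False)
    ratios = dotblot_ratio(blot_df, config.reference_condition)
    ratios.to_csv(save(out / "gap_dotblot_ratios.csv"), index=False)
    summary["gap_dotblot"] = {
        r["sample"]: r["mean_ratio"] for _, r in ratios.iterrows()
    }

    rio.write_json(summary, str(save(out / "summary.json")))

    cfg_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "files": {
            str(p.relative_to(out)): {"sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in sorted(files)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _hu_input(scfg: sim.SimulationConfig, genome: BinnedGenome):
    """Uniform input track for the HU sample (same stream as normal input)."""
    rng = sim.substream(scfg.seed, sim.Stream.INPUT)
    from replitime.binning import CountTrack

    return CountTrack(
        genome, rng.poisson(scfg.input_depth, size=genome.n_bins), label="input"
    )
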