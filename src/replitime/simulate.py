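"""Forward simulation of a replicating cell population.

The generative model mirrors a synchronised fission-yeast S phase: each
origin i fires in each cell at a Normal(tau_i, s_i) time (if competent, with
probability e_i), forks move outward at constant speed v, and a locus at
distance d from origin i replicates at ``firing_i + d / v``; the locus's
replication time in one cell is the minimum over competent origins.  Because
origins fire independently, the population replicated fraction has the
closed form

    R(t, x) = 1 - prod_i [ 1 - e_i * Phi((t - d_i / v - tau_i) / s_i) ]

which is checked against a seeded Monte-Carlo population in the tests.
BrdU is present from release, so IP signal tracks the *cumulative*
replicated fraction; IP read counts per bin are Poisson with mean
``ip_depth * R(t, x) * b(x)`` where ``b(x) = AT(x)/mean(AT)`` models the
antibody's A/T capture bias, and the pre-release input sample is uniform
Poisson.  Emitters also produce the dot-blot global-replication signals, a
hydroxyurea-arrested sample with replication confined near origins, and
S1-gel lanes with exponentially distributed fragment lengths emulating
stochastic gap spacing.

All randomness derives from one root seed through named substreams
(see ``Stream``), so every emitter is independently reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import ndtr

from replitime.binning import BinnedGenome, CountTrack
from replitime.gel import GelLane, LadderCalibration
from replitime.timing import GlobalReplicationCurve


class Stream(enum.IntEnum):
    """Named RNG substreams spawned from the root seed."""

    IP = 1
    INPUT = 2
    HU = 3
    DOTBLOT = 4
    GEL = 5
    GENOME = 6
    READS = 7
    MC = 8
    ORIGINS = 9


def substream(seed: int, stream: Stream, extra: int = 0) -> np.random.Generator:
    """Independent generator for one emitter under a single root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(int(stream), extra))
    )


@dataclass
class SimOrigin:
    """A replication origin in the simulated population."""

    chrom: str
    position: int  # bp
    mean_firing_time: float  # minutes after release
    firing_sd: float  # minutes, > 0
    efficiency: float = 1.0  # probability the origin is competent in a cell
    fork_speed_multiplier: float = 1.0  # local modifier of the global fork speed

    def __post_init__(self) -> None:
        if self.firing_sd <= 0:
            raise ValueError("firing_sd must be > 0")
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError("efficiency must be in (0, 1]")
        if self.fork_speed_multiplier <= 0:
            raise ValueError("fork_speed_multiplier must be > 0")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated time course."""

    chromosomes: list[tuple[str, int]]
    origins: list[SimOrigin]
    timepoints: list[float]
    bin_width: int = 300
    fork_speed_kb_min: float = 1.0
    ip_depth: float = 100.0  # expected reads per fully replicated bin
    input_depth: float = 100.0
    at_bias: bool = True
    hu_arrest_kb: float = 5.0
    hu_background: float = 0.02
    seed: int = 0
    n_cells: int = 10_000

    def __post_init__(self) -> None:
        if self.fork_speed_kb_min <= 0:
            raise ValueError("fork_speed must be > 0")
        if self.ip_depth <= 0 or self.input_depth <= 0:
            raise ValueError("depths must be > 0")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size and np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        lengths = dict(self.chromosomes)
        for o in self.origins:
            if o.chrom not in lengths:
                raise ValueError(f"origin on unknown chromosome {o.chrom}")
            if not (0 <= o.position < lengths[o.chrom]):
                raise ValueError(f"origin at {o.position} outside {o.chrom}")

    def genome(self) -> BinnedGenome:
        return BinnedGenome(list(self.chromosomes), self.bin_width)

    def to_dict(self) -> dict:
        return {
            "chromosomes": [[n, int(l)] for n, l in self.chromosomes],
            "origins": [
                {
                    "chrom": o.chrom,
                    "position": int(o.position),
                    "mean_firing_time": float(o.mean_firing_time),
                    "firing_sd": float(o.firing_sd),
                    "efficiency": float(o.efficiency),
                    "fork_speed_multiplier": float(o.fork_speed_multiplier),
                }
                for o in self.origins
            ],
            "timepoints": [float(t) for t in self.timepoints],
            "bin_width": self.bin_width,
            "fork_speed_kb_min": self.fork_speed_kb_min,
            "ip_depth": self.ip_depth,
            "input_depth": self.input_depth,
            "at_bias": self.at_bias,
            "hu_arrest_kb": self.hu_arrest_kb,
            "hu_background": self.hu_background,
            "seed": self.seed,
            "n_cells": self.n_cells,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["chromosomes"] = [tuple(c) for c in d["chromosomes"]]
        d["origins"] = [SimOrigin(**o) for o in d["origins"]]
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth retained for parameter-recovery tests."""

    genome: BinnedGenome
    timepoints: np.ndarray
    r: np.ndarray  # (n_timepoints, n_bins) true replicated fraction
    half_rep_g: np.ndarray  # per-bin global extent at which R crosses 0.5
    origin_positions: list[tuple[str, int]]

    def g_of_t(self) -> np.ndarray:
        """True global extent at each timepoint (bin-average of R)."""
        return self.r.mean(axis=1)


# -- closed-form population kinetics ------------------------------------


def _profile_at_t(config: SimulationConfig, t: float, genome: BinnedGenome) -> np.ndarray:
    """R(t, x) for every bin, vectorised per chromosome."""
    v_bp = config.fork_speed_kb_min * 1000.0
    out = np.zeros(genome.n_bins)
    for name in genome.names:
        sl = genome.chrom_slice(name)
        mids = np.arange(sl.stop - sl.start) * genome.bin_width + genome.bin_width // 2
        surv = np.ones(mids.size)
        for o in config.origins:
            if o.chrom != name:
                continue
            d = np.abs(mids - o.position)
            z = (t - d / (v_bp * o.fork_speed_multiplier) - o.mean_firing_time) / o.firing_sd
            surv *= 1.0 - o.efficiency * ndtr(z)
        out[sl] = 1.0 - surv
    return out


def replicated_fraction_closed_form(
    config: SimulationConfig, t: float, chrom: str, position: float
) -> float:
    """Exact population replicated fraction of one locus at time t.

    R(t,x) = 1 - prod_i [1 - e_i * Phi((t - d_i/v - tau_i)/s_i)]; zero origins
    on the chromosome gives 0.
    """
    v_bp = config.fork_speed_kb_min * 1000.0
    surv = 1.0
    for o in config.origins:
        if o.chrom != chrom:
            continue
        d = abs(position - o.position)
        z = (t - d / (v_bp * o.fork_speed_multiplier) - o.mean_firing_time) / o.firing_sd
        surv *= 1.0 - o.efficiency * float(ndtr(z))
    return 1.0 - surv


def replicated_fraction_mc(
    config: SimulationConfig,
    t: float,
    chrom: str,
    position: float,
    n_cells: int | None = None,
    seed: int | None = None,
) -> float:
    """Monte-Carlo estimate of R(t, x): simulate cells, take the min arrival."""
    n = int(n_cells if n_cells is not None else config.n_cells)
    if n < 1:
        raise ValueError("n_cells must be >= 1")
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else substream(config.seed, Stream.MC)
    )
    v_bp = config.fork_speed_kb_min * 1000.0
    arrival = np.full(n, np.inf)
    for o in config.origins:
        if o.chrom != chrom:
            continue
        firing = rng.normal(o.mean_firing_time, o.firing_sd, size=n)
        if o.efficiency < 1.0:
            firing[rng.random(n) >= o.efficiency] = np.inf
        d = abs(position - o.position)
        arrival = np.minimum(arrival, firing + d / (v_bp * o.fork_speed_multiplier))
    return float(np.mean(arrival <= t))


def _max_nearest_origin_distance(config: SimulationConfig, genome: BinnedGenome) -> float:
    """Largest distance (bp) from any bin midpoint to its nearest origin."""
    dmax = 0.0
    w = genome.bin_width
    for name in genome.names:
        pos = np.sort([o.position for o in config.origins if o.chrom == name])
        if pos.size == 0:
            continue
        sl = genome.chrom_slice(name)
        mids = np.arange(sl.stop - sl.start) * w + w // 2
        idx = np.searchsorted(pos, mids)
        d_right = np.abs(pos[np.clip(idx, 0, pos.size - 1)] - mids)
        d_left = np.abs(pos[np.clip(idx - 1, 0, pos.size - 1)] - mids)
        dmax = max(dmax, float(np.minimum(d_left, d_right).max()))
    return dmax


def compute_truth(
    config: SimulationConfig,
    *,
    fine_step_min: float = 1.0,
) -> SimTruth:
    """Closed-form truth: R at every timepoint plus per-bin half-replication G.

    The half-replication global extent is the G value (bin-average R) at the
    time each bin's own R crosses 0.5, read off a fine time grid.
    """
    genome = config.genome()
    tp = np.asarray(config.timepoints, dtype=float)
    r = np.stack([_profile_at_t(config, t, genome) for t in tp])

    t_hi = max(
        (o.mean_firing_time + 5 * o.firing_sd for o in config.origins),
        default=0.0,
    )
    slowest = min((o.fork_speed_multiplier for o in config.origins), default=1.0)
    t_hi += _max_nearest_origin_distance(config, genome) / (
        config.fork_speed_kb_min * 1000.0 * slowest
    )
    t_fine = np.arange(0.0, t_hi + fine_step_min, fine_step_min)
    r_fine = np.stack([_profile_at_t(config, t, genome) for t in t_fine])
    g_fine = r_fine.mean(axis=1)

    crossed = r_fine >= 0.5
    ever = crossed.any(axis=0)
    idx = np.argmax(crossed, axis=0)
    idx = np.clip(idx, 1, len(t_fine) - 1)
    r_lo = r_fine[idx - 1, np.arange(genome.n_bins)]
    r_hi = r_fine[idx, np.arange(genome.n_bins)]
    frac = np.where(r_hi > r_lo, (0.5 - r_lo) / (r_hi - r_lo), 0.0)
    t_cross = t_fine[idx - 1] + frac * fine_step_min
    half_g = np.interp(t_cross, t_fine, g_fine)
    half_g[~ever] = np.nan
    return SimTruth(
        genome=genome,
        timepoints=tp,
        r=r,
        half_rep_g=half_g,
        origin_positions=[(o.chrom, o.position) for o in config.origins],
    )


# -- emitters ------------------------------------------------------------


def _bias(config: SimulationConfig, at: np.ndarray | None, n_bins: int) -> np.ndarray:
    if config.at_bias and at is not None:
        at = np.asarray(at, dtype=float)
        b = at / np.nanmean(at)
        return np.where(np.isnan(b), 1.0, b)
    return np.ones(n_bins)


def emit_count_tracks(
    config: SimulationConfig,
    truth: SimTruth,
    at: np.ndarray | None = None,
) -> tuple[dict[float, CountTrack], CountTrack]:
    """Poisson read counts per bin: one IP track per timepoint plus the input.

    IP mean is ``ip_depth * R(t, x) * b(x)``; the pre-release input sample is
    uniform ``Poisson(input_depth)``.
    """
    genome = truth.genome
    if at is not None and np.asarray(at).shape != (genome.n_bins,):
        raise ValueError("AT array does not match the truth's binning")
    b = _bias(config, at, genome.n_bins)
    tracks: dict[float, CountTrack] = {}
    for i, t in enumerate(truth.timepoints):
        rng = substream(config.seed, Stream.IP, i)
        counts = rng.poisson(config.ip_depth * truth.r[i] * b)
        tracks[float(t)] = CountTrack(genome, counts, label="BrdU-IP", timepoint=float(t))
    rng = substream(config.seed, Stream.INPUT)
    input_track = CountTrack(
        genome,
        rng.poisson(config.input_depth, size=genome.n_bins),
        label="input",
    )
    return tracks, input_track


def emit_global_curve(
    truth: SimTruth,
    config: SimulationConfig | None = None,
    *,
    noise_sd: float = 0.0,
    scale: float = 1000.0,
) -> tuple[GlobalReplicationCurve, pd.DataFrame]:
    """Dot-blot signals proportional to the true global extent G(t).

    Returns the curve (reference = last timepoint) and the raw signal table
    the pipeline's dot-blot reader consumes.  ``noise_sd`` applies optional
    multiplicative log-normal noise.
    """
    g = truth.g_of_t()
    signal = scale * g
    if noise_sd > 0:
        if config is None:
            raise ValueError("config (for the seed) required when noise_sd > 0")
        rng = substream(config.seed, Stream.DOTBLOT)
        signal = signal * np.exp(rng.normal(0.0, noise_sd, size=g.size))
    df = pd.DataFrame({"timepoint_min": truth.timepoints, "signal": signal})
    curve = GlobalReplicationCurve(
        truth.timepoints, signal, t_ref=float(truth.timepoints[-1])
    )
    return curve, df


def emit_hu_sample(
    config: SimulationConfig,
    at: np.ndarray | None = None,
) -> tuple[CountTrack, np.ndarray]:
    """HU-arrested IP sample: replication confined near origins.

    Replication extent is a triangular bump of half-width ``hu_arrest_kb``
    and height ``efficiency`` around each origin, on a small uniform
    background; counts are Poisson as for normal IP tracks.  Returns the
    track and the ground-truth peak bin indices.
    """
    genome = config.genome()
    w = genome.bin_width
    arrest_bp = config.hu_arrest_kb * 1000.0
    r_hu = np.full(genome.n_bins, config.hu_background)
    peak_bins = []
    for o in config.origins:
        sl = genome.chrom_slice(o.chrom)
        mids = np.arange(sl.stop - sl.start) * w + w // 2
        d = np.abs(mids - o.position)
        b = genome.bin_index(o.chrom, o.position)
        if arrest_bp > 0:
            bump = o.efficiency * np.clip(1.0 - d / arrest_bp, 0.0, None)
        else:
            bump = np.zeros(mids.size)
            if b >= 0:
                bump[b - sl.start] = o.efficiency
        r_hu[sl] = np.maximum(r_hu[sl], bump + config.hu_background)
        if b >= 0:
            peak_bins.append(b)
    b = _bias(config, at, genome.n_bins)
    rng = substream(config.seed, Stream.HU)
    counts = rng.poisson(config.ip_depth * r_hu * b)
    track = CountTrack(genome, counts, label="BrdU-IP-HU")
    return track, np.array(sorted(set(peak_bins)), dtype=int)


def emit_s1_lane(
    fragment_mean_kb: float,
    n_fragments: int,
    ladder: LadderCalibration,
    band_sd_px: float = 2.0,
    seed: int = 0,
    *,
    pixel_range: tuple[int, int] | None = None,
    lengths: np.ndarray | None = None,
    label: str = "",
) -> GelLane:
    """Simulated S1-gel lane from exponentially distributed fragment lengths.

    Fragment lengths ~ Exponential(mean); each fragment deposits intensity
    proportional to its length (label per unit length) at its calibrated
    pixel position; the lane is then convolved with a Gaussian band spread of
    ``band_sd_px`` pixels.  ``lengths`` overrides the exponential draw with
    explicit fragment lengths (kb), e.g. for calibration round-trips.
    """
    if fragment_mean_kb <= 0:
        raise ValueError("fragment_mean_kb must be > 0")
    if lengths is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(int(Stream.GEL),))
        )
        lengths = rng.exponential(fragment_mean_kb, size=int(n_fragments))
    else:
        lengths = np.asarray(lengths, dtype=float)
    pos = ladder.kb_to_pixel(lengths)
    if pixel_range is None:
        lo = int(np.floor(ladder.kb_to_pixel(50.0)))
        hi = int(np.ceil(ladder.kb_to_pixel(0.02)))
        lo, hi = min(lo, hi), max(lo, hi)
    else:
        lo, hi = pixel_range
    pixels = np.arange(lo, hi + 1)
    idx = np.clip(np.rint(pos).astype(int) - lo, 0, pixels.size - 1)
    intensity = np.zeros(pixels.size)
    np.add.at(intensity, idx, lengths)
    if band_sd_px > 0:
        intensity = gaussian_filter1d(intensity, band_sd_px, mode="constant")
    return GelLane(pixels.astype(float), intensity, label=label)


def default_ladder(
    *,
    kb_marks=(10.0, 5.0, 3.0, 2.0, 1.5, 1.0, 0.5, 0.2, 0.1),
    pixel_top: float = 80.0,
    px_per_decade: float = 220.0,
) -> LadderCalibration:
    """A log-linear marker ladder resembling a standard 1-D agarose run."""
    kb = np.asarray(kb_marks, dtype=float)
    px = pixel_top + px_per_decade * (np.log10(kb[0]) - np.log10(kb))
    return LadderCalibration(pd.DataFrame({"pixel": px, "kb": kb}))


# -- synthetic reference genome and read intervals -----------------------


def synthetic_genome_sequences(
    config: SimulationConfig,
    *,
    at_mean: float = 0.60,
    at_amplitude: float = 0.10,
    at_period_bp: float = 150_000.0,
) -> dict[str, str]:
    """Random genome with smoothly varying A/T content (fission-yeast-like).

    Per-bin target A/T follows a sinusoid around ``at_mean``; bases are drawn
    i.i.d. within each bin.  Deterministic under the config seed.
    """
    rng = substream(config.seed, Stream.GENOME)
    out: dict[str, str] = {}
    for name, length in config.chromosomes:
        pos = np.arange(length)
        p_at = at_mean + at_amplitude * np.sin(2 * np.pi * pos / at_period_bp)
        u = rng.random(length)
        is_at = u < p_at
        u2 = rng.random(length)
        bases = np.where(
            is_at,
            np.where(u2 < 0.5, ord("A"), ord("T")),
            np.where(u2 < 0.5, ord("G"), ord("C")),
        ).astype(np.uint8)
        out[name] = bases.tobytes().decode("ascii")
    return out


def emit_reads_bed(
    track: CountTrack,
    path: str,
    *,
    read_length: int = 50,
    seed: int = 0,
) -> None:
    """Write a BED of read intervals whose centers reproduce ``track`` exactly.

    For each bin, ``count`` reads are placed with centers uniform inside the
    bin, so re-counting the BED recovers the identical count vector.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(int(Stream.READS),)))
    genome = track.genome
    w = genome.bin_width
    half = read_length // 2
    with open(path, "w") as fh:
        for name in genome.names:
            sl = genome.chrom_slice(name)
            for k, c in enumerate(track.counts[sl]):
                if c == 0:
                    continue
                centers = rng.integers(k * w + 1, (k + 1) * w, size=int(c))
                for ctr in centers:
                    start = int(ctr) - half
                    end = int(ctr) + half
                    if start < 0:
                        start, end = 0, 2 * int(ctr)
                    fh.write(f"{name}\t{start}\t{end}\n")


# -- packaged demo study conditions --------------------------------------

DEMO_CHROMOSOMES = [("chrI", 2_200_000), ("chrII", 1_600_000), ("chrIII", 1_200_000)]
DEMO_TIMEPOINTS = [60.0, 70.0, 75.0, 80.0, 85.0, 90.0, 160.0]
DEMO_FIT_TIMEPOINTS = [70.0, 75.0, 80.0, 85.0, 90.0]


def demo_origins(
    seed: int = 0,
    chromosomes=None,
    *,
    spacing_kb: tuple[float, float] = (55.0, 75.0),
    firing_window_min: tuple[float, float] = (55.0, 80.0),
    firing_sd_min: float = 6.0,
    efficiency_range: tuple[float, float] = (0.8, 1.0),
) -> list[SimOrigin]:
    """Origin layout for the packaged demo genome.

    Origins are spaced 55-75 kb apart (efficient-origin density), fire
    between ~55 and ~80 min after G2 release with 6 min cell-to-cell SD, at
    80-100% efficiency.  Deterministic under ``seed`` and shared between
    conditions so fork speed is the only contrast.
    """
    if chromosomes is None:
        chromosomes = DEMO_CHROMOSOMES
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(int(Stream.ORIGINS),)))
    origins: list[SimOrigin] = []
    for name, length in chromosomes:
        pos = 25_000.0 + rng.uniform(0, 10_000)
        while pos < length - 25_000:
            origins.append(
                SimOrigin(
                    chrom=name,
                    position=int(pos),
                    mean_firing_time=float(rng.uniform(*firing_window_min)),
                    firing_sd=firing_sd_min,
                    efficiency=float(rng.uniform(*efficiency_range)),
                )
            )
            pos += rng.uniform(spacing_kb[0] * 1000, spacing_kb[1] * 1000)
    return origins


def demo_config(
    seed: int = 0,
    *,
    fork_speed_kb_min: float = 1.0,
    ip_depth: float = 100.0,
    chromosomes=None,
    origins: list[SimOrigin] | None = None,
) -> SimulationConfig:
    """Packaged 5-Mb three-chromosome study conditions."""
    if chromosomes is None:
        chromosomes = DEMO_CHROMOSOMES
    if origins is None:
        origins = demo_origins(seed, chromosomes)
    return SimulationConfig(
        chromosomes=list(chromosomes),
        origins=origins,
        timepoints=list(DEMO_TIMEPOINTS),
        fork_speed_kb_min=fork_speed_kb_min,
        ip_depth=ip_depth,
        seed=seed,
    )


def slowed_config(config: SimulationConfig, factor: float = 0.8) -> SimulationConfig:
    """The same study with fork speed scaled by ``factor`` (mutant condition)."""
    return replace(config, fork_speed_kb_min=config.fork_speed_kb_min * factor)
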