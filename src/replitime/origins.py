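"""Origin detection and replication-track meta-analysis.

In hydroxyurea-arrested cells replication is confined to the vicinity of
fired origins, so smoothed BrdU enrichment profiles show isolated peaks at
origins.  Peaks are detected with a prominence threshold scaled to the
profile's dynamic range; origins flanked on both sides by at least 15 kb of
above-background enrichment ("shoulder") are designated replication tracks,
which are overlaid peak-normalised to build ensemble average profiles.
Origin-proximal and inter-origin (late) bin classes feed the early/late
meta-analysis of timing-model fits, including selection of the late loci
that deviate most between two conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from replitime.binning import BinnedGenome
from replitime.enrichment import EnrichmentTrack
from replitime.timing import ReplicationTimingResults

DEFAULT_MIN_PROMINENCE_FRAC = 0.25
DEFAULT_MIN_SEPARATION_KB = 9.0
DEFAULT_SHOULDER_MIN_KB = 15.0


@dataclass
class OriginSet:
    """Detected origin peaks, sorted by genomic position."""

    genome: BinnedGenome
    table: pd.DataFrame  # chrom, bin (global), pos (bp midpoint), height, prominence

    def __len__(self) -> int:
        return len(self.table)

    @property
    def bins(self) -> np.ndarray:
        return self.table["bin"].to_numpy(dtype=int)

    def to_bed(self, path: str) -> None:
        w = self.genome.bin_width
        with open(path, "w") as fh:
            for _, r in self.table.iterrows():
                start = int(r["pos"]) - w // 2
                fh.write(f"{r['chrom']}\t{start}\t{start + w}\torigin\t{r['height']:.6g}\n")


@dataclass
class ReplicationTrack:
    """An origin with >= 15 kb of enrichment shoulder on both sides."""

    chrom: str
    peak_bin: int  # global bin index
    peak_pos: int  # bp, bin midpoint
    left_shoulder_bp: float
    right_shoulder_bp: float
    span_bins: tuple[int, int]  # global [start, end) of the uniform overlay window


@dataclass
class RegionClasses:
    """Disjoint early (origin-proximal) and late (inter-origin) bin classes."""

    origin_bins: np.ndarray
    late_bins: np.ndarray
    deviant_late_bins: np.ndarray | None = None

    def as_dict(self) -> dict[str, np.ndarray]:
        out = {"origin": self.origin_bins, "late": self.late_bins}
        if self.deviant_late_bins is not None:
            out["deviant_late"] = self.deviant_late_bins
        return out


def detect_origins(
    hu_profile: EnrichmentTrack,
    *,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    min_separation_kb: float = DEFAULT_MIN_SEPARATION_KB,
) -> OriginSet:
    """Detect origins as peaks in a smoothed HU-arrest enrichment profile.

    The prominence threshold is ``min_prominence_frac`` times the profile's
    dynamic range (99th percentile minus median over unmasked bins).  Peaks
    closer than ``min_separation_kb`` are resolved greedily: the higher peak
    is kept, ties going to the leftmost.
    """
    genome = hu_profile.genome
    w = genome.bin_width
    values = hu_profile.values
    finite = values[~np.isnan(values)]
    if finite.size == 0:
        warnings.warn("empty or fully masked profile: no origins", stacklevel=2)
        return OriginSet(genome, _empty_origin_table())
    thr = min_prominence_frac * (np.percentile(finite, 99) - np.median(finite))
    thr = max(thr, np.finfo(float).tiny)
    min_sep_bins = max(1, int(np.ceil(min_separation_kb * 1000 / w)))

    rows = []
    median = np.median(finite)
    for name in genome.names:
        sl = genome.chrom_slice(name)
        v = values[sl]
        v = np.where(np.isnan(v), median, v)  # neutral fill for peak finding
        peaks, props = find_peaks(v, prominence=thr)
        if peaks.size == 0:
            continue
        # greedy separation: higher peak wins, ties leftmost
        order = np.lexsort((peaks, -v[peaks]))
        kept: list[int] = []
        for i in order:
            p = peaks[i]
            if all(abs(p - q) >= min_sep_bins for q in kept):
                kept.append(p)
        for i in sorted(kept):
            j = int(np.nonzero(peaks == i)[0][0])
            rows.append(
                {
                    "chrom": name,
                    "bin": sl.start + i,
                    "pos": i * w + w // 2,
                    "height": float(v[i]),
                    "prominence": float(props["prominences"][j]),
                }
            )
    table = pd.DataFrame(rows) if rows else _empty_origin_table()
    if len(table):
        table = table.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return OriginSet(genome, table)


def _empty_origin_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "bin", "pos", "height", "prominence"])


def designate_tracks(
    origins: OriginSet,
    hu_profile: EnrichmentTrack,
    *,
    shoulder_min_kb: float = DEFAULT_SHOULDER_MIN_KB,
    background: float | None = None,
) -> list[ReplicationTrack]:
    """Designate replication tracks: origins with long shoulders both sides.

    A shoulder extends from the peak while enrichment stays above
    ``background`` (profile median by default), stopping at the chromosome
    end and at the midpoint to the neighbouring origin.  An origin qualifies
    iff both shoulders reach ``shoulder_min_kb``; the overlay span is the
    uniform window peak ± shoulder_min_kb.
    """
    genome = origins.genome
    w = genome.bin_width
    values = hu_profile.values
    if background is None:
        finite = values[~np.isnan(values)]
        background = float(np.median(finite)) if finite.size else 0.0
    span_bins = int(round(shoulder_min_kb * 1000 / w))

    tracks: list[ReplicationTrack] = []
    tbl = origins.table
    for chrom in genome.names:
        sub = tbl[tbl["chrom"] == chrom]
        if sub.empty:
            continue
        sl = genome.chrom_slice(chrom)
        v = values[sl]
        n = v.size
        local_peaks = (sub["bin"].to_numpy(dtype=int) - sl.start).tolist()
        for idx, p in enumerate(local_peaks):
            prev_p = local_peaks[idx - 1] if idx > 0 else None
            next_p = local_peaks[idx + 1] if idx + 1 < len(local_peaks) else None
            left_stop = 0 if prev_p is None else (prev_p + p + 1) // 2
            right_stop = n - 1 if next_p is None else (p + next_p) // 2
            i = p
            while i - 1 >= left_stop and _above(v[i - 1], background):
                i -= 1
            left = (p - i) * w
            j = p
            while j + 1 <= right_stop and _above(v[j + 1], background):
                j += 1
            right = (j - p) * w
            # shoulders truncated by the chromosome itself cannot qualify
            if p - span_bins < 0 or p + span_bins >= n:
                continue
            if left >= shoulder_min_kb * 1000 and right >= shoulder_min_kb * 1000:
                tracks.append(
                    ReplicationTrack(
                        chrom=chrom,
                        peak_bin=sl.start + p,
                        peak_pos=p * w + w // 2,
                        left_shoulder_bp=float(left),
                        right_shoulder_bp=float(right),
                        span_bins=(sl.start + p - span_bins, sl.start + p + span_bins + 1),
                    )
                )
    return tracks


def _above(x: float, background: float) -> bool:
    return not np.isnan(x) and x > background


def overlay_tracks(
    tracks: list[ReplicationTrack],
    profile: EnrichmentTrack,
) -> dict:
    """Peak-normalised overlay of a profile across replication tracks.

    Each track's window is re-indexed to distance-from-peak and divided by
    its own maximum, so every overlaid track peaks at 1; the ensemble average
    is the masked-aware per-offset mean.  Returns offsets (bp), the
    ``(n_tracks, n_offsets)`` matrix, the average curve and its full width at
    half maximum (bp, sub-bin interpolated; NaN if undefined).
    """
    if not tracks:
        raise ValueError("no tracks to overlay")
    w = profile.genome.bin_width
    half = (tracks[0].span_bins[1] - tracks[0].span_bins[0]) // 2
    offsets = (np.arange(-half, half + 1)) * w
    mat = np.full((len(tracks), offsets.size), np.nan)
    for i, tr in enumerate(tracks):
        seg = profile.values[tr.span_bins[0] : tr.span_bins[1]]
        peak = np.nanmax(seg)
        if not np.isfinite(peak) or peak <= 0:
            continue
        mat[i] = seg / peak
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(mat, axis=0)
    return {
        "offsets_bp": offsets,
        "matrix": mat,
        "average": avg,
        "fwhm_bp": curve_fwhm(offsets, avg),
    }


def curve_fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum with linear sub-sample interpolation."""
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    if y.size < 3:
        return float("nan")
    imax = int(np.argmax(y))
    half = y[imax] / 2.0
    left = np.nan
    for i in range(imax, 0, -1):
        if y[i - 1] < half <= y[i]:
            left = x[i - 1] + (x[i] - x[i - 1]) * (half - y[i - 1]) / (y[i] - y[i - 1])
            break
    right = np.nan
    for i in range(imax, y.size - 1):
        if y[i + 1] < half <= y[i]:
            right = x[i] + (x[i + 1] - x[i]) * (y[i] - half) / (y[i] - y[i + 1])
            break
    return float(right - left)


def classify_regions(
    origins: OriginSet | list[ReplicationTrack],
    genome: BinnedGenome | None = None,
    *,
    results: ReplicationTimingResults | None = None,
    flank_bins: int = 1,
) -> RegionClasses:
    """Early (origin-proximal) vs late (inter-origin midpoint) bin classes.

    Origin class: bins within ±``flank_bins`` of each designated origin peak.
    Late class: bins within ±``flank_bins`` of the midpoint between adjacent
    origins on the same chromosome.  Classes are disjoint; when a fitted
    ``results`` is given, masked bins are excluded from both.
    """
    if isinstance(origins, OriginSet):
        genome = origins.genome
        tbl = origins.table
        peaks = list(zip(tbl["chrom"], tbl["bin"].astype(int)))
    else:
        if genome is None:
            raise ValueError("genome required when passing track list")
        peaks = [(t.chrom, t.peak_bin) for t in origins]

    origin_bins: set[int] = set()
    late_bins: set[int] = set()
    by_chrom: dict[str, list[int]] = {}
    for chrom, b in peaks:
        by_chrom.setdefault(chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs)
        sl = genome.chrom_slice(chrom)
        for b in bs:
            for d in range(-flank_bins, flank_bins + 1):
                if sl.start <= b + d < sl.stop:
                    origin_bins.add(b + d)
        for b1, b2 in zip(bs[:-1], bs[1:]):
            mid = (b1 + b2) // 2
            for d in range(-flank_bins, flank_bins + 1):
                if sl.start <= mid + d < sl.stop:
                    late_bins.add(mid + d)
    late_bins -= origin_bins
    ob = np.array(sorted(origin_bins), dtype=int)
    lb = np.array(sorted(late_bins), dtype=int)
    if results is not None:
        from replitime.timing import STATUS_MASKED

        ob = ob[results.status[ob] != STATUS_MASKED]
        lb = lb[results.status[lb] != STATUS_MASKED]
    return RegionClasses(origin_bins=ob, late_bins=lb)


def select_deviant_late(
    results_control: ReplicationTimingResults,
    results_mutant: ReplicationTimingResults,
    classes: RegionClasses,
    *,
    g: float = 0.5,
    k_sd: float = 2.0,
) -> np.ndarray:
    """Late bins whose timing deviates beyond the origin-class noise band.

    Δ(x) = F_control(G, x) − F_mutant(G, x); the origin class calibrates the
    null (origins barely shift between conditions), and late bins with
    Δ > mean_origin(Δ) + k_sd · SD_origin(Δ) are selected.  Returns global
    bin indices (also stored on ``classes.deviant_late_bins``).
    """
    fc = results_control.evaluate_extent([g])[0]
    fm = results_mutant.evaluate_extent([g])[0]
    delta = fc - fm
    ob = classes.origin_bins
    ref = delta[ob]
    ref = ref[~np.isnan(ref)]
    if ref.size == 0:
        raise ValueError("no usable origin-class bins to calibrate the threshold")
    with np.errstate(invalid="ignore"):
        thr = ref.mean() + k_sd * ref.std(ddof=0)
    lb = classes.late_bins
    if not np.isfinite(thr):  # e.g. k_sd = inf with zero spread
        sel = lb[:0]
    else:
        sel = lb[(~np.isnan(delta[lb])) & (delta[lb] > thr)]
    classes.deviant_late_bins = sel
    return sel
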