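"""Fixed-width genome binning, read-center counting and per-bin A/T content.

Reads are reduced to the midpoint of their aligned interval and assigned to
0-based half-open bins ``[k*w, (k+1)*w)`` of width ``w`` (300 bp by default,
the resolution at which *S. pombe* replication profiles are analysed).  The
terminal partial bin of each chromosome is dropped so every bin has the same
denominator for the A/T ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 300
DEFAULT_MIN_MAPQ = 10


@dataclass
class BinnedGenome:
    """Tiling of an ordered set of chromosomes into fixed-width bins.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_width
        Bin width in bp; bins are 0-based half-open, the terminal partial
        bin (< bin_width) of each chromosome is dropped.
    at
        Optional per-bin A/T base fraction in [0, 1], concatenated across
        chromosomes in order (NaN marks masked all-N bins).
    """

    chromosomes: list[tuple[str, int]]
    bin_width: int = DEFAULT_BIN_WIDTH
    at: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        self.chromosomes = [(str(n), int(length)) for n, length in self.chromosomes]
        for name, length in self.chromosomes:
            if length < self.bin_width:
                raise ValueError(f"chromosome {name} shorter than one bin")
        if self.at is not None:
            self.at = np.asarray(self.at, dtype=float)
            if self.at.shape != (self.n_bins,):
                raise ValueError("at array does not match bin count")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def bins_per_chrom(self) -> dict[str, int]:
        w = self.bin_width
        return {name: length // w for name, length in self.chromosomes}

    @property
    def offsets(self) -> dict[str, int]:
        """Global index of each chromosome's first bin."""
        out: dict[str, int] = {}
        acc = 0
        for name, length in self.chromosomes:
            out[name] = acc
            acc += length // self.bin_width
        return out

    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_chrom.values())

    def chrom_slice(self, name: str) -> slice:
        start = self.offsets[name]
        return slice(start, start + self.bins_per_chrom[name])

    def bin_index(self, chrom: str, position: int) -> int:
        """Global bin index containing ``position``; -1 if in the dropped tail."""
        k = position // self.bin_width
        if k >= self.bins_per_chrom[chrom]:
            return -1
        return self.offsets[chrom] + k

    def midpoints(self) -> np.ndarray:
        """Per-bin midpoint coordinate (bp, within its own chromosome)."""
        w = self.bin_width
        parts = [
            np.arange(n) * w + w // 2 for n in self.bins_per_chrom.values()
        ]
        return np.concatenate(parts)

    def bin_chroms(self) -> np.ndarray:
        """Per-bin chromosome name (object array, concatenated order)."""
        parts = [
            np.full(n, name, dtype=object)
            for name, n in self.bins_per_chrom.items()
        ]
        return np.concatenate(parts)

    def bins_dataframe(self) -> pd.DataFrame:
        w = self.bin_width
        frames = []
        for name, n in self.bins_per_chrom.items():
            start = np.arange(n, dtype=np.int64) * w
            frames.append(
                pd.DataFrame({"chrom": name, "start": start, "end": start + w})
            )
        return pd.concat(frames, ignore_index=True)

    def same_binning(self, other: "BinnedGenome") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.chromosomes == other.chromosomes
        )


@dataclass
class CountTrack:
    """Per-bin integer read counts for one sample."""

    genome: BinnedGenome
    counts: np.ndarray
    label: str = ""
    timepoint: float | None = None
    skipped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.genome.n_bins,):
            raise ValueError("counts do not match genome binning")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _iter_sam(path: str, min_mapq: int, fragments: bool) -> Iterator[tuple[str, int, int]]:
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if fragments:
                # template-interval mode: count each properly paired template
                # once, at its fragment midpoint (leftmost mate carries it)
                if rec.is_paired and rec.is_proper_pair:
                    if rec.template_length <= 0:
                        continue
                    start = rec.reference_start
                    end = start + rec.template_length
                else:
                    start, end = rec.reference_start, rec.reference_end
            else:
                start, end = rec.reference_start, rec.reference_end
            yield rec.reference_name, start, end


def _iter_bed(path: str) -> Iterator[tuple[str, int, int]]:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            yield f[0], int(f[1]), int(f[2])


def count_read_centers(
    alignments: str | Path | Iterable[tuple[str, int, int]],
    genome: BinnedGenome,
    *,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    fragments: bool = False,
    label: str = "",
    timepoint: float | None = None,
) -> CountTrack:
    """Count read centers into fixed-width bins.

    ``alignments`` may be a SAM/BAM path, a BED3+ path, or an iterable of
    ``(chrom, start, end)`` 0-based half-open intervals.  The center of each
    usable alignment, ``floor((start + end) / 2)``, increments the count of
    the bin containing it.  Reads on unknown chromosomes or in the dropped
    terminal partial bin are skipped and tallied in ``CountTrack.skipped``.
    """
    if isinstance(alignments, (str, Path)):
        p = str(alignments)
        if p.endswith((".sam", ".bam")):
            it: Iterable[tuple[str, int, int]] = _iter_sam(p, min_mapq, fragments)
        else:
            it = _iter_bed(p)
    else:
        it = alignments

    counts = np.zeros(genome.n_bins, dtype=np.int64)
    bins_per = genome.bins_per_chrom
    offsets = genome.offsets
    w = genome.bin_width
    skipped = {"unknown_chrom": 0, "out_of_bins": 0}
    n_usable = 0
    for chrom, start, end in it:
        n_usable += 1
        if chrom not in bins_per:
            skipped["unknown_chrom"] += 1
            continue
        k = ((start + end) // 2) // w
        if k >= bins_per[chrom]:
            skipped["out_of_bins"] += 1
            continue
        counts[offsets[chrom] + k] += 1
    if n_usable == 0:
        raise ValueError("no usable alignments in input")
    if skipped["unknown_chrom"]:
        warnings.warn(
            f"skipped {skipped['unknown_chrom']} alignments on unknown chromosomes",
            stacklevel=2,
        )
    return CountTrack(genome, counts, label=label, timepoint=timepoint, skipped=skipped)


_AT_BYTES = frozenset(b"ATat")


def compute_at_ratio(
    fasta: str | Path | dict[str, str],
    genome: BinnedGenome,
) -> np.ndarray:
    """Per-bin A/T base fraction from a reference FASTA.

    ``AT(x) = (#A + #T + #a + #t) / bin_width``; ambiguity codes count as
    non-AT.  Bins consisting entirely of ``N`` are masked (NaN).  Returns the
    concatenated per-bin array and also stores it on ``genome.at``.
    """
    if isinstance(fasta, dict):
        get = lambda name: fasta[name]  # noqa: E731
        seqlen = lambda name: len(fasta[name])  # noqa: E731
    else:
        from pyfaidx import Fasta

        fa = Fasta(str(fasta))
        get = lambda name: str(fa[name][:])  # noqa: E731
        seqlen = lambda name: len(fa[name])  # noqa: E731

    w = genome.bin_width
    parts = []
    for name, length in genome.chromosomes:
        if seqlen(name) != length:
            raise ValueError(
                f"FASTA length for {name} ({seqlen(name)}) != declared ({length})"
            )
        n = length // w
        raw = np.frombuffer(get(name)[: n * w].encode("ascii"), dtype=np.uint8)
        raw = raw.reshape(n, w)
        is_at = (
            (raw == ord("A")) | (raw == ord("T"))
            | (raw == ord("a")) | (raw == ord("t"))
        )
        is_n = (raw == ord("N")) | (raw == ord("n"))
        at = is_at.sum(axis=1) / w
        at[is_n.all(axis=1)] = np.nan
        parts.append(at)
    result = np.concatenate(parts)
    genome.at = result
    return result
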