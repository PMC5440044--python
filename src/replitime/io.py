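"""Text readers/writers for pipeline stage outputs.

All stage files are self-describing: a ``#`` header records the stage, the
binning (width and chromosome lengths) and any parameters, so a track can be
reloaded without the original config.  Formats are plain text throughout
(TSV, bedGraph, FASTA, CSV, JSON).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from replitime.binning import BinnedGenome, CountTrack
from replitime.enrichment import EnrichmentTrack


def _header_lines(genome: BinnedGenome, stage: str, **params) -> list[str]:
    chroms = ",".join(f"{n}:{l}" for n, l in genome.chromosomes)
    lines = [
        f"# stage={stage}",
        f"# bin_width={genome.bin_width}",
        f"# chromosomes={chroms}",
    ]
    for k, v in params.items():
        lines.append(f"# {k}={v}")
    return lines


def _parse_header(path: str) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    return meta


def _genome_from_meta(meta: dict) -> BinnedGenome:
    chroms = [
        (name, int(length))
        for name, _, length in (c.partition(":") for c in meta["chromosomes"].split(","))
    ]
    return BinnedGenome(chroms, int(meta["bin_width"]))


def write_count_tsv(track: CountTrack, path: str, **params) -> None:
    genome = track.genome
    df = genome.bins_dataframe()
    df["count"] = track.counts
    hdr = _header_lines(
        genome, "counts", label=track.label, timepoint=track.timepoint, **params
    )
    with open(path, "w") as fh:
        fh.write("\n".join(hdr) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_count_tsv(path: str, genome: BinnedGenome | None = None) -> CountTrack:
    meta = _parse_header(path)
    if genome is None:
        genome = _genome_from_meta(meta)
    df = pd.read_csv(path, sep="\t", comment="#")
    t = meta.get("timepoint")
    timepoint = None if t in (None, "None", "") else float(t)
    return CountTrack(
        genome,
        df["count"].to_numpy(),
        label=meta.get("label", ""),
        timepoint=timepoint,
    )


def write_track_tsv(track: EnrichmentTrack, path: str, **params) -> None:
    genome = track.genome
    df = genome.bins_dataframe()
    df["value"] = track.values
    hdr = _header_lines(
        genome, track.stage or "track", label=track.label,
        timepoint=track.timepoint, **params,
    )
    with open(path, "w") as fh:
        fh.write("\n".join(hdr) + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_track_tsv(path: str, genome: BinnedGenome | None = None) -> EnrichmentTrack:
    meta = _parse_header(path)
    if genome is None:
        genome = _genome_from_meta(meta)
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    t = meta.get("timepoint")
    timepoint = None if t in (None, "None", "") else float(t)
    return EnrichmentTrack(
        genome,
        df["value"].to_numpy(dtype=float),
        stage=meta.get("stage", ""),
        label=meta.get("label", ""),
        timepoint=timepoint,
    )


def write_bedgraph(track: EnrichmentTrack, path: str, name: str = "") -> None:
    """bedGraph writer; masked bins are encoded as omitted intervals."""
    genome = track.genome
    df = genome.bins_dataframe()
    df["value"] = track.values
    df = df[~np.isnan(df["value"])]
    with open(path, "w") as fh:
        if name:
            fh.write(f'track type=bedGraph name="{name}"\n')
        df.to_csv(fh, sep="\t", index=False, header=False, float_format="%.6g")


def write_bigwig(track: EnrichmentTrack, path: str) -> None:
    """Optional bigWig writer (binary output; requires pyBigWig)."""
    import pyBigWig

    genome = track.genome
    bw = pyBigWig.open(path, "w")
    bw.addHeader([(n, l) for n, l in genome.chromosomes])
    w = genome.bin_width
    for name in genome.names:
        sl = genome.chrom_slice(name)
        v = track.values[sl]
        ok = ~np.isnan(v)
        if not ok.any():
            continue
        starts = (np.nonzero(ok)[0] * w).astype(np.int64)
        bw.addEntries(
            [name] * int(ok.sum()),
            starts.tolist(),
            ends=(starts + w).tolist(),
            values=v[ok].astype(float).tolist(),
        )
    bw.close()


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed_bins(genome: BinnedGenome, bins: np.ndarray, path: str, name: str = "region") -> None:
    """BED of the given global bin indices (one interval per bin)."""
    w = genome.bin_width
    chroms = genome.bin_chroms()
    offs = genome.offsets
    with open(path, "w") as fh:
        for b in np.asarray(bins, dtype=int):
            chrom = chroms[b]
            start = (b - offs[chrom]) * w
            fh.write(f"{chrom}\t{start}\t{start + w}\t{name}\n")


def write_json(obj, path: str) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
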