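"""BrdU enrichment normalization chain: N, E, E' and the moving average.

Each BrdU-IP count track is normalised by its sequencing depth
(``N(x) = C(x) / ΣC``), divided by the equally normalised input track to give
the enrichment ``E(x) = N_B(x) / N_I(x)``, corrected for the A/T capture bias
of BrdU antibodies (``E'(x) = E(x) / AT(x)``) and finally smoothed with a
uniform moving average of 8 bins on either side.  Bins where a stage is
undefined (zero input coverage, vanishing A/T content, all-N sequence) are
masked with NaN, and masks only ever grow along the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from replitime.binning import BinnedGenome, CountTrack

DEFAULT_MIN_INPUT_COUNT = 5
DEFAULT_MIN_AT = 0.05
DEFAULT_HALF_WINDOW = 8


@dataclass
class EnrichmentTrack:
    """Per-bin real-valued signal with NaN marking masked bins."""

    genome: BinnedGenome
    values: np.ndarray
    stage: str = ""
    label: str = ""
    timepoint: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome.n_bins,):
            raise ValueError("values do not match genome binning")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the bin is masked."""
        return np.isnan(self.values)

    def _replace(self, values: np.ndarray, stage: str) -> "EnrichmentTrack":
        return EnrichmentTrack(
            self.genome, values, stage=stage, label=self.label, timepoint=self.timepoint
        )


def normalize_total(track: CountTrack) -> EnrichmentTrack:
    """Depth normalisation: N(x) = C(x) / ΣC(x); unmasked values sum to 1."""
    total = track.total
    if total <= 0:
        raise ValueError("cannot normalise a zero-total count track")
    return EnrichmentTrack(
        track.genome,
        track.counts / total,
        stage="N",
        label=track.label,
        timepoint=track.timepoint,
    )


def enrichment(
    nb: EnrichmentTrack,
    ni: EnrichmentTrack,
    *,
    input_counts: CountTrack | None = None,
    min_input_count: int = DEFAULT_MIN_INPUT_COUNT,
) -> EnrichmentTrack:
    """Input-normalised enrichment E(x) = N_B(x) / N_I(x).

    Bins whose raw input count falls below ``min_input_count`` are masked
    rather than zero-filled, so unreliable denominators cannot masquerade as
    extreme enrichment.  When ``input_counts`` is omitted the guard falls back
    to masking wherever N_I is zero.
    """
    if not nb.genome.same_binning(ni.genome):
        raise ValueError("BrdU-IP and input tracks are on different binnings")
    denom = ni.values.copy()
    if input_counts is not None:
        if not input_counts.genome.same_binning(nb.genome):
            raise ValueError("input_counts on a different binning")
        denom[input_counts.counts < min_input_count] = np.nan
    denom[denom == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        e = nb.values / denom
    return nb._replace(e, "E")


def at_correct(
    e: EnrichmentTrack,
    at: np.ndarray | None = None,
    *,
    min_at: float = DEFAULT_MIN_AT,
) -> EnrichmentTrack:
    """A/T-bias correction E'(x) = E(x) / AT(x); low-AT bins masked."""
    if at is None:
        at = e.genome.at
    if at is None:
        raise ValueError("no per-bin A/T ratio available")
    at = np.asarray(at, dtype=float)
    if at.shape != e.values.shape:
        raise ValueError("AT array does not match binning")
    denom = at.copy()
    denom[~(denom >= min_at)] = np.nan  # also masks NaN (all-N) bins
    with np.errstate(invalid="ignore", divide="ignore"):
        ep = e.values / denom
    return e._replace(ep, "Eprime")


def moving_average(
    track: EnrichmentTrack,
    half_window_bins: int = DEFAULT_HALF_WINDOW,
) -> EnrichmentTrack:
    """Uniform moving average over ±``half_window_bins`` bins, per chromosome.

    Windows are truncated at chromosome ends and renormalised by the number of
    contributing (unmasked) bins; a bin with no unmasked neighbour in its
    window stays masked.
    """
    if half_window_bins < 0:
        raise ValueError("half_window_bins must be >= 0")
    k = 2 * half_window_bins + 1
    kernel = np.ones(k)
    out = np.empty_like(track.values)
    for name in track.genome.names:
        sl = track.genome.chrom_slice(name)
        v = track.values[sl]
        n = v.size
        valid = ~np.isnan(v)
        filled = np.where(valid, v, 0.0)
        h = half_window_bins
        num = np.convolve(filled, kernel)[h : h + n]
        den = np.convolve(valid.astype(float), kernel)[h : h + n]
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        sm[den == 0] = np.nan
        out[sl] = sm
    return track._replace(out, "smoothed")


def enrichment_chain(
    brdu: CountTrack,
    input_track: CountTrack,
    at: np.ndarray | None = None,
    *,
    min_input_count: int = DEFAULT_MIN_INPUT_COUNT,
    min_at: float = DEFAULT_MIN_AT,
    half_window_bins: int = DEFAULT_HALF_WINDOW,
    smooth: bool = True,
) -> EnrichmentTrack:
    """Full chain counts → N → E → E' (→ smoothed E').

    The A/T correction is skipped when no per-bin A/T ratio is available
    (neither passed nor stored on the genome), e.g. for unbiased synthetic
    counts.
    """
    nb = normalize_total(brdu)
    ni = normalize_total(input_track)
    e = enrichment(nb, ni, input_counts=input_track, min_input_count=min_input_count)
    if at is None and brdu.genome.at is None:
        ep = e
    else:
        ep = at_correct(e, at, min_at=min_at)
    if smooth:
        return moving_average(ep, half_window_bins)
    return ep
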