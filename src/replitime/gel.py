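"""S1-nuclease gel densitometry: ladder calibration and fragment fractions.

S1 nuclease cuts nascent DNA at single-stranded gaps, so the size
distribution of the resulting fragments on a denaturing gel reports gap
density.  A lane's fluorescence intensity profile (BrdU signal per pixel) is
converted to a *number* fraction of fragments per pixel: migration position
is calibrated against a marker ladder (log-linear in size), and because label
deposits in proportion to fragment length, intensity divided by fragment
length counts molecules.  Fractions below a size threshold (1 kb by default)
summarise gap accumulation.  A simple normalised ratio analysis covers the
companion dot-blot gap-labelling assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD_KB = 1.0


@dataclass
class GelLane:
    """Densitometry profile of one gel lane along the migration axis."""

    pixel: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.pixel = np.asarray(self.pixel, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.pixel.size < 2:
            raise ValueError("a lane needs at least 2 pixels")
        if self.pixel.shape != self.intensity.shape:
            raise ValueError("pixel and intensity differ in length")
        if np.any(np.diff(self.pixel) <= 0):
            raise ValueError("pixel axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    @classmethod
    def from_csv(cls, path: str, label: str = "") -> "GelLane":
        df = pd.read_csv(path)
        return cls(df["pixel"].to_numpy(), df["intensity"].to_numpy(), label=label)


class LadderCalibration:
    """Pixel ↔ fragment-size mapping from a marker ladder.

    log10(size in kb) is piecewise-linearly interpolated against pixel
    position between adjacent markers; beyond the outermost markers the
    terminal segment is extrapolated and the affected pixels flagged.
    Orientation (larger fragments at smaller or larger pixel values) is
    auto-detected; the marker table must be strictly monotone.
    """

    def __init__(self, markers: pd.DataFrame | list[tuple[float, float]]):
        if not isinstance(markers, pd.DataFrame):
            markers = pd.DataFrame(markers, columns=["pixel", "kb"])
        markers = markers.sort_values("pixel").reset_index(drop=True)
        if len(markers) < 2:
            raise ValueError("need at least 2 ladder markers")
        px = markers["pixel"].to_numpy(dtype=float)
        kb = markers["kb"].to_numpy(dtype=float)
        if np.any(np.diff(px) <= 0):
            raise ValueError("marker pixels must be distinct")
        dk = np.diff(kb)
        if np.all(dk < 0):
            self.descending = True  # larger fragments migrate less: small pixel
        elif np.all(dk > 0):
            self.descending = False
        else:
            raise ValueError("ladder sizes must be strictly monotone in pixel")
        if np.any(kb <= 0):
            raise ValueError("marker sizes must be positive")
        self.pixels = px
        self.log_kb = np.log10(kb)
        self.markers = markers

    def pixel_to_kb(self, pixel) -> np.ndarray:
        """Fragment size (kb) at the given pixel position(s)."""
        pixel = np.asarray(pixel, dtype=float)
        slope_lo = (self.log_kb[1] - self.log_kb[0]) / (self.pixels[1] - self.pixels[0])
        slope_hi = (self.log_kb[-1] - self.log_kb[-2]) / (
            self.pixels[-1] - self.pixels[-2]
        )
        lk = np.interp(pixel, self.pixels, self.log_kb)
        below = pixel < self.pixels[0]
        above = pixel > self.pixels[-1]
        lk = np.where(below, self.log_kb[0] + slope_lo * (pixel - self.pixels[0]), lk)
        lk = np.where(above, self.log_kb[-1] + slope_hi * (pixel - self.pixels[-1]), lk)
        return 10.0**lk

    def kb_to_pixel(self, kb) -> np.ndarray:
        """Inverse mapping, used by the gel simulator."""
        lk = np.log10(np.asarray(kb, dtype=float))
        xp, fp = self.log_kb, self.pixels
        if self.descending:
            xp, fp = xp[::-1], fp[::-1]
        slope_lo = (fp[1] - fp[0]) / (xp[1] - xp[0])
        slope_hi = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        px = np.interp(lk, xp, fp)
        px = np.where(lk < xp[0], fp[0] + slope_lo * (lk - xp[0]), px)
        px = np.where(lk > xp[-1], fp[-1] + slope_hi * (lk - xp[-1]), px)
        return px

    def extrapolated(self, pixel) -> np.ndarray:
        """True where a pixel lies outside the marker range."""
        pixel = np.asarray(pixel, dtype=float)
        return (pixel < self.pixels[0]) | (pixel > self.pixels[-1])


def calibrate_ladder(markers) -> LadderCalibration:
    """Build a pixel → kb calibration from a marker table (pixel, kb)."""
    return LadderCalibration(markers)


@dataclass
class FragmentDistribution:
    """Number-fraction of fragments per pixel of the analysis range."""

    pixel: np.ndarray
    length_kb: np.ndarray
    fraction: np.ndarray
    extrapolated: np.ndarray

    def __post_init__(self) -> None:
        s = self.fraction.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"fractions must sum to 1 (got {s})")
        if np.any(self.fraction < 0):
            raise ValueError("fractions must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pixel": self.pixel,
                "length_kb": self.length_kb,
                "fraction": self.fraction,
                "extrapolated": self.extrapolated,
            }
        )


def intensity_to_fractions(
    lane: GelLane,
    calibration: LadderCalibration,
    analysis_range_px: tuple[float, float] | None = None,
    *,
    background: float | None = None,
    length_exponent: float = 1.0,
) -> FragmentDistribution:
    """Convert lane intensity to the number-fraction of fragments per pixel.

    Background (the in-range minimum intensity unless given) is subtracted,
    then each pixel's number weight is ``I_j / l_j**length_exponent``: label
    deposits in proportion to fragment length, so dividing by length converts
    label amount to molecule count (the exponent is exposed because gel
    transfer/staining nonlinearity can alter the effective power).  Weights
    are normalised to sum to 1 over the analysis range.
    """
    px = lane.pixel
    if analysis_range_px is None:
        sel = np.ones(px.size, dtype=bool)
    else:
        lo, hi = analysis_range_px
        sel = (px >= lo) & (px <= hi)
        if not sel.any():
            raise ValueError("analysis range contains no pixels")
    intensity = lane.intensity[sel].astype(float)
    if background is None:
        background = float(intensity.min())
    net = np.clip(intensity - background, 0.0, None)
    if net.sum() <= 0:
        raise ValueError("no signal left in range after background subtraction")
    lengths = calibration.pixel_to_kb(px[sel])
    weight = net / lengths**length_exponent
    return FragmentDistribution(
        pixel=px[sel],
        length_kb=lengths,
        fraction=weight / weight.sum(),
        extrapolated=calibration.extrapolated(px[sel]),
    )


def fraction_below(
    dist: FragmentDistribution, threshold_kb: float = DEFAULT_THRESHOLD_KB
) -> float:
    """Number-fraction of fragments shorter than ``threshold_kb``."""
    return float(dist.fraction[dist.length_kb < threshold_kb].sum())


def dotblot_ratio(
    signals: pd.DataFrame,
    reference_sample: str,
    *,
    sample_col: str = "sample",
    replicate_col: str = "replicate",
    intensity_col: str = "intensity",
) -> pd.DataFrame:
    """Per-sample mean ± SD of replicate-wise intensity ratios to a reference.

    Each replicate's intensity is divided by the reference sample's intensity
    in the *same* replicate before averaging, so blot-to-blot scale drops out.
    """
    df = signals.pivot(index=replicate_col, columns=sample_col, values=intensity_col)
    if reference_sample not in df.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in table")
    ratios = df.div(df[reference_sample], axis=0)
    out = pd.DataFrame(
        {
            "mean_ratio": ratios.mean(axis=0),
            "sd_ratio": ratios.std(axis=0, ddof=1).fillna(0.0),
            "n": ratios.count(axis=0),
        }
    )
    out.index.name = "sample"
    return out.reset_index()
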