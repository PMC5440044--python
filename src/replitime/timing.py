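"""Per-locus replication timing on the global-replication axis.

Local BrdU enrichment is placed on an absolute scale by multiplying with the
global replication extent G(t) measured by dot-blot, then standardised to the
final time point at which replication is complete:

    L(t, x)  = E'(t, x) * G(t)
    L'(t, x) = L(t, x) / L(t_last, x)

For each bin the standardised extents over several mid-S time points are
fitted with a cumulative normal in the *global* extent,

    F(G, x) = Phi((G - mu_x) / sigma_x),

so ``mu_x`` is the global extent at which locus x is half-replicated across
the population (small mu = early locus) and ``sigma_x`` the spread of its
replication over S phase.  ``ReplicationTimingModel.fit`` solves the bounded
least-squares problem for every bin simultaneously (coarse grid start, damped
Gauss-Newton refinement); bins where the sigmoid cannot beat a monotone
interpolant, or with no dynamic range, fall back to that interpolant, and the
status is recorded per bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import mannwhitneyu

from replitime.binning import BinnedGenome
from replitime.enrichment import EnrichmentTrack

DEFAULT_EVAL_G = (0.25, 0.5, 0.75)
MU_BOUNDS = (-0.25, 1.5)
SIGMA_BOUNDS = (0.01, 1.0)
LPRIME_CLIP = (0.0, 1.2)

STATUS_CONVERGED = 0
STATUS_FALLBACK = 1
STATUS_MASKED = 2
STATUS_LABELS = {0: "converged", 1: "fallback-interpolation", 2: "masked"}


@dataclass
class GlobalReplicationCurve:
    """Genome-wide replication extent per time point, from dot-blot signal.

    ``G(t) = s(t) / s(t_ref)`` where ``t_ref`` is the time point at which
    genome replication is complete (150 min in the original time course), so
    ``G(t_ref) = 1`` by construction.
    """

    timepoints: np.ndarray
    signal: np.ndarray
    t_ref: float

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.timepoints.shape != self.signal.shape:
            raise ValueError("timepoints and signal differ in length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.t_ref not in self.timepoints:
            raise ValueError("t_ref must be one of the timepoints")
        s_ref = self.signal[self.timepoints == self.t_ref][0]
        if s_ref <= 0:
            raise ValueError("reference signal must be positive")
        self.g = self.signal / s_ref
        if np.any(np.diff(self.g) < 0):
            warnings.warn("global replication curve is non-monotone", stacklevel=2)

    def g_at(self, t: float) -> float:
        idx = np.nonzero(self.timepoints == t)[0]
        if idx.size == 0:
            raise KeyError(f"no dot-blot measurement at t={t}")
        return float(self.g[idx[0]])

    def matched_timepoint(self, target_g: float) -> float:
        """Time point whose global extent is closest to ``target_g``."""
        return float(self.timepoints[np.argmin(np.abs(self.g - target_g))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timepoint_min": self.timepoints, "signal": self.signal, "G": self.g}
        )


def global_curve_from_dotblot(
    dotblot: str | pd.DataFrame,
    t_ref: float | None = None,
) -> GlobalReplicationCurve:
    """Build G(t) from a dot-blot CSV with columns ``timepoint_min,signal``.

    ``t_ref`` defaults to the last time point (replication complete).
    """
    df = pd.read_csv(dotblot) if not isinstance(dotblot, pd.DataFrame) else dotblot
    df = df.sort_values("timepoint_min")
    t = df["timepoint_min"].to_numpy(dtype=float)
    s = df["signal"].to_numpy(dtype=float)
    if t_ref is None:
        t_ref = float(t[-1])
    return GlobalReplicationCurve(t, s, t_ref)


@dataclass
class LocalExtentSeries:
    """Standardised local replication extents L'(t, x) over the time course."""

    genome: BinnedGenome
    timepoints: np.ndarray
    lprime: np.ndarray  # (n_timepoints, n_bins), NaN = masked
    t_last: float
    l_raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.lprime.shape != (self.timepoints.size, self.genome.n_bins):
            raise ValueError("lprime shape mismatch")


def local_extent(
    eprime_by_timepoint: dict[float, EnrichmentTrack],
    curve: GlobalReplicationCurve,
    t_last: float | None = None,
) -> LocalExtentSeries:
    """Scale enrichment to local extent and standardise to the last time point.

    L(t,x) = E'(t,x) * G(t);  L'(t,x) = L(t,x) / L(t_last,x).  Bins masked at
    any stage, or with L(t_last,x) = 0, stay masked.
    """
    ts = np.array(sorted(eprime_by_timepoint), dtype=float)
    if t_last is None:
        t_last = float(ts[-1])
    if t_last not in eprime_by_timepoint:
        raise ValueError(f"no enrichment track at t_last={t_last}")
    genome = eprime_by_timepoint[t_last].genome
    n = genome.n_bins
    l = np.empty((ts.size, n))
    for i, t in enumerate(ts):
        tr = eprime_by_timepoint[t]
        if not tr.genome.same_binning(genome):
            raise ValueError("tracks on different binnings")
        l[i] = tr.values * curve.g_at(t)
    denom = l[ts == t_last][0].copy()
    denom[denom == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        lp = l / denom
    return LocalExtentSeries(genome, ts, lp, t_last, l_raw=l)


def profile_at_matched_g(
    eprime_by_timepoint: dict[float, EnrichmentTrack],
    curve: GlobalReplicationCurve,
    g_target: float,
) -> EnrichmentTrack:
    """Enrichment profile standardised to an exact global extent.

    Linearly interpolates E'(t, x) between the two time points whose G(t)
    bracket ``g_target``, so two conditions can be compared at identical
    global replication extent even though their sampling grids differ.
    Clamps to the nearest measured profile outside the covered G range.
    """
    ts = sorted(eprime_by_timepoint)
    gs = np.array([curve.g_at(t) for t in ts])
    order = np.argsort(gs)
    gs, ts = gs[order], [ts[i] for i in order]
    if g_target <= gs[0]:
        return eprime_by_timepoint[ts[0]]
    if g_target >= gs[-1]:
        return eprime_by_timepoint[ts[-1]]
    hi = int(np.searchsorted(gs, g_target))
    lo = hi - 1
    alpha = (g_target - gs[lo]) / (gs[hi] - gs[lo])
    a = eprime_by_timepoint[ts[lo]]
    b = eprime_by_timepoint[ts[hi]]
    return EnrichmentTrack(
        a.genome,
        (1.0 - alpha) * a.values + alpha * b.values,
        stage=a.stage,
        label=f"{a.label}@G={g_target:g}",
    )


def _monotone_fallback(y: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Running-max monotonisation of y along axis 0, ignoring invalid points."""
    filled = np.where(valid, y, -np.inf)
    mono = np.maximum.accumulate(filled, axis=0)
    mono[~np.isfinite(mono)] = np.nan
    return mono


class ReplicationTimingModel:
    """Per-bin cumulative-normal timing model F(G, x) = Phi((G - mu)/sigma).

    Parameters
    ----------
    series
        Standardised local extents L'(t, x).
    curve
        Global replication curve providing G(t) for the fit time points.
    fit_timepoints
        Time points used in the fit (default: all series time points except
        the standardisation reference ``t_last``).  At least 3 are required.
    clip
        L' values are clipped to this range before fitting (noise can push
        ratios past 1).
    """

    def __init__(
        self,
        series: LocalExtentSeries,
        curve: GlobalReplicationCurve,
        fit_timepoints: list[float] | None = None,
        *,
        clip: tuple[float, float] = LPRIME_CLIP,
        mu_bounds: tuple[float, float] = MU_BOUNDS,
        sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
        flat_tol: float = 0.05,
    ) -> None:
        if fit_timepoints is None:
            fit_timepoints = [t for t in series.timepoints if t != series.t_last]
        fit_timepoints = sorted(float(t) for t in fit_timepoints)
        if len(fit_timepoints) < 3:
            raise ValueError("need at least 3 fit timepoints")
        for t in fit_timepoints:
            if t not in series.timepoints:
                raise ValueError(f"fit timepoint {t} not in series")
        self.series = series
        self.curve = curve
        self.fit_timepoints = fit_timepoints
        self.clip = clip
        self.mu_bounds = mu_bounds
        self.sigma_bounds = sigma_bounds
        self.flat_tol = flat_tol
        self.g_fit = np.array([curve.g_at(t) for t in fit_timepoints])
        rows = [int(np.nonzero(series.timepoints == t)[0][0]) for t in fit_timepoints]
        self.y = np.clip(series.lprime[rows], *clip)

    # -- fitting ---------------------------------------------------------

    def fit(self, max_iter: int = 80) -> "ReplicationTimingResults":
        g = self.g_fit
        y = self.y
        valid = ~np.isnan(y)
        n_bins = y.shape[1]
        usable = valid.sum(axis=0) >= 3
        yv = np.where(valid, y, 0.0)
        w = valid.astype(float)

        mu, sig = self._initial_params(g, yv, w, usable)
        mu, sig, sse, pgrad = self._refine(g, yv, w, mu, sig, max_iter)

        mono = _monotone_fallback(y, valid)
        res_fb = np.where(valid, mono - y, 0.0)
        sse_fb = np.nansum(res_fb**2, axis=0)

        ymin = np.where(valid, y, np.inf).min(axis=0)
        ymax = np.where(valid, y, -np.inf).max(axis=0)
        flat = (ymax - ymin) < self.flat_tol

        # a bin converged if the optimiser reached a (projected) stationary
        # point; flat bins carry no timing information and use the interpolant
        status = np.full(n_bins, STATUS_CONVERGED, dtype=np.int8)
        status[flat | (pgrad > 1e-5)] = STATUS_FALLBACK
        status[~usable] = STATUS_MASKED
        mu[~usable] = np.nan
        sig[~usable] = np.nan
        return ReplicationTimingResults(
            model=self, mu=mu, sigma=sig, status=status, sse=sse,
            sse_fallback=sse_fb, fallback_y=mono, fallback_valid=valid,
        )

    def _initial_params(self, g, yv, w, usable):
        """Coarse grid search plus a half-crossing heuristic."""
        lo, hi = self.mu_bounds
        mus = np.linspace(lo, hi, 36)
        sigmas = np.array([0.02, 0.05, 0.1, 0.2, 0.4, 0.8])
        mu_g, sig_g = np.meshgrid(mus, sigmas, indexing="ij")
        mu_c = mu_g.ravel()
        sig_c = sig_g.ravel()
        # predictions: (n_candidates, n_timepoints)
        pred = ndtr((g[None, :] - mu_c[:, None]) / sig_c[:, None])
        # sse: (n_candidates, n_bins)
        sse = (
            np.einsum("ct,tb->cb", pred**2, w)
            - 2.0 * pred @ yv
            + (yv**2 * w).sum(axis=0)[None, :]
        )
        best = np.argmin(sse, axis=0)
        return mu_c[best].copy(), sig_c[best].copy()

    def _refine(self, g, yv, w, mu, sig, max_iter):
        """Damped Gauss-Newton (Levenberg) on all bins simultaneously."""
        mu_lo, mu_hi = self.mu_bounds
        sig_lo, sig_hi = self.sigma_bounds

        def sse_of(m, s):
            z = (g[:, None] - m[None, :]) / s[None, :]
            p = ndtr(z)
            r = (p - yv) * w
            return np.einsum("tb,tb->b", r, r), z, p

        sse, z, p = sse_of(mu, sig)
        lam = np.full(mu.shape, 1e-3)
        sq2pi = np.sqrt(2.0 * np.pi)
        for _ in range(max_iter):
            phi = np.exp(-0.5 * z**2) / sq2pi
            j_mu = -(phi / sig[None, :]) * w
            j_sig = -(z * phi / sig[None, :]) * w
            r = (p - yv) * w
            a = np.einsum("tb,tb->b", j_mu, j_mu)
            b = np.einsum("tb,tb->b", j_mu, j_sig)
            c = np.einsum("tb,tb->b", j_sig, j_sig)
            gm = np.einsum("tb,tb->b", j_mu, r)
            gs = np.einsum("tb,tb->b", j_sig, r)
            aa = a * (1.0 + lam) + 1e-12
            cc = c * (1.0 + lam) + 1e-12
            det = aa * cc - b * b
            det[det == 0] = 1e-300
            step_mu = -(cc * gm - b * gs) / det
            step_sig = -(aa * gs - b * gm) / det
            mu_try = np.clip(mu + step_mu, mu_lo, mu_hi)
            sig_try = np.clip(sig + step_sig, sig_lo, sig_hi)
            sse_try, z_try, p_try = sse_of(mu_try, sig_try)
            better = sse_try <= sse
            mu = np.where(better, mu_try, mu)
            sig = np.where(better, sig_try, sig)
            sse = np.where(better, sse_try, sse)
            z = np.where(better[None, :], z_try, z)
            p = np.where(better[None, :], p_try, p)
            lam = np.where(better, lam * 0.3, lam * 5.0)
            np.clip(lam, 1e-9, 1e9, out=lam)
        # projected gradient: at an active bound, only an inward-pointing
        # gradient component counts against stationarity
        phi = np.exp(-0.5 * z**2) / sq2pi
        r = (p - yv) * w
        gm = np.einsum("tb,tb->b", -(phi / sig[None, :]) * w, r)
        gs = np.einsum("tb,tb->b", -(z * phi / sig[None, :]) * w, r)
        gm = np.where((mu <= mu_lo) & (gm > 0), 0.0, gm)
        gm = np.where((mu >= mu_hi) & (gm < 0), 0.0, gm)
        gs = np.where((sig <= sig_lo) & (gs > 0), 0.0, gs)
        gs = np.where((sig >= sig_hi) & (gs < 0), 0.0, gs)
        pgrad = np.hypot(gm, gs)
        return mu, sig, sse, pgrad


@dataclass
class ReplicationTimingResults:
    """Fitted per-bin timing parameters with diagnostics.

    ``mu`` is the half-replication global extent of each bin, ``sigma`` the
    spread of its replication on the G axis; ``status`` records whether the
    sigmoid converged, the bin fell back to monotone interpolation, or was
    masked.
    """

    model: ReplicationTimingModel
    mu: np.ndarray
    sigma: np.ndarray
    status: np.ndarray
    sse: np.ndarray
    sse_fallback: np.ndarray
    fallback_y: np.ndarray
    fallback_valid: np.ndarray
    _extent_cache: dict = field(default_factory=dict, repr=False)

    @property
    def genome(self) -> BinnedGenome:
        return self.model.series.genome

    def status_labels(self) -> np.ndarray:
        return np.array([STATUS_LABELS[int(s)] for s in self.status], dtype=object)

    def evaluate_extent(self, g_values=DEFAULT_EVAL_G) -> np.ndarray:
        """Local extents F(G, x) for each requested G, clipped to [0, 1].

        Returns an array of shape ``(len(g_values), n_bins)``; masked bins are
        NaN, fallback bins use the monotone interpolant of (G, L').
        """
        g_values = np.atleast_1d(np.asarray(g_values, dtype=float))
        key = tuple(g_values.tolist())
        if key in self._extent_cache:
            return self._extent_cache[key]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = ndtr((g_values[:, None] - self.mu[None, :]) / self.sigma[None, :])
        g_fit = self.model.g_fit
        for b in np.nonzero(self.status == STATUS_FALLBACK)[0]:
            v = self.fallback_valid[:, b]
            f[:, b] = np.interp(g_values, g_fit[v], self.fallback_y[v, b])
        f[:, self.status == STATUS_MASKED] = np.nan
        f = np.clip(f, 0.0, 1.0)
        self._extent_cache[key] = f
        return f

    def to_frame(self, g_values=DEFAULT_EVAL_G) -> pd.DataFrame:
        """Per-bin model table: chrom, start, end, mu, sigma, status, F(G)."""
        df = self.genome.bins_dataframe()
        df["mu"] = self.mu
        df["sigma"] = self.sigma
        df["status"] = self.status_labels()
        f = self.evaluate_extent(g_values)
        for gv, row in zip(np.atleast_1d(g_values), f):
            df[f"F{int(round(gv * 100))}"] = row
        return df

    def summary(self) -> str:
        n = self.status.size
        n_conv = int((self.status == STATUS_CONVERGED).sum())
        n_fb = int((self.status == STATUS_FALLBACK).sum())
        n_mask = int((self.status == STATUS_MASKED).sum())
        ok = self.status == STATUS_CONVERGED
        lines = [
            "Replication timing model (per-bin cumulative normal in G)",
            "=" * 60,
            f"bins: {n}   converged: {n_conv}   fallback: {n_fb}   masked: {n_mask}",
            f"fit timepoints (min): {self.model.fit_timepoints}",
            f"G at fit timepoints:  {np.round(self.model.g_fit, 4).tolist()}",
        ]
        if n_conv:
            qs = np.percentile(self.mu[ok], [25, 50, 75])
            lines.append(
                f"mu  (half-replication G): median {qs[1]:.4f}  IQR [{qs[0]:.4f}, {qs[2]:.4f}]"
            )
            qs = np.percentile(self.sigma[ok], [25, 50, 75])
            lines.append(
                f"sigma (spread on G axis): median {qs[1]:.4f}  IQR [{qs[0]:.4f}, {qs[2]:.4f}]"
            )
            lines.append(f"median per-bin SSE: {np.median(self.sse[ok]):.3g}")
        return "\n".join(lines)

    def compare(self, other: "ReplicationTimingResults", classes=None, g: float = 0.5,
                alternative: str = "two-sided"):
        return compare_conditions(self, other, classes, g=g, alternative=alternative)


def compare_conditions(
    results_a: ReplicationTimingResults,
    results_b: ReplicationTimingResults,
    classes=None,
    *,
    g: float = 0.5,
    alternative: str = "two-sided",
) -> dict:
    """Per-bin extent difference ΔF(G, x) = F_a - F_b with class summaries.

    ``classes`` maps a class name (e.g. ``origin``, ``late``) to a bin-index
    array; for each class the paired per-bin values of the two conditions are
    compared with a Mann-Whitney rank test (test name recorded in the output;
    ``alternative`` follows scipy's convention for F_a vs F_b).
    """
    if not results_a.genome.same_binning(results_b.genome):
        raise ValueError("results on different binnings")
    fa = results_a.evaluate_extent([g])[0]
    fb = results_b.evaluate_extent([g])[0]
    delta = fa - fb
    out = {
        "g": g,
        "delta": delta,
        "test": "mannwhitneyu",
        "alternative": alternative,
        "classes": {},
    }
    if classes is not None:
        class_items = (
            classes.items() if isinstance(classes, dict) else classes.as_dict().items()
        )
        for name, idx in class_items:
            idx = np.asarray(idx, dtype=int)
            sel = idx[~np.isnan(delta[idx])]
            summ = {
                "n": int(sel.size),
                "median_delta": float(np.median(delta[sel])) if sel.size else np.nan,
                "q1_delta": float(np.percentile(delta[sel], 25)) if sel.size else np.nan,
                "q3_delta": float(np.percentile(delta[sel], 75)) if sel.size else np.nan,
                "median_a": float(np.median(fa[sel])) if sel.size else np.nan,
                "median_b": float(np.median(fb[sel])) if sel.size else np.nan,
            }
            if sel.size >= 2 and (np.ptp(fa[sel]) > 0 or np.ptp(fb[sel]) > 0):
                stat, p = mannwhitneyu(fa[sel], fb[sel], alternative=alternative)
                summ["statistic"] = float(stat)
                summ["pvalue"] = float(p)
            else:
                summ["statistic"] = np.nan
                summ["pvalue"] = np.nan
            out["classes"][name] = summ
    return out
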