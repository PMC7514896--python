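"""Delay-embedding complexity measures for scalar time series.

Implements the standard nonlinear time-series toolchain: average mutual
information for the embedding delay, false nearest neighbours for the
embedding dimension, the Grassberger-Procaccia correlation dimension,
recurrence-plot diagonal-line Shannon entropy, and the Rosenstein
maximal Lyapunov exponent.  All estimators are scale-invariant: radii
and thresholds are chosen relative to the data (fixed recurrence rate,
quantile radii), so multiplying a series by a positive constant leaves
every estimate unchanged.

Entropies are reported in bits throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class EmbeddingParams:
    delay: int = 1  # samples
    dimension: int = 2
    theiler_window: int = 0  # samples excluded around the diagonal

    def __post_init__(self):
        if self.delay < 1 or self.dimension < 1 or self.theiler_window < 0:
            raise ValueError("need delay >= 1, dimension >= 1, theiler_window >= 0")


@dataclass
class ComplexityMetrics:
    """Bundle of complexity measures for one series."""

    correlation_dimension: float
    rqa_entropy: float  # bits
    max_lyapunov: float  # per sample
    max_lyapunov_per_ms: float
    embedding: EmbeddingParams
    diagnostics: dict = field(default_factory=dict)


def embed(series, delay: int, dimension: int) -> np.ndarray:
    """Time-delay embedding: row i is (x[i], x[i+τ], ..., x[i+(m-1)τ])."""
    x = np.asarray(series, dtype=float)
    n = x.size - (dimension - 1) * delay
    if n < 1:
        raise ValueError("series too short for this embedding")
    return np.lib.stride_tricks.sliding_window_view(x, (dimension - 1) * delay + 1)[
        :, :: delay
    ].copy()


def _hist_mi(x, y, n_bins):
    """Plug-in mutual information (bits) between two binned series."""
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))


def ami_delay(series, max_lag: int = 100, n_bins: int = 32,
              return_diagnostics: bool = False):
    """Embedding delay from the first local minimum of auto mutual information.

    If the AMI curve has no local minimum up to ``max_lag``, the first lag
    where AMI drops below ``AMI(1)/e`` is returned and flagged in the
    diagnostics; failing that, ``max_lag`` itself.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= max_lag + 1:
        raise ValueError("series too short for max_lag")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no embedding delay")
    ami = np.array([_hist_mi(x[:-lag], x[lag:], n_bins) for lag in range(1, max_lag + 1)])
    # light smoothing suppresses histogram-binning jitter before the
    # minimum search (the raw curve of clean deterministic signals is jagged)
    kernel = np.ones(3) / 3.0
    sm = np.convolve(ami, kernel, mode="same")
    sm[0], sm[-1] = ami[0], ami[-1]
    delay = None
    for i in range(1, len(sm) - 1):
        if sm[i] < sm[i - 1] and sm[i] <= sm[i + 1]:
            delay = i + 1
            break
    fallback = delay is None
    if fallback:
        below = np.flatnonzero(ami < ami[0] / np.e)
        delay = int(below[0] + 1) if below.size else max_lag
    if return_diagnostics:
        return delay, {"ami": ami, "fallback_1_over_e": fallback}
    return delay


def fnn_dimension(series, delay: int, max_dim: int = 10, rtol: float = 15.0,
                  atol: float = 2.0, fnn_threshold: float = 0.01,
                  theiler_window: int = 0, return_diagnostics: bool = False):
    """Minimal embedding dimension by the false-nearest-neighbour test.

    A neighbour is false in dimension m if adding the (m+1)-th delay
    coordinate stretches the pair by more than ``rtol`` relative to its
    m-dimensional distance, or beyond ``atol`` standard deviations of the
    data.  Returns the smallest m with FNN fraction below
    ``fnn_threshold``.
    """
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant series")
    fractions = []
    for m in range(1, max_dim + 1):
        span = m * delay  # need x[i + m*delay] for the test coordinate
        n = x.size - span
        if n < 50:
            raise ValueError("series too short for max_dim at this delay")
        pts = embed(x[: x.size - delay], delay, m)[:n]
        tree = cKDTree(pts)
        k = min(2 + 2 * theiler_window, n)
        dists, idxs = tree.query(pts, k=k)
        false = 0
        total = 0
        for i in range(n):
            j = -1
            for cand, d in zip(idxs[i][1:], dists[i][1:]):
                if abs(int(cand) - i) > theiler_window:
                    j = int(cand)
                    dm = d
                    break
            if j < 0:
                continue
            extra = abs(x[i + span] - x[j + span])
            total += 1
            if dm < 1e-8 * sd:
                # exact recurrence (noise-free periodic data): a true neighbour
                continue
            if extra / dm > rtol or np.hypot(dm, extra) / sd > atol:
                false += 1
        frac = false / max(total, 1)
        fractions.append(frac)
        if frac < fnn_threshold:
            if return_diagnostics:
                return m, {"fnn_fractions": fractions}
            return m
    if return_diagnostics:
        return max_dim, {"fnn_fractions": fractions, "saturated": True}
    return max_dim


def correlation_sum(points: np.ndarray, radii, theiler_window: int = 0) -> np.ndarray:
    """C(r): fraction of admissible point pairs (|i-j| > w) within r."""
    n = points.shape[0]
    tree = cKDTree(points)
    counts = tree.count_neighbors(tree, np.asarray(radii, dtype=float))
    # remove self-pairs and Theiler-band pairs, counted by brute force
    band_d = []
    for off in range(1, theiler_window + 1):
        band_d.append(np.linalg.norm(points[off:] - points[:-off], axis=1))
    band = np.sort(np.concatenate(band_d)) if band_d else np.empty(0)
    out = []
    for r, c in zip(radii, counts):
        c_adm = c - n - 2 * np.searchsorted(band, r, side="right")
        out.append(c_adm)
    n_pairs = n * (n - 1) - 2 * theiler_window * n + theiler_window * (theiler_window + 1)
    return np.asarray(out, dtype=float) / n_pairs


def _scaling_region(logr, logc, min_len: int = 4, rel_tol: float = 0.10):
    """Longest contiguous window of near-constant local slope."""
    slopes = np.diff(logc) / np.diff(logr)
    best = None
    for i in range(len(slopes)):
        for j in range(i + min_len - 1, len(slopes)):
            seg = slopes[i : j + 1]
            m = np.mean(seg)
            if m <= 0:
                break
            if np.max(np.abs(seg - m)) > rel_tol * abs(m):
                break
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
    return best


def correlation_dimension(series, embedding: EmbeddingParams, n_radii: int = 24,
                          return_diagnostics: bool = False):
    """Grassberger-Procaccia correlation dimension.

    The slope of log C(r) against log r is fitted over an automatically
    selected scaling region (the longest window where the local slope
    varies by less than 10%).  Returns NaN with a diagnostic when no
    scaling region exists.
    """
    pts = embed(series, embedding.delay, embedding.dimension)
    d0 = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    scale = np.median(d0) * 2 + 1e-300
    radii = np.logspace(np.log10(scale) - 2.2, np.log10(scale), n_radii)
    c = correlation_sum(pts, radii, embedding.theiler_window)
    # exclude the saturation regime near the attractor diameter: the
    # scaling law only holds where C(r) is well below its ceiling
    mask = (c > 0) & (c <= 0.25)
    logr = np.log10(radii[mask])
    logc = np.log10(c[mask])
    region = _scaling_region(logr, logc) if logr.size >= 5 else None
    if region is None:
        result = float("nan")
        diag = {"scaling_region": None, "fit_r2": float("nan")}
    else:
        i, j = region
        sel = slice(i, j + 2)  # slopes i..j involve points i..j+1
        coef, res = np.polyfit(logr[sel], logc[sel], 1, cov=False), None
        fit = np.polyval(coef, logr[sel])
        ss_res = np.sum((logc[sel] - fit) ** 2)
        ss_tot = np.sum((logc[sel] - logc[sel].mean()) ** 2) + 1e-300
        result = float(coef[0])
        diag = {
            "scaling_region": (float(10 ** logr[i]), float(10 ** logr[j + 1])),
            "fit_r2": float(1 - ss_res / ss_tot),
        }
    diag["log_r"] = logr
    diag["log_c"] = logc
    if return_diagnostics:
        return result, diag
    return result


def recurrence_radius(points: np.ndarray, target_rate: float,
                      theiler_window: int = 0) -> float:
    """Distance threshold giving the requested recurrence rate."""
    n = points.shape[0]
    iu, ju = np.triu_indices(n, k=theiler_window + 1)
    d = np.linalg.norm(points[iu] - points[ju], axis=1)
    return float(np.quantile(d, target_rate))


def diagonal_line_lengths(rec: np.ndarray, lmin: int = 2,
                          theiler_window: int = 0,
                          drop_border: bool = True) -> np.ndarray:
    """Lengths of diagonal line segments of a recurrence matrix.

    Lines touching the matrix border are dropped by default (their length
    is truncated by the observation window, which otherwise smears the
    line-length histogram of periodic signals).
    """
    n = rec.shape[0]
    lengths = []
    for off in range(theiler_window + 1, n):
        diag = np.diagonal(rec, offset=off)
        padded = np.concatenate(([False], diag, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[::2], edges[1::2]
        runs = ends - starts
        if drop_border:
            interior = (starts > 0) & (ends < diag.size)
            runs = runs[interior]
        lengths.extend(runs[runs >= lmin].tolist())
    return np.asarray(lengths, dtype=int)


def line_length_entropy(lengths) -> float:
    """Shannon entropy (bits) of a diagonal line-length histogram."""
    lengths = np.asarray(lengths, dtype=int)
    if lengths.size == 0:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def rqa_entropy(series, embedding: EmbeddingParams, target_recurrence_rate: float = 0.10,
                lmin: int = 2, max_points: int = 2000,
                return_diagnostics: bool = False):
    """Shannon entropy (bits) of the diagonal line-length distribution.

    The recurrence threshold is set to hit ``target_recurrence_rate``
    exactly (by quantile of the pairwise distances).  A perfectly
    periodic signal puts all (non-truncated) lines in one length class
    and scores 0 bits; richer line-length structure scores higher.
    """
    if not (0.0 < target_recurrence_rate < 1.0):
        raise ValueError("target recurrence rate must be in (0, 1)")
    pts = embed(series, embedding.delay, embedding.dimension)
    if pts.shape[0] > max_points:
        stride = int(np.ceil(pts.shape[0] / max_points))
        pts = pts[::stride]
    n = pts.shape[0]
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(pts))
    iu = np.triu_indices(n, k=embedding.theiler_window + 1)
    radius = float(np.quantile(d[iu], target_recurrence_rate))
    rec = d <= radius
    if rec.all() or not rec[np.triu_indices(n, k=embedding.theiler_window + 1)].any():
        raise ValueError("degenerate recurrence plot (all or no points recurrent)")
    lengths = diagonal_line_lengths(rec, lmin, embedding.theiler_window)
    entropy = line_length_entropy(lengths)
    counts = np.unique(lengths, return_counts=True)[1] if lengths.size else np.empty(0)
    if return_diagnostics:
        rr = rec[np.triu_indices(n, k=embedding.theiler_window + 1)].mean()
        return entropy, {
            "radius": radius,
            "recurrence_rate": float(rr),
            "n_lines": int(lengths.size),
            "n_length_classes": int(counts.size),
        }
    return entropy


def divergence_curve(series, embedding: EmbeddingParams, max_steps: int):
    """Rosenstein mean log divergence of nearest-neighbour pairs.

    Returns ``y`` where ``y[k]`` is the average natural log distance
    after k steps between trajectories that started as nearest
    neighbours (separated temporally by more than the Theiler window).
    """
    pts = embed(series, embedding.delay, embedding.dimension)
    n = pts.shape[0]
    if n < 100:
        raise ValueError("too few embedded points")
    w = max(embedding.theiler_window, 1)
    tree = cKDTree(pts)
    k = min(2 * w + 2, n)
    dists, idxs = tree.query(pts, k=k)
    nn = np.full(n, -1)
    for i in range(n):
        for cand in idxs[i][1:]:
            if abs(int(cand) - i) > w:
                nn[i] = int(cand)
                break
    valid = np.flatnonzero((nn >= 0))
    y = np.full(max_steps + 1, np.nan)
    for s in range(max_steps + 1):
        ii = valid[(valid + s < n) & (nn[valid] + s < n)]
        if ii.size < 10:
            break
        d = np.linalg.norm(pts[ii + s] - pts[nn[ii] + s], axis=1)
        d = d[d > 0]
        if d.size < 10:
            break
        y[s] = np.mean(np.log(d))
    return y


def _auto_divergence_slope(y, rise_threshold=1.5, plateau_margin=0.7):
    """Slope of the divergence curve's informative branch.

    If the curve rises appreciably (more than ``rise_threshold`` natural-log
    units from start to plateau), the exponent is the mean growth rate of
    the rising branch — the initial linear segment Rosenstein's method
    prescribes, which for fast divergence may span only a few samples.
    Otherwise the signal is non-divergent (periodic or contracting) and the
    exponent is the least-squares slope of the whole flat curve.
    """
    y = y[np.isfinite(y)]
    if y.size < 12:
        raise ValueError("insufficient neighbours to follow divergence")
    plateau = float(np.mean(y[-10:]))
    if plateau - y[0] < rise_threshold:
        ks = np.arange(1, y.size)
        return float(np.polyfit(ks, y[1:], 1)[0]), None
    k_star = max(int(np.argmax(y >= plateau - plateau_margin)), 1)
    return float((y[k_star] - y[0]) / k_star), k_star


def max_lyapunov(series, embedding: EmbeddingParams,
                 fit_window: Optional[tuple[int, int]] = None,
                 max_steps: int = 60,
                 sample_ms: Optional[float] = None, return_diagnostics: bool = False):
    """Maximal Lyapunov exponent by the Rosenstein method.

    With an explicit ``fit_window = (k_min, k_max)`` the exponent is the
    least-squares slope of the mean log divergence curve over that range
    of steps.  With ``fit_window=None`` the fitting branch is selected
    automatically: the rising (pre-saturation) segment when the curve
    diverges, the whole flat curve when it does not — so periodic or
    contracting signals yield exponents at or below zero while strongly
    chaotic signals are not misread as flat just because their divergence
    saturates within a few samples.

    Units are per sample; if ``sample_ms`` is given the per-ms value is
    included in the diagnostics.
    """
    if fit_window is not None:
        k0, k1 = fit_window
        if not (0 <= k0 < k1):
            raise ValueError("fit_window must satisfy 0 <= k0 < k1")
        y = divergence_curve(series, embedding, k1)
        ks = np.arange(k0, k1 + 1)
        yy = y[k0 : k1 + 1]
        ok = np.isfinite(yy)
        if ok.sum() < 3:
            raise ValueError("insufficient neighbours to follow divergence")
        slope = float(np.polyfit(ks[ok], yy[ok], 1)[0])
        used = (k0, k1)
    else:
        y = divergence_curve(series, embedding, max_steps)
        slope, k_star = _auto_divergence_slope(y)
        used = (0, k_star if k_star is not None else max_steps)
    if return_diagnostics:
        diag = {"divergence_curve": y, "fit_window": used}
        if sample_ms:
            diag["per_ms"] = slope / sample_ms
        return slope, diag
    return slope


def complexity_metrics(series, sample_ms: float, delay: Optional[int] = None,
                       dimension: Optional[int] = None,
                       theiler_factor: float = 1.0,
                       lyapunov_fit_ms: tuple[float, float] = (0.0, 40.0),
                       target_recurrence_rate: float = 0.10,
                       max_embed_points: int = 4000) -> ComplexityMetrics:
    """One-call pipeline: delay, dimension, D2, RQA entropy, Lyapunov.

    ``series`` is any scalar signal sampled every ``sample_ms``.  The
    embedding delay defaults to the first AMI minimum and the dimension
    to the FNN estimate; the Theiler window is ``theiler_factor`` times
    the delay-embedding span.
    """
    x = np.asarray(series, dtype=float)
    if x.size > max_embed_points:
        stride = int(np.ceil(x.size / max_embed_points))
        x = x[::stride]
        sample_ms = sample_ms * stride
    if delay is None:
        delay = ami_delay(x, max_lag=min(100, x.size // 10))
    if dimension is None:
        dimension = fnn_dimension(x, delay, max_dim=8, theiler_window=delay)
    theiler = max(1, int(round(theiler_factor * delay * dimension)))
    emb = EmbeddingParams(delay=delay, dimension=dimension, theiler_window=theiler)
    d2, d2_diag = correlation_dimension(x, emb, return_diagnostics=True)
    ent, ent_diag = rqa_entropy(x, emb, target_recurrence_rate,
                                max_points=2000, return_diagnostics=True)
    k0 = max(1, int(round(lyapunov_fit_ms[0] / sample_ms)))
    k1 = max(k0 + 2, int(round(lyapunov_fit_ms[1] / sample_ms)))
    lam, lam_diag = max_lyapunov(x, emb, (k0, k1), sample_ms, return_diagnostics=True)
    return ComplexityMetrics(
        correlation_dimension=d2,
        rqa_entropy=ent,
        max_lyapunov=lam,
        max_lyapunov_per_ms=lam / sample_ms,
        embedding=emb,
        diagnostics={
            "correlation_dimension": {k: v for k, v in d2_diag.items() if k not in ("log_r", "log_c")},
            "rqa": ent_diag,
            "lyapunov_fit_window_samples": lam_diag["fit_window"],
            "sample_ms": sample_ms,
        },
    )


#: embedding used for simulator region-voltage analysis: delay ~ the first
#: AMI minimum of control region voltage, dimension from FNN, and a Theiler
#: window longer than one theta cycle so neighbours come from distinct cycles
REGION_EMBEDDING = EmbeddingParams(delay=20, dimension=5, theiler_window=150)
REGION_SETTLE_MS = 4000.0  # discarded settling/learning transient


def region_complexity(result, config, region: str, sample_ms: float = 1.0,
                      settle_ms: float = REGION_SETTLE_MS) -> ComplexityMetrics:
    """Complexity measures of one region's average somatic voltage.

    The first ``settle_ms`` of the run (initial transient plus LTP
    saturation) are discarded; the remainder is analysed with the fixed
    region embedding and the automatic Lyapunov branch selection.
    """
    x = region_voltage(result, config, region, sample_ms)
    x = x[int(round(settle_ms / sample_ms)):]
    emb = REGION_EMBEDDING
    d2, d2_diag = correlation_dimension(x, emb, return_diagnostics=True)
    ent, ent_diag = rqa_entropy(x, emb, max_points=2000, return_diagnostics=True)
    lam, lam_diag = max_lyapunov(x, emb, sample_ms=sample_ms, return_diagnostics=True)
    return ComplexityMetrics(
        correlation_dimension=d2,
        rqa_entropy=ent,
        max_lyapunov=lam,
        max_lyapunov_per_ms=lam / sample_ms,
        embedding=emb,
        diagnostics={
            "region": region,
            "correlation_dimension": {k: v for k, v in d2_diag.items()
                                      if k not in ("log_r", "log_c")},
            "rqa": ent_diag,
            "lyapunov_fit_window_samples": lam_diag["fit_window"],
            "sample_ms": sample_ms,
            "settle_ms": settle_ms,
        },
    )


def region_voltage(result, config, region: str, sample_ms: float = 1.0) -> np.ndarray:
    """Region-average z-scored somatic voltage, resampled to ``sample_ms``.

    The analysis signal for complexity measures: each principal cell's
    somatic trace is z-scored, the region mean is taken, and the result
    is decimated from the integration step to ``sample_ms``.
    """
    from .network import region_cells

    cells = region_cells(config, region)
    stride = max(1, int(round(sample_ms / config.dt)))
    traces = []
    for cid in cells:
        v = result.voltage_traces[cid][::stride]
        sd = v.std()
        traces.append((v - v.mean()) / (sd if sd > 0 else 1.0))
    return np.mean(traces, axis=0)
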