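"""HRV feature bank: time-domain, spectral, and non-linear descriptors.

All statistics use the *population* variance convention (denominator n),
so the Poincaré identities sd1 = rmssd/√2 and sd1² + sd2² = 2·sdnn² hold
exactly. Spectral bands default to neonatal settings — LF 0.04–0.2 Hz,
HF 0.2–2.0 Hz — because the respiratory rate of a preterm infant
(~40–80 breaths/min) puts vagally mediated power far above the adult HF
band. Missing values are reported as NaN with a reason code rather than
raised, so one degenerate feature does not sink a segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .ingest import Segment

__all__ = [
    "HRVFeatureVector",
    "FEATURE_REGISTRY",
    "time_domain",
    "frequency_domain",
    "poincare",
    "sample_entropy",
    "dfa",
    "visibility_graph",
    "visibility_adjacency",
    "extract_features",
]

#: neonatal spectral bands in Hz
DEFAULT_BANDS: dict[str, tuple[float, float]] = {"lf": (0.04, 0.2), "hf": (0.2, 2.0)}

#: default DFA box-size ranges (beats)
DEFAULT_DFA_RANGES: dict[str, tuple[int, int]] = {
    "dfa_alpha1": (4, 11),
    "dfa_alpha2": (12, 64),
}

#: visibility graphs on longer segments are subsampled to this many beats
VG_CAP = 1024


def time_domain(rr_ms: Sequence[float]) -> dict[str, float]:
    """Time-domain statistics of an RR sequence (population variance).

    Returns mean_nn, sdnn, rmssd, sdsd, pnn20, pnn50; pnnX is the fraction
    of successive differences whose magnitude exceeds X ms.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        raise ValueError("time-domain features need at least 2 beats")
    d = np.diff(rr)
    return {
        "mean_nn": float(rr.mean()),
        "sdnn": float(rr.std()),
        "rmssd": float(np.sqrt(np.mean(d**2))),
        "sdsd": float(d.std()),
        "pnn20": float(np.mean(np.abs(d) > 20.0)),
        "pnn50": float(np.mean(np.abs(d) > 50.0)),
    }


def frequency_domain(
    beat_times: Sequence[float],
    rr_ms: Sequence[float],
    bands: Mapping[str, tuple[float, float]] | None = None,
    oversample: int = 2,
) -> dict[str, float]:
    """Band powers of the unevenly sampled RR series via Lomb–Scargle.

    The periodogram is evaluated on a grid from 1/T to the highest band
    edge (oversampled ``oversample``-fold relative to 1/T) and scaled so
    that integrating it over frequency recovers signal variance in ms²;
    band powers are trapezoidal integrals. ``lf_hf_ratio`` is NaN when HF
    power is zero (missing-with-reason downstream, never infinity).
    """
    t = np.asarray(beat_times, dtype=float)
    x = np.asarray(rr_ms, dtype=float)
    if t.size < 64:
        raise ValueError("frequency-domain features need at least 64 beats")
    if bands is None:
        bands = DEFAULT_BANDS
    _check_bands(bands)
    T = t[-1] - t[0]
    n = t.size
    f_lo = 1.0 / T
    f_hi = max(hi for _, hi in bands.values())
    freqs = np.arange(f_lo, f_hi + f_lo / oversample, f_lo / oversample)
    xc = x - x.mean()
    if np.allclose(xc, 0.0):
        power = np.zeros_like(freqs)
    else:
        pgram = lomb_periodogram(t, xc, 2.0 * math.pi * freqs)
        # scale so that ∫ psd df ≈ variance (ms²)
        power = pgram * 2.0 * T / n
    out: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        out[f"{name}_power"] = (
            float(np.trapezoid(power[sel], freqs[sel])) if sel.sum() > 1 else 0.0
        )
    out["total_power"] = float(np.trapezoid(power, freqs))
    hf = out.get("hf_power", 0.0)
    lf = out.get("lf_power", 0.0)
    out["lf_hf_ratio"] = lf / hf if hf > 0 else float("nan")
    return out


def lomb_periodogram(t: np.ndarray, x: np.ndarray, omegas: np.ndarray) -> np.ndarray:
    """Unnormalized Lomb periodogram of a centered, unevenly sampled series.

    Classic phase-offset (τ) formulation,
    P(ω) = ½ [ (Σ x cos ω(t−τ))²/Σ cos²ω(t−τ)
             + (Σ x sin ω(t−τ))²/Σ sin²ω(t−τ) ],
    tan 2ωτ = Σ sin 2ωt / Σ cos 2ωt, vectorized over blocks of frequencies
    (bounded memory, one trig evaluation per (ω, t) pair).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    out = np.empty(omegas.shape, dtype=float)
    block = 512
    for k in range(0, omegas.size, block):
        w = omegas[k : k + block, None]
        wt = w * t[None, :]
        tau = np.arctan2(np.sin(2 * wt).sum(axis=1), np.cos(2 * wt).sum(axis=1))
        arg = wt - 0.5 * tau[:, None]
        c, s = np.cos(arg), np.sin(arg)
        cc = (c * c).sum(axis=1)
        ss = (s * s).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 0.5 * ((x @ c.T) ** 2 / cc + (x @ s.T) ** 2 / ss)
        out[k : k + block] = np.where(np.isfinite(p), p, 0.0)
    return out


def _check_bands(bands: Mapping[str, tuple[float, float]]) -> None:
    intervals = sorted(bands.values())
    for (lo, hi) in intervals:
        if not 0 <= lo < hi:
            raise ValueError(f"invalid band ({lo}, {hi})")
    for (_, hi), (lo, _) in zip(intervals, intervals[1:]):
        if lo < hi:
            raise ValueError("bands must be disjoint")


def poincare(rr_ms: Sequence[float]) -> dict[str, float]:
    """Poincaré plot axes: sd1² = ½·⟨Δ²⟩, sd2² = 2·sdnn² − sd1² (floored).

    The successive-difference second moment is taken about zero (the mean
    successive difference of a stationary RR series), so the identity
    sd1 = rmssd/√2 is exact. The ratio sd1/sd2 is NaN on degenerate
    (constant) series.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 3:
        raise ValueError("Poincaré features need at least 3 beats")
    d = np.diff(rr)
    sd1_sq = 0.5 * float(np.mean(d**2))
    sd2_sq = max(2.0 * rr.var() - sd1_sq, 0.0)
    sd1, sd2 = math.sqrt(sd1_sq), math.sqrt(sd2_sq)
    return {
        "sd1": sd1,
        "sd2": sd2,
        "sd1_sd2_ratio": sd1 / sd2 if sd2 > 0 else float("nan"),
    }


def sample_entropy(rr_ms: Sequence[float], m: int = 2, r: float = 0.2) -> float:
    """Sample entropy: −ln(A/B) with Chebyshev distance, self-matches excluded.

    ``r`` is a fraction of the series' population standard deviation
    (absolute tolerance 0 when the series is constant, in which case every
    template matches and the entropy is 0). Templates are the N−m windows
    of length m (B) and their m+1 extensions (A), the Richman–Moorman
    counting convention. Returns NaN when no length-m or length-m+1 pair
    matches.
    """
    x = np.asarray(rr_ms, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"sample entropy needs more than m+1={m + 1} points")
    if r <= 0:
        raise ValueError("r must be positive")
    sd = x.std()
    tol = r * sd  # 0 for constant series: exact matches still count
    nt = n - m  # number of length-m templates restricted to have an extension
    # pairwise Chebyshev template distances, processed in row blocks so the
    # memory footprint stays O(block·n) even on long segments
    A = B = 0
    block = 512
    for start in range(0, nt - 1, block):
        stop = min(start + block, nt - 1)
        rows = np.arange(start, stop)
        cheb_m = np.abs(x[rows, None] - x[None, :nt])
        for k in range(1, m):
            np.maximum(cheb_m, np.abs(x[rows + k, None] - x[None, k : k + nt]),
                       out=cheb_m)
        cheb_m1 = np.maximum(
            cheb_m, np.abs(x[rows + m, None] - x[None, m : m + nt])
        )
        # count only pairs (i, j) with j > i
        mask = np.arange(nt)[None, :] > rows[:, None]
        B += int(np.count_nonzero((cheb_m <= tol) & mask))
        A += int(np.count_nonzero((cheb_m1 <= tol) & mask))
    if B == 0 or A == 0:
        return float("nan")
    return float(-math.log(A / B))


def _dfa_white_response(n: int) -> float:
    """Exact E[F²(n)] of linear-detrend DFA for unit-variance white noise.

    Within a box the profile has covariance Cov(y_j, y_k) = min(j, k) + 1;
    the expected mean squared residual after least-squares line removal is
    tr(M Σ)/n with M the annihilator of [1, t]. Used as the finite-size
    correction of modified DFA: dividing F²(n) by this response and
    multiplying by n makes uncorrelated noise scale exactly as n^0.5 at
    every box size, removing the well-known upward bias of the short-box
    (4–11 beat) exponent.
    """
    j = np.arange(n, dtype=float)
    sigma = np.minimum.outer(j, j) + 1.0
    X = np.column_stack([np.ones(n), j - j.mean()])
    H = X @ np.linalg.solve(X.T @ X, X.T)
    M = np.eye(n) - H
    return float(np.trace(M @ sigma) / n)


def dfa(
    rr_ms: Sequence[float],
    scale_ranges: Mapping[str, tuple[int, int]] | None = None,
) -> dict[str, float]:
    """Detrended fluctuation analysis exponents over beat-count box ranges.

    The mean-centered series is integrated; each box size n in a range
    tiles the profile with ⌊N/n⌋ non-overlapping boxes, each linearly
    detrended; F(n) is the root-mean-square residual with the modified-DFA
    finite-size correction (squared fluctuations divided by the exact
    white-noise response and rescaled by n, so an uncorrelated series has
    exponent 0.5 without short-box bias). The exponent is the
    least-squares slope of log F(n) on log n. A range with fewer than two
    usable box sizes yields NaN.
    """
    x = np.asarray(rr_ms, dtype=float)
    if x.size < 100:
        raise ValueError("DFA needs at least 100 beats")
    if scale_ranges is None:
        scale_ranges = DEFAULT_DFA_RANGES
    y = np.cumsum(x - x.mean())
    out: dict[str, float] = {}
    for name, (lo, hi) in scale_ranges.items():
        sizes, fluct = [], []
        for n in range(lo, hi + 1):
            k = y.size // n
            if k < 2:
                continue
            boxes = y[: k * n].reshape(k, n)
            t = np.arange(n, dtype=float)
            # per-box linear detrend via least squares on a shared design
            tc = t - t.mean()
            slope = boxes @ tc / (tc @ tc)
            resid = boxes - boxes.mean(axis=1, keepdims=True) - slope[:, None] * tc
            f_sq = float(np.mean(resid**2)) * n / _dfa_white_response(n)
            fluct.append(math.sqrt(f_sq))
            sizes.append(n)
        if len(sizes) < 2 or not all(f > 0 for f in fluct):
            out[name] = float("nan")
            continue
        alpha = np.polyfit(np.log(sizes), np.log(fluct), 1)[0]
        out[name] = float(alpha)
    return out


def visibility_adjacency(
    values: Sequence[float], times: Sequence[float] | None = None
) -> np.ndarray:
    """Natural-visibility adjacency matrix of a series.

    Nodes a < b are connected when every intermediate sample lies strictly
    below the chord from (t_a, y_a) to (t_b, y_b); equivalently, the slope
    from a to b strictly exceeds the slope from a to every intermediate
    point. Ties block visibility (strict inequality), so a constant series
    yields a path graph.
    """
    y = np.asarray(values, dtype=float)
    t = (
        np.arange(y.size, dtype=float)
        if times is None
        else np.asarray(times, dtype=float)
    )
    n = y.size
    adj = np.zeros((n, n), dtype=bool)
    for a in range(n - 1):
        slopes = (y[a + 1 :] - y[a]) / (t[a + 1 :] - t[a])
        prev_max = np.concatenate(([-np.inf], np.maximum.accumulate(slopes[:-1])))
        vis = slopes > prev_max
        adj[a, a + 1 :] = vis
        adj[a + 1 :, a] = vis
    return adj


def visibility_graph(
    rr_ms: Sequence[float],
    beat_times: Sequence[float] | None = None,
    cap: int = VG_CAP,
) -> dict[str, float]:
    """Natural-visibility-graph degree statistics of an RR sequence.

    RR values are placed at their beat times (not beat indices). Series
    longer than ``cap`` are subsampled deterministically (evenly spaced
    indices). Degree assortativity is NaN on degree-regular graphs.
    """
    y = np.asarray(rr_ms, dtype=float)
    if y.size < 10:
        return {
            "vg_mean_degree": float("nan"),
            "vg_degree_sd": float("nan"),
            "vg_assortativity": float("nan"),
        }
    t = (
        np.arange(y.size, dtype=float)
        if beat_times is None
        else np.asarray(beat_times, dtype=float)
    )
    if y.size > cap:
        idx = np.unique(np.linspace(0, y.size - 1, cap).round().astype(int))
        y, t = y[idx], t[idx]
    adj = visibility_adjacency(y, t)
    deg = adj.sum(axis=0).astype(float)
    g = nx.from_numpy_array(adj)
    if np.ptp(deg) == 0:
        assort = float("nan")  # degree-regular: correlation undefined
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            assort = float(nx.degree_assortativity_coefficient(g))
    return {
        "vg_mean_degree": float(deg.mean()),
        "vg_degree_sd": float(deg.std()),
        "vg_assortativity": assort,
    }


# ---------------------------------------------------------------------------
# Registry and per-segment extraction
# ---------------------------------------------------------------------------

#: canonical feature names grouped by the computation that produces them
FEATURE_REGISTRY: dict[str, str] = {
    "mean_nn": "time_domain",
    "sdnn": "time_domain",
    "rmssd": "time_domain",
    "sdsd": "time_domain",
    "pnn20": "time_domain",
    "pnn50": "time_domain",
    "lf_power": "frequency_domain",
    "hf_power": "frequency_domain",
    "total_power": "frequency_domain",
    "lf_hf_ratio": "frequency_domain",
    "sd1": "poincare",
    "sd2": "poincare",
    "sd1_sd2_ratio": "poincare",
    "sampen": "sample_entropy",
    "dfa_alpha1": "dfa",
    "dfa_alpha2": "dfa",
    "vg_mean_degree": "visibility_graph",
    "vg_degree_sd": "visibility_graph",
    "vg_assortativity": "visibility_graph",
}


@dataclass
class HRVFeatureVector:
    """Named feature values for one segment, with missing-value reasons."""

    patient_id: str
    pma_weeks: float
    segment_start_s: float
    quality: float
    values: dict[str, float]
    reasons: dict[str, str] = field(default_factory=dict)


def extract_features(
    segment: Segment,
    feature_names: Sequence[str] | None = None,
    bands: Mapping[str, tuple[float, float]] | None = None,
) -> HRVFeatureVector:
    """Compute the requested features on one segment.

    Unknown names raise a ``KeyError`` listing the registry. Features whose
    computation is degenerate or infeasible on the segment come back as NaN
    with a reason code in ``reasons``; requested features are otherwise
    never missing. Deterministic: the same segment always yields the same
    vector.
    """
    names = list(feature_names) if feature_names is not None else list(FEATURE_REGISTRY)
    unknown = [n for n in names if n not in FEATURE_REGISTRY]
    if unknown:
        raise KeyError(
            f"unknown feature(s) {unknown}; known features: {sorted(FEATURE_REGISTRY)}"
        )
    groups = {FEATURE_REGISTRY[n] for n in names}
    rr, t = segment.rr_ms, segment.beat_times
    pool: dict[str, float] = {}
    reasons: dict[str, str] = {}

    def run(group: str, fn, *args, **kwargs):
        try:
            res = fn(*args, **kwargs)
        except ValueError as exc:
            for n in names:
                if FEATURE_REGISTRY[n] == group:
                    pool[n] = float("nan")
                    reasons[n] = str(exc)
            return
        if isinstance(res, dict):
            pool.update(res)
        else:
            pool[group_scalar[group]] = res

    group_scalar = {"sample_entropy": "sampen"}
    if "time_domain" in groups:
        run("time_domain", time_domain, rr)
    if "frequency_domain" in groups:
        run("frequency_domain", frequency_domain, t, rr, bands)
    if "poincare" in groups:
        run("poincare", poincare, rr)
    if "sample_entropy" in groups:
        run("sample_entropy", sample_entropy, rr)
    if "dfa" in groups:
        run("dfa", dfa, rr)
    if "visibility_graph" in groups:
        run("visibility_graph", visibility_graph, rr, t)

    values: dict[str, float] = {}
    for n in names:
        v = pool.get(n, float("nan"))
        values[n] = float(v)
        if math.isnan(values[n]) and n not in reasons:
            reasons[n] = _NAN_REASONS.get(n, "degenerate_input")
    return HRVFeatureVector(
        patient_id=segment.patient_id,
        pma_weeks=segment.pma_weeks,
        segment_start_s=segment.start_s,
        quality=segment.quality,
        values=values,
        reasons=reasons,
    )


_NAN_REASONS = {
    "lf_hf_ratio": "hf_power_zero",
    "sd1_sd2_ratio": "sd2_zero",
    "sampen": "no_template_matches",
    "dfa_alpha1": "insufficient_scales",
    "dfa_alpha2": "insufficient_scales",
    "vg_mean_degree": "series_too_short",
    "vg_degree_sd": "series_too_short",
    "vg_assortativity": "degree_regular_graph",
}


def features_frame(vectors: Sequence[HRVFeatureVector]):
    """Feature table: one row per segment (metadata columns then features)."""
    import pandas as pd

    rows = []
    for v in vectors:
        row = {
            "patient_id": v.patient_id,
            "pma_weeks": v.pma_weeks,
            "segment_start_s": v.segment_start_s,
            "quality": v.quality,
        }
        row.update(v.values)
        rows.append(row)
    return pd.DataFrame(rows)
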