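"""Termination-efficiency quantification from dual-reporter growth curves.

A construct carries an RFP gene, an intrinsic terminator, and a downstream
GFP gene on one operon. The fraction of RNAPs that terminate is read out as
the deficit in GFP synthesis relative to RFP, each normalized to a
terminator-free reference construct:

    TE = 1 - (P_GFP / P_GFP_ref) / (P_RFP / P_RFP_ref)

where the per-cell synthesis rate of a fluorescent protein during balanced
exponential growth is

    P = mu * f * (1 + mu * tau / ln 2),

with mu the growth rate (1/min), f = dF/dOD the fluorescence-per-biomass
slope, and tau the fluorophore maturation half-time (min); the bracket
corrects for the pool of not-yet-fluorescent protein. For constructs whose
RFP gene was modified, the GFP-only form TE = 1 - P_GFP / P_GFP_ref is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GrowthSeries",
    "MaturationParams",
    "SynthesisRate",
    "TEMeasurement",
    "select_exponential_window",
    "estimate_growth_rate",
    "estimate_f_slope",
    "synthesis_rate",
    "te_dual",
    "te_gfp_only",
    "quantify_construct",
]

LN2 = math.log(2.0)


@dataclass
class GrowthSeries:
    """One replicate's time-resolved OD600 and two-channel fluorescence."""

    construct_id: str
    time: np.ndarray  # minutes, strictly increasing
    od: np.ndarray  # OD600, positive
    f_rfp: np.ndarray  # arbitrary units, non-negative
    f_gfp: np.ndarray  # arbitrary units, non-negative

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.f_rfp = np.asarray(self.f_rfp, dtype=float)
        self.f_gfp = np.asarray(self.f_gfp, dtype=float)
        n = len(self.time)
        if n < 4 or any(len(a) != n for a in (self.od, self.f_rfp, self.f_gfp)):
            raise ValueError("all arrays must have equal length >= 4")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.od <= 0):
            raise ValueError("invalid OD: all OD values must be positive")
        if np.any(self.f_rfp < 0) or np.any(self.f_gfp < 0):
            raise ValueError("fluorescence must be non-negative")

    def fluorescence(self, channel: str) -> np.ndarray:
        if channel == "RFP":
            return self.f_rfp
        if channel == "GFP":
            return self.f_gfp
        raise ValueError(f"channel must be 'RFP' or 'GFP', got {channel!r}")


@dataclass(frozen=True)
class MaturationParams:
    """Maturation half-times (min) of the two fluorophores.

    The defaults reflect typical fast-folding GFP variants (~15 min) and
    slower-maturing RFPs (~40 min); both are configurable and TE is
    insensitive to their exact values as long as the same tau is applied to
    construct and reference (the normalization cancels it).
    """

    tau_rfp: float = 40.0
    tau_gfp: float = 15.0

    def __post_init__(self) -> None:
        for name, tau in (("tau_rfp", self.tau_rfp), ("tau_gfp", self.tau_gfp)):
            if not np.isfinite(tau) or tau < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {tau}")

    def tau(self, channel: str) -> float:
        return self.tau_rfp if channel == "RFP" else self.tau_gfp


@dataclass(frozen=True)
class SynthesisRate:
    construct_id: str
    channel: str
    mu: float  # 1/min
    f_slope: float  # fluorescence per OD
    p: float  # fluorescence * OD^-1 * min^-1


@dataclass(frozen=True)
class TEMeasurement:
    construct_id: str
    series: str
    distance_nt: int
    te: float
    te_se: float
    method: str  # "dual" or "gfp_only"
    n_replicates: int = 1


def select_exponential_window(
    series: GrowthSeries,
    od_min: float = 0.02,
    od_max: float = 0.3,
    min_r2: float = 0.99,
    min_points: int = 3,
) -> np.ndarray:
    """Indices of the exponential-phase window.

    Default policy: the longest contiguous run of points with OD in
    [od_min, od_max] whose ln(OD)-vs-time regression reaches R^2 >= min_r2;
    ends are trimmed if needed. Earliest window wins ties.
    """
    in_range = (series.od >= od_min) & (series.od <= od_max)
    best: np.ndarray | None = None
    i = 0
    n = len(series.od)
    while i < n:
        if not in_range[i]:
            i += 1
            continue
        j = i
        while j < n and in_range[j]:
            j += 1
        # scan sub-windows of the run [i, j), longest first
        for length in range(j - i, min_points - 1, -1):
            if best is not None and length <= len(best):
                break
            for start in range(i, j - length + 1):
                idx = np.arange(start, start + length)
                r = stats.linregress(series.time[idx], np.log(series.od[idx]))
                if r.rvalue**2 >= min_r2:
                    best = idx
                    break
            if best is not None and len(best) == length:
                break
        i = j
    if best is None:
        raise ValueError(
            f"no exponential window: need >= {min_points} points with OD in "
            f"[{od_min}, {od_max}] and ln(OD) R^2 >= {min_r2}"
        )
    return best


def _window_indices(series: GrowthSeries, window) -> np.ndarray:
    if window is None:
        return select_exponential_window(series)
    if isinstance(window, slice):
        return np.arange(len(series.time))[window]
    return np.asarray(window, dtype=int)


def estimate_growth_rate(series: GrowthSeries, window=None) -> tuple[float, float]:
    """Exponential growth rate mu (1/min) and R^2 of ln(OD) vs time.

    A flat OD trace yields mu = 0 with R^2 reported as 0 (warned)."""
    idx = _window_indices(series, window)
    if len(idx) < 3:
        raise ValueError("insufficient points: window must select >= 3 points")
    od = series.od[idx]
    if np.any(od <= 0):
        raise ValueError("invalid OD: non-positive OD in window")
    t = series.time[idx]
    y = np.log(od)
    if np.allclose(y, y[0]):
        warnings.warn("constant OD in window; mu = 0, R^2 undefined", stacklevel=2)
        return 0.0, 0.0
    r = stats.linregress(t, y)
    return float(r.slope), float(r.rvalue**2)


def estimate_f_slope(
    series: GrowthSeries, channel: str, window=None, background: float = 0.0
) -> float:
    """OLS slope f = d(F - background)/dOD over the window."""
    idx = _window_indices(series, window)
    if len(idx) < 3:
        raise ValueError("insufficient points: window must select >= 3 points")
    od = series.od[idx]
    if np.allclose(od, od[0]):
        raise ValueError("degenerate window: zero OD variance")
    f = series.fluorescence(channel)[idx] - background
    if np.allclose(f, f[0]):
        return 0.0
    r = stats.linregress(od, f)
    return float(r.slope)


def synthesis_rate(mu: float, f_slope: float, tau: float) -> float:
    """Per-cell synthesis rate P = mu * f * (1 + mu * tau / ln 2)."""
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    return mu * f_slope * (1.0 + mu * tau / LN2)


def te_dual(p_gfp: float, p_rfp: float, p_gfp_ref: float, p_rfp_ref: float) -> float:
    """Dual-normalized TE = 1 - (P_GFP/P_GFP_ref) / (P_RFP/P_RFP_ref).

    Not clipped: noise can produce small negatives, which downstream fitting
    should see."""
    if p_gfp_ref <= 0 or p_rfp_ref <= 0 or p_rfp <= 0:
        raise ValueError("invalid normalization: reference rates and p_rfp must be > 0")
    return 1.0 - (p_gfp / p_gfp_ref) / (p_rfp / p_rfp_ref)


def te_gfp_only(p_gfp: float, p_gfp_ref: float) -> float:
    """GFP-only TE = 1 - P_GFP / P_GFP_ref (for RFP-modified constructs)."""
    if p_gfp_ref <= 0:
        raise ValueError("invalid normalization: reference rate must be > 0")
    return 1.0 - p_gfp / p_gfp_ref


def _replicate_rates(
    series: GrowthSeries, maturation: MaturationParams, window, background: dict | None
) -> dict[str, SynthesisRate]:
    """One mu from OD, shared by both channels (mu is a culture property)."""
    idx = _window_indices(series, window)
    mu, _ = estimate_growth_rate(series, idx)
    out = {}
    bg = background or {}
    for channel in ("RFP", "GFP"):
        f = estimate_f_slope(series, channel, idx, background=bg.get(channel, 0.0))
        p = synthesis_rate(mu, f, maturation.tau(channel))
        out[channel] = SynthesisRate(series.construct_id, channel, mu, f, p)
    return out


def quantify_construct(
    series: GrowthSeries | Sequence[GrowthSeries],
    reference_series: GrowthSeries | Sequence[GrowthSeries],
    maturation: MaturationParams = MaturationParams(),
    window=None,
    reference_window=None,
    background: dict | None = None,
    rfp_modified: bool = False,
    series_label: str = "other",
    distance_nt: int = 0,
) -> TEMeasurement:
    """Full quantification of one construct against the reference.

    Accepts one or several replicate GrowthSeries per side. Reference rates
    are averaged across reference replicates; TE is computed per construct
    replicate and aggregated as mean +/- standard error.
    """
    cons = [series] if isinstance(series, GrowthSeries) else list(series)
    refs = (
        [reference_series]
        if isinstance(reference_series, GrowthSeries)
        else list(reference_series)
    )
    if not cons or not refs:
        raise ValueError("need at least one construct and one reference series")

    ref_rates = [_replicate_rates(r, maturation, reference_window, background) for r in refs]
    p_gfp_ref = float(np.mean([r["GFP"].p for r in ref_rates]))
    p_rfp_ref = float(np.mean([r["RFP"].p for r in ref_rates]))

    tes = []
    for rep in cons:
        rates = _replicate_rates(rep, maturation, window, background)
        if rfp_modified:
            tes.append(te_gfp_only(rates["GFP"].p, p_gfp_ref))
        else:
            tes.append(te_dual(rates["GFP"].p, rates["RFP"].p, p_gfp_ref, p_rfp_ref))
    te = float(np.mean(tes))
    se = float(np.std(tes, ddof=1) / math.sqrt(len(tes))) if len(tes) > 1 else 0.0
    return TEMeasurement(
        construct_id=cons[0].construct_id,
        series=series_label,
        distance_nt=distance_nt,
        te=te,
        te_se=se,
        method="gfp_only" if rfp_modified else "dual",
        n_replicates=len(tes),
    )
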