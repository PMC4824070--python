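"""Poisson model of ribosome-RNAP coupling at intrinsic terminators.

In bacteria the pioneer ribosome trails RNAP on the nascent transcript. When
RNAP reaches a Rho-independent terminator, the hairpin can only fold if the
ribosome is far enough behind: a ribosome within ``alpha`` nt of the first
base of the hairpin stem occludes folding and forces readthrough. Because
both machines move stochastically, the ribosome-hairpin distance X at the
moment RNAP reaches the termination site is random; modelling it as
Poisson with mean ``lambda = d + c`` (d the stop-codon-to-hairpin spacer
length, c a sequence-specific offset) gives the termination efficiency

    TE(d) = TE0 * (1 - CDF_Poisson(alpha, d + c)),

where TE0 is the terminator's maximal (unoccluded) efficiency. This module
evaluates that model, fits it to TE-distance tables by exhaustive integer
grid search with a closed-form TE0, and provides bootstrap uncertainty. A
scikit-learn compatible estimator wraps the fit for pipeline use.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CouplingParams",
    "FitResult",
    "tr2_reference_params",
    "poisson_cdf",
    "predict_te",
    "fit_coupling",
    "bootstrap_ci",
    "TerminationCouplingModel",
]

_CONVENTIONS = ("inclusive", "strict")


@dataclass(frozen=True)
class CouplingParams:
    """Parameter set of the coupling model.

    Parameters
    ----------
    te0 : float
        Maximal termination efficiency, in [0, 1].
    alpha : int
        Occlusion threshold in nt: a ribosome at distance X from the first
        base of the hairpin stem represses folding iff X <= alpha
        (inclusive convention) or X <= alpha - 1 (strict).
    offsets : mapping of series label to int
        Per-series additive offset c such that lambda(d) = d + c.
    cdf_convention : {"inclusive", "strict"}
        Whether a ribosome exactly at the threshold still represses.
    """

    te0: float
    alpha: int
    offsets: Mapping[str, int]
    cdf_convention: str = "inclusive"

    def __post_init__(self) -> None:
        if not 0.0 <= self.te0 <= 1.0:
            raise ValueError(f"te0 must be in [0, 1], got {self.te0}")
        if self.alpha < 0 or int(self.alpha) != self.alpha:
            raise ValueError(f"alpha must be a non-negative integer, got {self.alpha}")
        if self.cdf_convention not in _CONVENTIONS:
            raise ValueError(f"cdf_convention must be one of {_CONVENTIONS}")
        object.__setattr__(self, "offsets", dict(self.offsets))

    @property
    def threshold_k(self) -> int:
        """CDF argument K: repression iff X <= K."""
        return self.alpha if self.cdf_convention == "inclusive" else self.alpha - 1


def tr2_reference_params(cdf_convention: str = "inclusive") -> CouplingParams:
    """Fitted parameters of the lambda-phage tR2 terminator system.

    TE0 = 0.9, alpha = 27 nt, lambda = d + 15 for the W-series (natural
    lambda-phage upstream sequences) and d + 7 for the R-series (random
    low-structure insertions).
    """
    return CouplingParams(
        te0=0.9, alpha=27, offsets={"W": 15, "R": 7}, cdf_convention=cdf_convention
    )


def poisson_cdf(k: int, lam: float) -> float:
    """P[X <= k] for X ~ Poisson(lam); k = -1 returns 0 exactly.

    Evaluated through the regularized incomplete gamma function
    (scipy.stats.poisson), exact to machine precision.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if k < 0:
        return 0.0
    return float(stats.poisson.cdf(k, lam))


def predict_te(d, series: str, params: CouplingParams):
    """Model TE at spacer distance(s) ``d`` for one construct series.

    ``d`` may be a scalar or array of non-negative distances (nt). Raises if
    the series has no fitted offset or if any d + c < 0 (the Poisson mean
    would be negative; such geometries are rejected, not clamped).
    """
    if series not in params.offsets:
        raise KeyError(f"unknown series {series!r}; have {sorted(params.offsets)}")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distances must be non-negative")
    lam = d_arr + params.offsets[series]
    if np.any(lam < 0):
        raise ValueError(
            f"d + c < 0 for series {series!r} (c={params.offsets[series]})"
        )
    te = params.te0 * (1.0 - stats.poisson.cdf(params.threshold_k, lam))
    return float(te) if np.isscalar(d) else te


@dataclass
class FitResult:
    """Outcome of the exhaustive grid fit."""

    params: CouplingParams
    rss: float
    n_points: int
    bootstrap_ci: dict | None = None
    objective_grid: pd.DataFrame | None = None
    n_degenerate_resamples: int = 0


def _as_fit_frame(data) -> pd.DataFrame:
    """Normalize TE measurements into a (series, distance_nt, te[, weight]) frame."""
    if isinstance(data, pd.DataFrame):
        df = data.copy()
    else:  # iterable of TEMeasurement-like objects
        rows = []
        for m in data:
            rows.append(
                {
                    "construct_id": getattr(m, "construct_id", ""),
                    "series": m.series,
                    "distance_nt": m.distance_nt,
                    "te": m.te,
                }
            )
        df = pd.DataFrame(rows)
    missing = {"series", "distance_nt", "te"} - set(df.columns)
    if missing:
        raise ValueError(f"TE table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("empty TE data")
    d = df["distance_nt"].to_numpy()
    if np.any(d < 0) or np.any(d != np.round(d)):
        raise ValueError("distances must be non-negative integers")
    return df


def fit_coupling(
    data,
    alpha_range: tuple[int, int] = (0, 60),
    c_range: tuple[int, int] = (-10, 40),
    cdf_convention: str = "inclusive",
    weights: np.ndarray | None = None,
    return_grid: bool = False,
) -> FitResult:
    """Fit the coupling model by exhaustive integer grid search.

    For every (alpha, c_series...) on the grid the model is linear in TE0,
    so TE0 has the closed-form weighted least-squares solution
    TE0 = sum(w * te * m) / sum(w * m**2) with m = 1 - CDF(K, d + c),
    clamped to [0, 1]. The global minimizer of the residual sum of squares
    is returned; ties are broken toward the smallest alpha, then the
    smallest offsets in series order.

    Parameters
    ----------
    data : DataFrame or iterable of TEMeasurement
        Must provide series, distance_nt and te per point.
    weights : array, optional
        Per-point weights (e.g. 1/SE**2). Default: unweighted.
    """
    if cdf_convention not in _CONVENTIONS:
        raise ValueError(f"cdf_convention must be one of {_CONVENTIONS}")
    df = _as_fit_frame(data)
    w = np.ones(len(df)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(df):
        raise ValueError("weights length mismatch")
    df = df.assign(_w=w)

    series_labels = sorted(df["series"].unique())
    per_series = {}
    for s in series_labels:
        sub = df[df["series"] == s]
        if len(sub) < 4:
            raise ValueError(f"series {s!r} has fewer than 4 points")
        per_series[s] = (
            sub["distance_nt"].to_numpy(dtype=float),
            sub["te"].to_numpy(dtype=float),
            sub["_w"].to_numpy(dtype=float),
        )

    alphas = np.arange(alpha_range[0], alpha_range[1] + 1)
    cs = np.arange(c_range[0], c_range[1] + 1)
    sse_const = sum(float(np.sum(w_ * te_**2)) for _, te_, w_ in per_series.values())

    best = None  # (rss, alpha, offsets tuple, te0)
    grid_rows = [] if return_grid else None
    for alpha in alphas:
        k = alpha if cdf_convention == "inclusive" else alpha - 1
        # Per-series sufficient statistics on the c grid.
        S = {}  # sum w te m
        Q = {}  # sum w m^2
        valid = {}
        for s, (d_, te_, w_) in per_series.items():
            lam = d_[None, :] + cs[:, None]  # (n_c, n_points)
            ok = np.all(lam >= 0, axis=1)
            m = 1.0 - stats.poisson.cdf(k, np.clip(lam, 0, None))
            S[s] = np.sum(w_ * te_ * m, axis=1)
            Q[s] = np.sum(w_ * m**2, axis=1)
            valid[s] = ok
        # Broadcast the shared-TE0 solution over the offset product grid.
        shape = (len(cs),) * len(series_labels)
        S_tot = np.zeros(shape)
        Q_tot = np.zeros(shape)
        ok_tot = np.ones(shape, dtype=bool)
        for i, s in enumerate(series_labels):
            idx = [None] * len(series_labels)
            idx[i] = slice(None)
            S_tot = S_tot + S[s][tuple(idx)]
            Q_tot = Q_tot + Q[s][tuple(idx)]
            ok_tot = ok_tot & valid[s][tuple(idx)]
        with np.errstate(divide="ignore", invalid="ignore"):
            te0 = np.clip(np.where(Q_tot > 0, S_tot / np.where(Q_tot > 0, Q_tot, 1.0), np.nan), 0.0, 1.0)
        rss = sse_const - 2.0 * te0 * S_tot + te0**2 * Q_tot
        rss = np.where(ok_tot & (Q_tot > 0), rss, np.inf)
        flat = np.argmin(rss)  # C-order: first (smallest) offsets win ties
        r = float(rss.flat[flat])
        if np.isfinite(r) and (best is None or r < best[0] - 1e-15):
            combo = np.unravel_index(flat, shape)
            best = (r, int(alpha), tuple(int(cs[j]) for j in combo), float(te0.flat[flat]))
        if return_grid:
            for combo in itertools.product(range(len(cs)), repeat=len(series_labels)):
                row = {"alpha": int(alpha), "rss": float(rss[combo])}
                for i, s in enumerate(series_labels):
                    row[f"c_{s}"] = int(cs[combo[i]])
                grid_rows.append(row)

    if best is None:
        raise ValueError("unidentifiable: model degenerate on all grid points")
    rss, alpha, offsets, te0 = best
    params = CouplingParams(
        te0=te0,
        alpha=alpha,
        offsets=dict(zip(series_labels, offsets)),
        cdf_convention=cdf_convention,
    )
    grid = pd.DataFrame(grid_rows) if return_grid else None
    return FitResult(params=params, rss=max(rss, 0.0), n_points=len(df), objective_grid=grid)


def bootstrap_ci(
    data,
    B: int = 500,
    seed: int = 0,
    level: float = 0.95,
    **fit_kwargs,
) -> dict:
    """Case-resampling bootstrap over constructs.

    Resamples construct IDs with replacement, refits on each resample and
    returns percentile intervals per parameter. Resamples on which the fit
    is degenerate (a series losing too many points) are skipped and counted.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    if B < 100:
        warnings.warn(f"B={B} is small for percentile intervals", stacklevel=2)
    df = _as_fit_frame(data)
    if "construct_id" not in df.columns or df["construct_id"].eq("").all():
        df = df.assign(construct_id=[f"pt{i}" for i in range(len(df))])
    ids = df["construct_id"].unique()
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {}
    skipped = 0
    for _ in range(B):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        parts = [df[df["construct_id"] == cid] for cid in chosen]
        boot = pd.concat(parts, ignore_index=True)
        try:
            fit = fit_coupling(boot, **fit_kwargs)
        except ValueError:
            skipped += 1
            continue
        draws.setdefault("te0", []).append(fit.params.te0)
        draws.setdefault("alpha", []).append(fit.params.alpha)
        for s, c in fit.params.offsets.items():
            draws.setdefault(f"c_{s}", []).append(c)
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    ci = {
        name: (float(np.percentile(v, lo)), float(np.percentile(v, hi)))
        for name, v in draws.items()
    }
    ci["n_degenerate_resamples"] = skipped
    return ci


class TerminationCouplingModel(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator for the TE-distance coupling model.

    Fits TE(d) = TE0 * (1 - CDF_Poisson(alpha, d + c_series)) by exhaustive
    integer grid search over alpha and per-series offsets with closed-form
    TE0 (see :func:`fit_coupling`).

    Parameters
    ----------
    alpha_range, c_range : (int, int)
        Inclusive integer search bounds for the occlusion threshold and the
        per-series lambda offsets.
    cdf_convention : {"inclusive", "strict"}
        Repression at X == alpha (inclusive) or only below it (strict).

    Attributes
    ----------
    params_ : CouplingParams
        Fitted parameter set.
    te0_ : float
    alpha_ : int
    offsets_ : dict
    rss_ : float
    n_points_ : int

    Examples
    --------
    >>> X = pd.DataFrame({"distance_nt": [5, 15, 25, 35, 45],
    ...                   "series": ["W"] * 5})
    >>> y = predict_te(X["distance_nt"].to_numpy(), "W", tr2_reference_params())
    >>> model = TerminationCouplingModel().fit(X, y)
    >>> model.alpha_
    27
    """

    def __init__(
        self,
        alpha_range: tuple[int, int] = (0, 60),
        c_range: tuple[int, int] = (-10, 40),
        cdf_convention: str = "inclusive",
    ):
        self.alpha_range = alpha_range
        self.c_range = c_range
        self.cdf_convention = cdf_convention

    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            if not {"distance_nt", "series"} <= set(X.columns):
                raise ValueError("X must have 'distance_nt' and 'series' columns")
            return X[["distance_nt", "series"]].copy()
        arr = np.asarray(X)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("array X must have two columns: distance, series label")
        return pd.DataFrame(
            {"distance_nt": arr[:, 0].astype(float), "series": arr[:, 1].astype(str)}
        )

    def fit(self, X, y):
        df = self._to_frame(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(df):
            raise ValueError("X and y length mismatch")
        df["te"] = y
        result = fit_coupling(
            df,
            alpha_range=self.alpha_range,
            c_range=self.c_range,
            cdf_convention=self.cdf_convention,
        )
        self.params_ = result.params
        self.te0_ = result.params.te0
        self.alpha_ = result.params.alpha
        self.offsets_ = dict(result.params.offsets)
        self.rss_ = result.rss
        self.n_points_ = result.n_points
        return self

    def predict(self, X):
        if not hasattr(self, "params_"):
            raise AttributeError("model is not fitted")
        df = self._to_frame(X)
        out = np.empty(len(df))
        for s in df["series"].unique():
            mask = (df["series"] == s).to_numpy()
            out[mask] = predict_te(
                df.loc[mask, "distance_nt"].to_numpy(), s, self.params_
            )
        return out
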