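"""Synthetic fixtures: construct panels, plate-reader curves, TE tables.

No public dataset accompanies the TE-distance measurements, so every
pipeline stage is exercised on generated data with known ground truth:

* construct panels emulating the W-series (natural lambda-phage upstream
  sequences, spacer lengths 8-48 nt) and R-series (random low-structure
  insertions, 9-59 nt), plus a terminator-free reference and uncoupled
  (-30U style) variants;
* exponential-phase growth curves whose fluorescence follows the balanced-
  growth steady state of a two-pool (immature -> mature) maturation model,
  so the (1 + mu*tau/ln2) synthesis-rate correction is exact and a noiseless
  round trip through the quantifier recovers the programmed TE to machine
  precision;
* TE-distance tables drawn from the coupling model with additive Gaussian
  noise, for fitter validation.

Noise is multiplicative lognormal for OD/fluorescence (scale-proportional
instrument noise) and additive Gaussian for TE tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coupling import CouplingParams, predict_te, tr2_reference_params
from .quantification import LN2, GrowthSeries, MaturationParams

__all__ = [
    "ConstructDesign",
    "NoiseModel",
    "make_construct_panel",
    "make_growth_series",
    "make_te_table",
    "DEFAULT_W_DISTANCES",
    "DEFAULT_R_DISTANCES",
]

# Spacer lengths spanning the measured ranges (W: 8-48 nt, R: 9-59 nt).
DEFAULT_W_DISTANCES: tuple[int, ...] = (8, 11, 14, 18, 22, 26, 30, 35, 40, 48)
DEFAULT_R_DISTANCES: tuple[int, ...] = (9, 13, 17, 22, 27, 32, 38, 45, 52, 59)


@dataclass(frozen=True)
class ConstructDesign:
    """Declarative description of one reporter construct."""

    construct_id: str
    series: str  # "W", "R" or "custom"
    distance_nt: int
    true_te: float  # ground truth used by the generators
    rfp_modified: bool = False
    translation_coupled: bool = True
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.distance_nt < 0:
            raise ValueError("distance_nt must be >= 0")
        if not -0.1 <= self.true_te <= 1.0:
            raise ValueError(f"true_te out of range: {self.true_te}")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings shared by the generators."""

    fluor_lognormal_sigma: float = 0.0
    od_lognormal_sigma: float = 0.0
    te_gaussian_sigma: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fluor_lognormal_sigma", "od_lognormal_sigma", "te_gaussian_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


NOISELESS = NoiseModel(replicates=1)


def make_construct_panel(
    params: CouplingParams | None = None,
    w_distances: Sequence[int] = DEFAULT_W_DISTANCES,
    r_distances: Sequence[int] = DEFAULT_R_DISTANCES,
    include_uncoupled: bool = True,
) -> list[ConstructDesign]:
    """W-like and R-like construct panels with model-implied ground-truth TE.

    Includes exactly one terminator-free reference (true_te = 0) and,
    optionally, uncoupled -30U-style constructs whose RBS deletion abolishes
    ribosome loading: their true TE is the unrepressed TE0 regardless of
    distance.
    """
    params = params or tr2_reference_params()
    panel: list[ConstructDesign] = []
    for series, distances in (("W", w_distances), ("R", r_distances)):
        for d in distances:
            panel.append(
                ConstructDesign(
                    construct_id=f"{series}{d:02d}",
                    series=series,
                    distance_nt=int(d),
                    true_te=predict_te(int(d), series, params),
                )
            )
    panel.append(
        ConstructDesign(
            construct_id="I21", series="custom", distance_nt=0, true_te=0.0,
            is_reference=True,
        )
    )
    if include_uncoupled:
        for series, d in (("W", min(w_distances)), ("R", min(r_distances))):
            panel.append(
                ConstructDesign(
                    construct_id=f"{series}{d:02d}-30U",
                    series=series,
                    distance_nt=int(d),
                    true_te=params.te0,
                    translation_coupled=False,
                    rfp_modified=True,
                )
            )
    return panel


def _mature_fraction_slope(p: float, mu: float, tau: float) -> float:
    """Steady-state mature protein per OD given synthesis rate p.

    Two-pool balanced growth: immature protein made at rate p matures at
    ln2/tau and both pools dilute at mu, giving a mature concentration of
    p / (mu * (1 + mu*tau/ln2)). The quantifier's correction inverts this
    exactly.
    """
    return p / (mu * (1.0 + mu * tau / LN2))


def make_growth_series(
    design: ConstructDesign,
    mu: float = 0.02,
    p_rfp_ref: float = 2000.0,
    p_gfp_ref: float = 1000.0,
    maturation: MaturationParams = MaturationParams(),
    noise: NoiseModel = NOISELESS,
    od0: float = 0.002,
    t_max: float = 360.0,
    dt: float = 30.0,
    background: float = 0.0,
) -> list[GrowthSeries]:
    """Plate-reader replicates for one construct.

    OD grows exponentially from ``od0`` at rate ``mu`` (1/min), sampled every
    ``dt`` minutes. GFP synthesis is scaled by (1 - true_te) relative to the
    reference; RFP synthesis is halved for RFP-modified constructs (their TE
    must be read out GFP-only) and absent for uncoupled constructs' upstream
    reporter only in reality -- here the -30U RFP signal is likewise halved,
    which the GFP-only readout ignores. Lognormal noise per NoiseModel.
    """
    if mu <= 0 or p_rfp_ref <= 0 or p_gfp_ref <= 0:
        raise ValueError("mu and reference synthesis rates must be positive")
    p_gfp = p_gfp_ref * (1.0 - design.true_te)
    p_rfp = p_rfp_ref * (0.5 if design.rfp_modified else 1.0)
    s_gfp = _mature_fraction_slope(p_gfp, mu, maturation.tau_gfp)
    s_rfp = _mature_fraction_slope(p_rfp, mu, maturation.tau_rfp)

    t = np.arange(0.0, t_max + 0.5 * dt, dt)
    od_clean = od0 * np.exp(mu * t)
    rng = np.random.default_rng(noise.seed)
    out = []
    for _ in range(noise.replicates):
        od = od_clean.copy()
        if noise.od_lognormal_sigma > 0:
            od = od * rng.lognormal(0.0, noise.od_lognormal_sigma, size=od.shape)
        f_rfp = background + s_rfp * od_clean
        f_gfp = background + s_gfp * od_clean
        if noise.fluor_lognormal_sigma > 0:
            f_rfp = f_rfp * rng.lognormal(0.0, noise.fluor_lognormal_sigma, size=t.shape)
            f_gfp = f_gfp * rng.lognormal(0.0, noise.fluor_lognormal_sigma, size=t.shape)
        out.append(
            GrowthSeries(
                construct_id=design.construct_id,
                time=t,
                od=od,
                f_rfp=np.maximum(f_rfp, 0.0),
                f_gfp=np.maximum(f_gfp, 0.0),
            )
        )
    return out


def make_te_table(
    params: CouplingParams | None = None,
    distances: dict[str, Iterable[int]] | None = None,
    noise: NoiseModel = NOISELESS,
) -> pd.DataFrame:
    """TE-distance table drawn from the coupling model plus Gaussian noise.

    Returns a long-format frame with columns construct_id, series,
    distance_nt, replicate, te. Deterministic given NoiseModel.seed.
    """
    params = params or tr2_reference_params()
    if distances is None:
        distances = {"W": DEFAULT_W_DISTANCES, "R": DEFAULT_R_DISTANCES}
    rng = np.random.default_rng(noise.seed)
    rows = []
    for series in sorted(distances):
        for d in distances[series]:
            te_true = predict_te(int(d), series, params)
            for rep in range(noise.replicates):
                te = te_true
                if noise.te_gaussian_sigma > 0:
                    te = te + rng.normal(0.0, noise.te_gaussian_sigma)
                rows.append(
                    {
                        "construct_id": f"{series}{int(d):02d}",
                        "series": series,
                        "distance_nt": int(d),
                        "replicate": rep,
                        "te": te,
                    }
                )
    return pd.DataFrame(rows)
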