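"""Growth-regime fitting and cytoplasm-dilution arithmetic.

Budding-yeast cells growing in a prolonged G1 arrest start out in an
exponential regime — growth rate proportional to volume, dV/dt = k*V —
and switch to linear growth (constant dV/dt) once they exceed a
transition volume V* (about 200 fL for haploids; the ceiling scales
with ploidy).  Beyond V*, macromolecule synthesis stops keeping up
with volume expansion and the cytoplasm becomes diluted.

This module fits the two-regime model to volume time courses, computes
fold changes and the dilution index (content fold / volume fold; 1 =
perfect scaling, < 1 = dilution), and predicts the relative drop in
total cell density from a dry-mass composition model: the excess of
cell density over water is proportional to dry-mass concentration, so
each component contributes its dry-mass fraction times its relative
concentration decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthTrajectory",
    "RegimeFit",
    "CompositionModel",
    "growth_rate_curve",
    "fit_growth_regimes",
    "fold_change",
    "dilution_index",
    "predict_density_drop",
    "ploidy_rate_ratio",
]

#: Approximate dry-mass composition of a yeast cell.  Lipids, inorganic
#: molecules and the unlisted remainder form a constant-concentration
#: "other" pool; fractions are deliberately NOT renormalized to 1.
DEFAULT_DRY_MASS_FRACTIONS: dict[str, float] = {
    "protein": 0.50,
    "carbohydrate": 0.30,
    "RNA": 0.10,
    "other": 0.07,
}


@dataclass(frozen=True)
class GrowthTrajectory:
    """Volume (and optional content) time course of one cell/culture.

    Attributes
    ----------
    t : ndarray, hours, strictly increasing
    V : ndarray, fL
    content : dict of name -> ndarray, a.u.
        Optional macromolecule tracks (``protein``, ``RNA``,
        ``soluble_protein``...).
    vacuole : ndarray, fL, optional
        Vacuolar volume, for computing vacuole-excluded folds.
    """

    t: np.ndarray
    V: np.ndarray
    content: dict[str, np.ndarray] = field(default_factory=dict)
    vacuole: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        V = np.asarray(self.V, dtype=float)
        if t.size != V.size:
            raise ValueError("t and V must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(V)):
            raise ValueError("t and V must be finite")
        if np.any(V <= 0):
            raise ValueError("V must be positive")
        content = {
            k: np.asarray(v, dtype=float) for k, v in self.content.items()
        }
        for k, v in content.items():
            if v.size != t.size:
                raise ValueError(f"content track {k!r} length mismatch")
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"content track {k!r} must be finite positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "content", content)
        if self.vacuole is not None:
            vac = np.asarray(self.vacuole, dtype=float)
            if vac.size != t.size:
                raise ValueError("vacuole track length mismatch")
            object.__setattr__(self, "vacuole", vac)

    def series(self, name: str) -> np.ndarray:
        """Return the volume (name='V') or a named content track."""
        if name == "V":
            return self.V
        if name == "vacuole_excluded":
            if self.vacuole is None:
                raise ValueError("no vacuole track present")
            return self.V - self.vacuole
        try:
            return self.content[name]
        except KeyError:
            raise KeyError(
                f"unknown series {name!r}; have V"
                + (", vacuole_excluded" if self.vacuole is not None else "")
                + ("".join(", " + k for k in self.content))
            ) from None


@dataclass(frozen=True)
class RegimeFit:
    """Fitted exponential-to-linear growth model.

    The model is continuous at the breakpoint: V(t) = V0*exp(k_exp*t)
    for t <= t_star, then V(t_star) + linear_rate*(t - t_star).
    ``V_star = V(t_star)`` under the fitted exponential.
    """

    k_exp: float  # 1/h
    linear_rate: float  # fL/h
    t_star: float  # h
    V_star: float  # fL
    sse: float


@dataclass(frozen=True)
class CompositionModel:
    """Dry-mass fractions and per-component concentration drops.

    ``drops[c]`` is the relative decrease of component c's
    concentration, in [0, 1]; components absent from ``drops`` are
    treated as unchanged.
    """

    fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRY_MASS_FRACTIONS)
    )
    drops: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        if sum(self.fractions.values()) > 1.01:
            raise ValueError("fractions must sum to at most 1.01")
        for c, d in self.drops.items():
            if c not in self.fractions:
                raise ValueError(f"unknown component in drops: {c!r}")
            if not 0 <= d <= 1:
                raise ValueError(f"drop for {c!r} must be in [0, 1]")


def growth_rate_curve(
    traj: GrowthTrajectory, smooth_window: int = 1
) -> pd.DataFrame:
    """Absolute (dV/dt) and specific ((dV/dt)/V) growth rates.

    Central finite differences at interior points, one-sided at the
    ends; ``smooth_window > 1`` applies a centered moving average to V
    before differencing (edges use shrunken windows).
    """
    if traj.t.size < 3:
        raise ValueError("need at least 3 time points")
    if smooth_window > traj.t.size:
        raise ValueError("smoothing window larger than the series")
    v = traj.V.astype(float)
    if smooth_window > 1:
        half = smooth_window // 2
        v = np.array(
            [
                v[max(0, i - half) : i + half + 1].mean()
                for i in range(v.size)
            ]
        )
    dvdt = np.gradient(v, traj.t)
    return pd.DataFrame(
        {"t": traj.t, "dV_dt": dvdt, "specific_rate": dvdt / v}
    )


def _regime_sse(t, v, i_star):
    """Fit exp segment up to index i_star, continuous linear after.

    Returns (k_exp, linear_rate, V_star, sse) or None if degenerate.
    """
    t_exp, v_exp = t[: i_star + 1], v[: i_star + 1]
    # log-linear fit stabilizes the small-V regime
    k, logv0 = np.polyfit(t_exp, np.log(v_exp), 1)
    v_star = float(np.exp(logv0 + k * t[i_star]))
    # linear segment through (t_star, V_star)
    t_lin, v_lin = t[i_star:], v[i_star:]
    dt = t_lin - t[i_star]
    denom = np.sum(dt * dt)
    if denom > 0:
        b = float(np.sum((v_lin - v_star) * dt) / denom)
    else:
        b = k * v_star
    pred = np.empty_like(v)
    pred[: i_star + 1] = np.exp(logv0 + k * t_exp)
    pred[i_star:] = v_star + b * dt
    sse = float(np.sum((v - pred) ** 2))
    return float(k), b, v_star, sse


def fit_growth_regimes(traj: GrowthTrajectory) -> RegimeFit:
    """Fit the continuous exponential-to-linear model by breakpoint grid search.

    Every interior time point (leaving at least 3 points in each
    segment, with the breakpoint shared) is a candidate breakpoint; for
    each, the exponential segment is fitted log-linearly on t <= t*,
    the linear segment is fitted on t >= t* constrained through the
    exponential's value at t*, and the candidate minimizing total
    raw-scale SSE wins.  A pure exponential therefore lands on the last
    grid point; a pure linear series on the first.
    """
    t, v = traj.t, traj.V
    if t.size < 6:
        raise ValueError("need at least 6 time points")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive for the exponential fit")
    best = None
    for i_star in range(2, t.size - 2):
        k, b, v_star, sse = _regime_sse(t, v, i_star)
        if best is None or sse < best[0]:
            best = (sse, i_star, k, b, v_star)
    sse, i_star, k, b, v_star = best
    return RegimeFit(
        k_exp=k, linear_rate=b, t_star=float(t[i_star]), V_star=v_star, sse=sse
    )


def fold_change(
    traj: GrowthTrajectory, name: str, t1: float, t2: float
) -> float:
    """value(t2)/value(t1) of a named series, interpolated in time."""
    if not t1 < t2:
        raise ValueError("t1 must precede t2")
    if t1 < traj.t[0] or t2 > traj.t[-1]:
        raise ValueError("t1 and t2 must lie within the sampled range")
    y = traj.series(name)
    v1 = float(np.interp(t1, traj.t, y))
    v2 = float(np.interp(t2, traj.t, y))
    if v1 == 0:
        raise ValueError("value at t1 is zero; fold undefined")
    return v2 / v1


def dilution_index(content_fold: float, volume_fold: float) -> float:
    """Content fold / volume fold; 1 = perfect scaling, < 1 = dilution."""
    if content_fold <= 0 or volume_fold <= 0:
        raise ValueError("folds must be positive")
    return content_fold / volume_fold


def predict_density_drop(m: CompositionModel) -> float:
    """Predicted relative decrease of total cell density.

    The excess of cell density over water is proportional to total
    dry-mass concentration, so the relative density drop is the
    dry-mass-fraction-weighted sum of per-component concentration
    drops::

        drop = sum_c fraction[c] * drops.get(c, 0)

    With the default composition and the measured 6 h drops (protein
    53%, RNA 68%, carbohydrates and other components unchanged) this
    gives 0.333, i.e. a predicted 33% density decrease.
    """
    return float(
        sum(f * m.drops.get(c, 0.0) for c, f in m.fractions.items())
    )


def ploidy_rate_ratio(fitA: RegimeFit, fitB: RegimeFit) -> float:
    """Ratio of maximal linear growth rates, fitA / fitB.

    The linear-regime ceiling scales with genome copy number, so
    diploid/haploid cohorts give a ratio near 2.
    """
    if fitA.linear_rate <= 0 or fitB.linear_rate <= 0:
        raise ValueError("both linear rates must be positive")
    return fitA.linear_rate / fitB.linear_rate
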