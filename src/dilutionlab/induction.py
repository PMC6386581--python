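"""Promoter-induction kinetics from single-cell fluorescence traces.

Mean GFP intensities of cells expressing an unstable reporter from an
inducible promoter are corrected in two steps — per-frame field
background, then the cell's own baseline (mean of the first few frames,
taken while the promoter is still off) — after which induction rate is
the slope of the linear rise and amplitude is max minus min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InductionTrace",
    "RateFit",
    "correct_trace",
    "induction_rate",
    "amplitude",
    "fraction_induced",
]


@dataclass(frozen=True)
class InductionTrace:
    """One cell's fluorescence time series.

    Attributes
    ----------
    cell_id : str
    t : ndarray, minutes, ascending
    raw : ndarray, a.u.
        Mean intensity before any correction.
    field_background : ndarray, a.u.
        Per-frame background measured in empty field positions.
    corrected : ndarray or None
        Filled by :func:`correct_trace`.
    """

    cell_id: str
    t: np.ndarray
    raw: np.ndarray
    field_background: np.ndarray
    corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        raw = np.asarray(self.raw, dtype=float)
        bg = np.asarray(self.field_background, dtype=float)
        if t.size < 4:
            raise ValueError("need at least 4 frames (3 baseline + 1)")
        if raw.size != t.size or bg.size != t.size:
            raise ValueError("raw and field_background must match t")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be ascending")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "field_background", bg)
        if self.corrected is not None:
            object.__setattr__(
                self, "corrected", np.asarray(self.corrected, dtype=float)
            )

    def _signal(self) -> np.ndarray:
        if self.corrected is None:
            raise ValueError("trace not corrected; run correct_trace first")
        return self.corrected


@dataclass(frozen=True)
class RateFit:
    """Linear-phase induction rate.

    ``flag`` is "ok", or "no_positive_window" when no window with a
    positive slope exists (rate reported as 0).
    """

    rate: float  # a.u./min
    r_squared: float
    window: tuple[int, int]  # inclusive frame range used
    flag: str = "ok"


def correct_trace(trace: InductionTrace, n_baseline: int = 3) -> InductionTrace:
    """Two-step background correction.

    Step 1 subtracts the per-frame field background; step 2 subtracts
    the mean of the cell's first ``n_baseline`` step-1-corrected values
    (the pre-induction frames), removing per-cell autofluorescence.
    Idempotent on traces that are already corrected and have zero
    background.
    """
    if trace.t.size < n_baseline + 1:
        raise ValueError(
            f"trace has {trace.t.size} frames; need more than "
            f"n_baseline={n_baseline}"
        )
    step1 = trace.raw - trace.field_background
    corrected = step1 - step1[:n_baseline].mean()
    return InductionTrace(
        cell_id=trace.cell_id,
        t=trace.t,
        raw=trace.raw,
        field_background=trace.field_background,
        corrected=corrected,
    )


def _ols_slope_r2(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        # flat window: perfect fit of a constant, slope 0
        return float(slope), 1.0
    return float(slope), float(1.0 - np.sum(resid**2) / ss_tot)


def induction_rate(
    trace: InductionTrace, window: tuple[int, int] | str = "auto"
) -> RateFit:
    """Induction rate by OLS over the linear rise of the corrected trace.

    With an explicit ``window=(first, last)`` (inclusive frame
    indices), fits that range.  In ``"auto"`` mode, every contiguous
    window of length >= max(3, 20% of frames) with a positive slope is
    scored and the one maximizing R-squared wins; ties go to the
    longest, then the earliest window.  If no window has a positive
    slope the rate is 0 with flag ``"no_positive_window"``.
    """
    y = trace._signal()
    t = trace.t
    n = t.size
    if window != "auto":
        lo, hi = window
        if hi - lo + 1 < 3:
            raise ValueError("window must span at least 3 frames")
        slope, r2 = _ols_slope_r2(t[lo : hi + 1], y[lo : hi + 1])
        return RateFit(rate=slope, r_squared=r2, window=(lo, hi))
    min_len = max(3, int(np.ceil(0.2 * n)))
    # prefix sums make every window's OLS slope and R^2 O(1)
    ct = np.concatenate([[0.0], np.cumsum(t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    ctt = np.concatenate([[0.0], np.cumsum(t * t)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    best: tuple | None = None  # (-r2, -length, start)
    best_fit = None
    for length in range(min_len, n + 1):
        for start in range(0, n - length + 1):
            end = start + length
            st = ct[end] - ct[start]
            sy = cy[end] - cy[start]
            sxx = (ctt[end] - ctt[start]) - st * st / length
            sxy = (cty[end] - cty[start]) - st * sy / length
            if sxy <= 0 or sxx <= 0:
                continue  # non-positive slope (or degenerate x)
            slope = sxy / sxx
            ss_tot = (cyy[end] - cyy[start]) - sy * sy / length
            if ss_tot <= 0:
                continue  # flat window, slope 0
            r2 = max(0.0, min(1.0, 1.0 - (ss_tot - slope * sxy) / ss_tot))
            key = (-r2, -length, start)
            if best is None or key < best:
                best = key
                best_fit = RateFit(
                    rate=float(slope),
                    r_squared=float(r2),
                    window=(start, end - 1),
                )
    if best_fit is None:
        return RateFit(
            rate=0.0, r_squared=0.0, window=(0, n - 1), flag="no_positive_window"
        )
    return best_fit


def amplitude(trace: InductionTrace) -> float:
    """Maximum minus minimum of the corrected trace."""
    y = trace._signal()
    return float(y.max() - y.min())


def fraction_induced(traces: list[InductionTrace], threshold: float) -> float:
    """Share of traces whose amplitude exceeds ``threshold``."""
    if not traces:
        raise ValueError("need at least one trace")
    return sum(amplitude(tr) > threshold for tr in traces) / len(traces)
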