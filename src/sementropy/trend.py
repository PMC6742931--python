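"""Developmental-trend fits: entropy vs days post-conception.

Normalized entropies over a staged series are fit with ordinary least
squares (linear) and with a two-parameter exponential E(t) = exp(a*t) + b.
The exponential form avoids the linear fit's pathology of eventually
predicting negative entropy; its asymptote b is the residual disorder the
model approaches late in development.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class StagePoint:
    model_id: str
    stage: str
    t: float  # days post-conception
    e0_norm: Optional[float]
    epi_norm: Optional[float]

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("days post-conception must be positive")


@dataclass
class StageSeries:
    """Normalized entropies of a developmental series against time in days."""

    points: List[StagePoint] = field(default_factory=list)

    def values(self, which: str) -> Tuple[np.ndarray, np.ndarray]:
        """(t, entropy) arrays for 'e0' or 'epi', skipping absent values."""
        if which not in ("e0", "epi"):
            raise ValueError("which must be 'e0' or 'epi'")
        pairs = [
            (p.t, p.e0_norm if which == "e0" else p.epi_norm)
            for p in self.points
            if (p.e0_norm if which == "e0" else p.epi_norm) is not None
        ]
        if not pairs:
            return np.array([]), np.array([])
        t, y = zip(*pairs)
        return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


@dataclass
class TrendFit:
    """A fitted trend: kind 'linear' (slope, intercept) or 'exponential'
    (rate a, offset b for exp(a*t)+b), with the mean squared residual."""

    kind: str
    params: Tuple[float, ...]
    mse: float
    degenerate: bool = False

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "linear":
            slope, intercept = self.params
            return slope * t + intercept
        a, b = self.params
        if self.degenerate:
            return np.full_like(t, b)
        return np.exp(a * t) + b


def fit_linear(series: StageSeries, which: str = "epi") -> TrendFit:
    """Ordinary least squares of normalized entropy on days post-conception."""
    t, y = series.values(which)
    if t.size < 2:
        raise ValueError("linear fit requires at least 2 points")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return TrendFit(kind="linear", params=(float(slope), float(intercept)),
                    mse=float(np.mean(resid**2)))


def fit_exponential(
    series: StageSeries,
    which: str = "epi",
    three_parameter: bool = False,
    max_iter: int = 10000,
) -> TrendFit:
    """Nonlinear least squares of E = exp(a*t) + b with a < 0.

    Initialized at a = -0.1, b = min observed entropy. A constant series has
    no identifiable rate (a drifts to -inf); it is guarded and returned as the
    degenerate fit b = mean with ``degenerate=True``. With
    ``three_parameter=True`` the amplitude is also free: A*exp(a*t) + b.
    """
    t, y = series.values(which)
    if t.size < 3:
        raise ValueError("exponential fit requires at least 3 points")
    if np.ptp(y) < 1e-12:
        b = float(y.mean())
        return TrendFit(kind="exponential", params=(float("nan"), b),
                        mse=float(np.mean((y - b) ** 2)), degenerate=True)
    try:
        if three_parameter:
            popt, _ = curve_fit(
                lambda tt, amp, a, b: amp * np.exp(a * tt) + b,
                t, y, p0=(1.0, -0.1, float(y.min())),
                bounds=([0.0, -np.inf, -np.inf], [np.inf, 0.0, np.inf]),
                maxfev=max_iter,
            )
        else:
            popt, _ = curve_fit(
                lambda tt, a, b: np.exp(a * tt) + b,
                t, y, p0=(-0.1, float(y.min())),
                bounds=([-np.inf, -np.inf], [0.0, np.inf]),
                maxfev=max_iter,
            )
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    params = tuple(float(p) for p in popt)
    if three_parameter:
        amp, a, b = params
        resid = y - (amp * np.exp(a * t) + b)
    else:
        a, b = params
        resid = y - (np.exp(a * t) + b)
    return TrendFit(kind="exponential", params=params, mse=float(np.mean(resid**2)))
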