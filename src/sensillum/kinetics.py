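"""Cumulative PSTH construction and sigmoid kinetics fitting.

Spikes of the first second after each response onset are binned in 10 ms
bins and summed across all stimulations of an animal.  The cumulative
histogram is fitted with

    AP(t) = ap_max / (1 + exp((t - t_half) / k)),   k < 0,

whose parameters quantify the response kinetics: ap_max is the cumulative
spike count within the horizon, t_half the midpoint time, and k the slope
factor (negative for a rising curve; magnitudes closer to zero mean steeper
kinetics).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["CumulativePsth", "SigmoidFit", "build_cumulative_psth", "fit_response_sigmoid", "sigmoid"]


@dataclasses.dataclass
class CumulativePsth:
    bin_edges: np.ndarray  # length n_bins + 1, seconds relative to onset
    counts: np.ndarray  # per-bin spike counts summed across stimulations
    cumulative: np.ndarray  # running sum of counts
    n_stimulations: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclasses.dataclass
class SigmoidFit:
    ap_max: float
    t_half: float  # s
    k: float  # s, negative
    rss: float
    converged: bool

    @property
    def abs_k(self) -> float:
        """Slope-factor magnitude, the quantity summarized in group tests."""
        return abs(self.k)


def sigmoid(t: np.ndarray, ap_max: float, t_half: float, k: float) -> np.ndarray:
    return ap_max / (1.0 + np.exp(np.clip((t - t_half) / k, -500.0, 500.0)))


def build_cumulative_psth(
    spike_trains: Sequence[np.ndarray],
    onsets: Sequence[float],
    bin_width: float = 0.01,
    horizon: float = 1.0,
) -> CumulativePsth:
    """Bin spikes relative to each onset and accumulate across stimulations.

    ``spike_trains`` and ``onsets`` are aligned 1:1 (one train per stimulus;
    a single recording-wide train may be repeated).  ``bin_width`` must
    divide ``horizon``; defaults give 100 bins of 10 ms over the first
    second.
    """
    if len(spike_trains) != len(onsets):
        raise ValueError(
            f"got {len(spike_trains)} spike trains for {len(onsets)} onsets"
        )
    n_bins = horizon / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide horizon {horizon}")
    n_bins = int(round(n_bins))
    edges = np.linspace(0.0, horizon, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    for train, onset in zip(spike_trains, onsets):
        rel = np.asarray(train, dtype=float) - onset
        rel = rel[(rel >= 0.0) & (rel < horizon)]
        counts += np.histogram(rel, bins=edges)[0]
    return CumulativePsth(
        bin_edges=edges,
        counts=counts,
        cumulative=np.cumsum(counts),
        n_stimulations=len(onsets),
    )


def _initial_guess(t: np.ndarray, y: np.ndarray, bin_width: float) -> tuple[float, float, float]:
    ap0 = float(y[-1])
    half = np.flatnonzero(y >= ap0 / 2.0)
    t_half0 = float(t[half[0]]) if half.size else float(t[len(t) // 2])
    q25 = np.flatnonzero(y >= 0.25 * ap0)
    q75 = np.flatnonzero(y >= 0.75 * ap0)
    spread = float(t[q75[0]] - t[q25[0]]) if q25.size and q75.size else 0.0
    k0 = -max(spread / 2.2, bin_width / 2.0)
    return ap0, t_half0, k0


def fit_response_sigmoid(cp: CumulativePsth, k_max: float = -1e-6) -> SigmoidFit:
    """Unweighted nonlinear least squares of the sigmoid to the cumulative PSTH.

    k is constrained negative so the fitted curve is non-decreasing.  The
    initialization is deterministic (asymptote, first half-crossing bin,
    quartile-spread slope), so identical inputs give identical fits.  Raises
    on an all-zero cumulative; non-convergence is reported via
    ``converged=False``, never by a silent fallback.
    """
    y = np.asarray(cp.cumulative, dtype=float)
    if y[-1] <= 0:
        raise ValueError("cannot fit an all-zero cumulative PSTH")
    t = cp.bin_centers
    bin_width = float(cp.bin_edges[1] - cp.bin_edges[0])
    ap0, t_half0, k0 = _initial_guess(t, y, bin_width)

    lo = np.array([1e-9, 0.0, -np.inf])
    hi = np.array([np.inf, 10.0 * float(cp.bin_edges[-1]), k_max])
    x0 = np.array([max(ap0, 1e-9), min(max(t_half0, lo[1]), hi[1]), min(k0, k_max)])

    def residuals(p):
        return sigmoid(t, *p) - y

    res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    rss = float(np.sum(res.fun**2))
    return SigmoidFit(
        ap_max=float(res.x[0]),
        t_half=float(res.x[1]),
        k=float(res.x[2]),
        rss=rss,
        converged=bool(res.success and np.isfinite(rss)),
    )
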