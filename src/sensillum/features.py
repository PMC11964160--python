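"""Spike detection and per-stimulus response parameterization.

Spikes are detected by a threshold search on the AC trace; the DC trace
yields the response onset (start of the negative sensillum-potential
deflection) and the sensillum potential amplitude (SPA).  Five parameters
are computed per stimulus: latency of the first spike relative to the
response onset, average instantaneous frequency of the first six spikes
(F_6AP), SPA, the spike count in a configurable early window (1 s, or
100 ms for paired-toxin protocols), and the late long-lasting response
count from 5 s after the stimulus to the next stimulus.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .sigio import Recording

__all__ = [
    "SpikeTrain",
    "ResponseFeatures",
    "detect_spikes",
    "detect_response_onset",
    "compute_response_features",
    "compute_llpr_count",
    "extract_features",
]


@dataclasses.dataclass
class SpikeTrain:
    """Detected spike times (seconds, strictly increasing)."""

    spike_times: np.ndarray
    threshold_used: float
    polarity: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike_times must be strictly increasing")

    def between(self, start: float, stop: float) -> np.ndarray:
        """Spikes with start <= t < stop."""
        return self.spike_times[
            (self.spike_times >= start) & (self.spike_times < stop)
        ]


@dataclasses.dataclass
class ResponseFeatures:
    """The five per-stimulus response parameters (missing values are NaN)."""

    response_onset: float  # s, NaN if no response detected
    latency: float  # ms
    f6ap: float  # Hz; NaN when <6 spikes in the first second
    spa: float  # mV, non-negative magnitude
    n_aps_early: float  # count; NaN when onset missing
    n_aps_llpr: float = math.nan  # filled by extract_features


def _mad_sd(x: np.ndarray) -> float:
    """Robust noise SD estimate from the median absolute deviation."""
    med = np.median(x)
    return float(np.median(np.abs(x - med)) / 0.6745)


def detect_spikes(
    ac: np.ndarray,
    sampling_rate: float,
    threshold: float | str = "auto",
    refractory: float = 0.001,
    polarity: str | None = None,
    auto_factor: float = 5.0,
) -> SpikeTrain:
    """Threshold search on the AC trace.

    One spike is reported per supra-threshold excursion, timestamped at the
    excursion extremum; extrema within ``refractory`` of an accepted spike
    are suppressed.  With ``threshold="auto"`` the threshold is
    ``auto_factor`` (default 5.0) times a MAD-based noise SD (robust to the
    spikes themselves) and the dominant polarity is chosen as the side with
    more (then larger) excursions.
    """
    ac = np.asarray(ac, dtype=np.float64)
    if refractory < 0:
        raise ValueError("refractory must be >= 0")
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        sd = _mad_sd(ac)
        if sd == 0:
            # noise-free trace: MAD vanishes when spikes are sparse; fall
            # back to the plain SD, which is nonzero as soon as anything is
            sd = float(np.std(ac)) / auto_factor
        if sd == 0:
            raise ValueError("cannot estimate noise: trace is constant")
        thr = auto_factor * sd
    else:
        thr = float(threshold)
        if thr <= 0:
            raise ValueError(f"threshold must be positive, got {thr}")

    if polarity is None:
        # count excursions at 1.5x threshold so secondary (half-amplitude)
        # lobes of the biphasic waveform do not sway the polarity vote
        pos = _excursion_extrema(ac, 1.5 * thr)
        neg = _excursion_extrema(-ac, 1.5 * thr)
        if len(pos) != len(neg):
            polarity = "positive" if len(pos) > len(neg) else "negative"
        else:
            polarity = "positive" if ac.max() >= -ac.min() else "negative"
    x = ac if polarity == "positive" else -ac

    idx = _excursion_extrema(x, thr)
    times = np.asarray(idx, dtype=float) / sampling_rate
    if refractory > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory:
                kept.append(t)
        times = np.asarray(kept)
    return SpikeTrain(spike_times=times, threshold_used=thr, polarity=polarity)


def _excursion_extrema(x: np.ndarray, thr: float) -> list[int]:
    """Index of the maximum of every contiguous supra-threshold excursion."""
    above = np.flatnonzero(x > thr)
    if above.size == 0:
        return []
    splits = np.flatnonzero(np.diff(above) > 1) + 1
    return [int(run[np.argmax(x[run])]) for run in np.split(above, splits)]


def detect_response_onset(
    dc: np.ndarray,
    stimulus_onset: float,
    sampling_rate: float,
    baseline_window: float = 0.5,
    search_window: float = 0.2,
    k_sd: float = 3.0,
    sustain: float = 0.002,
) -> float | None:
    """Earliest sustained negative DC departure from the pre-stimulus baseline.

    Baseline mean and SD are taken over ``baseline_window`` s before the
    stimulus; the onset is the first sample within ``search_window`` s after
    the stimulus that falls below baseline − ``k_sd``·SD and stays below for
    at least ``sustain`` s.  Invariant to constant offsets.  Returns None
    when no such departure exists (no-response).
    """
    dc = np.asarray(dc, dtype=np.float64)
    i_stim = int(round(stimulus_onset * sampling_rate))
    i_base = max(i_stim - int(round(baseline_window * sampling_rate)), 0)
    if i_base >= i_stim:
        raise ValueError("no baseline window before stimulus_onset")
    i_end = i_stim + int(round(search_window * sampling_rate))
    n_sustain = max(int(round(sustain * sampling_rate)), 1)
    if i_end + n_sustain > dc.size:
        raise ValueError("search window extends past the end of the recording")

    base = dc[i_base:i_stim]
    # median/MAD: spikes riding on the baseline must not move the threshold
    level = float(np.median(base))
    sd = _mad_sd(base)
    thr = level - max(k_sd * sd, 1e-6)

    below = (dc[i_stim : i_end + n_sustain] < thr).astype(np.int64)
    # sustained: n_sustain consecutive below-threshold samples starting at j
    csum = np.concatenate([[0], np.cumsum(below)])
    runsum = csum[n_sustain:] - csum[:-n_sustain]
    hits = np.flatnonzero(runsum[: i_end - i_stim] == n_sustain)
    if hits.size == 0:
        return None
    return (i_stim + int(hits[0])) / sampling_rate


def _spa(
    dc: np.ndarray,
    sampling_rate: float,
    stimulus_onset: float,
    response_onset: float,
    baseline_window: float,
    spa_window: float,
    smooth: float = 0.005,
) -> float:
    """Baseline-to-trough magnitude of the DC deflection, spike-suppressed.

    A running median (``smooth`` s) removes the riding spike waveforms
    before taking the post-onset minimum.
    """
    i_stim = int(round(stimulus_onset * sampling_rate))
    i_base = max(i_stim - int(round(baseline_window * sampling_rate)), 0)
    i_on = int(round(response_onset * sampling_rate))
    i_end = min(i_on + int(round(spa_window * sampling_rate)), dc.size)
    baseline = float(np.mean(dc[i_base:i_stim]))
    k = int(round(smooth * sampling_rate)) | 1  # odd kernel
    seg = ndimage.median_filter(dc[i_on:i_end], size=k, mode="nearest")
    return max(baseline - float(seg.min()), 0.0)


def compute_response_features(
    spikes: SpikeTrain,
    dc: np.ndarray,
    sampling_rate: float,
    stimulus_onset: float,
    response_onset: float | None,
    early_window: float = 1.0,
    baseline_window: float = 0.5,
    spa_window: float = 1.0,
    f6ap_method: str = "mean_reciprocal_isi",
) -> ResponseFeatures:
    """Latency, F_6AP, SPA and the early spike count for one stimulus.

    ``f6ap_method`` selects between the mean of the five reciprocal ISIs of
    the first six spikes (default) and the reciprocal of their mean ISI
    (``"reciprocal_mean_isi"``).  F_6AP is missing whenever fewer than six
    spikes fall within the first second after the response onset.  All
    features are missing when ``response_onset`` is None.
    """
    if early_window <= 0 or baseline_window <= 0 or spa_window <= 0:
        raise ValueError("windows must be positive")
    if f6ap_method not in ("mean_reciprocal_isi", "reciprocal_mean_isi"):
        raise ValueError(f"unknown f6ap_method {f6ap_method!r}")
    if response_onset is None:
        return ResponseFeatures(math.nan, math.nan, math.nan, math.nan, math.nan)

    first_second = spikes.between(response_onset, response_onset + 1.0)
    latency = (
        (first_second[0] - response_onset) * 1000.0 if first_second.size else math.nan
    )
    if first_second.size >= 6:
        isis = np.diff(first_second[:6])
        if f6ap_method == "mean_reciprocal_isi":
            f6ap = float(np.mean(1.0 / isis))
        else:
            f6ap = float(1.0 / np.mean(isis))
    else:
        f6ap = math.nan

    spa = _spa(
        np.asarray(dc, dtype=np.float64), sampling_rate, stimulus_onset,
        response_onset, baseline_window, spa_window,
    )
    n_early = int(spikes.between(response_onset, response_onset + early_window).size)
    return ResponseFeatures(response_onset, latency, f6ap, spa, float(n_early))


def compute_llpr_count(
    spikes: SpikeTrain,
    stimulus_onset: float,
    next_stimulus_onset: float,
    exclusion: float = 5.0,
) -> int:
    """Spike count in [stimulus + exclusion, next stimulus).

    At the protocol defaults (5 min interval, 5 s exclusion) this is the
    count over the 295 s preceding the next stimulus.
    """
    if next_stimulus_onset <= stimulus_onset + exclusion:
        raise ValueError(
            "next_stimulus_onset must exceed stimulus_onset + exclusion "
            f"({stimulus_onset + exclusion:g} s)"
        )
    return int(spikes.between(stimulus_onset + exclusion, next_stimulus_onset).size)


def extract_features(
    rec: Recording,
    early_window: float = 1.0,
    threshold: float | str = "auto",
    refractory: float = 0.001,
    llpr_exclusion: float = 5.0,
    f6ap_method: str = "mean_reciprocal_isi",
    onset_params: dict | None = None,
) -> pd.DataFrame:
    """Per-stimulus feature table for a whole recording.

    Detects spikes once over the full AC trace, then per stimulus finds the
    DC response onset and computes the five parameters.  The LLPR window of
    the last stimulus ends at the end of the recording.  Trials without a
    detectable response keep their row with missing cells.
    """
    spikes = detect_spikes(rec.ac, rec.sampling_rate, threshold, refractory)
    onsets = rec.stimulus_onsets
    rows = []
    for i, stim in enumerate(onsets):
        next_stim = onsets[i + 1] if i + 1 < len(onsets) else rec.duration
        try:
            response_onset = detect_response_onset(
                rec.dc, stim, rec.sampling_rate, **(onset_params or {})
            )
        except ValueError:
            response_onset = None
        feats = compute_response_features(
            spikes, rec.dc, rec.sampling_rate, stim, response_onset,
            early_window=early_window, f6ap_method=f6ap_method,
        )
        if next_stim > stim + llpr_exclusion:
            n_llpr = compute_llpr_count(spikes, stim, next_stim, llpr_exclusion)
        else:
            n_llpr = math.nan
        rows.append(
            dict(
                experiment_id=rec.meta.get("animal_id", ""),
                stimulation_time=stim / 60.0,
                response_onset=feats.response_onset,
                latency=feats.latency,
                f6ap=feats.f6ap,
                spa=feats.spa,
                n_aps_early=feats.n_aps_early,
                n_aps_llpr=n_llpr,
            )
        )
    return pd.DataFrame(rows)
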