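"""Synthetic tip-recordings and qPCR tables with known ground truth.

The simulator renders the three-component spiking response of a
pheromone-sensitive ORN — a near-regular high-frequency phasic burst, a
variable-rate tonic component, a pause, and a late long-lasting response —
together with a negative DC sensillum-potential deflection, onto a
dual-channel (DC + AC) recording at 20 kHz.  Ground truth is reported per
stimulus from the *realized* spike times, so downstream feature extraction
can be checked sample-exactly.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sigio import Recording

__all__ = [
    "GroundTruthParams",
    "CohortDesign",
    "SimulatedRecording",
    "generate_recording",
    "generate_cohort",
    "generate_qpcr_dataset",
]

#: minimal separation between rendered spikes; closer events are thinned
#: so every rendered waveform corresponds to exactly one detectable spike
ABS_REFRACTORY = 0.003

#: drift keys accepted in GroundTruthParams.drift
DRIFTABLE = ("f6ap", "latency", "spa", "tonic_rate", "llpr_rate")


@dataclasses.dataclass
class GroundTruthParams:
    """True response parameters driving the simulator.

    Rates are in Hz, durations in seconds, ``latency_true`` in milliseconds,
    ``spa_true`` (magnitude of the negative DC deflection) in millivolts.
    ``drift`` maps a parameter name (one of ``f6ap``, ``latency``, ``spa``,
    ``tonic_rate``, ``llpr_rate``) to a slope in parameter-units per minute
    of recording time.  ``phasic_shape`` is the gamma-renewal shape of the
    phasic burst; ``math.inf`` (default) renders perfectly regular ISIs.
    """

    n_phasic: int = 10
    f_phasic: float = 150.0
    tonic_rate: float = 40.0
    tonic_duration: float = 0.5
    pause_duration: float = 2.0
    llpr_rate: float = 1.0
    llpr_duration: float = 120.0
    spa_true: float = 5.0
    latency_true: float = 20.0
    drift: dict = dataclasses.field(default_factory=dict)
    spontaneous_rate: float = 0.1
    noise_sd: float = 0.05
    phasic_shape: float = math.inf
    spike_amplitude: float = 1.0
    response_delay: float = 0.02  # DC deflection onset after valve opening, s

    def __post_init__(self) -> None:
        for name in ("f_phasic", "tonic_rate", "llpr_rate", "spontaneous_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_phasic < 0:
            raise ValueError("n_phasic must be >= 0")
        for name in ("tonic_duration", "pause_duration", "llpr_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.drift) - set(DRIFTABLE)
        if unknown:
            raise ValueError(f"unknown drift keys {sorted(unknown)}; allowed: {DRIFTABLE}")


@dataclasses.dataclass
class CohortDesign:
    """Stimulation schedule and group layout of a simulated experiment."""

    groups: Sequence[tuple[str, str, int]] = ()
    stimulus_interval: float = 300.0
    stimulus_duration: float = 0.05
    recording_duration: float = 120.0  # minutes
    first_stimulus: float = 0.0  # s; schedule onsets at first + k*interval
    paired: bool = False
    paired_n_stimuli: tuple[int, int] = (3, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        for label, zt, n in self.groups:
            if n < 1:
                raise ValueError(f"group ({label}, {zt}) must have n_animals >= 1")
        if not self.stimulus_interval > self.stimulus_duration:
            raise ValueError("stimulus_interval must exceed stimulus_duration")
        if not self.recording_duration > 0:
            raise ValueError("recording_duration must be positive")

    def stimulus_onsets(self) -> np.ndarray:
        """Scheduled onsets in seconds: 0, interval, 2·interval, …"""
        total = self.recording_duration * 60.0
        n = int(math.ceil(total / self.stimulus_interval))
        onsets = self.first_stimulus + np.arange(n) * self.stimulus_interval
        return onsets[onsets < total]


@dataclasses.dataclass
class SimulatedRecording:
    """A rendered recording plus its realized ground truth."""

    recording: Recording
    truth: pd.DataFrame  # one row per stimulus
    spike_times: np.ndarray  # every rendered spike, seconds


# ---------------------------------------------------------------------------
# waveform primitives


def spike_template(sampling_rate: float, amplitude: float = 1.0) -> tuple[np.ndarray, int]:
    """Stereotyped biphasic extracellular spike, ~2 ms.

    Positive lobe (1 ms) followed by a half-amplitude negative lobe (1 ms).
    Returns (template, index of the positive extremum).
    """
    n = max(int(round(0.002 * sampling_rate)), 4)
    half = n // 2
    t1 = np.sin(np.linspace(0, np.pi, half, endpoint=False))
    t2 = -0.5 * np.sin(np.linspace(0, np.pi, n - half, endpoint=False))
    template = amplitude * np.concatenate([t1, t2])
    peak = int(np.argmax(template))
    return template, peak


def _dc_deflection(t: np.ndarray, spa: float, tau_fast: float = 0.01, tau_slow: float = 0.5) -> np.ndarray:
    """Difference-of-exponentials deflection reaching exactly -spa."""
    t_star = math.log(tau_slow / tau_fast) / (1.0 / tau_fast - 1.0 / tau_slow)
    norm = math.exp(-t_star / tau_slow) - math.exp(-t_star / tau_fast)
    shape = np.exp(-t / tau_slow) - np.exp(-t / tau_fast)
    return -(spa / norm) * shape


def _gamma_renewal_isis(rng, n: int, rate: float, shape: float) -> np.ndarray:
    """ISIs of a gamma-renewal process with mean 1/rate; inf shape = regular."""
    if n <= 0 or rate <= 0:
        return np.empty(0)
    if math.isinf(shape):
        return np.full(n, 1.0 / rate)
    return rng.gamma(shape, 1.0 / (shape * rate), size=n)


def _poisson_times(rng, rate: float, start: float, stop: float) -> np.ndarray:
    if rate <= 0 or stop <= start:
        return np.empty(0)
    n = rng.poisson(rate * (stop - start))
    return np.sort(rng.uniform(start, stop, size=n))


def _thin(times: np.ndarray, min_isi: float = ABS_REFRACTORY) -> np.ndarray:
    """Drop events closer than ``min_isi`` to the previously accepted one."""
    if times.size == 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= min_isi:
            keep.append(t)
    return np.asarray(keep)


# ---------------------------------------------------------------------------
# recording synthesis


def _drifted(base: float, key: str, drift: Mapping[str, float], t_min: float) -> tuple[float, bool]:
    """Parameter value at recording time t_min; clamped at 0 where negative."""
    value = base + drift.get(key, 0.0) * t_min
    if value < 0:
        return 0.0, True
    return value, False


def generate_recording(
    gt: GroundTruthParams,
    design: CohortDesign,
    seed: int,
    sampling_rate: float = 20_000.0,
    meta: dict | None = None,
    stimulus_onsets: np.ndarray | None = None,
) -> SimulatedRecording:
    """Render one dual-channel recording and its realized ground truth.

    The AC channel carries the spike waveforms plus noise; the DC channel
    additionally carries the negative sensillum-potential deflection.  The
    per-stimulus truth table reports feature values computed from the spike
    times actually rendered (after sub-refractory thinning and clamping), so
    extraction can be validated exactly.  Identical (gt, design, seed) give
    bit-identical output.
    """
    if not sampling_rate > 0:
        raise ValueError(f"sampling_rate must be positive, got {sampling_rate}")
    rng = np.random.default_rng(seed)
    onsets = design.stimulus_onsets() if stimulus_onsets is None else np.asarray(stimulus_onsets, float)
    duration = design.recording_duration * 60.0
    n_samples = int(round(duration * sampling_rate))
    dt = 1.0 / sampling_rate

    all_spikes: list[np.ndarray] = []
    epochs = []  # (onset, response_onset, latency_ms, spa, clamped)

    # spontaneous background over the whole recording
    all_spikes.append(_poisson_times(rng, gt.spontaneous_rate, 0.0, duration))

    for stim in onsets:
        t_min = stim / 60.0
        f_phasic, clamp_f = _drifted(gt.f_phasic, "f6ap", gt.drift, t_min)
        latency_ms, clamp_lat = _drifted(gt.latency_true, "latency", gt.drift, t_min)
        spa, clamp_spa = _drifted(gt.spa_true, "spa", gt.drift, t_min)
        tonic_rate, clamp_ton = _drifted(gt.tonic_rate, "tonic_rate", gt.drift, t_min)
        llpr_rate, clamp_llpr = _drifted(gt.llpr_rate, "llpr_rate", gt.drift, t_min)
        clamped = clamp_f or clamp_lat or clamp_spa or clamp_ton or clamp_llpr

        response_onset = stim + gt.response_delay
        first_spike = response_onset + latency_ms / 1000.0

        # phasic burst: near-regular gamma renewal at f_phasic
        if gt.n_phasic > 0 and f_phasic > 0:
            isis = _gamma_renewal_isis(rng, gt.n_phasic - 1, f_phasic, gt.phasic_shape)
            phasic = first_spike + np.concatenate([[0.0], np.cumsum(isis)])
        elif gt.n_phasic > 0:
            phasic = np.array([first_spike])
        else:
            phasic = np.empty(0)
        phasic_end = phasic[-1] if phasic.size else first_spike

        # tonic: homogeneous Poisson, lower and more variable
        tonic_start = phasic_end + (1.0 / f_phasic if f_phasic > 0 else 0.01)
        tonic = _poisson_times(rng, tonic_rate, tonic_start, tonic_start + gt.tonic_duration)

        # pause, then LLPR until the next stimulus
        llpr_start = tonic_start + gt.tonic_duration + gt.pause_duration
        llpr_stop = min(llpr_start + gt.llpr_duration, stim + _epoch_end(onsets, stim, duration))
        llpr = _poisson_times(rng, llpr_rate, llpr_start, min(llpr_stop, duration))

        all_spikes.extend([phasic, tonic, llpr])
        epochs.append((stim, response_onset, latency_ms, spa, clamped))

    spikes = np.sort(np.concatenate(all_spikes))
    spikes = _thin(spikes)
    # snap to the sample grid: rendered == reported ground truth
    spikes = np.round(spikes * sampling_rate) / sampling_rate
    spikes = _thin(spikes, min_isi=ABS_REFRACTORY - dt / 2)
    spikes = spikes[(spikes >= 0) & (spikes < duration - 0.002)]

    ac = np.zeros(n_samples)
    template, peak = spike_template(sampling_rate, gt.spike_amplitude)
    for t in spikes:
        idx = int(round(t * sampling_rate)) - peak
        lo, hi = max(idx, 0), min(idx + template.size, n_samples)
        ac[lo:hi] += template[lo - idx : hi - idx]

    dc = ac.copy()
    tail = int(round(min(5.0, duration) * sampling_rate))
    for stim, response_onset, _, spa, _ in epochs:
        if spa <= 0:
            continue
        i0 = int(round(response_onset * sampling_rate))
        i1 = min(i0 + int(round(4.0 * sampling_rate)), n_samples)  # 4 s render window
        if i0 >= n_samples:
            continue
        t_rel = (np.arange(i0, i1) - i0) * dt
        dc[i0:i1] += _dc_deflection(t_rel, spa)

    if gt.noise_sd > 0:
        ac = ac + rng.normal(0.0, gt.noise_sd, n_samples)
        dc = dc + rng.normal(0.0, gt.noise_sd, n_samples)

    rec = Recording(
        dc=dc, ac=ac, sampling_rate=sampling_rate, stimulus_onsets=onsets,
        meta=dict(meta or {}, stimulus_duration=design.stimulus_duration),
    )
    truth = _truth_table(spikes, epochs, onsets, duration, design)
    return SimulatedRecording(recording=rec, truth=truth, spike_times=spikes)


def _epoch_end(onsets: np.ndarray, stim: float, duration: float) -> float:
    later = onsets[onsets > stim]
    return (later[0] - stim) if later.size else (duration - stim)


def _truth_table(
    spikes: np.ndarray,
    epochs: list,
    onsets: np.ndarray,
    duration: float,
    design: CohortDesign,
    llpr_exclusion: float = 5.0,
) -> pd.DataFrame:
    rows = []
    for i, (stim, response_onset, latency_ms, spa, clamped) in enumerate(epochs):
        next_onset = onsets[i + 1] if i + 1 < len(onsets) else duration
        resp = spikes[(spikes >= response_onset) & (spikes < response_onset + 1.0)]
        latency = (resp[0] - response_onset) * 1000.0 if resp.size else np.nan
        if resp.size >= 6:
            f6ap = float(np.mean(1.0 / np.diff(resp[:6])))
        else:
            f6ap = np.nan
        n_1s = int(resp.size)
        n_100ms = int(np.count_nonzero(resp < response_onset + 0.1))
        lo, hi = stim + llpr_exclusion, next_onset
        n_llpr = int(np.count_nonzero((spikes >= lo) & (spikes < hi))) if hi > lo else 0
        rows.append(
            dict(
                stimulation_time=stim / 60.0,
                response_onset=response_onset,
                latency=latency,
                f6ap=f6ap,
                spa=spa,
                n_aps_1s=n_1s,
                n_aps_100ms=n_100ms,
                n_aps_llpr=n_llpr,
                clamped=clamped,
            )
        )
    return pd.DataFrame(rows)


def generate_cohort(
    design: CohortDesign,
    gt_by_group: Mapping[tuple[str, str] | str, GroundTruthParams],
    seed: int,
    sampling_rate: float = 20_000.0,
    paired_control: GroundTruthParams | None = None,
) -> tuple[list[SimulatedRecording], pd.DataFrame]:
    """Simulate one recording per animal (two when paired) across groups.

    ``gt_by_group`` is keyed by ``(condition, zt)`` tuples (or the condition
    label alone).  For a paired design each animal gets a day-1 control
    recording with ``paired_control`` parameters and the scheduled number of
    control stimuli, and a day-2 recording under the group's parameters.
    Returns the recordings and a concatenated ground-truth table with
    ``animal_id``, ``condition``, ``zt``, ``day`` columns and the per-animal
    true drift slopes.
    """
    recs: list[SimulatedRecording] = []
    frames = []
    root = np.random.default_rng(seed)
    for condition, zt, n_animals in design.groups:
        gt = gt_by_group.get((condition, zt), gt_by_group.get(condition))
        if gt is None:
            raise KeyError(f"no ground-truth parameters for group ({condition!r}, {zt!r})")
        for a in range(n_animals):
            animal_id = f"{condition}_{zt}_{a:02d}"
            if design.paired:
                if paired_control is None:
                    raise ValueError("paired design requires paired_control parameters")
                n_ctrl, n_tox = design.paired_n_stimuli
                for day, (params, n_stim, cond_label) in enumerate(
                    [(paired_control, n_ctrl, "ctrl"), (gt, n_tox, condition)], start=1
                ):
                    onsets = design.first_stimulus + np.arange(n_stim) * design.stimulus_interval
                    day_design = dataclasses.replace(
                        design,
                        recording_duration=(design.first_stimulus + n_stim * design.stimulus_interval) / 60.0,
                        paired=False,
                    )
                    sim = generate_recording(
                        params, day_design, seed=int(root.integers(2**31)),
                        sampling_rate=sampling_rate,
                        meta=dict(animal_id=animal_id, condition=cond_label, zt_window=zt, day=day),
                        stimulus_onsets=onsets,
                    )
                    recs.append(sim)
                    frames.append(_label(sim.truth, animal_id, cond_label, zt, day, params))
            else:
                sim = generate_recording(
                    gt, design, seed=int(root.integers(2**31)),
                    sampling_rate=sampling_rate,
                    meta=dict(animal_id=animal_id, condition=condition, zt_window=zt, day=1),
                )
                recs.append(sim)
                frames.append(_label(sim.truth, animal_id, condition, zt, 1, gt))
    truth = pd.concat(frames, ignore_index=True)
    return recs, truth


def _label(truth: pd.DataFrame, animal_id, condition, zt, day, gt: GroundTruthParams) -> pd.DataFrame:
    out = truth.copy()
    out.insert(0, "animal_id", animal_id)
    out.insert(1, "condition", condition)
    out.insert(2, "zt", zt)
    out.insert(3, "day", day)
    for key in DRIFTABLE:
        out[f"true_drift_{key}"] = gt.drift.get(key, 0.0)
    return out


# ---------------------------------------------------------------------------
# qPCR synthesis


def generate_qpcr_dataset(
    genes: Sequence[str],
    zts: Sequence[str],
    fold_changes: Mapping,
    sigma_ct: float,
    seed: int,
    n_biological: int = 3,
    n_technical: int = 3,
    reference_genes: Sequence[str] = ("RPS13", "G3PDH"),
    base_ct_target: float = 25.0,
    base_ct_reference: float = 20.0,
) -> pd.DataFrame:
    """Simulate a Ct table (gene × ZT × biological × technical).

    ``fold_changes`` maps ``(gene, zt)`` → true fold change relative to the
    first ZT in ``zts`` (missing entries default to 1).  Reference genes are
    generated flat (fold 1) across ZT.  A fold change f shifts the target Ct
    by −log2(f); technical noise is N(0, sigma_ct).
    """
    if sigma_ct < 0:
        raise ValueError("sigma_ct must be >= 0")
    for key, fold in dict(fold_changes).items():
        if not fold > 0:
            raise ValueError(f"fold change for {key} must be positive, got {fold}")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in list(genes) + [g for g in reference_genes if g not in genes]:
        is_ref = gene in reference_genes
        base = base_ct_reference if is_ref else base_ct_target
        for zt in zts:
            fold = 1.0 if is_ref else float(fold_changes.get((gene, zt), 1.0))
            ct_mean = base - math.log2(fold)
            for b in range(1, n_biological + 1):
                for t in range(1, n_technical + 1):
                    ct = ct_mean + (rng.normal(0.0, sigma_ct) if sigma_ct > 0 else 0.0)
                    rows.append(
                        dict(gene=gene, zt=zt, biological_replicate=b,
                             technical_replicate=t, ct=ct)
                    )
    return pd.DataFrame(rows)
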