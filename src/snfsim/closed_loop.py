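"""Closed-loop stimulation endpoint simulation.

Couples the synthetic LFP generator, the real-time detector and a
stochastic seizure-state model into per-arm session endpoints. Ictal
onsets arrive as a Poisson process; once ictal, the state terminates with
a hazard

    h(t) = base_hazard * multiplier(dose_active(t))

where the dose is the fraction of the hippocampal target covered at the
100 mV/mm field threshold by the active arm (summed over stimulated
hemispheres, union over the SNF sequence) and is non-zero only while a
stimulus train is on. ``multiplier(dose) = 1 + beta * dose`` by default;
randomizing the SNF firing order multiplies the effective dose by a
sequence-coherence factor < 1 (an unorchestrated field does not summate).

Detection — not the oracle state — gates stimulation: each event's onset
is rendered as synthetic LFP and passed through the detector to obtain the
trigger latency; the scheduler then delivers 5 s trains (acute: repeated
with a 10 s non-stimulation interval while the event persists; chronic:
one train per event with a 100 s lockout), blanking the detector during
trains.

Endpoint definitions: termination success means the event ends within 10 s
of the first train onset; termination latency is first-train onset to
seizure offset; percent time in seizure is total ictal time over session
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from . import detection as det
from .records import IctalParams, LFPRecord
from .synthetic import CROSSFADE_S, generate_baseline, generate_ictal_segment

ARMS = ("non-stim", "WF", "LIWF", "SNF")

#: Default per-hemisphere coverage doses at the arm's current cap
#: (fraction of one hippocampus with |E| >= 100 mV/mm on the default
#: 0.25 mm geometry; WF/SNF at 650 uA, LIWF at its 140 uA safety cap).
DEFAULT_SIDE_DOSE = {"WF": 0.693, "LIWF": 0.091, "SNF": 0.543}

SUCCESS_WINDOW_S = 10.0
MAX_EVENT_S = 600.0


@dataclass
class SeizureStateModel:
    """Stochastic ictal-state dynamics and its response to stimulation."""

    onset_rate_per_h: float = 20.0
    base_termination_hazard: float = 1.0 / 30.0   # 1/s while ictal
    hazard_beta: float = 6.0                       # multiplier slope vs dose
    sequence_coherence_factor: float = 0.3         # random-order SNF penalty
    multiplier: Callable[[float], float] | None = None

    def stim_multiplier(self, dose: float) -> float:
        if self.multiplier is not None:
            return float(self.multiplier(dose)) if dose > 0 else 1.0
        return 1.0 + self.hazard_beta * dose


@dataclass
class ControllerConfig:
    mode: str = "acute"               # 'acute' | 'chronic'
    arm: str = "SNF"
    laterality: str = "bilateral"     # 'unilateral' | 'bilateral'
    snf_order: str = "ordered"        # 'ordered' | 'random'
    train_duration: float = 5.0       # s
    refractory: float = 10.0          # s (acute); chronic lockout is 100 s
    chronic_lockout: float = 100.0    # s

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        if self.mode not in ("acute", "chronic"):
            raise ValueError("mode must be 'acute' or 'chronic'")


@dataclass
class SessionEndpoints:
    termination_success_rate: float
    latencies: list[float]            # s, first train onset -> seizure offset
    pct_time_in_seizure: float
    n_events: int
    n_triggers: int
    segmented_success: list[float]    # per 20 min segment
    duration_s: float

    @property
    def median_latency(self) -> float | None:
        return float(np.median(self.latencies)) if self.latencies else None


def arm_dose(controller: ControllerConfig,
             side_dose: dict | None = None) -> float:
    """Effective dose for an arm: per-side coverage summed over stimulated
    hemispheres, with the sequence-coherence penalty applied separately."""
    side_dose = side_dose or DEFAULT_SIDE_DOSE
    if controller.arm == "non-stim":
        return 0.0
    per_side = side_dose[controller.arm]
    n_sides = 2 if controller.laterality == "bilateral" else 1
    return per_side * n_sides


# ---------------------------------------------------------------------------
# scheduler
# ---------------------------------------------------------------------------

def scheduler(trigger_times: Sequence[float],
              controller: ControllerConfig,
              event_windows: Sequence[tuple[float, float]] | None = None
              ) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Map triggers to stimulation trains and blanking windows.

    Acute: a 5 s train per trigger, re-triggering allowed only after a 10 s
    non-stimulation interval (trains repeat while triggers persist).
    Chronic: one train per event, then a 100 s lockout. Blanking equals the
    train intervals. ``event_windows`` (chronic) groups triggers by event;
    without it every trigger cluster separated by the lockout counts as a
    new event.
    """
    trains: list[tuple[float, float]] = []
    if controller.mode == "acute":
        next_allowed = -np.inf
        for t in sorted(trigger_times):
            if t >= next_allowed:
                trains.append((t, t + controller.train_duration))
                next_allowed = (t + controller.train_duration
                                + controller.refractory)
    else:
        last_train = -np.inf
        for t in sorted(trigger_times):
            if event_windows is not None:
                in_prev = any(a <= last_train and t <= b
                              for a, b in event_windows
                              if a <= t <= b)
                fresh = not in_prev
            else:
                fresh = True
            if t >= last_train + controller.train_duration \
                    + controller.chronic_lockout and fresh:
                trains.append((t, t + controller.train_duration))
                last_train = t
            elif not trains:
                trains.append((t, t + controller.train_duration))
                last_train = t
    return trains, list(trains)


# ---------------------------------------------------------------------------
# per-event machinery
# ---------------------------------------------------------------------------

def _detected_latency(rng: np.random.Generator, controller: ControllerConfig,
                      detector_config: det.DetectorConfig,
                      baseline: det.BaselineStats,
                      ictal_params: IctalParams,
                      spike_config: det.SpikeFeatureConfig,
                      fs: float, channel_labels,
                      pre_s: float = 2.0, ictal_s: float = 6.0
                      ) -> float | None:
    """Render one event onset and return detector latency (s), or None."""
    seed_b = int(rng.integers(2**31))
    seed_i = int(rng.integers(2**31))
    base = generate_baseline(pre_s + ictal_s, seed_b, fs=fs,
                             channel_labels=channel_labels)
    laterality = ("bilateral" if controller.laterality == "bilateral"
                  else "right")
    seg = generate_ictal_segment(ictal_s, ictal_params, seed_i, fs=fs,
                                 channel_labels=channel_labels,
                                 laterality=laterality)
    i0 = int(pre_s * fs)
    n_fade = int(CROSSFADE_S * fs)
    w = np.ones(seg.shape[1])
    w[:n_fade] = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
    samples = base.samples.copy()
    samples[:, i0:] = (1 - w) * samples[:, i0:] + w * seg
    rec = LFPRecord(samples, fs=fs, channel_labels=tuple(channel_labels))
    if controller.mode == "chronic":
        result = det.detect_chronic(rec, detector_config, spike_config,
                                    baseline=baseline)
    else:
        result = det.detect_acute(rec, detector_config, baseline)
    trig = [t for t in result.triggers if t >= pre_s]
    return (trig[0] - pre_s) if trig else None


def _hazard_segments(latency: float | None, controller: ControllerConfig,
                     hazard_on: float, hazard_off: float):
    """Yield (duration, hazard) pieces from ictal onset onward."""
    if latency is None or controller.arm == "non-stim":
        while True:
            yield (np.inf, hazard_off)
    yield (latency, hazard_off)
    if controller.mode == "acute":
        while True:
            yield (controller.train_duration, hazard_on)
            yield (controller.refractory, hazard_off)
    else:
        yield (controller.train_duration, hazard_on)
        while True:
            yield (np.inf, hazard_off)


def _sample_duration(rng: np.random.Generator, segments) -> float:
    """Invert the piecewise-constant cumulative hazard with one Exp(1) draw."""
    u = rng.exponential()
    t = 0.0
    for dur, h in segments:
        if h <= 0:
            if not np.isfinite(dur):
                return MAX_EVENT_S
            t += dur
            continue
        if u <= h * min(dur, MAX_EVENT_S):
            return min(t + u / h, MAX_EVENT_S)
        if not np.isfinite(dur):
            return MAX_EVENT_S
        u -= h * dur
        t += dur
        if t >= MAX_EVENT_S:
            return MAX_EVENT_S
    return min(t, MAX_EVENT_S)


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def run_session(
    state_model: SeizureStateModel,
    controller: ControllerConfig,
    detector_config: det.DetectorConfig | None = None,
    side_dose: dict | None = None,
    duration_s: float = 10_800.0,
    seed: int = 0,
    ictal_params: IctalParams | None = None,
    spike_config: det.SpikeFeatureConfig | None = None,
) -> tuple[SessionEndpoints, list[dict]]:
    """Simulate one closed-loop session; returns endpoints and event log.

    Each event's onset is rendered as multichannel LFP and detected (the
    detector, not the hidden state, gates stimulation); the termination
    time is then drawn from the piecewise-exponential hazard implied by the
    stimulation schedule. The event log carries onset, trigger, per-train
    intervals, offset and stim-on/off ictal exposure for every event.
    """
    detector_config = detector_config or det.DetectorConfig()
    spike_config = spike_config or det.SpikeFeatureConfig()
    ictal_params = ictal_params or IctalParams(band_gain=(3.0, 3.0, 3.0))
    rng = np.random.default_rng(seed)

    fs = 500.0
    channels = ("HPC-L", "HPC-R", "CTX-L", "CTX-R")
    base_rec = generate_baseline(detector_config.baseline_duration,
                                 int(rng.integers(2**31)), fs=fs,
                                 channel_labels=channels)
    baseline = det.compute_baseline(base_rec, detector_config,
                                    window=detector_config.baseline_duration)

    dose = arm_dose(controller, side_dose)
    if controller.arm == "SNF" and controller.snf_order == "random":
        dose *= state_model.sequence_coherence_factor
    mult = state_model.stim_multiplier(dose)
    h_off = state_model.base_termination_hazard
    h_on = h_off * mult

    log: list[dict] = []
    t = 0.0
    mean_gap = 3600.0 / state_model.onset_rate_per_h
    while True:
        t += rng.exponential(mean_gap)
        if t >= duration_s:
            break
        latency = _detected_latency(rng, controller, detector_config,
                                    baseline, ictal_params, spike_config,
                                    fs, channels)
        duration = _sample_duration(
            rng, _hazard_segments(latency, controller, h_on, h_off))
        duration = min(duration, duration_s - t)
        trains = []
        if latency is not None and controller.arm != "non-stim":
            trig = t + latency
            ts = latency
            while ts < duration:
                trains.append((t + ts, t + min(ts + controller.train_duration,
                                               duration)))
                if controller.mode == "chronic":
                    break
                ts += controller.train_duration + controller.refractory
        else:
            trig = None
        on_exposure = sum(b - a for a, b in trains)
        off_exposure = duration - on_exposure
        censored = duration >= MAX_EVENT_S or t + duration >= duration_s
        terminated_in_train = bool(
            trains and any(a <= t + duration <= b + 1e-9 for a, b in trains)
        ) and not censored
        first_train = trains[0][0] if trains else None
        success = (first_train is not None
                   and t + duration <= first_train + SUCCESS_WINDOW_S)
        log.append({
            "onset": float(t), "offset": float(t + duration),
            "duration": float(duration),
            "trigger": None if trig is None else float(trig),
            "latency": None if latency is None else float(latency),
            "trains": [(float(a), float(b)) for a, b in trains],
            "stim_on_exposure": float(on_exposure),
            "stim_off_exposure": float(off_exposure),
            "terminated_in_train": bool(terminated_in_train),
            "censored": bool(censored),
            "success": bool(success),
            "arm": controller.arm, "dose": float(dose),
        })
        t += duration
    endpoints = _endpoints_from_log(log, duration_s)
    return endpoints, log


def _endpoints_from_log(log: list[dict], duration_s: float) -> SessionEndpoints:
    ictal = sum(e["duration"] for e in log)
    lat = [e["offset"] - e["trains"][0][0] for e in log if e["trains"]]
    n_seg = max(1, int(np.ceil(duration_s / 1200.0)))
    seg_success = []
    for s in range(n_seg):
        evs = [e for e in log if s * 1200.0 <= e["onset"] < (s + 1) * 1200.0]
        seg_success.append(
            float(np.mean([e["success"] for e in evs])) if evs else np.nan)
    succ = float(np.mean([e["success"] for e in log])) if log else 0.0
    return SessionEndpoints(
        termination_success_rate=succ,
        latencies=lat,
        pct_time_in_seizure=100.0 * ictal / duration_s,
        n_events=len(log),
        n_triggers=sum(e["trigger"] is not None for e in log),
        segmented_success=seg_success,
        duration_s=duration_s,
    )


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def recover_hazard_multiplier(log: Sequence[dict]) -> float:
    """MLE of the stimulation hazard multiplier from an event log.

    The terminations-per-exposure-time ratio of the stim-on stratum to the
    stim-off stratum estimates ``multiplier(dose)`` (exponential-rate MLEs;
    both strata must have exposure and at least one termination each).
    """
    t_on = sum(e["stim_on_exposure"] for e in log)
    t_off = sum(e["stim_off_exposure"] for e in log)
    n_on = sum(e["terminated_in_train"] for e in log)
    n_off = sum((not e["terminated_in_train"]) and not e["censored"]
                for e in log)
    if t_on <= 0 or t_off <= 0 or n_on == 0 or n_off == 0:
        raise ValueError("a stratum has zero exposure or zero terminations")
    return (n_on / t_on) / (n_off / t_off)


def compare_arms(endpoint_sets: dict[str, Sequence[SessionEndpoints]]) -> dict:
    """Per-arm summaries plus standard nonparametric group tests.

    Reports median/IQR of percent time in seizure and mean success rate per
    arm, a Kruskal-Wallis test across arms and pairwise one-sided
    Mann-Whitney U tests on percent time in seizure.
    """
    for arm, eps in endpoint_sets.items():
        if len(eps) < 2:
            raise ValueError(f"arm {arm!r} needs >= 2 sessions")
    summary = {}
    pct = {}
    for arm, eps in endpoint_sets.items():
        p = np.array([e.pct_time_in_seizure for e in eps])
        lat = np.concatenate([e.latencies for e in eps]) if any(
            e.latencies for e in eps) else np.array([])
        pct[arm] = p
        summary[arm] = {
            "n_sessions": len(eps),
            "pct_time_median": float(np.median(p)),
            "pct_time_iqr": (float(np.percentile(p, 25)),
                             float(np.percentile(p, 75))),
            "success_rate": float(np.mean(
                [e.termination_success_rate for e in eps])),
            "median_latency": float(np.median(lat)) if len(lat) else None,
        }
    tests = {}
    arms = list(endpoint_sets)
    if len(arms) > 2:
        kw = stats.kruskal(*[pct[a] for a in arms])
        tests["kruskal"] = {"stat": float(kw.statistic),
                            "p": float(kw.pvalue)}
    for i, a in enumerate(arms):
        for b in arms[i + 1:]:
            mw = stats.mannwhitneyu(pct[a], pct[b], alternative="two-sided")
            tests[f"mannwhitney {a} vs {b}"] = {
                "stat": float(mw.statistic), "p": float(mw.pvalue)}
    return {"summary": summary, "tests": tests}
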