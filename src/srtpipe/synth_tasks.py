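"""Generative simulators for task behavior, spiking, and kinematics.

The task simulator implements the deadline model of simple reaction time:
on each trial the subject draws an internal deadline D and responds at the
earlier of D and (stimulus onset + detection/motor latency L). Releases at
the deadline before stimulus onset are the premature (anticipatory)
responses; the anticipation function G(t) computed downstream estimates
the CDF of D. Distribution families for D and L are implementation
choices (the model itself does not prescribe them); the defaults are
right-skewed positive families whose medians echo trained-rat behavior,
and every family is pluggable through :class:`Dist`.

All generators are deterministic given (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from srtpipe.core_io import (
    BEHAVIOR_RESOLUTION,
    SPIKE_RESOLUTION,
    ParameterError,
    Session,
    SpikeTrain,
    Trajectory,
    Trial,
    TrialEvents,
    quantize,
)

# ---------------------------------------------------------------------------
# Distribution plumbing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dist:
    """A named scalar distribution family with parameters.

    Families: ``point(value)``, ``exponential(rate)``,
    ``normal(mu, sigma)``, ``lognormal(mu, sigma)`` (mu/sigma of log),
    and ``shifted_lognormal(shift, mu, sigma)``.
    """

    family: str
    params: tuple[float, ...]

    def _frozen(self):
        f, p = self.family, self.params
        if f == "exponential":
            (rate,) = p
            if rate <= 0:
                raise ParameterError("exponential rate must be > 0")
            return stats.expon(scale=1.0 / rate)
        if f == "normal":
            mu, sigma = p
            if sigma <= 0:
                raise ParameterError("normal sigma must be > 0")
            return stats.norm(loc=mu, scale=sigma)
        if f == "lognormal":
            mu, sigma = p
            if sigma <= 0:
                raise ParameterError("lognormal sigma must be > 0")
            return stats.lognorm(s=sigma, scale=math.exp(mu))
        if f == "shifted_lognormal":
            shift, mu, sigma = p
            if sigma <= 0:
                raise ParameterError("shifted_lognormal sigma must be > 0")
            return stats.lognorm(s=sigma, scale=math.exp(mu), loc=shift)
        raise ParameterError(f"unknown distribution family {f!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "point":
            (v,) = self.params
            return np.full(n, v, dtype=float)
        return self._frozen().rvs(size=n, random_state=rng)

    def cdf(self, x) -> np.ndarray:
        if self.family == "point":
            (v,) = self.params
            return (np.asarray(x, dtype=float) >= v).astype(float)
        return self._frozen().cdf(x)

    def scaled(self, factor: float) -> "Dist":
        """Scale the distribution of X to factor*X (location families scale loc)."""
        f, p = self.family, self.params
        if f == "point":
            return Dist("point", (p[0] * factor,))
        if f == "exponential":
            return Dist("exponential", (p[0] / factor,))
        if f == "normal":
            return Dist("normal", (p[0] * factor, p[1] * factor))
        if f == "lognormal":
            return Dist("lognormal", (p[0] + math.log(factor), p[1]))
        if f == "shifted_lognormal":
            return Dist("shifted_lognormal", (p[0] * factor, p[1] + math.log(factor), p[2]))
        raise ParameterError(f"unknown distribution family {f!r}")


POINT_INF = Dist("point", (math.inf,))


# ---------------------------------------------------------------------------
# Task parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeadlineModelParams:
    """Generative parameters of the SRT deadline-model simulator.

    Defaults reproduce the study conditions: three interleaved foreperiods
    {0.5, 1.0, 1.5} s with equal probability, a 600 ms response window,
    10% probe trials (no stimulus, release has no outcome), and a
    detection+motor latency floored at 0.1 s with median 0.3 s.
    The default deadline sits mostly beyond the longest foreperiod, as in
    well-trained animals.
    """

    fp_values: tuple[float, ...] = (0.5, 1.0, 1.5)
    fp_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    deadline_dist: Dist = Dist("shifted_lognormal", (0.2, math.log(1.7), 0.4))
    latency_dist: Dist = Dist("shifted_lognormal", (0.1, math.log(0.2), 0.35))
    response_window: float = 0.6
    late_cutoff: float = 2.0
    probe_fraction: float = 0.10
    iti_dist: Dist = Dist("shifted_lognormal", (2.0, math.log(3.0), 0.5))
    poke_latency_dist: Dist = Dist("lognormal", (math.log(1.5), 0.3))

    def __post_init__(self) -> None:
        if len(self.fp_values) != len(self.fp_probs):
            raise ParameterError("fp_values and fp_probs length mismatch")
        if abs(sum(self.fp_probs) - 1.0) > 1e-9:
            raise ParameterError("fp_probs must sum to 1")
        if self.response_window <= 0:
            raise ParameterError("response_window must be > 0")
        if not 0.0 <= self.probe_fraction <= 1.0:
            raise ParameterError("probe_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SelfTimingParams:
    """Self-timing task: hold a fixed foreperiod with (mostly) no cue.

    90% of trials are uncued; release timing is internally generated,
    modeled as a Gaussian hold duration. Releases within ``correct_window``
    after the foreperiod are rewarded. The default timed-release mean
    places the response mode slightly after the 1 s foreperiod, as trained
    rats do.
    """

    fp: float = 1.0
    cue_fraction: float = 0.10
    timed_mu: float = 1.14
    timed_sigma: float = 0.20
    correct_window: float = 1.0
    cued: DeadlineModelParams = field(
        default_factory=lambda: DeadlineModelParams(fp_values=(1.0,), fp_probs=(1.0,), probe_fraction=0.0)
    )
    iti_dist: Dist = Dist("shifted_lognormal", (2.0, math.log(3.0), 0.5))
    poke_latency_dist: Dist = Dist("lognormal", (math.log(1.5), 0.3))

    def __post_init__(self) -> None:
        if self.fp <= 0:
            raise ParameterError("fp must be > 0")
        if not 0.0 <= self.cue_fraction <= 1.0:
            raise ParameterError("cue_fraction must lie in [0, 1]")
        if self.timed_sigma <= 0:
            raise ParameterError("timed_sigma must be > 0")


@dataclass(frozen=True)
class RateTemplate:
    """Piecewise firing-rate template anchored to within-trial epochs.

    Baseline rates (Hz) apply over pre-press, Hold (press->stim),
    Response (stim->release), Poke (release->poke) and post-poke spans;
    Gaussian transients (amplitude Hz, width s) ride on top at each event.
    """

    pre_press: float = 2.0
    hold: float = 8.0
    response: float = 12.0
    poke: float = 6.0
    post_poke: float = 2.0
    transients: dict[str, tuple[float, float]] = field(default_factory=dict)
    # e.g. {"release": (20.0, 0.05)} -> 20 Hz transient, sigma 50 ms

    def __post_init__(self) -> None:
        rates = (self.pre_press, self.hold, self.response, self.poke, self.post_poke)
        if any(r < 0 for r in rates):
            raise ParameterError("epoch rates must be non-negative")
        for name, (amp, width) in self.transients.items():
            if name not in ("press", "stim", "release", "poke"):
                raise ParameterError(f"unknown transient anchor {name!r}")
            if amp < 0 or width <= 0:
                raise ParameterError("transient amplitude >= 0 and width > 0 required")

    def rate_on_grid(self, t: np.ndarray, ev: TrialEvents) -> np.ndarray:
        rate = np.full(t.shape, self.pre_press, dtype=float)
        rate[(t >= ev.press) & (t < ev.stim)] = self.hold
        rate[(t >= ev.stim) & (t < ev.release)] = self.response
        rate[(t >= ev.release) & (t < ev.poke)] = self.poke
        rate[t >= ev.poke] = self.post_poke
        anchors = dict(press=ev.press, stim=ev.stim, release=ev.release, poke=ev.poke)
        for name, (amp, width) in self.transients.items():
            rate += amp * np.exp(-0.5 * ((t - anchors[name]) / width) ** 2)
        return rate


@dataclass(frozen=True)
class KinematicParams:
    """Parameters of the synthetic trajectory generator (pixels, y-up)."""

    start: tuple[float, float] = (50.0, 50.0)
    end: tuple[float, float] = (400.0, 120.0)
    curvature: float = 0.3  # perpendicular control-point offset, fraction of chord
    mean_speed: float = 500.0  # px/s along the path
    noise_sd: float = 3.0  # per-sample positional jitter, px
    frame_rate: float = 50.0
    mirrored: bool = False  # locomotor turn handedness
    apex_height: float = 80.0  # paw reaches: rise above the endpoints, px

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.mean_speed <= 0:
            raise ParameterError("mean_speed must be > 0")


# ---------------------------------------------------------------------------
# Session simulators
# ---------------------------------------------------------------------------


def _finalize_session(
    rows: list[dict],
    rat_id: str,
    session_index: int,
    phase: str,
    post_ordinal: int,
    lesion_group: str,
    task: str,
) -> Session:
    trials = [Trial(**r) for r in rows]
    return Session(
        rat_id=rat_id, session_index=session_index, phase=phase,
        post_ordinal=post_ordinal, lesion_group=lesion_group, task=task,
        trials=trials,
    )


def simulate_srt_session(
    params: DeadlineModelParams,
    n_trials: int,
    seed: int,
    rat_id: str = "sim",
    session_index: int = 0,
    phase: str = "Pre",
    post_ordinal: int = 0,
    lesion_group: str = "none",
) -> Session:
    """Simulate one SRT session under the deadline-vs-detection race.

    Per trial: draw foreperiod FP, deadline D, latency L. On stimulus
    trials the lever is released at press+D if D < FP (premature, stimulus
    never delivered) and at press+FP+L otherwise (correct if L is within
    the response window, late otherwise). Probe trials run the same race
    against a stimulus that never comes: release at press + min(D, FP+L),
    no outcome. Rewarded (correct) trials get a poke time.
    """
    if n_trials <= 0:
        raise ParameterError("n_trials must be > 0")
    rng = np.random.default_rng(seed)
    fp_idx = rng.choice(len(params.fp_values), size=n_trials, p=np.asarray(params.fp_probs))
    fps = np.asarray(params.fp_values)[fp_idx]
    deadlines = params.deadline_dist.sample(rng, n_trials)
    latencies = params.latency_dist.sample(rng, n_trials)
    probes = rng.random(n_trials) < params.probe_fraction
    itis = params.iti_dist.sample(rng, n_trials)
    poke_latencies = params.poke_latency_dist.sample(rng, n_trials)

    rows: list[dict] = []
    clock = 10.0
    for i in range(n_trials):
        fp, d, lat = float(fps[i]), float(deadlines[i]), float(latencies[i])
        press = quantize(clock)
        stim_time = None
        poke_time = None
        if probes[i]:
            cue_kind = "probe"
            hold = min(d, fp + lat)
        elif d < fp:
            cue_kind = "stimulus"
            hold = d  # released before the stimulus: premature
        else:
            cue_kind = "stimulus"
            hold = fp + lat
            stim_time = quantize(press + fp)
            if lat <= params.response_window:
                poke_time = quantize(press + hold + float(poke_latencies[i]))
        hold = max(hold, BEHAVIOR_RESOLUTION)
        release = quantize(press + hold)
        if release <= press:
            release = quantize(press + BEHAVIOR_RESOLUTION)
        rows.append(
            dict(index=i, press_time=press, fp=fp, stim_time=stim_time,
                 release_time=release, poke_time=poke_time,
                 cue_kind=cue_kind, task="srt")
        )
        clock = (poke_time if poke_time is not None else release) + float(itis[i])
    return _finalize_session(rows, rat_id, session_index, phase, post_ordinal, lesion_group, "srt")


def simulate_selftiming_session(
    params: SelfTimingParams,
    n_trials: int,
    seed: int,
    rat_id: str = "sim",
    session_index: int = 0,
    phase: str = "Pre",
    post_ordinal: int = 0,
    lesion_group: str = "none",
) -> Session:
    """Simulate a self-timing session (90% uncued by default).

    Uncued trials release at press + max(eps, N(mu, sigma)); releases in
    [fp, fp + correct_window] are rewarded. Cued trials follow the SRT
    race at the task's fixed foreperiod.
    """
    if n_trials <= 0:
        raise ParameterError("n_trials must be > 0")
    rng = np.random.default_rng(seed)
    cued = rng.random(n_trials) < params.cue_fraction
    timed_holds = rng.normal(params.timed_mu, params.timed_sigma, size=n_trials)
    deadlines = params.cued.deadline_dist.sample(rng, n_trials)
    latencies = params.cued.latency_dist.sample(rng, n_trials)
    itis = params.iti_dist.sample(rng, n_trials)
    poke_latencies = params.poke_latency_dist.sample(rng, n_trials)

    fp = params.fp
    rows: list[dict] = []
    clock = 10.0
    for i in range(n_trials):
        press = quantize(clock)
        stim_time = None
        poke_time = None
        if cued[i]:
            cue_kind = "stimulus"
            d, lat = float(deadlines[i]), float(latencies[i])
            if d < fp:
                hold = d
            else:
                hold = fp + lat
                stim_time = quantize(press + fp)
                if lat <= params.cued.response_window:
                    poke_time = quantize(press + hold + float(poke_latencies[i]))
        else:
            cue_kind = "uncued"
            hold = max(float(timed_holds[i]), BEHAVIOR_RESOLUTION)
            if fp <= hold <= fp + params.correct_window:
                poke_time = quantize(press + hold + float(poke_latencies[i]))
        hold = max(hold, BEHAVIOR_RESOLUTION)
        release = quantize(press + hold)
        if release <= press:
            release = quantize(press + BEHAVIOR_RESOLUTION)
        if poke_time is not None and poke_time <= release:
            poke_time = quantize(release + BEHAVIOR_RESOLUTION)
        rows.append(
            dict(index=i, press_time=press, fp=fp, stim_time=stim_time,
                 release_time=release, poke_time=poke_time,
                 cue_kind=cue_kind, task="selftiming")
        )
        clock = (poke_time if poke_time is not None else release) + float(itis[i])
    return _finalize_session(
        rows, rat_id, session_index, phase, post_ordinal, lesion_group, "selftiming"
    )


# ---------------------------------------------------------------------------
# Spike simulator
# ---------------------------------------------------------------------------


def simulate_spike_unit(
    events: list[TrialEvents],
    template: RateTemplate,
    seed: int,
    unit_id: str = "u0",
    region: str = "MO",
    pre_margin: float = 1.0,
    post_margin: float = 1.0,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes following ``template`` on each trial.

    The rate profile is anchored to each trial's *actual* event times, so
    trial-to-trial reaction-time jitter is built into the spike train.
    Spike times are quantized to 1 ms; at most one spike per 1 ms bin.
    """
    rng = np.random.default_rng(seed)
    all_spikes: list[np.ndarray] = []
    for ev in events:
        t0 = ev.press - pre_margin
        t1 = ev.poke + post_margin
        n = int(round((t1 - t0) / SPIKE_RESOLUTION))
        t = t0 + SPIKE_RESOLUTION * np.arange(n)
        rate = template.rate_on_grid(t, ev)
        if np.any(rate < 0):
            raise ParameterError("rate template evaluates negative")
        p = rate * SPIKE_RESOLUTION  # P(spike in 1 ms bin), Bernoulli thinning
        fire = rng.random(n) < p
        spikes = t[fire]
        all_spikes.append(np.round(spikes / SPIKE_RESOLUTION) * SPIKE_RESOLUTION)
    merged = np.sort(np.concatenate(all_spikes)) if all_spikes else np.empty(0)
    return SpikeTrain(unit_id=unit_id, region=region, spike_times=merged)


# ---------------------------------------------------------------------------
# Trajectory simulator
# ---------------------------------------------------------------------------


def _bezier(p0: np.ndarray, pc: np.ndarray, p1: np.ndarray, u: np.ndarray) -> np.ndarray:
    u = u[:, None]
    return (1 - u) ** 2 * p0 + 2 * u * (1 - u) * pc + u**2 * p1


def simulate_trajectory_set(
    kind: str,
    params: KinematicParams,
    n: int,
    seed: int,
    rat_id: str = "sim",
    session_index: int = 0,
) -> list[Trajectory]:
    """Generate ``n`` noisy curved paths from start to end at the frame rate.

    Locomotor paths are single-bend curves (optionally mirrored for turn
    handedness); paw paths rise to an apex above the endpoints and descend
    onto the lever. Traversal duration is path length / mean speed.
    """
    if n <= 0:
        raise ParameterError("n must be > 0")
    p0 = np.asarray(params.start, dtype=float)
    p1 = np.asarray(params.end, dtype=float)
    chord = p1 - p0
    chord_len = float(np.hypot(*chord))
    if chord_len == 0:
        raise ParameterError("degenerate trajectory: start == end")
    rng = np.random.default_rng(seed)

    if kind == "paw":
        # control point above both endpoints -> rise to apex, descend to lever
        apex = 0.5 * (p0 + p1) + np.array([0.0, 2.0 * params.apex_height])
        pc = apex
    elif kind == "locomotor":
        perp = np.array([-chord[1], chord[0]]) / chord_len
        if params.mirrored:
            perp = -perp
        pc = 0.5 * (p0 + p1) + params.curvature * chord_len * perp
    else:
        raise ParameterError(f"unknown trajectory kind {kind!r}")

    # arc length of the quadratic curve, by dense polyline approximation
    uu = np.linspace(0.0, 1.0, 512)
    dense = _bezier(p0, pc, p1, uu)
    seglen = np.hypot(*np.diff(dense, axis=0).T)
    arclen = float(seglen.sum())
    duration = arclen / params.mean_speed
    dt = 1.0 / params.frame_rate
    n_frames = max(int(math.floor(duration / dt)) + 1, 2)

    # constant-speed parameterization: invert cumulative arc length
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    t_frames = dt * np.arange(n_frames)
    s_frames = np.minimum(t_frames * params.mean_speed, arclen)
    u_frames = np.interp(s_frames, cum, uu)

    out = []
    for i in range(n):
        pts = _bezier(p0, pc, p1, u_frames)
        pts = pts + rng.normal(0.0, params.noise_sd, size=pts.shape)
        out.append(
            Trajectory(
                kind=kind, t=t_frames.copy(), x=pts[:, 0], y=pts[:, 1],
                frame_interval=dt, rat_id=rat_id, session_index=session_index,
                trial_index=i,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohort-level convenience: lesion effects as parameter shifts
# ---------------------------------------------------------------------------


def lesioned_params(
    params: DeadlineModelParams,
    deadline_scale: float = 1.0,
    poke_scale: float = 1.0,
) -> DeadlineModelParams:
    """Model a lesion as a scale shift of the deadline and poke-latency laws.

    ``deadline_scale < 1`` shifts the deadline distribution leftward
    (more premature responses: a compromised-waiting phenotype);
    ``poke_scale > 1`` slows reward retrieval (a vigor deficit).
    """
    return replace(
        params,
        deadline_dist=params.deadline_dist.scaled(deadline_scale),
        poke_latency_dist=params.poke_latency_dist.scaled(poke_scale),
    )
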