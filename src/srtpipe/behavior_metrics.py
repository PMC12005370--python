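"""Behavioral metrics: outcomes, reaction times, and the anticipation function.

The anticipation function G(t) is the central statistic. Under the
deadline model, at each time t it estimates the fraction of still-eligible
trials (foreperiod longer than t) already released prematurely by t --
i.e. the CDF of the internal deadline variable. It is computed on the
10 ms task clock over [0, max FP), half-open at the longest foreperiod.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.stats import norm

from srtpipe.core_io import BEHAVIOR_RESOLUTION, ParameterError, Session, Trial, ValidationError
from srtpipe.stats_inference import bh_threshold

logger = logging.getLogger("srtpipe")

OUTCOME_LABELS = ("premature", "correct", "late", "probe_excluded", "subthreshold_reactive")


@dataclass(frozen=True)
class LabeledTrial:
    """A trial with its outcome label and derived latencies."""

    trial: Trial
    label: str
    rt: float | None  # stimulus-to-release latency, stimulus trials only

    @property
    def hold(self) -> float:
        return self.trial.hold

    @property
    def fp(self) -> float:
        return self.trial.fp


@dataclass
class AnticipationCurve:
    """G(t) on a 10 ms grid with per-foreperiod bookkeeping.

    ``g`` is NaN where the denominator is zero; ``defined`` flags the
    valid grid points. ``n_per_fp`` holds the trial counts N_i and
    ``f_per_fp`` the per-foreperiod premature fractions F_i(t).
    """

    t: np.ndarray
    g: np.ndarray
    defined: np.ndarray
    n_per_fp: dict[float, int]
    f_per_fp: dict[float, np.ndarray]


@dataclass
class DensityCurve:
    """Kernel density of hold durations on fixed-width bins."""

    centers: np.ndarray
    density: np.ndarray
    bandwidth: float
    bin_width: float


@dataclass
class TrialPool:
    """Whole sessions pooled to meet a per-foreperiod trial-count minimum."""

    condition: str  # Pre | Post_Early | Post_Late
    session_indices: list[int]
    trials: list[LabeledTrial]
    counts_per_fp: dict[float, int]
    complete: bool


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_trials(
    session: Session,
    response_window: float = 0.6,
    late_cutoff: float = 2.0,
    correct_window: float = 1.0,
) -> list[LabeledTrial]:
    """Assign exactly one outcome label to every trial of a session.

    Stimulus trials: release before the (scheduled) stimulus is premature;
    otherwise the reaction time rt = release - stimulus decides --
    rt < 0.1 s is too brief for a reactive response (labeled
    ``subthreshold_reactive``), rt within the response window is correct,
    later is late. Probe trials are excluded from outcome ratios. Uncued
    self-timing trials: hold < fp is premature, hold within
    [fp, fp + correct_window] correct, later late.
    """
    out: list[LabeledTrial] = []
    for tr in session.trials:
        hold = tr.hold
        if tr.cue_kind == "probe":
            out.append(LabeledTrial(tr, "probe_excluded", None))
            continue
        if tr.cue_kind == "uncued":
            if hold < tr.fp:
                label = "premature"
            elif hold <= tr.fp + correct_window:
                label = "correct"
            else:
                label = "late"
            out.append(LabeledTrial(tr, label, None))
            continue
        # stimulus trial; stimulus scheduled at press + fp whether or not delivered
        rt = round(hold - tr.fp, 6)
        if rt < 0:
            out.append(LabeledTrial(tr, "premature", None))
        elif rt < 0.1:
            out.append(LabeledTrial(tr, "subthreshold_reactive", rt))
        elif rt <= response_window:
            out.append(LabeledTrial(tr, "correct", rt))
        else:
            out.append(LabeledTrial(tr, "late", rt))
    return out


def outcome_counts(labeled: list[LabeledTrial]) -> dict[str, int]:
    counts = {k: 0 for k in OUTCOME_LABELS}
    for lt in labeled:
        counts[lt.label] += 1
    return counts


# ---------------------------------------------------------------------------
# Reaction times
# ---------------------------------------------------------------------------


def mad_filter(values: np.ndarray, k: float = 10.0) -> np.ndarray:
    """Remove x with |x - median| > k * 1.4826 * MAD (stable order).

    The 1.4826 factor scales the median absolute deviation to a
    consistent estimate of the standard deviation under normality, the
    convention of common outlier-removal routines. When the MAD is zero
    (more than half the sample sits on the median) the cutoff collapses
    to zero and only values equal to the median survive -- so a constant
    sample passes through unchanged while a lone deviant is removed.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return x
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return x[np.abs(x - med) <= k * 1.4826 * mad]


def extract_reaction_times(
    labeled: list[LabeledTrial],
    rt_min: float = 0.1,
    rt_max: float = 2.0,
    mad_k: float = 10.0,
) -> np.ndarray:
    """Pool correct + late reaction times, window them, and MAD-filter.

    Latencies below ``rt_min`` are too brief to be reactive and those
    above ``rt_max`` reflect disengagement; both are excluded before the
    MAD outlier pass.
    """
    rts = np.array(
        [lt.rt for lt in labeled if lt.label in ("correct", "late") and lt.rt is not None],
        dtype=float,
    )
    rts = rts[(rts >= rt_min) & (rts <= rt_max)]
    if rts.size == 0:
        logger.warning("extract_reaction_times: empty RT pool")
        return rts
    return mad_filter(rts, k=mad_k)


def rt_summary(rts: np.ndarray) -> dict[str, float]:
    """Median and quartiles of an RT sample."""
    if rts.size == 0:
        return dict(median=np.nan, q25=np.nan, q75=np.nan, n=0)
    q25, med, q75 = np.percentile(rts, [25, 50, 75])
    return dict(median=float(med), q25=float(q25), q75=float(q75), n=int(rts.size))


# ---------------------------------------------------------------------------
# Hold-duration density and Gaussian mode
# ---------------------------------------------------------------------------


def hold_density(
    durations: np.ndarray,
    bandwidth: float = 0.075,
    bin_width: float = 0.05,
) -> DensityCurve:
    """Gaussian-kernel density of hold durations at fixed bin centers.

    A fixed-bandwidth kernel estimate evaluated at bin centers spanning
    [0, max + 4*bandwidth]; bandwidth is the kernel sigma in seconds.
    """
    x = np.asarray(durations, dtype=float)
    if x.size == 0:
        raise ParameterError("hold_density: empty sample")
    if bandwidth <= 0 or bin_width <= 0:
        raise ParameterError("bandwidth and bin_width must be > 0")
    upper = float(np.max(x)) + 4.0 * bandwidth
    n_bins = int(np.ceil(upper / bin_width))
    centers = (np.arange(n_bins) + 0.5) * bin_width
    dens = norm.pdf(centers[:, None], loc=x[None, :], scale=bandwidth).mean(axis=1)
    return DensityCurve(centers=centers, density=dens, bandwidth=bandwidth, bin_width=bin_width)


def fit_gaussian_mode(release_holds: np.ndarray, bandwidth: float = 0.075) -> float:
    """Mode of a response distribution: center of a fitted Gaussian.

    Fits a*exp(-(t-mu)^2 / (2 sigma^2)) to the hold-duration density
    curve by nonlinear least squares, mu initialized at the empirical
    peak, and returns mu.
    """
    x = np.asarray(release_holds, dtype=float)
    if x.size < 20:
        raise ParameterError("fit_gaussian_mode: need n >= 20 responses")
    curve = hold_density(x, bandwidth=bandwidth)
    i0 = int(np.argmax(curve.density))
    p0 = (float(curve.density[i0]), float(curve.centers[i0]), max(float(np.std(x)), 1e-3))

    def gauss(t, a, mu, sigma):
        return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))

    try:
        popt, _ = curve_fit(gauss, curve.centers, curve.density, p0=p0, maxfev=10_000)
    except RuntimeError as err:  # pragma: no cover - pathological samples
        raise ParameterError(
            f"fit_gaussian_mode failed to converge (initializer mu={p0[1]:.3f})"
        ) from err
    return float(popt[1])


# ---------------------------------------------------------------------------
# Anticipation function
# ---------------------------------------------------------------------------


def anticipation_function(
    labeled: list[LabeledTrial],
    step: float = BEHAVIOR_RESOLUTION,
    include_subthreshold: bool = False,
) -> AnticipationCurve:
    """G(t): premature fraction of still-eligible trials at each time t.

    For each grid point t in [0, max FP), G(t) = (# premature trials with
    FP > t and hold <= t) / (# trials with FP > t). Probe trials never
    enter; releases within 100 ms after the stimulus are excluded unless
    ``include_subthreshold`` (their reactive/anticipatory status is
    ambiguous). Grid points with an empty denominator are flagged
    undefined, not zero. With foreperiods {0.5, 1.0, 1.5} this reduces to
    the familiar three-branch form
    (N1 F1 + N2 F2 + N3 F3)/(N1+N2+N3) for t < 0.5, etc.
    """
    eligible_labels = {"premature", "correct", "late"}
    if include_subthreshold:
        eligible_labels = eligible_labels | {"subthreshold_reactive"}
    use = [lt for lt in labeled if lt.label in eligible_labels]
    if not use:
        raise ParameterError("anticipation_function: no eligible trials")

    # integer ticks on the task clock avoid float boundary ambiguity
    fp_ticks = np.array([int(round(lt.fp / step)) for lt in use])
    hold_ticks = np.array([int(round(lt.hold / step)) for lt in use])
    premature = np.array([lt.label == "premature" for lt in use])

    max_fp_ticks = int(fp_ticks.max())
    grid_ticks = np.arange(max_fp_ticks)  # half-open at max FP
    t = grid_ticks * step

    g = np.full(grid_ticks.size, np.nan)
    defined = np.zeros(grid_ticks.size, dtype=bool)
    fps = sorted(set(fp_ticks.tolist()))
    n_per_fp = {round(fpt * step, 6): int((fp_ticks == fpt).sum()) for fpt in fps}
    f_per_fp: dict[float, np.ndarray] = {}

    # F_i(t): fraction of trials of foreperiod i premature at or before t
    for fpt in fps:
        sel = fp_ticks == fpt
        prem_holds = hold_ticks[sel & premature]
        f = np.array([(prem_holds <= k).sum() for k in grid_ticks], dtype=float) / sel.sum()
        f_per_fp[round(fpt * step, 6)] = f

    for j, k in enumerate(grid_ticks):
        elig = fp_ticks > k
        denom = int(elig.sum())
        if denom == 0:
            continue
        numer = int((elig & premature & (hold_ticks <= k)).sum())
        g[j] = numer / denom
        defined[j] = True
    return AnticipationCurve(t=t, g=g, defined=defined, n_per_fp=n_per_fp, f_per_fp=f_per_fp)


def anticipation_integral_change(pre: AnticipationCurve, post: AnticipationCurve) -> float:
    """Trapezoidal integral of (post - pre) over the common defined domain.

    Units: seconds. Integrates each contiguous run of jointly defined grid
    points and sums the runs.
    """
    if pre.t.size != post.t.size or not np.allclose(pre.t, post.t):
        raise ValidationError("anticipation curves are on different grids")
    both = pre.defined & post.defined
    if not both.any():
        raise ValidationError("anticipation curves share no defined domain")
    diff = post.g - pre.g
    total = 0.0
    # integrate per contiguous defined run
    idx = np.flatnonzero(both)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if run.size >= 2:
            total += float(np.trapezoid(diff[run], pre.t[run]))
    return total


# ---------------------------------------------------------------------------
# Session pooling
# ---------------------------------------------------------------------------


def _response_counts_per_fp(labeled: list[LabeledTrial]) -> dict[float, int]:
    counts: dict[float, int] = {}
    for lt in labeled:
        if lt.label in ("premature", "correct", "late"):
            counts[lt.fp] = counts.get(lt.fp, 0) + 1
    return counts


def pool_condition(
    sessions: list[Session],
    condition: str,
    min_per_fp: int | None = None,
    response_window: float = 0.6,
    correct_window: float = 1.0,
) -> TrialPool:
    """Pool whole sessions until every foreperiod count exceeds the minimum.

    Pre walks backward from the last prelesion session (default minimum
    500 per FP); Post_Early walks forward from the first postlesion
    session and Post_Late backward from the last (default 200). Sessions
    are never split; if the supply runs out the pool is flagged
    incomplete with its achieved counts.
    """
    if condition == "Pre":
        cand = [s for s in sessions if s.phase == "Pre"]
        cand = cand[::-1]
        minimum = 500 if min_per_fp is None else min_per_fp
    elif condition == "Post_Early":
        cand = [s for s in sessions if s.phase == "Post"]
        minimum = 200 if min_per_fp is None else min_per_fp
    elif condition == "Post_Late":
        cand = [s for s in sessions if s.phase == "Post"][::-1]
        minimum = 200 if min_per_fp is None else min_per_fp
    else:
        raise ParameterError(f"unknown pool condition {condition!r}")

    fp_universe: set[float] = set()
    for s in cand:
        fp_universe |= {tr.fp for tr in s.trials if tr.cue_kind != "probe"}

    chosen: list[Session] = []
    counts: dict[float, int] = {fp: 0 for fp in fp_universe}
    pooled: list[LabeledTrial] = []
    complete = False
    for s in cand:
        labeled = classify_trials(s, response_window=response_window, correct_window=correct_window)
        chosen.append(s)
        pooled.extend(labeled)
        for fp, c in _response_counts_per_fp(labeled).items():
            counts[fp] = counts.get(fp, 0) + c
        if fp_universe and all(counts.get(fp, 0) > minimum for fp in fp_universe):
            complete = True
            break
    if not complete:
        logger.warning(
            "pool_condition %s incomplete: achieved %s (minimum %d)", condition, counts, minimum
        )
    return TrialPool(
        condition=condition,
        session_indices=[s.session_index for s in chosen],
        trials=pooled,
        counts_per_fp=counts,
        complete=complete,
    )


def merge_small_sessions(sessions: list[Session], threshold: int = 50) -> list[list[Session]]:
    """Group postlesion sessions so every group reaches ``threshold`` responses.

    An undersized session attaches forward to the next session, and the
    attachment is transitive: a run of small sessions merges into the
    first subsequent session of full size. Prelesion sessions pass
    through one per group; a trailing undersized group is merged into
    its predecessor.
    """
    groups: list[list[Session]] = []
    bucket: list[Session] = []
    for s in sessions:
        n_resp = sum(1 for tr in s.trials if tr.cue_kind != "probe")
        if s.phase == "Pre":
            if bucket:
                groups.append(bucket)
                bucket = []
            groups.append([s])
            continue
        bucket.append(s)
        if n_resp >= threshold:
            groups.append(bucket)
            bucket = []
    if bucket:
        if groups and groups[-1] and groups[-1][-1].phase == "Post":
            groups[-1].extend(bucket)
        else:
            groups.append(bucket)
    return groups


# ---------------------------------------------------------------------------
# Speeding-effect classification
# ---------------------------------------------------------------------------


def speeding_classification(
    per_rat_rts: dict[str, tuple[np.ndarray, np.ndarray]],
    q: float = 0.05,
) -> tuple[dict[str, str], float]:
    """Classify each rat's RT-vs-foreperiod slope: speeding / anti / none.

    Per rat, fits RT ~ 1 + FP by ordinary least squares and takes the
    two-sided p-value of the FP coefficient. The family of slope p-values
    is thresholded with the Benjamini-Hochberg critical value at FDR
    ``q``; a significant negative slope is ``speeding`` (faster responses
    after longer foreperiods), a significant positive slope
    ``anti_speeding``, else ``none``. Returns (labels, critical p).
    """
    slopes: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for rat, (rts, fps) in per_rat_rts.items():
        rts = np.asarray(rts, dtype=float)
        fps = np.asarray(fps, dtype=float)
        if np.unique(fps).size < 2:
            logger.warning("speeding_classification: rat %s has a single FP; excluded", rat)
            continue
        X = sm.add_constant(fps)
        fit = sm.OLS(rts, X).fit()
        slopes[rat] = float(fit.params[1])
        pvals[rat] = float(fit.pvalues[1])
    rats = sorted(pvals)
    crit, mask = bh_threshold(np.array([pvals[r] for r in rats]), q=q)
    labels: dict[str, str] = {}
    for r, sig in zip(rats, mask):
        if sig and slopes[r] < 0:
            labels[r] = "speeding"
        elif sig and slopes[r] > 0:
            labels[r] = "anti_speeding"
        else:
            labels[r] = "none"
    return labels, crit


# ---------------------------------------------------------------------------
# Reward retrieval duration
# ---------------------------------------------------------------------------


def retrieval_durations(
    sessions: list[Session],
    merge_threshold: int = 30,
    mad_k: float = 10.0,
    response_window: float = 0.6,
    correct_window: float = 1.0,
) -> list[dict]:
    """Correct-release-to-poke latencies per session group.

    Postlesion sessions with fewer than ``merge_threshold`` responses are
    combined with subsequent sessions; each group's durations are MAD
    outlier-filtered. Returns one record per group with phase, member
    session indices, and the filtered duration sample.
    """
    groups = merge_small_sessions(sessions, threshold=merge_threshold)
    records = []
    for group in groups:
        durs = []
        for s in group:
            for lt in classify_trials(s, response_window=response_window, correct_window=correct_window):
                if lt.label == "correct" and lt.trial.poke_time is not None:
                    durs.append(lt.trial.poke_time - lt.trial.release_time)
        durs = mad_filter(np.array(durs, dtype=float), k=mad_k)
        records.append(
            dict(
                phase=group[0].phase,
                session_indices=[s.session_index for s in group],
                durations=durs,
            )
        )
    return records


def normalized_retrieval(records: list[dict]) -> list[dict]:
    """Express each group's median retrieval duration relative to Pre.

    The prelesion baseline is the mean of prelesion group medians; each
    group's normalized value is its median divided by that baseline (1.0
    means unchanged, 1.74 means 74% slower).
    """
    pre_medians = [np.median(r["durations"]) for r in records
                   if r["phase"] == "Pre" and len(r["durations"])]
    if not pre_medians:
        raise ParameterError("normalized_retrieval: no prelesion durations")
    baseline = float(np.mean(pre_medians))
    out = []
    for r in records:
        med = float(np.median(r["durations"])) if len(r["durations"]) else np.nan
        out.append(dict(r, median=med, normalized=med / baseline))
    return out
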