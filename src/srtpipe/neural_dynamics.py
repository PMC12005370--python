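"""Spike density functions, event-anchored time warping, and population PCA.

Trials of a reaction-time task differ in their event timing (reaction
time, release-to-poke interval), so event-aligned averages smear activity
between events. The warping procedure here resamples each trial's spike
density function segment by segment -- press->stimulus->release->poke --
onto the across-trial *median* event times, producing a single peri-event
trace per trial that aligns all four events at once. Warped traces are
averaged, z-scored, ranked by peak time, and stacked into a time x unit
matrix for PCA of the population dynamics.

Within a segment the map is linear in the sample index: target sample i
sits at source position i*s with s = (source span)/(target span), and the
value is the linear interpolation
(ceil(x)-x) * SDF(floor(x)) + (x-floor(x)) * SDF(ceil(x)), an integer x
returning SDF(x) exactly. The pre-press and post-poke margins are copied
unwarped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA

from srtpipe.core_io import (
    SPIKE_RESOLUTION,
    ParameterError,
    SpikeTrain,
    TrialEvents,
    ValidationError,
)

logger = logging.getLogger("srtpipe")


@dataclass
class SDFTrace:
    """Spike density function on a uniform 1 ms grid (rate in Hz)."""

    t0: float  # time of the first sample, s
    rate: np.ndarray
    sigma: float = 0.020

    @property
    def t(self) -> np.ndarray:
        return self.t0 + SPIKE_RESOLUTION * np.arange(self.rate.size)


@dataclass(frozen=True)
class WarpTarget:
    """Common target event times (medians across trials), 1 ms grid."""

    press: float
    stim: float
    release: float
    poke: float

    def __post_init__(self) -> None:
        if not (self.press < self.stim < self.release < self.poke):
            raise ValidationError("warp target events must be strictly increasing")

    def as_array(self) -> np.ndarray:
        return np.array([self.press, self.stim, self.release, self.poke])


@dataclass
class WarpedPETH:
    """A unit's z-scored warped trial-average on the target grid."""

    unit_id: str
    fp_condition: float
    t: np.ndarray
    z: np.ndarray
    peak_time: float
    flagged: bool = False  # zero-variance trace, z undefined


@dataclass
class PopulationDecomposition:
    loadings: np.ndarray  # units x components
    projections: np.ndarray  # time x components
    variance_fractions: np.ndarray


# ---------------------------------------------------------------------------
# Spike density
# ---------------------------------------------------------------------------


def spike_density(
    spikes: SpikeTrain | np.ndarray,
    window: tuple[float, float],
    sigma: float = 0.020,
) -> SDFTrace:
    """Gaussian-kernel spike density function on the 1 ms grid.

    A sum of unit-area Gaussians (sigma default 20 ms) centered at the
    spike times, evaluated over ``window``; an empty train gives an
    identically zero trace. Spikes outside the window still contribute
    through their kernel tails.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    start, end = window
    if end <= start:
        raise ParameterError("invalid window")
    st = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    n = int(round((end - start) / SPIKE_RESOLUTION)) + 1
    grid = start + SPIKE_RESOLUTION * np.arange(n)
    if st.size == 0:
        return SDFTrace(t0=start, rate=np.zeros(n), sigma=sigma)
    # bin spikes onto the grid (they are 1 ms-quantized) and convolve
    reach = 6.0 * sigma
    keep = st[(st >= start - reach) & (st <= end + reach)]
    pad = int(np.ceil(reach / SPIKE_RESOLUTION))
    counts = np.zeros(n + 2 * pad)
    idx = np.round((keep - start) / SPIKE_RESOLUTION).astype(int) + pad
    np.add.at(counts, idx, 1.0)
    kt = SPIKE_RESOLUTION * np.arange(-pad, pad + 1)
    kernel = np.exp(-0.5 * (kt / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    rate = signal.oaconvolve(counts, kernel, mode="same")[pad:-pad]
    return SDFTrace(t0=start, rate=np.maximum(rate, 0.0), sigma=sigma)


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------


def compute_target_events(events: list[TrialEvents]) -> WarpTarget:
    """Median event times across trials, rounded to the 1 ms grid."""
    if not events:
        raise ParameterError("compute_target_events: no trials")
    arr = np.stack([ev.as_array() for ev in events])
    med = np.round(np.median(arr, axis=0) / SPIKE_RESOLUTION) * SPIKE_RESOLUTION
    if np.any(np.diff(med) <= 0):
        raise ValidationError("median event times are not strictly increasing")
    return WarpTarget(press=med[0], stim=med[1], release=med[2], poke=med[3])


def _warp_segment(seg: np.ndarray, k: int) -> np.ndarray:
    """Resample a source segment of n samples onto k target samples."""
    n = seg.size
    if n == k:
        return seg.copy()
    if k == 1:
        return seg[:1].copy()
    s = (n - 1) / (k - 1)
    x = np.arange(k) * s
    lo = np.floor(x).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    frac = x - lo
    return (1.0 - frac) * seg[lo] + frac * seg[hi]


def warp_sdf(
    sdf: SDFTrace,
    events: TrialEvents,
    target: WarpTarget,
    pre_margin: float = 0.5,
    post_margin: float = 0.5,
) -> np.ndarray:
    """Warp one trial's SDF onto the target event times.

    Each inter-event span [e_j, e_j+1] is linearly resampled onto
    [e'_j, e'_j+1]; the ``pre_margin`` seconds before the press and
    ``post_margin`` after the poke are copied unwarped. Returns the
    warped trace on the target grid
    [target.press - pre_margin, target.poke + post_margin]. A trial whose
    events already equal the target is returned bit-exactly.
    """
    def src_idx(t: float) -> int:
        i = int(round((t - sdf.t0) / SPIKE_RESOLUTION))
        if i < 0 or i >= sdf.rate.size:
            raise ValidationError("event outside the SDF window")
        return i

    ev = events.as_array()
    tg = target.as_array()
    pre_n = int(round(pre_margin / SPIKE_RESOLUTION))
    post_n = int(round(post_margin / SPIKE_RESOLUTION))
    if src_idx(ev[0]) < pre_n or src_idx(ev[-1]) + post_n >= sdf.rate.size:
        raise ValidationError("SDF window does not cover the requested margins")

    pieces: list[np.ndarray] = []
    p0 = src_idx(ev[0])
    pieces.append(sdf.rate[p0 - pre_n : p0])  # unwarped pre-press margin
    for j in range(3):
        a, b = src_idx(ev[j]), src_idx(ev[j + 1])
        k = int(round((tg[j + 1] - tg[j]) / SPIKE_RESOLUTION)) + 1
        seg = _warp_segment(sdf.rate[a : b + 1], k)
        pieces.append(seg if j == 2 else seg[:-1])  # drop shared boundary samples
    p3 = src_idx(ev[3])
    pieces.append(sdf.rate[p3 + 1 : p3 + 1 + post_n])  # unwarped post-poke margin
    return np.concatenate(pieces)


def warp_grid(target: WarpTarget, pre_margin: float = 0.5, post_margin: float = 0.5) -> np.ndarray:
    start = target.press - pre_margin
    n = int(round((target.poke + post_margin - start) / SPIKE_RESOLUTION)) + 1
    return start + SPIKE_RESOLUTION * np.arange(n)


# ---------------------------------------------------------------------------
# Warped PETHs
# ---------------------------------------------------------------------------


def build_warped_peth(
    warped_trials: list[np.ndarray],
    target: WarpTarget,
    unit_id: str = "u0",
    fp_condition: float = 1.5,
    pre_margin: float = 0.5,
    post_margin: float = 0.5,
) -> WarpedPETH:
    """Average warped single-trial traces and z-score over the full grid.

    The z-normalization window (the whole warped grid, per foreperiod
    condition) is a convention of this package; it is exposed rather than
    fixed by the procedure itself. Zero-variance traces are flagged and
    their z left undefined (NaN).
    """
    if not warped_trials:
        raise ParameterError("build_warped_peth: no trials")
    lens = {w.size for w in warped_trials}
    if len(lens) != 1:
        raise ValidationError("warped trials have mismatched lengths")
    mean_trace = np.mean(np.stack(warped_trials), axis=0)
    t = warp_grid(target, pre_margin, post_margin)
    mu, sd = float(np.mean(mean_trace)), float(np.std(mean_trace))
    if sd == 0:
        logger.warning("unit %s: zero-variance PETH; z undefined", unit_id)
        return WarpedPETH(unit_id, fp_condition, t, np.full(t.size, np.nan),
                          peak_time=float(t[0]), flagged=True)
    z = (mean_trace - mu) / sd
    peak_i = int(np.argmax(z))  # first maximum: ties broken by earlier time
    return WarpedPETH(unit_id, fp_condition, t, z, peak_time=float(t[peak_i]))


def rank_units(peths: list[WarpedPETH]) -> list[WarpedPETH]:
    """Order units by peak time (ties: earlier time, then unit_id).

    By convention the ranking is computed on the long-foreperiod
    condition and applied unchanged to the short one.
    """
    return sorted((p for p in peths if not p.flagged), key=lambda p: (p.peak_time, p.unit_id))


def epoch_modulation(peth: WarpedPETH, target: WarpTarget) -> tuple[float, float, float]:
    """Mean |z| in the Hold, Response, and Poke epochs.

    Hold spans press->stimulus, Response stimulus->release, Poke
    release->poke, all on the warped target grid.
    """
    def mean_abs(a: float, b: float) -> float:
        sel = (peth.t >= a - 1e-12) & (peth.t <= b + 1e-12)
        return float(np.mean(np.abs(peth.z[sel])))

    return (
        mean_abs(target.press, target.stim),
        mean_abs(target.stim, target.release),
        mean_abs(target.release, target.poke),
    )


# ---------------------------------------------------------------------------
# Population PCA
# ---------------------------------------------------------------------------


def population_pca(peth_matrix: np.ndarray, n_components: int | None = None) -> PopulationDecomposition:
    """PCA of a time x unit matrix of z-scored warped PETHs.

    Columns (units) are mean-centered; projections are the time courses
    of the principal components. Each component is oriented so that its
    largest-magnitude unit loading is positive.
    """
    M = np.asarray(peth_matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ParameterError("population_pca: need a time x unit matrix with >= 2 units")
    if M.shape[0] < 2:
        raise ParameterError("population_pca: need >= 2 time points")
    k = min(M.shape) if n_components is None else n_components
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(M)  # time x components
    loadings = pca.components_.T  # units x components
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    return PopulationDecomposition(
        loadings=loadings,
        projections=scores,
        variance_fractions=pca.explained_variance_ratio_,
    )


def component_correlation(
    projA: np.ndarray,
    projB: np.ndarray,
    n_components: int = 3,
    align_signs: bool = True,
) -> np.ndarray:
    """Pearson r between two populations' component time courses.

    PCA component signs are arbitrary, so by default each pair is
    sign-aligned (r -> |r|) before reporting; disable to keep raw signs.
    """
    A = np.asarray(projA, dtype=float)
    B = np.asarray(projB, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValidationError("projections have different lengths")
    k = min(n_components, A.shape[1], B.shape[1])
    out = np.empty(k)
    for c in range(k):
        r = float(np.corrcoef(A[:, c], B[:, c])[0, 1])
        out[c] = abs(r) if align_signs else r
    return out
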