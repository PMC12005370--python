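"""Permutation tests and Benjamini-Hochberg FDR control.

Two-sample label-permutation and paired sign-flip tests with automatic
exact enumeration on small problems, plus the BH step-up critical
p-value used to declare within-subject changes significant across a
family of comparisons.

Monte-Carlo p-values use the add-one convention
p = (1 + #{|T*| >= |T_obs|}) / (n_perm + 1), so p is never zero and the
test remains valid at finite permutation counts; exact enumeration
reports the exact tail fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from srtpipe.core_io import ParameterError

EXACT_LIMIT = 20_000  # enumerate all arrangements at or below this count

STAT_KINDS = ("median_diff", "mean_diff", "proportion_diff")


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    n_perm: int
    p_value: float
    stat_kind: str
    seed: int | None
    exact: bool


def _stat_fn(kind: str):
    if kind == "median_diff":
        return lambda a, b: np.median(a) - np.median(b)
    if kind in ("mean_diff", "proportion_diff"):
        # a proportion is the mean of a 0/1 sample
        return lambda a, b: np.mean(a) - np.mean(b)
    raise ParameterError(f"unknown stat_kind {kind!r}")


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    stat_kind: str = "median_diff",
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
) -> PermutationResult:
    """Two-sided two-sample permutation test.

    Pools x and y and re-splits the labels; exact enumeration of all
    C(n, nx) splits is used when that count is at most 20,000, otherwise
    ``n_perm`` Monte-Carlo shuffles. ``method`` forces ``"exact"`` or
    ``"monte_carlo"`` regardless of size.
    """
    if method not in ("auto", "exact", "monte_carlo"):
        raise ParameterError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("permutation_test: both samples must be nonempty")
    stat = _stat_fn(stat_kind)
    pooled = np.concatenate([x, y])
    nx, n = x.size, x.size + y.size
    t_obs = float(stat(x, y))

    n_arrangements = comb(n, nx)
    use_exact = method == "exact" or (method == "auto" and n_arrangements <= EXACT_LIMIT)
    if method == "exact" and n_arrangements > EXACT_LIMIT:
        raise ParameterError("exact enumeration requested on too large a problem")
    if use_exact:
        count = 0
        idx_all = np.arange(n)
        for chosen in combinations(range(n), nx):
            sel = np.zeros(n, dtype=bool)
            sel[list(chosen)] = True
            t = stat(pooled[sel], pooled[~sel])
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        return PermutationResult(
            observed=t_obs, n_perm=n_arrangements,
            p_value=count / n_arrangements, stat_kind=stat_kind,
            seed=seed, exact=True,
        )

    rng = np.random.default_rng(seed)
    # vectorized shuffles: each row of idx is an independent permutation
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = pooled[idx]
    if stat_kind == "median_diff":
        t_all = np.median(shuffled[:, :nx], axis=1) - np.median(shuffled[:, nx:], axis=1)
    else:
        t_all = shuffled[:, :nx].mean(axis=1) - shuffled[:, nx:].mean(axis=1)
    count = int(np.sum(np.abs(t_all) >= abs(t_obs) - 1e-12))
    return PermutationResult(
        observed=t_obs, n_perm=n_perm,
        p_value=(1 + count) / (n_perm + 1), stat_kind=stat_kind,
        seed=seed, exact=False,
    )


def paired_permutation_test(
    diffs: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
) -> PermutationResult:
    """Two-sided paired (sign-flip) permutation test on mean difference.

    Exact over all 2^n sign patterns when that count is at most 20,000.
    All-zero differences give p = 1 by convention. ``method`` as in
    :func:`permutation_test`.
    """
    if method not in ("auto", "exact", "monte_carlo"):
        raise ParameterError(f"unknown method {method!r}")
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ParameterError("paired_permutation_test: empty differences")
    t_obs = float(np.mean(d))
    if np.all(d == 0):
        return PermutationResult(
            observed=0.0, n_perm=0, p_value=1.0,
            stat_kind="mean_paired_diff", seed=seed, exact=True,
        )
    n = d.size
    use_exact = method == "exact" or (method == "auto" and 2**n <= EXACT_LIMIT)
    if method == "exact" and 2**n > EXACT_LIMIT:
        raise ParameterError("exact enumeration requested on too large a problem")
    if use_exact:
        # enumerate sign patterns via the bits of 0..2^n-1
        patterns = np.arange(2**n, dtype=np.int64)
        bits = (patterns[:, None] >> np.arange(n)) & 1
        signs = 1 - 2 * bits  # 0 -> +1, 1 -> -1
        t_all = (signs * d).mean(axis=1)
        count = int(np.sum(np.abs(t_all) >= abs(t_obs) - 1e-12))
        return PermutationResult(
            observed=t_obs, n_perm=2**n, p_value=count / 2**n,
            stat_kind="mean_paired_diff", seed=seed, exact=True,
        )
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_all = (signs * d).mean(axis=1)
    count = int(np.sum(np.abs(t_all) >= abs(t_obs) - 1e-12))
    return PermutationResult(
        observed=t_obs, n_perm=n_perm, p_value=(1 + count) / (n_perm + 1),
        stat_kind="mean_paired_diff", seed=seed, exact=False,
    )


def bh_threshold(pvals: np.ndarray, q: float = 0.05) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up: critical p-value and significance mask.

    Sorts the m p-values ascending, finds the largest k with
    p_(k) <= (k/m) q, and reports p_(k) as the family's critical
    threshold (0.0 when no k qualifies). Significant = p <= critical p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return 0.0, np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("bh_threshold: p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    m = p.size
    ks = np.flatnonzero(sorted_p <= (np.arange(1, m + 1) / m) * q)
    if ks.size == 0:
        return 0.0, np.zeros(m, dtype=bool)
    critical = float(sorted_p[ks[-1]])
    return critical, p <= critical


def pooled_t_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, int]:
    """Two-sample pooled-variance t from summary statistics.

    Returns (t, df) with df = n1 + n2 - 2; useful when only the printed
    mean +/- SD and sample sizes of two groups are available.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("pooled_t_summary: need n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise ParameterError("pooled_t_summary: negative SD")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        if m1 == m2:
            return 0.0, df
        raise ParameterError("pooled_t_summary: zero pooled variance with unequal means")
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), df


def comparison_family_size(
    n_subjects: int, comparisons_per_measure: int, n_measures: int
) -> int:
    """Size of a planned within-subject multiple-comparison family.

    E.g. a cohort tested Pre-vs-Post_Early and Pre-vs-Post_Late on two
    measures contributes n_subjects * 2 * 2 tests to the BH family.
    """
    if min(n_subjects, comparisons_per_measure, n_measures) < 0:
        raise ParameterError("family dimensions must be non-negative")
    return n_subjects * comparisons_per_measure * n_measures
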