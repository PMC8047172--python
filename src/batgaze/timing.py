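"""Inter-pulse-interval extraction and sonar-sound-group classification.

A sonar sound group (SSG) is a run of two or more calls whose internal
intervals are short and mutually stable, flanked on both sides by longer
intervals.  Because published criteria vary between laboratories, all
thresholds are first-class parameters (:class:`SSGParams`) and every
reported proportion should cite the parameter set used.

Classification rule: a run of consecutive calls forms one group iff

(a) every within-run IPI is at most ``max_group_ipi_ms``;
(b) within-run IPIs are mutually stable (max - min at most ``stability_tol_ms``);
(c) both flanking IPIs are at least ``flank_ratio`` times the mean
    within-run IPI, where a sequence edge counts as a satisfied flank —
    but at least one flank must be a *real* interval satisfying the ratio
    (grouping requires temporal contrast: a perfectly uniform sequence has
    no groups).

Maximal admissible runs are selected greedily from the start of the
sequence; remaining calls are singletons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SSGParams", "IPIRecord", "SSGLabel",
    "compute_ipis", "classify_ssgs", "ssg_proportions", "fingerprint",
    "enumerate_ssgs_bruteforce",
]


@dataclass(frozen=True)
class SSGParams:
    """SSG classification thresholds.

    ``max_group_ipi_ms`` defaults to 50 ms, the conventional long/short IPI
    split for big brown bats in clutter.
    """

    max_group_ipi_ms: float = 50.0
    flank_ratio: float = 1.2
    stability_tol_ms: float = 5.0


@dataclass(frozen=True)
class IPIRecord:
    """Intervals around one call (milliseconds; None at sequence edges)."""

    call_index: int
    pre_ipi_ms: float | None
    post_ipi_ms: float | None


@dataclass(frozen=True)
class SSGLabel:
    """One group in the partition of a call sequence."""

    group_id: int
    group_size: int
    member_call_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.group_size != len(self.member_call_indices) or self.group_size < 1:
            raise ValueError("group size must match member count and be >= 1")


def compute_ipis(emission_times_s) -> list[IPIRecord]:
    """Pre- and post-intervals (ms) for an ordered emission-time sequence."""
    t = np.asarray(emission_times_s, float)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise ValueError("emission times must be strictly increasing")
    ipis = np.diff(t) * 1000.0
    out = []
    for i in range(len(t)):
        out.append(IPIRecord(
            call_index=i,
            pre_ipi_ms=float(ipis[i - 1]) if i > 0 else None,
            post_ipi_ms=float(ipis[i]) if i < len(t) - 1 else None,
        ))
    return out


def _admissible(ipis: np.ndarray, i: int, j: int, p: SSGParams) -> bool:
    """Is the run of calls i..j (inclusive, j > i) one admissible group?

    ``ipis[k]`` is the interval between calls k and k+1.
    """
    within = ipis[i:j]
    if np.any(within > p.max_group_ipi_ms):
        return False
    if within.max() - within.min() > p.stability_tol_ms:
        return False
    mean_w = float(within.mean())
    left_edge = i == 0
    right_edge = j == len(ipis)
    left_ok = left_edge or ipis[i - 1] >= p.flank_ratio * mean_w
    right_ok = right_edge or ipis[j] >= p.flank_ratio * mean_w
    if not (left_ok and right_ok):
        return False
    # contrast requirement: at least one flank must be a real long interval
    real_left = (not left_edge) and ipis[i - 1] >= p.flank_ratio * mean_w
    real_right = (not right_edge) and ipis[j] >= p.flank_ratio * mean_w
    return real_left or real_right


def classify_ssgs(ipis: list[IPIRecord] | np.ndarray,
                  params: SSGParams = SSGParams()) -> list[SSGLabel]:
    """Partition a call sequence into sonar sound groups and singletons.

    Scans left to right, at each call taking the longest admissible run
    starting there (see module docstring for the admissibility rule);
    calls in no admissible run are singletons.
    """
    if isinstance(ipis, (list, tuple)) and ipis and isinstance(ipis[0], IPIRecord):
        seq = np.array([r.post_ipi_ms for r in ipis[:-1]], float) if len(ipis) > 1 \
            else np.array([])
        n = len(ipis)
    else:
        seq = np.asarray(ipis, float)    # raw interval sequence
        n = len(seq) + 1
    labels: list[SSGLabel] = []
    gid = 0
    i = 0
    while i < n:
        # extend the run incrementally: clauses (a) and (b) are monotone in
        # the run length, so stop growing at the first violation; clause (c)
        # is checked per candidate end and the longest admissible end wins
        best_j = None
        w_max = -np.inf
        w_min = np.inf
        w_sum = 0.0
        for j in range(i + 1, n):
            w = seq[j - 1]
            if w > params.max_group_ipi_ms:
                break
            w_max, w_min = max(w_max, w), min(w_min, w)
            if w_max - w_min > params.stability_tol_ms:
                break
            w_sum += w
            if _flanks_ok(seq, i, j, w_sum / (j - i), params):
                best_j = j
        if best_j is None:
            labels.append(SSGLabel(gid, 1, (i,)))
            i += 1
        else:
            members = tuple(range(i, best_j + 1))
            labels.append(SSGLabel(gid, len(members), members))
            i = best_j + 1
        gid += 1
    return labels


def _flanks_ok(seq, i, j, mean_w, p: SSGParams) -> bool:
    left_edge = i == 0
    right_edge = j == len(seq)
    left_real = (not left_edge) and seq[i - 1] >= p.flank_ratio * mean_w
    right_real = (not right_edge) and seq[j] >= p.flank_ratio * mean_w
    left_ok = left_edge or left_real
    right_ok = right_edge or right_real
    return left_ok and right_ok and (left_real or right_real)


def enumerate_ssgs_bruteforce(interval_ms, params: SSGParams = SSGParams()) -> list[tuple[int, ...]]:
    """Independent brute-force reference partition (short sequences only).

    Enumerates *every* candidate run by exhaustive double loop, tests the
    admissibility clauses literally, then walks the sequence selecting the
    longest admissible run at each position.  O(n^3); intended for
    sequences of at most a dozen calls in oracle tests.
    """
    seq = np.asarray(interval_ms, float)
    n = len(seq) + 1
    admissible = set()
    for i in range(n):
        for j in range(i + 1, n):
            within = seq[i:j]
            if any(w > params.max_group_ipi_ms for w in within):
                continue
            if max(within) - min(within) > params.stability_tol_ms:
                continue
            mw = sum(within) / len(within)
            lf = None if i == 0 else seq[i - 1]
            rf = None if j == n - 1 else seq[j]
            ok_l = lf is None or lf >= params.flank_ratio * mw
            ok_r = rf is None or rf >= params.flank_ratio * mw
            contrast = (lf is not None and lf >= params.flank_ratio * mw) or \
                       (rf is not None and rf >= params.flank_ratio * mw)
            if ok_l and ok_r and contrast:
                admissible.add((i, j))
    out = []
    i = 0
    while i < n:
        ends = [j for (a, j) in admissible if a == i]
        if ends:
            j = max(ends)
            out.append(tuple(range(i, j + 1)))
            i = j + 1
        else:
            out.append((i,))
            i += 1
    return out


def ssg_proportions(labels: list[SSGLabel], max_size: int = 8) -> pd.Series:
    """Proportion of *calls* (not groups) in each group-size class.

    Sizes of ``max_size`` and above are pooled into the top class (``"8+"``
    by default).  Proportions sum to 1.
    """
    if not labels:
        raise ValueError("no labels")
    n_calls = sum(l.group_size for l in labels)
    counts = np.zeros(max_size)
    for l in labels:
        counts[min(l.group_size, max_size) - 1] += l.group_size
    props = counts / n_calls
    index = [str(s) for s in range(1, max_size)] + [f"{max_size}+"]
    return pd.Series(props, index=index, name="proportion_of_calls")


def grouped_vs_single_counts(labels: list[SSGLabel]) -> tuple[int, int]:
    """(calls in groups of >= 2, single calls) — input to the SSG chi-square."""
    grouped = sum(l.group_size for l in labels if l.group_size >= 2)
    single = sum(1 for l in labels if l.group_size == 1)
    return grouped, single


def fingerprint(ipis: list[IPIRecord], bins=None, max_ipi_ms: float = 120.0,
                diagonal_threshold_ms: float = 5.0):
    """Joint (pre-IPI, post-IPI) distribution of interior calls.

    Returns ``(hist, pre_edges, post_edges, ssg_presence_index)``: a 2-D
    histogram over the pre/post plane, and the fraction of interior calls
    with ``|pre - post| > diagonal_threshold_ms`` — mass off the pre=post
    diagonal, an algorithm-free index that sound groups are present.
    """
    pairs = np.array([(r.pre_ipi_ms, r.post_ipi_ms) for r in ipis
                      if r.pre_ipi_ms is not None and r.post_ipi_ms is not None])
    if len(pairs) == 0:
        raise ValueError("need at least one call with both intervals")
    if bins is None:
        bins = np.arange(0.0, max_ipi_ms + 2.0, 2.0)
    hist, pre_edges, post_edges = np.histogram2d(pairs[:, 0], pairs[:, 1],
                                                 bins=[bins, bins])
    off = np.abs(pairs[:, 0] - pairs[:, 1]) > diagonal_threshold_ms
    return hist, pre_edges, post_edges, float(np.mean(off))
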