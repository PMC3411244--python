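"""Sliding-window diversity scan with the missing-data heuristic.

Each window of the query's forward strand (together with its reverse
complement) is profiled against the full doubled subject, and the
maximum-likelihood estimate of pi is computed from that window's shustring
histogram.  Windows that lack a full homolog in the subject accumulate an
excess of short random shustrings and would be assigned a spuriously high
diversity; such windows are detected by counting new-shustring starts
(strict rises of the length profile) on the forward strand and flagging
the window as missing data when the count exceeds
``window_length * max_pi``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .index import (
    SequencePool,
    ShustringHistogram,
    SubjectIndex,
    count_new_shustrings,
)
from .model import estimate_pi_d, estimate_pi_m
from .simulate import SimPair

__all__ = ["WindowResult", "scan", "per_window_truth", "write_table", "window_starts"]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 10_000
DEFAULT_MAX_PI = 0.06


@dataclass
class WindowResult:
    """Estimates for one query window (0-based, half-open coordinates)."""

    window_start: int
    window_end: int
    pi_d: float  # nan when missing or not estimable
    pi_m: float
    peaks: int
    missing: bool
    converged: bool = True


def window_starts(length: int, window: int, step: int) -> range:
    """Start coordinates 0, step, 2*step, ... of fully contained windows."""
    if window > length:
        raise ValueError(f"window ({window}) exceeds sequence length ({length})")
    if step < 1:
        raise ValueError("step must be >= 1")
    return range(0, length - window + 1, step)


def scan(
    query: SequencePool,
    subject: SequencePool | SubjectIndex,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    max_pi: float = DEFAULT_MAX_PI,
    p: float | None = None,
    min_total: int = 100,
) -> list[WindowResult]:
    """Estimate pi in sliding windows of the query against the subject.

    Windows are placed on the query's forward strand at multiples of
    ``step`` from coordinate 0; only fully contained windows are emitted.
    Each window is strand-doubled before profiling, so the likelihood sees
    ``2 * window`` positions with ``ell_Q = window``.  New-shustring
    starts are counted on the forward half only; a window with more than
    ``window * max_pi`` of them is reported missing (``pi_d`` = NaN).

    ``p`` (half GC-content of the background model) defaults to half the
    subject's observed GC fraction.
    """
    index = subject if isinstance(subject, SubjectIndex) else SubjectIndex(subject)
    sub_pool = index.subject
    if p is None:
        p = sub_pool.gc_content / 2.0
    n_forward = query.half_length
    if window > n_forward:
        raise ValueError(f"window ({window}) exceeds query length ({n_forward})")
    # one profile of the whole doubled query; windows are slices of it, so
    # shustrings may extend beyond the window's right edge into the rest of
    # the query (capping them there would mimic a contig border and bias
    # the estimates upward)
    full = index.profile(query.codes)
    lengths = full.lengths
    doubled = 2 * n_forward if query.strand_doubled else n_forward
    threshold = window * max_pi
    results: list[WindowResult] = []
    for start in window_starts(n_forward, window, step):
        end = start + window
        fwd_lengths = lengths[start:end]
        if query.strand_doubled:
            # the reverse complement of query[start:end] occupies
            # [doubled - end, doubled - start) of the doubled sequence
            win_lengths = np.concatenate(
                [fwd_lengths, lengths[doubled - end : doubled - start]]
            )
        else:
            win_lengths = fwd_lengths
        peaks = count_new_shustrings(fwd_lengths)
        pi_m = estimate_pi_m(win_lengths)
        missing = peaks > threshold
        if missing:
            results.append(
                WindowResult(start, end, float("nan"), pi_m, peaks, True, False)
            )
            continue
        counts = np.bincount(win_lengths)
        hist = ShustringHistogram(
            counts=counts, xi=int(win_lengths.max()), total=int(len(win_lengths))
        )
        est = estimate_pi_d(
            hist, p=p, ell_S=sub_pool.half_length, ell_Q=window, min_total=min_total
        )
        results.append(
            WindowResult(start, end, est.pi_hat, pi_m, peaks, False, est.converged)
        )
    n_missing = sum(r.missing for r in results)
    logger.info("scanned %d windows, %d flagged missing", len(results), n_missing)
    return results


def per_window_truth(sim_pair: SimPair, window: int, step: int) -> np.ndarray:
    """Alignment-based mismatch fraction on the same window grid as scan."""
    mask = sim_pair.mismatch_mask.astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(mask)])
    starts = np.asarray(window_starts(sim_pair.L, window, step))
    return (cum[starts + window] - cum[starts]) / float(window)


def _fmt(value: float) -> str:
    if math.isnan(value):
        return "NA"
    return f"{value:.6g}"


def write_table(results: list[WindowResult], handle) -> None:
    """Write window results as a tab-delimited table.

    Coordinates are reported 1-based inclusive; missing windows carry NA
    in the pi_d column and 1 in the missing column.
    """
    handle.write("#window_start\twindow_end\tpi_d\tpi_m\tpeaks\tmissing\n")
    for r in results:
        handle.write(
            f"{r.window_start + 1}\t{r.window_end}\t{_fmt(r.pi_d)}\t"
            f"{_fmt(r.pi_m)}\t{r.peaks}\t{int(r.missing)}\n"
        )
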