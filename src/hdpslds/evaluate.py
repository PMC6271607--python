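"""Segmentation scoring: label alignment, Hamming distance, Match Score.

Inferred mode labels are arbitrary, so scoring first finds the injective
estimated-label -> true-label map minimizing mismatches (Hungarian
assignment on the negated confusion matrix; surplus estimated labels map
to a sink and count as errors wherever they occur).  The average Hamming
distance is the fraction of time points still mismatched after
alignment; Match Score = 1 - Hamming (1 = perfect segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

SINK = -1   # unmatched estimated labels map here (always a mismatch)


@dataclass
class MatchResult:
    hamming: float
    match_score: float
    permutation: Dict[int, int]       # estimated label -> true label (or SINK)
    confusion: np.ndarray             # true x estimated (aligned) counts
    true_labels: np.ndarray
    est_labels: np.ndarray


def align_labels(true_seq, est_seq) -> Dict[int, int]:
    """Injective map estimated -> true labels minimizing mismatches."""
    true_seq = np.asarray(true_seq)
    est_seq = np.asarray(est_seq)
    if true_seq.shape != est_seq.shape:
        raise ValueError("sequences must have equal length")
    t_vals = np.unique(true_seq)
    e_vals = np.unique(est_seq)
    agree = np.zeros((e_vals.size, t_vals.size))
    for i, e in enumerate(e_vals):
        me = est_seq == e
        for j, t in enumerate(t_vals):
            agree[i, j] = np.count_nonzero(me & (true_seq == t))
    # pad to square so surplus estimated labels can fall through to the sink
    n = max(e_vals.size, t_vals.size)
    cost = np.zeros((n, n))
    cost[:e_vals.size, :t_vals.size] = -agree
    row, col = linear_sum_assignment(cost)
    mapping = {}
    for r, c in zip(row, col):
        if r < e_vals.size:
            mapping[int(e_vals[r])] = int(t_vals[c]) if c < t_vals.size else SINK
    return mapping


def average_hamming(true_seq, est_seq) -> MatchResult:
    """Label-aligned average Hamming distance (0 = perfect, 1 = no match)."""
    true_seq = np.asarray(true_seq)
    est_seq = np.asarray(est_seq)
    if true_seq.shape != est_seq.shape:
        raise ValueError("sequences must have equal length")
    mapping = align_labels(true_seq, est_seq)
    aligned = np.array([mapping[int(e)] for e in est_seq])
    mismatch = np.count_nonzero(aligned != true_seq)
    h = mismatch / true_seq.size
    t_vals = np.unique(true_seq)
    conf = np.zeros((t_vals.size, t_vals.size), dtype=np.int64)
    for j, t in enumerate(t_vals):
        sel = true_seq == t
        for j2, t2 in enumerate(t_vals):
            conf[j, j2] = np.count_nonzero(sel & (aligned == t2))
    return MatchResult(hamming=float(h), match_score=float(1.0 - h),
                       permutation=mapping, confusion=conf,
                       true_labels=true_seq, est_labels=aligned)


def conditional_assignment_matrix(results: Sequence[MatchResult], labels=None):
    """Empirical P(aligned estimate = j | true state = k) over an ensemble.

    Rows follow ``labels`` (default: union of true labels seen); a true
    state absent from the ensemble yields a row of NaNs flagged in the
    returned mask rather than propagating silently.
    """
    if len(results) == 0:
        raise ValueError("need at least one scored trajectory")
    if labels is None:
        labels = np.unique(np.concatenate([r.true_labels for r in results]))
    labels = np.asarray(labels)
    K = labels.size
    counts = np.zeros((K, K + 1))   # extra column collects sink/unseen assignments
    col_of = {int(l): i for i, l in enumerate(labels)}
    for r in results:
        for t, e in zip(r.true_labels, r.est_labels):
            counts[col_of[int(t)], col_of.get(int(e), K)] += 1
    row_tot = counts.sum(axis=1)
    defined = row_tot > 0
    P = np.full((K, K + 1), np.nan)
    P[defined] = counts[defined] / row_tot[defined, None]
    return P[:, :K], defined, labels


def ensemble_summary(results: Sequence[MatchResult]):
    """Mean Hamming distance over trajectories with its empirical SE.

    Returns (mean, se, sd, n); se = sd / sqrt(n) — the sd itself is also
    returned since printed '(x.xx)' dispersion conventions vary.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 trajectories to summarize")
    h = np.array([r.hamming for r in results])
    n = h.size
    sd = float(h.std(ddof=1))
    return float(h.mean()), sd / np.sqrt(n), sd, n
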