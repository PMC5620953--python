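"""Feasibility automaton over activity tags and confidence-gated correction.

A prediction sequence produced window-by-window can contain successions that
are physically impossible (a ``stand2lie`` directly after ``sit``, say).  The
logic filter encodes the allowed successions as a boolean adjacency matrix
``theta`` over the ten tags and, whenever a prediction arrives with fused
confidence below a calibrated bound ``delta``, checks the recent retained
history for a valid path; an infeasible low-confidence prediction is replaced
by the previously retained tag (carry-forward).

The confidence bound is calibrated on held-out labelled predictions as the
ROC operating point closest to the ideal corner (0, 1):

    delta = argmin_i sqrt(ROCx(i)^2 + (1 - ROCy(i))^2)

where the ROC treats the fused confidence as a score for "prediction is
correct".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .tags import (
    ActivityTag,
    STATIC_TAGS,
    TAG_INDEX,
    TAG_ORDER,
    TRANSITION_ENDPOINTS,
    TRANSITION_TAGS,
    as_tag,
)

__all__ = [
    "default_adjacency",
    "allowed",
    "is_feasible_sequence",
    "save_adjacency",
    "load_adjacency",
    "ThresholdCalibration",
    "confidence_threshold",
    "apply_filter",
]


# ---------------------------------------------------------------------------
# Adjacency matrix
# ---------------------------------------------------------------------------

def default_adjacency() -> np.ndarray:
    """The default 10x10 allowed-succession matrix.

    ``theta[a, b]`` is True iff tag ``a`` (row, predecessor, canonical tag
    order) may immediately precede tag ``b``.  Rules:

    * every tag may follow itself (activities span several windows);
    * a static posture may be followed by the transitions departing it
      (stand additionally by walk);
    * a transition may be followed by its destination posture and by the
      transitions departing that destination (plus walk when the
      destination is stand);
    * walking may be followed by stand and by the transitions departing
      stand — the walking exception: no intermediate transition tag exists
      for walk<->stand.
    """
    n = len(TAG_ORDER)
    theta = np.zeros((n, n), dtype=bool)

    def allow(a: ActivityTag, b: ActivityTag) -> None:
        theta[TAG_INDEX[a], TAG_INDEX[b]] = True

    departures: dict[ActivityTag, list[ActivityTag]] = {p: [] for p in STATIC_TAGS}
    for tr, (src, _dst) in TRANSITION_ENDPOINTS.items():
        departures[src].append(tr)

    for t in TAG_ORDER:
        allow(t, t)
    for posture in STATIC_TAGS:
        for tr in departures[posture]:
            allow(posture, tr)
    for tr, (_src, dst) in TRANSITION_ENDPOINTS.items():
        allow(tr, dst)
        for nxt in departures[dst]:
            allow(tr, nxt)
        if dst is ActivityTag.STAND:
            allow(tr, ActivityTag.WALK)
    # walking exception: direct walk <-> stand without a transition tag
    allow(ActivityTag.STAND, ActivityTag.WALK)
    allow(ActivityTag.WALK, ActivityTag.STAND)
    for tr in departures[ActivityTag.STAND]:
        allow(ActivityTag.WALK, tr)
    return theta


def allowed(theta: np.ndarray, a: "ActivityTag | str", b: "ActivityTag | str") -> bool:
    """True iff ``a`` may immediately precede ``b`` under ``theta``."""
    return bool(theta[TAG_INDEX[as_tag(a)], TAG_INDEX[as_tag(b)]])


def is_feasible_sequence(tags: Iterable["ActivityTag | str"], theta: np.ndarray | None = None) -> bool:
    """True iff every consecutive pair in ``tags`` is theta-allowed."""
    if theta is None:
        theta = default_adjacency()
    seq = [as_tag(t) for t in tags]
    return all(allowed(theta, a, b) for a, b in itertools.pairwise(seq))


def save_adjacency(theta: np.ndarray, path) -> None:
    """Write theta as a CSV table (rows = predecessor, columns = successor, 0/1)."""
    names = [t.value for t in TAG_ORDER]
    pd.DataFrame(theta.astype(int), index=names, columns=names).to_csv(path, index_label="tag")


def load_adjacency(path) -> np.ndarray:
    """Read a theta override table written by :func:`save_adjacency`."""
    df = pd.read_csv(path, index_col=0)
    names = [t.value for t in TAG_ORDER]
    theta = df.loc[names, names].to_numpy().astype(bool)
    _validate_adjacency(theta)
    return theta


def _validate_adjacency(theta: np.ndarray) -> None:
    if theta.shape != (10, 10):
        raise ValueError(f"adjacency matrix must be 10x10, got {theta.shape}")
    if not theta.any(axis=1).all():
        bad = TAG_ORDER[int(np.flatnonzero(~theta.any(axis=1))[0])]
        raise ValueError(f"tag {bad.value!r} has no allowed successor")
    if not theta.any(axis=0).all():
        bad = TAG_ORDER[int(np.flatnonzero(~theta.any(axis=0))[0])]
        raise ValueError(f"tag {bad.value!r} has no allowed predecessor")


# ---------------------------------------------------------------------------
# Confidence-bound calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdCalibration:
    """Calibrated confidence bound with its ROC curve.

    ``delta`` is the threshold at the ROC point nearest (0, 1); predictions
    with fused confidence >= delta bypass the logic filter.
    """

    delta: float
    distance: float
    roc_x: np.ndarray = field(repr=False)
    roc_y: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)


def confidence_threshold(
    confidences: Sequence[float], correct: Sequence[bool]
) -> ThresholdCalibration:
    """Pick the confidence bound delta from labelled held-out predictions.

    Builds the ROC of confidence as a score for prediction correctness and
    returns the threshold minimizing the Euclidean distance to the ideal
    corner (0, 1).  Ties are broken toward the higher threshold (the more
    conservative bound, triggering the filter more often).
    """
    conf = np.asarray(confidences, dtype=float)
    corr = np.asarray(correct, dtype=bool)
    if corr.all() or (~corr).all():
        raise ValueError("confidence_threshold needs both correct and incorrect predictions")
    fpr, tpr, thr = roc_curve(corr.astype(int), conf)
    # roc_curve's first threshold is +inf (no positives predicted); clamp it to
    # the maximum observed confidence so delta is an actual operating point.
    thr = thr.copy()
    thr[0] = min(thr[0], conf.max())
    dist = np.sqrt(fpr**2 + (1.0 - tpr) ** 2)
    best = dist.min()
    # ties toward the higher threshold = earliest index on the curve
    idx = int(np.flatnonzero(np.isclose(dist, best))[0])
    return ThresholdCalibration(
        delta=float(thr[idx]), distance=float(best), roc_x=fpr, roc_y=tpr, thresholds=thr
    )


# ---------------------------------------------------------------------------
# State-machine correction
# ---------------------------------------------------------------------------

def apply_filter(
    tags: Sequence["ActivityTag | str"],
    confidences: Sequence[float],
    theta: np.ndarray | None = None,
    delta: float = 0.5,
    order: int = 1,
    literal_indexing: bool = False,
) -> tuple[list[ActivityTag], np.ndarray]:
    """Correct infeasible low-confidence predictions in a tag sequence.

    Scans left to right over the retained labels.  A prediction at position t
    is examined only when its fused confidence is below ``delta`` AND its tag
    differs from the previously retained tag.  It is kept iff

        beta = [exists i in 1..order: theta(retained[t-1-i] -> retained[t-1])]
               and theta(retained[t-1] -> candidate[t]),

    i.e. some recent retained predecessor validly leads into the previous
    retained tag, and the previous retained tag validly leads into the
    candidate.  Otherwise the candidate is replaced by the previously
    retained label (carry-forward).  ``order`` is truncated to the available
    history; with no history at all the predecessor check is vacuously true.

    Returns ``(corrected tags, corrected mask)``.  Predictions with
    confidence >= delta are never altered.

    ``literal_indexing=True`` switches to the variant where the gate fires at
    t but the correction is applied to position t-1 (replacing it with the
    retained label at t-2).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    seq = [as_tag(t) for t in tags]
    if len(seq) < 2:
        raise ValueError("apply_filter needs a sequence of length >= 2")
    conf = np.asarray(confidences, dtype=float)
    if conf.shape[0] != len(seq):
        raise ValueError("tags and confidences must have equal length")
    if theta is None:
        theta = default_adjacency()

    if literal_indexing:
        return _apply_filter_literal(seq, conf, theta, delta, order)

    retained: list[ActivityTag] = [seq[0]]
    changed = np.zeros(len(seq), dtype=bool)
    for t in range(1, len(seq)):
        cand = seq[t]
        prev = retained[t - 1]
        if conf[t] >= delta or cand is prev:
            retained.append(cand)
            continue
        lo = max(0, t - 1 - order)
        history = retained[lo : t - 1]
        prev_ok = True if not history else any(allowed(theta, h, prev) for h in history)
        beta = prev_ok and allowed(theta, prev, cand)
        if beta:
            retained.append(cand)
        else:
            retained.append(prev)
            changed[t] = True
    return retained, changed


def _apply_filter_literal(
    seq: list[ActivityTag], conf: np.ndarray, theta: np.ndarray, delta: float, order: int
) -> tuple[list[ActivityTag], np.ndarray]:
    """Literal-index variant: the gate at t corrects position t-1."""
    out = list(seq)
    changed = np.zeros(len(seq), dtype=bool)
    for t in range(1, len(seq)):
        if out[t - 1] is out[t] or conf[t - 1] >= delta:
            continue
        lo = max(0, t - 1 - order)
        history = out[lo : t - 1]
        prev_ok = True if not history else any(allowed(theta, h, out[t - 1]) for h in history)
        beta = prev_ok and allowed(theta, out[t - 1], out[t])
        if not beta:
            out[t - 1] = out[t - 2] if t >= 2 else out[t - 1]
            changed[t - 1] = t >= 2 and out[t - 1] is not seq[t - 1]
    return out, changed
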