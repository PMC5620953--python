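"""Per-window signal descriptors and SFFS wrapper feature selection.

Each 3-second window exposes six channels — three body-acceleration axes
and three orientation angles.  For every channel, 14 descriptors are
computed (mean, variance, RMS, peak/trough statistics, zero crossings,
coefficient of variation, IQR, entropy, power, dominant frequency and the
power around it); for each of the two signal types (body acceleration,
orientation) the 3 pairwise axis cross-correlations plus mean/variance of
the signal magnitude area and of the signal magnitude vector are added.
That is 6*14 + 2*7 = 98 descriptors per window.

Implementation conventions (the descriptor list fixes the *what*, not the
*how*):

* peaks/troughs are local extrema with prominence >= 0.05 channel units;
* entropy is Shannon entropy (bits) of a 16-bin histogram of the channel;
* coefficient of variation is std/|mean|, 0 when |mean| < 1e-9;
* power around the dominant frequency integrates the periodogram over a
  +-0.5 Hz band;
* cross-correlation is the Pearson correlation at lag 0;
* signal magnitude area statistics are taken across the three 1-s thirds
  of the window.

Feature selection is classic sequential forward floating selection (SFFS):
greedy inclusion of the best-improving descriptor followed by conditional
exclusions while they improve the criterion, which is stratified k-fold
accuracy of a configurable classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .preprocess import SignalFrame, Window, window as cut_windows
from .synthdata import Session
from . import preprocess as _pp

logger = logging.getLogger(__name__)

__all__ = [
    "DESCRIPTOR_NAMES",
    "compute_descriptors",
    "feature_table",
    "extract_session_features",
    "cohort_feature_table",
    "FeatureSubset",
    "sffs_select",
]

_PEAK_PROMINENCE = 0.05
_ENTROPY_BINS = 16
_CHANNEL_STATS = [
    "mean", "var", "rms", "n_peaks", "peak_trough_range", "n_troughs",
    "peak_trough_dist", "zero_cross", "cv", "iqr", "entropy", "power",
    "dom_freq", "dom_band_power",
]
_AXES = ["x", "y", "z"]
_TYPES = ["bacc", "orient"]
_PAIRS = [("x", "y"), ("x", "z"), ("y", "z")]


def _build_names() -> list[str]:
    names = []
    for typ in _TYPES:
        for ax in _AXES:
            names += [f"{typ}_{ax}_{st}" for st in _CHANNEL_STATS]
    for typ in _TYPES:
        names += [f"{typ}_xcorr_{a}{b}" for a, b in _PAIRS]
        names += [f"{typ}_sma_mean", f"{typ}_sma_var", f"{typ}_smv_mean", f"{typ}_smv_var"]
    return names


#: The 98 descriptor names, in computation order.
DESCRIPTOR_NAMES: list[str] = _build_names()


def _channel_descriptors(x: np.ndarray, fs: float) -> list[float]:
    mean = float(x.mean())
    var = float(x.var())
    rms = float(np.sqrt(np.mean(x**2)))
    peaks, _ = sps.find_peaks(x, prominence=_PEAK_PROMINENCE)
    troughs, _ = sps.find_peaks(-x, prominence=_PEAK_PROMINENCE)
    if len(peaks):
        ptr = float(x[peaks].max() - x[peaks].min())
    else:
        ptr = 0.0
    if len(peaks) and len(troughs):
        # mean gap (samples) between consecutive peak/trough extrema
        extrema = np.sort(np.concatenate([peaks, troughs]))
        ptd = float(np.mean(np.diff(extrema))) if len(extrema) > 1 else 0.0
    else:
        ptd = 0.0
    centered = x - mean
    zc = int(np.sum(np.signbit(centered[1:]) != np.signbit(centered[:-1])))
    std = float(x.std())
    cv = std / abs(mean) if abs(mean) >= 1e-9 else 0.0
    iqr = float(stats.iqr(x))
    hist, _ = np.histogram(x, bins=_ENTROPY_BINS)
    p = hist / hist.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    power = float(np.mean(x**2))
    freqs, pxx = sps.periodogram(x, fs=fs, detrend="constant")
    k = int(np.argmax(pxx))
    dom_freq = float(freqs[k])
    band = (freqs >= dom_freq - 0.5) & (freqs <= dom_freq + 0.5)
    dom_band_power = float(np.trapezoid(pxx[band], freqs[band]))
    return [mean, var, rms, float(len(peaks)), ptr, float(len(troughs)),
            ptd, float(zc), cv, iqr, entropy, power, dom_freq, dom_band_power]


def _pearson0(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _type_descriptors(mat: np.ndarray, fs: float) -> list[float]:
    out = [_pearson0(mat[:, i], mat[:, j])
           for (i, j) in ((0, 1), (0, 2), (1, 2))]
    thirds = np.array_split(np.abs(mat).sum(axis=1), 3)
    sma = np.array([t.mean() for t in thirds])
    smv = np.linalg.norm(mat, axis=1)
    out += [float(sma.mean()), float(sma.var()), float(smv.mean()), float(smv.var())]
    return out


def compute_descriptors(win: Window) -> np.ndarray:
    """Compute the 98-descriptor vector for one window.

    Raises if the descriptor vector contains non-finite values.
    """
    fs = win.frame.fs
    bacc, orient = win.body_acc, win.orientation
    if bacc.shape[1] != 3 or orient.shape[1] != 3:
        raise ValueError("window must expose 3 body-acc and 3 orientation channels")
    vals: list[float] = []
    for mat in (bacc, orient):
        for ax in range(3):
            vals += _channel_descriptors(mat[:, ax], fs)
    for mat in (bacc, orient):
        vals += _type_descriptors(mat, fs)
    x = np.asarray(vals, dtype=float)
    if not np.isfinite(x).all():
        bad = [DESCRIPTOR_NAMES[i] for i in np.flatnonzero(~np.isfinite(x))]
        raise FloatingPointError(f"non-finite descriptors: {bad}")
    return x


def feature_table(
    frame: SignalFrame,
    windows: Sequence[Window] | None = None,
    subject_id: str = "",
) -> pd.DataFrame:
    """One row per window: subject, start_s, end_s, tag, 98 descriptors."""
    if windows is None:
        windows = cut_windows(frame)
    rows = []
    for w in windows:
        rows.append(
            {
                "subject": subject_id,
                "start_s": w.start_s,
                "end_s": w.end_s,
                "tag": w.tag.value if w.tag is not None else "",
                **dict(zip(DESCRIPTOR_NAMES, compute_descriptors(w))),
            }
        )
    return pd.DataFrame(rows)


def extract_session_features(session: Session, **preprocess_kwargs) -> pd.DataFrame:
    """Preprocess a synthetic session and compute its labelled feature table."""
    frame = _pp.preprocess(session.acc, session.fs, time=session.time, **preprocess_kwargs)
    windows = cut_windows(frame)
    for w, tag in zip(windows, session.window_tags):
        w.tag = tag
    df = feature_table(frame, windows, subject_id=session.subject_id)
    df.insert(1, "group", session.profile.group)
    return df


def cohort_feature_table(cohort, **preprocess_kwargs) -> pd.DataFrame:
    """Feature tables of every session in a cohort, concatenated."""
    return pd.concat(
        [extract_session_features(s, **preprocess_kwargs) for s in cohort],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# SFFS
# ---------------------------------------------------------------------------

@dataclass
class FeatureSubset:
    """An ordered descriptor-index subset with its criterion value."""

    indices: list[int]
    criterion: float
    history: list[tuple[tuple[int, ...], float]] = field(default_factory=list, repr=False)


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    estimator: BaseEstimator,
    cv_folds: int,
    seed: int,
) -> float:
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return float(cross_val_score(clone(estimator), X, y, cv=cv, error_score=0.0).mean())


def _nb_cv_accuracy(X: np.ndarray, y: np.ndarray, splits, classes: np.ndarray) -> float:
    """Stratified-CV accuracy of a diagonal Gaussian naive Bayes classifier.

    Vectorized re-implementation used as the default SFFS criterion: the
    wrapper evaluates thousands of candidate subsets, and per-call
    estimator overhead would dominate the selection otherwise.
    """
    var_floor = 1e-9 * max(float(X.var(axis=0).max()), 1e-9)
    accs = []
    for tr, te in splits:
        Xtr, ytr, Xte = X[tr], y[tr], X[te]
        ll = np.empty((len(te), len(classes)))
        for ci, c in enumerate(classes):
            Xc = Xtr[ytr == c]
            mu = Xc.mean(axis=0)
            var = Xc.var(axis=0) + var_floor
            ll[:, ci] = (
                -0.5 * (np.log(2 * np.pi * var) + (Xte - mu) ** 2 / var).sum(axis=1)
                + np.log(len(Xc) / len(tr))
            )
        accs.append(float(np.mean(classes[np.argmax(ll, axis=1)] == y[te])))
    return float(np.mean(accs))


def sffs_select(
    X: np.ndarray,
    y: np.ndarray,
    estimator: BaseEstimator | None = None,
    max_features: int = 10,
    cv_folds: int = 3,
    rng_seed: int = 0,
    floating: bool = True,
    random_start: bool = True,
    candidates: Sequence[int] | None = None,
    criterion: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> FeatureSubset:
    """Sequential forward floating selection of descriptor columns.

    Starts from a single randomly drawn descriptor (``random_start=False``
    starts from the single best), then repeats conditional inclusion of the
    best-improving descriptor followed by conditional exclusions while they
    improve the criterion.  Terminates at ``max_features`` or when no
    inclusion improves.  Returns the best subset observed; criterion ties
    are broken toward the lowest descriptor index.

    ``criterion(X_subset, y) -> float`` overrides the default stratified
    ``cv_folds``-fold accuracy of ``estimator`` (Gaussian naive Bayes when
    not given).  ``candidates`` restricts the searched column pool.
    ``floating=False`` disables the exclusion step (plain SFS).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("sffs_select needs at least 2 classes")
    m = X.shape[1]
    if max_features > m:
        raise ValueError("max_features exceeds the number of descriptors")
    pool = list(range(m)) if candidates is None else sorted(set(candidates))
    rng = np.random.default_rng(rng_seed)
    if criterion is None:
        cv_seed = int(rng.integers(2**31 - 1))
        _, counts = np.unique(y, return_counts=True)
        cv_folds = max(2, min(cv_folds, int(counts.min())))
        if estimator is None:
            # fast path: vectorized Gaussian NB on fixed stratified splits
            cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=cv_seed)
            splits = list(cv.split(X, y))
            classes = np.unique(y)

            def criterion(Xs: np.ndarray, ys: np.ndarray) -> float:
                return _nb_cv_accuracy(Xs, ys, splits, classes)

        else:

            def criterion(Xs: np.ndarray, ys: np.ndarray) -> float:
                return _cv_accuracy(Xs, ys, estimator, cv_folds, cv_seed)

    def score(idx: Sequence[int]) -> float:
        return criterion(X[:, list(idx)], y)

    singles = {j: score([j]) for j in pool}
    if random_start and max_features > 1:
        current = [int(rng.choice(pool))]
    else:
        best_j = max(sorted(singles), key=lambda j: singles[j])
        current = [best_j]
    best_by_size: dict[int, tuple[float, list[int]]] = {1: (singles[current[0]], list(current))}
    history = [(tuple(current), singles[current[0]])]

    while len(current) < max_features:
        crit_now = best_by_size[len(current)][0]
        remaining = [j for j in pool if j not in current]
        if not remaining:
            break
        scores = {j: score(current + [j]) for j in remaining}
        j_best = max(sorted(scores), key=lambda j: scores[j])
        if scores[j_best] <= crit_now:
            break  # no inclusion improves the criterion
        current = current + [j_best]
        best_by_size[len(current)] = (scores[j_best], list(current))
        history.append((tuple(current), scores[j_best]))
        # conditional exclusion: drop features while that improves the best
        # known subset of the smaller size
        while floating and len(current) > 2:
            excl = {j: score([i for i in current if i != j]) for j in current}
            j_worst = max(sorted(excl), key=lambda j: excl[j])
            size = len(current) - 1
            prev_best = best_by_size.get(size, (-np.inf, []))[0]
            if j_worst != current[-1] and excl[j_worst] > prev_best:
                current = [i for i in current if i != j_worst]
                best_by_size[size] = (excl[j_worst], list(current))
                history.append((tuple(current), excl[j_worst]))
            else:
                break

    crit_best, idx_best = max(
        best_by_size.values(), key=lambda t: (t[0], -len(t[1]))
    )
    return FeatureSubset(indices=list(idx_best), criterion=float(crit_best), history=history)
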