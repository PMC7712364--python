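"""RR-interval time features and SMOTE class balancing.

Six per-beat timing features complement the waveform: the intervals to
the previous and next R peak, a 10-second local mean interval, the
record-wide mean interval, and range-normalized versions of the pre/post
intervals that cancel each patient's baseline heart rate.  Minority
classes are then oversampled to the majority count by interpolating
between same-class nearest neighbors (SMOTE), applied to the
concatenated [beat waveform || time features] vector so synthetic beats
carry consistent timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

N_TIME_FEATURES = 6


class SmoteError(ValueError):
    pass


@dataclass
class RRFeatures:
    pre_rr: float        # seconds to the previous R peak
    post_rr: float       # seconds to the next R peak
    local_rr: float      # mean RR over the trailing 10 s window
    avg_rr: float        # mean RR over the whole record
    norm_pre_rr: float   # (pre_rr - mean pre_rr) / (max - min), per record
    norm_post_rr: float
    local_fallback: bool = False  # True when the 10 s window was empty

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pre_rr, self.post_rr, self.local_rr, self.avg_rr,
             self.norm_pre_rr, self.norm_post_rr],
            dtype=np.float64,
        )


def _normalize(values: np.ndarray) -> np.ndarray:
    """Range normalization (x - mean) / (max - min); degenerate range -> 0.

    A span at floating-point noise level (a metronomic rhythm whose
    intervals differ only in the last ulp) counts as degenerate.
    """
    span = float(values.max() - values.min())
    if span <= 1e-9 * max(1.0, float(np.abs(values).max())):
        return np.zeros_like(values)
    return (values - values.mean()) / span


def compute_rr_features(r_peaks: np.ndarray, fs: float,
                        local_window_s: float = 10.0) -> list[RRFeatures]:
    """Compute the six time features for every interior beat of a record.

    Returns one :class:`RRFeatures` per beat i with 1 <= i <= n-2, in
    beat order (matching :func:`ecgdann.preprocess.segment_beats`).
    The local mean uses RR intervals whose terminating R peak lies in
    (t_i - window, t_i]; if none land in the window (cannot happen for
    the beat's own pre-RR unless the window is tiny) it falls back to
    the record average and is flagged.
    """
    r = np.asarray(r_peaks, dtype=np.int64)
    if r.size < 3:
        raise ValueError("need >= 3 R peaks for interior beats")
    t = r / fs
    rr = np.diff(t)                      # rr[k] = interval ending at peak k+1
    pre = rr[:-1]                        # pre_rr of beat i = rr[i-1], i = 1..n-2
    post = rr[1:]                        # post_rr of beat i = rr[i]
    avg = float(rr.mean())
    norm_pre = _normalize(pre)
    norm_post = _normalize(post)
    out: list[RRFeatures] = []
    for k, i in enumerate(range(1, r.size - 1)):
        t_i = t[i]
        in_window = (t[1 : i + 1] > t_i - local_window_s) & (t[1 : i + 1] <= t_i)
        fallback = not np.any(in_window)
        local = avg if fallback else float(rr[:i][in_window].mean())
        out.append(
            RRFeatures(
                pre_rr=float(pre[k]),
                post_rr=float(post[k]),
                local_rr=local,
                avg_rr=avg,
                norm_pre_rr=float(norm_pre[k]),
                norm_post_rr=float(norm_post[k]),
                local_fallback=fallback,
            )
        )
    return out


@dataclass
class BalancedSet:
    """Class-balanced training matrix with provenance of synthetic rows."""

    beats: np.ndarray          # (n, D)
    features: np.ndarray       # (n, 6)
    labels: np.ndarray         # (n,) strings
    synthetic_mask: np.ndarray  # (n,) bool, True for SMOTE rows


def smote_balance(beats: np.ndarray, features: np.ndarray, labels: np.ndarray,
                  k: int = 5, seed: int = 0) -> BalancedSet:
    """Oversample every minority class to the majority count with SMOTE.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ U[0, 1]``,
    where ``x_nn`` is one of the ``k`` same-class nearest neighbors of a
    randomly chosen real minority row; interpolation acts on the
    concatenated [beat || features] vector.  Deterministic under ``seed``.
    """
    beats = np.asarray(beats, dtype=np.float64)
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if k < 1:
        raise SmoteError("k must be >= 1")
    if beats.shape[0] != features.shape[0] or beats.shape[0] != labels.shape[0]:
        raise ValueError("row-count mismatch between beats, features, labels")

    classes, counts = np.unique(labels, return_counts=True)
    majority = int(counts.max())
    rng = np.random.default_rng(seed)

    X = np.hstack([beats, features])
    new_rows: list[np.ndarray] = []
    new_labels: list[str] = []
    for cls, cnt in zip(classes, counts):
        need = majority - int(cnt)
        if need == 0:
            continue
        if cnt < 2:
            raise SmoteError(f"class {cls!r} has {cnt} sample(s); need >= 2")
        if k >= cnt:
            raise SmoteError(f"k={k} too large for class {cls!r} with {cnt} samples")
        Xc = X[labels == cls]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # column 0 is the point itself
        base = rng.integers(0, Xc.shape[0], size=need)
        pick = rng.integers(1, k + 1, size=need)
        u = rng.random(need)
        x = Xc[base]
        x_nn = Xc[idx[base, pick]]
        new_rows.append(x + u[:, None] * (x_nn - x))
        new_labels.extend([cls] * need)

    if new_rows:
        X_new = np.vstack(new_rows)
        X_all = np.vstack([X, X_new])
        labels_all = np.concatenate([labels, np.asarray(new_labels)])
        synth = np.concatenate(
            [np.zeros(X.shape[0], bool), np.ones(X_new.shape[0], bool)]
        )
    else:
        X_all, labels_all = X, labels
        synth = np.zeros(X.shape[0], bool)

    D = beats.shape[1]
    return BalancedSet(
        beats=X_all[:, :D],
        features=X_all[:, D:],
        labels=labels_all,
        synthetic_mask=synth,
    )
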