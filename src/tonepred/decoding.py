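"""Multiclass shrinkage-LDA time-generalization decoding.

Implements the three decoding schemes of the analysis:

* *sound-to-sound*: carrier-frequency decoding trained on random-sequence
  (RD) sounds, cross-validated within RD (5-fold x 5 repeats) or applied
  cross-condition to MM/MP/OR sounds without cross-validation;
* *sound-to-omission*: the RD-sound classifier applied to omission trials
  labelled by the tone that would have been presented;
* *entropy-level*: 4-class decoding of the sequence condition, 5x5 CV on
  sounds, and sound-trained / omission-tested without CV.

A classifier is fitted at every training time point on the sensor vector and
tested at every testing time point, yielding a train-time x test-time
accuracy map (chance 1/4).  Sounds preceded by an omission are discarded and
carrier-frequency decoding is N-1/N balanced: within each target class the
counts of the four previous-tone classes are equalised by subsampling, so the
previous trial carries no information about the current label.

The estimator follows a statsmodels-like Model/Results split:
``TimeGeneralizationDecoder(...).fit()`` returns a :class:`TimeGenResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf_shrinkage

from .simulate import EpochSet

CHANCE = 0.25


class InfeasibleBalancingError(ValueError):
    """An (class, previous-class) cell required by N-1/N balancing is empty."""


# ---------------------------------------------------------------------------
# shrinkage LDA
# ---------------------------------------------------------------------------

@dataclass
class ClassifierModel:
    """Fitted multiclass LDA: score_k(x) = x . W[:, k] + b[k].

    The pooled within-class covariance is shrunk toward a scaled identity,
    sigma = (1 - lam) * S_pooled + lam * (tr S / d) * I.  ``cov_x`` (the raw
    covariance of the training data) is retained for activation-pattern
    correction.
    """

    classes: np.ndarray
    weights: np.ndarray  # sensors x classes
    biases: np.ndarray  # classes
    means: np.ndarray  # classes x sensors
    cov_pooled: np.ndarray
    shrinkage: float
    cov_x: np.ndarray

    def scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.biases

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax; ties resolved toward the lowest class index
        return self.classes[np.argmax(self.scores(X), axis=1)]


def fit_lda(X: np.ndarray, y: np.ndarray,
            shrinkage: float | str = "auto") -> ClassifierModel:
    """Fit a multiclass shrinkage-LDA on trials x features.

    ``shrinkage='auto'`` selects lambda by Ledoit-Wolf analytic shrinkage on
    the class-centred residuals; a float in [0, 1] fixes it.  Uniform class
    priors are used (trial balancing makes classes near-equal by design).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 trials")
    n, d = X.shape

    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    resid = X - means[np.searchsorted(classes, y)]
    cov_pooled = resid.T @ resid / (n - classes.size)

    if shrinkage == "auto":
        lam = float(ledoit_wolf_shrinkage(resid, assume_centered=True))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")

    target = (np.trace(cov_pooled) / d) * np.eye(d)
    cov_shrunk = (1.0 - lam) * cov_pooled + lam * target
    try:
        inv_m = np.linalg.solve(cov_shrunk, means.T)  # d x K
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; use shrinkage > 0") from err
    biases = -0.5 * np.einsum("kd,dk->k", means, inv_m) + np.log(1.0 / classes.size)
    cov_x = np.cov(X, rowvar=False, bias=False)
    return ClassifierModel(classes, inv_m, biases, means, cov_pooled, lam,
                           np.atleast_2d(cov_x))


# ---------------------------------------------------------------------------
# balancing and exclusions
# ---------------------------------------------------------------------------

def balance_n1n(labels: np.ndarray, prev_labels: np.ndarray,
                seed: int) -> np.ndarray:
    """N-1/N balancing: indices of a subsample in which every target class is
    preceded equally often by each of the four previous classes.

    Within each target class the four previous-class cells are subsampled to
    the size of the smallest cell.  Returns sorted kept indices.
    """
    labels = np.asarray(labels)
    prev_labels = np.asarray(prev_labels)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in np.unique(labels):
        cells = [np.flatnonzero((labels == cls) & (prev_labels == p))
                 for p in np.unique(prev_labels)]
        m = min(len(c) for c in cells)
        if m == 0:
            bad = int(np.argmin([len(c) for c in cells]))
            raise InfeasibleBalancingError(
                f"empty cell: class {cls!r} preceded by class index {bad}")
        for c in cells:
            # sort first so the draw is invariant to input trial order
            keep.append(rng.choice(np.sort(c), size=m, replace=False))
    return np.sort(np.concatenate(keep))


def drop_post_omission(epochs: EpochSet) -> EpochSet:
    """Discard sounds preceded by an omission (prediction-error carry-over)."""
    keep = ~((epochs.labels["event_type"] == "sound")
             & (epochs.labels["prev_was_omission"] == 1)).to_numpy()
    return epochs.select(keep)


# ---------------------------------------------------------------------------
# time generalization
# ---------------------------------------------------------------------------

@dataclass
class TimeGenMap:
    """Train-time x test-time accuracy matrix with metadata."""

    train_times: np.ndarray  # seconds
    test_times: np.ndarray
    accuracy: np.ndarray  # train x test
    chance: float = CHANCE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.accuracy.shape != (self.train_times.size, self.test_times.size):
            raise ValueError("accuracy shape must be train x test")
        if np.any(self.accuracy < 0) or np.any(self.accuracy > 1):
            raise ValueError("accuracies must lie in [0, 1]")

    def diagonal(self) -> np.ndarray:
        if self.train_times.size != self.test_times.size:
            raise ValueError("diagonal requires matching grids")
        return np.diag(self.accuracy)

    def to_long_frame(self) -> pd.DataFrame:
        tr, te = np.meshgrid(self.train_times, self.test_times, indexing="ij")
        df = pd.DataFrame({
            "train_ms": np.round(tr.ravel() * 1000, 6),
            "test_ms": np.round(te.ravel() * 1000, 6),
            "accuracy": self.accuracy.ravel(),
        })
        for k, v in self.meta.items():
            df[k] = v
        return df

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.accuracy)
        pd.DataFrame({"train_s": self.train_times}).to_csv(
            prefix.parent / (prefix.name + ".train_times.csv"), index=False)
        pd.DataFrame({"test_s": self.test_times}).to_csv(
            prefix.parent / (prefix.name + ".test_times.csv"), index=False)


def window_average(tg: TimeGenMap, train_window_ms: tuple[float, float]) -> np.ndarray:
    """Mean accuracy over train times inside the closed window -> test-time course."""
    lo, hi = train_window_ms
    t_ms = tg.train_times * 1000.0
    mask = (t_ms >= lo) & (t_ms <= hi)
    if not mask.any():
        raise ValueError(f"no train times inside window {train_window_ms}")
    return tg.accuracy[mask].mean(axis=0)


def _time_indices(times: np.ndarray, window_s: tuple[float, float] | None) -> np.ndarray:
    if window_s is None:
        return np.arange(times.size)
    lo, hi = window_s
    return np.flatnonzero((times >= lo - 1e-9) & (times <= hi + 1e-9))


def _lw_shrinkage_batch(R: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage intensity per time point, vectorized.

    ``R``: centred residuals (trials x features x times); ``G`` = R^T R per
    time (times x d x d).  Same formula as
    ``sklearn.covariance.ledoit_wolf_shrinkage(assume_centered=True)``,
    evaluated for every time slice at once.
    """
    n, d, _ = R.shape
    R2 = R**2
    trace_t = R2.sum(axis=(0, 1)) / n  # tr(emp_cov) per time
    mu = trace_t / d
    beta_ = np.einsum("ndt,net->t", R2, R2, optimize=True)
    delta_ = (G**2).sum(axis=(1, 2)) / n**2
    beta = (beta_ / n - delta_) / (d * n)
    delta = (delta_ - 2.0 * mu * trace_t + d * mu**2) / d
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(beta <= 0, 0.0, np.minimum(beta, delta) / delta)
    return np.clip(np.nan_to_num(lam), 0.0, 1.0)


def _fit_all_times(X: np.ndarray, y: np.ndarray, train_idx: np.ndarray,
                   shrinkage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit one LDA per training time (vectorized over time).

    Equivalent to calling :func:`fit_lda` per time slice; returns stacked
    weights (times x d x K), biases (times x K) and the class labels.
    """
    classes = np.unique(y)
    K = classes.size
    n, d = X.shape[0], X.shape[1]
    Xt = np.asarray(X[:, :, train_idx], dtype=float)
    means = np.stack([Xt[y == c].mean(axis=0) for c in classes])  # K x d x T
    R = Xt - means[np.searchsorted(classes, y)]
    G = np.einsum("ndt,net->tde", R, R, optimize=True)
    cov = G / (n - K)
    if shrinkage == "auto":
        lam = _lw_shrinkage_batch(R, G)
    else:
        lam = np.full(train_idx.size, float(shrinkage))
    tr = np.trace(cov, axis1=1, axis2=2) / d
    cov_shrunk = ((1.0 - lam)[:, None, None] * cov
                  + (lam * tr)[:, None, None] * np.eye(d))
    M = means.transpose(2, 1, 0)  # T x d x K
    W = np.linalg.solve(cov_shrunk, M)  # T x d x K
    b = -0.5 * np.einsum("tdk,tdk->tk", M, W) + np.log(1.0 / K)
    return W, b, classes


def _accuracy_map(W: np.ndarray, b: np.ndarray, classes: np.ndarray,
                  X_test: np.ndarray, y_test: np.ndarray,
                  test_idx: np.ndarray) -> np.ndarray:
    """Accuracy (train x test) of stacked per-train-time classifiers."""
    n = X_test.shape[0]
    k_train, d, K = W.shape
    Xs = np.ascontiguousarray(
        np.asarray(X_test[:, :, test_idx], dtype=float).transpose(0, 2, 1)
    ).reshape(n * test_idx.size, d)
    # one GEMM: (n*T_test, d) @ (d, k_train*K)
    scores = Xs @ W.transpose(1, 0, 2).reshape(d, k_train * K)
    scores = scores.reshape(n, test_idx.size, k_train, K) + b[None, None, :, :]
    pred = classes[np.argmax(scores, axis=-1)]  # ties -> lowest class index
    return (pred == y_test[:, None, None]).mean(axis=0).T


@dataclass
class TimeGenResults:
    """Results of a fitted time-generalization decoder."""

    map: TimeGenMap
    scheme: dict
    n_train_trials: int
    n_test_trials: int

    def window_course(self, train_window_ms: tuple[float, float]) -> np.ndarray:
        return window_average(self.map, train_window_ms)

    def summary(self) -> str:
        m = self.map
        lines = [
            "Time-generalization decoding results",
            "====================================",
            f"scheme:          {self.scheme}",
            f"train times:     {m.train_times[0]*1000:.0f}..{m.train_times[-1]*1000:.0f} ms"
            f" ({m.train_times.size} points)",
            f"test times:      {m.test_times[0]*1000:.0f}..{m.test_times[-1]*1000:.0f} ms"
            f" ({m.test_times.size} points)",
            f"train trials:    {self.n_train_trials}",
            f"test trials:     {self.n_test_trials}",
            f"chance level:    {m.chance:.3f}",
            f"mean accuracy:   {m.accuracy.mean():.4f}",
            f"peak accuracy:   {m.accuracy.max():.4f}",
        ]
        return "\n".join(lines)


class TimeGeneralizationDecoder:
    """Multiclass LDA time-generalization decoder (Model object).

    Parameters
    ----------
    train : EpochSet
        Training trials.
    y_train : array-like
        Class label per training trial (carrier frequency or entropy level).
    test, y_test : optional
        Held-out trials for cross-decoding.  When omitted, `fit` runs a
        stratified 5-fold cross-validation repeated 5 times on the training
        set.  Cross-decoding and cross-validation are mutually exclusive;
        train and test must be disjoint trial sets.
    shrinkage : 'auto' or float
    train_window_s, test_window_s : optional (lo, hi) in seconds restricting
        the time grids.
    """

    def __init__(self, train: EpochSet, y_train, *, test: EpochSet | None = None,
                 y_test=None, folds: int = 5, repeats: int = 5,
                 shrinkage: float | str = "auto",
                 train_window_s: tuple[float, float] | None = None,
                 test_window_s: tuple[float, float] | None = None,
                 meta: dict | None = None):
        self.train = train
        self.y_train = np.asarray(y_train)
        self.test = test
        self.y_test = None if y_test is None else np.asarray(y_test)
        if (test is None) != (y_test is None):
            raise ValueError("provide test and y_test together")
        if test is not None and test.data is train.data:
            raise ValueError("train and test trial sets must be disjoint")
        if test is not None and test.n_trials == train.n_trials and np.shares_memory(
                test.data, train.data):
            raise ValueError("train and test trial sets must be disjoint")
        self.folds = folds
        self.repeats = repeats
        self.shrinkage = shrinkage
        self.train_window_s = train_window_s
        self.test_window_s = test_window_s
        self.meta = meta or {}

    def fit(self, seed: int = 0) -> TimeGenResults:
        times = self.train.times
        tr_idx = _time_indices(times, self.train_window_s)
        te_idx = _time_indices(self.test.times if self.test is not None else times,
                               self.test_window_s)
        X, y = self.train.data, self.y_train
        if self.test is not None:
            W, b, classes = _fit_all_times(X, y, tr_idx, self.shrinkage)
            acc = _accuracy_map(W, b, classes, self.test.data, self.y_test, te_idx)
            n_test = self.test.n_trials
        else:
            acc, n_test = self._crossval(X, y, tr_idx, te_idx, seed)
        tg = TimeGenMap(times[tr_idx],
                        (self.test.times if self.test is not None else times)[te_idx],
                        acc, meta=dict(self.meta))
        return TimeGenResults(tg, scheme=self._scheme_dict(),
                              n_train_trials=X.shape[0], n_test_trials=n_test)

    def _scheme_dict(self) -> dict:
        return {
            "cv": None if self.test is not None else f"{self.folds}x{self.repeats}",
            "cross_decoding": self.test is not None,
            "shrinkage": self.shrinkage,
            **self.meta,
        }

    def _crossval(self, X, y, tr_idx, te_idx, seed):
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < self.folds:
            raise ValueError("every class needs at least `folds` trials")
        acc_sum = np.zeros((tr_idx.size, te_idx.size))
        ss = np.random.SeedSequence(seed)
        for rep_seed in ss.spawn(self.repeats):
            rng = np.random.default_rng(rep_seed)
            fold_of = np.empty(y.size, dtype=int)
            for c in classes:  # stratified fold assignment, re-drawn per repeat
                members = np.flatnonzero(y == c)
                rng.shuffle(members)
                fold_of[members] = np.arange(members.size) % self.folds
            for f in range(self.folds):
                tr = fold_of != f
                W, b, cl = _fit_all_times(X[tr], y[tr], tr_idx, self.shrinkage)
                acc_sum += _accuracy_map(W, b, cl, X[~tr], y[~tr], te_idx)
        return acc_sum / (self.folds * self.repeats), X.shape[0]


# ---------------------------------------------------------------------------
# spec-surface convenience functions
# ---------------------------------------------------------------------------

def crossval_timegen(epochs: EpochSet, y, seed: int = 0, *, folds: int = 5,
                     repeats: int = 5, shrinkage="auto",
                     train_window_s=None, test_window_s=None,
                     meta=None) -> TimeGenMap:
    """Stratified 5x5 cross-validated time-generalization decoding."""
    res = TimeGeneralizationDecoder(
        epochs, y, folds=folds, repeats=repeats, shrinkage=shrinkage,
        train_window_s=train_window_s, test_window_s=test_window_s,
        meta=meta).fit(seed)
    return res.map


def cross_condition_timegen(train: EpochSet, y_train, test: EpochSet, y_test,
                            *, shrinkage="auto", train_window_s=None,
                            test_window_s=None, meta=None) -> TimeGenMap:
    """Train on the full training set (no folding), test on held-out trials."""
    res = TimeGeneralizationDecoder(
        train, y_train, test=test, y_test=y_test, shrinkage=shrinkage,
        train_window_s=train_window_s, test_window_s=test_window_s,
        meta=meta).fit()
    return res.map


def sound_to_sound_maps(epochs: EpochSet, seed: int = 0, *, shrinkage="auto",
                        train_window_s=None, test_window_s=None,
                        balance_seed: int | None = None) -> dict[str, TimeGenMap]:
    """Carrier-frequency decoding: RD-trained, tested per condition.

    RD sounds are decoded with 5x5 CV; MM/MP/OR sounds by cross-decoding from
    the full RD training set.  Sounds preceded by an omission are discarded
    and the training set is N-1/N balanced.
    """
    clean = drop_post_omission(epochs)
    rd = clean.where(condition="RD", event_type="sound")
    bal = balance_n1n(rd.labels["tone_class"].to_numpy(),
                      rd.labels["prev_tone_class"].to_numpy(),
                      seed if balance_seed is None else balance_seed)
    rd = rd.select(bal)
    y_rd = rd.labels["tone_class"].to_numpy()
    maps = {"RD": crossval_timegen(rd, y_rd, seed, shrinkage=shrinkage,
                                   train_window_s=train_window_s,
                                   test_window_s=test_window_s,
                                   meta={"condition": "RD", "event_type": "sound"})}
    for cond in ("MM", "MP", "OR"):
        te = clean.where(condition=cond, event_type="sound")
        maps[cond] = cross_condition_timegen(
            rd, y_rd, te, te.labels["tone_class"].to_numpy(),
            shrinkage=shrinkage, train_window_s=train_window_s,
            test_window_s=test_window_s,
            meta={"condition": cond, "event_type": "sound"})
    return maps


def sound_to_omission_maps(epochs: EpochSet, seed: int = 0, *, shrinkage="auto",
                           train_window_s=None, test_window_s=None) -> dict[str, TimeGenMap]:
    """RD-sound-trained classifiers tested on omissions of each condition.

    Omissions are labelled by the carrier frequency of the sound that would
    have been presented.
    """
    clean = drop_post_omission(epochs)
    rd = clean.where(condition="RD", event_type="sound")
    bal = balance_n1n(rd.labels["tone_class"].to_numpy(),
                      rd.labels["prev_tone_class"].to_numpy(), seed)
    rd = rd.select(bal)
    y_rd = rd.labels["tone_class"].to_numpy()
    maps = {}
    for cond in ("RD", "MM", "MP", "OR"):
        te = epochs.where(condition=cond, event_type="omission")
        maps[cond] = cross_condition_timegen(
            rd, y_rd, te, te.labels["tone_class"].to_numpy(),
            shrinkage=shrinkage, train_window_s=train_window_s,
            test_window_s=test_window_s,
            meta={"condition": cond, "event_type": "omission"})
    return maps


def decode_entropy(epochs: EpochSet, event_type: str = "sound", seed: int = 0,
                   *, shrinkage="auto") -> np.ndarray:
    """Entropy-level (condition) decoding accuracy time course.

    Sounds: 4-class LDA per time point with 5x5 CV (sounds preceded by an
    omission discarded).  Omissions: classifiers trained on all sounds and
    tested on all omissions (cross-decoding, no CV).  Chance is 0.25.
    """
    cond_code = {"RD": 0, "MM": 1, "MP": 2, "OR": 3}
    if event_type == "sound":
        ep = drop_post_omission(epochs).where(event_type="sound")
        y = ep.labels["condition"].map(cond_code).to_numpy()
        return _diagonal_timecourse(ep, y, seed, shrinkage)
    if event_type == "omission":
        tr = drop_post_omission(epochs).where(event_type="sound")
        te = epochs.where(event_type="omission")
        y_tr = tr.labels["condition"].map(cond_code).to_numpy()
        y_te = te.labels["condition"].map(cond_code).to_numpy()
        all_t = np.arange(tr.times.size)
        W, b, cl = _fit_all_times(tr.data, y_tr, all_t, shrinkage)
        return _matched_time_accuracy(W, b, cl, te.data, y_te)
    raise ValueError("event_type must be 'sound' or 'omission'")


def _matched_time_accuracy(W, b, classes, X_test, y_test) -> np.ndarray:
    """Accuracy at train time == test time only (time-resolved decoding)."""
    scores = np.einsum("ndt,tdc->ntc", np.asarray(X_test, dtype=float), W,
                       optimize=True) + b[None, :, :]
    pred = classes[np.argmax(scores, axis=-1)]
    return (pred == y_test[:, None]).mean(axis=0)


def _diagonal_timecourse(ep: EpochSet, y, seed, shrinkage,
                         folds: int = 5, repeats: int = 5) -> np.ndarray:
    """Time-resolved (train time == test time) cross-validated accuracy."""
    X = ep.data
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` trials")
    y = np.asarray(y)
    n_t = X.shape[2]
    all_t = np.arange(n_t)
    acc = np.zeros(n_t)
    ss = np.random.SeedSequence(seed)
    for rep_seed in ss.spawn(repeats):
        rng = np.random.default_rng(rep_seed)
        fold_of = np.empty(len(y), dtype=int)
        for c in classes:  # same stratified scheme as the time-gen CV
            members = np.flatnonzero(y == c)
            rng.shuffle(members)
            fold_of[members] = np.arange(members.size) % folds
        for f in range(folds):
            tr, te = fold_of != f, fold_of == f
            W, b, cl = _fit_all_times(X[tr], y[tr], all_t, shrinkage)
            acc += _matched_time_accuracy(W, b, cl, X[te], y[te])
    return acc / (folds * repeats)
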