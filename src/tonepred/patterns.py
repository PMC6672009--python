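"""Activation patterns from classifier weights.

Linear classifier weights are a backward (extraction) model: large weights do
not imply strong underlying activity, because weights also suppress
correlated noise.  Multiplying the weights by the data covariance (and
normalising by the covariance of the discriminant scores) converts them to a
forward-model activation pattern, A = Cov(x) W Cov(s)^-1 — the sensor
topography whose activity the classifier actually extracts.  These corrected
patterns can then be projected through externally supplied spatial filters
(e.g. beamformer filters) to obtain an "informative activity" map in source
space.  Filter construction is out of scope; filters are consumed as input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoding import ClassifierModel


@dataclass
class ActivationPattern:
    """Forward-model pattern per class, same shape as the weights."""

    A: np.ndarray  # sensors x classes (or sensors x 1)
    normalization: str = "raw"  # raw | baseline-relative

    def to_frame(self, train_ms: float | None = None) -> pd.DataFrame:
        s, k = np.meshgrid(np.arange(self.A.shape[0]),
                           np.arange(self.A.shape[1]), indexing="ij")
        df = pd.DataFrame({"sensor": s.ravel(), "class": k.ravel(),
                           "value": self.A.ravel()})
        if train_ms is not None:
            df.insert(0, "train_ms", train_ms)
        return df


@dataclass
class SpatialFilterBank:
    """Sources x sensors projection matrix supplied by the user."""

    filters: np.ndarray

    def __post_init__(self) -> None:
        F = np.asarray(self.filters, dtype=float)
        if F.ndim != 2 or not np.all(np.isfinite(F)):
            raise ValueError("filters must be a finite 2-D matrix")
        self.filters = F


def haufe_correct(model: ClassifierModel,
                  cov_x: np.ndarray | None = None,
                  center: bool = True) -> ActivationPattern:
    """Covariance-correct classifier weights into activation patterns.

    A = Cov(x) . W . Cov(s)^-1, where Cov(s) is the covariance of the
    discriminant scores implied by the training data (pseudo-inverse when
    rank-deficient).  With white data (Cov(x) = I) and a single discriminant,
    A is proportional to W.

    With ``center=True`` (default) the class discriminants are first centred
    across classes: for K classes only the (K-1)-dimensional subspace of
    between-class contrasts is informative, and the common mode is a
    near-degenerate score direction whose "pattern" is noise-dominated.
    Centring removes it before the pseudo-inverse.
    """
    W = model.weights
    if center and W.shape[1] > 1:
        W = W - W.mean(axis=1, keepdims=True)
    S = np.asarray(model.cov_x if cov_x is None else cov_x, dtype=float)
    if S.shape[0] != S.shape[1] or S.shape[0] != W.shape[0]:
        raise ValueError("covariance must be square and match the sensor dimension")
    if np.max(np.abs(S - S.T)) > 1e-8 * max(1.0, np.max(np.abs(S))):
        raise ValueError("covariance must be symmetric")
    cov_s = W.T @ S @ W
    A = S @ W @ np.linalg.pinv(cov_s, hermitian=True)
    return ActivationPattern(A)


def project_patterns(A: ActivationPattern | np.ndarray,
                     F: SpatialFilterBank | np.ndarray) -> np.ndarray:
    """Project sensor-space patterns through spatial filters: F . A."""
    A_ = A.A if isinstance(A, ActivationPattern) else np.asarray(A, float)
    F_ = F.filters if isinstance(F, SpatialFilterBank) else np.asarray(F, float)
    if F_.shape[1] != A_.shape[0]:
        raise ValueError(
            f"filter sensor dimension {F_.shape[1]} != pattern dimension {A_.shape[0]}")
    return F_ @ A_


def baseline_relative(x: np.ndarray, times_s: np.ndarray,
                      baseline_window_s: tuple[float, float] = (-0.1, 0.0)
                      ) -> np.ndarray:
    """Relative change with respect to the mean in a baseline window.

    (x - mean_baseline) / mean_baseline per location; locations with a zero
    baseline mean are returned as NaN (flagged undefined).
    """
    x = np.asarray(x, dtype=float)
    times_s = np.asarray(times_s)
    lo, hi = baseline_window_s
    mask = (times_s >= lo - 1e-9) & (times_s <= hi + 1e-9)
    if not mask.any():
        raise ValueError("baseline window outside the time grid")
    base = x[..., mask].mean(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (x - base) / base
    out = np.where(base == 0, np.nan, out)
    return out


def synthetic_filter_bank(n_sources: int, n_sensors: int,
                          seed: int = 0) -> SpatialFilterBank:
    """Synthetic spatial filters for testing pattern projection.

    Random unit-norm rows; a stand-in for externally computed beamformer
    filters, which this package does not construct.
    """
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n_sources, n_sensors))
    F /= np.linalg.norm(F, axis=1, keepdims=True)
    return SpatialFilterBank(F)
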