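"""Group-level inference for time-generalization decoding maps.

Four tools, all nonparametric or Bonferroni-corrected:

* ``depsamples_reg_t`` — dependent-samples regression: per subject, the
  least-squares slope of accuracy on the entropy-condition code; the group
  statistic is a one-sample t of the slopes against zero (df = n - 1).
* ``cluster_perm_2d`` — cluster-based permutation test on a 2-D
  (train-time x test-time) statistic map: threshold at the t quantile for a
  per-tail alpha (default 0.025), 4-connected clusters scored by summed
  statistic, null distribution from within-subject permutation of the
  condition codes.
* ``bonferroni_timecourse`` / ``paired_diff_test`` — pointwise t tests with
  Bonferroni correction over time.
* ``spearman_corr_map`` — across-subject rank correlation of a scalar
  covariate with a map, with cluster inference over the correlation-t
  transform, permuting the subject pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sstats

#: 4-connectivity on the train x test lattice
_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ClusterResult:
    """Clusters of a 2-D statistic map with permutation p-values."""

    stat_map: np.ndarray
    cluster_labels: np.ndarray  # int map; 0 = background
    cluster_masses: np.ndarray  # signed maxsum per cluster (1-based ids)
    cluster_pvalues: np.ndarray
    n_permutations: int
    cf_threshold: float  # cluster-forming |t| threshold
    tail: str  # 'two' | 'pos' | 'neg'

    @property
    def n_clusters(self) -> int:
        return self.cluster_masses.size

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        """Boolean map of samples in clusters with p < alpha."""
        sig = np.zeros_like(self.cluster_labels, dtype=bool)
        for cid in np.flatnonzero(self.cluster_pvalues < alpha) + 1:
            sig |= self.cluster_labels == cid
        return sig

    def to_frame(self, train_times=None, test_times=None) -> pd.DataFrame:
        rows = []
        for cid in range(1, self.n_clusters + 1):
            where = np.argwhere(self.cluster_labels == cid)
            (r0, c0), (r1, c1) = where.min(axis=0), where.max(axis=0)
            row = {"cluster": cid, "mass": self.cluster_masses[cid - 1],
                   "p": self.cluster_pvalues[cid - 1], "n_samples": len(where)}
            if train_times is not None:
                row["train_ms_lo"], row["train_ms_hi"] = (
                    train_times[r0] * 1000, train_times[r1] * 1000)
            if test_times is not None:
                row["test_ms_lo"], row["test_ms_hi"] = (
                    test_times[c0] * 1000, test_times[c1] * 1000)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Cluster permutation test",
            "========================",
            f"tail: {self.tail}; cluster-forming |t| = {self.cf_threshold:.3f}; "
            f"{self.n_permutations} permutations",
            f"clusters found: {self.n_clusters}",
        ]
        for cid in range(1, self.n_clusters + 1):
            lines.append(f"  cluster {cid}: mass={self.cluster_masses[cid-1]:+.2f}, "
                         f"p={self.cluster_pvalues[cid-1]:.4f}")
        return "\n".join(lines)


def _subject_slopes(values: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Per-subject least-squares slope of value on condition code.

    values: subjects x conditions x (...map); codes: conditions (or
    subjects x conditions for permuted codes).  Returns subjects x (...map).
    """
    values = np.asarray(values, dtype=float)
    codes = np.asarray(codes, dtype=float)
    if codes.ndim == 1:
        codes = np.broadcast_to(codes, values.shape[:2])
    xc = codes - codes.mean(axis=1, keepdims=True)
    denom = (xc**2).sum(axis=1)
    extra = values.ndim - 2
    xc_b = xc.reshape(xc.shape + (1,) * extra)
    num = (xc_b * (values - values.mean(axis=1, keepdims=True))).sum(axis=1)
    return num / denom.reshape(denom.shape + (1,) * extra)


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    """One-sample t vs 0 along axis 0; zero-variance locations -> NaN."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # exactly-zero effect with zero variance is a genuine zero; a nonzero
    # effect with zero variance is undefined and flagged as NaN
    return np.where(sd == 0, np.where(mean == 0, 0.0, np.nan), t)


def depsamples_reg_t(values: np.ndarray,
                     condition_codes: np.ndarray | None = None) -> np.ndarray:
    """Dependent-samples regression t map over entropy levels.

    ``values``: subjects x conditions x map (any trailing shape); conditions
    ordered from random to ordered.  Default codes are 1..n_conditions.
    Returns the t map (df = n_subjects - 1); locations with zero
    across-subject slope variance are NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    codes = (np.arange(1, values.shape[1] + 1, dtype=float)
             if condition_codes is None else np.asarray(condition_codes, float))
    return _one_sample_t(_subject_slopes(values, codes))


def _clusters(t_map: np.ndarray, threshold: float, tail: str):
    """4-connected supra-threshold clusters and their signed masses."""
    t = np.nan_to_num(np.asarray(t_map, dtype=float))
    labels = np.zeros(t.shape, dtype=int)
    masses: list[float] = []
    sides = []
    if tail in ("two", "pos"):
        sides.append(t > threshold)
    if tail in ("two", "neg"):
        sides.append(t < -threshold)
    nxt = 1
    for mask in sides:
        lab, n = ndimage.label(mask, structure=_STRUCTURE)
        for k in range(1, n + 1):
            labels[lab == k] = nxt
            masses.append(float(t[lab == k].sum()))
            nxt += 1
    return labels, np.array(masses)


def cluster_perm_2d(
    values: np.ndarray,
    n_perm: int = 1000,
    cf_alpha: float = 0.025,
    tail: str = "two",
    seed: int = 0,
    condition_codes: np.ndarray | None = None,
    stat_fn=None,
) -> ClusterResult:
    """Cluster-based permutation test of the entropy regression on a 2-D map.

    ``values``: subjects x conditions x rows x cols.  The observed map is the
    dependent-samples regression t; the null distribution permutes the
    condition codes independently within each subject (the exchangeability
    unit).  Cluster mass is the summed t (maxsum); the permutation p-value of
    a cluster is (1 + #{null max-mass >= observed}) / (n_perm + 1), per tail.
    A custom ``stat_fn(values, codes) -> t map`` may replace the regression.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 3:
        values = values[:, :, None, :]
    n_sub, n_cond = values.shape[:2]
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if 1.0 / (n_perm + 1) > cf_alpha:
        import warnings
        warnings.warn("n_perm too small to resolve the requested alpha")
    codes = (np.arange(1, n_cond + 1, dtype=float)
             if condition_codes is None else np.asarray(condition_codes, float))
    custom_stat = stat_fn is not None
    if stat_fn is None:
        stat_fn = lambda v, c: _one_sample_t(_subject_slopes(v, c))

    df = n_sub - 1
    thr = float(sstats.t.ppf(1.0 - cf_alpha, df))
    t_obs = stat_fn(values, codes)
    labels, masses = _clusters(t_obs, thr, tail)

    rng = np.random.default_rng(seed)
    null_pos = np.zeros(n_perm)
    null_neg = np.zeros(n_perm)
    if custom_stat:
        for p in range(n_perm):
            perm_codes = np.stack([rng.permutation(codes)
                                   for _ in range(n_sub)])
            t_null = stat_fn(values, perm_codes)
            _, m = _clusters(t_null, thr, tail)
            null_pos[p] = m.max(initial=0.0)
            null_neg[p] = m.min(initial=0.0)
    else:
        _regression_null(values, codes, thr, tail, n_perm, rng,
                         null_pos, null_neg)

    pvals = _cluster_pvalues(masses, null_pos, null_neg, tail, n_perm)
    return ClusterResult(t_obs, labels, masses, pvals, n_perm, thr, tail)


def _regression_null(values, codes, thr, tail, n_perm, rng,
                     null_pos, null_neg, chunk: int = 64):
    """Null max/min cluster masses for the regression statistic, evaluating
    permutations in vectorized chunks."""
    n_sub, n_cond = values.shape[:2]
    vc = values - values.mean(axis=1, keepdims=True)  # centred over conditions
    xc = codes - codes.mean()
    denom = (xc**2).sum()
    flat = vc.reshape(n_sub, n_cond, -1)
    map_shape = values.shape[2:]
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # independent permutation of condition codes within each subject
        w = np.stack([[rng.permutation(xc) for _ in range(n_sub)]
                      for _ in range(m)])  # m x n_sub x n_cond
        slopes = np.einsum("psc,scm->psm", w, flat, optimize=True) / denom
        mean = slopes.mean(axis=1)
        sd = slopes.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = mean / (sd / np.sqrt(n_sub))
        # degenerate permutations (zero slope variance) carry no evidence
        t_null = np.nan_to_num(t_null, nan=0.0, posinf=0.0, neginf=0.0)
        for i in range(m):
            _, masses = _clusters(t_null[i].reshape(map_shape), thr, tail)
            null_pos[done + i] = masses.max(initial=0.0)
            null_neg[done + i] = masses.min(initial=0.0)
        done += m


def _cluster_pvalues(masses, null_pos, null_neg, tail, n_perm):
    """Permutation p per cluster.  For a two-tailed test each cluster is
    scored against the null distribution of the maximum |cluster mass| over
    both tails, which keeps the family-wise error at the nominal level."""
    if tail == "two":
        null_max = np.maximum(null_pos, -null_neg)
        obs = np.abs(masses)
        return np.array([(1 + np.sum(null_max >= m)) / (n_perm + 1)
                         for m in obs])
    pvals = np.empty(masses.size)
    for i, mass in enumerate(masses):
        if mass >= 0:
            pvals[i] = (1 + np.sum(null_pos >= mass)) / (n_perm + 1)
        else:
            pvals[i] = (1 + np.sum(null_neg <= mass)) / (n_perm + 1)
    return pvals


class EntropyRegression:
    """Model object: entropy-level regression with cluster-permutation inference.

    Parameters
    ----------
    values : subjects x conditions x (train x test) accuracy maps, conditions
        ordered random -> ordered.
    condition_codes : regression codes (default 1..4).
    """

    def __init__(self, values: np.ndarray, condition_codes=None,
                 train_times=None, test_times=None):
        self.values = np.asarray(values, dtype=float)
        self.condition_codes = condition_codes
        self.train_times = train_times
        self.test_times = test_times

    def fit(self, n_perm: int = 1000, cf_alpha: float = 0.025,
            tail: str = "two", seed: int = 0) -> "EntropyRegressionResults":
        res = cluster_perm_2d(self.values, n_perm=n_perm, cf_alpha=cf_alpha,
                              tail=tail, seed=seed,
                              condition_codes=self.condition_codes)
        return EntropyRegressionResults(self, res)


@dataclass
class EntropyRegressionResults:
    model: EntropyRegression
    clusters: ClusterResult

    def summary(self) -> str:
        head = (f"Entropy regression on {self.model.values.shape[0]} subjects x "
                f"{self.model.values.shape[1]} conditions\n")
        return head + self.clusters.summary()

    def to_frame(self) -> pd.DataFrame:
        return self.clusters.to_frame(self.model.train_times, self.model.test_times)


def bonferroni_timecourse(accuracy: np.ndarray, chance: float = 0.25,
                          alpha: float = 0.05,
                          alternative: str = "two-sided") -> np.ndarray:
    """Pointwise one-sample t vs chance, Bonferroni-corrected over time.

    ``accuracy``: subjects x time.  Returns a boolean significance mask;
    zero-variance time points are non-significant.
    """
    acc = np.asarray(accuracy, dtype=float)
    if acc.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    n, n_t = acc.shape
    t = _one_sample_t(acc - chance)
    if alternative == "two-sided":
        p = 2 * sstats.t.sf(np.abs(t), n - 1)
    elif alternative == "greater":
        p = sstats.t.sf(t, n - 1)
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    p = np.where(np.isnan(t), 1.0, p)
    return p < alpha / n_t


def paired_diff_test(acc_a: np.ndarray, acc_b: np.ndarray,
                     alpha: float = 0.05) -> np.ndarray:
    """Paired t per time point on matched subjects, Bonferroni over time."""
    a, b = np.asarray(acc_a, float), np.asarray(acc_b, float)
    if a.shape != b.shape:
        raise ValueError("matched subjects required: shapes must agree")
    return bonferroni_timecourse(a - b, chance=0.0, alpha=alpha)


def _rank(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.apply_along_axis(sstats.rankdata, axis, x)


def spearman_rho_map(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Spearman rho of a per-subject scalar against each map location."""
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rx = sstats.rankdata(x)
    rY = _rank(Y.reshape(Y.shape[0], -1), axis=0)
    rx_c = rx - rx.mean()
    rY_c = rY - rY.mean(axis=0)
    denom = np.sqrt((rx_c**2).sum() * (rY_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx_c @ rY_c) / denom
    return rho.reshape(Y.shape[1:])


def spearman_corr_map(x: np.ndarray, Y: np.ndarray, n_perm: int = 1000,
                      cf_alpha: float = 0.025, tail: str = "two",
                      seed: int = 0) -> tuple[np.ndarray, ClusterResult]:
    """Across-subject Spearman correlation map with cluster inference.

    ``x``: subjects (scalar covariate, >= 2 distinct values); ``Y``: subjects
    x map.  The statistic map is the correlation-t transform
    t = rho sqrt((n-2)/(1-rho^2)); the null permutes the subject pairing
    (x relative to Y).  Ties use average ranks.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if np.unique(x).size < 2:
        raise ValueError("x must have at least 2 distinct values")
    if Y.ndim == 2:
        Y_map = Y[:, None, :]
    else:
        Y_map = Y

    def rho_to_t(rho):
        rho = np.clip(rho, -0.999999, 0.999999)
        return rho * np.sqrt((n - 2) / (1 - rho**2))

    rho = spearman_rho_map(x, Y_map)
    thr = float(sstats.t.ppf(1.0 - cf_alpha, n - 2))
    t_obs = rho_to_t(rho)
    labels, masses = _clusters(t_obs, thr, tail)

    rng = np.random.default_rng(seed)
    null_pos = np.zeros(n_perm)
    null_neg = np.zeros(n_perm)
    # permuting x is a permutation of its ranks: all null rho maps in one GEMM
    rx = sstats.rankdata(x)
    rY = _rank(Y_map.reshape(n, -1), axis=0)
    rY_c = rY - rY.mean(axis=0)
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum() * (rY_c**2).sum(axis=0))
    perm_rx = np.stack([rng.permutation(rx_c) for _ in range(n_perm)])
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_null = (perm_rx @ rY_c) / denom
    t_all = rho_to_t(np.nan_to_num(rho_null)).reshape((n_perm,) + Y_map.shape[1:])
    for p in range(n_perm):
        _, m = _clusters(t_all[p], thr, tail)
        null_pos[p] = m.max(initial=0.0)
        null_neg[p] = m.min(initial=0.0)
    pvals = _cluster_pvalues(masses, null_pos, null_neg, tail, n_perm)
    result = ClusterResult(t_obs, labels, masses, pvals, n_perm, thr, tail)
    rho_out = rho if Y.ndim > 2 else rho[0]
    return rho_out, result
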