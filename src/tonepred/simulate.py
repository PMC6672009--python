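"""Synthetic MEG-like epoch generator with injectable prediction effects.

Generates trials x sensors x time tensors with the statistical structure the
decoding analysis assumes: each tone class drives a distinct but mutually
correlated sensor topography (auditory sources are spatially compact, so
tonotopic patterns overlap), an evoked response peaking ~100 ms after tone
onset that wanes slowly (a persistence/memory-trace component carried into
the next trial), spatially correlated band-limited Gaussian noise, and three
ground-truth prediction effects whose amplitude scales with the
predictability of the sequence:

* anticipatory preactivation of the *expected* tone's topography in a
  pre-onset window,
* an omission response expressing the expected tone's topography after an
  expected-but-omitted onset,
* a condition-specific sensor offset that makes the sequence's entropy
  level decodable from single trials.

The expected tone is the dominant successor of the previous tone; in the
random condition predictability is zero so no prediction effect is injected.
All effects are linear in the predictability index g = (p_dom - 0.25)/0.5,
i.e. g = 0 (RD), 1/3 (MM), 2/3 (MP), 1 (OR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import (
    CONDITIONS,
    DEFAULT_DOMINANT_MAP,
    N_TONES,
    BlockDesign,
    StimulusBlock,
    _spawn_seeds,
    make_block,
    standard_matrices,
)

SFREQ = 100.0  # Hz, epoch sampling rate
EPOCH_TMIN, EPOCH_TMAX = -1.0, 1.0  # s around event onset


def epoch_times(sfreq: float = SFREQ, tmin: float = EPOCH_TMIN,
                tmax: float = EPOCH_TMAX) -> np.ndarray:
    n = int(round((tmax - tmin) * sfreq)) + 1
    return tmin + np.arange(n) / sfreq


@dataclass(frozen=True)
class TopographySet:
    """One unit-norm sensor pattern per tone class, with controlled overlap."""

    patterns: np.ndarray  # n_sensors x 4
    inter_class_corr: float

    @property
    def n_sensors(self) -> int:
        return self.patterns.shape[0]

    def gram(self) -> np.ndarray:
        return self.patterns.T @ self.patterns


@dataclass(frozen=True)
class ResponseKernel:
    """Temporal response shapes on the epoch grid.

    ``evoked`` is a transient kernel that is zero before onset and peaks at
    ``peak_ms``; ``persistence`` decays exponentially with time constant
    ``tau_ms`` and models the slowly waning trace of the preceding tone.
    """

    times_ms: np.ndarray
    evoked: np.ndarray
    persistence: np.ndarray
    peak_ms: float = 100.0
    tau_ms: float = 400.0
    persist_gain: float = 0.3


def make_kernel(
    sfreq: float = SFREQ,
    tmin: float = EPOCH_TMIN,
    tmax: float = EPOCH_TMAX,
    peak_ms: float = 100.0,
    tau_ms: float = 400.0,
    persist_gain: float = 0.3,
    soa_ms: float = 1000.0 / 3.0,
) -> ResponseKernel:
    """Evoked + persistence kernels on the epoch time grid.

    The evoked kernel is a gamma-like bump ``(t/p) exp(1 - t/p)`` (unit peak
    at ``peak_ms``); the persistence kernel is the same response launched one
    stimulus-onset asynchrony earlier, i.e. what remains of the previous
    tone's response inside the current epoch, scaled by ``persist_gain`` and
    decaying with ``tau_ms``.
    """
    t = epoch_times(sfreq, tmin, tmax)
    t_ms = t * 1000.0

    def bump(ts):
        x = np.where(ts > 0, ts / peak_ms, 0.0)
        return np.where(ts > 0, x * np.exp(1.0 - x), 0.0)

    evoked = bump(t_ms)
    # previous tone's trace: evoked launched soa earlier, decaying slowly
    prev = bump(t_ms + soa_ms) * np.exp(-np.clip(t_ms + soa_ms, 0, None) / tau_ms)
    persistence = persist_gain * prev
    return ResponseKernel(t_ms, evoked, persistence, peak_ms, tau_ms, persist_gain)


@dataclass(frozen=True)
class SimulationParams:
    """Gains and noise parameters of the generative model.

    All gains are expressed relative to the unit-peak evoked response.
    """

    anticipation_gain: float = 0.6
    omission_gain: float = 0.6
    entropy_signature_gain: float = 0.15
    noise_sd: float = 1.0
    noise_corr_length: float = 0.3  # spatial correlation length (embedding units)
    amplitude_jitter_sd: float = 0.1  # log-normal sd of per-trial gain
    anticipation_window_ms: tuple[float, float] = (-250.0, 0.0)
    omission_window_ms: tuple[float, float] = (0.0, 250.0)

    def __post_init__(self) -> None:
        if min(self.anticipation_gain, self.omission_gain,
               self.entropy_signature_gain) < 0:
            raise ValueError("gains must be >= 0")


def predictability_index(p_dom: float) -> float:
    """g = (p_dom - 0.25)/0.5: 0 for RD, 1/3 MM, 2/3 MP, 1 OR."""
    return (p_dom - 0.25) / 0.5


@dataclass
class EpochSet:
    """Labelled trials x sensors x time tensor; the universal exchange type."""

    data: np.ndarray  # trials x sensors x time
    labels: pd.DataFrame  # tone_class, condition, event_type, prev_tone_class, prev_was_omission, subject_id
    times: np.ndarray  # seconds

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels must have one row per trial")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask],
                        self.labels.iloc[mask].reset_index(drop=True),
                        self.times)

    def where(self, **conditions) -> "EpochSet":
        mask = np.ones(self.n_trials, dtype=bool)
        for key, val in conditions.items():
            col = self.labels[key].to_numpy()
            mask &= np.isin(col, val) if isinstance(val, (list, tuple, set)) else col == val
        return self.select(mask)

    def save(self, prefix: str | Path) -> None:
        """Persist as <prefix>.npy (data) + <prefix>.labels.csv + <prefix>.times.csv."""
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.data)
        self.labels.to_csv(prefix.parent / (prefix.name + ".labels.csv"), index=False)
        np.savetxt(prefix.parent / (prefix.name + ".times.csv"), self.times)

    @classmethod
    def load(cls, prefix: str | Path) -> "EpochSet":
        prefix = Path(prefix)
        data = np.load(prefix.with_suffix(".npy"))
        labels = pd.read_csv(prefix.parent / (prefix.name + ".labels.csv"))
        times = np.loadtxt(prefix.parent / (prefix.name + ".times.csv"))
        return cls(data, labels, np.atleast_1d(times))


def concat_epochs(sets: list[EpochSet]) -> EpochSet:
    times = sets[0].times
    return EpochSet(
        np.concatenate([s.data for s in sets], axis=0),
        pd.concat([s.labels for s in sets], ignore_index=True),
        times,
    )


@dataclass
class CohortDataset:
    """Per-subject epoch sets simulated with independent noise."""

    subjects: list[EpochSet]
    master_seed: int
    params: SimulationParams

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def make_topographies(n_sensors: int, inter_class_corr: float,
                      seed: int) -> TopographySet:
    """Unit-norm class topographies with a target pairwise correlation.

    Built as a shared component plus orthogonalised class-specific residuals:
    with weights sqrt(c) and sqrt(1-c) the Gram matrix has off-diagonal
    entries exactly ``c`` by construction.
    """
    if not 0 <= inter_class_corr < 1:
        raise ValueError("inter_class_corr must be in [0, 1)")
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    rng = np.random.default_rng(seed)
    # orthonormal basis: 1 shared direction + 4 class-specific directions
    raw = rng.standard_normal((n_sensors, N_TONES + 1))
    q, _ = np.linalg.qr(raw)
    shared, resid = q[:, 0], q[:, 1:]
    c = inter_class_corr
    patterns = np.sqrt(c) * shared[:, None] + np.sqrt(1 - c) * resid
    patterns /= np.linalg.norm(patterns, axis=0, keepdims=True)
    return TopographySet(patterns, inter_class_corr)


def _spatial_noise_chol(n_sensors: int, corr_length: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Cholesky factor of an exponential-decay spatial covariance over a
    random 2-D sensor embedding."""
    pos = rng.random((n_sensors, 2))
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cov = np.exp(-d / corr_length)
    cov += 1e-6 * np.eye(n_sensors)
    return np.linalg.cholesky(cov)


def _bandlimited_noise(shape: tuple, chol: np.ndarray,
                       rng: np.random.Generator, sfreq: float = SFREQ,
                       f_cut: float = 30.0) -> np.ndarray:
    """Spatially correlated Gaussian noise, band-limited to ``f_cut`` Hz.

    Generated in the frequency domain (white spectrum truncated at the
    cutoff, inverse FFT along time), then coloured spatially by the Cholesky
    factor and renormalised to unit variance.
    """
    n_trials, n_sensors, n_times = shape
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    keep = freqs <= f_cut
    n_bins = freqs.size
    # draw the band-limited spectrum directly (Hermitian symmetry is implied
    # by the rfft layout); each kept bin carries E|X|^2 = n_times
    spec = np.zeros((n_trials, n_sensors, n_bins), dtype=np.complex64)
    k = int(keep.sum())
    re = rng.standard_normal((n_trials, n_sensors, k), dtype=np.float32)
    im = rng.standard_normal((n_trials, n_sensors, k), dtype=np.float32)
    amp = np.sqrt(n_times / 2.0)
    spec[..., :k] = (re + 1j * im) * amp
    spec[..., 0] = re[..., 0] * np.sqrt(n_times)  # DC bin is real
    filt = np.fft.irfft(spec, n=n_times, axis=-1)
    # Parseval: variance after truncation is (2k - 1) / n_times
    filt /= np.sqrt((2 * k - 1) / n_times)
    out = np.matmul(chol.astype(np.float32), filt)
    return out / np.sqrt(np.diag(chol @ chol.T)).mean()


def _raised_cosine(times_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    env = np.zeros_like(times_ms)
    inside = (times_ms >= lo) & (times_ms <= hi)
    phase = (times_ms[inside] - lo) / (hi - lo)
    env[inside] = 0.5 * (1 - np.cos(2 * np.pi * phase))
    return env


def simulate_subject(
    blocks: dict[str, StimulusBlock],
    topo: TopographySet,
    kernel: ResponseKernel,
    params: SimulationParams,
    seed: int,
    subject_id: int = 0,
    dominant_map: tuple[int, ...] = DEFAULT_DOMINANT_MAP,
    p_dom: dict[str, float] | None = None,
    dtype=np.float32,
) -> EpochSet:
    """Simulate all epochs of one subject from four condition blocks.

    Sound trial:   evoked kernel (x) tone topography
                 + persistence of the previous tone
                 + a * g_c * anticipation envelope (x) expected tone topography
                 + e * condition signature + noise.
    Omission trial: same minus the evoked term,
                 + o * g_c * omission envelope (x) expected tone topography.
    """
    missing = set(CONDITIONS) - set(blocks)
    if missing:
        raise ValueError(f"missing condition blocks: {sorted(missing)}")
    mats = standard_matrices(dominant_map, p_dom)
    times = epoch_times()
    t_ms = times * 1000.0
    n_times = times.size
    rng = np.random.default_rng(seed)
    chol = _spatial_noise_chol(topo.n_sensors, params.noise_corr_length, rng)

    antic_env = _raised_cosine(t_ms, params.anticipation_window_ms)
    omis_env = _raised_cosine(t_ms, params.omission_window_ms)

    # stable condition signature patterns, shared across subjects: seeded
    # from the condition name so the entropy level is a decodable class
    sig_rng = np.random.default_rng(12345)
    signatures = {c: sig_rng.standard_normal(topo.n_sensors) / np.sqrt(topo.n_sensors)
                  for c in CONDITIONS}

    chunks, rows = [], []
    for cond in CONDITIONS:
        block = blocks[cond]
        g = predictability_index(mats[cond].p_dom)
        tones = block.tone_classes
        omis = block.omission_flags
        n_ev = len(tones) - 1  # skip event 0 (no previous tone)
        idx = np.arange(1, len(tones))
        prev = tones[idx - 1]
        expected = np.array([dominant_map[p] for p in prev])
        cur = tones[idx]
        is_om = omis[idx]

        X = np.zeros((n_ev, topo.n_sensors, n_times), dtype=float)
        jitter = np.exp(rng.normal(0.0, params.amplitude_jitter_sd, size=n_ev))

        evoked_term = topo.patterns[:, cur].T[:, :, None] * kernel.evoked[None, None, :]
        evoked_term[is_om] = 0.0
        persist_term = topo.patterns[:, prev].T[:, :, None] * kernel.persistence[None, None, :]
        X += evoked_term + persist_term
        if g > 0:
            exp_topo = topo.patterns[:, expected].T[:, :, None]
            X += params.anticipation_gain * g * exp_topo * antic_env[None, None, :]
            X[is_om] += (params.omission_gain * g
                         * exp_topo[is_om] * omis_env[None, None, :])
        X *= jitter[:, None, None]
        X += params.entropy_signature_gain * signatures[cond][None, :, None]
        X += params.noise_sd * _bandlimited_noise(X.shape, chol, rng)

        chunks.append(X.astype(dtype))
        rows.append(pd.DataFrame({
            "tone_class": cur,
            "condition": cond,
            "event_type": np.where(is_om, "omission", "sound"),
            "prev_tone_class": prev,
            "prev_was_omission": omis[idx - 1].astype(int),
            "subject_id": subject_id,
        }))

    return EpochSet(np.concatenate(chunks), pd.concat(rows, ignore_index=True), times)


def simulate_cohort(
    n_subjects: int = 12,
    n_sensors: int = 32,
    design: BlockDesign | None = None,
    params: SimulationParams | None = None,
    inter_class_corr: float = 0.5,
    seed: int = 0,
    entropy_gain_sd: float = 0.0,
    dominant_map: tuple[int, ...] = DEFAULT_DOMINANT_MAP,
) -> CohortDataset:
    """Simulate a cohort of mutually independent subjects.

    ``entropy_gain_sd`` > 0 draws each subject's entropy-signature gain from
    a truncated normal around the shared default, creating the
    between-subject variability that drives accuracy-correlation analyses.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    design = design or BlockDesign(n_stimuli=880, omission_rate=0.10)
    params = params or SimulationParams()
    seeds = _spawn_seeds(seed, 2 * n_subjects + 1)
    topo_seed, subj_seeds = seeds[0], seeds[1:]
    topo = make_topographies(n_sensors, inter_class_corr, topo_seed)
    kernel = make_kernel()

    subjects = []
    for s in range(n_subjects):
        block_seed, sim_seed = subj_seeds[2 * s], subj_seeds[2 * s + 1]
        blk_seeds = _spawn_seeds(block_seed, len(CONDITIONS))
        blocks = {c: make_block(c, design, blk_seeds[i], dominant_map)
                  for i, c in enumerate(CONDITIONS)}
        p = params
        if entropy_gain_sd > 0:
            gain_rng = np.random.default_rng(sim_seed + 7)
            e = max(0.0, gain_rng.normal(params.entropy_signature_gain,
                                         entropy_gain_sd))
            p = replace(params, entropy_signature_gain=e)
        subjects.append(simulate_subject(blocks, topo, kernel, p, sim_seed,
                                         subject_id=s, dominant_map=dominant_map))
    return CohortDataset(subjects, seed, params)
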