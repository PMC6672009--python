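"""Entropy-graded Markov tone sequences with omissions.

Stimulus design for a passive-listening auditory prediction experiment:
four pure tones, log-spaced in frequency, presented isochronously at 3 Hz.
The order of tones follows a first-order Markov chain whose transition
matrix sets the sequence entropy, from fully random (RD) through two
intermediate regularities (MM, MP) to highly ordered (OR), where each tone
is followed by a designated successor with 75% probability.  The diagonal
(immediate self-repetition) is fixed at 25% in every condition so that
repetition effects cannot distinguish the conditions.  Ten percent of the
stimuli are replaced by omissions (silence at an expected tone onset),
split exactly equally across the four tone classes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("RD", "MM", "MP", "OR")

#: Probability of the dominant successor per condition, linearly spaced on
#: [0.25, 0.75].  RD = chance, OR = 0.75; the intermediate values are
#: configurable because only their ordering, the 25% diagonal and double
#: stochasticity are fixed by the design.
DEFAULT_P_DOM = {"RD": 0.25, "MM": 0.25 + 1 / 6, "MP": 0.25 + 2 / 6, "OR": 0.75}

#: Default dominant-successor map: the cyclic permutation i -> (i+1) mod 4.
DEFAULT_DOMINANT_MAP = (1, 2, 3, 0)

N_TONES = 4


class InfeasibleDesignError(ValueError):
    """Raised when a stimulus block cannot satisfy its balance constraints."""


@dataclass(frozen=True)
class ToneSet:
    """Four carrier frequencies in Hz, strictly ascending and log-spaced."""

    frequencies_hz: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        if f.size != N_TONES:
            raise ValueError(f"expected {N_TONES} frequencies, got {f.size}")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        ratios = f[1:] / f[:-1]
        if np.max(np.abs(ratios / ratios[0] - 1)) > 0.005:
            raise ValueError("frequencies must be log-spaced (equal ratios)")

    @property
    def rounded_hz(self) -> tuple[int, ...]:
        """Frequencies rounded to integer Hz for display."""
        return tuple(int(round(f)) for f in self.frequencies_hz)


@dataclass(frozen=True)
class TransitionMatrix:
    """First-order Markov transition matrix for one entropy condition.

    ``probs[i, j]`` is the probability that tone ``j`` follows tone ``i``.
    Every matrix has 0.25 on the diagonal and is doubly stochastic, which
    guarantees a uniform stationary tone distribution in every condition.
    """

    condition: str
    probs: np.ndarray
    dominant_map: tuple[int, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_TONES, N_TONES):
            raise ValueError("transition matrix must be 4x4")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.max(np.abs(p.sum(axis=1) - 1)) > 1e-12:
            raise ValueError("rows must sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def p_dom(self) -> float:
        i = 0
        return float(self.probs[i, self.dominant_map[i]])


@dataclass(frozen=True)
class BlockDesign:
    """Timing and count parameters of one stimulation block."""

    n_stimuli: int = 4000
    rate_hz: float = 3.0
    tone_duration_ms: float = 100.0
    omission_rate: float = 0.10
    fade_ms: float = 5.0  # metadata only; no audio is synthesised

    def __post_init__(self) -> None:
        if self.n_stimuli % N_TONES:
            raise ValueError("n_stimuli must be divisible by 4")
        n_om = self.omission_rate * self.n_stimuli
        if abs(n_om - round(n_om)) > 1e-9 or round(n_om) % N_TONES:
            raise ValueError("omission_rate * n_stimuli must be divisible by 4")

    @property
    def n_omissions(self) -> int:
        return int(round(self.omission_rate * self.n_stimuli))

    @property
    def duration_s(self) -> float:
        return self.n_stimuli / self.rate_hz


@dataclass(frozen=True)
class StimulusEvent:
    index: int
    onset_s: float
    tone_class: int
    is_omission: bool


@dataclass
class StimulusBlock:
    """Ordered event list for one condition block."""

    condition: str
    design: BlockDesign
    events: list[StimulusEvent]
    seed: int

    @property
    def tone_classes(self) -> np.ndarray:
        return np.array([e.tone_class for e in self.events], dtype=int)

    @property
    def omission_flags(self) -> np.ndarray:
        return np.array([e.is_omission for e in self.events], dtype=bool)

    def to_frame(self, tones: ToneSet | None = None) -> pd.DataFrame:
        freq = (
            [tones.frequencies_hz[e.tone_class] for e in self.events]
            if tones is not None
            else [np.nan] * len(self.events)
        )
        return pd.DataFrame(
            {
                "index": [e.index for e in self.events],
                "onset_s": [e.onset_s for e in self.events],
                "tone_class": [e.tone_class for e in self.events],
                "freq_hz": freq,
                "is_omission": [int(e.is_omission) for e in self.events],
                "condition": self.condition,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, design: BlockDesign | None = None,
                 seed: int = -1) -> "StimulusBlock":
        df = pd.read_csv(path_or_buf)
        events = [
            StimulusEvent(int(idx), float(onset), int(tone), bool(int(om)))
            for idx, onset, tone, om in zip(df["index"], df["onset_s"],
                                            df["tone_class"], df["is_omission"])
        ]
        if design is None:
            n = len(events)
            rate = 1.0 / (events[1].onset_s - events[0].onset_s)
            n_om = int(sum(e.is_omission for e in events))
            design = BlockDesign(n_stimuli=n, rate_hz=round(rate, 9),
                                 omission_rate=n_om / n)
        return cls(str(df["condition"].iloc[0]), design, events, seed)


def make_tone_set(f_min: float, f_max: float, n: int = N_TONES) -> ToneSet:
    """Geometrically spaced carrier frequencies from ``f_min`` to ``f_max``.

    The default experimental set is (200, 2000, 4) -> 200, 431, 928, 2000 Hz
    (to the nearest integer).
    """
    if f_min <= 0 or f_max <= f_min:
        raise ValueError("need 0 < f_min < f_max")
    if n < 2:
        raise ValueError("need at least 2 frequencies")
    freqs = np.geomspace(f_min, f_max, n)
    return ToneSet(tuple(float(f) for f in freqs))


def make_transition_matrix(
    condition: str,
    dominant_map: tuple[int, ...] = DEFAULT_DOMINANT_MAP,
    p_dom: float | None = None,
) -> TransitionMatrix:
    """Build the transition matrix for one entropy condition.

    Row ``i`` places 0.25 on the diagonal, ``p_dom`` on ``dominant_map[i]``
    and splits the remaining mass equally over the other two tones.  With a
    fixed-point-free permutation as the dominant map this is doubly
    stochastic for any ``p_dom`` in [0.25, 0.75].
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    dm = tuple(int(i) for i in dominant_map)
    if sorted(dm) != list(range(N_TONES)):
        raise ValueError("dominant_map must be a permutation of 0..3")
    if any(dm[i] == i for i in range(N_TONES)):
        raise ValueError("dominant_map must be fixed-point-free "
                         "(diagonal is reserved for the 25% self-repetition)")
    p = DEFAULT_P_DOM[condition] if p_dom is None else float(p_dom)
    if not 0.25 <= p <= 0.75:
        raise ValueError("p_dom must lie in [0.25, 0.75]")
    T = np.full((N_TONES, N_TONES), (0.75 - p) / 2.0)
    for i in range(N_TONES):
        T[i, i] = 0.25
        T[i, dm[i]] = p
    return TransitionMatrix(condition, T, dm)


def standard_matrices(
    dominant_map: tuple[int, ...] = DEFAULT_DOMINANT_MAP,
    p_dom: dict[str, float] | None = None,
) -> dict[str, TransitionMatrix]:
    """The four condition matrices RD, MM, MP, OR."""
    pd_ = dict(DEFAULT_P_DOM)
    if p_dom:
        pd_.update(p_dom)
    return {c: make_transition_matrix(c, dominant_map, pd_[c]) for c in CONDITIONS}


def stationary_distribution(T: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Stationary distribution of the chain (left eigenvector for eigenvalue 1)."""
    P = T.probs if isinstance(T, TransitionMatrix) else np.asarray(T, float)
    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = pi / pi.sum()
    if np.any(pi < -1e-10):
        raise ValueError("matrix is not stochastic")
    return np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()


def markov_entropy_rate(T: TransitionMatrix | np.ndarray) -> float:
    """Entropy rate of the Markov chain in bits per transition.

    H = sum_i pi_i * ( -sum_j T_ij log2 T_ij ), with 0 log 0 := 0.
    """
    P = T.probs if isinstance(T, TransitionMatrix) else np.asarray(T, float)
    if np.max(np.abs(P.sum(axis=1) - 1)) > 1e-9 or np.any(P < 0):
        raise ValueError("matrix is not row-stochastic")
    pi = stationary_distribution(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log2(P), 0.0)
    return float(-(pi * plogp.sum(axis=1)).sum())


def _draw_sequence(P: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    seq = np.empty(n, dtype=int)
    seq[0] = rng.integers(N_TONES)
    u = rng.random(n)
    for t in range(1, n):
        seq[t] = int(np.searchsorted(cum[seq[t - 1]], u[t]))
    return seq


def generate_sequence(
    T: TransitionMatrix,
    n: int,
    seed: int,
    balance_tol: float = 0.10,
    max_attempts: int = 100,
) -> np.ndarray:
    """Sample a tone sequence of length ``n`` from the chain.

    The first tone is uniform; each subsequent tone is drawn from the row of
    the current tone.  Blocks are balanced across tone frequencies: the draw
    is repeated with a fresh sub-seed until every class count lies within
    ``balance_tol`` of n/4.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    target = n / N_TONES
    for child in ss.spawn(max_attempts):
        seq = _draw_sequence(T.probs, n, np.random.default_rng(child))
        counts = np.bincount(seq, minlength=N_TONES)
        if np.max(np.abs(counts - target)) <= balance_tol * target:
            return seq
    raise InfeasibleDesignError(
        f"could not balance tone counts within {balance_tol:.0%} "
        f"after {max_attempts} attempts")


def empirical_transition_matrix(tones: np.ndarray) -> np.ndarray:
    """Row-normalised bigram frequencies of a tone sequence.

    Rows for classes that never occur as a predecessor are NaN.
    """
    tones = np.asarray(tones, dtype=int)
    if tones.size < 2:
        raise ValueError("need at least 2 tones")
    counts = np.zeros((N_TONES, N_TONES))
    np.add.at(counts, (tones[:-1], tones[1:]), 1.0)
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return counts / rowsum


def insert_omissions(
    tones: np.ndarray,
    design: BlockDesign,
    seed: int,
    condition: str = "RD",
    warmup: int = 3,
    max_attempts: int = 200,
) -> StimulusBlock:
    """Replace a class-balanced subset of tones by omissions.

    Exactly ``design.n_omissions / 4`` events of each tone class are flagged
    as omissions; the flagged event keeps the tone class that *would* have
    been presented.  Constraints: no omission in the first ``warmup`` events
    and no two consecutive omissions (protects downstream exclusion of
    sounds preceded by an omission from cascading).  Onsets are isochronous
    at 1/rate spacing.
    """
    tones = np.asarray(tones, dtype=int)
    if tones.size != design.n_stimuli:
        raise ValueError("tone list length must equal design.n_stimuli")
    per_class = design.n_omissions // N_TONES
    counts = np.bincount(tones, minlength=N_TONES)
    if np.any(counts < per_class):
        short = int(np.argmin(counts))
        raise InfeasibleDesignError(
            f"class {short} has {counts[short]} tones but {per_class} omissions required")

    ss = np.random.SeedSequence(seed)
    chosen: set[int] | None = None
    for child in ss.spawn(max_attempts):
        rng = np.random.default_rng(child)
        sel: set[int] = set()
        ok = True
        for cls in rng.permutation(N_TONES):
            cand = np.flatnonzero((tones == cls) & (np.arange(tones.size) >= warmup))
            rng.shuffle(cand)
            taken = 0
            for idx in cand:
                if taken == per_class:
                    break
                if (idx - 1) in sel or (idx + 1) in sel:
                    continue
                sel.add(int(idx))
                taken += 1
            if taken < per_class:
                ok = False
                break
        if ok:
            chosen = sel
            break
    if chosen is None:
        raise InfeasibleDesignError("could not place omissions without adjacency")

    dt = 1.0 / design.rate_hz
    events = [
        StimulusEvent(i, i * dt, int(tones[i]), i in chosen)
        for i in range(tones.size)
    ]
    return StimulusBlock(condition, design, events, seed)


def make_block(
    condition: str,
    design: BlockDesign | None = None,
    seed: int = 0,
    dominant_map: tuple[int, ...] = DEFAULT_DOMINANT_MAP,
    p_dom: float | None = None,
) -> StimulusBlock:
    """Generate one complete condition block: sequence draw plus omissions."""
    design = design or BlockDesign()
    T = make_transition_matrix(condition, dominant_map, p_dom)
    seq_seed, om_seed = _spawn_seeds(seed, 2)
    seq = generate_sequence(T, design.n_stimuli, seq_seed)
    return insert_omissions(seq, design, om_seed, condition=condition)


def _spawn_seeds(master: int, n: int) -> list[int]:
    """Derive ``n`` documented sub-seeds from a master seed (counter scheme)."""
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
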