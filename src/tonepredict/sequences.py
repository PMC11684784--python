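"""Entropy-graded Markov tone sequences.

The stimulation paradigm presents four pure tones at a constant 3 Hz rate.
Presentation order is governed by a first-order Markov transition matrix whose
Shannon entropy sets the regularity of the sequence: in the *random* condition
every transition is equiprobable, while in the *ordered* condition each tone is
followed by one designated successor in 75% of trials.  Self-repetitions are
pinned to 25% in every condition so that repetition effects cannot confound the
entropy manipulation.  Two intermediate conditions (*midminus*, *midplus*)
interpolate the successor concentration between the two extremes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITIONS = ("random", "midminus", "midplus", "ordered")

#: fraction of the distance from random to ordered successor concentration
_CONDITION_MIX = {"random": 0.0, "midminus": 1.0 / 3.0, "midplus": 2.0 / 3.0, "ordered": 1.0}

SOA_S = 1.0 / 3.0  # stimulus-onset asynchrony at the 3 Hz presentation rate


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic tone transition matrix (row = current tone, col = next)."""

    probs: np.ndarray
    condition_label: str
    K: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (self.K, self.K):
            raise ValueError(f"expected a {self.K}x{self.K} matrix, got {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every row of a transition matrix must sum to 1")
        object.__setattr__(self, "probs", p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probs,
            index=pd.Index(range(self.K), name="tone_id"),
            columns=[f"to_{j}" for j in range(self.K)],
        )


@dataclass
class ToneSequence:
    """Ordered stimulus events sampled from a transition matrix.

    ``tone_id`` is retained on omitted events: an omission silences the sound
    but the underlying sequence position still has an identity.
    """

    tone_id: np.ndarray          # int, shape (n,)
    onset_s: np.ndarray          # float, strictly increasing, constant spacing
    condition: np.ndarray        # str per event
    is_omission: np.ndarray      # bool per event
    soa_s: float = SOA_S
    block: int = 0

    def __post_init__(self) -> None:
        n = len(self.tone_id)
        for name in ("onset_s", "condition", "is_omission"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if n > 1:
            d = np.diff(self.onset_s)
            if np.any(d <= 0) or not np.allclose(d, self.soa_s, atol=1e-9):
                raise ValueError("onsets must increase in constant steps of soa_s")

    def __len__(self) -> int:
        return len(self.tone_id)

    def to_frame(self, carrier_freqs_hz=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial_index": np.arange(len(self)),
                "onset_s": self.onset_s,
                "tone_id": self.tone_id,
                "condition": self.condition,
                "block": self.block,
                "is_omission": self.is_omission,
            }
        )
        if carrier_freqs_hz is not None:
            df.insert(3, "carrier_freq_hz", np.asarray(carrier_freqs_hz)[self.tone_id])
        return df


@dataclass(frozen=True)
class StudyDesign:
    """Stimulus-design preset: carrier set, conditions, counts and epoching."""

    study_id: str
    carrier_freqs_hz: tuple
    conditions: tuple
    n_trials_per_condition: int
    omission_rate: float
    block_layout: tuple  # ordered (condition, n_stimuli) segments, grouped per block
    epoch_window_s: tuple
    K: int = 4
    sfreq: float = 100.0

    @property
    def n_blocks(self) -> int:
        return len(self.block_layout)


def study1_design() -> StudyDesign:
    """Four entropy conditions, 1000 stimuli per condition block, 10% omissions."""
    return StudyDesign(
        study_id="study1",
        carrier_freqs_hz=(200, 431, 928, 2000),
        conditions=CONDITIONS,
        n_trials_per_condition=1000,
        omission_rate=0.10,
        block_layout=tuple(((cond, 1000),) for cond in CONDITIONS),
        epoch_window_s=(-1.0, 1.0),
    )


def study2_design() -> StudyDesign:
    """Random and ordered only, 1500 stimuli each in two alternating blocks."""
    return StudyDesign(
        study_id="study2",
        carrier_freqs_hz=(440, 587, 782, 1043),
        conditions=("random", "ordered"),
        n_trials_per_condition=1500,
        omission_rate=0.0,
        block_layout=(
            (("random", 500), ("ordered", 500), ("random", 500)),
            (("ordered", 500), ("random", 500), ("ordered", 500)),
        ),
        epoch_window_s=(-0.4, 0.5),
    )


DESIGNS = {"study1": study1_design, "study2": study2_design}


def get_design(name: str, **overrides) -> StudyDesign:
    try:
        design = DESIGNS[name]()
    except KeyError:
        raise ValueError(f"unknown design {name!r}; choose from {sorted(DESIGNS)}") from None
    return replace(design, **overrides) if overrides else design


def build_transition_matrix(
    condition_label: str, K: int = 4, order_strength: float = 0.75
) -> TransitionMatrix:
    """Build the transition matrix for one entropy condition.

    The diagonal (self-repetition) is fixed at 1/K in every condition.  The
    designated successor of tone *i* is tone *(i+1) mod K*; in the ordered
    condition it receives probability ``order_strength`` (default 0.75) and in
    the random condition 1/K.  The two mid conditions place the successor mass
    one third and two thirds of the way between those endpoints, with the
    remaining probability spread evenly over the other K−2 tones.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if condition_label not in _CONDITION_MIX:
        raise ValueError(f"unknown condition label {condition_label!r}")
    if not 0.0 <= order_strength <= (K - 1) / K:
        raise ValueError(f"order_strength must be in [0, {(K - 1) / K}]")

    mix = _CONDITION_MIX[condition_label]
    diag = 1.0 / K
    p_next = diag + mix * (order_strength - diag)
    probs = np.zeros((K, K))
    for i in range(K):
        probs[i, i] = diag
        probs[i, (i + 1) % K] = p_next
        rest = 1.0 - diag - p_next
        others = [j for j in range(K) if j not in (i, (i + 1) % K)]
        if others:
            probs[i, others] = rest / len(others)
        elif rest > 1e-12:
            raise ValueError("no tones left to absorb residual probability")
    return TransitionMatrix(probs=probs, condition_label=condition_label, K=K)


def matrix_entropy(m: TransitionMatrix) -> tuple[np.ndarray, float]:
    """Per-row Shannon entropy in bits (0·log 0 := 0) and the mean across rows."""
    p = m.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    row_bits = terms.sum(axis=1)
    return row_bits, float(row_bits.mean())


def generate_sequence(
    m: TransitionMatrix,
    n: int,
    seed,
    *,
    start_onset_s: float = 0.0,
    block: int = 0,
) -> ToneSequence:
    """Sample an n-tone Markov chain; the first tone is drawn uniformly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(m.probs, axis=1)
    tones = np.empty(n, dtype=np.int64)
    tones[0] = rng.integers(m.K)
    u = rng.random(n - 1)
    for t in range(1, n):
        tones[t] = np.searchsorted(cdf[tones[t - 1]], u[t - 1], side="right")
    onsets = start_onset_s + SOA_S * np.arange(n)
    return ToneSequence(
        tone_id=tones,
        onset_s=onsets,
        condition=np.full(n, m.condition_label, dtype=object),
        is_omission=np.zeros(n, dtype=bool),
        block=block,
    )


def insert_omissions(seq: ToneSequence, rate: float, seed) -> ToneSequence:
    """Flag exactly round(rate·n) uniformly chosen events as omitted."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    n = len(seq)
    k = int(round(rate * n))
    flags = np.zeros(n, dtype=bool)
    if k:
        rng = np.random.default_rng(seed)
        flags[rng.choice(n, size=k, replace=False)] = True
    return ToneSequence(
        tone_id=seq.tone_id.copy(),
        onset_s=seq.onset_s.copy(),
        condition=seq.condition.copy(),
        is_omission=flags,
        soa_s=seq.soa_s,
        block=seq.block,
    )


def make_study_blocks(design: StudyDesign, seed) -> list[ToneSequence]:
    """Generate every block of a study as one ToneSequence per block.

    Within a block, consecutive segments follow their own transition matrix and
    their onsets continue on the common 3 Hz grid.  Segment sums must match the
    declared per-condition trial totals.
    """
    totals: dict[str, int] = {}
    for segs in design.block_layout:
        for cond, n in segs:
            totals[cond] = totals.get(cond, 0) + n
    for cond in design.conditions:
        if totals.get(cond, 0) != design.n_trials_per_condition:
            raise ValueError(
                f"block layout yields {totals.get(cond, 0)} stimuli for {cond!r}; "
                f"design requires {design.n_trials_per_condition}"
            )

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    matrices = {c: build_transition_matrix(c, K=design.K) for c in design.conditions}
    blocks: list[ToneSequence] = []
    for b, segs in enumerate(design.block_layout):
        parts = []
        onset = 0.0
        for (cond, n), child in zip(segs, ss.spawn(len(segs))):
            part = generate_sequence(matrices[cond], n, child, start_onset_s=onset, block=b)
            onset = part.onset_s[-1] + SOA_S
            parts.append(part)
        seq = ToneSequence(
            tone_id=np.concatenate([p.tone_id for p in parts]),
            onset_s=np.concatenate([p.onset_s for p in parts]),
            condition=np.concatenate([p.condition for p in parts]),
            is_omission=np.concatenate([p.is_omission for p in parts]),
            block=b,
        )
        if design.omission_rate > 0:
            seq = insert_omissions(seq, design.omission_rate, ss.spawn(1)[0])
        blocks.append(seq)
    return blocks


def log_spaced_freqs(f_lo: float, f_hi: float, K: int) -> list[int]:
    """K geometrically spaced frequencies between the endpoints, rounded to Hz."""
    if f_lo <= 0 or f_hi <= f_lo:
        raise ValueError("need 0 < f_lo < f_hi")
    if K < 2:
        raise ValueError("K must be >= 2")
    return [int(round(f)) for f in np.geomspace(f_lo, f_hi, K)]
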