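"""Design-constant and chance-level calibration computations.

These routines recompute, from scratch, quantities that are fixed by the
stimulus design (transition-matrix constants, long-run sequence statistics)
or by construction of the decoder (chance level under label permutation).
They are used by the acceptance script and the calibration tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .decoding import DecoderConfig, cv_decode_random
from .sequences import (
    CONDITIONS,
    build_transition_matrix,
    generate_sequence,
    get_design,
    make_study_blocks,
)
from .simulate import (
    AUDIOGRAM_FREQS_HZ,
    DEFAULT_SNR,
    Audiogram,
    EpochsContainer,
    ResponseKernel,
    SubjectSpec,
    make_sensor_model,
    simulate_subject,
)


def ordered_sequence_stats(seed, n: int = 100_000) -> tuple[float, float]:
    """Self-repetition and designated-successor percentages of an ordered chain."""
    m = build_transition_matrix("ordered")
    seq = generate_sequence(m, n, seed=seed)
    prev, nxt = seq.tone_id[:-1], seq.tone_id[1:]
    self_rep = 100.0 * np.mean(nxt == prev)
    successor = 100.0 * np.mean(nxt == (prev + 1) % m.K)
    return float(self_rep), float(successor)


def permuted_label_accuracy(seed, n_trials: int = 800, n_repeats: int = 20) -> float:
    """Mean CV decoding accuracy (%) of one subject with permuted tone labels.

    Simulates a single random-condition subject at the default generator
    settings, shuffles the tone labels, runs fivefold CV decoding, and averages
    accuracy over all time points and ``n_repeats`` label permutations.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    design = replace(
        get_design("study2"),
        conditions=("random",),
        n_trials_per_condition=n_trials,
        block_layout=((("random", n_trials),),),
    )
    model_seed, seq_seed, noise_seed, perm_seed = ss.spawn(4)
    sensors = make_sensor_model(seed=model_seed)
    kernel = ResponseKernel()
    flat = np.full(len(AUDIOGRAM_FREQS_HZ), 10.0)
    spec = SubjectSpec(
        "chance", "tinnitus", alpha_pre=0.0, snr=DEFAULT_SNR,
        audiogram=Audiogram(AUDIOGRAM_FREQS_HZ, flat, flat.copy()),
    )
    seqs = make_study_blocks(design, seq_seed)
    epochs = simulate_subject(design, seqs, sensors, kernel, spec, noise_seed)
    rng = np.random.default_rng(perm_seed)
    means = []
    for _ in range(n_repeats):
        shuffled = EpochsContainer(
            data=epochs.data,
            times_s=epochs.times_s,
            labels=rng.permutation(epochs.labels),
            condition=epochs.condition,
            sfreq=epochs.sfreq,
            subject_id=epochs.subject_id,
        )
        timecourse, _, _ = cv_decode_random(shuffled, DecoderConfig())
        means.append(timecourse.mean())
    return float(100.0 * np.mean(means))


def transition_diagonals_percent() -> float:
    """Diagonal entry (in %) shared by all four condition transition matrices."""
    diags = np.concatenate(
        [np.diag(build_transition_matrix(c).probs) for c in CONDITIONS]
    )
    if not np.allclose(diags, diags[0]):
        raise AssertionError("diagonals differ across conditions")
    return float(100.0 * diags[0])
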