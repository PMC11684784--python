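"""Shared fixtures: small, fast synthetic designs and cohorts."""

from dataclasses import replace

import numpy as np
import pytest

from tonepredict.decoding import DecoderConfig
from tonepredict.sequences import get_design, make_study_blocks
from tonepredict.simulate import (
    Audiogram,
    AUDIOGRAM_FREQS_HZ,
    ResponseKernel,
    SubjectSpec,
    make_sensor_model,
    simulate_subject,
)


def scaled_study2(n_per_condition: int):
    """Study-2 layout shrunk to ``n_per_condition`` stimuli per condition."""
    half = n_per_condition // 2
    return replace(
        get_design("study2"),
        n_trials_per_condition=2 * half,
        block_layout=(
            (("random", half), ("ordered", half)),
            (("ordered", half), ("random", half)),
        ),
    )


@pytest.fixture(scope="session")
def small_design():
    return scaled_study2(120)


@pytest.fixture(scope="session")
def small_sensors():
    # 24 channels keeps LDA fits fast while staying well-conditioned
    return make_sensor_model(n_channels=24, K=4, seed=11)


@pytest.fixture(scope="session")
def kernel():
    return ResponseKernel()


def flat_audiogram(level_db: float = 15.0) -> Audiogram:
    n = len(AUDIOGRAM_FREQS_HZ)
    return Audiogram(
        freqs_hz=AUDIOGRAM_FREQS_HZ,
        left_db=np.full(n, level_db),
        right_db=np.full(n, level_db),
    )


def make_subject(design, sensors, kernel, alpha_pre=0.0, snr=2.5, seed=0, seq_seed=1):
    spec = SubjectSpec(
        subject_id=f"sub_{seed}",
        group="control" if alpha_pre < 0 else "tinnitus",
        alpha_pre=alpha_pre,
        snr=snr,
        audiogram=flat_audiogram(),
    )
    seqs = make_study_blocks(design, seq_seed)
    epochs = simulate_subject(design, seqs, sensors, kernel, spec, seed)
    return spec, seqs, epochs


@pytest.fixture(scope="session")
def noisy_subject(small_design, small_sensors, kernel):
    """One subject at the default SNR, no anticipatory effect."""
    return make_subject(small_design, small_sensors, kernel, alpha_pre=0.0, seed=3)


@pytest.fixture(scope="session")
def noiseless_subject(small_design, small_sensors, kernel):
    """Deterministic epochs: snr=inf disables the noise term."""
    return make_subject(small_design, small_sensors, kernel, alpha_pre=0.0, snr=np.inf, seed=3)


@pytest.fixture(scope="session")
def fast_decoder_cfg():
    return DecoderConfig(train_window_s=(0.470, 0.570))
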