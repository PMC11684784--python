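"""Synthetic epoched MEG sensor data with a controllable anticipatory effect.

Each of the K tones evokes a fixed spatial topography over the (magnetometer)
sensor array, modulated in time by a response kernel with an early (~100 ms)
and a late (~450 ms) component.  Epochs are built by linear superposition of
the kernels of every tone overlapping the epoch window (neighbouring tones at
±333 ms bleed in by design), plus spatially correlated Gaussian noise.

The anticipatory effect of interest is injected as a pre-stimulus (de)activation
of the *predicted* tone's late pattern on ordered-condition trials: the tone
predicted by the learned regularity — the cyclic successor of the preceding
tone — has its topography added with gain ``alpha_pre`` in a bump centred at
−380 ms.  A negative gain in the control-like group produces below-chance
pre-stimulus cross-decoding, the signature the group statistics are built to
detect.

Per-subject audiograms (for PTA covariate analyses) and a tinnitus-distress
score on the Mini-TQ scale are drawn alongside the sensor data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import SOA_S, StudyDesign, ToneSequence, make_study_blocks

AUDIOGRAM_FREQS_HZ = (125, 250, 500, 1000, 2000, 4000, 6000, 8000)
PTA4_FREQS_HZ = (500, 1000, 2000, 4000)
PTA_EXTENDED_FREQS_HZ = (500, 1000, 2000, 4000, 6000, 8000)

# Default gain of the late-pattern pre-activation, expressed as a fraction of
# the late-component amplitude: controls deactivate, tinnitus-like subjects
# neither activate nor deactivate.
DEFAULT_ALPHA_FRACTION_CONTROL = -0.3
DEFAULT_SNR = 2.5


@dataclass(frozen=True)
class SensorModel:
    """Spatial model of the sensor array: tone topographies and noise covariance."""

    n_channels: int
    topographies: np.ndarray      # K x n_channels, unit Euclidean norm rows
    noise_cov: np.ndarray         # n_channels x n_channels, symmetric PSD
    smoothness: float
    _noise_chol: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.topographies.shape[1] != self.n_channels:
            raise ValueError("topography width must equal n_channels")
        if not np.allclose(np.linalg.norm(self.topographies, axis=1), 1.0, atol=1e-9):
            raise ValueError("topographies must be unit-norm")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise ValueError("noise covariance must be symmetric")
        chol = np.linalg.cholesky(
            self.noise_cov + 1e-10 * np.eye(self.n_channels)
        )
        object.__setattr__(self, "_noise_chol", chol)

    @property
    def K(self) -> int:
        return self.topographies.shape[0]


@dataclass(frozen=True)
class ResponseKernel:
    """Causal evoked-response kernel: early and late unimodal components."""

    sfreq: float = 100.0
    early_latency_s: float = 0.10
    early_width_s: float = 0.025
    a_early: float = 1.0
    late_latency_s: float = 0.45
    late_width_s: float = 0.05
    a_late: float = 0.6
    duration_s: float = 0.7

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s, 1.0 / self.sfreq)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Kernel values at arbitrary times; identically zero for t < 0."""
        t = np.asarray(t, dtype=float)
        early = self.a_early * np.exp(-0.5 * ((t - self.early_latency_s) / self.early_width_s) ** 2)
        late = self.a_late * np.exp(-0.5 * ((t - self.late_latency_s) / self.late_width_s) ** 2)
        return np.where(t >= 0, early + late, 0.0)

    def pre_bump(self, t: np.ndarray, center_s: float = -0.38) -> np.ndarray:
        """Unit-amplitude anticipatory bump in the pre-stimulus interval."""
        t = np.asarray(t, dtype=float)
        return np.where(t < 0, np.exp(-0.5 * ((t - center_s) / self.late_width_s) ** 2), 0.0)


@dataclass
class Audiogram:
    """Hearing thresholds in dB HL per ear at the standard audiometric frequencies."""

    freqs_hz: tuple
    left_db: np.ndarray
    right_db: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.left_db, self.right_db):
            if len(arr) != len(self.freqs_hz):
                raise ValueError("threshold array length must match frequency list")
            if np.any(arr < -10) or np.any(arr > 120):
                raise ValueError("thresholds must lie in [-10, 120] dB HL")

    def thresholds(self, freq_hz: int) -> tuple[float, float]:
        try:
            i = self.freqs_hz.index(freq_hz)
        except ValueError:
            raise KeyError(f"audiogram has no threshold at {freq_hz} Hz") from None
        return float(self.left_db[i]), float(self.right_db[i])


@dataclass
class SubjectSpec:
    subject_id: str
    group: str                    # "tinnitus" or "control"
    alpha_pre: float              # signed gain of the predicted tone's late pattern
    snr: float
    audiogram: Audiogram
    distress: float | None = None   # Mini-TQ score; tinnitus-like subjects only


@dataclass
class EpochsContainer:
    """Per-subject epoched sensor data: trials x channels x time at 100 Hz."""

    data: np.ndarray
    times_s: np.ndarray
    labels: np.ndarray            # tone_id per trial
    condition: np.ndarray         # condition label per trial
    sfreq: float
    subject_id: str
    is_omission: np.ndarray = None

    def __post_init__(self) -> None:
        n, c, t = self.data.shape
        if len(self.times_s) != t or len(self.labels) != n or len(self.condition) != n:
            raise ValueError("epoch dimensions inconsistent with metadata")
        dt = np.diff(self.times_s)
        if len(dt) and not np.allclose(dt, 1.0 / self.sfreq, atol=1e-9):
            raise ValueError("time grid must be uniform at 1/sfreq")
        if self.is_omission is None:
            self.is_omission = np.zeros(n, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "EpochsContainer":
        return EpochsContainer(
            data=self.data[mask],
            times_s=self.times_s,
            labels=self.labels[mask],
            condition=self.condition[mask],
            sfreq=self.sfreq,
            subject_id=self.subject_id,
            is_omission=self.is_omission[mask],
        )

    def sound_trials(self, condition: str | None = None) -> "EpochsContainer":
        mask = ~self.is_omission
        if condition is not None:
            mask &= self.condition == condition
        return self.select(mask)


def _smooth_patterns(n_patterns, n_channels, smoothness, rng):
    """Spatially smooth random sensor patterns via a squared-exponential kernel."""
    pos = np.linspace(0.0, 1.0, n_channels)
    cov = np.exp(-0.5 * ((pos[:, None] - pos[None, :]) / smoothness) ** 2)
    chol = np.linalg.cholesky(cov + 1e-8 * np.eye(n_channels))
    return rng.standard_normal((n_patterns, n_channels)) @ chol.T


def make_sensor_model(
    n_channels: int = 102,
    K: int = 4,
    smoothness: float = 0.08,
    seed=None,
    max_cosine: float = 0.8,
    max_redraws: int = 50,
    orthogonal: bool = False,
) -> SensorModel:
    """Draw K unit-norm, mutually discriminable tone topographies plus noise covariance.

    Patterns are redrawn (up to ``max_redraws`` times) until every pairwise
    absolute cosine similarity is below ``max_cosine``.  With
    ``orthogonal=True`` the patterns are orthonormalized (pairwise cosine 0).
    """
    if n_channels < K:
        raise ValueError("need at least as many channels as tone classes")
    rng = np.random.default_rng(seed)
    for _ in range(max_redraws):
        pats = _smooth_patterns(K, n_channels, smoothness, rng)
        if orthogonal:
            pats = np.linalg.qr(pats.T)[0].T
        pats /= np.linalg.norm(pats, axis=1, keepdims=True)
        gram = np.abs(pats @ pats.T)
        np.fill_diagonal(gram, 0.0)
        if gram.max() < max_cosine:
            break
    else:
        raise RuntimeError(
            f"could not draw {K} topographies with |cos| < {max_cosine} "
            f"in {max_redraws} attempts"
        )
    pos = np.linspace(0.0, 1.0, n_channels)
    noise_cov = np.exp(-0.5 * ((pos[:, None] - pos[None, :]) / (2 * smoothness)) ** 2)
    noise_cov = 0.5 * noise_cov + 0.5 * np.eye(n_channels)
    return SensorModel(
        n_channels=n_channels,
        topographies=pats,
        noise_cov=noise_cov,
        smoothness=smoothness,
    )


def predicted_next_tone(tone_id: np.ndarray, K: int) -> np.ndarray:
    """Tone predicted by the learned regularity: the cyclic successor of the
    previous tone.  Position 0 has no predecessor; its prediction is its own
    successor-of-self placeholder (never used pre-stimulus at the sequence start)."""
    pred = np.empty_like(tone_id)
    pred[1:] = (tone_id[:-1] + 1) % K
    pred[0] = (tone_id[0] + 1) % K
    return pred


def simulate_subject(
    design: StudyDesign,
    sequences: list[ToneSequence],
    sensors: SensorModel,
    kernel: ResponseKernel,
    spec: SubjectSpec,
    seed,
    pre_center_s: float = -0.38,
) -> EpochsContainer:
    """Render one subject's epochs from the study's tone sequences.

    Every epoch is the superposition of topography⊗kernel for each non-omitted
    tone overlapping the window, plus — on ordered-condition trials — the
    anticipatory term alpha_pre · topography(predicted tone) ⊗ pre-stimulus
    bump, plus spatially correlated noise with per-channel standard deviation
    a_early / snr.
    """
    if sensors.K != design.K:
        raise ValueError("sensor model and design disagree on the number of tones")
    rng = np.random.default_rng(seed)
    tmin, tmax = design.epoch_window_s
    times = np.round(np.arange(round(tmin * design.sfreq), round(tmax * design.sfreq) + 1)
                     ) / design.sfreq

    all_data, all_labels, all_cond, all_omit = [], [], [], []
    # neighbours within this lag range can contribute to the epoch window
    max_lag = int(np.ceil((tmax + kernel.duration_s) / SOA_S)) + 1
    for seq in sequences:
        n = len(seq)
        pred = predicted_next_tone(seq.tone_id, design.K)
        # per-trial kernel weight of every tone class, assembled lag by lag;
        # kernel sampled once per lag since onsets sit exactly on the 3 Hz grid
        coef = np.zeros((n, design.K, len(times)), dtype=np.float32)
        for lag in range(-max_lag, max_lag + 1):
            kvals = kernel.evaluate(times - lag * SOA_S).astype(np.float32)
            if not np.any(kvals):
                continue
            src = np.arange(n) + lag          # sequence position sounding at this lag
            ok = (src >= 0) & (src < n)
            ok &= ~seq.is_omission[np.clip(src, 0, n - 1)]
            if not np.any(ok):
                continue
            coef[np.flatnonzero(ok), seq.tone_id[src[ok]]] += kvals
        if spec.alpha_pre != 0.0:
            bump = kernel.pre_bump(times, center_s=pre_center_s).astype(np.float32)
            if np.any(bump):
                ordered_mask = np.flatnonzero(seq.condition == "ordered")
                coef[ordered_mask, pred[ordered_mask]] += (
                    np.float32(spec.alpha_pre * kernel.a_late) * bump
                )
        clean = np.ascontiguousarray(
            np.tensordot(coef, sensors.topographies.astype(np.float32), axes=([1], [0])
                         ).transpose(0, 2, 1)
        )
        if np.isfinite(spec.snr):
            sigma = kernel.a_early / spec.snr
            n_tr, C, T = clean.shape
            z = rng.standard_normal((C, n_tr * T), dtype=np.float32)
            chol32 = sensors._noise_chol.astype(np.float32)
            noise = (chol32 @ z).reshape(C, n_tr, T)
            clean += sigma * np.transpose(noise, (1, 0, 2))
        all_data.append(clean)
        all_labels.append(seq.tone_id)
        all_cond.append(seq.condition)
        all_omit.append(seq.is_omission)

    return EpochsContainer(
        data=np.concatenate(all_data, axis=0),
        times_s=times,
        labels=np.concatenate(all_labels),
        condition=np.concatenate(all_cond),
        sfreq=design.sfreq,
        subject_id=spec.subject_id,
        is_omission=np.concatenate(all_omit),
    )


def _draw_audiogram(rng) -> Audiogram:
    """Audiometric thresholds with a mild high-frequency slope, shared by both groups."""
    base = rng.normal(10.0, 5.0)
    slope = rng.normal(0.0, 4.0) + np.array([0, 0, 0, 1, 2, 5, 8, 10], dtype=float)
    left = np.clip(base + slope + rng.normal(0, 3, len(AUDIOGRAM_FREQS_HZ)), -10, 120)
    right = np.clip(base + slope + rng.normal(0, 3, len(AUDIOGRAM_FREQS_HZ)), -10, 120)
    return Audiogram(freqs_hz=AUDIOGRAM_FREQS_HZ, left_db=left, right_db=right)


def default_group_params(kernel: ResponseKernel | None = None) -> dict:
    """Group-level anticipatory gains: controls deactivate, tinnitus-like do not."""
    return {
        "tinnitus": {"alpha_pre": 0.0, "snr": DEFAULT_SNR},
        "control": {"alpha_pre": DEFAULT_ALPHA_FRACTION_CONTROL, "snr": DEFAULT_SNR},
    }


def simulate_cohort(
    design: StudyDesign,
    n_per_group: int,
    group_params: dict | None = None,
    seed=None,
    sensors: SensorModel | None = None,
    kernel: ResponseKernel | None = None,
) -> list[tuple[SubjectSpec, EpochsContainer]]:
    """Simulate a matched two-group cohort.

    Audiograms come from one shared distribution (groups are hearing-matched by
    construction); Mini-TQ distress is drawn for tinnitus-like subjects only.
    Per-subject seeds are spawned from the master seed.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    kernel = kernel or ResponseKernel(sfreq=design.sfreq)
    group_params = group_params or default_group_params(kernel)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    if sensors is None:
        sensors = make_sensor_model(K=design.K, seed=ss.spawn(1)[0])
    cohort = []
    for group in ("tinnitus", "control"):
        gp = group_params[group]
        for i in range(n_per_group):
            sub_ss = ss.spawn(1)[0]
            rng = np.random.default_rng(sub_ss)
            spec = SubjectSpec(
                subject_id=f"{group}_{i:03d}",
                group=group,
                alpha_pre=float(gp.get("alpha_pre", 0.0)),
                snr=float(gp.get("snr", DEFAULT_SNR)),
                audiogram=_draw_audiogram(rng),
                distress=float(np.clip(rng.normal(11.0, 5.0), 0, 24))
                if group == "tinnitus"
                else None,
            )
            seqs = make_study_blocks(design, sub_ss.spawn(1)[0])
            epochs = simulate_subject(design, seqs, sensors, kernel, spec, sub_ss.spawn(1)[0])
            cohort.append((spec, epochs))
    return cohort


def pta(audiogram: Audiogram, freqs_hz=PTA4_FREQS_HZ) -> dict:
    """Pure-tone average over the given frequencies, per ear and ear-averaged."""
    pairs = [audiogram.thresholds(f) for f in freqs_hz]
    left = float(np.mean([p[0] for p in pairs]))
    right = float(np.mean([p[1] for p in pairs]))
    return {"left": left, "right": right, "mean": (left + right) / 2.0}


def pta4(audiogram: Audiogram) -> float:
    """Ear-averaged pure-tone average at 500/1000/2000/4000 Hz."""
    return pta(audiogram, PTA4_FREQS_HZ)["mean"]


def pta_extended(audiogram: Audiogram) -> float:
    """PTA extended to 6000 and 8000 Hz for the high-frequency sensitivity analysis."""
    return pta(audiogram, PTA_EXTENDED_FREQS_HZ)["mean"]


def hearing_loss_flag(audiogram: Audiogram) -> bool:
    """True iff any threshold exceeds 30 dB HL (strictly) at any frequency, either ear."""
    return bool(np.any(audiogram.left_db > 30) or np.any(audiogram.right_db > 30))
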