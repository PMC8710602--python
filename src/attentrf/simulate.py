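"""Synthetic cocktail-party trials with known attentional ground truth.

Each trial emulates the statistical structure the analysis assumes: two
time-aligned speech-like streams (11–18 s), three keyword response windows
(early/middle/late), a latent binary attention trajectory that starts on the
target and switches at Poisson times whose hazard encodes task difficulty,
ternary behavioral responses consistent with attention inside the windows
(with a lapse probability producing extraneous answers), and multichannel EEG
generated as a lagged linear convolution of the attended envelope plus noise.

Everything is a pure function of (configuration, master seed), with
hierarchical seeding master → subject → trial → named stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dsp import EEGRecord, Envelope, MODEL_RATE_HZ
from .inference import KeywordInterval, ResponseWindow, make_windows

__all__ = [
    "ConditionSpec",
    "EEGSimSpec",
    "SimConfig",
    "ForwardTRF",
    "AttentionTrajectory",
    "SimulatedSubject",
    "gen_stream",
    "gen_keyword_times",
    "gen_attention_trajectory",
    "gen_responses",
    "gen_eeg",
    "gen_trial",
    "gen_dataset",
]


@dataclass(frozen=True)
class ConditionSpec:
    """A difficulty level: attentional-switch hazard and response lapse rate."""

    label: str
    switch_hazard_per_s: float
    lapse_prob: float

    def __post_init__(self) -> None:
        if self.switch_hazard_per_s < 0:
            raise ValueError("switch_hazard_per_s must be >= 0")
        if not 0 <= self.lapse_prob <= 1:
            raise ValueError("lapse_prob must be in [0, 1]")


@dataclass(frozen=True)
class EEGSimSpec:
    """Forward-model parameters for simulated EEG."""

    n_channels: int = 31
    kernel_latency_s: float = 0.15
    kernel_width_s: float = 0.4
    snr: float = 0.05  # signal-power / noise-power; np.inf for noiseless


# Default difficulty ladder: hazards chosen so simulated response error rates
# bracket the ~2-3x error-rate ratio between the hardest and easiest levels.
DEFAULT_CONDITIONS = (
    ConditionSpec("easy", 0.00, 0.05),
    ConditionSpec("intermediate", 0.02, 0.10),
    ConditionSpec("difficult", 0.08, 0.15),
)


@dataclass(frozen=True)
class SimConfig:
    """Full simulation design: subjects × conditions × trials."""

    n_subjects: int = 20
    n_trials_per_condition: int = 48
    trial_duration_range_s: tuple[float, float] = (11.0, 18.0)
    rate_hz: float = MODEL_RATE_HZ
    audio_rate_hz: float = 16000.0
    conditions: tuple[ConditionSpec, ...] = DEFAULT_CONDITIONS
    eeg: EEGSimSpec = EEGSimSpec()
    master_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.trial_duration_range_s
        if not (0 < lo <= hi):
            raise ValueError("invalid trial duration range")
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ValueError("need at least one subject and one trial")


@dataclass
class ForwardTRF:
    """Per-channel forward kernels mapping the attended envelope to EEG.

    The base kernel is a gamma-windowed sinusoid peaking near 150 ms with
    ~400 ms support — typical speech-tracking response morphology — scaled by
    per-channel gains (which may flip sign, as scalp topographies do).
    """

    kernels: np.ndarray  # (n_channels, n_kernel_samples)
    rate_hz: float

    @classmethod
    def speech_like(
        cls,
        n_channels: int,
        rate_hz: float = MODEL_RATE_HZ,
        latency_s: float = 0.15,
        width_s: float = 0.4,
        osc_hz: float = 3.0,
        seed=None,
    ) -> "ForwardTRF":
        t = np.arange(int(round(width_s * rate_hz))) / rate_hz
        shape_k = 2.0
        scale = latency_s / shape_k  # gamma mode at the latency
        window = (t / scale) ** shape_k * np.exp(-t / scale)
        base = window * np.cos(2.0 * np.pi * osc_hz * (t - latency_s))
        base = base / np.linalg.norm(base)
        rng = np.random.default_rng(seed)
        gains = rng.normal(1.0, 0.3, size=n_channels)
        return cls(gains[:, None] * base[None, :], rate_hz)

    @property
    def n_channels(self) -> int:
        return self.kernels.shape[0]


@dataclass
class AttentionTrajectory:
    """Latent attended source over time: alternating target/masker segments."""

    switch_times_s: np.ndarray  # times of switches; attention starts on target
    duration_s: float

    def source_at(self, t: float) -> str:
        n = int(np.searchsorted(self.switch_times_s, t, side="right"))
        return "target" if n % 2 == 0 else "masker"

    def target_indicator(self, rate_hz: float) -> np.ndarray:
        """1 where the target is attended, 0 where the masker is, hard edges."""
        n = int(round(self.duration_s * rate_hz))
        t = np.arange(n) / rate_hz
        flips = np.searchsorted(self.switch_times_s, t, side="right")
        return (flips % 2 == 0).astype(float)

    def weights(self, rate_hz: float, crossfade_s: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
        """(w_target, w_masker) with raised-cosine crossfades at each switch."""
        n = int(round(self.duration_s * rate_hz))
        t = np.arange(n) / rate_hz
        w_t = self.target_indicator(rate_hz)
        half = crossfade_s / 2.0
        for j, st in enumerate(self.switch_times_s):
            going_to_masker = j % 2 == 0
            mask = (t >= st - half) & (t < st + half)
            fade = 0.5 * (1.0 + np.cos(np.pi * (t[mask] - (st - half)) / crossfade_s))
            w_t[mask] = fade if going_to_masker else 1.0 - fade
        return w_t, 1.0 - w_t

    def target_fraction(self) -> float:
        edges = np.concatenate([[0.0], self.switch_times_s, [self.duration_s]])
        seg = np.diff(edges)
        return float(seg[::2].sum() / self.duration_s)

    def majority_source(self, start_s: float, end_s: float) -> str:
        edges = np.concatenate([[0.0], self.switch_times_s, [self.duration_s]])
        t_time = 0.0
        for i in range(len(edges) - 1):
            lo, hi = max(edges[i], start_s), min(edges[i + 1], end_s)
            if hi > lo and i % 2 == 0:
                t_time += hi - lo
        return "target" if t_time >= 0.5 * (end_s - start_s) else "masker"


@dataclass
class SimulatedSubject:
    """All trials of one simulated subject, with seed provenance."""

    subject_id: str
    trials: list  # list[TrialRecord]
    seed_entropy: int = 0

    def trials_in(self, condition: str) -> list:
        return [t for t in self.trials if t.condition == condition]

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.condition, None)
        return list(seen)


# ---------------------------------------------------------------------------
# generators


def gen_stream(
    duration_s: float,
    seed,
    mode: str = "envelope",
    rate_hz: float = MODEL_RATE_HZ,
    audio_rate_hz: float = 16000.0,
    n_components: int = 8,
) -> np.ndarray:
    """Speech-like stream: rectified sum of randomized syllabic-rate components.

    In "envelope" mode returns a nonnegative 64 Hz envelope whose modulation
    spectrum peaks in the 2–8 Hz syllabic range.  In "waveform" mode the
    envelope (interpolated to the audio rate) modulates a Gaussian noise
    carrier.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if mode not in ("envelope", "waveform"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    freqs = rng.uniform(2.0, 8.0, size=n_components)
    amps = rng.uniform(0.5, 1.5, size=n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_components)
    env = np.maximum(0.0, np.sin(2.0 * np.pi * freqs[:, None] * t + phases[:, None]).T @ amps)
    if mode == "envelope":
        return env
    n_audio = int(round(duration_s * audio_rate_hz))
    t_audio = np.arange(n_audio) / audio_rate_hz
    carrier = rng.standard_normal(n_audio)
    return np.interp(t_audio, t, env) * carrier


def gen_keyword_times(duration_s: float, seed) -> list[tuple[KeywordInterval, KeywordInterval]]:
    """Three target–masker keyword pairs in the early/middle/late thirds.

    Keyword lengths are 0.3–0.8 s; paired onsets differ by 0–1 s; each union
    window lies strictly inside its third, so windows are ordered and disjoint.
    """
    if duration_s < 9.0:
        raise ValueError("need at least 9 s to place three keyword windows")
    rng = np.random.default_rng(seed)
    third = duration_s / 3.0
    margin = 0.1
    pairs = []
    for i in range(3):
        lo = i * third
        t_len = rng.uniform(0.3, 0.8)
        m_len = rng.uniform(0.3, 0.8)
        offset = rng.uniform(0.0, 1.0) * rng.choice([-1.0, 1.0])
        # the union window [t_on+min(0,offset), t_on+max(t_len, offset+m_len)]
        # must fit within [lo+margin, lo+third-margin]; with lengths <= 0.8 s
        # and |offset| <= 1 s this interval is nonempty for any trial >= 9 s
        start_min = lo + margin + max(0.0, -offset)
        start_max = lo + third - margin - max(t_len, offset + m_len)
        t_on = rng.uniform(start_min, start_max)
        m_on = t_on + offset
        pairs.append(
            (
                KeywordInterval(t_on, t_on + t_len, "target"),
                KeywordInterval(m_on, m_on + m_len, "masker"),
            )
        )
    return pairs


def gen_attention_trajectory(duration_s: float, hazard_per_s: float, seed) -> AttentionTrajectory:
    """Latent attention: starts on target, Poisson switches, 1 s minimum dwell."""
    if hazard_per_s < 0:
        raise ValueError("hazard_per_s must be >= 0")
    rng = np.random.default_rng(seed)
    switches = []
    if hazard_per_s > 0:
        t = 0.0
        while True:
            t += 1.0 + rng.exponential(1.0 / hazard_per_s)
            if t >= duration_s:
                break
            switches.append(t)
    return AttentionTrajectory(np.asarray(switches), duration_s)


def gen_responses(
    trajectory: AttentionTrajectory,
    windows: Sequence[ResponseWindow] | Sequence[tuple],
    lapse_prob: float,
    seed,
) -> list[str]:
    """Window responses: the majority-attended source, lapsing to extraneous."""
    rng = np.random.default_rng(seed)
    out = []
    for w in windows:
        start, end = (w.start_s, w.end_s) if isinstance(w, ResponseWindow) else w
        if rng.random() < lapse_prob:
            out.append("extraneous")
        else:
            out.append(trajectory.majority_source(start, end))
    return out


def gen_eeg(
    attended: np.ndarray,
    trf: ForwardTRF,
    snr: float,
    seed,
    rate_hz: float = MODEL_RATE_HZ,
) -> EEGRecord:
    """Channel n = kernel_n ⊗ attended + Gaussian noise at the given SNR.

    ``snr`` is the signal-power/noise-power ratio; ``np.inf`` gives noiseless
    channels.  A zero kernel yields unit-variance pure-noise channels.
    """
    if not snr > 0:
        raise ValueError("snr must be positive (np.inf for noiseless)")
    attended = np.asarray(attended, dtype=float)
    t0 = attended.size
    clean = np.stack([np.convolve(attended, k)[:t0] for k in trf.kernels])
    p_signal = float(np.mean(clean**2))
    rng = np.random.default_rng(seed)
    if np.isinf(snr):
        return EEGRecord(clean, rate_hz)
    noise_std = np.sqrt(p_signal / snr) if p_signal > 0 else 1.0
    return EEGRecord(clean + noise_std * rng.standard_normal(clean.shape), rate_hz)


def gen_trial(
    condition: ConditionSpec,
    eeg_spec: EEGSimSpec,
    trf: ForwardTRF,
    duration_s: float,
    seed: np.random.SeedSequence,
    trial_id: str = "",
    rate_hz: float = MODEL_RATE_HZ,
):
    """One complete simulated trial (returns a decoding.TrialRecord)."""
    from .decoding import TrialRecord

    s_target, s_masker, s_kw, s_att, s_resp, s_eeg = seed.spawn(6)
    env_t = gen_stream(duration_s, s_target, rate_hz=rate_hz)
    env_m = gen_stream(duration_s, s_masker, rate_hz=rate_hz)
    kw_pairs = gen_keyword_times(duration_s, s_kw)
    trajectory = gen_attention_trajectory(duration_s, condition.switch_hazard_per_s, s_att)
    spans = [
        (min(t.onset_s, m.onset_s), max(t.offset_s, m.offset_s)) for t, m in kw_pairs
    ]
    responses = gen_responses(trajectory, spans, condition.lapse_prob, s_resp)
    windows = make_windows([t for t, _ in kw_pairs], [m for _, m in kw_pairs], responses)

    w_t, w_m = trajectory.weights(rate_hz)
    attended = w_t * env_t + w_m * env_m
    eeg = gen_eeg(attended, trf, eeg_spec.snr, s_eeg, rate_hz)

    return TrialRecord(
        eeg=eeg,
        envelope_target=Envelope(env_t, rate_hz, trial_id=trial_id),
        envelope_masker=Envelope(env_m, rate_hz, trial_id=trial_id),
        condition=condition.label,
        trial_id=trial_id,
        windows=windows,
        attention=trajectory,
    )


def gen_dataset(cfg: SimConfig = SimConfig()) -> list[SimulatedSubject]:
    """Full factorial subjects × conditions × trials with hierarchical seeding."""
    master = np.random.SeedSequence(cfg.master_seed)
    subject_seeds = master.spawn(cfg.n_subjects)
    lo, hi = cfg.trial_duration_range_s
    subjects = []
    for si, sseed in enumerate(subject_seeds):
        subject_id = f"sub{si + 1:02d}"
        trf_seed, trials_seed = sseed.spawn(2)
        trf = ForwardTRF.speech_like(
            cfg.eeg.n_channels,
            cfg.rate_hz,
            cfg.eeg.kernel_latency_s,
            cfg.eeg.kernel_width_s,
            seed=trf_seed,
        )
        trials = []
        cond_seeds = trials_seed.spawn(len(cfg.conditions))
        for cond, cseed in zip(cfg.conditions, cond_seeds):
            trial_seeds = cseed.spawn(cfg.n_trials_per_condition)
            for ti, tseed in enumerate(trial_seeds):
                dur_rng = np.random.default_rng(tseed.spawn(1)[0])
                duration = float(dur_rng.uniform(lo, hi))
                trial_id = f"{subject_id}_{cond.label}_{ti + 1:03d}"
                trials.append(
                    gen_trial(cond, cfg.eeg, trf, duration, tseed, trial_id, cfg.rate_hz)
                )
        subjects.append(SimulatedSubject(subject_id, trials, seed_entropy=cfg.master_seed))
    return subjects
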