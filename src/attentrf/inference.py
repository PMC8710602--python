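"""Behaviorally inferred attended stimulus.

Given the two competing streams (target x_T, masker x_M), three keyword
response windows and the listener's ternary answers (target / masker /
extraneous), build the piecewise "inferred" stimulus

    x̂(t) = f(x_T, x_M, R_i)(t)   if t lies in keyword window i,
           g(x_T, x_M)(t)        otherwise,

where f selects x_T for a target answer, x_M for a masker answer and a filler
signal h(x_T, x_M) for an extraneous answer.  Outside the probed windows the
attentional locus is extrapolated by one of two scopes: "segments" (each
window's source holds over a whole segment, cut halfway between consecutive
windows) or "target_windows" (the target is assumed attended everywhere
outside the windows).  Every change of source is a complementary raised-cosine
crossfade whose length models the attentional switch duration.

The mixing is realised as a partition of unity: per-sample weights
w_T + w_M + w_F = 1, with x̂ = w_T·x_T + w_M·x_M + w_F·filler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

RESPONSE_LABELS = ("target", "masker", "extraneous")
SCOPES = ("segments", "target_windows")
FILLERS = ("mixture", "target", "masker", "noise", "other_speech")

#: the configuration behind the "behavioral decoder": target-windows scope,
#: mixture filler, 2 s attentional switch
BEHAVIORAL_CONFIG_FIELDS = ("target_windows", "mixture", 2.0)

__all__ = [
    "KeywordInterval",
    "ResponseWindow",
    "InferenceConfig",
    "SourcePair",
    "AttentionWeights",
    "make_windows",
    "attention_weights",
    "make_filler",
    "build_inferred_signal",
    "behavioral_config",
]


@dataclass(frozen=True)
class KeywordInterval:
    """A keyword's time extent within a trial, tagged by its stream."""

    onset_s: float
    offset_s: float
    stream: str  # "target" or "masker"

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.offset_s):
            raise ValueError("need 0 <= onset_s < offset_s")
        if self.stream not in ("target", "masker"):
            raise ValueError(f"unknown stream {self.stream!r}")


@dataclass(frozen=True)
class ResponseWindow:
    """The union of a paired target and masker keyword, with the answer given.

    The window starts at the earlier keyword onset and ends at the later
    keyword offset, so windows have varying durations (paired keywords may
    overlap or be separated by up to ~1 s).
    """

    index: int
    target_kw: KeywordInterval
    masker_kw: KeywordInterval
    response: str

    def __post_init__(self) -> None:
        if self.response not in RESPONSE_LABELS:
            raise ValueError(f"unknown response {self.response!r}")

    @property
    def start_s(self) -> float:
        return min(self.target_kw.onset_s, self.masker_kw.onset_s)

    @property
    def end_s(self) -> float:
        return max(self.target_kw.offset_s, self.masker_kw.offset_s)

    @property
    def center_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)

    def attended_source(self) -> str:
        """The mixing source dictated by the response: target/masker/filler."""
        return {"target": "target", "masker": "masker", "extraneous": "filler"}[self.response]


@dataclass(frozen=True)
class InferenceConfig:
    """(scope, filler, switch duration) selecting one inferred-stimulus strategy."""

    scope: str = "target_windows"
    filler: str = "mixture"
    switch_duration_s: float = 2.0

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.filler not in FILLERS:
            raise ValueError(f"unknown filler {self.filler!r}")
        if self.switch_duration_s < 0:
            raise ValueError("switch_duration_s must be >= 0")


def behavioral_config() -> InferenceConfig:
    """The best-performing configuration: (target_windows, mixture, 2 s)."""
    return InferenceConfig(*BEHAVIORAL_CONFIG_FIELDS)


@dataclass
class SourcePair:
    """Time-aligned target and masker signals at a common rate."""

    x_target: np.ndarray
    x_masker: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.x_target = np.asarray(self.x_target, dtype=float)
        self.x_masker = np.asarray(self.x_masker, dtype=float)
        if self.x_target.shape != self.x_masker.shape:
            raise ValueError("target and masker must have equal length")
        if self.x_target.ndim != 1:
            raise ValueError("signals must be one-dimensional")

    @property
    def n_samples(self) -> int:
        return self.x_target.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class AttentionWeights:
    """Per-sample mixing weights for target, masker and filler (sum to 1)."""

    w_target: np.ndarray
    w_masker: np.ndarray
    w_filler: np.ndarray
    rate_hz: float

    def as_array(self) -> np.ndarray:
        return np.vstack([self.w_target, self.w_masker, self.w_filler])


def make_windows(
    target_kws: Sequence[KeywordInterval],
    masker_kws: Sequence[KeywordInterval],
    responses: Sequence[str],
) -> list[ResponseWindow]:
    """Pair the i-th target and masker keywords into union response windows."""
    if not (len(target_kws) == len(masker_kws) == len(responses)):
        raise ValueError("need equal numbers of target keywords, masker keywords, responses")
    windows = [
        ResponseWindow(i + 1, t, m, r)
        for i, (t, m, r) in enumerate(zip(target_kws, masker_kws, responses))
    ]
    for a, b in zip(windows, windows[1:]):
        if b.start_s < a.end_s:
            raise ValueError(
                f"windows {a.index} and {b.index} overlap "
                f"([{a.start_s:.3f},{a.end_s:.3f}] vs [{b.start_s:.3f},{b.end_s:.3f}])"
            )
    return windows


def _source_segments(
    windows: Sequence[ResponseWindow], cfg: InferenceConfig, duration_s: float
) -> list[tuple[float, str]]:
    """Piecewise-constant source labels as (start_time, source) breakpoints."""
    for w in windows:
        if w.end_s > duration_s + 1e-9:
            raise ValueError(f"window {w.index} extends past trial end")
    if cfg.scope == "segments":
        # one segment per window, cut halfway between consecutive windows
        pieces = []
        for i, w in enumerate(windows):
            start = 0.0 if i == 0 else 0.5 * (windows[i - 1].end_s + w.start_s)
            pieces.append((start, w.attended_source()))
        return pieces
    # target_windows: target everywhere except inside the windows themselves
    pieces = [(0.0, "target")]
    for w in windows:
        pieces.append((w.start_s, w.attended_source()))
        pieces.append((w.end_s, "target"))
    return pieces


def _merge_pieces(pieces: list[tuple[float, str]]) -> list[tuple[float, str]]:
    merged: list[tuple[float, str]] = []
    for start, src in pieces:
        if merged and merged[-1][1] == src:
            continue
        merged.append((start, src))
    return merged


def attention_weights(
    windows: Sequence[ResponseWindow],
    cfg: InferenceConfig,
    duration_s: float,
    rate_hz: float,
) -> AttentionWeights:
    """Partition-of-unity mixing weights realising the piecewise model.

    Source changes are complementary raised-cosine crossfades of length
    ``cfg.switch_duration_s`` centered on each boundary.  Ramps are truncated
    at the midpoint between boundaries that are closer than the switch
    duration (and at the trial edges), which keeps the weights a partition of
    unity by construction.
    """
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    pieces = _merge_pieces(_source_segments(windows, cfg, duration_s))

    idx = {"target": 0, "masker": 1, "filler": 2}
    w = np.zeros((3, n))
    # hard piecewise-constant assignment
    bounds = [start for start, _ in pieces[1:]] + [np.inf]
    for (start, src), end in zip(pieces, bounds):
        w[idx[src], (t >= start) & (t < end)] = 1.0

    # raised-cosine crossfades centered on every source-change boundary
    boundary_times = [start for start, _ in pieces[1:]]
    half = cfg.switch_duration_s / 2.0
    for j, bt in enumerate(boundary_times):
        prev_b = boundary_times[j - 1] if j > 0 else 0.0
        next_b = boundary_times[j + 1] if j + 1 < len(boundary_times) else duration_s
        h = min(half, (bt - prev_b) / 2.0, (next_b - bt) / 2.0, bt, duration_s - bt)
        if h < half - 1e-12:
            logger.warning(
                "crossfade at %.3f s truncated from ±%.3f s to ±%.3f s", bt, half, h
            )
        if h <= 0:
            continue
        src_from = idx[pieces[j][1]]
        src_to = idx[pieces[j + 1][1]]
        mask = (t >= bt - h) & (t < bt + h)
        # weight of the outgoing source: 1 -> 0, exactly 0.5 at the boundary
        fade = 0.5 * (1.0 + np.cos(np.pi * (t[mask] - (bt - h)) / (2.0 * h)))
        w[:, mask] = 0.0
        w[src_from, mask] = fade
        w[src_to, mask] = 1.0 - fade

    return AttentionWeights(w[0], w[1], w[2], rate_hz)


def make_filler(
    cfg: InferenceConfig,
    pair: SourcePair,
    other_speech: np.ndarray | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """The signal substituted where an extraneous keyword was chosen.

    Noise and other-speech fillers are scaled so their root-mean-square level
    matches that of the target stream.
    """
    x_t, x_m = pair.x_target, pair.x_masker
    if cfg.filler == "mixture":
        return x_t + x_m
    if cfg.filler == "target":
        return x_t.copy()
    if cfg.filler == "masker":
        return x_m.copy()

    target_rms = float(np.sqrt(np.mean(x_t**2)))
    if cfg.filler == "noise":
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(pair.n_samples)
        noise_rms = float(np.sqrt(np.mean(noise**2)))
        return noise * (target_rms / noise_rms if noise_rms > 0 else 1.0)
    # other_speech: loop/truncate to trial length, match target RMS
    if other_speech is None:
        raise ValueError("filler='other_speech' requires an other_speech signal")
    other = np.asarray(other_speech, dtype=float)
    if other.size == 0:
        raise ValueError("other_speech signal is empty")
    reps = int(np.ceil(pair.n_samples / other.size))
    looped = np.tile(other, reps)[: pair.n_samples]
    other_rms = float(np.sqrt(np.mean(looped**2)))
    return looped * (target_rms / other_rms if other_rms > 0 else 1.0)


def build_inferred_signal(
    pair: SourcePair,
    windows: Sequence[ResponseWindow],
    cfg: InferenceConfig = InferenceConfig(),
    seed: int | None = None,
    other_speech: np.ndarray | None = None,
    weights: AttentionWeights | None = None,
) -> np.ndarray:
    """x̂ = w_T·x_T + w_M·x_M + w_F·filler on the pair's sample grid.

    When every response is "target" the weights are identically one on the
    target, and x̂ equals x_T bit-for-bit.
    """
    if weights is None:
        weights = attention_weights(windows, cfg, pair.duration_s, pair.rate_hz)
    if weights.w_target.size != pair.n_samples:
        raise ValueError("weights and signals have mismatched lengths")
    if np.any(weights.w_filler > 0):
        filler = make_filler(cfg, pair, other_speech=other_speech, seed=seed)
    else:
        filler = np.zeros(pair.n_samples)
    return (
        weights.w_target * pair.x_target
        + weights.w_masker * pair.x_masker
        + weights.w_filler * filler
    )
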