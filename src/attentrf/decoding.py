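"""Backward TRF (decoder) estimation and stimulus reconstruction.

A decoder is a channels × lags weight array d mapping lagged EEG to a
reconstructed speech envelope,

    Ŝ(t) = Σ_n Σ_τ d(τ, n) R(t − τ, n),

with lags τ from −900 ms to 0 ms in steps of one 64 Hz sample (the stimulus
precedes the EEG by up to 900 ms).  Weights are the ridge solution of the
normal equations

    d = (R Rᵀ + λ I)⁻¹ (R Sᵀ),

with λ = 10^(1/2) by default.  Reconstruction accuracy is the Pearson
correlation r between Ŝ and the original target envelope on a held-out trial,
using the leave-one-out scheme: each trial is reconstructed with the unweighted
mean of the decoders fitted on all other trials.

The module exposes both the individual operations and a statsmodels-style
model object, :class:`StimulusReconstruction`, whose ``fit`` returns a
:class:`StimulusReconstructionResults` carrying per-trial accuracies, the
decoders, and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .dsp import EEGRecord, Envelope, MODEL_RATE_HZ
from .inference import ResponseWindow

#: default ridge regularization, λ = 10^(1/2)
RIDGE_LAMBDA_DEFAULT = 10.0**0.5

#: optional λ search grid (off by default), log-spaced 10^-3 … 10^5
LAMBDA_GRID = np.logspace(-3, 5, 17)

__all__ = [
    "RIDGE_LAMBDA_DEFAULT",
    "LAMBDA_GRID",
    "LagSpec",
    "LagMatrix",
    "Decoder",
    "TrialRecord",
    "ReconstructionResult",
    "build_lag_matrix",
    "fit_ridge_decoder",
    "reconstruct_envelope",
    "pearson_r",
    "fisher_z",
    "loo_reconstruction_accuracy",
    "StimulusReconstruction",
    "StimulusReconstructionResults",
]


@dataclass(frozen=True)
class LagSpec:
    """Decoder lag grid: −900 to 0 ms in steps of one sample at 64 Hz.

    −900 ms at 64 Hz is 57.6 samples; integer lags −57…0 are used (58 lags).
    """

    min_lag_ms: float = -900.0
    max_lag_ms: float = 0.0
    rate_hz: float = MODEL_RATE_HZ

    def __post_init__(self) -> None:
        if self.min_lag_ms > self.max_lag_ms:
            raise ValueError("min_lag_ms must be <= max_lag_ms")

    @property
    def lag_samples(self) -> np.ndarray:
        lo = int(np.trunc(self.min_lag_ms / 1000.0 * self.rate_hz))
        hi = int(np.trunc(self.max_lag_ms / 1000.0 * self.rate_hz))
        return np.arange(lo, hi + 1)

    @property
    def n_lags(self) -> int:
        return self.lag_samples.size

    @property
    def step_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def delays(self) -> np.ndarray:
        """Nonnegative per-row delays of the lag matrix (max lag first at 0)."""
        return self.lag_samples - self.lag_samples[0]

    @property
    def n_pad(self) -> int:
        """Zero-padding added to the envelope/time axis (lag span in samples)."""
        return int(self.lag_samples[-1] - self.lag_samples[0])


@dataclass
class LagMatrix:
    """Time-lagged EEG, (channels·lags) × T, rows grouped by channel then lag."""

    values: np.ndarray
    n_channels: int
    spec: LagSpec

    @property
    def n_lags(self) -> int:
        return self.spec.n_lags

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass
class Decoder:
    """Backward TRF weights with their lag grid and ridge parameter."""

    weights: np.ndarray  # (channels·lags,) vector
    n_channels: int
    spec: LagSpec
    ridge_lambda: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("decoder weights must be finite")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")

    def as_channel_lag(self) -> np.ndarray:
        """Weights viewed as a channels × lags array."""
        return self.weights.reshape(self.n_channels, self.spec.n_lags)


@dataclass
class TrialRecord:
    """One trial's aligned EEG and envelopes, plus optional behavioral data."""

    eeg: EEGRecord
    envelope_target: Envelope
    envelope_masker: Envelope | None = None
    envelope_inferred: Envelope | None = None
    condition: str = ""
    trial_id: str = ""
    windows: list[ResponseWindow] | None = None
    attention: object | None = None  # latent trajectory when simulated

    @property
    def responses(self) -> list[str] | None:
        if self.windows is None:
            return None
        return [w.response for w in self.windows]


@dataclass(frozen=True)
class ReconstructionResult:
    """Held-out reconstruction accuracy of one trial."""

    trial_id: str
    condition: str
    decoder_kind: str  # "target" or "behavioral"
    r: float
    z: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.isnan(self.z):
            object.__setattr__(self, "z", fisher_z(self.r))


# ---------------------------------------------------------------------------
# elementary operations


def build_lag_matrix(eeg: EEGRecord, spec: LagSpec = LagSpec()) -> LagMatrix:
    """Shift-and-pad the EEG into the (channels·lags) × T design matrix.

    T equals the trial length plus the lag span; each row is the channel
    delayed by (τ − τ_min) samples with zeros outside the trial support, so
    column j corresponds to stimulus time t = j + τ_min.  The envelope must be
    padded with |τ_min| leading zeros to share this grid (see
    :func:`pad_envelope`).
    """
    if eeg.n_samples == 0:
        raise ValueError("empty EEG record")
    X = eeg.data
    n, t0 = X.shape
    delays = spec.delays
    T = t0 + spec.n_pad
    out = np.zeros((n * spec.n_lags, T))
    for c in range(n):
        for k, d in enumerate(delays):
            out[c * spec.n_lags + k, d : d + t0] = X[c]
    return LagMatrix(out, n, spec)


def pad_envelope(env: np.ndarray, spec: LagSpec) -> np.ndarray:
    """Zero-pad an envelope with the lag span's leading zeros to length T."""
    return np.concatenate([np.zeros(spec.n_pad), np.asarray(env, dtype=float)])


def fit_ridge_decoder(R: LagMatrix, S, ridge_lambda: float = RIDGE_LAMBDA_DEFAULT) -> Decoder:
    """Exact ridge solution d = (R Rᵀ + λ I)⁻¹ (R Sᵀ).

    ``S`` may be an :class:`~attentrf.dsp.Envelope` or a plain vector; it is
    zero-padded automatically if it is shorter than the lag-matrix time axis
    by exactly the lag span.  For λ > 0 with more rows than time points the
    algebraically identical dual form d = R (Rᵀ R + λ I)⁻¹ Sᵀ is used.  At
    λ = 0 a singular system falls back to the pseudo-inverse with a warning.
    """
    s = np.asarray(S.samples if isinstance(S, Envelope) else S, dtype=float).ravel()
    V = R.values
    if s.size == R.n_times - R.spec.n_pad:
        s = pad_envelope(s, R.spec)
    if s.size != R.n_times:
        raise ValueError(f"envelope length {s.size} does not match lag matrix T {R.n_times}")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")

    m, T = V.shape
    if ridge_lambda == 0:
        G = V @ V.T
        b = V @ s
        try:
            w = np.linalg.solve(G, b)
        except np.linalg.LinAlgError:
            warnings.warn("singular system at lambda=0; using pseudo-inverse")
            w = np.linalg.pinv(G) @ b
        if not np.all(np.isfinite(w)):
            warnings.warn("singular system at lambda=0; using pseudo-inverse")
            w = np.linalg.pinv(G) @ b
    elif m <= T:
        G = V @ V.T + ridge_lambda * np.eye(m)
        w = cho_solve(cho_factor(G), V @ s)
    else:
        M = V.T @ V + ridge_lambda * np.eye(T)
        w = V @ cho_solve(cho_factor(M), s)
    return Decoder(w, R.n_channels, R.spec, ridge_lambda)


def reconstruct_envelope(d: Decoder, R: LagMatrix) -> Envelope:
    """Ŝ = dᵀR on the padded time grid, at the model rate."""
    if d.weights.size != R.values.shape[0]:
        raise ValueError("decoder and lag matrix dimensions disagree")
    return Envelope(d.weights @ R.values, R.spec.rate_hz)


def pearson_r(a, b) -> float:
    """Product-moment correlation of two equal-length signals."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("signals must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0:
        raise ValueError("zero-variance input to pearson_r")
    return float(np.clip((ac @ bc) / denom, -1.0, 1.0))


def fisher_z(r: float) -> float:
    """Variance-stabilising transform z = atanh(r)."""
    if not np.abs(r) < 1:
        raise ValueError("|r| must be < 1")
    return float(np.arctanh(r))


# ---------------------------------------------------------------------------
# fast per-trial solver exploiting the lag-matrix shift structure


class TrialSolver:
    """Per-trial ridge context with a Cholesky factor shared across envelopes.

    The lag matrix R consists of delayed copies of the EEG channels, so
    RᵀR[j, j'] is a moving sum over delays of (XᵀX)[j−d, j'−d]: each diagonal
    of RᵀR is a windowed running sum along the corresponding diagonal of XᵀX.
    Factoring RᵀR + λI once lets decoders for any number of training envelopes
    be obtained with cheap triangular solves via the dual ridge identity
    d = R (RᵀR + λI)⁻¹ Sᵀ.
    """

    def __init__(
        self,
        eeg: EEGRecord,
        spec: LagSpec = LagSpec(),
        ridge_lambda: float = RIDGE_LAMBDA_DEFAULT,
        standardize: bool = True,
    ):
        if ridge_lambda <= 0:
            raise ValueError("TrialSolver requires ridge_lambda > 0")
        X = eeg.data.astype(float)
        if standardize:
            X = X - X.mean(axis=1, keepdims=True)
            sd = X.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            X = X / sd
        self.X = X
        self.spec = spec
        self.ridge_lambda = ridge_lambda
        self.standardize = standardize
        self.n_channels, self.t0 = X.shape
        self.T = self.t0 + spec.n_pad
        self.delays = spec.delays
        self._factor = cho_factor(self._gram() + ridge_lambda * np.eye(self.T))

    def _gram(self) -> np.ndarray:
        """RᵀR via diagonal running sums of P = XᵀX (zero padding is exact)."""
        P = self.X.T @ self.X
        T, t0, L = self.T, self.t0, len(self.delays)
        # diagonal cumulative sum: C[i, j] = P[i, j] + C[i-1, j-1]
        C = np.zeros((T, T))
        C[:t0, :t0] = P
        for i in range(1, T):
            C[i, 1:] += C[i - 1, :-1]
        M = C.copy()
        M[L:, L:] -= C[:-L, :-L]
        return M

    def _prepare(self, envelope) -> np.ndarray:
        s = np.asarray(
            envelope.samples if isinstance(envelope, Envelope) else envelope, dtype=float
        ).ravel()
        if s.size != self.t0:
            raise ValueError(f"envelope length {s.size} != trial length {self.t0}")
        if self.standardize:
            s = s - s.mean()
        return pad_envelope(s, self.spec)

    def fit(self, envelope) -> Decoder:
        """Ridge decoder for one training envelope (triangular solves only)."""
        v = cho_solve(self._factor, self._prepare(envelope))
        # d[(c, k)] = Σ_t X[c, t] v[t + delay_k]
        W = np.empty((self.n_channels, len(self.delays)))
        for k, d in enumerate(self.delays):
            W[:, k] = self.X @ v[d : d + self.t0]
        return Decoder(W.ravel(), self.n_channels, self.spec, self.ridge_lambda)

    def reconstruct(self, decoder: Decoder) -> np.ndarray:
        """Ŝ = dᵀR on the padded grid without materialising R."""
        W = decoder.as_channel_lag()
        out = np.zeros(self.T)
        for k, d in enumerate(self.delays):
            out[d : d + self.t0] += W[:, k] @ self.X
        return out

    def score(self, decoder: Decoder, reference_envelope) -> float:
        """Pearson r between dᵀR and the (padded) reference envelope."""
        return pearson_r(self.reconstruct(decoder), self._prepare(reference_envelope))


def _training_envelope(trial: TrialRecord, kind: str) -> Envelope:
    if kind == "target":
        return trial.envelope_target
    if kind in ("inferred", "behavioral"):
        if trial.envelope_inferred is None:
            raise ValueError(f"trial {trial.trial_id!r} has no inferred envelope")
        return trial.envelope_inferred
    raise ValueError(f"unknown training envelope kind {kind!r}")


def loo_reconstruction_accuracy(
    trials: Sequence[TrialRecord],
    training_envelope_kind: str = "target",
    ridge_lambda: float = RIDGE_LAMBDA_DEFAULT,
    spec: LagSpec = LagSpec(),
    standardize: bool = True,
    solvers: Sequence[TrialSolver] | None = None,
) -> list[ReconstructionResult]:
    """Leave-one-trial-out accuracies, training on target or inferred envelopes.

    One decoder is fitted per trial; each held-out trial is reconstructed with
    the unweighted mean of the other trials' decoders and scored (Pearson r,
    Fisher z) against the held-out trial's ORIGINAL TARGET envelope, whatever
    the training envelope kind — this makes target- and behaviorally-trained
    decoders directly comparable.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials for leave-one-out")
    if solvers is None:
        solvers = [TrialSolver(t.eeg, spec, ridge_lambda, standardize) for t in trials]
    weights = np.stack(
        [sv.fit(_training_envelope(t, training_envelope_kind)).weights
         for sv, t in zip(solvers, trials)]
    )
    total = weights.sum(axis=0)
    kind_label = "behavioral" if training_envelope_kind in ("inferred", "behavioral") else "target"
    results = []
    for i, (sv, t) in enumerate(zip(solvers, trials)):
        mean_w = (total - weights[i]) / (len(trials) - 1)
        dec = Decoder(mean_w, sv.n_channels, spec, ridge_lambda)
        r = sv.score(dec, t.envelope_target)
        results.append(ReconstructionResult(t.trial_id, t.condition, kind_label, r))
    return results


# ---------------------------------------------------------------------------
# model / results objects


class StimulusReconstruction:
    """Leave-one-out backward-TRF stimulus reconstruction model.

    Parameters
    ----------
    trials
        Trial records sharing a condition (EEG and envelopes at 64 Hz).
    train_on
        "target" (assume attention never leaves the target) or "inferred"
        (train on the behaviorally inferred envelopes stored on the trials).
    ridge_lambda
        Ridge regularization λ; default 10^(1/2).
    lags
        Lag grid; default −900…0 ms at 64 Hz.
    standardize
        Z-score EEG channels and mean-center envelopes per trial before
        fitting (default True), so a fixed λ is meaningful across scales.
    """

    def __init__(
        self,
        trials: Sequence[TrialRecord],
        train_on: str = "target",
        ridge_lambda: float = RIDGE_LAMBDA_DEFAULT,
        lags: LagSpec = LagSpec(),
        standardize: bool = True,
    ):
        if len(trials) < 2:
            raise ValueError("need at least 2 trials")
        self.trials = list(trials)
        self.train_on = train_on
        self.ridge_lambda = ridge_lambda
        self.lags = lags
        self.standardize = standardize
        self._solvers: list[TrialSolver] | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, eeg_map: dict, env_map: dict, **kwargs):
        """Build from a tidy manifest DataFrame plus id → signal lookups."""
        trials = [
            TrialRecord(
                eeg=eeg_map[row.trial_id],
                envelope_target=env_map[row.trial_id],
                condition=getattr(row, "condition", ""),
                trial_id=row.trial_id,
            )
            for row in df.itertuples()
        ]
        return cls(trials, **kwargs)

    @property
    def solvers(self) -> list[TrialSolver]:
        if self._solvers is None:
            self._solvers = [
                TrialSolver(t.eeg, self.lags, self.ridge_lambda, self.standardize)
                for t in self.trials
            ]
        return self._solvers

    def fit(self) -> "StimulusReconstructionResults":
        results = loo_reconstruction_accuracy(
            self.trials,
            training_envelope_kind=self.train_on,
            ridge_lambda=self.ridge_lambda,
            spec=self.lags,
            standardize=self.standardize,
            solvers=self.solvers,
        )
        return StimulusReconstructionResults(self, results)


class StimulusReconstructionResults:
    """Held-out reconstruction accuracies from :class:`StimulusReconstruction`."""

    def __init__(self, model: StimulusReconstruction, results: list[ReconstructionResult]):
        self.model = model
        self.results = results

    @property
    def r(self) -> np.ndarray:
        return np.array([x.r for x in self.results])

    @property
    def z(self) -> np.ndarray:
        return np.array([x.z for x in self.results])

    @property
    def mean_r(self) -> float:
        return float(self.r.mean())

    @property
    def mean_z(self) -> float:
        """Mean of the Fisher-z values (not atanh of the mean r)."""
        return float(self.z.mean())

    @property
    def sem_z(self) -> float:
        return float(self.z.std(ddof=1) / np.sqrt(self.z.size)) if self.z.size > 1 else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": [x.trial_id for x in self.results],
                "condition": [x.condition for x in self.results],
                "decoder_kind": [x.decoder_kind for x in self.results],
                "r": self.r,
                "z": self.z,
            }
        )

    def summary(self) -> str:
        lines = [
            "Stimulus reconstruction (leave-one-trial-out backward TRF)",
            "=" * 60,
            f"trials:            {len(self.results)}",
            f"training envelope: {self.model.train_on}",
            f"ridge lambda:      {self.model.ridge_lambda:.4f}",
            f"lags:              {self.model.lags.min_lag_ms:.0f}..."
            f"{self.model.lags.max_lag_ms:.0f} ms ({self.model.lags.n_lags} lags)",
            f"mean r:            {self.mean_r:.4f}",
            f"mean Fisher z:     {self.mean_z:.4f} (SEM {self.sem_z:.4f})",
            "=" * 60,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Histogram of held-out per-trial accuracies."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.r, bins=20)
        ax.axvline(self.mean_r, color="k", linestyle="--", label=f"mean r = {self.mean_r:.3f}")
        ax.set_xlabel("held-out reconstruction accuracy r")
        ax.set_ylabel("trials")
        ax.legend()
        return ax
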