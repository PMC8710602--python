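"""Evaluation layer: modeling-parameter grid and decoder contrast.

Reproduces the comparison structure of the analysis on a dataset with known
responses: the scope × filler × switch-speed grid of inferred-stimulus
strategies (each cell trains decoders on its inferred envelopes and reports
held-out accuracy), and the headline contrast of the "behavioral" decoder
(target-windows scope, mixture filler, 2 s switch) against the conventional
target-trained decoder, as paired tests on subject-level Fisher-z means with
Benjamini–Hochberg correction across conditions.

Also houses the small closed-form utilities tied to printed study numbers:
the target–masker voice distance in semitones and the relative gain of one
reconstruction accuracy over another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decoding import (
    RIDGE_LAMBDA_DEFAULT,
    LagSpec,
    TrialRecord,
    TrialSolver,
    loo_reconstruction_accuracy,
)
from .dsp import Envelope
from .inference import InferenceConfig, SourcePair, behavioral_config, build_inferred_signal
from .simulate import SimulatedSubject

__all__ = [
    "GridResult",
    "ContrastResult",
    "semitone_distance",
    "relative_gain",
    "adjust_pvalues_bh",
    "attach_inferred_envelopes",
    "run_grid",
    "contrast_decoders",
    "grid_to_frame",
    "contrast_to_frame",
]


@dataclass(frozen=True)
class GridResult:
    """Mean held-out accuracy for one (condition, scope, filler, speed) cell.

    ``mean_z`` is the mean of the per-trial Fisher z values (not the transform
    of the mean r).
    """

    condition: str
    scope: str
    filler: str
    switch_duration_s: float
    mean_r: float
    mean_z: float
    n_trials: int
    subject_mean_z: tuple[float, ...] = ()


@dataclass(frozen=True)
class ContrastResult:
    """Per-condition paired comparison of behavioral vs target training."""

    condition: str
    mean_r_target_decoder: float
    mean_r_behavioral_decoder: float
    mean_z_target_decoder: float
    mean_z_behavioral_decoder: float
    statistic: float
    p_value: float
    adjusted_p: float = np.nan
    n_subjects: int = 0


# ---------------------------------------------------------------------------
# closed-form utilities


def semitone_distance(delta_f0_st: float, delta_vtl_st: float) -> float:
    """Total voice distance √(ΔF0² + ΔVTL²) in semitones.

    The F0 and vocal-tract-length shifts of the masker voice relative to the
    target voice combine Euclideanly; rounding is for display only.
    """
    if not (math.isfinite(delta_f0_st) and math.isfinite(delta_vtl_st)):
        raise ValueError("voice shifts must be finite")
    return math.hypot(delta_f0_st, delta_vtl_st)


def relative_gain(r_old: float, r_new: float) -> int:
    """Relative improvement 100·(r_new − r_old)/r_old, nearest integer percent."""
    if r_old == 0:
        raise ValueError("relative gain undefined for r_old = 0")
    return int(round(100.0 * (r_new - r_old) / r_old))


def adjust_pvalues_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# inferred-envelope plumbing (envelope-domain fast path)


def attach_inferred_envelopes(
    trials: Sequence[TrialRecord],
    cfg: InferenceConfig,
    seed: int = 0,
    other_speech_lookup=None,
) -> list[TrialRecord]:
    """Return copies of ``trials`` with ``envelope_inferred`` built under ``cfg``.

    Envelopes are mixed directly (the envelope-domain fast path).  For the
    other-speech filler, the target envelope of the next trial in the sequence
    stands in for a story from another trial unless a lookup is supplied.
    """
    import dataclasses

    out = []
    for i, t in enumerate(trials):
        if t.windows is None:
            raise ValueError(f"trial {t.trial_id!r} carries no response windows")
        if t.envelope_masker is None:
            raise ValueError(f"trial {t.trial_id!r} carries no masker envelope")
        pair = SourcePair(
            t.envelope_target.samples, t.envelope_masker.samples, t.envelope_target.rate_hz
        )
        other = None
        if cfg.filler == "other_speech":
            if other_speech_lookup is not None:
                other = other_speech_lookup(t)
            else:
                other = trials[(i + 1) % len(trials)].envelope_target.samples
        x_hat = build_inferred_signal(
            pair, t.windows, cfg, seed=seed + i, other_speech=other
        )
        out.append(
            dataclasses.replace(
                t,
                envelope_inferred=Envelope(
                    x_hat, t.envelope_target.rate_hz, trial_id=t.trial_id
                ),
            )
        )
    return out


def _subject_solvers(
    trials: Sequence[TrialRecord],
    spec: LagSpec,
    ridge_lambda: float,
    standardize: bool,
) -> list[TrialSolver]:
    return [TrialSolver(t.eeg, spec, ridge_lambda, standardize) for t in trials]


# ---------------------------------------------------------------------------
# grid and contrast


def run_grid(
    dataset: Sequence[SimulatedSubject],
    scopes: Sequence[str] = ("segments", "target_windows"),
    fillers: Sequence[str] = ("mixture", "target", "masker", "noise", "other_speech"),
    speeds: Sequence[float] = (1.0, 2.0, 3.0),
    ridge_lambda: float = RIDGE_LAMBDA_DEFAULT,
    spec: LagSpec = LagSpec(),
    standardize: bool = True,
) -> list[GridResult]:
    """Held-out accuracy for every (condition, scope, filler, speed) cell.

    For each cell the inferred envelopes are rebuilt, decoders are trained on
    them and evaluated leave-one-out against the target envelopes.  Per-trial
    Cholesky factors are shared across all cells of a subject × condition
    block, since the EEG does not change.
    """
    if not dataset or not scopes or not fillers or not speeds:
        raise ValueError("dataset and every grid axis must be non-empty")
    conditions = dataset[0].conditions
    cells: dict[tuple, dict] = {}
    for subject in dataset:
        for condition in conditions:
            trials = subject.trials_in(condition)
            if len(trials) < 2:
                raise ValueError(
                    f"subject {subject.subject_id} has <2 trials in {condition!r}"
                )
            solvers = _subject_solvers(trials, spec, ridge_lambda, standardize)
            for scope, filler, speed in product(scopes, fillers, speeds):
                cfg = InferenceConfig(scope, filler, speed)
                with_inf = attach_inferred_envelopes(trials, cfg)
                res = loo_reconstruction_accuracy(
                    with_inf,
                    "inferred",
                    ridge_lambda,
                    spec,
                    standardize,
                    solvers=solvers,
                )
                cell = cells.setdefault(
                    (condition, scope, filler, speed),
                    {"r": [], "z": [], "subj_z": [], "n": 0},
                )
                rs = [x.r for x in res]
                zs = [x.z for x in res]
                cell["r"].extend(rs)
                cell["z"].extend(zs)
                cell["subj_z"].append(float(np.mean(zs)))
                cell["n"] += len(res)
    return [
        GridResult(
            condition=c,
            scope=s,
            filler=f,
            switch_duration_s=sp,
            mean_r=float(np.mean(v["r"])),
            mean_z=float(np.mean(v["z"])),
            n_trials=v["n"],
            subject_mean_z=tuple(v["subj_z"]),
        )
        for (c, s, f, sp), v in cells.items()
    ]


def contrast_decoders(
    dataset: Sequence[SimulatedSubject],
    ridge_lambda: float = RIDGE_LAMBDA_DEFAULT,
    cfg: InferenceConfig | None = None,
    spec: LagSpec = LagSpec(),
    standardize: bool = True,
    alternative: str = "two-sided",
) -> list[ContrastResult]:
    """Behavioral vs target decoder, per condition, on subject-level Fisher z.

    Both trainings share each trial's Cholesky factor, so the comparison is
    numerically paired down to the linear solves.  When every paired
    difference is exactly zero (no behavioral deviation from the target, as
    with error-free responses), p = 1 by convention.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 subjects for a paired contrast")
    cfg = cfg or behavioral_config()
    conditions = dataset[0].conditions
    per_cond: dict[str, dict] = {
        c: {"z_t": [], "z_b": [], "r_t": [], "r_b": []} for c in conditions
    }
    for subject in dataset:
        for condition in conditions:
            trials = subject.trials_in(condition)
            solvers = _subject_solvers(trials, spec, ridge_lambda, standardize)
            with_inf = attach_inferred_envelopes(trials, cfg)
            res_t = loo_reconstruction_accuracy(
                trials, "target", ridge_lambda, spec, standardize, solvers=solvers
            )
            res_b = loo_reconstruction_accuracy(
                with_inf, "inferred", ridge_lambda, spec, standardize, solvers=solvers
            )
            acc = per_cond[condition]
            acc["z_t"].append(float(np.mean([x.z for x in res_t])))
            acc["z_b"].append(float(np.mean([x.z for x in res_b])))
            acc["r_t"].append(float(np.mean([x.r for x in res_t])))
            acc["r_b"].append(float(np.mean([x.r for x in res_b])))

    results = []
    pvals = []
    for condition in conditions:
        acc = per_cond[condition]
        z_t, z_b = np.asarray(acc["z_t"]), np.asarray(acc["z_b"])
        diffs = z_b - z_t
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_rel(z_b, z_t, alternative=alternative)
        pvals.append(p)
        results.append(
            ContrastResult(
                condition=condition,
                mean_r_target_decoder=float(np.mean(acc["r_t"])),
                mean_r_behavioral_decoder=float(np.mean(acc["r_b"])),
                mean_z_target_decoder=float(z_t.mean()),
                mean_z_behavioral_decoder=float(z_b.mean()),
                statistic=float(stat),
                p_value=float(p),
                n_subjects=len(z_t),
            )
        )
    adjusted = adjust_pvalues_bh(pvals)
    return [
        ContrastResult(
            **{**r.__dict__, "adjusted_p": float(a)}
        )
        for r, a in zip(results, adjusted)
    ]


def grid_to_frame(results: Sequence[GridResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": [g.condition for g in results],
            "scope": [g.scope for g in results],
            "filler": [g.filler for g in results],
            "switch_duration_s": [g.switch_duration_s for g in results],
            "mean_r": [g.mean_r for g in results],
            "mean_z": [g.mean_z for g in results],
            "n_trials": [g.n_trials for g in results],
        }
    )


def contrast_to_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": [c.condition for c in results],
            "mean_r_target_decoder": [c.mean_r_target_decoder for c in results],
            "mean_r_behavioral_decoder": [c.mean_r_behavioral_decoder for c in results],
            "mean_z_target_decoder": [c.mean_z_target_decoder for c in results],
            "mean_z_behavioral_decoder": [c.mean_z_behavioral_decoder for c in results],
            "statistic": [c.statistic for c in results],
            "p_value": [c.p_value for c in results],
            "adjusted_p": [c.adjusted_p for c in results],
            "n_subjects": [c.n_subjects for c in results],
        }
    )
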