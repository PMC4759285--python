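"""Preprocessing, condition summaries, vincentiles and repetition effects.

The analysis conventions throughout: only Block-2 responses are analysed;
the RT analysis set keeps correct responses with 250 <= RT <= 1500 ms while
the accuracy set keeps all Block-2 trials; empirical quantiles use linear
interpolation with midpoint plotting positions (Hazen convention,
``numpy`` method ``"hazen"``), identically everywhere including the fitter;
group ("vincentized") quantiles are unweighted means over subjects of the
subject-level quantiles at the same probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import CONDITIONS, Condition
from .predict import DEFAULT_QUANTILE_PROBS

#: RT analysis window, ms
RT_MIN_MS, RT_MAX_MS = 250.0, 1500.0

#: minimum aggregated error count for a cell to get error-RT quantiles
MIN_ERRORS_FOR_QUANTILES = 11

QUANTILE_METHOD = "hazen"


def quantiles(x, probs=DEFAULT_QUANTILE_PROBS) -> np.ndarray:
    """Empirical quantiles, Hazen (midpoint plotting position) convention."""
    return np.quantile(np.asarray(x, dtype=float), probs, method=QUANTILE_METHOD)


def transform_rt(rt_ms):
    """Reciprocal transform ``-1000 / RT`` (strictly increasing in RT)."""
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt <= 0):
        raise ValueError("RT must be positive for the -1000/RT transform")
    out = -1000.0 / rt
    return float(out) if np.isscalar(rt_ms) else out


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_block2: int
    n_errors: int
    n_fast: int
    n_slow: int
    n_rt_set: int

    @property
    def prop_errors(self) -> float:
        return self.n_errors / self.n_block2 if self.n_block2 else 0.0

    @property
    def prop_rt_excluded(self) -> float:
        return (self.n_fast + self.n_slow) / self.n_block2 if self.n_block2 else 0.0


def preprocess(trials: pd.DataFrame):
    """Split a trial table into RT and accuracy analysis sets.

    Returns ``(rt_set, accuracy_set, report)``.  The accuracy set is all
    Block-2 trials; the RT set additionally keeps only correct responses
    inside the 250–1500 ms window.
    """
    if len(trials) == 0:
        rep = ExclusionReport(0, 0, 0, 0, 0, 0)
        return trials.copy(), trials.copy(), rep
    acc_set = trials[trials["block"] == 2].copy()
    correct = acc_set[acc_set["correct"].astype(bool)]
    fast = correct["rt_ms"] < RT_MIN_MS
    slow = correct["rt_ms"] > RT_MAX_MS
    rt_set = correct[~fast & ~slow].copy()
    report = ExclusionReport(
        n_input=len(trials),
        n_block2=len(acc_set),
        n_errors=int((~acc_set["correct"].astype(bool)).sum()),
        n_fast=int(fast.sum()),
        n_slow=int(slow.sum()),
        n_rt_set=len(rt_set),
    )
    return rt_set, acc_set, report


@dataclass
class ConditionSummary:
    condition: Condition
    n_trials: int
    accuracy: float
    mean_rt_ms: float | None
    quantile_probs: tuple
    correct_quantiles_ms: np.ndarray | None = field(repr=False, default=None)
    error_quantiles_ms: np.ndarray | None = field(repr=False, default=None)
    n_errors_in_window: int = 0
    missing: bool = False


def _cells(df: pd.DataFrame):
    return df.groupby(["lexicality", "repetition"], sort=False)


def condition_summaries(
    rt_set: pd.DataFrame,
    accuracy_set: pd.DataFrame,
    quantile_probs: Sequence[float] = DEFAULT_QUANTILE_PROBS,
) -> list[ConditionSummary]:
    """One summary per design cell from preprocessed trial sets.

    Error-RT quantiles are reported only when the cell has at least
    :data:`MIN_ERRORS_FOR_QUANTILES` in-window errors at the aggregated
    level; empty cells are flagged missing, never fabricated.
    """
    out = []
    probs = tuple(quantile_probs)
    for cond in CONDITIONS:
        lex, rep = cond
        acc_cell = accuracy_set[
            (accuracy_set["lexicality"] == lex) & (accuracy_set["repetition"] == rep)
        ]
        rt_cell = rt_set[(rt_set["lexicality"] == lex) & (rt_set["repetition"] == rep)]
        if len(acc_cell) == 0:
            out.append(
                ConditionSummary(cond, 0, float("nan"), None, probs, missing=True)
            )
            continue
        acc = float(acc_cell["correct"].astype(bool).mean())
        err_rt = acc_cell[
            ~acc_cell["correct"].astype(bool)
            & acc_cell["rt_ms"].between(RT_MIN_MS, RT_MAX_MS)
        ]["rt_ms"]
        summary = ConditionSummary(
            condition=cond,
            n_trials=len(acc_cell),
            accuracy=acc,
            mean_rt_ms=float(rt_cell["rt_ms"].mean()) if len(rt_cell) else None,
            quantile_probs=probs,
            correct_quantiles_ms=quantiles(rt_cell["rt_ms"], probs) if len(rt_cell) else None,
            error_quantiles_ms=(
                quantiles(err_rt, probs) if len(err_rt) >= MIN_ERRORS_FOR_QUANTILES else None
            ),
            n_errors_in_window=len(err_rt),
        )
        out.append(summary)
    return out


def summaries_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Tidy frame of condition summaries (one row per cell)."""
    rows = []
    for s in summaries:
        row = {
            "lexicality": s.condition[0],
            "repetition": s.condition[1],
            "n_trials": s.n_trials,
            "accuracy": s.accuracy,
            "percent_error": 100.0 * (1.0 - s.accuracy) if s.n_trials else float("nan"),
            "mean_rt_ms": s.mean_rt_ms,
        }
        for p, q in zip(s.quantile_probs, s.correct_quantiles_ms if s.correct_quantiles_ms is not None else []):
            row[f"q{p:g}"] = q
        rows.append(row)
    return pd.DataFrame(rows)


def per_subject_quantiles(
    rt_set: pd.DataFrame, quantile_probs: Sequence[float] = DEFAULT_QUANTILE_PROBS
) -> pd.DataFrame:
    """Subject x condition x probability table of correct-RT quantiles (ms)."""
    rows = []
    for (subj, lex, rep), g in rt_set.groupby(["subject_id", "lexicality", "repetition"], sort=False):
        qs = quantiles(g["rt_ms"], quantile_probs)
        for p, q in zip(quantile_probs, qs):
            rows.append({"subject_id": subj, "lexicality": lex, "repetition": rep, "prob": p, "rt_ms": q})
    return pd.DataFrame(rows)


def vincentize(per_subject: pd.DataFrame):
    """Group quantiles: unweighted mean over subjects, per condition and probability.

    Subjects missing a condition are excluded from that condition's mean;
    the count of such exclusions is returned alongside.
    """
    n_subjects = per_subject["subject_id"].nunique()
    group = (
        per_subject.groupby(["lexicality", "repetition", "prob"], sort=False)["rt_ms"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "rt_ms", "count": "n_subjects"})
    )
    group["n_missing_subjects"] = n_subjects - group["n_subjects"]
    return group


@dataclass
class EffectSummary:
    lexicality: str
    effect_ms: float
    ci_low_ms: float | None
    ci_high_ms: float | None
    per_quantile_effect_ms: Mapping[float, float]
    n_subjects: int


def repetition_effects(
    rt_set: pd.DataFrame,
    vincentiles: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    rng: np.random.Generator | int | None = 0,
) -> list[EffectSummary]:
    """Repetition effect (nonrepeated - repeated mean correct RT) per lexicality.

    The point effect is the difference of the means of the per-subject
    condition means; the CI is a seeded percentile bootstrap over subjects
    of the per-subject effects.  The per-quantile profile is the
    nonrepeated-minus-repeated difference of group vincentiles.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if vincentiles is None:
        vincentiles = vincentize(per_subject_quantiles(rt_set))
    out = []
    for lex in ("word", "nonword"):
        sub = rt_set[rt_set["lexicality"] == lex]
        means = sub.groupby(["subject_id", "repetition"])["rt_ms"].mean().unstack("repetition")
        have_both = means.dropna(subset=["nonrepeated", "repeated"], how="any") if {
            "nonrepeated",
            "repeated",
        } <= set(means.columns) else means.iloc[0:0]
        if len(have_both) == 0:
            raise ValueError(f"both repetition cells required for lexicality {lex!r}")
        eff_subj = (have_both["nonrepeated"] - have_both["repeated"]).to_numpy()
        effect = float(np.mean(eff_subj))
        if len(eff_subj) >= 2 and rng is not None:
            idx = rng.integers(0, len(eff_subj), size=(n_boot, len(eff_subj)))
            boot = eff_subj[idx].mean(axis=1)
            ci_low, ci_high = (float(q) for q in np.percentile(boot, [2.5, 97.5]))
        else:
            ci_low = ci_high = None
        vlex = vincentiles[vincentiles["lexicality"] == lex]
        prof = {}
        for p, g in vlex.groupby("prob"):
            by_rep = dict(zip(g["repetition"], g["rt_ms"]))
            if {"nonrepeated", "repeated"} <= set(by_rep):
                prof[float(p)] = float(by_rep["nonrepeated"] - by_rep["repeated"])
        out.append(
            EffectSummary(
                lexicality=lex,
                effect_ms=effect,
                ci_low_ms=ci_low,
                ci_high_ms=ci_high,
                per_quantile_effect_ms=prof,
                n_subjects=len(eff_subj),
            )
        )
    return out


@dataclass
class GroupData:
    """Grouped (vincentized) data for one fit: per-condition summaries.

    ``correct_quantiles_ms`` are vincentized over subjects; error-side
    quantiles are pooled over subjects (subject-level error counts are too
    sparse to vincentize) and present only when the aggregated cell has at
    least :data:`MIN_ERRORS_FOR_QUANTILES` in-window errors.
    """

    quantile_probs: tuple
    accuracy: Mapping[Condition, float]
    n_trials: Mapping[Condition, int]
    correct_quantiles_ms: Mapping[Condition, np.ndarray]
    error_quantiles_ms: Mapping[Condition, np.ndarray | None]

    @property
    def conditions(self) -> tuple:
        return tuple(self.accuracy.keys())


def group_data(
    trials: pd.DataFrame,
    quantile_probs: Sequence[float] = DEFAULT_QUANTILE_PROBS,
    use_error_quantiles: bool = True,
) -> GroupData:
    """Assemble the grouped fitting target from a raw trial table.

    With ``use_error_quantiles=False`` the error side is summarised by its
    count only (the fitter then uses a single error bin per condition).
    """
    rt_set, acc_set, _ = preprocess(trials)
    probs = tuple(quantile_probs)
    vinc = vincentize(per_subject_quantiles(rt_set, probs))
    accuracy, n_trials, cq, eq = {}, {}, {}, {}
    for cond in CONDITIONS:
        lex, rep = cond
        acc_cell = acc_set[(acc_set["lexicality"] == lex) & (acc_set["repetition"] == rep)]
        if len(acc_cell) == 0:
            continue
        accuracy[cond] = float(acc_cell["correct"].astype(bool).mean())
        n_trials[cond] = len(acc_cell)
        v = vinc[(vinc["lexicality"] == lex) & (vinc["repetition"] == rep)].sort_values("prob")
        cq[cond] = v["rt_ms"].to_numpy()
        err_rt = acc_cell[
            ~acc_cell["correct"].astype(bool) & acc_cell["rt_ms"].between(RT_MIN_MS, RT_MAX_MS)
        ]["rt_ms"]
        eq[cond] = (
            quantiles(err_rt, probs)
            if use_error_quantiles and len(err_rt) >= MIN_ERRORS_FOR_QUANTILES
            else None
        )
    return GroupData(probs, accuracy, n_trials, cq, eq)
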