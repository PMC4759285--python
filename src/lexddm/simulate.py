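"""Trial-level sampling and synthetic two-block lexical decision experiments.

The generator realises the repetition design: two blocks of 200 trials per
subject (100 words / 100 nonwords each).  Half of the Block-2 experimental
items were already shown in Block 1 ("repeated"); which half is repeated is
counterbalanced across subjects via two material sets.  Block-1 trials (and
fillers, which only exist to preserve design counts) are first
presentations and are generated from the nonrepeated-condition parameters;
only Block 2 enters the analyses.

Responses come from Euler–Maruyama path simulation of the diffusion
process (step 1e-4 s for dataset generation; 1e-5 s in oracle mode for
validating the analytic kernel).  Trial-level drift, starting point and
non-decision time are drawn from their across-trial distributions; with
probability ``p0`` a trial is a contaminant (uniform RT on the analysis
window, accuracy equal to the diffusion-predicted accuracy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .params import (
    CONTAMINANT_WINDOW,
    CONDITIONS,
    CORRECT_SIDE,
    Condition,
    DiffusionParams,
    ResponseSide,
)
from .predict import predicted_accuracy

#: Euler step sizes (seconds)
DT_GENERATE = 1e-4
DT_ORACLE = 1e-5

#: decision-stage timeout (seconds); timed-out trials are resampled
MAX_RT = 2.0

TRIAL_COLUMNS = (
    "subject_id",
    "item_id",
    "block",
    "lexicality",
    "repetition",
    "response",
    "correct",
    "rt_ms",
)


class DesignError(ValueError):
    """Raised for inconsistent experiment designs or parameter maps."""


@dataclass(frozen=True)
class DesignSpec:
    """Layout of the two-block repetition experiment.

    Defaults reproduce the study design: 24 subjects, 50 trials per
    repetition x lexicality cell in Block 2 (200 Block-2 trials), Block 1
    padded to the same length with fillers, and two counterbalancing sets
    so that each experimental item is repeated for half of the subjects.
    """

    n_subjects: int = 24
    trials_per_condition: int = 50
    conditions: tuple = CONDITIONS
    counterbalance_sets: tuple = ("Set1", "Set2")
    subject_ter_sd: float = 0.0  # optional subject random effect on t_er (s)
    dt: float = DT_GENERATE

    def __post_init__(self):
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise DesignError("n_subjects and trials_per_condition must be >= 1")
        if self.subject_ter_sd < 0:
            raise DesignError("subject_ter_sd must be >= 0")

    @property
    def block2_trials(self) -> int:
        return len(self.conditions) * self.trials_per_condition

    @property
    def block1_trials(self) -> int:
        # half of each lexicality's experimental items plus fillers
        return self.block2_trials

    def to_dict(self) -> dict:
        return asdict(self)


def _euler_paths(v, z, a, s, dt, rng, max_t=MAX_RT):
    """Simulate paths to absorption; per-trial drift/start arrays.

    Returns (upper: bool array, decision time array).  Paths still alive at
    ``max_t`` are reported with time ``nan`` (caller resamples them).
    """
    v = np.asarray(v, dtype=float)
    z = np.asarray(z, dtype=float)
    n = v.size
    x = z.copy()
    upper = np.zeros(n, dtype=bool)
    t_dec = np.full(n, np.nan)
    alive = np.arange(n)
    sigma = s * np.sqrt(dt)
    n_steps = int(np.ceil(max_t / dt))
    for step in range(1, n_steps + 1):
        x[alive] += v[alive] * dt + sigma * rng.standard_normal(alive.size)
        hit_up = x[alive] >= a
        hit_lo = x[alive] <= 0.0
        done = hit_up | hit_lo
        if np.any(done):
            idx = alive[done]
            upper[idx] = hit_up[done]
            t_dec[idx] = step * dt
            alive = alive[~done]
            if alive.size == 0:
                break
    return upper, t_dec


def sample_trials(
    params: DiffusionParams,
    n: int,
    rng: np.random.Generator,
    dt: float = DT_GENERATE,
    accuracy_for_contaminants: float | None = None,
    correct_side: ResponseSide = ResponseSide.UPPER,
):
    """Draw ``n`` trials from the full model (variability + contaminants).

    Returns ``(sides, rts, n_resampled)`` where ``sides`` is a boolean
    array (True = upper boundary) and ``rts`` are total RTs in seconds.
    Trials whose total RT would exceed the 2 s response deadline are
    resampled (fresh trial-level draws) and counted.

    ``accuracy_for_contaminants`` is the response-accuracy assigned to
    contaminant trials; it defaults to the diffusion-predicted accuracy of
    ``params`` with correct side ``correct_side``.
    """
    if accuracy_for_contaminants is None:
        lex = "word" if correct_side is ResponseSide.UPPER else "nonword"
        accuracy_for_contaminants = predicted_accuracy(params, lex)
    upper = np.zeros(n, dtype=bool)
    rt = np.full(n, np.nan)
    n_resampled = 0
    todo = np.arange(n)
    while todo.size:
        m = todo.size
        is_cont = rng.random(m) < params.p0
        # contaminants: uniform RT on the analysis window, diffusion accuracy
        if np.any(is_cont):
            k = int(np.sum(is_cont))
            lo, hi = CONTAMINANT_WINDOW
            rt_c = rng.uniform(lo, hi, k)
            corr = rng.random(k) < accuracy_for_contaminants
            up_c = corr if correct_side is ResponseSide.UPPER else ~corr
            upper[todo[is_cont]] = up_c
            rt[todo[is_cont]] = rt_c
        # diffusion trials
        idx = todo[~is_cont]
        if idx.size:
            v = rng.normal(params.v, params.eta, idx.size) if params.eta > 0 else np.full(idx.size, params.v)
            z = (
                rng.uniform(params.z - params.sz / 2, params.z + params.sz / 2, idx.size)
                if params.sz > 0
                else np.full(idx.size, params.z)
            )
            ndt = (
                rng.uniform(params.t_er - params.st / 2, params.t_er + params.st / 2, idx.size)
                if params.st > 0
                else np.full(idx.size, params.t_er)
            )
            up, t_dec = _euler_paths(v, z, params.a, params.s, dt, rng)
            total = t_dec + ndt
            ok = np.isfinite(total) & (total <= MAX_RT)
            upper[idx[ok]] = up[ok]
            rt[idx[ok]] = total[ok]
            todo = idx[~ok]
            n_resampled += int(np.sum(~ok))
        else:
            todo = idx
    return upper, rt, n_resampled


def sample_trial(params: DiffusionParams, rng: np.random.Generator, dt: float = DT_GENERATE):
    """Single trial: returns ``(ResponseSide, rt_seconds)``."""
    up, rt, _ = sample_trials(params, 1, rng, dt=dt)
    return (ResponseSide.UPPER if up[0] else ResponseSide.LOWER), float(rt[0])


def _item_table(design: DesignSpec):
    """Experimental and filler items with per-set repetition assignment."""
    t = design.trials_per_condition
    rows = []
    for lex, prefix in (("word", "w"), ("nonword", "n")):
        for i in range(2 * t):
            # first half of each lexicality is shown in Block 1 for Set1,
            # the second half for Set2
            rows.append(
                {
                    "item_id": f"{prefix}{i:03d}",
                    "lexicality": lex,
                    "in_block1": {"Set1": i < t, "Set2": i >= t},
                    "filler": False,
                }
            )
        for i in range(t):
            rows.append(
                {
                    "item_id": f"f{prefix}{i:03d}",
                    "lexicality": lex,
                    "in_block1": {"Set1": True, "Set2": True},
                    "filler": True,
                }
            )
    return rows


def generate_experiment(
    design: DesignSpec,
    params_by_condition: Mapping[Condition, DiffusionParams],
    rng: np.random.Generator | int,
):
    """Generate a complete synthetic experiment.

    Returns ``(trials, metadata)``: a tidy trial table (one row per
    presentation, both blocks) and a metadata dict recording resample and
    contaminant bookkeeping.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    missing = [c for c in design.conditions if c not in params_by_condition]
    if missing:
        raise DesignError(f"params_by_condition missing design cells: {missing}")

    acc = {c: predicted_accuracy(params_by_condition[c], c[0]) for c in design.conditions}
    items = _item_table(design)
    sets = design.counterbalance_sets

    # collect trial stubs, then batch-sample RTs per (condition, subject offset)
    stubs = []  # (subject, item, block, lexicality, repetition)
    ter_offsets = (
        rng.normal(0.0, design.subject_ter_sd, design.n_subjects)
        if design.subject_ter_sd > 0
        else np.zeros(design.n_subjects)
    )
    for s_idx in range(design.n_subjects):
        subj = f"s{s_idx + 1:02d}"
        cb = sets[s_idx % len(sets)]
        for it in items:
            if it["in_block1"][cb]:
                stubs.append((subj, it["item_id"], 1, it["lexicality"], "nonrepeated"))
            if not it["filler"]:
                rep = "repeated" if it["in_block1"][cb] else "nonrepeated"
                stubs.append((subj, it["item_id"], 2, it["lexicality"], rep))

    df = pd.DataFrame(stubs, columns=["subject_id", "item_id", "block", "lexicality", "repetition"])
    # Block-1 presentations are first presentations: nonrepeated parameters
    cond_of_row = list(zip(df["lexicality"], np.where(df["block"] == 1, "nonrepeated", df["repetition"])))
    df["_cond"] = [f"{l}:{r}" for l, r in cond_of_row]

    df["response"] = ""
    df["rt_ms"] = np.nan
    n_resampled = 0
    subj_offset = dict(zip([f"s{i + 1:02d}" for i in range(design.n_subjects)], ter_offsets))
    for cond in design.conditions:
        key = f"{cond[0]}:{cond[1]}"
        mask = df["_cond"] == key
        if not mask.any():
            continue
        base = params_by_condition[cond]
        correct_side = CORRECT_SIDE[cond[0]]
        if design.subject_ter_sd > 0:
            for subj, off in subj_offset.items():
                m2 = mask & (df["subject_id"] == subj)
                if not m2.any():
                    continue
                p = base.replace(t_er=max(base.t_er + off, base.st / 2))
                up, rts, nr = sample_trials(
                    p, int(m2.sum()), rng, dt=design.dt,
                    accuracy_for_contaminants=acc[cond], correct_side=correct_side,
                )
                df.loc[m2, "response"] = np.where(up, "word", "nonword")
                df.loc[m2, "rt_ms"] = np.round(rts * 1000.0, 3)
                n_resampled += nr
        else:
            up, rts, nr = sample_trials(
                base, int(mask.sum()), rng, dt=design.dt,
                accuracy_for_contaminants=acc[cond], correct_side=correct_side,
            )
            df.loc[mask, "response"] = np.where(up, "word", "nonword")
            df.loc[mask, "rt_ms"] = np.round(rts * 1000.0, 3)
            n_resampled += nr
    df["correct"] = df["response"] == df["lexicality"]

    # per-subject randomised presentation order within each block
    order = np.zeros(len(df), dtype=int)
    for subj in df["subject_id"].unique():
        for block in (1, 2):
            m = (df["subject_id"] == subj) & (df["block"] == block)
            order[np.flatnonzero(m)] = rng.permutation(int(m.sum()))
    df["trial_order"] = order
    df = (
        df.sort_values(["subject_id", "block", "trial_order"])
        .drop(columns=["_cond", "trial_order"])
        .reset_index(drop=True)
    )
    df = df[list(TRIAL_COLUMNS)]

    metadata = {
        "design": design.to_dict(),
        "params_by_condition": {
            f"{c[0]}:{c[1]}": params_by_condition[c].to_dict() for c in design.conditions
        },
        "n_trials": int(len(df)),
        "n_block2_trials": int((df["block"] == 2).sum()),
        "n_resampled": int(n_resampled),
    }
    return df, metadata


def write_trials(trials: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write the trial table as CSV with a JSON metadata sidecar."""
    path = Path(path)
    trials.to_csv(path, index=False)
    if metadata is not None:
        path.with_suffix(".meta.json").write_text(json.dumps(metadata, indent=2))


def read_trials(path) -> pd.DataFrame:
    """Read a trial table, validating the expected schema."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise DesignError(f"trial table missing columns: {sorted(missing)}")
    return df
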