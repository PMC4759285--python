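"""Constrained quantile-based fitting of the diffusion model to grouped data.

The estimation target is the grouped (vincentized) data: per condition, the
observed defective RT distributions are cut at the observed quantiles into
six correct-side bins (and six error-side bins where the error count
permits; otherwise the error side collapses to a single accuracy bin).
Predicted bin probabilities come from the model's defective CDFs, and the
objective is a Pearson-type chi-square over bins and conditions,

    X^2 = sum_c N_c * sum_b (p_obs - p_pred)^2 / max(p_pred, floor),

with a likelihood-ratio (G^2) alternative available.  Minimisation is a
derivative-free Nelder–Mead simplex with seeded random restarts on a
transformed parameter space (log for positive parameters, logit for
proportions) that enforces the box constraints.

The default constraint scheme fixes six of the nine parameters to values
from earlier experiments with the same subject population (zr = 0.54,
eta = 0.034, sz = 0.002, st = 0.14 s, p0 = 0.005), shares the boundary
separation across conditions, and frees drift and non-decision time per
condition.  A drift-only variant shares the non-decision time as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .params import CONDITIONS, CORRECT_SIDE, Condition, DiffusionParams, ParameterError
from .predict import defective_cdf, predict_condition, response_probability
from .summaries import GroupData, group_data

PARAM_NAMES = ("v", "a", "zr", "t_er", "eta", "sz", "st", "p0")

#: probability floor protecting the chi-square denominator
PROB_FLOOR = 1e-5

_PENALTY = 1e12

#: prior-study values used for the six fixed parameters
DEFAULT_FIXED = {"zr": 0.54, "eta": 0.034, "sz": 0.002, "st": 0.14, "p0": 0.005}

_LOG = {"a", "t_er", "eta", "sz", "st"}
_LOGIT = {"zr", "p0"}


def _to_internal(name: str, x: float) -> float:
    if name in _LOG:
        return float(np.log(x))
    if name in _LOGIT:
        return float(np.log(x / (1.0 - x)))
    return float(x)


def _from_internal(name: str, y: float) -> float:
    if name in _LOG:
        return float(np.exp(y))
    if name in _LOGIT:
        return float(1.0 / (1.0 + np.exp(-y)))
    return float(y)


class FitSpecError(ValueError):
    pass


@dataclass(frozen=True)
class FitSpec:
    """Which parameters are fixed, free per condition, or shared-free.

    ``statuses`` maps each parameter name to ``("fixed", value)``,
    ``("free",)`` (one value per condition) or ``("shared",)`` (one value
    for all conditions).
    """

    statuses: Mapping[str, tuple]
    objective: str = "chisq"  # "chisq" | "gsq"
    n_restarts: int = 5
    maxiter_restart: int = 300
    maxiter_polish: int = 1200
    perturb_scale: float = 0.1
    xatol: float = 1e-4
    fatol: float = 1e-4

    def __post_init__(self):
        for name in PARAM_NAMES:
            if name not in self.statuses:
                raise FitSpecError(f"parameter {name!r} has no status")
            st = self.statuses[name]
            if st[0] not in ("fixed", "free", "shared") or (st[0] == "fixed") != (len(st) == 2):
                raise FitSpecError(f"bad status for {name!r}: {st!r}")
        if self.objective not in ("chisq", "gsq"):
            raise FitSpecError(f"unknown objective {self.objective!r}")
        if not any(self.statuses[n][0] != "fixed" for n in PARAM_NAMES):
            # all-fixed specs are allowed for evaluation-only "fits"
            pass

    @classmethod
    def constrained(cls, **kwargs) -> "FitSpec":
        """Default scheme: a shared; v and t_er free per condition."""
        statuses = {n: ("fixed", v) for n, v in DEFAULT_FIXED.items()}
        statuses.update({"v": ("free",), "t_er": ("free",), "a": ("shared",)})
        return cls(statuses=statuses, **kwargs)

    @classmethod
    def drift_only(cls, **kwargs) -> "FitSpec":
        """Variant with only drift free per condition (t_er shared)."""
        statuses = {n: ("fixed", v) for n, v in DEFAULT_FIXED.items()}
        statuses.update({"v": ("free",), "t_er": ("shared",), "a": ("shared",)})
        return cls(statuses=statuses, **kwargs)

    @classmethod
    def all_fixed(cls, params_by_condition: Mapping[Condition, DiffusionParams], **kwargs) -> "FitSpec":
        """Degenerate spec evaluating a given parameter set (no free parameters).

        Condition-varying parameters are not representable as single fixed
        values, so this uses the first condition's values for every status;
        intended for single-condition or shared-parameter checks.
        """
        p0 = next(iter(params_by_condition.values()))
        statuses = {n: ("fixed", getattr(p0, n)) for n in PARAM_NAMES}
        return cls(statuses=statuses, **kwargs)

    def free_entries(self, conditions: Sequence[Condition]) -> list[tuple[str, Condition | None]]:
        """Ordered layout of the free vector: (name, condition-or-None)."""
        entries: list[tuple[str, Condition | None]] = []
        for name in PARAM_NAMES:
            kind = self.statuses[name][0]
            if kind == "shared":
                entries.append((name, None))
            elif kind == "free":
                entries.extend((name, c) for c in conditions)
        return entries

    def to_dict(self) -> dict:
        return {
            "statuses": {k: list(v) for k, v in self.statuses.items()},
            "objective": self.objective,
            "n_restarts": self.n_restarts,
            "maxiter_restart": self.maxiter_restart,
            "maxiter_polish": self.maxiter_polish,
            "perturb_scale": self.perturb_scale,
            "xatol": self.xatol,
            "fatol": self.fatol,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitSpec":
        d = dict(d)
        d["statuses"] = {k: tuple(v) for k, v in d["statuses"].items()}
        return cls(**d)


def _params_from_vector(
    vec: np.ndarray,
    spec: FitSpec,
    conditions: Sequence[Condition],
) -> Mapping[Condition, DiffusionParams]:
    entries = spec.free_entries(conditions)
    values: dict[Condition, dict] = {c: {} for c in conditions}
    for name in PARAM_NAMES:
        st = spec.statuses[name]
        if st[0] == "fixed":
            for c in conditions:
                values[c][name] = st[1]
    for (name, cond), y in zip(entries, vec):
        x = _from_internal(name, float(y))
        if cond is None:
            for c in conditions:
                values[c][name] = x
        else:
            values[cond][name] = x
    return {c: DiffusionParams(**values[c]) for c in conditions}


def binned_statistic(n, p_obs, p_pred, kind: str = "chisq", floor: float = PROB_FLOOR):
    """Pearson chi-square or G^2 over one set of bin probabilities.

    ``chisq``: ``n * sum((p_obs - p_pred)^2 / max(p_pred, floor))``;
    ``gsq``: ``2n * sum(p_obs * log(p_obs / max(p_pred, floor)))`` over
    bins with positive observed mass.
    """
    po = np.asarray(p_obs, dtype=float)
    pp_f = np.maximum(np.asarray(p_pred, dtype=float), floor)
    if kind == "chisq":
        return float(n * np.sum((po - np.asarray(p_pred, dtype=float)) ** 2 / pp_f))
    if kind == "gsq":
        pos = po > 0
        return float(2.0 * n * np.sum(po[pos] * np.log(po[pos] / pp_f[pos])))
    raise FitSpecError(f"unknown objective {kind!r}")


def _condition_bins(group: GroupData, cond: Condition, params: DiffusionParams):
    """Observed/predicted bin probabilities for one condition.

    Returns ``(p_obs, p_pred, labels)`` as arrays/lists; labels are
    ``(side, bin)`` pairs.
    """
    lex = cond[0]
    corr_side = CORRECT_SIDE[lex]
    err_side = corr_side.opposite
    acc = group.accuracy[cond]
    probs = np.asarray(group.quantile_probs, dtype=float)
    edge_masses = np.diff(np.concatenate([[0.0], probs, [1.0]]))
    p_obs, p_pred, labels = [], [], []
    for side_name, side, mass, qs in (
        ("correct", corr_side, acc, group.correct_quantiles_ms[cond]),
        ("error", err_side, 1.0 - acc, group.error_quantiles_ms.get(cond)),
    ):
        p_side = response_probability(params, side)
        if qs is None:
            p_obs.append(mass)
            p_pred.append(p_side)
            labels.append((side_name, 0))
            continue
        g = defective_cdf(np.asarray(qs, dtype=float) / 1000.0, params, side)
        p_pred.extend(np.diff(np.concatenate([[0.0], g, [p_side]])))
        p_obs.extend(mass * edge_masses)
        labels.extend((side_name, b) for b in range(edge_masses.size))
    return np.asarray(p_obs), np.asarray(p_pred), labels


def quantile_objective(
    group: GroupData,
    params_by_condition: Mapping[Condition, DiffusionParams],
    kind: str = "chisq",
    floor: float = PROB_FLOOR,
    return_bins: bool = False,
):
    """Quantile-bin objective over all conditions.

    Returns the objective value, or ``(value, bins, n_floored)`` when
    ``return_bins`` is set.  Predicted probabilities below ``floor`` are
    floored in the denominator (chi-square) / logarithm (G^2) and counted.
    """
    total = 0.0
    n_floored = 0
    rows = []
    for cond in group.conditions:
        po, pp, labels = _condition_bins(group, cond, params_by_condition[cond])
        n_floored += int(np.sum(pp < floor))
        total += binned_statistic(group.n_trials[cond], po, pp, kind, floor)
        if return_bins:
            rows.extend(
                {
                    "lexicality": cond[0],
                    "repetition": cond[1],
                    "side": side,
                    "bin": b,
                    "p_obs": float(o),
                    "p_pred": float(p),
                }
                for (side, b), o, p in zip(labels, po, pp)
            )
    if return_bins:
        return total, pd.DataFrame(rows), n_floored
    return total


def _start_vector(group: GroupData, spec: FitSpec) -> np.ndarray:
    """Data-driven start values on the internal (transformed) scale."""
    conditions = group.conditions
    t_er0 = {
        c: 0.9 * group.correct_quantiles_ms[c][0] / 1000.0 for c in conditions
    }
    v0 = {c: (0.2 if c[0] == "word" else -0.2) for c in conditions}
    start = []
    for name, cond in spec.free_entries(conditions):
        if name == "v":
            x = v0[cond] if cond is not None else float(np.mean(list(v0.values())))
        elif name == "t_er":
            x = t_er0[cond] if cond is not None else float(np.mean(list(t_er0.values())))
        elif name == "a":
            x = 0.1
        else:
            x = DEFAULT_FIXED.get(name, 0.1)
        start.append(_to_internal(name, x))
    return np.asarray(start, dtype=float)


@dataclass
class DiffusionFitResults:
    """Fitted parameters, objective diagnostics and convenience methods."""

    model: "QuantileDiffusionModel"
    spec: FitSpec
    params_by_condition: Mapping[Condition, DiffusionParams]
    objective: float
    objective_kind: str
    n_free: int
    n_bins: int
    converged: bool
    nfev: int
    n_floored: int
    seed: int
    bins: pd.DataFrame = field(repr=False)
    trace: list = field(repr=False, default_factory=list)

    @property
    def dof(self) -> int:
        """Fitted bins minus free parameters (descriptive, no p-value attached)."""
        return self.n_bins - self.n_free

    def predict(self, quantile_probs=None):
        """Model predictions (accuracy + defective quantiles) per condition."""
        kw = {} if quantile_probs is None else {"quantile_probs": quantile_probs}
        return {
            c: predict_condition(p, c[0], **kw) for c, p in self.params_by_condition.items()
        }

    def simulate(self, design=None, rng: np.random.Generator | int = 0):
        """Generate a synthetic experiment at the fitted parameter values."""
        from .simulate import DesignSpec, generate_experiment

        return generate_experiment(design or DesignSpec(), self.params_by_condition, rng)

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for (lex, rep), p in self.params_by_condition.items():
            rows.append({"lexicality": lex, "repetition": rep, **p.to_dict()})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Quantile diffusion model fit",
            "=" * 64,
            f"objective ({self.objective_kind}): {self.objective:.3f}"
            f"   bins: {self.n_bins}   free parameters: {self.n_free}   dof: {self.dof}",
            f"converged: {self.converged}   function evaluations: {self.nfev}"
            + (f"   floored bins: {self.n_floored}" if self.n_floored else ""),
            "-" * 64,
        ]
        pf = self.params_frame()
        with pd.option_context("display.width", 120, "display.float_format", "{:.4f}".format):
            lines.append(pf.to_string(index=False))
        lines.append("-" * 64)
        acc = {c: response_probability(p, CORRECT_SIDE[c[0]]) for c, p in self.params_by_condition.items()}
        for c in self.params_by_condition:
            obs = self.model.data.accuracy.get(c)
            lines.append(
                f"accuracy {c[0]:>7s}/{c[1]:<11s}  observed {obs:.3f}  predicted {acc[c]:.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "params_by_condition": {
                f"{c[0]}:{c[1]}": p.to_dict() for c, p in self.params_by_condition.items()
            },
            "objective": self.objective,
            "objective_kind": self.objective_kind,
            "n_free": self.n_free,
            "n_bins": self.n_bins,
            "dof": self.dof,
            "converged": self.converged,
            "nfev": self.nfev,
            "n_floored": self.n_floored,
            "seed": self.seed,
            "trace": self.trace,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class QuantileDiffusionModel:
    """Diffusion model bound to grouped lexical-decision data.

    Built either from a :class:`~lexddm.summaries.GroupData` (vincentized
    quantiles, accuracies and Ns per condition) or, via
    :meth:`from_trials`, from a raw trial table.  :meth:`fit` runs the
    constrained simplex search and returns :class:`DiffusionFitResults`.
    """

    def __init__(self, data: GroupData, spec: FitSpec | None = None):
        if not data.conditions:
            raise ValueError("group data contains no conditions")
        self.data = data
        self.spec = spec or FitSpec.constrained()

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, spec: FitSpec | None = None, quantile_probs=None):
        from .predict import DEFAULT_QUANTILE_PROBS

        gd = group_data(trials, quantile_probs or DEFAULT_QUANTILE_PROBS)
        missing = [c for c in CONDITIONS if c not in gd.accuracy]
        if missing:
            raise ValueError(f"trial table missing conditions: {missing}")
        return cls(gd, spec)

    def objective(self, params_by_condition, kind=None):
        return quantile_objective(
            self.data, params_by_condition, kind or self.spec.objective
        )

    def _objective_vec(self, vec: np.ndarray, spec: FitSpec) -> float:
        try:
            pbc = _params_from_vector(vec, spec, self.data.conditions)
        except (ParameterError, OverflowError, FloatingPointError):
            return _PENALTY
        try:
            return quantile_objective(self.data, pbc, spec.objective)
        except (ParameterError, ValueError):
            return _PENALTY

    def fit(
        self,
        seed: int = 0,
        spec: FitSpec | None = None,
        start_params: Mapping[Condition, DiffusionParams] | None = None,
    ) -> DiffusionFitResults:
        """Minimise the quantile objective; deterministic given ``seed``.

        ``start_params``, when given, contributes an extra start point (on
        top of the data-driven start and the seeded restarts).
        """
        spec = spec or self.spec
        conditions = self.data.conditions
        entries = spec.free_entries(conditions)
        rng = np.random.default_rng(seed)
        trace = []
        nfev_total = 0

        if not entries:  # degenerate all-fixed spec: evaluate only
            pbc = _params_from_vector(np.empty(0), spec, conditions)
            obj, bins, n_floored = quantile_objective(
                self.data, pbc, spec.objective, return_bins=True
            )
            return DiffusionFitResults(
                model=self, spec=spec, params_by_condition=pbc, objective=obj,
                objective_kind=spec.objective, n_free=0, n_bins=len(bins),
                converged=True, nfev=1, n_floored=n_floored, seed=seed,
                bins=bins, trace=[{"stage": "evaluate", "objective": obj}],
            )

        base = _start_vector(self.data, spec)
        starts = [base]
        if start_params is not None:
            warm = np.array(
                [
                    _to_internal(
                        name,
                        getattr(start_params[cond if cond is not None else conditions[0]], name),
                    )
                    for name, cond in entries
                ]
            )
            starts.append(warm)
        for _ in range(max(spec.n_restarts - 1, 0)):
            starts.append(base + spec.perturb_scale * rng.standard_normal(base.size))

        nm_opts = dict(xatol=spec.xatol, fatol=spec.fatol, adaptive=True)
        best = None
        for i, x0 in enumerate(starts):
            res = minimize(
                self._objective_vec, x0, args=(spec,), method="Nelder-Mead",
                options={**nm_opts, "maxiter": spec.maxiter_restart},
            )
            nfev_total += res.nfev
            trace.append({"stage": f"restart{i}", "objective": float(res.fun), "nfev": int(res.nfev)})
            if best is None or res.fun < best.fun:
                best = res
        polish = minimize(
            self._objective_vec, best.x, args=(spec,), method="Nelder-Mead",
            options={**nm_opts, "maxiter": spec.maxiter_polish},
        )
        nfev_total += polish.nfev
        trace.append({"stage": "polish", "objective": float(polish.fun), "nfev": int(polish.nfev)})
        final = polish if polish.fun <= best.fun else best
        converged = bool(final.success and final.fun < _PENALTY)

        pbc = _params_from_vector(final.x, spec, conditions)
        obj, bins, n_floored = quantile_objective(
            self.data, pbc, spec.objective, return_bins=True
        )
        return DiffusionFitResults(
            model=self, spec=spec, params_by_condition=pbc, objective=obj,
            objective_kind=spec.objective, n_free=len(entries), n_bins=len(bins),
            converged=converged, nfev=nfev_total, n_floored=n_floored, seed=seed,
            bins=bins, trace=trace,
        )


def fit(group: GroupData, spec: FitSpec | None = None, seed: int = 0) -> DiffusionFitResults:
    """Functional wrapper: fit ``spec`` (default constrained scheme) to ``group``."""
    return QuantileDiffusionModel(group, spec).fit(seed=seed)


@dataclass
class ModelComparison:
    """Relative fit of the full (drift + t_er free) vs reduced (drift-only) model."""

    objective_full: float
    objective_reduced: float
    n_free_full: int
    n_free_reduced: int
    valid: bool
    results_full: DiffusionFitResults = field(repr=False, default=None)
    results_reduced: DiffusionFitResults = field(repr=False, default=None)

    @property
    def improvement(self) -> float:
        """(reduced - full) / reduced; positive when the full model fits better."""
        if self.objective_reduced == 0:
            return 0.0
        return (self.objective_reduced - self.objective_full) / self.objective_reduced


def compare_models(
    group: GroupData,
    spec_full: FitSpec | None = None,
    spec_reduced: FitSpec | None = None,
    seed: int = 0,
) -> ModelComparison:
    """Fit both model variants and report the relative improvement.

    The full fit is warm-started from the reduced solution (in addition to
    its own starts), so a nested full model can never do worse than the
    reduced one beyond simplex tolerance.
    """
    spec_full = spec_full or FitSpec.constrained()
    spec_reduced = spec_reduced or FitSpec.drift_only()
    model = QuantileDiffusionModel(group)
    res_reduced = model.fit(seed=seed, spec=spec_reduced)
    res_full = model.fit(seed=seed, spec=spec_full, start_params=res_reduced.params_by_condition)
    valid = res_full.converged and res_reduced.converged
    return ModelComparison(
        objective_full=res_full.objective,
        objective_reduced=res_reduced.objective,
        n_free_full=res_full.n_free,
        n_free_reduced=res_reduced.n_free,
        valid=valid,
        results_full=res_full,
        results_reduced=res_reduced,
    )
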