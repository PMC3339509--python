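"""Linear-programming core: FBA, FVA, flux spans, span ratios, classification.

All optimization is over the steady-state flux polytope

    {v : S.v = 0, alpha <= v <= beta}

solved with the HiGHS solver behind ``scipy.optimize.linprog``. Flux
Variability Analysis (FVA) maximizes and minimizes every reaction's flux over
that polytope, the Flux Span is the width of the resulting interval in one
condition, and the Flux Span Ratio is the reaction-wise ratio of spans between
two conditions — the comparison statistic this package exists to compute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import Model

#: Spans at or below this are treated as numerically zero in ratio denominators.
EPS_SPAN = 1e-9

#: Feasibility asserted on returned solutions (steady state and bounds).
FEASIBILITY_TOL = 1e-6


class SolverError(RuntimeError):
    """The LP solver failed numerically; the result cannot be trusted."""


class InfeasibleModelError(RuntimeError):
    """The constrained flux polytope is empty."""


# Hooks called with (S, lower, upper, x, context) after every optimal LP solve;
# used by the test suite to enforce steady-state/bounds invariants globally.
_solution_hooks: list[Callable] = []


def register_solution_hook(hook: Callable) -> None:
    _solution_hooks.append(hook)


def unregister_solution_hook(hook: Callable) -> None:
    _solution_hooks.remove(hook)


def _solve_lp(
    S: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    c: np.ndarray,
    context: str = "",
):
    """Minimize c.v subject to S.v = 0 and lower <= v <= upper.

    Returns (status, objective_value, x) with status in
    {"optimal", "infeasible", "unbounded"}.
    """
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lower, upper)),
        method="highs",
        options={"presolve": True, "primal_feasibility_tolerance": 1e-9},
    )
    if res.status == 0:
        x = np.asarray(res.x)
        residual = float(np.max(np.abs(S @ x))) if S.size else 0.0
        if residual > FEASIBILITY_TOL:
            raise SolverError(
                f"LP reported optimal but ||S.v||_inf = {residual:.2e} exceeds "
                f"{FEASIBILITY_TOL:.0e} ({context})"
            )
        for hook in _solution_hooks:
            hook(S, lower, upper, x, context)
        return "optimal", float(res.fun), x
    if res.status == 2:
        return "infeasible", np.nan, None
    if res.status == 3:
        return "unbounded", np.nan, None
    raise SolverError(f"LP solver failure (status {res.status}): {res.message} ({context})")


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObjectiveSpec:
    """A linear objective c over reactions, maximized or minimized."""

    coefficients: Mapping[str, float]
    sense: str = "maximize"

    def __post_init__(self) -> None:
        if self.sense not in ("maximize", "minimize"):
            raise ValueError(f"sense must be maximize/minimize, got {self.sense!r}")
        if not any(v != 0 for v in self.coefficients.values()):
            raise ValueError("objective needs at least one nonzero coefficient")
        object.__setattr__(self, "coefficients", dict(self.coefficients))


@dataclass(frozen=True)
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Optional[Mapping[str, float]] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve_fba(model: Model, objective: ObjectiveSpec) -> FluxSolution:
    """Flux Balance Analysis: optimize a linear objective over the flux polytope."""
    rxn_ids = model.reaction_ids
    unknown = set(objective.coefficients) - set(rxn_ids)
    if unknown:
        raise KeyError(f"objective references unknown reactions: {sorted(unknown)}")
    S = model.stoichiometric_matrix()
    lower, upper = model.bounds_arrays()
    c = np.zeros(len(rxn_ids))
    for rid, weight in objective.coefficients.items():
        c[rxn_ids.index(rid)] = weight
    sign = -1.0 if objective.sense == "maximize" else 1.0
    status, fun, x = _solve_lp(S, lower, upper, sign * c, context=f"FBA[{objective.sense}]")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=np.nan)
    return FluxSolution(
        status="optimal",
        objective_value=sign * fun,
        fluxes=dict(zip(rxn_ids, x)),
    )


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FvaInterval:
    minimum: float
    maximum: float
    min_status: str = "optimal"
    max_status: str = "optimal"


@dataclass(frozen=True)
class FvaResult:
    """Per-reaction flux extrema over a fixed constraint set."""

    intervals: Mapping[str, FvaInterval]

    def __getitem__(self, rxn_id: str) -> FvaInterval:
        return self.intervals[rxn_id]

    def __iter__(self):
        return iter(self.intervals)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction": list(self.intervals),
                "minimum": [iv.minimum for iv in self.intervals.values()],
                "maximum": [iv.maximum for iv in self.intervals.values()],
                "min_status": [iv.min_status for iv in self.intervals.values()],
                "max_status": [iv.max_status for iv in self.intervals.values()],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run_fva(
    model: Model,
    reactions: Optional[Sequence[str]] = None,
    extra_fixings: Optional[Mapping[str, tuple[float, float]]] = None,
) -> FvaResult:
    """Flux Variability Analysis: min and max flux of each requested reaction.

    A feasibility LP runs first so an empty polytope is diagnosed once, not per
    reaction. ``extra_fixings`` temporarily overrides bounds (e.g. to pin an
    optimized objective at its optimum).
    """
    rxn_ids = model.reaction_ids
    if reactions is None:
        reactions = rxn_ids
    unknown = set(reactions) - set(rxn_ids)
    if unknown:
        raise KeyError(f"FVA requested for unknown reactions: {sorted(unknown)}")
    S = model.stoichiometric_matrix()
    lower, upper = model.bounds_arrays()
    if extra_fixings:
        missing = set(extra_fixings) - set(rxn_ids)
        if missing:
            raise KeyError(f"extra_fixings for unknown reactions: {sorted(missing)}")
        for rid, (lb, ub) in extra_fixings.items():
            j = rxn_ids.index(rid)
            lower[j], upper[j] = lb, ub

    status, _, _ = _solve_lp(S, lower, upper, np.zeros(len(rxn_ids)), context="FVA feasibility pre-check")
    if status != "optimal":
        raise InfeasibleModelError(
            f"FVA feasibility pre-check failed: model is {status} under the given constraints"
        )

    intervals: dict[str, FvaInterval] = {}
    for rid in reactions:
        j = rxn_ids.index(rid)
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        min_status, vmin, _ = _solve_lp(S, lower, upper, c, context=f"FVA min[{rid}]")
        max_status, vmax, _ = _solve_lp(S, lower, upper, -c, context=f"FVA max[{rid}]")
        vmin = vmin if min_status == "optimal" else -np.inf
        vmax = -vmax if max_status == "optimal" else np.inf
        intervals[rid] = FvaInterval(
            minimum=vmin, maximum=vmax, min_status=min_status, max_status=max_status
        )
    return FvaResult(intervals=intervals)


# ---------------------------------------------------------------------------
# Spans, span ratios, classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpanTable:
    """Per-reaction flux span (FVA interval width) in one condition."""

    spans: Mapping[str, float]
    condition: str = ""

    def __getitem__(self, rxn_id: str) -> float:
        return self.spans[rxn_id]

    def __iter__(self):
        return iter(self.spans)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reaction": list(self.spans), "span": list(self.spans.values())}
        )

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.insert(0, "condition", self.condition)
        frame.to_csv(path, sep="\t", index=False)


def flux_span(fva: FvaResult, condition: str = "") -> SpanTable:
    """Flux Span per reaction: max - min, with tiny numerical negatives clipped to 0."""
    spans = {
        rid: max(iv.maximum - iv.minimum, 0.0) for rid, iv in fva.intervals.items()
    }
    return SpanTable(spans=spans, condition=condition)


@dataclass(frozen=True)
class SpanRatio:
    ratio: Optional[float]
    flag: str  # defined | undefined | both-zero


@dataclass(frozen=True)
class SpanRatioTable:
    """Reaction-wise ratio of flux spans, numerator condition over denominator."""

    entries: Mapping[str, SpanRatio]
    numerator_condition: str
    denominator_condition: str
    epsilon: float = EPS_SPAN

    def __getitem__(self, rxn_id: str) -> SpanRatio:
        return self.entries[rxn_id]

    def __iter__(self):
        return iter(self.entries)

    def defined(self) -> dict[str, float]:
        return {
            rid: e.ratio for rid, e in self.entries.items() if e.flag == "defined"
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction": list(self.entries),
                "ratio": [e.ratio for e in self.entries.values()],
                "flag": [e.flag for e in self.entries.values()],
            }
        )

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.insert(0, "numerator", self.numerator_condition)
        frame.insert(1, "denominator", self.denominator_condition)
        frame.to_csv(path, sep="\t", index=False)


def flux_span_ratio(
    span_a: SpanTable, span_b: SpanTable, epsilon: float = EPS_SPAN
) -> SpanRatioTable:
    """Flux Span Ratio: span_a / span_b per reaction.

    Entries with denominator span <= epsilon are flagged ``undefined`` (or
    ``both-zero`` when the numerator is also <= epsilon).
    """
    set_a, set_b = set(span_a.spans), set(span_b.spans)
    if set_a != set_b:
        raise ValueError(
            "span tables cover different reactions; symmetric difference: "
            f"{sorted(set_a ^ set_b)}"
        )
    entries: dict[str, SpanRatio] = {}
    for rid in span_a.spans:
        a, b = span_a.spans[rid], span_b.spans[rid]
        if b > epsilon:
            entries[rid] = SpanRatio(ratio=a / b, flag="defined")
        elif a > epsilon:
            entries[rid] = SpanRatio(ratio=None, flag="undefined")
        else:
            entries[rid] = SpanRatio(ratio=None, flag="both-zero")
    return SpanRatioTable(
        entries=entries,
        numerator_condition=span_a.condition,
        denominator_condition=span_b.condition,
        epsilon=epsilon,
    )


#: Reaction classes in a two-condition comparison.
CLASSES = ("increased", "decreased", "intermediate", "unchanged", "undefined")


@dataclass(frozen=True)
class ComparisonReport:
    """Classified span ratios between two conditions.

    ``increased``/``decreased`` mark strong changes of the ratio away from 1
    (by the ``delta_strong`` threshold), ``intermediate`` marks changes beyond
    ``delta_weak`` but short of strong, ``unchanged`` covers ratios within the
    weak band — including reactions whose span is numerically zero in both
    conditions — and ``undefined`` marks a zero-span denominator with a
    nonzero numerator.
    """

    ratios: SpanRatioTable
    classes: Mapping[str, str]
    delta_weak: float
    delta_strong: float

    @property
    def numerator_condition(self) -> str:
        return self.ratios.numerator_condition

    @property
    def denominator_condition(self) -> str:
        return self.ratios.denominator_condition

    def reactions_in_class(self, cls: str) -> list[str]:
        return [rid for rid, c in self.classes.items() if c == cls]

    def to_frame(self) -> pd.DataFrame:
        frame = self.ratios.to_frame()
        frame["class"] = [self.classes[rid] for rid in frame["reaction"]]
        return frame

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.insert(0, "numerator", self.numerator_condition)
        frame.insert(1, "denominator", self.denominator_condition)
        frame.insert(2, "delta_weak", self.delta_weak)
        frame.insert(3, "delta_strong", self.delta_strong)
        frame.to_csv(path, sep="\t", index=False)


def classify_reactions(
    ratios: SpanRatioTable, delta_strong: float = 0.5, delta_weak: float = 0.1
) -> ComparisonReport:
    """Classify each reaction by how far its span ratio departs from 1."""
    if not (0 < delta_weak < delta_strong):
        raise ValueError(
            f"need 0 < delta_weak < delta_strong, got {delta_weak}, {delta_strong}"
        )
    classes: dict[str, str] = {}
    for rid, entry in ratios.entries.items():
        if entry.flag == "both-zero":
            classes[rid] = "unchanged"  # equal (zero) spans: no change
        elif entry.flag == "undefined":
            classes[rid] = "undefined"
        else:
            r = entry.ratio
            if r >= 1 + delta_strong:
                classes[rid] = "increased"
            elif r <= 1 / (1 + delta_strong):
                classes[rid] = "decreased"
            elif 1 / (1 + delta_weak) <= r <= 1 + delta_weak:
                classes[rid] = "unchanged"
            else:
                classes[rid] = "intermediate"
    return ComparisonReport(
        ratios=ratios, classes=classes, delta_weak=delta_weak, delta_strong=delta_strong
    )
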