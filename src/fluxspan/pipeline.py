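"""End-to-end condition comparison: media, open bounds, pseudo-objectives, FVA.

The inference chain implemented here turns two qualitatively different
metabolite profiles into two condition-specific networks and compares them:

1. apply a "rich media" uptake constraint set to the model;
2. replace every reaction's bounds by its FVA interval under that media
   (the "open set" bounding box);
3. measure the secretion (exchange) maximum of each profile metabolite and use
   those maxima as coefficients of a single drain pseudo-reaction per
   condition — analogous to a non-growth-associated biomass objective;
4. optimize each condition for its own pseudo-objective, fix the drain flux at
   its optimum, rerun FVA, and compare the two conditions reaction-by-reaction
   via Flux Span Ratios.

A pseudo-objective whose metabolite maxima cannot be met simultaneously is
rescued by down-scaling its coefficients; the largest feasible scale can be
found automatically by bisection (:func:`max_feasible_scale`).
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping as AbcMapping
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Union

import numpy as np

from .flux import (
    EPS_SPAN,
    ComparisonReport,
    FvaResult,
    InfeasibleModelError,
    ObjectiveSpec,
    SpanTable,
    classify_reactions,
    flux_span,
    flux_span_ratio,
    run_fva,
    solve_fba,
)
from .model import DEFAULT_BOUND, Metabolite, Model, ModelError, Reaction

#: Default per-uptake magnitude for media presets (flux units).
DEFAULT_UPTAKE = 10.0

#: Span-noise floor used by the pipeline's ratio step. The optimize-then-fix
#: step leaves residual spans of order fixing_slack * coefficient (~1e-5) on
#: structurally pinned reactions; 1e-4 sits above that leakage and far below
#: any real span.
PIPELINE_EPS_SPAN = 1e-4

#: Metabolite base ids of the rich-media uptake set: the 20 proteinogenic
#: amino acids, glucose, palmitate and oxygen.
RICH_MEDIA_UPTAKES: tuple[str, ...] = (
    "ala__L", "arg__L", "asn__L", "asp__L", "cys__L", "gln__L", "glu__L",
    "gly", "his__L", "ile__L", "leu__L", "lys__L", "met__L", "phe__L",
    "pro__L", "ser__L", "thr__L", "trp__L", "tyr__L", "val__L",
    "glc__D", "hdca", "o2",
)

#: Metabolite base ids allowed unlimited two-way exchange: protons and water.
RICH_MEDIA_FREE: tuple[str, ...] = ("h", "h2o")


@dataclass(frozen=True)
class MediaSpec:
    """Uptake permissions: limited uptakes plus freely exchanged species."""

    allowed_uptakes: Mapping[str, float]
    free_exchange: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = [rid for rid, mag in self.allowed_uptakes.items() if mag <= 0]
        if bad:
            raise ValueError(f"non-positive uptake magnitudes for {sorted(bad)}")
        object.__setattr__(self, "allowed_uptakes", dict(self.allowed_uptakes))
        object.__setattr__(self, "free_exchange", frozenset(self.free_exchange))


def apply_media(model: Model, media: MediaSpec, default_max: float = DEFAULT_BOUND) -> Model:
    """Constrain exchange reactions to a media specification.

    Allowed uptakes get bounds [-magnitude, default_max]; free exchanges get
    [-default_max, default_max]; every other exchange has its lower bound set
    to 0 (uptake closed, secretion left open). Internal reactions are untouched.
    """
    exchange_ids = {r.id for r in model.exchanges}
    for rid in list(media.allowed_uptakes) + list(media.free_exchange):
        if rid not in set(model.reaction_ids):
            raise ModelError(f"media references unknown reaction {rid!r}")
        if rid not in exchange_ids:
            raise ModelError(f"media reaction {rid!r} is not an exchange reaction")
    new_reactions = []
    for rxn in model.reactions:
        if not rxn.is_exchange:
            new_reactions.append(rxn)
        elif rxn.id in media.free_exchange:
            new_reactions.append(rxn.with_bounds(-default_max, default_max))
        elif rxn.id in media.allowed_uptakes:
            new_reactions.append(
                rxn.with_bounds(-media.allowed_uptakes[rxn.id], default_max)
            )
        else:
            new_reactions.append(rxn.with_bounds(0.0, rxn.upper_bound))
    return Model(metabolites=model.metabolites, reactions=tuple(new_reactions), name=model.name)


def _metabolite_base_id(met_id: str, compartment: str) -> str:
    suffix = f"_{compartment}" if compartment else ""
    return met_id[: -len(suffix)] if suffix and met_id.endswith(suffix) else met_id


def rich_media_spec(model: Model, uptake_magnitude: float = DEFAULT_UPTAKE) -> MediaSpec:
    """Build the rich-media spec against a model's exchange reactions.

    Matches the rich-media species (20 amino acids, glucose, palmitate,
    oxygen; protons and water free) to the model's exchange reactions by the
    exchanged metabolite's id with any compartment suffix stripped.
    """
    allowed: dict[str, float] = {}
    free: set[str] = set()
    for rxn in model.exchanges:
        (met_id,) = rxn.stoichiometry
        met = model.metabolite(met_id)
        base = _metabolite_base_id(met.id, met.compartment)
        if base in RICH_MEDIA_UPTAKES:
            allowed[rxn.id] = uptake_magnitude
        elif base in RICH_MEDIA_FREE:
            free.add(rxn.id)
    missing = set(RICH_MEDIA_UPTAKES) - {
        _metabolite_base_id(
            model.metabolite(next(iter(model.reaction(r).stoichiometry))).id,
            model.metabolite(next(iter(model.reaction(r).stoichiometry))).compartment,
        )
        for r in allowed
    }
    if missing:
        warnings.warn(f"rich media species without exchange reactions: {sorted(missing)}")
    return MediaSpec(allowed_uptakes=allowed, free_exchange=frozenset(free))


def open_bounds_from_fva(
    model: Model, reactions: Optional[Iterable[str]] = None
) -> Model:
    """Replace each reaction's bounds by its FVA interval under current constraints.

    This is the "open set": the bounding box of the feasible flux polytope.
    Reactions with zero span become fixed at their (unique) feasible flux —
    unreachable reactions are effectively knocked out.
    """
    which = list(reactions) if reactions is not None else model.reaction_ids
    fva = run_fva(model, reactions=which)
    new_reactions = []
    for rxn in model.reactions:
        if rxn.id in fva.intervals:
            iv = fva.intervals[rxn.id]
            lb = min(iv.minimum, iv.maximum)  # guard tiny numerical inversions
            new_reactions.append(rxn.with_bounds(lb, iv.maximum))
        else:
            new_reactions.append(rxn)
    return Model(metabolites=model.metabolites, reactions=tuple(new_reactions), name=model.name)


# ---------------------------------------------------------------------------
# Exchange maxima -> pseudo-objective coefficients
# ---------------------------------------------------------------------------


class ExchangeMaxima(AbcMapping):
    """Secretion maxima per metabolite, usable directly as a coefficient map.

    ``added_drains`` lists metabolites that had no exchange reaction and were
    measured through a temporary drain; ``blocked`` lists metabolites whose
    secretion maximum was numerically zero (reported with weight 0).
    """

    def __init__(
        self,
        weights: Mapping[str, float],
        reactions: Mapping[str, str],
        added_drains: frozenset[str] = frozenset(),
        blocked: frozenset[str] = frozenset(),
    ) -> None:
        self.weights = dict(weights)
        self.reactions = dict(reactions)
        self.added_drains = frozenset(added_drains)
        self.blocked = frozenset(blocked)

    def __getitem__(self, key: str) -> float:
        return self.weights[key]

    def __iter__(self):
        return iter(self.weights)

    def __len__(self) -> int:
        return len(self.weights)

    def __repr__(self) -> str:
        return f"ExchangeMaxima({self.weights!r})"

    def positive(self) -> dict[str, float]:
        """The strictly positive weights (what a pseudo-objective can use)."""
        return {k: v for k, v in self.weights.items() if v > 0}


def _resolve_metabolites(model: Model, names: Iterable[str]) -> dict[str, str]:
    """Map requested names to metabolite ids, matching id first then display name."""
    by_id = {m.id: m.id for m in model.metabolites}
    by_name: dict[str, str] = {}
    for met in model.metabolites:
        if met.name:
            by_name.setdefault(met.name, met.id)
    resolved: dict[str, str] = {}
    unmatched = []
    for name in names:
        if name in by_id:
            resolved[name] = name
        elif name in by_name:
            resolved[name] = by_name[name]
        else:
            unmatched.append(name)
    if unmatched:
        raise KeyError(f"metabolites not in model: {sorted(unmatched)}")
    return resolved


def exchange_maxima(
    model: Model,
    metabolite_names: Iterable[str],
    epsilon: float = EPS_SPAN,
    default_max: float = DEFAULT_BOUND,
) -> ExchangeMaxima:
    """Secretion (exchange) maximum of each named metabolite under current bounds.

    For each metabolite the FVA maximum of its exchange reaction in the
    secretion direction is measured; a temporary drain is installed when the
    metabolite has no exchange reaction. Metabolites whose maximum is <= epsilon
    get weight 0 with a warning.
    """
    resolved = _resolve_metabolites(model, metabolite_names)
    work = model
    rxn_for: dict[str, str] = {}
    coef_for: dict[str, float] = {}
    added: set[str] = set()
    for met_id in sorted(set(resolved.values())):
        exchange = None
        for rxn in work.exchanges:
            if met_id in rxn.stoichiometry:
                exchange = rxn
                break
        if exchange is None:
            drain = Reaction(
                id=f"DM_{met_id}", stoichiometry={met_id: -1.0},
                lower_bound=0.0, upper_bound=default_max,
            )
            work = work.with_reaction(drain)
            exchange = drain
            added.add(met_id)
        rxn_for[met_id] = exchange.id
        coef_for[met_id] = exchange.stoichiometry[met_id]

    fva = run_fva(work, reactions=sorted(set(rxn_for.values())))
    weights: dict[str, float] = {}
    blocked: set[str] = set()
    for name, met_id in resolved.items():
        iv = fva.intervals[rxn_for[met_id]]
        # Secretion removes the metabolite: rate = -coef * v, so the secretion
        # maximum is max(-coef * v) over the interval.
        coef = coef_for[met_id]
        secretion_max = max(-coef * iv.minimum, -coef * iv.maximum)
        if secretion_max <= epsilon:
            warnings.warn(f"secretion of {name!r} is blocked; weight set to 0")
            weights[met_id] = 0.0
            blocked.add(met_id)
        else:
            weights[met_id] = float(secretion_max)
    return ExchangeMaxima(
        weights=weights,
        reactions=rxn_for,
        added_drains=frozenset(added),
        blocked=frozenset(blocked),
    )


# ---------------------------------------------------------------------------
# Pseudo-objective construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PseudoObjective:
    """A condition's drain pseudo-reaction descriptor.

    The installed reaction consumes ``scale * weight`` units of each listed
    metabolite per unit of drain flux and produces nothing; maximizing it
    represents the condition's net metabolite demand.
    """

    coefficients: Mapping[str, float]
    scale: float
    reaction_id: str
    group_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", dict(self.coefficients))


def build_pseudo_objective(
    model: Model,
    coefficients: Mapping[str, float],
    scale: float,
    label: str,
    default_max: float = DEFAULT_BOUND,
) -> tuple[Model, PseudoObjective]:
    """Install a drain pseudo-reaction sum(scale * w_i * met_i) -> nothing."""
    coefficients = dict(coefficients)
    if not coefficients:
        raise ValueError("pseudo-objective needs at least one coefficient")
    bad = {k: v for k, v in coefficients.items() if v <= 0}
    if bad:
        raise ValueError(f"non-positive pseudo-objective coefficients: {bad}")
    if not 0 < scale <= 1:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    rxn_id = f"pseudo_{label}"
    if rxn_id in set(model.reaction_ids):
        raise ModelError(f"pseudo-objective label {label!r} already installed")
    drain = Reaction(
        id=rxn_id,
        stoichiometry={met: -scale * w for met, w in coefficients.items()},
        lower_bound=0.0,
        upper_bound=default_max,
        name=f"pseudo-objective drain ({label})",
    )
    return model.with_reaction(drain), PseudoObjective(
        coefficients=coefficients, scale=scale, reaction_id=rxn_id, group_label=label
    )


def max_feasible_scale(
    model: Model,
    coefficients: Mapping[str, float],
    demand_floor: float,
    tolerance: float = 1e-7,
    default_max: float = DEFAULT_BOUND,
) -> float:
    """Largest scale s in (0, 1] at which the s-scaled drain can carry demand_floor.

    Found by bisection to ``tolerance``. Returns 0.0 if even vanishing scales
    are infeasible (no supply at all). The model must be feasible on its own.
    """
    if demand_floor <= 0:
        raise ValueError("demand_floor must be positive")
    # own-model feasibility pre-check (raises InfeasibleModelError)
    run_fva(model, reactions=[])

    def feasible(s: float) -> bool:
        work, pseudo = build_pseudo_objective(
            model, coefficients, s, label="scale_probe", default_max=default_max
        )
        work = work.with_reaction_bounds(pseudo.reaction_id, demand_floor, default_max)
        try:
            run_fva(work, reactions=[])
        except InfeasibleModelError:
            return False
        return True

    if feasible(1.0):
        return 1.0
    lo, hi = 0.0, 1.0
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo


# ---------------------------------------------------------------------------
# Full two-condition comparison
# ---------------------------------------------------------------------------

#: Scale policy: a fixed value in (0, 1], or "auto" for bisection.
ScalePolicy = Union[float, str]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the two-condition comparison.

    The patient-side ("high"/ketone-like) pseudo-objective defaults to scale
    0.5 and the control-side ("low"/amino-acid-like) one to 1.0 — the one-half
    scaling is the feasibility fix for demands that cannot be met simultaneously
    at full magnitude. ``fva_fixing_fraction`` multiplies the optimum before the
    drain flux is pinned (1.0 = fix at the optimum, softened by an absolute
    ``fixing_slack`` so the equality is numerically feasible).
    """

    media: Optional[MediaSpec] = None
    scale_high: ScalePolicy = 0.5
    scale_low: ScalePolicy = 1.0
    fva_fixing_fraction: float = 1.0
    fixing_slack: float = 1e-6
    epsilon: float = PIPELINE_EPS_SPAN
    delta_weak: float = 0.1
    delta_strong: float = 0.5
    demand_floor: float = 1.0
    default_max: float = DEFAULT_BOUND
    label_high: str = "patient"
    label_low: str = "non_patient"

    def __post_init__(self) -> None:
        if not 0 < self.fva_fixing_fraction <= 1:
            raise ValueError("fva_fixing_fraction must be in (0, 1]")
        for name in ("fixing_slack", "epsilon", "demand_floor", "default_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("scale_high", "scale_low"):
            policy = getattr(self, name)
            if isinstance(policy, str):
                if policy != "auto":
                    raise ValueError(f"{name} must be a float in (0,1] or 'auto'")
            elif not 0 < policy <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class ConditionComparison:
    """Everything compare_conditions computed, with provenance.

    ``report`` classifies each shared reaction by its Flux Span Ratio with the
    non-patient condition in the numerator and the patient condition in the
    denominator (a "decreased" ratio therefore means a larger span in the
    patient condition).
    """

    report: ComparisonReport
    fva: Mapping[str, FvaResult]
    spans: Mapping[str, SpanTable]
    pseudo_objectives: Mapping[str, PseudoObjective]
    optima: Mapping[str, float]
    scales: Mapping[str, float]
    config: PipelineConfig

    @property
    def classes(self) -> Mapping[str, str]:
        return self.report.classes

    @property
    def ratios(self):
        return self.report.ratios


def _condition_fva(
    base: Model,
    coefficients: Mapping[str, float],
    scale_policy: ScalePolicy,
    label: str,
    config: PipelineConfig,
) -> tuple[FvaResult, PseudoObjective, float, float]:
    coeffs = dict(coefficients)
    if not coeffs:
        raise ValueError(f"condition {label!r}: empty coefficient map")
    if scale_policy == "auto":
        scale = max_feasible_scale(
            base, coeffs, demand_floor=config.demand_floor, default_max=config.default_max
        )
        if scale <= 0:
            raise InfeasibleModelError(
                f"condition {label!r}: no positive scale is feasible"
            )
    else:
        scale = float(scale_policy)
    work, pseudo = build_pseudo_objective(
        base, coeffs, scale, label=label, default_max=config.default_max
    )
    solution = solve_fba(work, ObjectiveSpec({pseudo.reaction_id: 1.0}, "maximize"))
    if not solution.optimal:
        raise InfeasibleModelError(
            f"condition {label!r}: pseudo-objective optimization is {solution.status}"
        )
    optimum = solution.objective_value
    target = config.fva_fixing_fraction * optimum
    fixing = (max(target - config.fixing_slack, 0.0), target + config.fixing_slack)
    try:
        fva = run_fva(work, reactions=base.reaction_ids, extra_fixings={pseudo.reaction_id: fixing})
    except InfeasibleModelError as exc:
        raise InfeasibleModelError(
            f"condition {label!r} infeasible with drain fixed at {target:g} "
            f"(+/- {config.fixing_slack:g}): {exc}"
        ) from exc
    return fva, pseudo, optimum, scale


def compare_conditions(
    model: Model,
    group_high_coeffs: Mapping[str, float],
    group_low_coeffs: Mapping[str, float],
    config: Optional[PipelineConfig] = None,
) -> ConditionComparison:
    """Compare a patient-side and a control-side condition on one base model.

    Both condition models are built from the same open-set base (media applied,
    bounds replaced by the rich-media FVA box); each gets its own drain
    pseudo-reaction, is optimized for it, has the drain flux fixed at the
    optimum, and is then fully characterized by FVA. Flux Span Ratios are
    reported with the non-patient condition in the numerator.
    """
    config = config or PipelineConfig()
    if config.media is not None:
        model = apply_media(model, config.media, default_max=config.default_max)
    base = open_bounds_from_fva(model)

    fva_high, pseudo_high, opt_high, scale_high = _condition_fva(
        base, group_high_coeffs, config.scale_high, config.label_high, config
    )
    fva_low, pseudo_low, opt_low, scale_low = _condition_fva(
        base, group_low_coeffs, config.scale_low, config.label_low, config
    )

    span_high = flux_span(fva_high, condition=config.label_high)
    span_low = flux_span(fva_low, condition=config.label_low)
    ratios = flux_span_ratio(span_low, span_high, epsilon=config.epsilon)
    report = classify_reactions(
        ratios, delta_strong=config.delta_strong, delta_weak=config.delta_weak
    )
    return ConditionComparison(
        report=report,
        fva={config.label_high: fva_high, config.label_low: fva_low},
        spans={config.label_high: span_high, config.label_low: span_low},
        pseudo_objectives={
            config.label_high: pseudo_high,
            config.label_low: pseudo_low,
        },
        optima={config.label_high: opt_high, config.label_low: opt_low},
        scales={config.label_high: scale_high, config.label_low: scale_low},
        config=config,
    )
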