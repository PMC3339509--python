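"""Stoichiometric model containers, plain-text and SBML I/O, and balance checking.

A model is an ordered collection of metabolites (rows of the stoichiometric
matrix ``S``) and reactions (columns of ``S``). Each reaction carries its own
flux bounds, the ``alpha``/``beta`` entries of the constraint-based problem

    S . v = 0,   alpha <= v <= beta.

Exchange reactions are boundary reactions with a single metabolite
participant; by convention a coefficient of -1 means negative flux is uptake
into the system and positive flux is secretion.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

#: Conventional "effectively unbounded" flux magnitude.
DEFAULT_BOUND = 1000.0


class FormatError(ValueError):
    """A file or value does not conform to the expected format."""


class ModelError(ValueError):
    """A model-level consistency violation (duplicate ids, bad references...)."""


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``C6H12O6`` into element counts.

    Raises :class:`FormatError` if the string is not a sequence of
    element-count pairs.
    """
    if not formula or not isinstance(formula, str):
        raise FormatError(f"empty or non-string formula: {formula!r}")
    counts: Counter[str] = Counter()
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise FormatError(f"unparseable formula {formula!r} at position {pos}")
        element, digits = match.groups()
        counts[element] += int(digits) if digits else 1
        pos = match.end()
    if pos != len(formula):
        raise FormatError(f"unparseable formula {formula!r} at position {pos}")
    return dict(counts)


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment."""

    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")

    @property
    def elements(self) -> Optional[dict[str, int]]:
        """Element counts, or None when the formula is absent or unparseable.

        Unparseable formulas (polymers, R-groups) are tolerated here; the
        balance checker reports reactions involving them as "unknown".
        """
        if self.formula is None:
            return None
        try:
            return parse_formula(self.formula)
        except FormatError:
            return None


@dataclass(frozen=True)
class Reaction:
    """A reaction column of S: signed stoichiometry plus flux bounds.

    Negative coefficients are consumed, positive are produced. A reaction with
    exactly one metabolite participant is an exchange (boundary) reaction.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        if any(coef == 0 for coef in self.stoichiometry.values()):
            raise ModelError(f"reaction {self.id!r} stores a zero coefficient")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass(frozen=True)
class Model:
    """An ordered stoichiometric model with ``m`` metabolites and ``n`` reactions."""

    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        for label, ids in (("metabolite", met_ids), ("reaction", rxn_ids)):
            dupes = [i for i, c in Counter(ids).items() if c > 1]
            if dupes:
                raise ModelError(f"duplicate {label} ids: {sorted(dupes)}")
        known = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {rxn.id!r} references unknown metabolites {sorted(missing)}"
                )

    # -- lookups ---------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for met in self.metabolites:
            if met.id == met_id:
                return met
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(rxn_id)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- numerics --------------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense m x n stoichiometric matrix in model order."""
        index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                S[index[met_id], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """The (alpha, beta) bound vectors in reaction order."""
        lower = np.array([r.lower_bound for r in self.reactions])
        upper = np.array([r.upper_bound for r in self.reactions])
        return lower, upper

    # -- value-semantics edits -------------------------------------------

    def with_reaction(
        self, reaction: Reaction, new_metabolites: Iterable[Metabolite] = ()
    ) -> "Model":
        """Return a new model with ``reaction`` appended; ``self`` is unmodified."""
        new_mets = tuple(new_metabolites)
        if reaction.id in set(self.reaction_ids):
            raise ModelError(f"reaction id {reaction.id!r} already present")
        known = set(self.metabolite_ids) | {m.id for m in new_mets}
        missing = set(reaction.stoichiometry) - known
        if missing:
            raise ModelError(
                f"reaction {reaction.id!r} references unknown metabolites "
                f"{sorted(missing)}; pass them via new_metabolites"
            )
        return Model(
            metabolites=self.metabolites + new_mets,
            reactions=self.reactions + (reaction,),
            name=self.name,
        )

    def without_reaction(self, rxn_id: str) -> "Model":
        if rxn_id not in set(self.reaction_ids):
            raise KeyError(rxn_id)
        return Model(
            metabolites=self.metabolites,
            reactions=tuple(r for r in self.reactions if r.id != rxn_id),
            name=self.name,
        )

    def with_reaction_bounds(self, rxn_id: str, lower: float, upper: float) -> "Model":
        if rxn_id not in set(self.reaction_ids):
            raise KeyError(rxn_id)
        return Model(
            metabolites=self.metabolites,
            reactions=tuple(
                r.with_bounds(lower, upper) if r.id == rxn_id else r
                for r in self.reactions
            ),
            name=self.name,
        )


def add_reaction(
    model: Model, reaction: Reaction, new_metabolites: Iterable[Metabolite] = ()
) -> Model:
    """Functional form of :meth:`Model.with_reaction`."""
    return model.with_reaction(reaction, new_metabolites)


# ---------------------------------------------------------------------------
# Plain-text matrix I/O
# ---------------------------------------------------------------------------


def read_matrix_tsv(matrix_path, bounds_path=None) -> Model:
    """Read a model from a tab-delimited stoichiometric matrix.

    The matrix file has metabolite ids in the first column and reaction ids in
    the header row; cells are signed stoichiometric coefficients with zeros
    meaning "does not participate". An optional bounds file has columns
    ``reaction``, ``lower``, ``upper``; reactions absent from it default to
    ``[-1000, 1000]``.
    """
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        raise FormatError(f"duplicate metabolite ids in {matrix_path}")
    if frame.columns.has_duplicates:
        raise FormatError(f"duplicate reaction ids in {matrix_path}")
    try:
        values = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in {matrix_path}: {exc}") from exc
    if values.isna().any().any():
        raise FormatError(f"missing/non-numeric cell in {matrix_path}")

    bounds: dict[str, tuple[float, float]] = {}
    if bounds_path is not None:
        btab = pd.read_csv(bounds_path, sep="\t")
        expected = {"reaction", "lower", "upper"}
        if not expected.issubset(btab.columns):
            raise FormatError(
                f"bounds file {bounds_path} must have columns {sorted(expected)}"
            )
        unknown = set(btab["reaction"].astype(str)) - set(map(str, values.columns))
        if unknown:
            raise FormatError(f"bounds for unknown reactions: {sorted(unknown)}")
        for _, row in btab.iterrows():
            bounds[str(row["reaction"])] = (float(row["lower"]), float(row["upper"]))

    metabolites = tuple(Metabolite(id=str(m)) for m in values.index)
    reactions = []
    for rxn_id in values.columns:
        col = values[rxn_id]
        stoich = {str(m): float(c) for m, c in col.items() if c != 0}
        if not stoich:
            raise FormatError(f"reaction {rxn_id!r} has an all-zero column")
        lb, ub = bounds.get(str(rxn_id), (-DEFAULT_BOUND, DEFAULT_BOUND))
        reactions.append(
            Reaction(id=str(rxn_id), stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
        )
    return Model(metabolites=metabolites, reactions=tuple(reactions))


def write_matrix_tsv(model: Model, matrix_path, bounds_path=None) -> None:
    """Write the dense stoichiometric matrix (and optionally bounds) as TSV."""
    frame = pd.DataFrame(
        model.stoichiometric_matrix(),
        index=model.metabolite_ids,
        columns=model.reaction_ids,
    )
    frame.to_csv(matrix_path, sep="\t")
    if bounds_path is not None:
        btab = pd.DataFrame(
            {
                "reaction": model.reaction_ids,
                "lower": [r.lower_bound for r in model.reactions],
                "upper": [r.upper_bound for r in model.reactions],
            }
        )
        btab.to_csv(bounds_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SBML I/O (via python-libsbml)
# ---------------------------------------------------------------------------


def read_sbml(path) -> Model:
    """Read an SBML file (Level 2, or Level 3 with the fbc package).

    Bounds are taken from fbc flux-bound parameters when present, else from
    Level-2 kinetic-law parameters named LOWER_BOUND/UPPER_BOUND, else derived
    from reversibility: reversible -> [-1000, 1000], irreversible -> [0, 1000].
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise FormatError(f"malformed SBML in {path}: {'; '.join(msgs[:3])}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"no model element in {path}")

    metabolites = []
    for species in sbml_model.getListOfSpecies():
        formula = None
        charge = None
        splug = species.getPlugin("fbc")
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula() or None
            if splug.isSetCharge():
                charge = int(splug.getCharge())
        if charge is None and species.isSetCharge():
            charge = int(species.getCharge())
        metabolites.append(
            Metabolite(
                id=species.getId(),
                name=species.getName() or "",
                compartment=species.getCompartment() or "",
                formula=formula,
                charge=charge,
            )
        )
    known = {m.id for m in metabolites}

    def _fbc_bound(rplug, getter, default):
        if rplug is None:
            return None
        pid = getter()
        if not pid:
            return None
        param = sbml_model.getParameter(pid)
        return param.getValue() if param is not None else default

    reactions = []
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            if ref.getSpecies() not in known:
                raise FormatError(
                    f"reaction {rxn.getId()!r} references undeclared species "
                    f"{ref.getSpecies()!r}"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            if ref.getSpecies() not in known:
                raise FormatError(
                    f"reaction {rxn.getId()!r} references undeclared species "
                    f"{ref.getSpecies()!r}"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}

        rplug = rxn.getPlugin("fbc")
        lb = _fbc_bound(rplug, rplug.getLowerFluxBound if rplug else None, -DEFAULT_BOUND)
        ub = _fbc_bound(rplug, rplug.getUpperFluxBound if rplug else None, DEFAULT_BOUND)
        if lb is None or ub is None:
            klaw = rxn.getKineticLaw()
            if klaw is not None:
                plb = klaw.getParameter("LOWER_BOUND")
                pub = klaw.getParameter("UPPER_BOUND")
                lb = plb.getValue() if (lb is None and plb is not None) else lb
                ub = pub.getValue() if (ub is None and pub is not None) else ub
        if lb is None:
            lb = -DEFAULT_BOUND if rxn.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        reactions.append(
            Reaction(
                id=rxn.getId(),
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                name=rxn.getName() or "",
            )
        )
    return Model(
        metabolites=tuple(metabolites),
        reactions=tuple(reactions),
        name=sbml_model.getId() or sbml_model.getName() or "",
    )


def write_sbml(model: Model, path) -> None:
    """Write a minimal SBML Level 3 + fbc document (ids, stoichiometry, bounds)."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.name or "model")
    sm.getPlugin("fbc").setStrict(False)

    compartments = {m.compartment or "c" for m in model.metabolites}
    for comp_id in sorted(compartments):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment or "c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(met.charge)

    bound_params: dict[float, str] = {}

    def _param_for(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sm.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId(rxn.id)
        sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(_param_for(rxn.lower_bound))
        rplug.setUpperFluxBound(_param_for(rxn.upper_bound))

    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Mass and charge balance checking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionBalance:
    """Per-reaction balance verdict.

    ``status`` is one of ``balanced``, ``unbalanced``, ``unknown`` (a
    participant lacks a parseable formula) or ``exempt`` (boundary reaction).
    """

    reaction_id: str
    status: str
    element_imbalance: Mapping[str, float] = field(default_factory=dict)
    charge_imbalance: Optional[float] = None

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


@dataclass(frozen=True)
class BalanceReport:
    entries: tuple[ReactionBalance, ...]

    def __getitem__(self, rxn_id: str) -> ReactionBalance:
        for entry in self.entries:
            if entry.reaction_id == rxn_id:
                return entry
        raise KeyError(rxn_id)

    def summary(self) -> dict[str, int]:
        counts = Counter(entry.status for entry in self.entries)
        return {
            status: counts.get(status, 0)
            for status in ("balanced", "unbalanced", "unknown", "exempt")
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for entry in self.entries:
            imbalance = ";".join(
                f"{el}:{cnt:g}" for el, cnt in sorted(entry.element_imbalance.items())
            )
            rows.append(
                {
                    "reaction": entry.reaction_id,
                    "status": entry.status,
                    "element_imbalance": imbalance,
                    "charge_imbalance": entry.charge_imbalance,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def check_mass_charge_balance(model: Model, atol: float = 1e-9) -> BalanceReport:
    """Check elemental and charge balance of every non-boundary reaction.

    Exchange (single-participant) reactions are intentionally unbalanced
    boundary reactions and are reported ``exempt``. Reactions involving a
    metabolite without a parseable formula are reported ``unknown``. Missing
    charges are treated as zero.
    """
    entries = []
    for rxn in model.reactions:
        if rxn.is_exchange:
            entries.append(ReactionBalance(rxn.id, "exempt"))
            continue
        mets = {mid: model.metabolite(mid) for mid in rxn.stoichiometry}
        unknown = False
        for met in mets.values():
            if met.formula is None:
                unknown = True
            else:
                try:
                    parse_formula(met.formula)
                except FormatError:
                    warnings.warn(
                        f"metabolite {met.id!r} has unparseable formula "
                        f"{met.formula!r}; reaction {rxn.id!r} marked unknown"
                    )
                    unknown = True
        if unknown:
            entries.append(ReactionBalance(rxn.id, "unknown"))
            continue
        net: Counter[str] = Counter()
        charge = 0.0
        for mid, coef in rxn.stoichiometry.items():
            met = mets[mid]
            for element, count in parse_formula(met.formula).items():
                net[element] += coef * count
            charge += coef * (met.charge or 0)
        imbalance = {el: c for el, c in net.items() if abs(c) > atol}
        charge_ok = abs(charge) <= atol
        status = "balanced" if not imbalance and charge_ok else "unbalanced"
        entries.append(
            ReactionBalance(rxn.id, status, imbalance, charge if not charge_ok else 0.0)
        )
    return BalanceReport(entries=tuple(entries))
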