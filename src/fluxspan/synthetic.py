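"""Synthetic fixtures: toy networks, metabolomic studies, and condition pairs.

Everything here is generated, seed-reproducible data with hand-solvable ground
truth: toy flux networks whose FVA intervals follow from inspection, a plasma
metabolomics study generator that emulates the structure of a small fasting
cohort (replicated controls, one patient sampled twice before treatment and
once after, one non-fasting draw), and a small condition-pair network with a
provably differential branch for end-to-end pipeline checks.

The baseline concentration table below is synthetic: metabolite names follow
the standard 30-metabolite plasma NMR panel, but the magnitudes are round
plausible values chosen for realism, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import DEFAULT_BOUND, Metabolite, Model, Reaction
from .panels import (
    AMINO_ACID_GROUP,
    DECREASED_IN_PATIENT,
    INCREASED_IN_PATIENT,
    KETONE_GROUP,
    PLASMA_METABOLITES,
)
from .pipeline import RICH_MEDIA_FREE, RICH_MEDIA_UPTAKES, exchange_maxima, open_bounds_from_fva
from .profiles import ProfileTable

#: SYNTHETIC baseline plasma concentrations (mM) and coefficients of variation.
#: Plausible round magnitudes for a fasting adult panel; not measured values.
SYNTHETIC_BASELINES: dict[str, float] = {
    "3-Hydroxybutyrate": 0.35,
    "Acetate": 0.06,
    "Acetone": 0.03,
    "Alanine": 0.35,
    "Arginine": 0.08,
    "Asparagine": 0.05,
    "Citrate": 0.11,
    "Creatinine": 0.07,
    "Formate": 0.03,
    "Glucose": 5.0,
    "Glutamate": 0.06,
    "Glutamine": 0.55,
    "Glycerol": 0.08,
    "Glycine": 0.25,
    "Glycolate": 0.02,
    "Isoleucine": 0.06,
    "Lactate": 1.2,
    "Leucine": 0.12,
    "Lysine": 0.17,
    "Methanol": 0.04,
    "Methionine": 0.03,
    "Phenylalanine": 0.06,
    "Pyruvate": 0.07,
    "Serine": 0.11,
    "Succinate": 0.02,
    "Taurine": 0.06,
    "Threonine": 0.13,
    "Tyrosine": 0.06,
    "Valine": 0.22,
    "sn-Glycero-3-phosphocholine": 0.02,
}

#: SYNTHETIC per-metabolite coefficients of variation (draw-to-draw, fasting).
#: Ketone bodies vary strongly with fasting depth; glucose is tightly regulated.
SYNTHETIC_CVS: dict[str, float] = {
    name: 0.15 for name in PLASMA_METABOLITES
}
SYNTHETIC_CVS.update(
    {
        "3-Hydroxybutyrate": 0.50,
        "Acetone": 0.40,
        "Acetate": 0.30,
        "Formate": 0.25,
        "Glucose": 0.05,
        "Lactate": 0.15,
        "Glycerol": 0.25,
        "Pyruvate": 0.25,
        "Glutamine": 0.12,
        "Creatinine": 0.10,
        "Valine": 0.12,
    }
)

#: Metabolites that move with fasting depth in the same direction as ketosis;
#: the non-fasting draw flips every panel metabolite against its fasting trend,
#: i.e. these go down after feeding and everything else goes up.
KETONE_LIKE: tuple[str, ...] = ("3-Hydroxybutyrate", "Acetate", "Acetone")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted by a generator, sufficient to score recovery."""

    high_set: frozenset[str] = frozenset()
    low_set: frozenset[str] = frozenset()
    effect_size: float = 0.0
    differential_reactions: Mapping[str, str] = field(default_factory=dict)
    parameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "differential_reactions", dict(self.differential_reactions))
        object.__setattr__(self, "parameters", dict(self.parameters))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"kind": "high_set", "key": m, "value": ""} for m in sorted(self.high_set)]
        rows += [{"kind": "low_set", "key": m, "value": ""} for m in sorted(self.low_set)]
        rows += [
            {"kind": "differential_reaction", "key": rid, "value": cls}
            for rid, cls in self.differential_reactions.items()
        ]
        rows += [
            {"kind": "parameter", "key": k, "value": repr(v)}
            for k, v in self.parameters.items()
        ]
        return pd.DataFrame(rows, columns=["kind", "key", "value"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Toy networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Recipe for a small feasible test network.

    ``chain`` is inlet -> A -> B -> drain; ``branch`` splits A into two drained
    products; ``diamond`` reconverges two parallel paths; ``random`` is a seeded
    sparse network built around a guaranteed inlet-to-drain chain.
    """

    kind: str = "chain"
    inlet_capacity: float = 10.0
    n_metabolites: int = 4
    n_reactions: int = 8
    max_coefficient: int = 3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("chain", "branch", "diamond", "random"):
            raise ValueError(f"unknown toy network kind {self.kind!r}")
        if self.inlet_capacity <= 0:
            raise ValueError("inlet_capacity must be positive")


def _mets(*ids: str) -> tuple[Metabolite, ...]:
    return tuple(Metabolite(id=i, name=i) for i in ids)


def make_toy_network(spec: ToyNetworkSpec = ToyNetworkSpec()) -> Model:
    """Build a toy model per the spec; deterministic given (spec, seed)."""
    cap = spec.inlet_capacity
    if spec.kind == "chain":
        return Model(
            metabolites=_mets("A", "B"),
            reactions=(
                Reaction("SRC_A", {"A": 1.0}, 0.0, cap),
                Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0.0, DEFAULT_BOUND),
                Reaction("SNK_B", {"B": -1.0}, 0.0, DEFAULT_BOUND),
            ),
            name="chain",
        )
    if spec.kind == "branch":
        return Model(
            metabolites=_mets("A", "B", "C"),
            reactions=(
                Reaction("SRC_A", {"A": 1.0}, 0.0, cap),
                Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0.0, DEFAULT_BOUND),
                Reaction("R_AC", {"A": -1.0, "C": 1.0}, 0.0, DEFAULT_BOUND),
                Reaction("SNK_B", {"B": -1.0}, 0.0, DEFAULT_BOUND),
                Reaction("SNK_C", {"C": -1.0}, 0.0, DEFAULT_BOUND),
            ),
            name="branch",
        )
    if spec.kind == "diamond":
        return Model(
            metabolites=_mets("A", "B", "C", "D"),
            reactions=(
                Reaction("SRC_A", {"A": 1.0}, 0.0, cap),
                Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0.0, DEFAULT_BOUND),
                Reaction("R_AC", {"A": -1.0, "C": 1.0}, 0.0, DEFAULT_BOUND),
                Reaction("R_BD", {"B": -1.0, "D": 1.0}, 0.0, DEFAULT_BOUND),
                Reaction("R_CD", {"C": -1.0, "D": 1.0}, 0.0, DEFAULT_BOUND),
                Reaction("SNK_D", {"D": -1.0}, 0.0, DEFAULT_BOUND),
            ),
            name="diamond",
        )

    # random: a guaranteed inlet->...->drain chain plus seeded extra reactions
    if spec.seed is None:
        raise ValueError("random toy networks require a seed")
    from .flux import InfeasibleModelError, run_fva  # local import avoids cycle

    rng = np.random.default_rng(spec.seed)
    m = int(rng.integers(2, max(3, spec.n_metabolites) + 1))
    met_ids = [f"M{i}" for i in range(m)]
    for attempt in range(50):
        reactions = [Reaction("SRC", {met_ids[0]: 1.0}, 0.0, cap)]
        for i in range(m - 1):
            lb = 0.0 if rng.random() < 0.5 else -cap
            reactions.append(
                Reaction(f"CH{i}", {met_ids[i]: -1.0, met_ids[i + 1]: 1.0}, lb, cap)
            )
        reactions.append(Reaction("SNK", {met_ids[-1]: -1.0}, 0.0, cap))
        n_extra = max(0, min(spec.n_reactions, 8) - len(reactions))
        for k in range(n_extra):
            stoich: dict[str, float] = {}
            for met in rng.choice(met_ids, size=min(m, int(rng.integers(1, 4))), replace=False):
                coef = int(rng.integers(1, spec.max_coefficient + 1))
                stoich[str(met)] = float(coef if rng.random() < 0.5 else -coef)
            lb = 0.0 if rng.random() < 0.5 else -cap
            reactions.append(Reaction(f"RX{k}", stoich, lb, cap))
        model = Model(metabolites=_mets(*met_ids), reactions=tuple(reactions), name=f"random-{spec.seed}")
        try:
            run_fva(model, reactions=[])  # feasibility check only
        except InfeasibleModelError:
            continue
        return model
    raise RuntimeError(f"could not generate a feasible random network for seed {spec.seed}")


# ---------------------------------------------------------------------------
# Synthetic metabolomic study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileSimSpec:
    """Recipe for a synthetic fasting plasma metabolomics study.

    Defaults emulate a small cohort: 5 control subjects each contributing
    2 fasting draws, one patient with 2 pre-treatment draws whose profile is
    shifted up by ``effect_size`` baseline SDs on ``high_set`` and down on
    ``low_set``, one control-like post-treatment patient draw, and one
    non-fasting draw whose deviations run against the fasting trend across the
    whole panel. Noise is lognormal multiplicative per cell.
    """

    panel: tuple[str, ...] = PLASMA_METABOLITES
    baselines: Mapping[str, float] = field(default_factory=lambda: dict(SYNTHETIC_BASELINES))
    cvs: Mapping[str, float] = field(default_factory=lambda: dict(SYNTHETIC_CVS))
    n_controls: int = 5
    control_draws: int = 2
    n_patient_pre: int = 2
    high_set: tuple[str, ...] = INCREASED_IN_PATIENT
    low_set: tuple[str, ...] = DECREASED_IN_PATIENT
    effect_size: float = 5.0
    include_post_treatment: bool = True
    include_nonfasting: bool = True
    nonfasting_effect: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        panel = set(self.panel)
        if set(self.high_set) & set(self.low_set):
            raise ValueError("high_set and low_set overlap")
        outside = (set(self.high_set) | set(self.low_set)) - panel
        if outside:
            raise ValueError(f"effect sets outside the panel: {sorted(outside)}")
        missing = panel - set(self.baselines)
        if missing:
            raise ValueError(f"panel metabolites without baselines: {sorted(missing)}")
        missing_cv = panel - set(self.cvs)
        if missing_cv:
            raise ValueError(f"panel metabolites without CVs: {sorted(missing_cv)}")
        if self.n_controls < 1 or self.control_draws < 1 or self.n_patient_pre < 1:
            raise ValueError("need at least one control, one draw, one patient draw")


def simulate_profiles(spec: ProfileSimSpec = ProfileSimSpec()) -> tuple[ProfileTable, PlantedTruth]:
    """Generate a synthetic study; bit-reproducible for a given spec and seed.

    Control draws are lognormal around the baselines (mean-preserving). Patient
    pre-treatment draws add ``effect_size`` baseline SDs to ``high_set``
    metabolites and subtract the same from ``low_set`` metabolites after the
    multiplicative noise, so the planted shift does not inflate the patient's
    own draw-to-draw variance. The post-treatment draw is control-like. The
    non-fasting draw deviates by ``nonfasting_effect`` SDs against the fasting
    trend: ketone-like metabolites down, everything else up. Concentrations are
    floored at 1% of baseline to stay positive.
    """
    rng = np.random.default_rng(spec.seed)
    panel = list(spec.panel)
    mu = np.array([spec.baselines[m] for m in panel])
    cv = np.array([spec.cvs[m] for m in panel])
    sigma_log = np.sqrt(np.log1p(cv**2))
    sd = mu * cv

    def draw(n: int) -> np.ndarray:
        # mean-preserving lognormal: E[mu * exp(N(-s^2/2, s))] = mu
        eps = rng.normal(-0.5 * sigma_log**2, sigma_log, size=(n, len(panel)))
        return mu * np.exp(eps)

    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    groups: dict[str, str] = {}

    for i in range(1, spec.n_controls + 1):
        draws = draw(spec.control_draws)
        for j in range(spec.control_draws):
            sid = f"N{i}" if spec.control_draws == 1 else f"N{i}_d{j + 1}"
            rows.append(draws[j])
            sample_ids.append(sid)
            groups[sid] = "control"

    shift = np.zeros(len(panel))
    for k, name in enumerate(panel):
        if name in spec.high_set:
            shift[k] = spec.effect_size * sd[k]
        elif name in spec.low_set:
            shift[k] = -spec.effect_size * sd[k]
    for j in range(spec.n_patient_pre):
        sid = f"Pre{j + 1}"
        rows.append(np.maximum(draw(1)[0] + shift, 0.01 * mu))
        sample_ids.append(sid)
        groups[sid] = "patient_pre"

    if spec.include_post_treatment:
        rows.append(draw(1)[0])
        sample_ids.append("Post")
        groups["Post"] = "patient_post"

    if spec.include_nonfasting:
        trend = np.array([-1.0 if m in KETONE_LIKE else 1.0 for m in panel])
        nf = draw(1)[0] + spec.nonfasting_effect * sd * trend
        rows.append(np.maximum(nf, 0.01 * mu))
        sample_ids.append(f"NF{spec.n_controls}")
        groups[f"NF{spec.n_controls}"] = "nonfasting"

    table = ProfileTable(
        data=pd.DataFrame(np.vstack(rows), index=sample_ids, columns=panel),
        groups=groups,
    )
    truth = PlantedTruth(
        high_set=frozenset(spec.high_set),
        low_set=frozenset(spec.low_set),
        effect_size=spec.effect_size,
        parameters={
            "seed": spec.seed,
            "n_controls": spec.n_controls,
            "control_draws": spec.control_draws,
            "n_patient_pre": spec.n_patient_pre,
            "nonfasting_effect": spec.nonfasting_effect,
            "include_post_treatment": spec.include_post_treatment,
            "include_nonfasting": spec.include_nonfasting,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# Media panel fixture
# ---------------------------------------------------------------------------


def make_media_panel_model(extra_species: Sequence[str] = ("co2", "urea", "lac__L")) -> Model:
    """A boundary-only model carrying one exchange per rich-media species.

    Includes the 23 limited-uptake species (20 amino acids, glucose, palmitate,
    oxygen), the 2 freely exchanged species (protons, water), and a few extra
    species whose exchanges should be closed to uptake by any media — a fixture
    for media-application logic, not a metabolic network.
    """
    species = list(RICH_MEDIA_UPTAKES) + list(RICH_MEDIA_FREE) + list(extra_species)
    metabolites = tuple(
        Metabolite(id=f"{base}_e", name=base, compartment="e") for base in species
    )
    reactions = tuple(
        Reaction(
            id=f"EX_{base}_e",
            stoichiometry={f"{base}_e": -1.0},
            lower_bound=-DEFAULT_BOUND,
            upper_bound=DEFAULT_BOUND,
            name=f"{base} exchange",
        )
        for base in species
    )
    return Model(metabolites=metabolites, reactions=reactions, name="media-panel")


# ---------------------------------------------------------------------------
# Condition-pair network with a planted differential branch
# ---------------------------------------------------------------------------


def make_condition_pair(seed: int = 0) -> tuple[Model, dict[str, float], dict[str, float], PlantedTruth]:
    """A small network where the patient-side objective provably enlarges spans.

    One limited inlet feeds two product branches: a ketone-like product K and
    an amino-acid-like product M, each synthesized by two parallel routes and
    secreted by an exchange. Coefficients come from exchange maxima under the
    open-set bounds. Under the default pipeline (patient objective on K at
    scale 0.5, non-patient on M at scale 1.0, optimize-fix-FVA), only the sum
    of the demanded branch's parallel routes is pinned, so each route keeps a
    span equal to the whole inlet in the condition that demands it and is
    pinned to zero in the other: the planted ketone routes classify
    "decreased" under the non-patient/patient span-ratio orientation.
    """
    rng = np.random.default_rng(seed)
    inlet = float(rng.integers(5, 16))
    cap = 2 * inlet
    metabolites = (
        Metabolite("A", name="shared precursor", compartment="e"),
        Metabolite("K", name="ketone-like product", compartment="e"),
        Metabolite("M", name="amino-acid-like product", compartment="e"),
        Metabolite("W", name="waste product", compartment="e"),
    )
    reactions = (
        Reaction("EX_A", {"A": -1.0}, -inlet, 0.0, name="precursor uptake"),
        Reaction("RK1", {"A": -1.0, "K": 1.0}, 0.0, cap, name="ketone route 1"),
        Reaction("RK2", {"A": -1.0, "K": 1.0}, 0.0, cap, name="ketone route 2"),
        Reaction("EX_K", {"K": -1.0}, 0.0, DEFAULT_BOUND, name="ketone secretion"),
        Reaction("RM1", {"A": -1.0, "M": 1.0}, 0.0, cap, name="amino route 1"),
        Reaction("RM2", {"A": -1.0, "M": 1.0}, 0.0, cap, name="amino route 2"),
        Reaction("EX_M", {"M": -1.0}, 0.0, DEFAULT_BOUND, name="amino secretion"),
        Reaction("RW", {"A": -1.0, "W": 1.0}, 0.0, DEFAULT_BOUND, name="waste route"),
        Reaction("EX_W", {"W": -1.0}, 0.0, DEFAULT_BOUND, name="waste secretion"),
    )
    model = Model(metabolites=metabolites, reactions=reactions, name=f"condition-pair-{seed}")

    base = open_bounds_from_fva(model)
    high = exchange_maxima(base, ["K"]).positive()
    low = exchange_maxima(base, ["M"]).positive()
    truth = PlantedTruth(
        high_set=frozenset({"K"}),
        low_set=frozenset({"M"}),
        differential_reactions={"RK1": "decreased", "RK2": "decreased"},
        parameters={"seed": seed, "inlet_capacity": inlet, "route_capacity": cap},
    )
    return model, high, low, truth
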