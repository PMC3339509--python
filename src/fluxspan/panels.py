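"""Named metabolite panels and group presets for plasma NMR profiles.

The default panel is the 30 plasma metabolites quantified by NMR in the study
this package reproduces. Two pairs of group presets are shipped because the
study reports two slightly different partitions of the separating metabolites:
the figure-level increased/decreased lists, and the methods-level "ketone
group" / "amino acid group" lists that fed the pseudo-objectives. Which list
feeds which analysis step is an explicit caller choice, never inferred.
"""

from __future__ import annotations

#: The 30-metabolite plasma NMR panel, in the study's numbering order.
PLASMA_METABOLITES: tuple[str, ...] = (
    "3-Hydroxybutyrate",
    "Acetate",
    "Acetone",
    "Alanine",
    "Arginine",
    "Asparagine",
    "Citrate",
    "Creatinine",
    "Formate",
    "Glucose",
    "Glutamate",
    "Glutamine",
    "Glycerol",
    "Glycine",
    "Glycolate",
    "Isoleucine",
    "Lactate",
    "Leucine",
    "Lysine",
    "Methanol",
    "Methionine",
    "Phenylalanine",
    "Pyruvate",
    "Serine",
    "Succinate",
    "Taurine",
    "Threonine",
    "Tyrosine",
    "Valine",
    "sn-Glycero-3-phosphocholine",
)

#: Metabolites relatively increased in the patient (figure-level list).
INCREASED_IN_PATIENT: tuple[str, ...] = ("3-Hydroxybutyrate", "Acetate")

#: Metabolites relatively decreased in the patient (figure-level list).
DECREASED_IN_PATIENT: tuple[str, ...] = (
    "Alanine",
    "Glycine",
    "Lysine",
    "Serine",
    "Tyrosine",
    "Glutamine",
    "Creatinine",
)

#: "Ketone group" preset used to build the patient-side pseudo-objective.
KETONE_GROUP: tuple[str, ...] = ("Acetone", "Formate", "Acetate")

#: "Amino acid group" preset used to build the control-side pseudo-objective.
AMINO_ACID_GROUP: tuple[str, ...] = (
    "Tyrosine",
    "Taurine",
    "Serine",
    "Glycine",
    "Alanine",
    "Citrate",
    "Lactate",
    "Methanol",
    "Creatinine",
)
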