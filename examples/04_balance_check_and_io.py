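"""Mass/charge balance checking and model I/O round trips.

Builds a tiny model with one balanced split, one elementally broken variant,
and an exchange reaction; writes it to both the plain-matrix TSV format and
SBML, reads both back, and prints the balance report.
"""

import tempfile
from pathlib import Path

from fluxspan import (
    Metabolite,
    Model,
    Reaction,
    check_mass_charge_balance,
    read_matrix_tsv,
    read_sbml,
    write_matrix_tsv,
    write_sbml,
)

model = Model(
    metabolites=(
        Metabolite("glc_c", name="glucose", compartment="c", formula="C6H12O6", charge=0),
        Metabolite("lac_c", name="lactate", compartment="c", formula="C3H6O3", charge=0),
    ),
    reactions=(
        Reaction("GLYC", {"glc_c": -1.0, "lac_c": 2.0}, 0.0, 1000.0, name="glycolysis (lumped)"),
        Reaction("BROKEN", {"glc_c": -1.0, "lac_c": 1.0}, 0.0, 1000.0, name="mis-stoichiometric"),
        Reaction("EX_glc", {"glc_c": -1.0}, -10.0, 1000.0, name="glucose exchange"),
    ),
    name="balance-demo",
)

report = check_mass_charge_balance(model)
print(f"{'reaction':8s} {'status':>11s}  imbalance")
for entry in report.entries:
    imbalance = dict(entry.element_imbalance) or "-"
    print(f"{entry.reaction_id:8s} {entry.status:>11s}  {imbalance}")
print(f"summary: {report.summary()}")
print("One glucose holds two lactates' worth of atoms, so the 1:1 variant is "
      "short C3H6O3; the exchange is exempt (boundary reaction).")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_matrix_tsv(model, tmp / "S.tsv", tmp / "bounds.tsv")
    write_sbml(model, tmp / "model.xml")
    from_tsv = read_matrix_tsv(tmp / "S.tsv", tmp / "bounds.tsv")
    from_sbml = read_sbml(tmp / "model.xml")
    print(f"\nTSV round trip:  {from_tsv.reaction_ids == model.reaction_ids}")
    print(f"SBML round trip: {from_sbml.reaction_ids == model.reaction_ids}")
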