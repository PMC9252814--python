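"""Use archived pKa-predictor output instead of fixed model pKas.

Structure mode normally perturbs nothing: every Asp titrates at 3.8, every
His at 6.5.  An empirical predictor shifts each residue's pKa according to
its structural environment; its .pka output file can be parsed directly, so
archived predictions are reusable without the predictor installed.  The
summary text below is synthetic (written here for the demonstration) but
follows the predictor's output layout exactly.
"""

from phdelta import (
    FixtureSpec, assign_states, detect_all, make_motif, parse_predictor_output,
)

model, table_pkas = make_motif(FixtureSpec("salt_bridge_pair", distance=3.0))

SYNTHETIC_PKA_TEXT = """\
propka3.5.1                                                  demo
-------------------------------------------------------------
SUMMARY OF THIS PREDICTION
       Group      pKa  model-pKa   ligand atom-type
   ARG   2 A    11.80      12.50
   GLU  10 A     6.20       4.50
   N+     2 A     7.70       8.00
   C-    10 A     3.30       3.20
"""

pred_pkas = parse_predictor_output(SYNTHETIC_PKA_TEXT, model)
print(f"predictor version recorded: {pred_pkas.predictor_version}")

for label, pkas in (("model table", table_pkas), ("predictor", pred_pkas)):
    bonds = detect_all(model, assign_states(pkas, 5.5))
    kinds = [r.kind for r in bonds.records]
    print(f"pH 5.5 with {label:<12}: {kinds}")
print("\nwith the environment-shifted Glu pKa of 6.2, pH 5.5 already")
print("neutralizes the carboxylate, so the salt bridge is gone — the fixed")
print("table (pKa 4.5) would still report it.")
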