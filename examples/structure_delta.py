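"""Created/destroyed noncovalent bonds between two pH values.

An Arg/Glu pair posed at salt-bridge distance: at pH 7 both side chains are
charged and the bridge is detected; at pH 2 (below the Glu pKa of 4.5) the
carboxylate is neutralized and the bridge disappears from the inventory.
"""

from phdelta import (
    FixtureSpec, assign_states, detect_all, interaction_delta, make_motif,
)

model, pkas = make_motif(FixtureSpec("salt_bridge_pair", distance=3.0))
set_ph7 = detect_all(model, assign_states(pkas, 7.0))
set_ph2 = detect_all(model, assign_states(pkas, 2.0))

for iset in (set_ph7, set_ph2):
    print(f"pH {iset.ph:g}: {[(r.kind, str(r.key_a), str(r.key_b)) for r in iset.records]}")

delta = interaction_delta(set_ph7, set_ph2)  # reference pH 7 -> interest pH 2
print(f"\ndestroyed going to pH 2: "
      f"{[(r.kind, r.label_a, r.label_b, r.distance) for r in delta.destroyed]}")
print(f"created going to pH 2:   "
      f"{[(r.kind, r.label_a, r.label_b) for r in delta.created]}")
print("\nthe salt bridge exists only while both partners are charged; its")
print("loss on acidification is exactly the kind of pH-switch this reports.")
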