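"""Locate the steady states of the published parameter set.

The three-gene network (GATA-1, GATA-2, PU.1) supports up to four fixed
points: the unstable origin, two committed lineage states in closed form
(erythroid = high GATA-1, myeloid = high PU.1), and a numerically located
interior "primed" progenitor state with low co-expression of all three
factors.  Tristability means the two committed states and the primed
state are simultaneously stable.
"""

from gataswitch import figure3_parameters, steady_state_set, stability_margins

params = figure3_parameters()
states = steady_state_set(params, seed=0)

print("steady states of the published parameter set:")
for st in (states.trivial, states.erythroid, states.myeloid, states.primed):
    print(f"  {st.label:>10}: (x={st.x:10.4f}, y={st.y:10.4f}, z={st.z:10.4f})"
          f"  stable={st.stable}")
print(f"tristable: {states.tristable}")

print("\nsigned margins of the seven stability inequalities (all must be > 0):")
for name, margin in stability_margins(params).items():
    print(f"  {name:>12}: {margin:12.2f}")

# The erythroid state holds x = (a1 - k1 a3)/(k1 a4) ~ 659 concentration
# units of GATA-1 and none of the other two factors; the primed state
# keeps all three genes expressed at low level, which is what makes it a
# progenitor condition poised between the two lineages.
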