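"""Staged-penalty GA inference of the ten free rate constants.

Thirteen of the 23 rate constants are pinned by experimental data
(half-lives, dissociation constants, shared-binding-site equalities and
the a3 = b2 = c2 = 1 normalization).  The remaining ten are searched in
a unit-cube genome whose mapping to rate constants enforces the seven
tristability inequalities by construction.  Candidates are scored by the
staged penalty: 4 = no primed state, 3 = a state fails perturbation
validation, 2 = no genetic switching, else the fraction of perturbed
parameter sets that lose tristability (0 = perfectly robust).

This is the desk-scale configuration (population 50, 10 generations,
50 robustness sets); the study-scale search uses 1000/100/1000.
"""

from gataswitch import GAConfig, run_ga, steady_state_set

cfg = GAConfig(population_size=50, n_generations=10, seed=0,
               robustness_n=50, robustness_sigma=0.5)
result = run_ga(cfg)

print("per-generation penalty (best / population mean):")
print(result.history.to_string(index=False))
print(f"\nbest penalty: {result.best_score.value:.3f} "
      f"(stage failed: {result.best_score.stage_failed})")

best = result.best_params
print(f"best candidate synthesis rates: a1={best.a1:.1f} b1={best.b1:.1f} c1={best.c1:.1f}")
states = steady_state_set(best, seed=0)
print(f"tristable: {states.tristable}")

# A best penalty below 2 means the candidate is tristable, validated and
# realizes genetic switching; below 1 the value is the fraction of
# sigma=0.5 perturbations under which tristability is lost.
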