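"""Select the analysis populations and tabulate treatment sequences.

Runs cohort selection on a simulated bundle, prints the attrition log,
per-stratum transition rates and the most common regimens per line.
"""

from crclot import DrugVocabulary, SimulationConfig, build_cohorts, simulate_bundle
from crclot.metrics import sequence_table, transition_rates
from crclot.simulate import analysis_config_for_simulation

config = SimulationConfig(n_patients=400, seed=11)
bundle, _ = simulate_bundle(config)
vocab = DrugVocabulary.default()
res = build_cohorts(bundle, vocab, analysis_config_for_simulation(config))

print("first-line population attrition:")
for criterion, n in res.logs["first_line"].steps:
    print(f"  {criterion:45s} {n:5d}")

print("\ntransition rates (evaluable denominators):")
tr = transition_rates(res.lines, res.members)
print(tr[tr.n_evaluable > 0].to_string(index=False))

print("\nmost common first-line regimens (RAS-mutant stratum):")
seq = sequence_table(res.lines, res.members, vocab)
sub = seq[(seq.line == "1") & (seq.presumed_ras == "mutant")]
print(sub.head(5).to_string(index=False))
# Transition rates use only patients whose non-transition is observable
# (a next line, or more than 60 days of data after the line ended).
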