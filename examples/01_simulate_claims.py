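"""Generate a synthetic claims bundle and peek at its contents.

The generator emits raw prescription/diagnosis/procedure/assessment tables
plus a ground-truth record of each patient's latent therapy lines; the
line structure must be *recovered* by the derivation algorithm, which is
what makes the generator useful for testing.
"""

from crclot import SimulationConfig, simulate_bundle, write_bundle

config = SimulationConfig(n_patients=100, seed=7)
bundle, truth = simulate_bundle(config)
write_bundle(bundle, "scratch/example_bundle")

print("table sizes:")
for name, table in bundle.tables().items():
    print(f"  {name:14s} {len(table):6d} rows")

pid = "P000001"
tp = truth.patients[pid]
print(f"\n{pid}: population={tp.population}, "
      f"presumed RAS wild={tp.presumed_ras_wild}")
for line in tp.lines:
    print(f"  true line {line.line_number}: {line.start_date} .. {line.end_date} "
          f"({line.end_reason}) drugs={sorted(line.base_drugs)}")
rx = bundle.prescriptions
print(f"\nfirst prescriptions for {pid}:")
print(rx[rx.patient_id == pid].head(6).to_string(index=False))
# The true lines above are bookkeeping only -- the CSV bundle contains
# nothing but dated claims, exactly like a real hospital extract.
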