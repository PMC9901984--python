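"""Fit per-diagnosis mortality likelihood ratios on a training cohort.

The LR of a diagnosis is its prevalence among patients dead within 183
days of their index date divided by its prevalence among survivors.
Codes with fewer than 100 carriers inherit the LR of their broader ICD-9
concept (rollup), and codes whose carriers all die or all survive get
the smoothed values n+1 and 1/(n+1).
"""
from mmindex import fit_lr_table, generate_cohort, parse_icd9, preset_scenarios

spec = preset_scenarios("rare_signal_non_charlson", n_patients=50_000, seed=7)
diagnoses, outcomes, truth = generate_cohort(spec)
diagnoses = diagnoses.rename(columns={"icd9": "code"})

table = fit_lr_table(diagnoses, outcomes, horizon_days=183, min_cases=100)
print(f"codes in table: {len(table)}; training deaths {table.n_dead_total}, "
      f"survivors {table.n_alive_total}\n")
print(f"{'code':>7} {'true':>5} {'fitted LR':>9}  {'carriers':>8}  rollup")
for d in sorted(truth["diseases"], key=lambda d: -d["true_effect"])[:8]:
    e = table.lookup(parse_icd9(d["code"]))
    provenance = "own counts" if e.rollup_depth == 0 else f"from {e.source_code.dotted}"
    print(f"{d['code']:>7} {d['true_effect']:>5} {e.lr:>9.2f}  {e.n_total:>8}  {provenance}")
# Fitted LRs track the generating odds multipliers; rare codes (carriers
# < 100) show the LR of their broader concept instead of their own noisy one.
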