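"""Score a patient: worst disease per body system, multiplied odds.

A patient with both iatrogenic hypotension (458.2) and cardiac arrest
(427.5) — both circulatory — is scored only on the cardiac arrest, the
worst (highest-LR) disease of that system.  Diagnoses in different body
systems multiply.
"""
from mmindex import PatientHistory, parse_icd9, score_patient
from mmindex.lr import LREntry, LRTable


def toy_table(lrs):
    entries = {}
    for text, lr in lrs.items():
        code = parse_icd9(text)
        entries[code.canonical_text] = LREntry(code, lr, 1000, code, 0)
    return LRTable(entries, horizon_days=183, min_cases=100,
                   n_dead_total=1000, n_alive_total=9000)


table = toy_table({
    "458.2": 0.10,   # iatrogenic hypotension      (circulatory)
    "427.5": 2.26,   # cardiac arrest              (circulatory)
    "511.81": 3.28,  # malignant pleural effusion  (respiratory)
})

patient = PatientHistory(
    "example", frozenset(parse_icd9(c) for c in ["458.2", "427.5", "511.81"]), age=72
)
score = score_patient(patient, table)
for system, (code, lr) in sorted(score.per_system.items(), key=lambda kv: kv[0].name):
    print(f"{system.value:<40} worst: {code.dotted:>7}  LR = {lr}")
print(f"\nodds score = 2.26 x 3.28 = {score.odds:.4f}   (log-odds {score.log_odds:.4f})")
# The hypotension (LR 0.10) is ignored: within a body system only the
# worst disease counts, so the score never decreases as a system worsens.
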