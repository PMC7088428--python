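"""Dataset curation: annotation, length and alphabet filters + redundancy cap.

Builds a handful of annotated records, runs the curation chain and the
greedy 70%-identity reduction, and prints what each filter removed.
"""

import submitoloc as sm

CLEAN = "ACDEFGHIKLMNPQRSTVWY" * 4  # 80 residues

records = [
    sm.ProteinRecord("ok_matrix", CLEAN, "matrix"),
    sm.ProteinRecord("hedged", CLEAN, "matrix; Probable"),          # ambiguous
    sm.ProteinRecord("dual", CLEAN, "inner membrane and matrix"),   # two places
    sm.ProteinRecord("short", CLEAN[:60], "matrix"),                # < 80 aa
    sm.ProteinRecord("odd", CLEAN[:-1] + "X", "matrix"),            # nonstandard
    sm.ProteinRecord("near_dup", CLEAN[:40] + "W" * 4 + CLEAN[44:], "matrix"),
]

report = sm.curate(records)
print(f"input: {report.input_count} records")
for name, count in report.removed_by_filter.items():
    print(f"  removed by {name}: {count}")
print(f"retained after filters: {[r.id for r in report.retained]}")

representatives = sm.reduce_redundancy(report.retained, identity_threshold=0.70)
print(f"after 70% identity reduction: {[r.id for r in representatives]}")
# 'near_dup' is 95% identical to 'ok_matrix', so only one representative
# of that pair survives; every other filter removed exactly one record.
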