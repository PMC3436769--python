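"""Recover per-stage kappas from a published percentage table.

Validation studies usually print epoch-by-epoch agreement tables as row
percentages plus row totals.  This example rebuilds the integer counts for
the bundled reference tables (normal/mild and moderate/severe
sleep-disordered breathing groups) and recomputes the one-vs-rest Cohen's
kappa per stage, which matches the published values to two decimals.
"""

from eogstage import STAGES, per_stage_kappa, percent_agreement, reconstruct_counts
from eogstage import reference_tables as ref

for group, (pct, totals, published) in ref.GROUPS.items():
    table = reconstruct_counts(pct, totals)
    rows, overall = percent_agreement(table)
    print(f"{group}: {table.total} epochs, overall agreement {overall:.1f}%")
    for stage, expected in zip(STAGES, published):
        k = per_stage_kappa(table, stage)
        print(f"  {stage:>2}: kappa {k:.2f} (published {expected:.2f})")
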