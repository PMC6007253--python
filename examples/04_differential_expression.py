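"""Clinical group-wise contrasts and model-to-clinic integration.

Runs the five patient contrasts (>2-fold and P < 0.05 gate) on a
synthetic discovery cohort, then intersects the gated transcripts with
the PDX temporal classes to produce the per-class NEtD lncRNA sets.
"""

from netdlnc.diffexp import compare_groups
from netdlnc.synthetic_data import (
    SimulationConfig,
    generate_clinical_cohorts,
    generate_pdx_timeseries,
)
from netdlnc.temporal import classify_all, integrate_clinical

config = SimulationConfig(seed=1)
(matrix_a, meta_a), _cohort_b, truth = generate_clinical_cohorts(config)

comparisons = (
    "NEPC_vs_AD",
    "NEPC_vs_NHT",
    "CRPC_vs_AD",
    "NHT_vs_NAIVE",
    "COMBINED_E",
)
all_results = []
for comparison in comparisons:
    results = compare_groups(matrix_a, meta_a, comparison)
    gated = sum(r.passes_gate for r in results)
    print(f"{comparison:>14}: {gated:4d} transcripts pass the gate")
    all_results += results

pdx, pdx_meta, _ = generate_pdx_timeseries(config)
netd_sets = integrate_clinical(classify_all(pdx, pdx_meta), all_results)
print("\nNEtD sets after integrating PDX classes with clinical gates:")
for cls, members in netd_sets.items():
    print(f"  {cls:>15}: {len(members)} lncRNAs "
          f"({config.n_planted_per_class} planted)")
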