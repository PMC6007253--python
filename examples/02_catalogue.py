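"""Building the lncRNA catalogue and cleaning expression values.

Constructs a miniature annotation, keeps the three informative lncRNA
subclasses (antisense, lincRNA, pseudogene) while removing Ig/TCR
pseudogenes, floors sub-detection expression values, and unifies
transcript keys across two cohorts by (Ensembl id, length).
"""

import pandas as pd

from netdlnc.catalogue import (
    TranscriptRecord,
    build_lncrna_catalogue,
    floor_expression,
    merge_cohort_keys,
    remove_uncharacterized,
)


def rec(tid, biotype, length):
    return TranscriptRecord(
        transcript_id=tid, gene_name=tid, biotype=biotype,
        chrom="chr1", strand="+", exons=((0, length),),
    )


annotation = [
    rec("ENST01", "antisense", 800),
    rec("ENST02", "lincRNA", 1200),
    rec("ENST03", "processed_pseudogene", 600),
    rec("ENST04", "IG_C_pseudogene", 400),   # immunoglobulin: removed
    rec("ENST05", "protein_coding", 2000),   # not a lncRNA subclass
    rec("ENST06", "retained_intron", 900),   # not used downstream
]
kept, summary = build_lncrna_catalogue(annotation)
print("catalogue summary:", summary)

matrix = pd.DataFrame(
    {"sample1": [5.0, 0.09, 0.2], "sample2": [3.0, 0.05, 0.11]},
    index=["ENST01", "ENST02", "ENST03"],
)
floored = floor_expression(matrix)
print("\nfloored matrix (values < 0.1 are quantification artifacts):")
print(floored)

# same id assembled at two lengths stays two keys; identical pairs unify
keys = merge_cohort_keys([rec("ENST01", "antisense", 800)],
                         [rec("ENST01", "antisense", 620)])
print("\ncross-cohort keys for ENST01 at lengths 800 vs 620:", sorted(keys))

names = ["H19", "RP11-123A4.2", "AC012345.1", "SSTR5-AS1"]
print("after uncharacterized-id removal:", remove_uncharacterized(names))
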