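"""Score a small synthetic cohort for APOBEC TCW fold enrichment.

Builds a random reference contig, plants one sample whose C>T mutations all
fall in the TCW motif and one whose mutations hit arbitrary cytosines, and
prints the per-sample fold enrichment E, adjusted p, and APOBEC class.
E measures how much more often mutations hit TCW than the local sequence
content would predict; E >= 3 with adjusted p < 0.01 is "APOBEC high".
"""

import numpy as np

from apohm import Mutation, cohort_enrichment

rng = np.random.default_rng(1)
seq = "".join(rng.choice(list("ACGT"), size=6000))
reference = {"chr1": seq}


def mutations_at(predicate, sample, limit):
    out = []
    for i in range(1, len(seq) - 2):
        if seq[i] == "C" and predicate(i):
            out.append(
                Mutation(sample_id=sample, chrom="chr1", pos=i + 1, ref="C",
                         alt="T", alt_reads=5, depth=10)
            )
        if len(out) == limit:
            break
    return out


cohort = {
    "apobec_like": mutations_at(lambda i: seq[i - 1] == "T" and seq[i + 1] in "AT",
                                "apobec_like", 30),
    "background": mutations_at(lambda i: True, "background", 30),
}

table = cohort_enrichment(cohort, reference)
print(table[["sample_id", "E", "p", "adj_p", "apobec_class"]].to_string(index=False))
print(
    "\nThe TCW-targeted sample shows E >> 1 with a significant adjusted p"
    "\n(APOBEC-like targeting); the unselected sample is not significantly"
    "\nenriched and is classified as non-APOBEC."
)
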