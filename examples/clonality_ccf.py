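"""Variant copy number, clonality, and cancer cell fraction for single SNVs.

The variant copy number corrects the variant allele frequency for tumor
purity and copy number; mutations with variant copy number > 0.75 are called
clonal.  The CCF divides by the maximum-likelihood number of mutated allelic
copies, so it reads as "fraction of cancer cells carrying this mutation".
"""

from apohm import cancer_cell_fraction, variant_copy_number

cases = [
    # (alt_reads, depth, purity, tumor_cn, normal_cn, note)
    (50, 100, 1.0, 2.0, 2.0, "heterozygous clonal, pure tumor"),
    (25, 100, 1.0, 2.0, 2.0, "subclonal: present in ~half the cells"),
    (25, 100, 0.5, 3.0, 2.0, "impure tumor, local gain"),
    (100, 100, 1.0, 2.0, 2.0, "homozygous: two mutated copies"),
]

print(f"{'alt/depth':>10} {'purity':>6} {'C_t':>4} | {'n_snv':>6} {'n_chr':>5} "
      f"{'CCF':>5} {'clonal':>6}")
for alt, depth, purity, c_t, c_h, note in cases:
    n_snv = variant_copy_number(alt / depth, purity, c_t, c_h)
    res = cancer_cell_fraction(alt, depth, purity, c_t, c_h)
    print(f"{alt}/{depth:>6} {purity:>6.2f} {c_t:>4.1f} | {n_snv:>6.2f} "
          f"{res.n_chr:>5d} {res.ccf:>5.2f} {str(res.clonal):>6}   # {note}")
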