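"""Shared fixtures: synthetic reference genome, VCF, and narrowPeak files.

All fixtures are generated programmatically at test time; no data files ship
with the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from apohm.io import revcomp

# --- synthetic contigs -----------------------------------------------------

RNG_SEED = 20240528

# a stable 6-bp-stem hairpin with the didymi loop TCAAC:
HAIRPIN_LEFT_ARM = "GGCGAC"
HAIRPIN_LOOP = "TCAAC"
HAIRPIN_RIGHT_ARM = revcomp(HAIRPIN_LEFT_ARM)


def _random_seq(rng: np.random.Generator, n: int, p=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=list(p)))


def build_contigs() -> dict[str, str]:
    rng = np.random.default_rng(RNG_SEED)
    # chrEnr: balanced random sequence for enrichment context counting
    chr_enr = _random_seq(rng, 4000)
    # chrHp: A-rich flanks (suppress spurious stems) around a planted hairpin
    a_rich = (0.7, 0.1, 0.1, 0.1)
    left = _random_seq(rng, 80, a_rich)
    right = _random_seq(rng, 80, a_rich)
    chr_hp = left + HAIRPIN_LEFT_ARM + HAIRPIN_LOOP + HAIRPIN_RIGHT_ARM + right
    # chrCtx: fixed motifs for context read-off tests
    chr_ctx = "AAAA" + "ATCAG" + "AAAA" + "CTGAT" + "AAAA" + "AACAG" + "AAAA"
    return {"chrEnr": chr_enr, "chrHp": chr_hp, "chrCtx": chr_ctx}


CONTIGS = build_contigs()
# 1-based positions of the two loop cytosines of the planted hairpin
HAIRPIN_LOOP_START = 80 + len(HAIRPIN_LEFT_ARM) + 1  # first loop base, 1-based
DIDYMI_POS_A = HAIRPIN_LOOP_START + 1  # loop TCAAC index 1 -> TpC cytosine
DIDYMI_POS_B = HAIRPIN_LOOP_START + 4  # loop TCAAC index 4 -> ApC cytosine


@pytest.fixture(scope="session")
def contigs() -> dict[str, str]:
    return dict(CONTIGS)


@pytest.fixture(scope="session")
def reference(tmp_path_factory):
    """An indexed FASTA of the synthetic contigs (pyfaidx)."""
    import pyfaidx

    path = tmp_path_factory.mktemp("ref") / "ref.fa"
    with open(path, "w") as fh:
        for name, seq in CONTIGS.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return pyfaidx.Fasta(str(path))


VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(path, records, sample="s1", contigs=None):
    """Write a small VCF; records are (chrom, pos, ref, alt, ad, dp) tuples."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for name, seq in (contigs or CONTIGS).items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for chrom, pos, ref, alt, ad, dp in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD:DP\t"
                f"0/1:{dp - ad},{ad}:{dp}\n"
            )
    return path


@pytest.fixture()
def vcf_writer(tmp_path):
    def _write(records, sample="s1", name="test.vcf"):
        return write_vcf(tmp_path / name, records, sample=sample)

    return _write
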