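"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own translation/scan code
paths: translation goes through Biopython, and stop-search is a plain string
scan, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from ptcrescue.gene_model import ReferenceSeq, build_transcript
from ptcrescue.simulate import make_toy_locus


@pytest.fixture(scope="session")
def toy():
    """Default toy locus: 5 exons (30/168/45/255/33 nt), all in-frame skippable."""
    return make_toy_locus(1)


@pytest.fixture(scope="session")
def toy_oof():
    """Toy locus with out-of-frame skippable exons (44 and 256 nt)."""
    return make_toy_locus(2, exon_lengths=(30, 168, 44, 256, 33))


@pytest.fixture(scope="session")
def tiny():
    """Hand-built 3-exon gene (9/12/9 nt), CDS covering all 30 nt."""
    # exon1: ATG GCT GCA | exon2: TTC GGA CCA TGG | exon3: AAA GGT TAA
    # (exon2 codon boundaries deliberately cross the splice sites)
    e1, e2, e3 = "ATGGCTGCA", "TTCGGACCATGG", "AAAGGTTAA"
    i1 = "GT" + "C" * 16 + "AG"
    i2 = "GT" + "T" * 16 + "AG"
    genome = "ACGTA" + e1 + i1 + e2 + i2 + e3 + "TACGT"
    ref = ReferenceSeq("tiny", genome)
    x1 = (5, 14)
    x2 = (34, 46)
    x3 = (66, 75)
    model = build_transcript(ref, [x1, x2, x3], "+", (x1[0], x3[1]), name="tiny_tx")
    return ref, model


# ---------------------------------------------------------------------------
# Independent oracles


def oracle_first_premature_stop(seq: str, cds_start: int, canonical_stop: int | None):
    """Brute-force stop scan via Biopython translation.

    Returns the 1-based codon index of the first stop strictly before
    ``canonical_stop`` (a sequence offset), or None.
    """
    coding = seq[cds_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())
    idx = protein.find("*")
    if idx == -1:
        return None
    stop_offset = cds_start + 3 * idx
    if canonical_stop is not None and stop_offset >= canonical_stop:
        return None
    if canonical_stop is None and stop_offset >= len(seq) - 3:
        return None
    return idx + 1


def oracle_snv_consequence(cds: str, cds_pos: int, alt: str) -> str:
    """Classify an exonic SNV by direct codon translation (Biopython)."""
    ci = (cds_pos - 1) // 3
    codon = cds[3 * ci : 3 * ci + 3]
    off = (cds_pos - 1) % 3
    mutant = codon[:off] + alt + codon[off + 1 :]
    aa_old = str(Seq(codon).translate())
    aa_new = str(Seq(mutant).translate())
    if aa_new == "*" and aa_old != "*":
        return "nonsense"
    if aa_new == aa_old:
        return "synonymous"
    return "missense"


def oracle_hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value with rational arithmetic (independent of the package).

    Enumerates all genotype configurations compatible with the observed
    allele counts and sums the conditional probabilities of configurations no
    more probable than the observed one.
    """
    from fractions import Fraction
    from math import factorial

    n = n_AA + n_Aa + n_aa
    na = 2 * n_AA + n_Aa
    nb = 2 * n_aa + n_Aa
    if na == 0 or nb == 0:
        return 1.0

    def weight(h: int) -> Fraction:
        aa = (na - h) // 2
        bb = (nb - h) // 2
        return Fraction(factorial(n) * 2**h, factorial(aa) * factorial(h) * factorial(bb))

    hs = [h for h in range(min(na, nb) % 2, min(na, nb) + 1, 2)]
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    p_obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
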