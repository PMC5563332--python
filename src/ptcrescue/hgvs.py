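"""Coding-HGVS parsing, consequence classification, and the missense filter.

The parser covers the subset of coding HGVS needed for PTC-mutation work:
substitutions (including intronic offsets like ``c.67-1G>A``), deletions,
duplications, and insertions.  Classification follows the standard taxonomy:
frameshift, nonsense, canonical splice donor/acceptor (offsets +-1/+-2),
splice region (|offset| >= 3), in-frame indel, missense, synonymous.

Grammar-level classification (:func:`classify_by_grammar`) uses only the HGVS
string plus an optional protein label; sequence-level classification
(:func:`classify_with_sequence`) applies the variant to a transcript model and
translates.  The two never disagree on a category the grammar determines.

Notes on conventions (HGVS):
* positive intron offsets count from the preceding exon's 3' end (donor side),
  negative offsets from the following exon's 5' start (acceptor side);
* inputs are assumed 3'-normalized already — the parser does not re-normalize.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .gene_model import (
    STOP_CODONS,
    MatureTranscript,
    ReferenceSeq,
    TranscriptModel,
    mature_sequence,
    ptc_scan,
)

__all__ = [
    "Variant",
    "ConsequenceCall",
    "MissenseRecord",
    "HgvsParseError",
    "parse_chgvs",
    "affected_codon",
    "classify_by_grammar",
    "classify_with_sequence",
    "filter_deleterious_missense",
    "load_ptc_variant_table",
    "annotate_variant_table",
]

PTC_CATEGORIES = frozenset(
    {"frameshift", "nonsense", "splice_canonical_donor", "splice_canonical_acceptor"}
)


class HgvsParseError(ValueError):
    """Raised for HGVS strings outside the supported grammar."""


@dataclass(frozen=True)
class Variant:
    """A parsed coding-HGVS mutation."""

    raw: str
    kind: str  # SNV | deletion | duplication | insertion
    cds_pos: int  # 1-based CDS position of the first affected (or anchor) base
    intron_offset: Optional[int]  # signed; None <=> purely exonic
    span_length: int
    ref_allele: str = ""
    alt_allele: str = ""
    protein_label: Optional[str] = None
    cds_end: Optional[int] = None  # 1-based end for ranged del/dup/ins

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise HgvsParseError(f"cds_pos must be >= 1 (got {self.cds_pos})")
        if self.span_length < 1:
            raise HgvsParseError("span_length must be >= 1")

    @property
    def is_exonic(self) -> bool:
        return self.intron_offset is None

    @property
    def cds_length_delta(self) -> int:
        """Signed change in CDS length caused by this variant."""
        if self.intron_offset is not None or self.kind == "SNV":
            return 0
        if self.kind == "deletion":
            return -self.span_length
        return self.span_length  # duplication / insertion

    def normalized(self) -> str:
        """Re-serialize to a normalized coding-HGVS string."""
        off = ""
        if self.intron_offset is not None:
            off = f"{self.intron_offset:+d}"
        if self.kind == "SNV":
            return f"c.{self.cds_pos}{off}{self.ref_allele}>{self.alt_allele}"
        tag = {"deletion": "del", "duplication": "dup", "insertion": "ins"}[self.kind]
        pos = f"{self.cds_pos}{off}"
        if self.cds_end is not None and self.cds_end != self.cds_pos:
            pos += f"_{self.cds_end}"
        seq = self.alt_allele if self.kind == "insertion" else self.ref_allele
        return f"c.{pos}{tag}{seq}"


@dataclass(frozen=True)
class ConsequenceCall:
    category: str
    affected_codon: Optional[int]
    ptc_codon: Optional[int]
    frame_delta: int

    def __post_init__(self) -> None:
        if self.category == "nonsense" and self.ptc_codon != self.affected_codon:
            raise ValueError("nonsense calls must have ptc_codon == affected_codon")
        if self.category == "frameshift" and self.frame_delta % 3 == 0:
            raise ValueError("frameshift calls must have frame_delta % 3 != 0")

    @property
    def is_ptc_class(self) -> bool:
        return self.category in PTC_CATEGORIES


# ---------------------------------------------------------------------------
# Parsing

# Typographic minus / dashes seen in published tables.
_DASHES = {"−": "-", "–": "-", "—": "-"}

_POS = r"(\d+)([+-]\d+)?"
_RE_SNV = re.compile(rf"^{_POS}([ACGT])>([ACGT])$")
_RE_DELDUP = re.compile(rf"^{_POS}(?:_{_POS})?(del|dup)([ACGT]*)$")
_RE_INS = re.compile(rf"^{_POS}_{_POS}ins([ACGT]+)$")


def _clean(s: str) -> str:
    s = s.strip()
    for bad, good in _DASHES.items():
        s = s.replace(bad, good)
    return s.replace(" ", "")


def parse_chgvs(s: str, protein_label: Optional[str] = None) -> Variant:
    """Parse a coding-HGVS string (must start with ``c.``).

    A protein label concatenated onto the string (as printed in some tables,
    e.g. ``c.206G>Ap.Trp69*``) is split off and kept; an explicit
    ``protein_label`` argument takes precedence.
    """
    raw = s
    s = _clean(s)
    if not s.startswith("c."):
        raise HgvsParseError(f"{raw!r}: coding HGVS must start with 'c.'")
    body = s[2:]
    if "p." in body:
        body, _, attached = body.partition("p.")
        if protein_label is None:
            protein_label = "p." + attached
    if protein_label is not None:
        protein_label = _clean(protein_label)
        if protein_label in ("", "-", "."):
            protein_label = None

    m = _RE_SNV.match(body)
    if m:
        pos, off, ref, alt = m.groups()
        return Variant(
            raw=raw,
            kind="SNV",
            cds_pos=int(pos),
            intron_offset=int(off) if off else None,
            span_length=1,
            ref_allele=ref,
            alt_allele=alt,
            protein_label=protein_label,
        )
    m = _RE_INS.match(body)
    if m:
        p1, o1, p2, o2, seq = m.groups()
        if o1 or o2:
            raise HgvsParseError(f"{raw!r}: intronic insertions are not supported")
        if int(p2) != int(p1) + 1:
            raise HgvsParseError(f"{raw!r}: insertion flanks must be adjacent")
        return Variant(
            raw=raw,
            kind="insertion",
            cds_pos=int(p1),
            intron_offset=None,
            span_length=len(seq),
            alt_allele=seq,
            protein_label=protein_label,
            cds_end=int(p2),
        )
    m = _RE_DELDUP.match(body)
    if m:
        p1, o1, p2, o2, op, seq = m.groups()
        if o1 or o2:
            raise HgvsParseError(f"{raw!r}: intronic del/dup coordinates are not supported")
        start = int(p1)
        end = int(p2) if p2 else start
        if end < start:
            raise HgvsParseError(f"{raw!r}: range end precedes start")
        span = end - start + 1
        if seq and len(seq) != span:
            raise HgvsParseError(
                f"{raw!r}: sequence length {len(seq)} does not match span {span}"
            )
        kind = "deletion" if op == "del" else "duplication"
        return Variant(
            raw=raw,
            kind=kind,
            cds_pos=start,
            intron_offset=None,
            span_length=span,
            ref_allele=seq,
            protein_label=protein_label,
            cds_end=end,
        )
    raise HgvsParseError(f"{raw!r}: unrecognized token {body!r}")


def affected_codon(cds_pos: int) -> int:
    """1-based codon index containing 1-based CDS position ``cds_pos``."""
    if cds_pos < 1:
        raise ValueError("cds_pos must be >= 1 and exonic")
    return (cds_pos - 1) // 3 + 1


# ---------------------------------------------------------------------------
# Classification


def classify_by_grammar(v: Variant) -> ConsequenceCall:
    """Classify a variant from its HGVS grammar alone.

    Exonic SNVs without a decisive protein label are ``undetermined``
    (sequence needed); a protein label ending in ``*`` resolves to nonsense,
    one ending in ``fs`` to frameshift.
    """
    if v.intron_offset is not None:
        off = v.intron_offset
        if off in (1, 2):
            cat = "splice_canonical_donor"
        elif off in (-1, -2):
            cat = "splice_canonical_acceptor"
        else:
            cat = "splice_region"
        return ConsequenceCall(cat, None, None, 0)

    codon = affected_codon(v.cds_pos)
    label = v.protein_label or ""
    if v.kind in ("deletion", "duplication", "insertion"):
        delta = v.cds_length_delta
        cat = "frameshift" if delta % 3 else "inframe_indel"
        return ConsequenceCall(cat, codon, None, delta)
    # exonic SNV
    if label.endswith("*"):
        return ConsequenceCall("nonsense", codon, codon, 0)
    if label.endswith("fs"):
        return ConsequenceCall("frameshift", codon, None, 1)
    return ConsequenceCall("undetermined", codon, None, 0)


def _translate_codon(codon: str) -> str:
    from Bio.Seq import Seq

    if codon in STOP_CODONS:
        return "*"
    return str(Seq(codon).translate())


def classify_with_sequence(
    v: Variant, model: TranscriptModel, reference: ReferenceSeq
) -> ConsequenceCall:
    """Resolve a variant's consequence by applying it to the mature transcript.

    Intronic variants fall back to the grammar call (their effect is a splice
    outcome, not a sequence edit).  Categories decided by the grammar are
    preserved; only exonic SNVs gain nonsense/missense/synonymous resolution,
    and indels gain a ``ptc_codon`` from the shifted-frame translation.
    """
    if v.intron_offset is not None:
        return classify_by_grammar(v)
    cds_len = model.cds_end_t - model.cds_start_t
    if v.cds_pos > cds_len:
        raise ValueError(f"variant CDS position {v.cds_pos} outside CDS of length {cds_len}")
    codon_idx = affected_codon(v.cds_pos)
    canonical = mature_sequence(model, reference)
    mutated = mature_sequence(model, reference, (), v)

    if v.kind == "SNV":
        lo = canonical.cds_start_t + 3 * (codon_idx - 1)
        old = canonical.sequence[lo : lo + 3]
        new = mutated.sequence[lo : lo + 3]
        if new in STOP_CODONS and old not in STOP_CODONS:
            return ConsequenceCall("nonsense", codon_idx, codon_idx, 0)
        if _translate_codon(new) == _translate_codon(old):
            return ConsequenceCall("synonymous", codon_idx, None, 0)
        return ConsequenceCall("missense", codon_idx, None, 0)

    delta = v.cds_length_delta
    cat = "frameshift" if delta % 3 else "inframe_indel"
    ptc = ptc_scan(mutated).ptc_codon
    return ConsequenceCall(cat, codon_idx, ptc, delta)


# ---------------------------------------------------------------------------
# Deleterious-missense filter


@dataclass(frozen=True)
class MissenseRecord:
    variant: Variant
    maf: float
    depth: int
    ref_count: int
    alt_count: int
    cadd_phred: float

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0 or self.depth < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.maf <= 1:
            raise ValueError("maf must be a fraction in [0, 1]")


@dataclass(frozen=True)
class MissenseFilterResult:
    kept: tuple[MissenseRecord, ...]
    flagged_zero_count: tuple[MissenseRecord, ...]


def filter_deleterious_missense(
    records: Iterable[MissenseRecord],
    maf_max: float = 0.0001,
    min_depth: int = 20,
    max_balance_ratio: float = 3.0,
    min_cadd: float = 20.0,
) -> MissenseFilterResult:
    """Apply the rare deleterious-missense validation filter.

    Keeps records with MAF < ``maf_max`` (rare), depth >= ``min_depth``, a
    less-than-``max_balance_ratio``-fold difference between reference and
    alternate allele counts (heterozygote balance), and Phred-scaled CADD
    strictly above ``min_cadd``.  All comparisons are strict except depth.
    A putative heterozygote with a zero allele count cannot satisfy the
    balance rule; it is excluded and flagged separately.
    """
    kept: list[MissenseRecord] = []
    flagged: list[MissenseRecord] = []
    for r in records:
        if min(r.ref_count, r.alt_count) == 0:
            flagged.append(r)
            continue
        balance = max(r.ref_count, r.alt_count) / min(r.ref_count, r.alt_count)
        if (
            r.maf < maf_max
            and r.depth >= min_depth
            and balance < max_balance_ratio
            and r.cadd_phred > min_cadd
        ):
            kept.append(r)
    return MissenseFilterResult(tuple(kept), tuple(flagged))


# ---------------------------------------------------------------------------
# Packaged variant table (observed ABCA7 PTC/splice mutation strings)


def load_ptc_variant_table() -> pd.DataFrame:
    """The packaged table of observed ABCA7 PTC and splice-affecting mutations.

    Columns: id, chgvs, protein_label, patient_carriers, patient_maf_pct,
    control_carriers, control_maf_pct, ptc_expression_pct, rescue_note.
    Missing values are '.' in the file and NaN/None here.
    """
    with resources.files("ptcrescue.data").joinpath("abca7_ptc_variants.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["."], dtype={"chgvs": str})
    return df


def annotate_variant_table(df: pd.DataFrame) -> pd.DataFrame:
    """Parse and grammar-classify a variant table (columns ``chgvs``, optional
    ``protein_label``); returns the table with category/codon columns added."""
    out = df.copy()
    cats, codons, ptcs, deltas, normalized = [], [], [], [], []
    for _, row in df.iterrows():
        label = row.get("protein_label")
        if pd.isna(label):
            label = None
        v = parse_chgvs(str(row["chgvs"]), protein_label=label)
        call = classify_by_grammar(v)
        cats.append(call.category)
        codons.append(call.affected_codon)
        ptcs.append(call.ptc_codon)
        deltas.append(call.frame_delta)
        normalized.append(v.normalized())
    out["category"] = cats
    out["affected_codon"] = codons
    out["ptc_codon"] = ptcs
    out["frame_delta"] = deltas
    out["chgvs_normalized"] = normalized
    out["is_ptc_class"] = [c in PTC_CATEGORIES for c in cats]
    return out
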