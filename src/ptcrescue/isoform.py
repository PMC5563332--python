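"""Classify spliced long-read amplicon alignments into WT / PTC / rescue reads.

Input is a set of spliced alignments (SAM with N-gap CIGARs, or in-memory
:class:`AlignedRead` objects) of a mutation-spanning cDNA amplicon.  Each read
is assigned an allele (WT / MUT / REMOVED / UNASSIGNED), its splice events
(exon skipping, cryptic donor/acceptor usage, intron retention) are detected
from the junction chain, the implied mature transcript is built and translated,
and the read is classed as

* ``WT``      — wild-type allele, no premature stop, no deleterious event;
* ``PTC``     — a premature termination codon attributable to the variant;
* ``RESCUE``  — mutant (or mutation-excised) allele whose splicing restores an
  open reading frame with no premature stop;
* ``OTHER``   — everything else (unassigned allele, deleterious events on the
  WT allele, unresolvable junctions).

The PTC expression fraction is n_PTC / (n_PTC + n_WT): 0 means complete decay
of PTC-bearing transcripts, 0.5 equal expression of PTC and WT alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .gene_model import (
    ReferenceSeq,
    SpliceEvent,
    TranscriptModel,
    EventConflictError,
    mature_sequence,
    ptc_scan,
)
from .hgvs import Variant, classify_by_grammar

__all__ = [
    "AlignedRead",
    "Segment",
    "ReadClassification",
    "QuantResult",
    "UndefinedFractionError",
    "read_sam",
    "junction_chain",
    "detect_events",
    "call_allele",
    "classify_read",
    "classify_reads",
    "quantify",
    "event_frequency",
    "classification_table",
]

DEFAULT_TOLERANCE = 3  # nt of junction wobble accepted as canonical
DEFAULT_GAP_THRESHOLD = 30  # deletions >= this many nt are treated as junctions
DEFAULT_WINDOW = 12  # nt of flank used for allele voting
DEFAULT_MIN_AGREE = 0.7  # required agreement of flanking bases with the reference


class UndefinedFractionError(ZeroDivisionError):
    pass


# ---------------------------------------------------------------------------
# Alignment container


@dataclass(frozen=True)
class Segment:
    """One contiguous aligned block between splice gaps.

    ``cigar`` covers the block with ops in {M, I, D}; M consumes reference and
    query, I query only, D reference only.  Reference length must equal
    ``gend - gstart`` and query length ``len(query)``.
    """

    gstart: int
    gend: int
    cigar: tuple[tuple[str, int], ...]
    query: str

    def __post_init__(self) -> None:
        ref = sum(n for op, n in self.cigar if op in "MD")
        qry = sum(n for op, n in self.cigar if op in "MI")
        if ref != self.gend - self.gstart:
            raise ValueError(f"cigar reference length {ref} != {self.gend - self.gstart}")
        if qry != len(self.query):
            raise ValueError(f"cigar query length {qry} != {len(self.query)}")


@dataclass(frozen=True)
class AlignedRead:
    """A spliced alignment decomposed into blocks and splice gaps."""

    read_id: str
    reference_name: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        prev = None
        for seg in self.segments:
            if prev is not None and seg.gstart <= prev:
                raise ValueError("segments must be ascending and non-overlapping")
            prev = seg.gend

    @property
    def blocks(self) -> tuple[tuple[int, int], ...]:
        return tuple((s.gstart, s.gend) for s in self.segments)

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        """(donor_end, acceptor_start) pairs between consecutive blocks."""
        return tuple(
            (a.gend, b.gstart) for a, b in zip(self.segments, self.segments[1:])
        )

    @property
    def span(self) -> tuple[int, int]:
        return (self.segments[0].gstart, self.segments[-1].gend)

    def query_sequence(self) -> str:
        return "".join(s.query for s in self.segments)

    # -- per-base access ----------------------------------------------------

    def query_base_at(self, gpos: int) -> Optional[str]:
        """Query base aligned to genomic position ``gpos`` (None if deleted/uncovered)."""
        for seg in self.segments:
            if seg.gstart <= gpos < seg.gend:
                g, q = seg.gstart, 0
                for op, n in seg.cigar:
                    if op == "M":
                        if g <= gpos < g + n:
                            return seg.query[q + (gpos - g)]
                        g += n
                        q += n
                    elif op == "D":
                        if g <= gpos < g + n:
                            return None
                        g += n
                    else:  # I
                        q += n
                return None
        return None

    def aligned_bases(self, glo: int, ghi: int) -> list[Optional[str]]:
        """Query bases aligned to each genomic position in [glo, ghi), one walk."""
        out: list[Optional[str]] = [None] * (ghi - glo)
        for seg in self.segments:
            if seg.gend <= glo or seg.gstart >= ghi:
                continue
            g, q = seg.gstart, 0
            for op, n in seg.cigar:
                if op == "M":
                    lo = max(g, glo)
                    hi = min(g + n, ghi)
                    for p in range(lo, hi):
                        out[p - glo] = seg.query[q + (p - g)]
                    g += n
                    q += n
                elif op == "D":
                    g += n
                else:
                    q += n
                if g >= ghi:
                    break
        return out

    def query_slice(self, glo: int, ghi: int) -> Optional[str]:
        """Contiguous query subsequence aligned across genomic window [glo, ghi).

        Includes inserted bases anchored inside the window; None if the window
        is not fully covered by a single block.
        """
        for seg in self.segments:
            if seg.gstart <= glo and ghi <= seg.gend:
                g, q = seg.gstart, 0
                q_lo = q_hi = None
                for op, n in seg.cigar:
                    if op == "M":
                        if g < ghi and g + n > glo:
                            lo = max(g, glo)
                            hi = min(g + n, ghi)
                            if q_lo is None:
                                q_lo = q + (lo - g)
                            q_hi = q + (hi - g)
                        g += n
                        q += n
                    elif op == "D":
                        g += n
                    else:  # I: belongs to the window if anchored inside it
                        if glo < g < ghi and q_lo is not None:
                            q_hi = q + n
                        q += n
                if q_lo is None or q_hi is None:
                    return None
                return seg.query[q_lo:q_hi]
        return None

    def net_indel_in(self, glo: int, ghi: int) -> int:
        """Net query-minus-reference length over genomic window [glo, ghi)."""
        net = 0
        for seg in self.segments:
            if seg.gend <= glo or seg.gstart >= ghi:
                continue
            g = seg.gstart
            for op, n in seg.cigar:
                if op == "M":
                    g += n
                elif op == "D":
                    ov = max(0, min(g + n, ghi) - max(g, glo))
                    net -= ov
                    g += n
                else:  # I attributed to its anchor position
                    if glo <= g < ghi:
                        net += n
        return net

    def covers(self, glo: int, ghi: int) -> bool:
        """True if every genomic position in [glo, ghi) lies inside a block."""
        pos = glo
        for s, e in self.blocks:
            if s <= pos < e:
                pos = min(e, ghi)
                if pos >= ghi:
                    return True
        return pos >= ghi


def from_pysam(aln, gap_threshold: int = DEFAULT_GAP_THRESHOLD) -> AlignedRead:
    """Convert a pysam AlignedSegment into an :class:`AlignedRead`.

    N operations, and D operations of at least ``gap_threshold`` nt, split
    blocks (splice gaps); smaller deletions stay inside a block.
    """
    query = aln.query_sequence or ""
    segments: list[Segment] = []
    cur_cigar: list[tuple[str, int]] = []
    cur_query: list[str] = []
    g = aln.reference_start
    seg_start = g
    q = 0

    def close_segment(end: int) -> None:
        nonlocal cur_cigar, cur_query
        if cur_cigar:
            segments.append(
                Segment(seg_start, end, _merge_cigar(cur_cigar), "".join(cur_query))
            )
        cur_cigar, cur_query = [], []

    for op, n in aln.cigartuples or ():
        # 0=M,1=I,2=D,3=N,4=S,5=H,7==,8=X
        if op in (0, 7, 8):
            cur_cigar.append(("M", n))
            cur_query.append(query[q : q + n])
            g += n
            q += n
        elif op == 1:
            cur_cigar.append(("I", n))
            cur_query.append(query[q : q + n])
            q += n
        elif op == 2:
            if n >= gap_threshold:
                close_segment(g)
                g += n
                seg_start = g
            else:
                cur_cigar.append(("D", n))
                g += n
        elif op == 3:
            close_segment(g)
            g += n
            seg_start = g
        elif op == 4:
            q += n
        elif op == 5:
            pass
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    close_segment(g)
    return AlignedRead(aln.query_name, aln.reference_name, tuple(segments))


def _merge_cigar(ops: list[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return tuple(out)


def read_sam(
    path: str,
    reference_name: Optional[str] = None,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
) -> tuple[list[AlignedRead], dict]:
    """Read primary spliced alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary/chimeric records are dropped; the
    returned stats dict counts them.  Reads aligned to the reverse strand are
    stored as pysam presents them (forward-strand SEQ), so no extra
    reverse-complementing is needed here.
    """
    import pysam

    reads: list[AlignedRead] = []
    stats = {"total": 0, "dropped_unmapped": 0, "dropped_secondary_supplementary": 0,
             "dropped_other_reference": 0}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for aln in fh:
            stats["total"] += 1
            if aln.is_unmapped:
                stats["dropped_unmapped"] += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                stats["dropped_secondary_supplementary"] += 1
                continue
            if reference_name is not None and aln.reference_name != reference_name:
                stats["dropped_other_reference"] += 1
                continue
            reads.append(from_pysam(aln, gap_threshold=gap_threshold))
    return reads, stats


# ---------------------------------------------------------------------------
# Junctions and splice-event detection


def junction_chain(read: AlignedRead) -> list[tuple[int, int]]:
    """Ordered (donor_end, acceptor_start) junctions of a read."""
    return list(read.gaps)


def detect_events(
    read: AlignedRead,
    model: TranscriptModel,
    tolerance: int = DEFAULT_TOLERANCE,
) -> tuple[list[SpliceEvent], bool]:
    """Detect splice events from a read's junction chain and block layout.

    Returns (events, unresolved): junctions matching a canonical junction
    within +-tolerance produce no event; donor->skip->acceptor patterns yield
    ``exon_skip``; a junction with exactly one canonical end yields a cryptic
    donor/acceptor; contiguous alignment crossing an exon-intron boundary by
    at least ``tolerance`` yields ``intron_retention``.  Junctions matching
    nothing are flagged unresolved (the read is later classed OTHER).

    Events are reported in transcript-order exon indices.  Only the read's own
    span is informative; boundaries outside it are ignored.
    """
    exons = model.exons  # genomic ascending
    n = len(exons)
    donors = [e for s, e in exons[:-1]]  # genomic junction donors (plus-strand sense)
    acceptors = [s for s, e in exons[1:]]
    events: list[SpliceEvent] = []
    unresolved = False

    def t_index(genomic_index: int) -> int:
        return genomic_index if model.strand == "+" else n - 1 - genomic_index

    gap_donor_points = set()
    gap_acceptor_points = set()

    for d, a in read.gaps:
        gap_donor_points.add(d)
        gap_acceptor_points.add(a)
        di = _nearest(donors, d)
        ai = _nearest(acceptors, a)
        d_ok = di is not None and abs(donors[di] - d) <= tolerance
        a_ok = ai is not None and abs(acceptors[ai] - a) <= tolerance
        if d_ok and a_ok:
            if ai == di:
                continue  # canonical junction
            if ai > di:
                for k in range(di + 1, ai + 1):
                    events.append(SpliceEvent("exon_skip", t_index(k)))
                continue
            unresolved = True  # acceptor upstream of donor: not interpretable
            continue
        if d_ok and not a_ok:
            # acceptor moved: find the exon whose start it replaces
            j = _nearest(acceptors, a)
            if j is None:
                unresolved = True
                continue
            # exon j+1 (genomic) gains a shifted acceptor; exons strictly
            # between the donor exon and it are skipped
            shift = acceptors[j] - a  # positive: extension into intron
            for k in range(di + 1, j + 1):
                events.append(SpliceEvent("exon_skip", t_index(k)))
            target = j + 1
            if model.strand == "+":
                events.append(SpliceEvent("cryptic_acceptor", t_index(target), shift))
            else:
                events.append(SpliceEvent("cryptic_donor", t_index(target), shift))
            continue
        if a_ok and not d_ok:
            j = _nearest(donors, d)
            if j is None:
                unresolved = True
                continue
            shift = d - donors[j]  # positive: extension into intron
            for k in range(j + 1, ai + 1):
                events.append(SpliceEvent("exon_skip", t_index(k)))
            if model.strand == "+":
                events.append(SpliceEvent("cryptic_donor", t_index(j), shift))
            else:
                events.append(SpliceEvent("cryptic_acceptor", t_index(j), shift))
            continue
        unresolved = True

    # Intron retention: a block running past an exon boundary with no junction
    # explaining the crossing (a crossing that terminates at a gap is a cryptic
    # site and was handled above).
    retained: dict[int, int] = {}  # genomic intron index -> retained length
    blocks = read.blocks
    for bi, (s, e) in enumerate(blocks):
        followed_by_gap = bi < len(blocks) - 1
        preceded_by_gap = bi > 0
        for gi in range(n - 1):
            ilo, ihi = exons[gi][1], exons[gi + 1][0]
            # donor-side crossing: block continues past the exon end into the intron
            if s < ilo and e >= ilo + tolerance:
                if followed_by_gap and e < ihi:
                    continue  # ends at a junction inside the intron: cryptic donor
                length = min(e, ihi) - ilo
                retained[gi] = max(retained.get(gi, 0), min(length, ihi - ilo))
            # acceptor-side crossing: block starts inside the intron and runs
            # into the next exon (visible at a read edge)
            elif ilo <= s <= ihi - tolerance and e > ihi:
                if preceded_by_gap:
                    continue  # starts at a junction: cryptic acceptor
                length = ihi - s
                retained[gi] = max(retained.get(gi, 0), min(length, ihi - ilo))
    for gi, length in sorted(retained.items()):
        full = length >= exons[gi + 1][0] - exons[gi][1]
        # transcript-order index of the exon preceding this intron
        if model.strand == "+":
            t_exon = gi
        else:
            t_exon = n - 2 - gi
        events.append(
            SpliceEvent("intron_retention", t_exon, None if full else length)
        )

    events.sort(key=lambda ev: (ev.exon_index, ev.kind))
    return events, unresolved


def _nearest(values: Sequence[int], x: int) -> Optional[int]:
    if not values:
        return None
    return min(range(len(values)), key=lambda i: abs(values[i] - x))


# ---------------------------------------------------------------------------
# Allele calling


def _variant_genomic_site(variant: Variant, model: TranscriptModel) -> tuple[int, int]:
    """Genomic interval [lo, hi) of the variant's reference footprint."""
    t0 = model.cds_start_t + variant.cds_pos - 1
    span = 1 if variant.kind in ("SNV", "insertion") else variant.span_length
    g = sorted(model.transcript_to_genomic(t0 + k) for k in (0, span - 1))
    return g[0], g[1] + 1


def _site_removed(variant: Variant, model: TranscriptModel, events: Sequence[SpliceEvent]) -> bool:
    t0 = model.cds_start_t + variant.cds_pos - 1
    exon = model.exon_index_at_transcript(t0)
    spans = model.exon_t_spans()
    for ev in events:
        if ev.kind == "exon_skip" and ev.exon_index == exon:
            return True
        if ev.kind in ("cryptic_donor", "cryptic_acceptor") and ev.exon_index == exon:
            if ev.length_delta is not None and ev.length_delta < 0:
                ts, te = spans[exon]
                cut = (
                    (te + ev.length_delta, te)
                    if ev.kind == "cryptic_donor"
                    else (ts, ts - ev.length_delta)
                )
                if cut[0] <= t0 < cut[1]:
                    return True
    return False


def call_allele(
    read: AlignedRead,
    variant: Variant,
    model: TranscriptModel,
    window: int = DEFAULT_WINDOW,
    min_agree: float = DEFAULT_MIN_AGREE,
    reference: Optional[ReferenceSeq] = None,
    events: Optional[Sequence[SpliceEvent]] = None,
) -> str:
    """Error-tolerant allele assignment: WT / MUT / REMOVED / UNASSIGNED.

    SNV: vote on the base aligned to the variant position, requiring that at
    least ``min_agree`` of the flanking window bases match the reference (a
    misaligned or garbage read abstains); a base that is neither the
    reference nor the alternate allele abstains.  Deletions/duplications:
    compare the net query-minus-reference length within +-window around the
    site against 0 (WT) and the variant's length change (MUT), choosing the
    nearer, abstaining on ties.  Canonical-splice (intronic) variants return
    UNASSIGNED — their classification falls to the junction outcome.
    """
    if variant.intron_offset is not None:
        return "UNASSIGNED"
    if events and _site_removed(variant, model, events):
        return "REMOVED"

    glo, ghi = _variant_genomic_site(variant, model)
    # clip the voting window to the variant's exon and to the read's block
    # (an event may legitimately remove part of the exon near the variant)
    t0 = model.cds_start_t + variant.cds_pos - 1
    exon = model.exon_index_at_transcript(t0)
    gex = model.exons[model.genomic_exon_index(exon)]
    wlo = max(gex[0], glo - window)
    whi = min(gex[1], ghi + window)
    block = next(
        (b for b in read.blocks if b[0] <= glo and ghi <= b[1]), None
    )
    if block is None:
        return "UNASSIGNED"
    wlo = max(wlo, block[0])
    whi = min(whi, block[1])
    if not read.covers(wlo, whi):
        return "UNASSIGNED"

    if variant.kind == "SNV":
        if reference is None:
            raise ValueError("SNV allele calling requires the reference sequence")
        window_bases = read.aligned_bases(wlo, whi)
        base = window_bases[glo - wlo]
        if base is None:
            return "UNASSIGNED"
        ref_fwd, alt_fwd = variant.ref_allele, variant.alt_allele
        if model.strand == "-":
            comp = str.maketrans("ACGT", "TGCA")
            ref_fwd, alt_fwd = ref_fwd.translate(comp), alt_fwd.translate(comp)
        n_flank = 0
        agree = 0
        for p in range(wlo, whi):
            if p == glo:
                continue
            n_flank += 1
            if window_bases[p - wlo] == reference.sequence[p]:
                agree += 1
        if n_flank and agree / n_flank < min_agree:
            return "UNASSIGNED"
        if base == alt_fwd:
            return "MUT"
        if base == ref_fwd:
            return "WT"
        return "UNASSIGNED"

    # deletion / duplication / insertion: compare the read's local sequence
    # against the wild-type and mutant local haplotypes by edit distance
    if reference is None:
        raise ValueError("indel allele calling requires the reference sequence")
    qs = read.query_slice(wlo, whi)
    if qs is None:
        return "UNASSIGNED"
    wt_local = reference.sequence[wlo:whi]
    off = glo - wlo
    span = variant.span_length
    if variant.kind == "deletion":
        mut_local = wt_local[:off] + wt_local[off + span :]
    elif variant.kind == "duplication":
        mut_local = wt_local[: off + span] + wt_local[off : off + span] + wt_local[off + span :]
    else:  # insertion
        ins = variant.alt_allele
        if model.strand == "-":
            ins = ins.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        mut_local = wt_local[: off + 1] + ins + wt_local[off + 1 :]
    d_wt = _edit_distance(qs, wt_local)
    d_mut = _edit_distance(qs, mut_local)
    if d_wt == d_mut:
        return "UNASSIGNED"
    return "MUT" if d_mut < d_wt else "WT"


def _edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (small strings; banded DP is unnecessary here)."""
    if a == b:
        return 0
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ca != b[j - 1]),
            )
        prev = cur
    return prev[lb]


# ---------------------------------------------------------------------------
# Per-read classification


from functools import lru_cache


@lru_cache(maxsize=4096)
def _implied_scan(model, reference, events, variant):
    """Cached (mature transcript, PTC scan) for an (events, variant) combination.

    Reads overwhelmingly share a small set of implied transcripts, so the
    translation work is memoized on the frozen model/reference/event/variant
    values.
    """
    mt = mature_sequence(model, reference, events, variant)
    return mt, ptc_scan(mt)


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    allele: str  # WT | MUT | REMOVED | UNASSIGNED
    events: tuple[SpliceEvent, ...]
    transcript_class: str  # WT | PTC | RESCUE | OTHER
    ptc_codon: Optional[int] = None
    reason: str = ""


def _splice_variant_intron(variant: Variant, model: TranscriptModel) -> int:
    """Transcript-order intron index mutated by an intronic variant."""
    t0 = model.cds_start_t + variant.cds_pos - 1
    exon = model.exon_index_at_transcript(t0)
    return exon if variant.intron_offset > 0 else exon - 1


def _events_touch_intron(ev: SpliceEvent, intron: int) -> bool:
    if ev.kind == "exon_skip":
        return ev.exon_index - 1 <= intron <= ev.exon_index
    if ev.kind in ("cryptic_donor", "intron_retention"):
        return ev.exon_index == intron
    return ev.exon_index - 1 == intron  # cryptic_acceptor


def classify_read(
    read: AlignedRead,
    model: TranscriptModel,
    reference: ReferenceSeq,
    variant: Variant,
    tolerance: int = DEFAULT_TOLERANCE,
    window: int = DEFAULT_WINDOW,
    min_agree: float = DEFAULT_MIN_AGREE,
) -> ReadClassification:
    """Full per-read call: allele, splice events, implied transcript class."""
    events, unresolved = detect_events(read, model, tolerance=tolerance)
    events_t = tuple(events)

    if variant.intron_offset is not None:
        # canonical splice / splice-region variant: junction-inferred allele
        intron = _splice_variant_intron(variant, model)
        ilo, ihi = model.intron(intron)
        s, e = read.span
        # the read must bracket the mutated intron (an exon-skip read does not
        # touch the flanking exon, but its span is still informative)
        if not (s <= ilo - 1 and e >= ihi + 1):
            if unresolved:
                return ReadClassification(read.read_id, "UNASSIGNED", events_t, "OTHER",
                                          reason="unresolved_junction")
            return ReadClassification(read.read_id, "UNASSIGNED", events_t, "OTHER",
                                      reason="junction_not_covered")
        site_events = tuple(ev for ev in events if _events_touch_intron(ev, intron))
        if unresolved:
            return ReadClassification(read.read_id, "UNASSIGNED", events_t, "OTHER",
                                      reason="unresolved_junction")
        if not site_events:
            # canonical splicing at the mutated site -> WT allele outcome
            other_del = _deleterious(model, reference, events_t)
            if other_del:
                return ReadClassification(read.read_id, "WT", events_t, "OTHER",
                                          reason="deleterious_event_on_wt")
            return ReadClassification(read.read_id, "WT", events_t, "WT",
                                      reason="junction_inferred")
        allele = "MUT"  # aberrant junction at the mutated splice site
        try:
            mt, scan = _implied_scan(model, reference, events_t, None)
        except (EventConflictError, ValueError) as exc:
            return ReadClassification(read.read_id, allele, events_t, "OTHER",
                                      reason=f"event_conflict:{exc}")
        if scan.ptc_codon is not None:
            return ReadClassification(read.read_id, allele, events_t, "PTC",
                                      scan.ptc_codon, reason="junction_inferred")
        if scan.nonstop:
            return ReadClassification(read.read_id, allele, events_t, "OTHER",
                                      reason="nonstop")
        return ReadClassification(read.read_id, allele, events_t, "RESCUE",
                                  reason="junction_inferred")

    # exonic variant
    allele = call_allele(read, variant, model, window=window, min_agree=min_agree,
                         reference=reference, events=events)
    if unresolved:
        return ReadClassification(read.read_id, allele, events_t, "OTHER",
                                  reason="unresolved_junction")
    try:
        mt, scan = _implied_scan(
            model, reference, events_t, variant if allele == "MUT" else None
        )
    except (EventConflictError, ValueError) as exc:
        return ReadClassification(read.read_id, allele, events_t, "OTHER",
                                  reason=f"event_conflict:{exc}")

    if allele == "WT":
        if scan.ptc_codon is None and not scan.nonstop:
            return ReadClassification(read.read_id, "WT", events_t, "WT")
        return ReadClassification(read.read_id, "WT", events_t, "OTHER",
                                  reason="deleterious_event_on_wt")
    if allele == "MUT":
        if scan.ptc_codon is not None:
            return ReadClassification(read.read_id, "MUT", events_t, "PTC", scan.ptc_codon)
        if scan.nonstop:
            return ReadClassification(read.read_id, "MUT", events_t, "OTHER", reason="nonstop")
        if events_t:
            return ReadClassification(read.read_id, "MUT", events_t, "RESCUE")
        # mutant allele, canonical splicing, no premature stop: the variant
        # does not truncate here (e.g. in-frame indel) — not a PTC read
        return ReadClassification(read.read_id, "MUT", events_t, "OTHER",
                                  reason="mut_without_ptc")
    if allele == "REMOVED":
        if scan.ptc_codon is None and not scan.nonstop:
            return ReadClassification(read.read_id, "REMOVED", events_t, "RESCUE")
        return ReadClassification(read.read_id, "REMOVED", events_t, "OTHER",
                                  reason="event_introduces_ptc")
    return ReadClassification(read.read_id, "UNASSIGNED", events_t, "OTHER",
                              reason="unassigned_allele")


def _deleterious(model, reference, events) -> bool:
    """Do these events alone introduce a premature stop or break the frame?"""
    if not events:
        return False
    try:
        mt, scan = _implied_scan(model, reference, events, None)
    except (EventConflictError, ValueError):
        return True
    return scan.ptc_codon is not None or scan.nonstop


def classify_reads(
    reads: Iterable[AlignedRead],
    model: TranscriptModel,
    reference: ReferenceSeq,
    variant: Variant,
    tolerance: int = DEFAULT_TOLERANCE,
    window: int = DEFAULT_WINDOW,
    min_agree: float = DEFAULT_MIN_AGREE,
) -> list[ReadClassification]:
    return [
        classify_read(r, model, reference, variant,
                      tolerance=tolerance, window=window, min_agree=min_agree)
        for r in reads
    ]


# ---------------------------------------------------------------------------
# Quantification


@dataclass(frozen=True)
class QuantResult:
    n_wt: int
    n_ptc: int
    n_rescue: int
    n_other: int
    n_unassigned_allele: int
    ptc_expression_fraction: float
    rescue_fraction: float
    event_frequencies: tuple[tuple[tuple, float], ...] = ()

    @property
    def n_reads(self) -> int:
        return self.n_wt + self.n_ptc + self.n_rescue + self.n_other


def quantify(classifications: Sequence[ReadClassification]) -> QuantResult:
    """Counts and expression fractions over a classified read set.

    ``ptc_expression_fraction`` = n_PTC / (n_PTC + n_WT); RESCUE and OTHER
    reads are excluded from that denominator.  ``rescue_fraction`` =
    n_RESCUE / (n_PTC + n_WT + n_RESCUE).  Raw counts are always reported so
    any other convention can be recomputed.
    """
    n_wt = sum(1 for c in classifications if c.transcript_class == "WT")
    n_ptc = sum(1 for c in classifications if c.transcript_class == "PTC")
    n_rescue = sum(1 for c in classifications if c.transcript_class == "RESCUE")
    n_other = sum(1 for c in classifications if c.transcript_class == "OTHER")
    n_unassigned = sum(1 for c in classifications if c.allele == "UNASSIGNED")
    if n_ptc + n_wt == 0:
        raise UndefinedFractionError("no reads classified WT or PTC")
    ptc_frac = n_ptc / (n_ptc + n_wt)
    denom = n_ptc + n_wt + n_rescue
    rescue_frac = n_rescue / denom
    return QuantResult(n_wt, n_ptc, n_rescue, n_other, n_unassigned, ptc_frac, rescue_frac)


def event_frequency(
    reads: Sequence[AlignedRead],
    event: SpliceEvent,
    model: TranscriptModel,
    tolerance: int = DEFAULT_TOLERANCE,
) -> float:
    """Fraction of reads spanning the event's genomic extent that exhibit it.

    Allele-agnostic: every spanning read counts in the denominator.
    """
    lo, hi = _event_extent(event, model)
    spanning = 0
    hits = 0
    for read in reads:
        s, e = read.span
        if s <= lo and e >= hi:
            spanning += 1
            evs, _ = detect_events(read, model, tolerance=tolerance)
            if any(_same_event(ev, event, tolerance) for ev in evs):
                hits += 1
    if spanning == 0:
        raise UndefinedFractionError("no reads span the event's extent")
    return hits / spanning


def _event_extent(event: SpliceEvent, model: TranscriptModel) -> tuple[int, int]:
    g = model.genomic_exon_index(event.exon_index)
    exons = model.exons
    if event.kind == "exon_skip":
        lo = exons[g - 1][1] if g > 0 else exons[g][0]
        hi = exons[g + 1][0] if g + 1 < len(exons) else exons[g][1]
        return lo, hi
    if event.kind == "intron_retention":
        return model.intron(event.exon_index)
    # cryptic sites: the affected canonical boundary plus the shift
    s, e = exons[g]
    if (event.kind == "cryptic_donor") == (model.strand == "+"):
        point = e
    else:
        point = s
    delta = event.length_delta or 0
    return min(point - abs(delta), point) - 1, max(point + abs(delta), point) + 1


def _same_event(a: SpliceEvent, b: SpliceEvent, tolerance: int) -> bool:
    if a.kind != b.kind or a.exon_index != b.exon_index:
        return False
    if a.kind in ("exon_skip",):
        return True
    la = a.length_delta if a.length_delta is not None else -1
    lb = b.length_delta if b.length_delta is not None else -1
    if la == -1 or lb == -1:
        return la == lb
    return abs(la - lb) <= tolerance


def classification_table(classifications: Sequence[ReadClassification]) -> pd.DataFrame:
    """Per-read classification as a DataFrame (TSV-ready)."""
    rows = []
    for c in classifications:
        rows.append(
            {
                "read_id": c.read_id,
                "allele": c.allele,
                "transcript_class": c.transcript_class,
                "ptc_codon": c.ptc_codon,
                "events": ";".join(
                    f"{e.kind}:{e.exon_index}"
                    + (f":{e.length_delta}" if e.length_delta is not None else "")
                    for e in c.events
                )
                or ".",
                "reason": c.reason or ".",
            }
        )
    return pd.DataFrame(rows)
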