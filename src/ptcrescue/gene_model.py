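"""Single-transcript gene models and mature-transcript construction.

This module is the coordinate backbone of the package: it represents one
transcript (an ordered set of exons on a reference sequence, plus a CDS span),
converts between genomic and transcript coordinates, builds mature transcript
sequences under arbitrary splice-event sets and small variants, and locates
premature termination codons (PTCs) by translation.

Conventions
-----------
* All internal coordinates are 0-based, half-open.  1-based conventions (HGVS,
  SAM, BED display) are converted at I/O boundaries only.
* Transcript coordinates run 5'->3' along the mature transcript; on the minus
  strand this is the reverse-complement traversal of the genomic exons.
* Stop codons are the standard nuclear set {TAA, TAG, TGA}.
* "Premature" means an in-frame stop strictly upstream of the canonical
  terminal codon.  No 50-nt NMD rule is applied here: downstream code measures
  NMD from read counts rather than predicting it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

__all__ = [
    "STOP_CODONS",
    "START_CODON",
    "ReferenceSeq",
    "TranscriptModel",
    "MatureTranscript",
    "SpliceEvent",
    "PtcScan",
    "ModelError",
    "ModelValidationError",
    "EventConflictError",
    "DegenerateTranscriptError",
    "revcomp",
    "build_transcript",
    "mature_sequence",
    "scan_for_ptc",
    "ptc_scan",
    "frame_delta",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ModelError(ValueError):
    """Structural problem with exon intervals or coordinates."""


class ModelValidationError(ModelError):
    """The model violates a CDS invariant (start/stop codon, frame, N bases)."""


class EventConflictError(ValueError):
    """Two splice events (or an event and a variant) edit overlapping regions."""


class DegenerateTranscriptError(ValueError):
    """The edited CDS is too short to translate."""


# ---------------------------------------------------------------------------
# Reference sequence


@dataclass(frozen=True)
class ReferenceSeq:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ModelError("reference sequence must be non-empty")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ModelError(f"reference contains invalid characters: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_fasta(cls, path: str, name: Optional[str] = None) -> "ReferenceSeq":
        """Load one record from a FASTA file (chosen by ``name``, else first)."""
        for rec in SeqIO.parse(path, "fasta"):
            if name is None or rec.id == name:
                return cls(rec.id, str(rec.seq))
        raise ModelError(f"no FASTA record named {name!r} in {path}")

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Transcript model


@dataclass(frozen=True)
class TranscriptModel:
    """Exon architecture and CDS span of a single transcript.

    ``exons`` are genomic intervals, 0-based half-open, ascending and
    disjoint.  ``cds_start_t``/``cds_end_t`` are offsets in *transcript*
    coordinates (5'->3' along the mature transcript).
    """

    reference_name: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_t: int
    cds_end_t: int
    name: str = "transcript"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ModelError("at least one exon is required")
        prev_end = None
        for s, e in self.exons:
            if s < 0 or e <= s:
                raise ModelError(f"invalid exon interval ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ModelError("exons overlap or are unsorted")
            prev_end = e
        total = self.total_length
        if not (0 <= self.cds_start_t < self.cds_end_t <= total):
            raise ModelError(
                f"CDS span ({self.cds_start_t}, {self.cds_end_t}) outside transcript "
                f"of length {total}"
            )
        if (self.cds_end_t - self.cds_start_t) % 3:
            raise ModelValidationError("CDS length is not divisible by 3")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_transcript_order(self) -> tuple[tuple[int, int], ...]:
        """Genomic exon intervals listed 5'->3' along the transcript."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def exon_t_spans(self) -> list[tuple[int, int]]:
        """Transcript-coordinate interval of each exon (transcript order)."""
        spans = []
        off = 0
        for s, e in self.exons_transcript_order():
            spans.append((off, off + (e - s)))
            off += e - s
        return spans

    def genomic_exon_index(self, t_index: int) -> int:
        """Map a transcript-order exon index to the genomic (ascending) index."""
        return t_index if self.strand == "+" else self.n_exons - 1 - t_index

    def intron(self, t_index: int) -> tuple[int, int]:
        """Genomic interval of the intron following exon ``t_index`` (transcript order)."""
        g = self.genomic_exon_index(t_index)
        if self.strand == "+":
            if g + 1 >= self.n_exons:
                raise ModelError("no intron after the last exon")
            return (self.exons[g][1], self.exons[g + 1][0])
        if g - 1 < 0:
            raise ModelError("no intron after the last exon")
        return (self.exons[g - 1][1], self.exons[g][0])

    # -- coordinate conversion --------------------------------------------

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.total_length:
            raise ModelError(f"transcript position {tpos} out of range")
        off = tpos
        for s, e in self.exons_transcript_order():
            n = e - s
            if off < n:
                return s + off if self.strand == "+" else e - 1 - off
            off -= n
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, gpos: int) -> Optional[int]:
        """Transcript position of an exonic genomic base; None if intronic/outside."""
        off = 0
        for s, e in self.exons_transcript_order():
            if s <= gpos < e:
                return off + (gpos - s if self.strand == "+" else e - 1 - gpos)
            off += e - s
        return None

    def exon_index_at_transcript(self, tpos: int) -> int:
        for i, (ts, te) in enumerate(self.exon_t_spans()):
            if ts <= tpos < te:
                return i
        raise ModelError(f"transcript position {tpos} out of range")

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_bed12(cls, path: str) -> "TranscriptModel":
        """Read a single-line BED12 gene model.

        blockStarts/blockSizes define the exons, thickStart/thickEnd the CDS,
        and the strand column is honored.
        """
        with open(path) as fh:
            lines = [ln for ln in fh if ln.strip() and not ln.startswith(("#", "track"))]
        if len(lines) != 1:
            raise ModelError(f"expected exactly one BED12 line, found {len(lines)}")
        f = lines[0].rstrip("\n").split("\t")
        if len(f) < 12:
            raise ModelError("BED12 requires 12 columns")
        chrom, start = f[0], int(f[1])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = tuple((start + st, start + st + sz) for st, sz in zip(starts, sizes))
        model = cls(chrom, strand, exons, 0, 3, name=name)  # placeholder CDS
        cds_t = _cds_span_to_transcript(model, (thick_start, thick_end))
        return cls(chrom, strand, exons, cds_t[0], cds_t[1], name=name)

    def to_bed12(self, path: Optional[str] = None) -> str:
        start = self.exons[0][0]
        end = self.exons[-1][1]
        g_lo = self.transcript_to_genomic(self.cds_start_t)
        g_hi = self.transcript_to_genomic(self.cds_end_t - 1)
        thick_lo, thick_hi = min(g_lo, g_hi), max(g_lo, g_hi) + 1
        sizes = ",".join(str(e - s) for s, e in self.exons)
        starts = ",".join(str(s - start) for s, e in self.exons)
        line = "\t".join(
            [
                self.reference_name,
                str(start),
                str(end),
                self.name,
                "0",
                self.strand,
                str(thick_lo),
                str(thick_hi),
                "0",
                str(self.n_exons),
                sizes,
                starts,
            ]
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(line + "\n")
        return line


def _cds_span_to_transcript(
    model: TranscriptModel, cds_span_genomic: tuple[int, int]
) -> tuple[int, int]:
    g_lo, g_hi = cds_span_genomic
    t_a = model.genomic_to_transcript(g_lo)
    t_b = model.genomic_to_transcript(g_hi - 1)
    if t_a is None or t_b is None:
        raise ModelError("CDS span does not fall inside the exons")
    lo, hi = min(t_a, t_b), max(t_a, t_b) + 1
    return lo, hi


def exonic_sequence(model: TranscriptModel, reference: ReferenceSeq) -> str:
    """Concatenated exon sequence, 5'->3' (reverse-complemented on '-')."""
    parts = [reference.sequence[s:e] for s, e in model.exons]
    seq = "".join(parts)
    return seq if model.strand == "+" else revcomp(seq)


def build_transcript(
    reference: ReferenceSeq,
    exons: Sequence[tuple[int, int]],
    strand: str,
    cds_span_genomic: tuple[int, int],
    name: str = "transcript",
) -> TranscriptModel:
    """Construct and validate a :class:`TranscriptModel`.

    Raises :class:`ModelError` for overlapping/out-of-bounds exons and
    :class:`ModelValidationError` when the CDS does not begin with ATG, does
    not end in a stop codon, or contains N bases.
    """
    exons = tuple(sorted((int(s), int(e)) for s, e in exons))
    for s, e in exons:
        if e > len(reference):
            raise ModelError(f"exon ({s}, {e}) outside reference of length {len(reference)}")
    probe = TranscriptModel(reference.name, strand, exons, 0, 3, name=name)
    cds_start_t, cds_end_t = _cds_span_to_transcript(probe, cds_span_genomic)
    model = TranscriptModel(reference.name, strand, exons, cds_start_t, cds_end_t, name=name)
    cds = exonic_sequence(model, reference)[cds_start_t:cds_end_t]
    if "N" in cds:
        raise ModelValidationError("CDS contains N bases; translation would be ambiguous")
    if cds[:3] != START_CODON:
        raise ModelValidationError(f"CDS does not start with ATG (found {cds[:3]})")
    if cds[-3:] not in STOP_CODONS:
        raise ModelValidationError(f"CDS does not end in a stop codon (found {cds[-3:]})")
    for i in range(3, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            raise ModelValidationError(
                f"internal in-frame stop at codon {i // 3 + 1} of the canonical CDS"
            )
    return model


# ---------------------------------------------------------------------------
# Splice events


@dataclass(frozen=True)
class SpliceEvent:
    """A deviation from the canonical junction chain.

    kind
        one of ``exon_skip``, ``cryptic_donor``, ``cryptic_acceptor``,
        ``intron_retention``.
    exon_index
        transcript-order exon index (0-based).  For ``intron_retention`` this
        is the exon *preceding* the retained intron.
    length_delta
        for cryptic sites: the signed change in exon length (positive extends
        into the intron, negative truncates the exon).  For retention: the
        retained length in nt, or None for the full intron.  Ignored for
        ``exon_skip``.
    """

    kind: str
    exon_index: int
    length_delta: Optional[int] = None

    _KINDS = ("exon_skip", "cryptic_donor", "cryptic_acceptor", "intron_retention")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown splice event kind {self.kind!r}")
        if self.kind in ("cryptic_donor", "cryptic_acceptor"):
            if not self.length_delta:
                raise ValueError(f"{self.kind} requires a nonzero length_delta")

    def resolved_length(self, model: TranscriptModel) -> int:
        """Signed transcript-length change caused by this event."""
        if self.kind == "exon_skip":
            ts, te = model.exon_t_spans()[self.exon_index]
            return -(te - ts)
        if self.kind == "intron_retention":
            lo, hi = model.intron(self.exon_index)
            length = hi - lo if self.length_delta is None else self.length_delta
            if length < 0 or length > hi - lo:
                raise ValueError(f"retention length {length} exceeds intron length {hi - lo}")
            return length
        return int(self.length_delta)  # cryptic sites

    def anchor_t(self, model: TranscriptModel) -> int:
        """Original transcript coordinate at which the length change applies."""
        ts, te = model.exon_t_spans()[self.exon_index]
        if self.kind in ("exon_skip", "cryptic_acceptor"):
            return ts
        return te  # donor side / retained intron insertion point

    def delta_cds(self, model: TranscriptModel) -> int:
        """Signed change in *coding* length (intersection with the CDS)."""
        cs, ce = model.cds_start_t, model.cds_end_t
        if self.kind == "exon_skip":
            ts, te = model.exon_t_spans()[self.exon_index]
            return -max(0, min(te, ce) - max(ts, cs))
        anchor = self.anchor_t(model)
        if cs <= anchor <= ce:
            return self.resolved_length(model)
        return 0

    def key(self) -> tuple:
        return (self.kind, self.exon_index, self.length_delta)


# ---------------------------------------------------------------------------
# Mature transcripts


@dataclass
class MatureTranscript:
    """A spliced (and possibly variant-edited) transcript sequence.

    ``canonical_stop_t`` is the position, in *this* sequence, where the first
    base of the canonical terminal codon now sits (None if removed by an
    event).  ``scan_for_ptc`` compares translated stop positions against it.
    """

    sequence: str
    cds_start_t: int
    canonical_stop_t: Optional[int]
    provenance: tuple = ()
    variant_removed: bool = False
    variant_applied: bool = False


def _edited_intervals(
    model: TranscriptModel, events: Sequence[SpliceEvent]
) -> list[tuple[int, int]]:
    """Apply splice events to the genomic exon list; return surviving intervals."""
    intervals: list[Optional[list[int]]] = [list(x) for x in model.exons]
    merges: list[tuple[int, int]] = []
    for ev in events:
        g = model.genomic_exon_index(ev.exon_index)
        if ev.kind == "exon_skip":
            if intervals[g] is None:
                raise EventConflictError(f"exon {ev.exon_index} edited twice")
            intervals[g] = None
        elif ev.kind == "cryptic_donor":
            iv = intervals[g]
            if iv is None:
                raise EventConflictError("cryptic donor on a skipped exon")
            if model.strand == "+":
                iv[1] += ev.length_delta
            else:
                iv[0] -= ev.length_delta
        elif ev.kind == "cryptic_acceptor":
            iv = intervals[g]
            if iv is None:
                raise EventConflictError("cryptic acceptor on a skipped exon")
            if model.strand == "+":
                iv[0] -= ev.length_delta
            else:
                iv[1] += ev.length_delta
        elif ev.kind == "intron_retention":
            length = ev.resolved_length(model)
            lo, hi = model.intron(ev.exon_index)
            full = length == hi - lo
            iv = intervals[g]
            if iv is None:
                raise EventConflictError("retention next to a skipped exon")
            if model.strand == "+":
                iv[1] += length
                if full:
                    merges.append((g, g + 1))
            else:
                iv[0] -= length
                if full:
                    merges.append((g - 1, g))
    for a, b in merges:
        if intervals[a] is None or intervals[b] is None:
            raise EventConflictError("full retention next to a skipped exon")
        intervals[a] = [intervals[a][0], intervals[b][1]]
        intervals[b] = None
    out = [tuple(iv) for iv in intervals if iv is not None]
    prev = None
    for s, e in out:
        if e <= s or (prev is not None and s < prev):
            raise EventConflictError("splice events produce overlapping or empty intervals")
        prev = e
    return out


def mature_sequence(
    model: TranscriptModel,
    reference: ReferenceSeq,
    events: Sequence[SpliceEvent] = (),
    variant=None,
) -> MatureTranscript:
    """Build the mature transcript implied by a set of splice events and a variant.

    Events are applied first (exon removal, boundary shifts, retained-intron
    insertion), then the variant's edit is applied if its CDS position
    survived the events; otherwise ``variant_removed`` is flagged.  Intronic
    variants (``intron_offset`` set) never edit the mature sequence — their
    effect is carried by the splice events they cause.
    """
    intervals = _edited_intervals(model, events)
    parts = [reference.sequence[s:e] for s, e in intervals]
    seq = "".join(parts)
    if model.strand == "-":
        seq = revcomp(seq)

    shifts = [(ev.anchor_t(model), ev.resolved_length(model), ev) for ev in events]
    removed_spans: list[tuple[int, int]] = []
    for ev in events:
        if ev.kind == "exon_skip":
            removed_spans.append(model.exon_t_spans()[ev.exon_index])
        elif ev.kind in ("cryptic_donor", "cryptic_acceptor") and ev.length_delta < 0:
            ts, te = model.exon_t_spans()[ev.exon_index]
            if ev.kind == "cryptic_donor":
                removed_spans.append((te + ev.length_delta, te))
            else:
                removed_spans.append((ts, ts - ev.length_delta))

    def shift_pos(p: int) -> Optional[int]:
        """Map an original transcript position into the edited sequence."""
        for lo, hi in removed_spans:
            if lo <= p < hi:
                return None
        new = p
        for anchor, delta, ev in shifts:
            if ev.kind in ("exon_skip", "cryptic_acceptor"):
                if anchor <= p:
                    new += delta
            else:  # donor-side edits and retention apply strictly before p
                if anchor <= p:
                    new += delta
        return new

    cds_start = shift_pos(model.cds_start_t)
    if cds_start is None:
        cds_start = 0  # CDS start removed: translate from transcript start
    canonical_stop = shift_pos(model.cds_end_t - 3)

    variant_removed = False
    variant_applied = False
    if variant is not None and getattr(variant, "intron_offset", None) is None:
        tv_orig = model.cds_start_t + variant.cds_pos - 1
        tv = shift_pos(tv_orig)
        if tv is None:
            variant_removed = True
        else:
            seq, stop_shift = _apply_variant_edit(seq, tv, variant)
            variant_applied = True
            if canonical_stop is not None and tv < canonical_stop:
                canonical_stop += stop_shift
    return MatureTranscript(
        sequence=seq,
        cds_start_t=cds_start,
        canonical_stop_t=canonical_stop,
        provenance=tuple(events) + ((variant,) if variant is not None else ()),
        variant_removed=variant_removed,
        variant_applied=variant_applied,
    )


def _apply_variant_edit(seq: str, tv: int, variant) -> tuple[str, int]:
    """Apply a small exonic edit at transcript position ``tv``; return (seq, delta)."""
    kind = variant.kind
    span = variant.span_length
    if kind == "SNV":
        return seq[:tv] + variant.alt_allele + seq[tv + 1 :], 0
    if kind == "deletion":
        return seq[:tv] + seq[tv + span :], -span
    if kind == "duplication":
        dup = seq[tv : tv + span]
        return seq[: tv + span] + dup + seq[tv + span :], span
    if kind == "insertion":
        return seq[: tv + 1] + variant.alt_allele + seq[tv + 1 :], len(variant.alt_allele)
    raise ValueError(f"cannot apply variant kind {kind!r}")


# ---------------------------------------------------------------------------
# Translation scan


@dataclass(frozen=True)
class PtcScan:
    """Result of translating a mature transcript from its CDS start."""

    ptc_codon: Optional[int]  # 1-based codon index of the first premature stop
    nonstop: bool  # translation ran off the 3' end without any stop
    stop_t: Optional[int]  # sequence position of the stop that terminated translation


def ptc_scan(mature: MatureTranscript) -> PtcScan:
    seq = mature.sequence
    start = mature.cds_start_t
    if len(seq) - start < 3:
        raise DegenerateTranscriptError("CDS shorter than one codon after edits")
    canonical = mature.canonical_stop_t
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            if canonical is not None and i >= canonical:
                return PtcScan(None, False, i)
            if canonical is None and i >= len(seq) - 3:
                return PtcScan(None, False, i)  # stop in the final codon position
            return PtcScan((i - start) // 3 + 1, False, i)
    return PtcScan(None, True, None)


def scan_for_ptc(mature: MatureTranscript) -> Optional[int]:
    """1-based codon index of the first premature stop, or None.

    None covers both the canonical outcome (translation reaches the canonical
    terminal codon) and the nonstop outcome (no stop before the 3' end); use
    :func:`ptc_scan` to distinguish them.
    """
    return ptc_scan(mature).ptc_codon


def frame_delta(
    model: TranscriptModel,
    events: Sequence[SpliceEvent] = (),
    variant=None,
) -> tuple[int, bool]:
    """Net signed coding-length change of events + variant, and whether it is in frame."""
    delta = sum(ev.delta_cds(model) for ev in events)
    if variant is not None and getattr(variant, "intron_offset", None) is None:
        delta += variant.cds_length_delta
    return delta, delta % 3 == 0
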