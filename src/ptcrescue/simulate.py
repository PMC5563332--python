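"""Synthetic loci, planted mutations, amplicon cDNA reads, and cohort tables.

The read simulator implements an explicit generative model for amplicon cDNA
sequencing of a heterozygous PTC-mutation carrier:

* each sequenced molecule derives from the wild-type allele with probability
  ``wt_allele_share`` (default 0.5, balanced allelic expression);
* a mutant-allele molecule uses rescue isoform *k* with probability ``r_k``
  (frame-restoring alternative splicing), otherwise it is the PTC-bearing
  canonical-splice isoform, which survives nonsense-mediated decay with
  probability ``1 - nmd_efficiency``;
* wild-type molecules always survive; surviving molecules are sampled
  uniformly to ``n_reads``;
* each read's sequence is the implied mature amplicon with per-base
  substitution/insertion/deletion errors (defaults 0.05/0.03/0.05, an
  order-of-magnitude match to early nanopore base-calling error).

The expected PTC expression fraction under this model is

    f = (1 - R)(1 - e) m / ((1 - R)(1 - e) m + w)

with m = 1 - wt_allele_share, w = wt_allele_share, e = nmd_efficiency and
R = sum of rescue proportions; it is recorded in the output metadata.

Truth alignments (blocks + N gaps, with the planted errors encoded in the
CIGAR) are emitted directly, so no external spliced aligner is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gene_model import (
    STOP_CODONS,
    MatureTranscript,
    ReferenceSeq,
    SpliceEvent,
    TranscriptModel,
    _edited_intervals,
    build_transcript,
    mature_sequence,
    ptc_scan,
    revcomp,
)
from .hgvs import Variant, parse_chgvs
from .isoform import AlignedRead, Segment

__all__ = [
    "SimConfig",
    "RescueIsoform",
    "SimResult",
    "make_toy_locus",
    "plant_variant",
    "simulate_amplicon_reads",
    "simulate_cohort",
    "nmd_efficiency_for_fraction",
    "expected_ptc_fraction",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one amplicon sequencing simulation."""

    seed: int
    n_reads: int = 2000
    nmd_efficiency: float = 0.0
    wt_allele_share: float = 0.5
    p_sub: float = 0.05
    p_ins: float = 0.03
    p_del: float = 0.05
    wt_rescue_proportion: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nmd_efficiency", "wt_allele_share", "p_sub", "p_ins", "p_del",
                     "wt_rescue_proportion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_reads < 1:
            raise SimConfigError("n_reads must be >= 1")


@dataclass(frozen=True)
class RescueIsoform:
    """A frame-restoring alternative-splicing isoform with its usage proportion."""

    name: str
    events: tuple[SpliceEvent, ...]
    proportion: float

    def __post_init__(self) -> None:
        if not 0 <= self.proportion <= 1:
            raise SimConfigError("rescue proportion must be in [0, 1]")


# ---------------------------------------------------------------------------
# Toy locus


def make_toy_locus(
    seed: int,
    exon_lengths: Sequence[int] = (30, 168, 45, 255, 33),
    intron_lengths: Sequence[int] = (90, 85, 100, 95),
    strand: str = "+",
    flank: int = 50,
    name: str = "toylocus",
) -> tuple[ReferenceSeq, TranscriptModel]:
    """Generate a random single-transcript locus with a clean ORF.

    The CDS covers all exons: it starts with ATG, ends with a stop codon, and
    contains no internal in-frame stop (codons are drawn uniformly from the 61
    sense codons, so no rejection sampling is needed).  Introns start with GT
    and end with AG, and carry an early in-frame stop in the frame a retained
    intron would be read in, mirroring the fact that retained intronic
    sequence almost always truncates the reading frame quickly.

    Default exon sizes echo commonly skipped coding exons of the system this
    package models (including 168, 255, and 33 nt exons).  Total exon length
    must be divisible by 3 and at least 6 (start + stop codon).
    """
    exon_lengths = tuple(int(x) for x in exon_lengths)
    intron_lengths = tuple(int(x) for x in intron_lengths)
    if len(intron_lengths) != len(exon_lengths) - 1:
        raise SimConfigError("need exactly one intron length per internal junction")
    if any(x < 1 for x in exon_lengths) or any(x < 12 for x in intron_lengths):
        raise SimConfigError("exon lengths must be >= 1 and intron lengths >= 12")
    total = sum(exon_lengths)
    if total % 3 or total < 6:
        raise SimConfigError("total CDS length must be >= 6 and divisible by 3")

    rng = np.random.default_rng(seed)
    n_codons = total // 3
    codons = ["ATG"]
    codons += list(rng.choice(_NON_STOP_CODONS, size=n_codons - 2))
    codons.append(str(rng.choice(("TAA", "TAG", "TGA"))))
    cds = "".join(codons)

    # split the CDS across exons and interleave introns
    pieces = []
    pos = 0
    cut = 0
    exon_bounds = []
    cursor = flank
    frame_offset = 0
    introns = []
    for i, L in enumerate(exon_lengths):
        exon_seq = cds[cut : cut + L]
        cut += L
        exon_bounds.append((cursor, cursor + L))
        pieces.append(exon_seq)
        cursor += L
        frame_offset = (frame_offset + L) % 3
        if i < len(intron_lengths):
            iln = intron_lengths[i]
            body = "".join(rng.choice(_BASES, size=iln - 4))
            intron = "GT" + body + "AG"
            # plant an in-frame stop early in the retained-intron frame:
            # the next codon boundary after the GT dinucleotide
            stop_at = (3 - frame_offset) % 3 + 3
            intron = intron[:stop_at] + "TAA" + intron[stop_at + 3 :]
            pieces.append(intron)
            introns.append(intron)
            cursor += iln
    left = "".join(rng.choice(_BASES, size=flank))
    right = "".join(rng.choice(_BASES, size=flank))
    genome_plus = left + "".join(pieces) + right

    if strand == "+":
        ref = ReferenceSeq(name, genome_plus)
        exons = exon_bounds
    else:
        glen = len(genome_plus)
        ref = ReferenceSeq(name, revcomp(genome_plus))
        exons = sorted((glen - e, glen - s) for s, e in exon_bounds)
    cds_lo = min(s for s, _ in exons) if strand == "-" else exon_bounds[0][0]
    # genomic CDS span covers all exons
    g_lo = exons[0][0]
    g_hi = exons[-1][1]
    model = build_transcript(ref, exons, strand, (g_lo, g_hi), name=name + "_tx")
    return ref, model


# ---------------------------------------------------------------------------
# Variant planting


def plant_variant(
    model: TranscriptModel,
    reference: ReferenceSeq,
    kind: str,
    exon_index: int,
    span: int = 7,
    offset_in_exon: Optional[int] = None,
    alt_rule: str = "first",
) -> Variant:
    """Plant a mutation of the requested class in the given exon.

    kind: ``nonsense`` (single substitution creating a stop), ``frameshift_del``
    / ``frameshift_dup`` (span % 3 != 0), ``inframe_del`` (span % 3 == 0),
    ``splice_donor`` / ``splice_acceptor`` (the canonical GT/AG dinucleotide).
    Returns the variant with its coding-HGVS string.
    """
    cds = _canonical_cds(model, reference)
    spans = model.exon_t_spans()
    ts, te = spans[exon_index]
    cs = model.cds_start_t

    if kind == "nonsense":
        first_codon = max(1, (ts - cs) // 3 + 2)
        last_codon = (te - cs) // 3 - 1
        for ci in range(first_codon, last_codon + 1):
            lo = 3 * (ci - 1)
            codon = cds[lo : lo + 3]
            for j in range(3):
                for b in "ACGT":
                    if b == codon[j]:
                        continue
                    mutant = codon[:j] + b + codon[j + 1 :]
                    if mutant in STOP_CODONS:
                        cds_pos = lo + j + 1
                        return parse_chgvs(
                            f"c.{cds_pos}{codon[j]}>{b}",
                            protein_label=f"p.X{ci}*",
                        )
        raise SimConfigError(f"no nonsense-capable codon inside exon {exon_index}")

    if kind in ("frameshift_del", "frameshift_dup", "inframe_del"):
        want_frameshift = kind != "inframe_del"
        if (span % 3 != 0) != want_frameshift:
            raise SimConfigError(f"span {span} inconsistent with {kind}")
        if offset_in_exon is None:
            offset_in_exon = max(0, (te - ts) // 2 - span)
        t0 = ts + offset_in_exon
        if t0 + span > te:
            raise SimConfigError("variant span does not fit in the exon")
        cds_pos = t0 - cs + 1
        seq = cds[cds_pos - 1 : cds_pos - 1 + span]
        op = "del" if kind.endswith("del") else "dup"
        pos = f"{cds_pos}" if span == 1 else f"{cds_pos}_{cds_pos + span - 1}"
        return parse_chgvs(f"c.{pos}{op}{seq}")

    if kind in ("splice_donor", "splice_acceptor"):
        if kind == "splice_donor":
            anchor = spans[exon_index][1] - cs  # last CDS base of the exon (1-based)
            return parse_chgvs(f"c.{anchor}+1G>T")
        anchor = spans[exon_index][0] - cs + 1  # first CDS base of the exon
        return parse_chgvs(f"c.{anchor}-1G>A")

    raise SimConfigError(f"unknown variant kind {kind!r}")


def _canonical_cds(model: TranscriptModel, reference: ReferenceSeq) -> str:
    mt = mature_sequence(model, reference)
    return mt.sequence[model.cds_start_t : model.cds_end_t]


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class TruthRecord:
    read_id: str
    source_allele: str  # WT | MUT
    source_isoform: str  # canonical | rescue_<name> | aberrant
    expected_class: str  # WT | PTC | RESCUE | OTHER


@dataclass
class SimResult:
    reads: list[AlignedRead]
    truth: pd.DataFrame
    config: SimConfig
    reference: ReferenceSeq
    model: TranscriptModel
    variant: Variant
    expected_ptc_fraction: float
    rescue_isoforms: tuple[RescueIsoform, ...] = ()

    def metadata(self) -> dict:
        return {
            "config": asdict(self.config),
            "variant": self.variant.raw,
            "rescue_isoforms": [
                {"name": r.name, "proportion": r.proportion,
                 "events": [e.key() for e in r.events]}
                for r in self.rescue_isoforms
            ],
            "expected_ptc_fraction": self.expected_ptc_fraction,
            "n_reads": len(self.reads),
        }

    # -- writers -----------------------------------------------------------

    def write_fastq(self, path: str) -> None:
        with open(path, "w") as fh:
            for read in self.reads:
                seq = read.query_sequence()
                fh.write(f"@{read.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_sam(self, path: str) -> None:
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": self.reference.name, "LN": len(self.reference)}],
        }
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for read in self.reads:
                a = pysam.AlignedSegment(out.header)
                a.query_name = read.read_id
                a.reference_name = self.reference.name
                a.reference_start = read.segments[0].gstart
                a.mapping_quality = 60
                a.flag = 0
                ops = []
                opcode = {"M": 0, "I": 1, "D": 2}
                for i, seg in enumerate(read.segments):
                    if i:
                        gap = seg.gstart - read.segments[i - 1].gend
                        ops.append((3, gap))
                    ops.extend((opcode[op], n) for op, n in seg.cigar)
                a.cigartuples = ops
                seq = read.query_sequence()
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                out.write(a)

    def write_truth_tsv(self, path: str) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_metadata_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)
            fh.write("\n")


def expected_ptc_fraction(config: SimConfig, rescue_total: float = 0.0) -> float:
    """Expected PTC expression fraction under the generative model."""
    m = 1.0 - config.wt_allele_share
    w = config.wt_allele_share
    surviving_ptc = (1.0 - rescue_total) * (1.0 - config.nmd_efficiency) * m
    denom = surviving_ptc + w
    if denom == 0:
        raise SimConfigError("no surviving transcripts (empty pool)")
    return surviving_ptc / denom


def nmd_efficiency_for_fraction(
    f: float, wt_allele_share: float = 0.5, rescue_total: float = 0.0
) -> float:
    """NMD efficiency that yields expected PTC fraction ``f``."""
    if not 0 <= f < 1:
        raise SimConfigError("target fraction must be in [0, 1)")
    m = 1.0 - wt_allele_share
    w = wt_allele_share
    surviving = f * w / (1.0 - f)
    e = 1.0 - surviving / ((1.0 - rescue_total) * m)
    if not 0.0 <= e <= 1.0:
        raise SimConfigError(f"fraction {f} not reachable with these parameters")
    return e


def _template_segments(
    model: TranscriptModel,
    reference: ReferenceSeq,
    events: Sequence[SpliceEvent],
    variant: Optional[Variant],
) -> list[tuple[int, int, list[tuple[str, int]], str]]:
    """Error-free alignment template (per-block cigar + query) for one isoform."""
    if model.strand != "+":
        raise SimConfigError("read simulation supports plus-strand models")
    intervals = _edited_intervals(model, events)
    blocks = [
        [s, e, [("M", e - s)], reference.sequence[s:e]] for s, e in intervals
    ]
    mt = mature_sequence(model, reference, events, variant)
    if variant is not None and variant.intron_offset is None and not mt.variant_removed:
        g_lo = None
        t0 = model.cds_start_t + variant.cds_pos - 1
        gpos = model.transcript_to_genomic(t0)
        for blk in blocks:
            if blk[0] <= gpos < blk[1]:
                off = gpos - blk[0]
                q = blk[3]
                span = variant.span_length
                if variant.kind == "SNV":
                    blk[3] = q[:off] + variant.alt_allele + q[off + 1 :]
                elif variant.kind == "deletion":
                    blk[3] = q[:off] + q[off + span :]
                    blk[2] = [("M", off), ("D", span), ("M", blk[1] - blk[0] - off - span)]
                elif variant.kind == "duplication":
                    blk[3] = q[: off + span] + q[off : off + span] + q[off + span :]
                    blk[2] = [("M", off + span), ("I", span),
                              ("M", blk[1] - blk[0] - off - span)]
                elif variant.kind == "insertion":
                    blk[3] = q[: off + 1] + variant.alt_allele + q[off + 1 :]
                    blk[2] = [("M", off + 1), ("I", len(variant.alt_allele)),
                              ("M", blk[1] - blk[0] - off - 1)]
                break
        else:
            raise SimConfigError("variant site not inside any template block")
    return [(b[0], b[1], b[2], b[3]) for b in blocks]


def _apply_errors(
    template: Sequence[tuple[int, int, list[tuple[str, int]], str]],
    rng: np.random.Generator,
    p_sub: float,
    p_ins: float,
    p_del: float,
) -> list[Segment]:
    """Plant random substitution/insertion/deletion errors into a template.

    Error positions are known, so the emitted CIGAR is the exact alignment of
    the errorful read (M for matches and substitutions, I/D for error indels,
    on top of the template's own variant ops).
    """
    if p_sub == 0 and p_ins == 0 and p_del == 0:
        return [
            Segment(gstart, gend, tuple(cigar), query)
            for gstart, gend, cigar, query in template
        ]
    segments = []
    for gstart, gend, cigar, query in template:
        # per-column representation: (consumes_ref, query_base or None)
        out_ops: list[tuple[str, int]] = []
        out_query: list[str] = []

        def emit(op: str, n: int = 1) -> None:
            if out_ops and out_ops[-1][0] == op:
                out_ops[-1] = (op, out_ops[-1][1] + n)
            else:
                out_ops.append((op, n))

        qlen = len(query)
        subs = rng.random(qlen) < p_sub
        dels = rng.random(qlen) < p_del
        inss = rng.random(qlen) < p_ins
        subbase = rng.integers(0, 3, size=qlen)
        insbase = rng.integers(0, 4, size=qlen)
        qi = 0
        for op, n in cigar:
            if op == "D":
                emit("D", n)
                continue
            for _ in range(n):
                base = query[qi]
                if dels[qi]:
                    if op == "M":
                        emit("D")
                    # deleted inserted base: vanishes entirely
                else:
                    if subs[qi]:
                        others = [b for b in "ACGT" if b != base]
                        base = others[subbase[qi]]
                    emit(op)
                    out_query.append(base)
                if inss[qi]:
                    emit("I")
                    out_query.append("ACGT"[insbase[qi]])
                qi += 1
        segments.append(Segment(gstart, gend, tuple(out_ops), "".join(out_query)))
    return segments


def simulate_amplicon_reads(
    model: TranscriptModel,
    reference: ReferenceSeq,
    variant: Variant,
    rescue_isoforms: Sequence[RescueIsoform],
    config: SimConfig,
    splice_variant_events: Sequence[SpliceEvent] = (),
) -> SimResult:
    """Simulate amplicon cDNA reads for a heterozygous mutation carrier.

    ``rescue_isoforms`` lists frame-restoring isoforms of the mutant allele;
    at template-build time each is verified (by translation) to carry no
    premature stop, and the PTC isoform is verified to carry one.  For a
    canonical-splice variant, ``splice_variant_events`` describes the aberrant
    splicing outcome of the mutant allele (e.g. an out-of-frame exon skip),
    since an intronic base change cannot appear in the mature cDNA itself.
    """
    rescue_isoforms = tuple(rescue_isoforms)
    R = sum(r.proportion for r in rescue_isoforms)
    if R > 1:
        raise SimConfigError("rescue proportions sum to more than 1")
    e = config.nmd_efficiency
    w = config.wt_allele_share
    m = 1.0 - w
    if m * ((1 - R) * (1 - e) + R) + w == 0:
        raise SimConfigError("no surviving transcripts (empty pool)")

    rng = np.random.default_rng(config.seed)

    wt_template = _template_segments(model, reference, (), None)
    if variant.intron_offset is None:
        ptc_template = _template_segments(model, reference, (), variant)
        ptc_mt = mature_sequence(model, reference, (), variant)
    else:
        if not splice_variant_events:
            raise SimConfigError(
                "canonical-splice variants need splice_variant_events"
            )
        ptc_template = _template_segments(
            model, reference, tuple(splice_variant_events), None
        )
        ptc_mt = mature_sequence(model, reference, tuple(splice_variant_events), None)
    if ptc_scan(ptc_mt).ptc_codon is None:
        raise SimConfigError(
            "the mutant isoform carries no premature stop; nothing to degrade"
        )
    rescue_templates = []
    for iso in rescue_isoforms:
        mt = mature_sequence(model, reference, iso.events,
                             variant if variant.intron_offset is None else None)
        scan = ptc_scan(mt)
        if scan.ptc_codon is not None or scan.nonstop:
            raise SimConfigError(
                f"rescue isoform {iso.name!r} does not restore an open frame"
            )
        rescue_templates.append(
            _template_segments(model, reference, iso.events,
                               variant if variant.intron_offset is None else None)
        )

    # conditional isoform distribution among surviving molecules
    choices = [("WT", "canonical", wt_template, w)]
    choices.append(("MUT", "canonical", ptc_template, m * (1 - R) * (1 - e)))
    for iso, tpl in zip(rescue_isoforms, rescue_templates):
        choices.append(("MUT", f"rescue_{iso.name}", tpl, m * iso.proportion))
    weights = np.array([c[3] for c in choices])
    total_weight = weights.sum()
    if total_weight <= 0:
        raise SimConfigError("no surviving transcripts (empty pool)")
    probs = weights / total_weight

    expected = expected_ptc_fraction(config, rescue_total=R)
    draw = rng.choice(len(choices), size=config.n_reads, p=probs)

    reads: list[AlignedRead] = []
    truth_rows = []
    for i, ci in enumerate(draw):
        allele, isoform, template, _ = choices[ci]
        read_id = f"read{i:06d}"
        segs = _apply_errors(template, rng, config.p_sub, config.p_ins, config.p_del)
        reads.append(AlignedRead(read_id, reference.name, tuple(segs)))
        expected_class = (
            "WT" if allele == "WT" else ("PTC" if isoform == "canonical" else "RESCUE")
        )
        truth_rows.append(
            (read_id, allele, isoform, expected_class)
        )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "source_allele", "source_isoform", "expected_class"]
    )
    return SimResult(
        reads=reads,
        truth=truth,
        config=config,
        reference=reference,
        model=model,
        variant=variant,
        expected_ptc_fraction=expected,
        rescue_isoforms=rescue_isoforms,
    )


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_cohort(
    strata: Sequence[dict],
    carrier_freq_pat: float,
    carrier_freq_ctl: float,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-individual carrier status stratified by country.

    Each stratum dict has ``label``, ``n_pat``, ``n_ctl``.  Carrier status is
    an independent Bernoulli draw per individual.  Returns the per-individual
    table (id, cohort, stratum, carrier) and metadata with the implied true
    odds ratio.
    """
    if not 0 <= carrier_freq_pat <= 1 or not 0 <= carrier_freq_ctl <= 1:
        raise SimConfigError("carrier frequencies must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for st in strata:
        label = st["label"]
        for i in range(int(st["n_pat"])):
            rows.append(
                (f"{label}_pat{i:05d}", "patient", label,
                 int(rng.random() < carrier_freq_pat))
            )
        for i in range(int(st["n_ctl"])):
            rows.append(
                (f"{label}_ctl{i:05d}", "control", label,
                 int(rng.random() < carrier_freq_ctl))
            )
    df = pd.DataFrame(rows, columns=["id", "cohort", "stratum", "carrier"])
    if 0 < carrier_freq_ctl < 1 and 0 < carrier_freq_pat < 1:
        true_or = (carrier_freq_pat / (1 - carrier_freq_pat)) / (
            carrier_freq_ctl / (1 - carrier_freq_ctl)
        )
    else:
        true_or = float("inf") if carrier_freq_pat > 0 else 0.0
    meta = {
        "seed": seed,
        "carrier_freq_pat": carrier_freq_pat,
        "carrier_freq_ctl": carrier_freq_ctl,
        "true_or": true_or,
    }
    return df, meta
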