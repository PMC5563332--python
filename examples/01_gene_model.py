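"""Build a toy single-transcript locus and inspect its coordinate system.

Generates a random 5-exon gene with a clean open reading frame, converts
between genomic and transcript coordinates, and shows what an exon skip does
to the mature transcript and its translation.
"""

from ptcrescue.gene_model import SpliceEvent, mature_sequence, scan_for_ptc
from ptcrescue.simulate import make_toy_locus

ref, model = make_toy_locus(seed=1)
print(f"locus: {len(ref)} nt, {model.n_exons} exons on '{model.strand}'")
print(f"exons (genomic): {model.exons}")
print(f"CDS (transcript coords): [{model.cds_start_t}, {model.cds_end_t})")

g = model.transcript_to_genomic(100)
print(f"transcript position 100 -> genomic {g} -> back {model.genomic_to_transcript(g)}")

canonical = mature_sequence(model, ref)
print(f"canonical mature transcript: {len(canonical.sequence)} nt, "
      f"premature stop: {scan_for_ptc(canonical)}")

# skipping the 255-nt exon keeps the frame (255 % 3 == 0) and the ORF stays open
skipped = mature_sequence(model, ref, (SpliceEvent("exon_skip", 3),))
print(f"after skipping exon 3 (255 nt): {len(skipped.sequence)} nt, "
      f"premature stop: {scan_for_ptc(skipped)}")

# retaining an intron pushes intronic sequence into the reading frame
retained = mature_sequence(model, ref, (SpliceEvent("intron_retention", 2),))
print(f"after retaining intron 2: {len(retained.sequence)} nt, "
      f"premature stop at codon {scan_for_ptc(retained)}")
print("-> an in-frame skip is silent at the protein level; retention truncates.")
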