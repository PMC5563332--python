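"""Quantify NMD escape from simulated long-read amplicon cDNA.

Simulates 5000 nanopore-error reads from a heterozygous nonsense-mutation
carrier at a chosen NMD efficiency, classifies every read (allele + splice
events + implied transcript), and reports the PTC expression fraction:
0% = complete decay of the mutant transcript, 50% = no decay.
"""

from ptcrescue.isoform import classify_reads, quantify
from ptcrescue.simulate import (
    SimConfig,
    make_toy_locus,
    nmd_efficiency_for_fraction,
    plant_variant,
    simulate_amplicon_reads,
)

ref, model = make_toy_locus(seed=1)
variant = plant_variant(model, ref, "nonsense", exon_index=2)
print(f"planted nonsense mutation: {variant.raw}")

for target in (0.50, 0.41, 0.21, 0.05):
    e = nmd_efficiency_for_fraction(target)
    sim = simulate_amplicon_reads(
        model, ref, variant, (),
        SimConfig(seed=7, n_reads=5000, nmd_efficiency=e),
    )
    q = quantify(classify_reads(sim.reads, model, ref, variant))
    print(
        f"NMD efficiency {e:.3f}: expected PTC fraction {target:.0%}, "
        f"estimated {q.ptc_expression_fraction:.1%} "
        f"({q.n_ptc} PTC / {q.n_wt} WT reads, {q.n_other} other)"
    )
print("-> the estimate tracks the generative truth to within sampling noise "
      "plus a small base-calling misvote floor.")
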