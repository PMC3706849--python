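"""Consensus genotyping across runs: depth resolves conflicting calls.

Two published conflicts drive the example: a warfarin-sensitivity site where
a 2-read whole-genome call said homozygous but 65 exome reads say
heterozygous, and a site where a 3-read homozygous call dissolves into a
heterozygote across four deeper runs. Shallow runs are set aside when deep
runs agree; disagreement among adequate runs pools their read counts.
"""

import concordx as cx
from concordx.casedata import CYP2C9_EVIDENCE, NHLRC1_EVIDENCE

for name, evidence in (("CYP2C9 p.Arg144Cys", CYP2C9_EVIDENCE), ("NHLRC1 p.P111L", NHLRC1_EVIDENCE)):
    print(name)
    for run in evidence.runs:
        gt = run.genotype or cx.assign_genotype(run.rr, run.vr)
        print(f"  {run.run_id:10s} rr={run.rr:<3d} vr={run.vr:<3d} depth={run.depth:<3d} -> {gt}")
    consensus = cx.resolve_site(evidence)
    print(
        f"  consensus: {consensus.genotype} via {consensus.rule} "
        f"(runs: {', '.join(consensus.supporting_runs)}; pooled rr:vr = "
        f"{consensus.pooled_counts[0]}:{consensus.pooled_counts[1]})\n"
    )

print("pooled re-call when adequate runs disagree:")
counts = [(9, 6), (9, 14), (9, 11)]
print(f"  {counts} -> pooled genotype {cx.pooled_recall(counts)} (27:31, vf 0.534)")
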