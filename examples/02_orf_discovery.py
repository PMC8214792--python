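"""ORF discovery: linear and circular search, uORF candidates.

Shows the search conventions: the stop codon is included in every reported
interval, only ORFs with a downstream in-frame stop are reported, and
circular search additionally reports ORFs wrapping the sequence origin.
"""

from riboflow import find_orfs, near_cognate_starts, uorf_candidates
from riboflow.simulate import make_genome

seq = "ATGATGAAATAACCCATG"
print(f"sequence: {seq}")
for o in find_orfs(seq, {"ATG"}, {"TAA", "TAG", "TGA"}):
    print(f"  linear ORF [{o.start}, {o.end}) width {o.width}")
for o in find_orfs(seq, {"ATG"}, {"TAA", "TAG", "TGA"}, circular=True):
    if o.wrapped:
        print(f"  wrapped ORF starting at {o.start}, width {o.width} (crosses the origin)")

print(f"near-cognate start set: {sorted(near_cognate_starts())}")

sim = make_genome(n_genes=10, plant_uorf_genes=3, seed=21)
uorfs, skipped = uorf_candidates(sim.annotation, sim.genome)
print(f"\n{len(uorfs)} uORF candidates in {len(sim.annotation.transcripts)} leaders "
      f"({skipped} transcripts without a leader)")
planted = sim.truth["planted_uorfs"]
hits = sum((t, s, e) in {(r.tx_id, r.start, r.end) for r in uorfs}
           for t, (s, e) in planted.items())
print(f"planted uORFs recovered: {hits}/{len(planted)}")
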