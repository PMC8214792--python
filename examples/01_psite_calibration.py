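"""P-site calibration on a simulated ribo-seq library.

Builds a small genome, simulates footprints whose 5' ends sit 12 nt (length
28) and 13 nt (length 29) upstream of the decoded codon, then runs the full
calibration: periodicity-based length selection, change-point offset
estimation, P-site shifting and frame QC.
"""

from riboflow import (
    estimate_offsets,
    frame_usage,
    psites_by_length,
    select_lengths,
)
from riboflow.simulate import make_genome, simulate_riboseq

sim = make_genome(n_genes=20, exon_count_range=(1, 1), seed=42)
reads, truth = simulate_riboseq(
    sim.annotation, offsets={28: 12, 29: 13}, frame0_frac=0.9, depth=12002, seed=43
)
print(f"simulated {reads.total_weight} footprints over {len(sim.annotation.transcripts)} genes")

results = select_lengths(reads, sim.annotation, min_reads=1000)
for r in results:
    print(f"  length {r.read_length}: {r.n_reads:.0f} profile reads, "
          f"dominant period {r.dominant_period}, passes={r.passes}")
passing = [r.read_length for r in results if r.passes]

offsets = estimate_offsets(reads, sim.annotation, passing)
print(f"estimated offsets: {offsets.offsets} (truth: {truth['offsets']})")

psites = psites_by_length(reads, offsets, sim.annotation)
usage = frame_usage(psites, sim.annotation, by_length=True)
print(usage.to_string(index=False))
print("frame0 near 90% confirms the generated frame enrichment was recovered "
      "after shifting 5' ends to P-sites.")
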