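"""Capture-C pipeline on a simulated paired-end library.

Simulates viewpoint/partner ligation-junction molecules with 50% PCR
duplication, then runs pair filtering, overlap merging, in-silico
digestion, exact-match mapping, three-class classification,
composition-based deduplication and the per-fragment reporter profile.
"""
from vpcontact import (
    SimConfig,
    ViewpointSpec,
    class_counts,
    dedup_reads,
    make_genome,
    process_pairs,
    reporter_profile,
    simulate_capturec_reads,
)
from vpcontact.capture import profile_to_bedgraph

config = SimConfig(
    chrom_lengths={"chr1": 400_000, "chr2": 200_000},
    spacing=1000,
    enzyme="DpnII",
    bait_chrom="chr1",
    n_molecules=1500,
    duplication_rate=0.5,
    seed=7,
)
genome, rmap, _ = make_genome(config)
pairs, truth = simulate_capturec_reads(genome, rmap, config)
chrom, idx = truth.bait
vp = ViewpointSpec(chrom, *rmap.fragment_of_site(chrom, idx), flank=1000)
print(f"viewpoint fragment {vp.chrom}:{vp.start}-{vp.end} (+/-{vp.flank} bp exclusion)")
print(f"library: {len(pairs)} read pairs from {truth.n_molecules} unique molecules")

records, stats = process_pairs(pairs, genome, vp, rmap.enzyme.motif)
unique = dedup_reads(records)
print(f"filtered {stats['kept']}/{stats['total']} pairs, {stats['merged']} merged; "
      f"{len(unique)} unique reads after composition dedup "
      f"(PCR duplicates removed exactly: {len(unique)} == {truth.n_molecules})")

counts = class_counts(unique)
print("sub-fragment classes:", counts)

profile, n_reporters = reporter_profile(unique, rmap)
rows = sorted(profile_to_bedgraph(profile, rmap), key=lambda r: -r[3])[:5]
print(f"{n_reporters} reporter sub-fragments over "
      f"{sum(int((v > 0).sum()) for v in profile.values())} fragments; top fragments:")
for chrom, start, end, value in rows:
    print(f"  {chrom}:{start}-{end}\t{value}")
print("Reporter counts concentrate on near-viewpoint cis fragments outside the "
      "1 kb exclusion zone, the expected 4C/Capture-C contact decay.")
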