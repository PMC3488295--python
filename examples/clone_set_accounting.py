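"""Clone-set gene accounting: from arrayed clones to gene coverage.

Builds two small overlapping clone sets, maps their accessions to genes,
estimates genes with a full-length clone per set and combined, and turns
gene counts into coverage percentages of an assumed gene complement.
"""

import xenqc as xq

gene_map = xq.GeneMap({f"acc{i:03d}": f"gene{i % 60:03d}" for i in range(90)})

set_a = [
    xq.CloneRecord(f"a{i}", "IMAGE/XGC", "X. tropicalis", accession=f"acc{i:03d}")
    for i in range(70)
]
set_b = [
    xq.CloneRecord(f"b{i}", "Wellcome/Sanger", "X. tropicalis",
                   accession=f"acc{i:03d}")
    for i in range(40, 90)
]

rate_a = 0.90                     # sampled full-length rate
rate_b = xq.fl_rate_from_qc(xq.fixture_tally("wellcome_sanger_qc"))

sum_a = xq.summarize_set(set_a, gene_map, plates=1, fl_rate=rate_a)
sum_b = xq.summarize_set(set_b, gene_map, plates=1, fl_rate=rate_b)
combined = xq.combine_sets([sum_a, sum_b], [set_a, set_b], gene_map)

for s in (sum_a, sum_b, combined):
    print(
        f"{s.set_name:20s} wells={s.wells:4d} clones={s.distinct_clones:3d} "
        f"genes={s.distinct_genes:3d} est. FL genes={s.est_fl_genes:3d}"
    )

pct = xq.coverage_percent(combined.distinct_genes, 100)
print(
    f"\nAssuming 100 protein-coding genes in total, the combined sets give "
    f"cDNA evidence for {pct}% of them; distinct genes are deduplicated "
    "across sets, so the combined count is below the per-set sum."
)
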