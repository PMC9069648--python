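"""Call positive and low-contact EP pairs from a contact dump.

A bin pair is interacting when its normalized contact value exceeds 30
(strictly) and non-interacting below 5; annotated enhancers/promoters
overlapping the two bins form EP pairs within [2.5 kb, 2 Mb].
"""

from epmotif import SimConfig, simulate
from epmotif.ep_pairs import call_interacting_bins, call_noninteracting_bins, build_ep_pairs

bundle = simulate(SimConfig(n_ep_pairs=150, n_negative_blocks=150, seed=2))
values = {(r.chrom, r.bin_a, r.bin_b): r.value for r in bundle.contacts}

high = call_interacting_bins(bundle.contacts, cutoff=30)
low = call_noninteracting_bins(bundle.contacts, bundle.all_bin_pairs, cutoff=5)
res = bundle.config.resolution

pos = build_ep_pairs(high, bundle.enhancers, bundle.promoters, res, "positive", values)
neg = build_ep_pairs(low, bundle.enhancers, bundle.promoters, res, "negative3", values)

print(f"{len(high)} interacting bin pairs -> {len(pos)} positive EP pairs")
print(f"{len(low)} low-contact bin pairs -> {len(neg)} type-3 negative EP pairs")
p = pos[0]
print(f"example: enhancer {p.enhancer.start}-{p.enhancer.end} / gene {p.gene_id}, "
      f"distance {p.distance} bp, contact {p.contact_value:.1f}")
# Distances are enhancer-midpoint to TSS; all pass the 2.5 kb floor.
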