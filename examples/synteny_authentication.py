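"""Authenticate candidate zonadhesin loci by domain architecture and synteny.

Builds the three locus scenarios — intact (a >100 kb candidate with the
MAM-mucin-tandem-VWD architecture between Ephb4 and Epo), deleted (a 30 kb
anchor gap with no candidate), and Zan-like (a candidate lacking MAM domains
with doubled VWD count) — and classifies each against the intact reference.
"""

from divsel.simulate import simulate_locus_table
from divsel.synteny import classify_locus

reference, _ = simulate_locus_table("zan_intact", seed=0)
for scenario in ("zan_intact", "zan_deleted", "zanl_no_mam", "shuffled_order"):
    table, arch = simulate_locus_table(scenario, seed=1)
    result = classify_locus(table, reference, arch)
    arch_str = ",".join(arch) if arch else "-"
    print(f"{scenario:15s} -> {result.label:6s} "
          f"(content={result.scores.content:.2f} order={result.scores.order:.2f} "
          f"orientation={result.scores.orientation:.2f} "
          f"gap={result.flank_gap_bp/1000:.0f}kb arch={arch_str})")
# intact -> ZAN, deleted -> ABSENT (30 kb gap cannot hold a 100+ kb gene),
# no-MAM candidate -> ZANL; shuffling order degrades the order score
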