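"""Simulate a small cohort, write/read a VCF, QC-filter it, profile LD.

Run:  python examples/01_filter_and_ld.py
"""

import tempfile
from pathlib import Path

from popgea import (
    SimConfig,
    SiteFilterConfig,
    filter_dataset,
    ld_decay,
    ld_prune,
    minor_allele_freq,
    pairwise_r2,
    read_vcf,
    simulate,
    simulate_linked_chromosome,
    write_vcf,
)

# three drifted populations, a little missing data
gm, env, truth = simulate(
    SimConfig(seed=1, n_pops=3, n_per_pop=20, n_loci=2000, fst_per_pop=0.1,
              missing_rate=0.02)
)

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "cohort.vcf"
    write_vcf(gm, vcf)
    gm = read_vcf(vcf)

out, report = filter_dataset(
    gm,
    SiteFilterConfig(min_mean_depth=5, max_mean_depth=12, min_qual=50,
                     max_missing_frac=0.10, maf_min=0.05),
)
print(f"sites {report.n_sites_in} -> {report.n_sites_out} "
      f"(per-rule removals: {report.site_rules})")
print(f"median MAF of survivors: {sorted(minor_allele_freq(out))[out.n_sites // 2]:.3f}")

# LD structure needs linked sites; the block simulator provides them
linked = simulate_linked_chromosome(40, 200, seed=2, decay_bp=40_000)
pairs = pairwise_r2(linked, window_snps=100, max_dist_kb=1000)
decay = ld_decay(pairs, bin_width_kb=50)
print("\nLD decay (mean r2 per 50 kb bin):")
print(decay[decay.n_pairs > 0].head(5).to_string(index=False))

pruned = ld_prune(linked, window_kb=50, step_kb=10, r2_threshold=0.2)
print(f"\nLD pruning at r2 > 0.2 removed {len(pruned.removed)} of 200 sites;")
print("no surviving pair within a 50 kb window exceeds the threshold.")
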