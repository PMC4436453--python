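"""IsomiR expression profiling and cohort dispersion comparison.

Simulates collapsed small-RNA read sets for disease and control cohorts
(the disease cohort has a 4x smaller Dirichlet concentration, i.e. noisier
isomiR proportions), re-extracts isomiRs, and compares the per-isomiR SD
distributions of the two cohorts.
"""

from armiso.isomir import build_locus_profile, dispersion_compare, profile_summary
from armiso.synthetic import SyntheticConfig, generate_isomir_readsets, generate_phylo_families

cfg = SyntheticConfig(seed=5)
fam = generate_phylo_families(cfg)
hsa_h = {h.id: h for h in fam.hairpins["hsa"]}
loci = [(hsa_h[m.hairpin_ids[0]], m) for m in fam.matures["hsa"] if m.id.endswith("-5p")][:3]

sim = generate_isomir_readsets(cfg, loci)
disease = [rs for rs in sim.readsets if rs.condition == "disease"]
control = [rs for rs in sim.readsets if rs.condition == "control"]

hp, canonical = loci[0]
profile = build_locus_profile(control, hp, canonical)
summary = profile_summary(profile)
print(f"locus {canonical.id}: top isomiRs by mean relative expression (controls)")
print(summary.head(5)[["mean_percent", "sd_percent", "rank"]].round(2))
# variant labels are offset5|offset3|tail3; +0|+0|. is the canonical sequence,
# expected near the generated 70% dominance (minus the tailed fraction).

dis_profiles = [build_locus_profile(disease, h, c) for h, c in loci]
ctl_profiles = [build_locus_profile(control, h, c) for h, c in loci]
res = dispersion_compare(dis_profiles, ctl_profiles)
print(f"median per-isomiR SD: disease {res['disease']['median']:.2f} "
      f"vs control {res['control']['median']:.2f} (rank-sum p={res['ranksum_p']:.2g})")
# The noisier disease cohort shows the larger median SD — more flexible
# isomiR expression across samples.
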