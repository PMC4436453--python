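"""Cross-species divergence profiling and diversity statistics per arm.

Generates 40 miRNA families across 10 species with a conserved 5p arm
(substitution rate 0.02/site) and a variable 3p arm (0.12/site), profiles
per-position divergence against the human reference, and summarizes each
arm as a sequence population (pi, Hd, k).
"""

from armiso.evolution import (
    AlignedFamily,
    arm_divergence_compare,
    diversity_stats,
    divergence_profile,
    trim_core,
)
from armiso.synthetic import SyntheticConfig, generate_phylo_families

cfg = SyntheticConfig(seed=11)
fam = generate_phylo_families(cfg)

profiles = {"5p": [], "3p": []}
for i in (1, 2, 3):
    for arm in ("5p", "3p"):
        rows = fam.family_rows(f"mir-{i}", arm)
        prof = divergence_profile(trim_core(AlignedFamily(f"mir-{i}", arm, rows)))
        profiles[arm].append(prof)
        st = diversity_stats(list(rows.values()), aligned=True)
        print(f"mir-{i} {arm}: mean substitution rate {prof.mean_rate:.3f}, "
              f"pi={st.pi:.3f}+/-{st.pi_sd:.3f}  Hd={st.hd:.2f}+/-{st.hd_sd:.2f}  k={st.k:.2f}")

res = arm_divergence_compare(profiles["5p"], profiles["3p"])
print(f"Wilcoxon 5p vs 3p: Z={res['wilcoxon_z']:.2f}, p={res['wilcoxon_p']:.4f}")
# The 3p arm's higher per-site rate shows up directly in pi/k and in the
# signed-rank comparison — the generated arm asymmetry is recovered.
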