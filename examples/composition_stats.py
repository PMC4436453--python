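"""Compare length and nucleotide composition between 5p- and 3p-miRNAs.

Runs the full census (lengths with t tests, A/U/C/G and homopolymer-run
composition with chi-square contingency tests) on a synthetic miRNAome.
"""

from armiso.pipeline import primary_analysis
from armiso.synthetic import SyntheticConfig, generate_phylo_families

fam = generate_phylo_families(SyntheticConfig(seed=3, n_species=2, n_families=60))
res = primary_analysis(fam.matures["hsa"], fam.hairpins["hsa"])

c = res["counts"]
print(f"{c['matures']} matures: {c['5p']} from 5p arms, {c['3p']} from 3p arms, {c['pairs']} pairs")

ln = res["length"]
print(f"length 5p {ln['5p'].mean:.2f} +/- {ln['5p'].sem:.2f}, "
      f"3p {ln['3p'].mean:.2f} +/- {ln['3p'].sem:.2f} "
      f"(Student's t={ln['t_unpaired']:.2f}, p={ln['p_unpaired']:.3f})")

comp = res["composition"]
print("A/U/C/G percent, 5p:", [f"{p:.1f}" for p in comp["5p"].percents])
print("A/U/C/G percent, 3p:", [f"{p:.1f}" for p in comp["3p"].percents])
print(f"composition chi2={comp['chi2']:.2f} (df={comp['df']}, p={comp['p']:.3f})")
# On random synthetic sequences the two arms look alike (large p); on a real
# miRNAome the arms differ markedly (G-rich 5p, C-rich 3p).
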