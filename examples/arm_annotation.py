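"""Classify mature miRNAs onto hairpin arms and pair 5p/3p products.

Builds a small synthetic miRNA family set, annotates every mature onto its
hairpin and pairs the two arms of each precursor.
"""

from armiso import pair_arms
from armiso.mirbase_io import annotate_all
from armiso.synthetic import SyntheticConfig, generate_phylo_families

cfg = SyntheticConfig(seed=1, n_species=2, n_families=6)
fam = generate_phylo_families(cfg)
matures, hairpins = fam.matures["hsa"], fam.hairpins["hsa"]

annotations, unlocatable = annotate_all(matures, hairpins)
pairs, unpaired = pair_arms(matures, hairpins)

print(f"{len(matures)} matures on {len(hairpins)} hairpins")
for ann in annotations[:4]:
    print(f"  {ann.mature_id}: arm={ann.arm} via {ann.method} at {ann.start}-{ann.end}")
print(f"pairs: {len(pairs)} (every hairpin here carries one mature per arm)")
# Each pair is a 5p/3p duo excised from the same stem-loop precursor — the
# unit on which arm selection and arm switching are defined.
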