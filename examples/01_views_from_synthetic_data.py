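"""Generate a small synthetic dataset and inspect the six similarity views.

The generator plants four miRNA/drug association blocks and leaks block
identity into sequences (3-mer motifs), fingerprints (block templates)
and gene profiles.  Each view is a thresholded similarity graph; the
densities below show how much of each graph survives the theta = 0.5
cut-off.
"""

from mgcna.synthetic import SyntheticConfig, generate
from mgcna.views import build_view_bundle

sd = generate(SyntheticConfig(seed=1))
ds = sd.dataset
print(f"dataset: {len(ds.mirna_ids)} miRNAs, {len(ds.drug_ids)} drugs, "
      f"{len(ds.mda.pairs)} known associations")

bundle = build_view_bundle(ds.sequences, ds.fingerprints, ds.mga, ds.dga,
                           ds.mda)
for name, view in {**bundle.mirna_views, **bundle.drug_views}.items():
    n = view.matrix.shape[0]
    density = view.matrix.mean()
    print(f"  {name:12s}  {n}x{n}  edge density {density:.3f}")

# Edge density counts self-loops; a density near 1/n means the similarity
# threshold removed almost every off-diagonal relationship.
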