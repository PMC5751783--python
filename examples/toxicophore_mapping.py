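"""Recover the planted toxicophore: sensitivity ranking + back-projection.

Runs the full pipeline on a clean planted-rule dataset and shows that the
most sensitive bin decodes to the planted chemistry (aromatic-class carbon,
amine-class nitrogen, 7-8 A) with ring-centroid anchored match instances.
"""

from sdar3d import SyntheticSpec, recovery_harness

summary = recovery_harness(SyntheticSpec(n_compounds=60), n_members=200, seed=3)

print(f"retained bins: {summary.n_retained_bins}")
print(f"external accuracy {summary.external_accuracy:.3f}, "
      f"sensitivity {summary.external_sensitivity:.3f}")
print(f"planted bin rank: {summary.planted_best_rank} "
      f"({100 * summary.planted_rank_fraction:.2f}% of retained bins)")

print("\ntop features (rank / sensitivity / support / decode):")
for feat in summary.features[:5]:
    print(f"  {feat.rank:>3}  {feat.aggregate_sensitivity:.3f}  "
          f"{feat.support:>2}  {feat.decode.describe()}")

top = summary.top_feature
inst = top.instances[0]
print(f"\nfirst match of the top feature, compound {inst.compound_id}:")
print(f"  atoms {inst.atom_indices}, anchors {inst.anchor1} / {inst.anchor2}")
print(f"  raw distance {inst.raw_distance:.2f} A, "
      f"centroid-anchored {inst.anchor_distance:.2f} A")
# A 'ring' anchor means the matched atom sits in an aromatic ring and the
# reported distance is measured from the ring centroid -- the way ring
# features are presented to medicinal chemists.
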