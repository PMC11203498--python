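"""Score a generated set: Valid / Unique@k / Novel, property distributions
against a reference sample, and the drug-like good-range table.
"""

from targen import (good_range_report, novel_fraction, property_profile,
                    unique_fraction, valid_fraction, wasserstein_1d)

generated = ["CCO", "CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O",
             "CCN(CC)CC", "C((", "CCCCCCCC"]
training = ["CCO", "CCCCCCCC"]

valid, P = valid_fraction(generated)
print(f"valid: {valid:.3f} ({len(P)}/{len(generated)} parse)")
print(f"unique@{len(P)}: {unique_fraction(P, c=len(P), seed=0):.3f}")
print(f"novel: {novel_fraction(P, training):.3f} "
      "(fraction of valid molecules absent from training)")

profiles = [property_profile(s) for s in P]
print("\naspirin profile:", property_profile("CC(=O)Oc1ccccc1C(=O)O"))
print("\ngood-range percentages over the valid set:")
for prop, pct in good_range_report(profiles).items():
    print(f"  {prop:5s} {pct:6.1f} %")

mw_gen = [p.MW for p in profiles]
mw_ref = [46.07, 78.11, 180.16, 101.19, 114.23]
print(f"\n1-Wasserstein MW distance to the reference sample: "
      f"{wasserstein_1d(mw_gen, mw_ref):.2f} Da")
print("Smaller distances mean the generated property distribution tracks")
print("the reference distribution more closely.")
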