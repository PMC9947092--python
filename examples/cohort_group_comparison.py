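"""Simulate the four study groups, run the full analysis pipeline and
compare the outcome metrics across groups.

The group templates encode the qualitative contrasts of interest: faster
oral glucose appearance after gastric bypass, a blunted glucagon
response in all surgical groups, and a near-absent pancreatic
polypeptide response in the hypoglycaemia-prone (PBH) group.
"""

import hypoclamp as hc
from hypoclamp.pipeline import analyze_cohort, compare_cohort

dataset, truths = hc.simulate_cohort(n_per_group=8, seed=42, noise=True)
print(f"simulated {len(dataset)} subjects: {dataset.group_sizes()}")

# write / re-read the cohort as long-format CSV (the interchange format)
import tempfile, os
with tempfile.TemporaryDirectory() as d:
    hc.write_cohort(dataset, os.path.join(d, "cohort"))
    dataset = hc.read_cohort(os.path.join(d, "cohort"))

steele = hc.SteeleConfig(pool_fraction=1.0, v_steele=160.0)
metrics = analyze_cohort(dataset, steele=steele)

for var in ("glucagon_iauc_hypo", "pp_t160", "glucose_mean_hypo",
            "recovery_percent"):
    med = metrics.groupby("group")[var].median()
    print(f"\nmedian {var}:")
    for group in ("PBH", "RYGB", "SG", "CN"):
        print(f"  {group:4s} {med[group]:10.1f}")

results = compare_cohort(metrics, variables=("glucagon_iauc_hypo",
                                             "pp_t160",
                                             "glucose_mean_hypo"))
print()
for r in results:
    print(f"{r.variable}: {r.test_used}, global p = {r.p_global:.4f}")
    if r.variable == "glucagon_iauc_hypo":
        for pair, p in sorted(r.pairwise.items()):
            if "CN" in pair:
                print(f"    {pair[0]} vs {pair[1]}: p = {p:.4f}")

# Expected pattern: glucagon exposure during the hold is clearly larger
# in the non-surgical group (at or near significance against each
# surgical group at n=8), the PP level at t160 is lowest in the PBH
# group, and the clamped glucose does not differ -- the clamp equalises
# the hypoglycaemic stimulus across groups.
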