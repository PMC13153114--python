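"""Pooled N-source preferences from the packaged volumetric-rate table.

Pools the printed rates per (lake, fraction) across sampling dates (ratio of
sums, missing cells as zero) and prints the percentage of total uptake each
nitrogen form receives — e.g. ammonium carries ~52% of whole-water uptake in
the Lake in Central Park while urea carries ~69-72% in Lake Erie.
"""

from ntracer.fixtures import table2_long
from ntracer.preference import fraction_fold_ratio, preference_pooled, round_half_away

rates = table2_long()
pref = preference_pooled(rates, ["lake", "fraction"])

for (lake, frac), grp in pref.groupby(["lake", "fraction"]):
    parts = ", ".join(
        f"{row['form']} {round_half_away(row['preference_pct']):.0f}%"
        for _, row in grp.iterrows()
    )
    print(f"{lake:4s} {frac}: {parts}")

for lake in ("NT", "HE"):
    fold = fraction_fold_ratio(rates.query("lake == @lake"), "MC", "FL").iloc[0]
    print(f"{lake}: colony fraction takes up {fold:.2f}x more N than free-living")
# Percentages within each lake x fraction sum to 100; the fold ratio compares
# summed volumetric uptake (all N forms) between plankton fractions.
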