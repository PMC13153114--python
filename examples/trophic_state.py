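"""Trophic State Index from transparency, chlorophyll and phosphorus.

Computes Carlson sub-indices for a turbid urban pond and a clear lake,
averages them into a composite, and maps the composite onto the trophic
bands (>74 hypereutrophic, 54-74 eutrophic, ...).
"""

from ntracer.trophic import LakeEnvironment, tsi

for env in (
    LakeEnvironment("urban pond", secchi_m=0.4, chla_ug_l=180.0, tp_ug_l=600.0),
    LakeEnvironment("clear lake", secchi_m=5.0, chla_ug_l=2.0, tp_ug_l=8.0),
):
    res = tsi(env)
    subs = ", ".join(f"{k}={v:.1f}" for k, v in res.sub_indices.items())
    print(f"{env.lake}: {subs} -> composite {res.composite:.1f} ({res.trophic_class.value})")
# Each sub-index maps its driver onto the same 0-100 productivity scale, so
# the composite is comparable across lakes even when some drivers are missing.
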