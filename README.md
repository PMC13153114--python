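# ntracer

Nitrogen-assimilation analysis for *Microcystis*-bloom lakes from ¹⁵N stable-isotope
tracer incubations: uptake-rate computation, N-source preference, trophic state
indexing, the community statistics layer (diversity, PERMANOVA, SIMPER, CCA),
and a forward incubation simulator with known ground truth.

## Who this is for

Aquatic microbial ecologists and biogeochemists measuring how plankton
fractions — whole water, free-living (<20 µm) plankton, and buoyancy-isolated
*Microcystis* colonies — assimilate nitrate, ammonium, urea and glutamic acid
during cyanobacterial harmful algal blooms, and relating those rates to lake
trophic state and 16S community composition.

## The core calculation

A substrate pool is spiked with highly enriched (≥98 atom%) ¹⁵N tracer at
~10% of its ambient concentration and incubated briefly (~60 min). The
volumetric uptake rate follows from the ¹⁵N mass balance

```
V = (AP_s − AP_NA) / (AP_Enr − AP_NA) · PON / T      [µmol N L⁻¹ h⁻¹]
```

where AP_NA and AP_s are the atom% ¹⁵N of the cells before and after the
incubation, AP_Enr is the substrate atom% after the spike, PON is particulate
organic nitrogen (>0.7 µm) and T the incubation time. Derived quantities:

* **N-specific uptake** `V · 24 / PON` (d⁻¹) — biomass-weighted uptake;
* **relative preference** — each form's share of summed volumetric uptake,
  pooled across dates as a ratio of sums and expressed as a percentage;
* **trophic state index** — Carlson log-linear sub-indices of Secchi depth,
  chlorophyll-*a* and phosphorus, averaged and classified (>74 hypereutrophic,
  54–74 eutrophic, 44–54 mesotrophic, 24–44 oligotrophic, ≤24 ultraoligotrophic).

Rates are *net* uptake: no isotope-dilution correction is applied. The
`ntracer.simulate` module quantifies the resulting bias exactly — with
regeneration rate r on a pool of size S, net/gross = (S/(rT))(1 − e^(−rT/S)).

## Worked example

```python
from ntracer.fixtures import table2_long
from ntracer.preference import preference_pooled, round_half_away

pref = preference_pooled(table2_long(), ["lake", "fraction"])
lcp = pref.query("lake == 'LCP' and form == 'NH4'")
for _, row in lcp.iterrows():
    print(row["fraction"], f"{round_half_away(row['preference_pct']):.0f}%")
```

prints

```
WW 52%
FL 55%
MC 61%
```

i.e. pooling the packaged volumetric-rate table across the Lake in Central
Park's six sampling dates, ammonium carries 52% of whole-water nitrogen
uptake, 55% in the free-living fraction and 61% in the *Microcystis* colony
fraction. The `examples/` directory holds one short script per capability
(uptake rates, preference and fold ratios, trophic state, dilution bias,
community statistics); each prints the numbers it computes and a line on
what they mean.

A thin CLI wraps the same library:

```bash
ntracer rates --input samples.csv --output rates.csv
ntracer preference --input rates.csv --output pref.csv --digits 0
ntracer tsi --env env.csv --output tsi.csv
ntracer simulate --kind incubation --seed 1 --out sim/
ntracer run --config pipeline.yaml --out results/
```

## Layout

- `src/ntracer/isotope.py` — conversions and the mass-balance rate equations
- `src/ntracer/preference.py` — N-source preference and fold ratios
- `src/ntracer/trophic.py` — TSI sub-indices, composite, classification
- `src/ntracer/community.py` — feature-table ingestion, diversity, Bray–Curtis
- `src/ntracer/stats.py` — factorial tests, correlations, Mantel/PERMANOVA/SIMPER/CCA
- `src/ntracer/simulate.py` — incubation, community and environment generators
- `src/ntracer/fixtures.py`, `io.py`, `pipeline.py`, `cli.py` — packaged study
  tables, CSV dialects, orchestration, CLI

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
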