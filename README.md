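# isoflux

Stable-isotope tracer analysis of microbial gas production in anaerobic
slurries (manure, sludge), from amendment recipe to pathway fractions.

Anaerobic slurries emit methane and reduced sulfur compounds (H2S,
methanethiol) through competing microbial pathways. Which pathway
dominates matters when evaluating mitigation additives: an inhibitor that
suppresses acetoclastic methanogens achieves little if CH4 is mostly made
by CO2 reduction. `isoflux` implements the inference used in
isotope-labeling incubations that resolve this:

* **Carbon.** Acetate spiked with 2-13C (methyl-position) label. Under
  acetoclastic methanogenesis the methyl carbon becomes CH4 and the
  carboxyl carbon CO2; under syntrophic acetate oxidation coupled to
  hydrogenotrophic methanogenesis (SAO-HM) both carbons are oxidized to
  CO2 first. Measured delta13C_CH4 / delta13C_CO2 time series are fit by
  a two-parameter carbon mass balance for **f_ac** (fraction of CH4
  carbon from acetate) and **f_am** (acetoclastic fraction of
  acetate-derived CH4; 1 − f_am is the SAO-HM share).
* **Sulfur.** Sulfate spiked with 33S. With the s-amino-acid sulfur
  pools unlabeled, two-endmember mixing of excess isotope ratios
  Rex(33/32S) = 33S/32S − 0.0078791 (reported in %) apportions H2S
  between sulfate reduction and cysteine degradation
  (f = Rex_H2S / Rex_SO4) and CH3SH between H2S methylation and
  methionine degradation (f = Rex_CH3SH / Rex_H2S).

The package covers the full chain:

| module | role |
|---|---|
| `isoflux.isotopes` / `references` | delta (permil) / ratio / atom-fraction conversions, excess ratios, exact pool mixing |
| `isoflux.labeling` | amendment recipes (mL of stock, mg of salt) → pool compositions delta13C_2-C-Ac and Rex(SO4), with uncertainty |
| `isoflux.headspace` | port-multiplexed CRDS/PTR-MS series → per-bottle per-cycle production records (trapezoidal flux integration, washout-tail correction, 13C-shoulder correction on m/z 50) |
| `isoflux.pathways` | carbon mass-balance forward model + weighted least-squares inversion; sulfur source apportionment |
| `isoflux.simulate` | reactor + instrument simulator (exact linear-washout integration, seeded noise) providing ground truth for every stage |

## Worked example

```python
import isoflux as ix

# 1) Label design: 100 g slurry + 2.15 mL of 1.67 M unlabeled acetate
#    + 0.25 mL of 1.67 M methyl-13C acetate (99 atom %)
delta, sd = ix.acetate_methyl_delta_with_uncertainty(ix.swine_acetate_plan())
print(f"delta13C_2-C-Ac = {delta.value:.0f} +/- {sd:.0f} permil")
# delta13C_2-C-Ac = 7717 +/- 112 permil

rex, sd = ix.sulfate_excess_with_uncertainty(ix.swine_sulfate_plan())
print(f"Rex(SO4) = {rex.value:.2f} +/- {sd:.2f} %")
# Rex(SO4) = 5.28 +/- 0.26 %

# 2) Simulate a labeled sulfur incubation and run the pipeline on it
fx = ix.make_fixture_suite(seed=1, duration_h=6.0, n_replicates=3)
inst_flow = ix.FlowConfig(flow_rate_L_min=0.35, headspace_volume_L=0.06)
recs = ix.records_from_simulation(fx["sulfur_control"], inst_flow)
app = ix.apportion_sulfur_from_records(recs, rex_so4_percent=5.28)
print(f"H2S from sulfate reduction: {app.f_sulfate_reduction.value:.2f}")
# H2S from sulfate reduction: 0.80
print(f"CH3SH from H2S methylation: {app.f_methylation.value:.2f}")
# CH3SH from H2S methylation: 0.50
```

The first two numbers are the pool compositions implied by the amendment
recipe: the acetate methyl carbon ends up ~7700 permil above VPDB and the
sulfate pool carries ~5.3 percentage points of excess 33S. The last two
are the source fractions the pipeline recovers from the simulated
instrument series — here matching the 80 % sulfate-derived H2S and 50 %
methylation-derived CH3SH the simulation actually emitted.

A `click` CLI mirrors the stages
(`isoflux design-label / simulate / process / fit-carbon /
apportion-sulfur`); run `isoflux example-config` for a documented
pipeline config.

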