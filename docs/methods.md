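# Methods

## Isotope bookkeeping

Carbon isotope ratios are reported in delta notation against VPDB
(13C/12C = 0.01118): delta13C = 1000·(R_sample/R_VPDB − 1) permil.
Sulfur is reported as the excess ratio Rex(33/32S) =
33S/32S − 0.0078791 in percent, anchored to the IAEA-S-1-derived
reference ratio; no delta scale is used because no consensus delta-33S
assignment exists for V-CDT. Both reference ratios ship as immutable
constants (`docs/isotope_references.csv`); users may register others.

All mixing is computed in **atom-fraction space** (x = R/(1+R), mixed
amount-weighted, converted back). Delta-space averaging is linear only
for small enrichments; the labeled acetate pools used here reach
delta13C of 5 000–28 000 permil, where the nonlinearity is several
percent. Conversions delta ↔ ratio ↔ atom fraction are exact inverses
to 1e-12 relative over delta ∈ (−999, 1e5) permil (property-tested).

Sulfur has four stable isotopes but only the 32/33 pair is observable at
the measured m/z channels (35/36 for H2S, 49/50 for CH3SH). 34S and 36S
are therefore lumped into an invisible "other" share via a configurable
abundance vector (default 32S share 0.9499, 34S 0.0425, 36S 0.0001,
with the 33S share tied to the reference ratio so a natural pool has
exactly zero excess). The 2 % non-33S remainder of the labeled sulfate
spike is spread across 32/34/36S in natural proportions; a sensitivity
test shows that assigning it entirely to 32S instead shifts Rex(SO4) by
less than 0.1 percentage point.

## Label design

`labeling.SpikePlan` captures one bottle's recipe: inoculum mass and
pool concentration, unlabeled spike, labeled spike and label purity.
The methyl-carbon delta of the pooled acetate mixes three pools
(inoculum acetate and unlabeled spike at −28.5 permil — the convention
for slurry organic matter, with fermentative fractionation neglected —
and the labeled spike at 99 atom % at the methyl position only; the
labeled carboxyl carbon is natural and never enters the methyl pool).
The sulfate excess mixes inoculum sulfate and the Na2SO4 spike at
natural composition with the 98 atom % 33S spike. Uncertainties are
first-order propagated from the inoculum-concentration SD, which is the
dominant measured uncertainty; reported error bars from other
propagation conventions will differ.

The shipped default inoculum concentrations — acetate 12.3 mmol/kg
slurry (SD 0.7) and sulfate 2.86 mmol/kg (SD 0.29) — are **synthetic,
back-calculated values** chosen so the shipped recipes reproduce the
package's reference label-design outputs (delta13C_2-C-Ac ≈ 7.7e3
permil, Rex(SO4) ≈ 5.3 %); real analyses must pass measured
concentrations.

## Headspace processing

Input is a long-format CSV (`time_s, port, channel, value`) with CRDS
channels (12CH4, 13CH4, 12CO2, 13CO2) in ppm and PTR-MS channels
(mz35, mz36, mz49, mz50) in ppb, assumed concentration-calibrated
upstream (humidity-dependent H2S calibration and PTR-MS rate-constant
quantification are out of scope; per-channel pass-through gains are
configurable).

* **Demultiplexing.** Open-valve windows are the maximal contiguous
  runs of a constant port; a configurable transient (default 120 s) is
  discarded at each window start to drop line-flush artifacts on real
  instruments. The simulator does not model that transient, so
  synthetic data are processed with a zero discard.
* **Flux integration.** Trapezoidal integration of (C − background)·Q
  on raw timestamps (no resampling — CRDS at 0.2 Hz and PTR-MS dwell
  schedules are irregular in general), converted to moles by the ideal
  gas law at the configured temperature and pressure (defaults 23 °C,
  1 atm; the reporting convention must be stated because it is not
  fixed by the data format).
* **Accumulate-release attribution.** With the carrier flowing only
  through the open port, the released pulse represents production over
  the whole multiplex cycle. The washout tail truncated at the window
  end is added analytically as V·(C_end − background) — the integral of
  the exponential washout with time constant V/Q — and the residual
  inherited from the bottle's previous window is subtracted. The
  corrections telescope, so cumulative production closes exactly up to
  trapezoid error; the uncorrected (truncated) estimator is also
  available since published cumulative curves may use either.
* **Continuous flow.** Nothing accumulates; the window integral is
  scaled to the multiplex period inferred from consecutive window
  starts. Treated-vs-control emission reductions are ratios of group
  means, so this attribution factor cancels.
* **Isotope quantities.** Window deltas are flux-weighted by
  construction (ratios of isotopologue integrals). The methanethiol
  m/z 50 channel carries the 13C isotopologue of CH3-32SH; it is
  removed as (s50 − 0.01086·s49)/s49 using the natural 13C/12C ratio
  1.086 % (delta13C = −28.5 permil). Degenerate windows produce flagged
  records (light integral zero → undefined; heavy integral zero →
  −1000 permil sentinel) rather than exceptions.

Measured mass closure on noise-free simulations (2 bottles, 15-min
dwell, V/Q ≈ 10 s): better than 1 % per gas in both modes; the stated
guarantees are 2 % for accumulate-release (trapezoid error on the
release pulse at 5-s CRDS sampling) and 1 % for continuous flow.

## Carbon mass-balance model

The static two-parameter model distributes CH4 carbon among three
routes — acetoclastic (f_ac·f_am), SAO-HM (f_ac·(1−f_am)) and
background hydrogenotrophic from non-acetate CO2 (1−f_ac) — and the CO2
pool among the stoichiometric companions: carboxyl-composition CO2 from
the acetoclastic route, net acetate-mean CO2 from the SAO route (both
carbons oxidized into a well-mixed acetate-derived CO2 sub-pool, from
which CH4 is then formed), and background CO2 for the remainder
(requiring m_CO2 ≥ f_ac·m_CH4 per interval). A sensitivity variant
draws SAO-derived CH4 from the bulk CO2 pool instead
(`sao_source="bulk_co2"`); neither convention is forced by the
measurement and both are exposed.

Fractionation offsets eps_ac and eps_hm (additive permil on the product
delta) default to 0, with the caveat that they are not separately
identifiable from two observables. Measured sensitivity at
delta_methyl = 7719 permil, truth (0.21, 0.01): ignoring offsets of up
to ±80 permil moves the fitted f_ac by < 0.02 and f_am by < 0.05 —
f_ac is robust; f_am less so at the SAO-dominated boundary, where an
80-permil shift is comparable to the acetoclastic signal itself.

Inversion is weighted least squares over (f_ac, f_am) ∈ [0,1]²
(per-observation residuals scaled by the stated delta SDs), by
exhaustive evaluation on a 0.005-spaced grid followed by bounded
L-BFGS-B refinement. The full objective grid is returned so flat
valleys (e.g. a single observation, or delta_methyl near background)
are visible; boundary solutions are flagged, not errors. The model can
be fit per window or to a whole trajectory — pointwise statements such
as a pathway split "at peak delta13C_CH4" use the per-window mode.
Noise-free inversion is exact to the grid/refinement tolerance (0.005)
anywhere in the interior; at n = 20 windows with 5-permil Gaussian
delta noise, 200 seeded replicates give bias < 1e-3 and RMSE < 0.01 on
both fractions (the stated guarantees are 0.01 and 0.03).

## Sulfur apportionment

Linear two-endmember mixing: unlabeled sources carry zero excess, so
f_sulfate(H2S) = Rex_H2S/Rex_SO4 and
f_methylation(CH3SH) = Rex_CH3SH/Rex_H2S, with contemporaneous H2S as
the methylation donor pool (if methylation drew on a differently
labeled micro-environment this ratio would be biased; the data cannot
distinguish that case). Fractions are scale-invariant in the common Rex
scale and are reported clipped to [0,1] with the raw value and a QC
flag retained, since noise near the endmembers legitimately produces
values slightly outside.

## Simulator

Each bottle is a continuously stirred headspace (V, default 0.06 L)
flushed at Q (default 0.35 L/min) while its port is open;
dC/dt = e(t)/V − (Q/V)·C·[open]. Within each sub-step the forcing is
constant and the linear equation is solved **exactly**, so no
integrator tolerance enters the ground truth; vented amounts come from
the exact per-step mass balance (emitted = vented + residual to
rounding, verified to 1e-6). Sub-steps never exceed 0.1·V/Q nor 5 % of
any rate-decay timescale — chosen automatically, so no unstable step
can be taken regardless of the sampling grid. Pathway rates are
constant or first-order decaying; treatments are rate multipliers per
pathway.

Isotopologue channels are generated from the configured compositions:
CH4/CO2 split by the pathway atom fractions (SAO CH4 at the acetate
mean), sulfur species split as 32S share × (R_ref + Rex/100), and the
m/z 50 channel includes the 13C shoulder (1.086 % of m/z 49) so the
correction is exercised end-to-end. Gaussian channel noise (defaults:
0.5/0.05 ppm on 12/13CH4, 2/0.05 ppm on CO2, 5 ppb on m/z 35/36, 2 ppb
on m/z 49/50) is added at sampling time behind one seeded generator;
unseeded stochastic runs are refused. Noise is unbiased — baseline-
subtracted calibrated channels may go slightly negative — because
clipping at zero would bias the weak-signal isotopologue integrals.
CRDS channels sample every 5 s (0.2 Hz), PTR-MS channels every 2 s; a
sample landing exactly on a valve switch is attributed to the opening
port so the release peak is observed.

The canonical fixture suite reproduces the studied regimes with
3 replicate bottles, 15-min dwell and 6 h duration: (a) SAO-HM-dominated
swine-manure-like carbon labeling (f_ac = 0.21, f_am = 0.01,
delta_methyl = 7719 permil, total CH4 2 µmol/h — headspace
concentrations in the hundreds of ppm, as for a CRDS); (b) an
acetoclastic-dominated wastewater-like variant (f_am = 0.9,
delta_methyl = 5152 permil); (c) a sulfur experiment with 80 %
sulfate-derived H2S, 50 % methylation-derived CH3SH, Rex(SO4) = 5.28 %
and H2S at 0.1 µmol/h (tens of ppm); (d) a combined-inhibitor variant
with H2S reduced 82.1 %, > 95 % of the remainder sulfate-derived, and
CH3SH reduced 94.5 % with methylation hit hardest. Emission rates and
noise magnitudes are package choices tuned to realistic instrument
ranges, not measured values.

The simulator emulates constant or smoothly decaying emission, perfect
stirring, instant valve switching and white channel noise. It does not
model line-volume transients, drift, humidity effects, NH4·H2O+
spectral interference (only a QC hook exists), pH-dependent H2S
speciation, pool depletion (Rayleigh behavior) or microbial dynamics —
so passing tests demonstrate the correctness of the inference chain,
not robustness to those real-data effects.

## Known limitations

* The carbon model is static per interval; it does not track acetate
  pool turnover or time-varying background CO2 composition within an
  interval.
* f_am is weakly identified when f_ac·(delta_methyl − delta_bg) is
  small, and sensitive to unmodeled fractionation near its boundaries;
  inspect the returned objective grid.
* Excess-ratio apportionment assumes the unlabeled sources are exactly
  at the reference composition; natural delta-34S/33S variation in
  amino-acid sulfur is below the instrument precision assumed here but
  is not modeled.
* Uncertainty on emission reductions is first-order propagation of
  replicate scatter of group means; with 2–3 replicates these SDs are
  themselves noisy.
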