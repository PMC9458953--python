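# Methods

## Reactor model

The simulator represents a hybrid channel reactor as a single well-mixed
continuous-flow compartment.  Tracer studies on this reactor class show
complete mixing within a few hours against a 2-day hydraulic residence
time, so spatial gradients are treated as negligible: the four bulk
sampling ports and the effluent port all report the same underlying truth
and differ only by measurement noise.

State variables are the dissolved species (sulphate, sulphide, lactate,
acetate, propionate; mmol/L), the fractional biofilm coverage of the
air-liquid interface, and the film sulphur/dry-mass pools (g) accumulated
since the last harvest.  All dissolved species experience dilution
D = 1/HRT toward their feed values.

**Sulphate reduction.**  The volumetric rate is

    r_BSR = k_max · f(T) · S/(K_S + S) · g(donor)

with `k_max` the community-scale maximum rate at the reference temperature
(biomass is folded into `k_max`: the data this emulates are rates, not
biomass inventories, so an explicit biomass state would not be
identifiable), `K_S` a sulphate half-saturation, and `g` a Monod gate on
the fed electron donor.  A fraction `aux_donor_frac` of the reduction is
supported by donors other than the fed carbon source (yeast extract in the
medium, biomass turnover) and bypasses the gate.  This term is essential
to an honest carbon budget: a feed supplying 0.228 mmol lactate/L.h cannot
stoichiometrically sustain 0.144 mmol/L.h of sulphate reduction through
incomplete lactate oxidation (which needs 2 lactate per sulphate) while
also fermenting part of the lactate, yet exactly such rate combinations
are observed in practice, together with more acetate than the fed carbon
could yield.  Routing part of the reduction (default 50% in the lactate
scenarios) through auxiliary donors that release acetate reproduces both
observations; the flux-partition diagnostics then flag the excess acetate
and the over-attribution of lactate, as the analysis of real data does.

**Temperature factor.**  `f(T)` is a continuous two-regime Arrhenius
multiplier: `exp(-Ea_above/R · (1/T - 1/T_ref))` at and above the critical
temperature `T_crit`, continuing below it with the steeper stress-regime
energy `Ea_below`.  Defaults for the 2 L lactate scenario (k_max = 0.144
mmol/L.h at 303.15 K, Ea = 19.0/65.7 kJ/mol, T_crit = 288.15 K) are chosen
so the staged run reproduces the published endpoint rates of such a
reactor (0.144 at 30 °C, 0.059 at 10 °C) within a few percent; the 8 L
lactate (0.128; 30.6/63.4 kJ/mol) and 2 L acetate (0.127; 50.4/209.9
kJ/mol) scenarios are calibrated the same way.

**Carbon routing.**  In lactate mode a fixed fraction `ferm_fraction`
(default 0.25) of the total lactate flux is fermented
(3 lactate → 1 acetate + 2 propionate) and the rest incompletely oxidised
(2 lactate + SO₄²⁻ → HS⁻ + 2 acetate); propionate is a pure fermentation
marker.  In acetate mode the donor is consumed 1:1 with sulphate
(complete oxidation).  A small background acetate source
(`yeast_extract_acetate_rate`, default 0.02 mmol/L.h, temperature scaled)
stands for fermentation of the yeast extract.

**Sulphide oxidation and the film.**  Sulphide is oxidised at the surface
at `r_SOX = k_ox_max · (1 - coverage) · HS/(K_HS + HS)`: a growing film
throttles oxygen transfer, which is why the film must be disrupted
periodically.  A fraction `eta_s0` (default 0.30) of oxidised sulphur is
captured in the film; the remainder becomes colloidal sulphur tracked as
the gap pool.  Coverage regrows at `biofilm_regrowth · (1 - coverage)`
scaled by sulphide availability; disruption resets it to zero instantly
(partial disruption is not modelled).  Film dry mass accrues in a fixed
default composition (10% C, 2% H, 3% N, 29% S, 56% inorganic - the
struvite-like mineral fraction seen in such films by CHNS difference).
`k_ox_max` = 2.0 mmol/L.h and `K_HS` = 0.5 mmol/L keep bulk sulphide low,
so nearly all generated sulphide is oxidised rather than washed out; this
is what makes a 30% film-capture fraction appear as ≈30% ledger recovery,
consistent with the observation that the gap pool (≈70%) is dominated by
colloidal sulphur rather than aqueous sulphide losses.

**Integration.**  An explicit fixed-step update (default dt = 0.1 h,
guarded at dt ≤ HRT/100) advances the state; a step that would drive any
species negative raises an error naming the species rather than clipping.
The fixed point of the explicit map coincides with the continuous steady
state, so steady-state checks against closed forms are exact, and every
sulphur transfer is accumulated into a running ledger so atom conservation
holds to floating-point precision (observed ~1e-13 relative).  The
oxidation parameters were chosen with the step size in mind: the linear
rate constant `k_ox_max/K_HS` = 4/h keeps the explicit update positive.

**Schedule and events.**  The default programme stages temperature
30 → 10 °C in 5 °C decrements at a 48 h HRT, disrupting the film every 3
residence times and harvesting the settled material every 6 (one harvest
per 12-day stage).  A burn-in of 6 residence times at the first stage
temperature precedes t = 0, because the reactors this emulates had
operated continuously for months to years before any temperature study -
starting from operating steady state rather than from fresh medium.
Samples are drawn daily at the four bulk ports and the effluent with
multiplicative Gaussian noise (default CV 5%, clipped at zero; assay
precision is otherwise unspecified, so this is a declared convention).

## Rate summaries

Each stage is reduced over its final three daily samples (by which point
the previous stage's residence-time transient has decayed below 1%):
conversion X from the bulk-mean residual sulphate, VSRR = X·C_feed/HRT,
expected sulphide = X·C_feed (1:1 molar with reduced sulphate, no
speciation correction since measurements report total dissolved sulphide),
and VSOR = (expected − measured)/HRT separately for the bulk ports and the
effluent.  Utilisation rates are (feed − residual)/HRT for fed species,
production rates residual/HRT for species absent from the feed; a
negative utilisation surfaces as positive net production.  Unit
conversions use molar masses SO₄²⁻ 96.06, S 32.06, lactate 90.08, acetate
60.05, propionate 74.08 g/mol.

## Arrhenius analysis

ln k is regressed on 1/T (kelvin; the 1000/T axis used on conventional
plots is display only) and E_a = −slope·R.  The two-segment model shares
the boundary point between segments, matching the convention of fitting an
optimal range down to the boundary temperature and a stress range from it.
Automatic breakpoint search enumerates every shared-boundary position with
at least two points per segment and minimises pooled RSS, breaking ties
toward the warmest boundary; for the small point counts involved this is
exact and is verified against an independent enumeration oracle.  T_crit
is the intersection of the two lines; slopes differing by less than 1e-9
relative raise a no-intersection error instead of returning an absurd
extrapolation.  Zero or negative rates are excluded with a warning rather
than failing the fit, since cold stages can report ≈0 conversion.

A note on estimator geometry: when the generating break sits exactly on a
shared boundary point, the noiseless estimated T_crit converges to the
boundary temperature itself, and the mild curvature that Monod saturation
adds to the warm segment can place it a few hundredths of a degree to
either side.  End-to-end checks therefore assert recovery of the
generating critical temperature to within 0.5 °C rather than strict
containment in an open interval.

## Sulphur ledger

Per interval: converted-S = VSRR·V·Δt·(32.06/1000) grams; FSB-S sums
dry mass × S fraction over harvests; aqueous effluent S integrates the
effluent sulphide series (trapezoid × volume/HRT); re-oxidation to
sulphate defaults to zero (negligible in the systems emulated, but exposed
as a scenario knob because poorly covered low-temperature operation can
completely re-oxidise elemental sulphur); gap-S closes the balance by
subtraction and is not a measured pool.  Recovery with zero converted
sulphur but non-zero film sulphur raises an undefined-recovery error
rather than imputing a value.  Gaseous H₂S loss is fixed at zero
(measured <0.5% in covered-reactor tests of this reactor class).

## ASV generator and community summaries

Sample proportions follow a softmax of per-community baseline logits plus
`sensitivity × (T − 30 °C)`; counts are Dirichlet-multinomial at 35,000
reads with concentration 200 (typical amplicon overdispersion).  The
default 16-taxon design encodes the expected ecology: sulphate reducers
and fermenters prominent in the anoxic communities at 30 °C and declining
on cooling, cold-adapted biofilm formers (Pseudomonas, Arcobacter,
Myroides) expanding until they dominate the floating film at 10 °C, while
the bulk communities become more even - so mean Shannon diversity rises
slightly on cooling even though the film community's falls.  Linear-in-
logit is the minimal structure consistent with directional shifts; it does
not emulate the appearance of genuinely novel taxa, so richness changes
are out of reach of the generator (a real dataset's rising ASV count at
low temperature would need an open community model).

Shannon diversity is reported in nats (the log base is otherwise a
convention).  Bray-Curtis is computed on raw counts - equal read depth is
guaranteed by construction here - with a normalise-first option for
unequal depths.  Diversity is computed on unrarefied counts by default.
Shift tables report relabund(cold) − relabund(warm) per taxon and
community, filtered at the usual ≥1% relative-abundance display threshold
(configurable).

## Problem sizes and determinism

A full five-stage scenario integrates 1440 h at 0.1 h steps plus burn-in
(~17,000 steps, well under a second), and the whole pipeline including
the ASV tables runs in ~0.1 s, so the test suite and the acceptance
script rerun everything from scratch.  All randomness flows through
numpy Generators seeded from the run seed; identical config + seed
reproduces identical artifacts, and the run manifest records the seed and
a hash of the resolved configuration.

## Known limitations

- No spatial structure, oxygen state, pH/alkalinity dynamics or struvite
  kinetics; the HCO₃⁻/H⁺ terms of the reactions are not propagated.
- Biomass, and hence adaptation or washout dynamics, is implicit in
  `k_max`; community change affects rates only through the temperature
  factor.
- Film composition is constant across temperature, although real films
  shift their sulphur fraction by several points between stages.
- Port-to-port variation is pure noise; real reactors show mild gradients.
- The generator's flux routing (fixed `ferm_fraction`, fixed
  `aux_donor_frac`) is time- and temperature-invariant apart from the
  global rate factor.
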