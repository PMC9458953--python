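# lfcr

Temperature-response analysis for hybrid sulphate-reducing channel
bioreactors.

Semi-passive channel reactors treat sulphate-rich mine water by coupling
biological sulphate reduction (BSR) in an anoxic bulk volume with partial
sulphide oxidation in a floating sulphur biofilm (FSB) at the air-liquid
interface.  Field installations cannot control temperature, so the key
engineering question is how volumetric sulphate reduction rate (VSRR),
sulphide oxidation, elemental sulphur recovery and the underlying microbial
community respond as the reactor cools - and in particular where the
*critical temperature* lies, below which activity collapses.

`lfcr` is built for bioprocess engineers and environmental microbiologists
who need that analysis chain as tested, reproducible code:

- a **reactor simulator** (well-mixed continuous flow, Monod kinetics with a
  two-regime Arrhenius temperature factor, stoichiometric carbon routing,
  biofilm capture of oxidised sulphur) that generates realistic sample,
  harvest and ASV-count records with exact sulphur-atom bookkeeping;
- **rate reduction** of time series to per-stage pseudo-steady-state
  summaries: conversion X, VSRR = X·C_feed/HRT, expected sulphide, bulk and
  effluent volumetric sulphide oxidation rates (VSOR), VFA rates;
- **stoichiometric flux partitioning** of lactate between fermentation
  (3 lactate → acetate + 2 propionate), incomplete oxidation
  (2 lactate + SO₄²⁻ → HS⁻ + 2 acetate) and complete acetate oxidation
  (acetate + SO₄²⁻ → HS⁻ + 2 HCO₃⁻), with excess-acetate diagnostics;
- **segmented Arrhenius analysis**: ln k = ln A − E_a/(R·T) fitted in one or
  two segments, activation energies, R², and the critical temperature
  T_crit as the intersection of the optimal-range and stress-range lines;
- a **sulphur ledger** partitioning converted sulphide-S between harvested
  biofilm sulphur (FSB-S), aqueous effluent, re-oxidation and the
  unaccounted colloidal "gap-S" pool, plus CHNS elemental closure;
- **community summaries** on ASV count tables: Shannon and Simpson
  diversity, Bray-Curtis dissimilarity, rank aggregation and per-taxon
  relative-abundance shift tables.

## Worked example

Three bundled scenarios (`lactate_2L`, `lactate_8L`, `acetate_2L`) stage a
calibrated reactor from 30 to 10 °C in 5 °C decrements, two residence
times (48 h HRT) per biofilm cycle, six per stage:

```python
import lfcr
from lfcr import pipeline

cfg = pipeline.scenario("lactate_2L")
res = lfcr.simulate(cfg.feed, cfg.params, cfg.schedule, noise_cv=0.0,
                    seed=1, volume=cfg.volume, dt=cfg.dt)
summ = lfcr.stage_summaries(res.samples, cfg.feed, cfg.schedule)
print(summ[["temperature_C", "conversion", "vsrr_mmol_L_h"]].round(4).to_string(index=False))
model, _ = pipeline.arrhenius_from_summaries(summ)
print(f"Ea(warm) = {model.warm.ea/1000:.1f} kJ/mol, "
      f"Ea(cold) = {model.cold.ea/1000:.1f} kJ/mol, "
      f"T_crit = {model.t_crit_c:.2f} degC")
```

prints

```
 temperature_C  conversion  vsrr_mmol_L_h
          30.0      0.6473         0.1404
          25.0      0.5742         0.1245
          20.0      0.5056         0.1096
          15.0      0.4426         0.0960
          10.0      0.2743         0.0595
Ea(warm) = 18.4 kJ/mol, Ea(cold) = 64.9 kJ/mol, T_crit = 15.02 degC
```

Sulphate conversion falls from 65% to 27% on cooling and the VSRR from
0.140 to 0.060 mmol/L.h.  The Arrhenius plot is linear from 30 to 15 °C
(E_a ≈ 18 kJ/mol) and breaks to a much steeper stress response below the
critical temperature, detected at ≈15 °C by the automatic breakpoint
search.  The sulphur ledger on the same run recovers 29.7% of converted
sulphur in the harvested biofilm, with 67.7% remaining as colloidal gap-S -
the reason downstream sedimentation is usually needed.

The same chain runs from the shell:

```sh
lfcr run --scenario lactate_2L --seed 1 --out results/lactate_2L
```

writing sample/harvest/truth CSVs, stage summaries, flux partitions, the
Arrhenius report, sulphur ledgers, ASV tables, diversity tables and a
manifest with the seed and config hash.

## Layout

```
src/lfcr/reactor.py        simulator: feed/kinetics/schedule, explicit mass balance
src/lfcr/asv.py            Dirichlet-multinomial ASV table generator
src/lfcr/rates.py          conversion, VSRR/VSOR, stage summaries
src/lfcr/stoichiometry.py  reaction table, flux partitioning, COD ratios
src/lfcr/arrhenius.py      segmented fits, breakpoint search, T_crit
src/lfcr/sulphur.py        sulphur ledgers and CHNS closure
src/lfcr/community.py      diversity metrics and shift tables
src/lfcr/pipeline.py       scenario configs and orchestration
src/lfcr/cli.py            `lfcr` command
docs/methods.md            model description, parameters, limitations
```
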