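# n2osource

Isotope-based source attribution of nitrous-oxide (N₂O) emissions.

`n2osource` implements, as a tested reusable pipeline, the inference
chain used to attribute N₂O emitted from a cultivation system (the
motivating application is hydroponic tomato culture on rock wool, but
nothing is specific to it) to microbial source processes, and to
estimate the N₂ losses that cannot be measured directly:

1. **Closed-chamber flux estimation** — headspace N₂O mole fractions
   are converted to molar concentrations with the ideal gas law and the
   accumulation slope is fitted by robust (Huber) or ordinary linear
   regression, scaled by chamber volume over covered area.
2. **Atmospheric-mixing correction** — chamber N₂O is a two-component
   mixture of ambient and substrate-emitted gas; emitted isotopocule
   values follow from
   δ_emitted = (C_s δ_s − C_atm δ_atm)/(C_s − C_atm), applied to
   δ¹⁵Nα, δ¹⁵Nβ and δ¹⁸O separately, with first-order Gaussian error
   propagation and a concentration threshold (default: 65 ppb above
   ambient) that excludes samples whose corrected values diverge.
3. **Dual-isotope mapping** — in the (δ¹⁸O, δ¹⁵N^SP) plane the emitted
   signature is decomposed into a bacterial-denitrification (bD)
   fraction f_bD and a residual product ratio r = N₂O/(N₂O + N₂),
   using literature endmembers for bD, fungal denitrification (fD),
   nitrifier denitrification (nD) and nitrification (Ni), closed-system
   Rayleigh fractionation δ = δ₀ + ε·ln r for N₂O → N₂ reduction, and
   two process orders (reduce-then-mix, mix-then-reduce).  The N₂ flux
   is back-calculated as f_bD·F·(1−r)/r or F·(1−r)/r.
4. **¹⁵N-tracer partitioning** — after labeling the NO₃⁻ or NH₄⁺ pool,
   the fraction of emitted N₂O drawn from each pool follows either from
   the non-equilibrium distribution of the N₂O isotopologue masses
   44/45/46 (which yields both the active-pool enrichment ap_N₂O and
   the labeled fraction) or from bulk mixing,
   f_PN2O = (¹⁵a_N2O − ¹⁵a_NH4)/(¹⁵a_NO3 − ¹⁵a_NH4).
5. **Excess-¹⁵N mass balance** — per-pool excess ¹⁵N
   (= APE/100 × N_pool) over dissolved pools, plant biomass and
   cumulative N₂O, with the solution volume estimated from label
   dilution, summed into a tracer recovery rate.

A forward simulator (`n2osource.synthetic`) generates complete
synthetic campaigns with known ground truth, so every stage has a
parameter-recovery test without any external data.

## Worked example

One chamber closure and one headspace isotopocule sample:

```python
import n2osource as n2o

series = n2o.ChamberSeries.from_ppb(
    times_h=[0.0, 1/3, 2/3, 1.0],
    n2o_ppb=[331.2, 396.8, 464.1, 530.9],
    temperature_k=295.15,
)
est = n2o.fit_flux(series)
print(f"flux: {est.flux_umol_m2_h:.4f} umol m-2 h-1 "
      f"= {est.flux_ug_n_m2_h:.2f} ug N m-2 h-1  ({est.method})")

ambient = n2o.AmbientAir(conc_ppb=272.0, d15n_alpha=15.6,
                         d15n_beta=-3.1, d18o=44.5)
sample = n2o.IsotopoculeSample(conc_ppb=530.9, d15n_alpha=-1.0,
                               d15n_beta=-17.0, d18o=43.4, ambient=ambient)
emitted = n2o.correct_delta_mixing(sample)
print(f"emitted: SP {emitted.sp:.2f}+/-{emitted.sigma_sp:.2f}, "
      f"d18O {emitted.d18o:.2f}+/-{emitted.sigma_d18o:.2f}")

endmembers, eps = n2o.default_endmembers()
endmembers = endmembers.adjust_for_water(-8.5)   # site water d18O
for cell in n2o.map_sample((emitted.sp, emitted.d18o), endmembers, eps,
                           n2o_flux=est.flux_ug_n_m2_h):
    r = cell.result
    print(f"{r.scenario:6s} {r.case:8s}  f_bD = {r.f_bd:.2f}  "
          f"r = {r.r_n2o:.3f}  N2 = {cell.n2.n2_flux:.1f}")
```

prints

```
flux: 0.1320 umol m-2 h-1 = 3.70 ug N m-2 h-1  (robust)
emitted: SP 13.16+/-1.63, d18O 42.24+/-1.15
bD_fD  red_mix   f_bD = 0.93  r = 0.109  N2 = 28.0
bD_fD  mix_red   f_bD = 0.93  r = 0.128  N2 = 25.2
bD_Ni  red_mix   f_bD = 0.91  r = 0.111  N2 = 27.1
bD_Ni  mix_red   f_bD = 0.91  r = 0.135  N2 = 23.8
```

Read: the chamber accumulated ~200 ppb N₂O per hour (3.7 µg N m⁻² h⁻¹);
after removing the atmospheric share, the emitted N₂O has a site
preference of 13 ‰ and δ¹⁸O of 42 ‰ — far above the fresh
bacterial-denitrification endmember along the reduction line — so
~90 % of the emission is attributed to bD and only r ≈ 0.11–0.14 of
the N₂O produced by denitrification escaped reduction.  The implied N₂
loss (24–28 µg N m⁻² h⁻¹) is six to eight times the measured N₂O flux.

## Command line

```bash
n2osource simulate --seed 1 --out campaign/          # synthetic campaign + truth sidecar
n2osource flux campaign/chamber_series.csv           # stage-wise
n2osource correct campaign/isotopocule_samples.csv
n2osource run --config run.yaml                      # full pipeline
```

`run.yaml` points at a data directory (CSV schemas are documented in
`n2osource/io.py`) and sets the campaign metadata (label form,
concentration margin, water δ¹⁸O, excluded units, seed).  The pipeline
writes per-stage CSV outputs plus `run_log.json` with versions, the
endmember-table hash, and every excluded record with its reason.

The endmember table and reduction isotope effects ship as an editable
YAML (`n2osource/data/endmembers.yaml`) with documented literature
defaults; pass `--endmembers` / `endmember_path` to use a revised
compilation.

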