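# Methods

This note documents the models implemented in `n2osource`, the
defaults chosen where the underlying experimental literature leaves a
choice open, and what the synthetic experiments do and do not
demonstrate.

## Isotope notation

Delta values are per-mil deviations from atmospheric N₂ (¹⁵N/¹⁴N =
0.0036765) or VSMOW (¹⁸O/¹⁶O = 0.0020052).  Conversions between delta
notation and atom fraction are exact,

x = ((δ/1000 + 1)·R_STD) / (1 + (δ/1000 + 1)·R_STD),

never the small-ratio linearisation; the inverse round-trips to
10⁻⁹ ‰ over δ ∈ (−999, 10⁶).  The ¹⁵N site preference of N₂O is
SP = δ¹⁵Nα − δ¹⁵Nβ (central minus peripheral nitrogen); bulk δ¹⁵N
defaults to the positional mean, and an independently measured bulk
value is accepted with a consistency check against that mean.  Atom-%
¹⁵N excess (APE) is the atom-% of a labeled sample minus that of the
paired natural-abundance sample, falling back to the reference value
0.36630 atom-% when no paired sample exists; slightly negative APEs of
unlabeled pools are retained (below-detection), not zeroed, so that
sums stay unbiased.

## Chamber fluxes

Headspace mole fractions (ppb) are converted to µmol m⁻³ with the
ideal gas law at the per-sample temperature and a fixed pressure of
101 325 Pa (chamber pressure is rarely logged; the value is
configurable).  The flux is the regression slope of concentration on
hours since closure, times volume/area (defaults 0.016 m³ and 1 m²,
the geometry of a chamber sealed over one rock wool slab at a planting
density of two plants per m²).  Series with ≥ 4 points use a Huber
M-estimator (tuning constant 1.345, iterated to 10⁻⁸ convergence, via
statsmodels RLM) — the default of the robust chamber-flux tools in
this field; 2–3-point series fall back to OLS.  An exactly linear
series defeats any robust scale estimate, so the implementation first
checks the OLS residuals and short-circuits to the (then exact) OLS
slope.  Negative fitted fluxes are retained to keep cumulative sums
unbiased.  Unit conversion uses two N atoms per N₂O and 14.007 g
mol⁻¹: 1 µmol N₂O m⁻² h⁻¹ = 28.014 µg N m⁻² h⁻¹ = 6.723 g N ha⁻¹ d⁻¹.

Cumulative emissions over the 24 h labeling window integrate the
rates at 0, 4 and 24 h by the exact trapezoid (identical to hourly
summation of linearly interpolated rates, removing any step-size
ambiguity); unplanted slabs, unaffected by plant activity, use one
constant rate.  Per experimental unit the total is 2 × planted slab +
1 × unplanted slab.

## Atmospheric-mixing correction

Chamber N₂O is a two-pool mixture of ambient and substrate-emitted
gas.  Because delta values mix linearly when concentration-weighted,
δ_emitted = (C_s δ_s − C_atm δ_atm)/(C_s − C_atm).  The correction is
applied to δ¹⁵Nα and δ¹⁵Nβ individually and SP is formed afterwards:
SP of a mixture is not the mixture of SPs, but α and β each mix
linearly, so this is exact.  Since the formula is linear in δ, SP
itself obeys the same formula, which is how its uncertainty is
propagated jointly (σ of the measured SP is √2 times the per-delta σ;
the α/β correlation through the shared concentrations is then handled
exactly).

Uncertainty uses the first-order delta method over σ(C_s), σ(C_atm),
σ(δ_s), σ(δ_atm); it matches a 10⁵-draw Monte-Carlo SD within 5 % at
the campaign's concentration contrasts (tested).  Defaults, chosen as
typical IRMS/GC repeatabilities and configurable: 0.5 ‰ per delta,
2 ppb per concentration.  The corrected value diverges as C_s → C_atm,
so samples less than a margin above ambient are excluded with a
recorded reason.  The default margin of 65 ppb is inclusive (a
*minimum difference*, so a sample exactly at ambient + margin is
retained) and, applied to the two campaigns' ambient concentrations of
272 and 294 ppb, yields absolute thresholds of 337 and 359 ppb.  Under
the default σs this margin keeps the propagated errors of retained
samples below 6 ‰ (SP) and 5 ‰ (δ¹⁸O), which is the rationale for its
magnitude.

## Dual-isotope mapping

Endmembers are literature (δ¹⁵N^SP, δ¹⁸O) signatures (mean ± SD) of
freshly produced N₂O for bD, fD, nD and Ni.  They are not universal
constants: they ship as an editable, versioned YAML whose content hash
is recorded in every result.  Denitrifier oxygen derives mostly from
water, so the δ¹⁸O of bD, fD and nD is shifted once by the measured
water δ¹⁸O (idempotency guarded); Ni oxygen derives from atmospheric
O₂ and is never shifted.  N₂O → N₂ reduction enriches the residual
N₂O along δ = δ₀ + ε·ln r (closed-system Rayleigh residual
approximation) with net isotope effects ε_SP = −5.9 ‰ and
ε_¹⁸O = −15.4 ‰ (slope 0.38) as defaults from the same compilation
literature.

Two process orders are solved per sample and per scenario (minor
endmember fD or Ni):

* **red_mix** — bD-produced N₂O is reduced to the residual fraction r,
  then mixed with the minor source at fraction f.  f is eliminated
  through the δ¹⁸O equation and the SP residual is driven to zero by
  bracketed root finding on ln r over r ∈ [10⁻⁴, 1] (801-point scan +
  Brent to ~10⁻¹⁴).  f(r) has one pole (where the Rayleigh path of bD
  crosses the minor endmember's δ¹⁸O); sign changes across it are
  discarded, and among genuine roots the one with f inside [0, 1] is
  preferred.  With no root in the bracket the boundary solution with
  the smallest residual is reported, clipped and flagged.
* **mix_red** — the sources mix first (point M on the endmember
  segment), then the mixture is reduced; M is the intersection of the
  segment with the line through the sample along (ε_¹⁸O, ε_SP),
  solved as an exact 2×2 linear system, and r = exp((δ¹⁸O_s −
  δ¹⁸O_M)/ε_¹⁸O).

Both solvers invert their forward models to 10⁻⁶ (tested over grids
and by property tests).  A structural consequence worth knowing: the
two cases share the same linear relation for f, so f_bD is identical
between red_mix and mix_red for a given sample — which is why campaign
tables report one f_bD per scenario "across cases" — while
r_red = r_mix^(1/f) ≤ r_mix.  Out-of-domain samples (f outside [0, 1],
r > 1) are clipped and flagged rather than dropped, so campaign
summaries keep complete cells with honesty preserved in the flags.
Campaign summaries default to per-sample solutions averaged afterwards
(a mean-delta mode exists; the two differ by Jensen effects when the
solvers are nonlinear in the deltas).  Per-cell uncertainty is
available by seeded Monte Carlo over endmember SDs and sample sigmas
(default 1000 draws).

The N₂ flux implied by a solution is F·(1−r)/r scaled by f_bD in the
red_mix case (only the bD stream passed the reduction step) and
unscaled in mix_red (the whole mixture passed it).  f_bD is
interpreted as the bD share of *emitted* N₂O — the convention under
which the back-calculated N₂ fluxes reproduce the published campaign
cells (tested to 2 %).

## ¹⁵N-tracer partitioning

With one dissolved pool labeled, the ¹⁵N content of emitted N₂O
identifies its source pool.  Two routes:

* **Non-equilibrium isotopologue route** (default for ¹⁵NO₃⁻ labeling):
  assuming a binomial ¹⁵N distribution *within* each source pool, the
  bulk atom fraction a_m and the doubly-substituted species fraction
  m₂ of N₂O from a two-pool mixture satisfy u = a_m − a_bgd,
  v = m₂ − a_bgd², ap = v/u − a_bgd, x = u/(ap − a_bgd), yielding both
  the enrichment ap of the *active* labeled pool and the fraction x of
  N₂O derived from it.  The inversion is the exact algebraic inverse of
  the forward model (tested to 10⁻¹⁰ over x ∈ [0.05, 1],
  ap ∈ [0.004, 0.11]).  Ion-current ratios 45R/46R are reduced to
  (a_m, m₂) exactly in ratio space after removing the oxygen
  contributions: ¹⁸R from the (supplied or assumed) δ¹⁸O of the N₂O —
  the ¹⁵N label does not alter the oxygen — and ¹⁷R from the
  mass-dependent relation ¹⁷R = K·¹⁸R^0.516 anchored at VSMOW.
  u ≤ 0 (no detectable label) returns a below-detection marker, never
  NaNs.  The ratio ap_N₂O / a(bulk pool) is exposed as a diagnostic:
  the active pool feeding N₂O production need not equal the bulk
  dissolved pool, and no interpretation is baked in.
* **Bulk mixing route** (mandatory for ¹⁵NH₄⁺ labeling, where labeled N
  can reach N₂O through both pools after nitrification):
  f_PN2O = (¹⁵a_N2O − ¹⁵a_NH4)/(¹⁵a_NO3 − ¹⁵a_NH4), with the *measured*
  pool enrichments at the matching time point (label dilution matters),
  not nominal label strengths.

The labeled fraction of *measured* N₂O is rescaled to the emitted
basis by conc/(conc − ambient), atmospheric N₂O carrying no label.
Fractions are clipped to [0, 1] only at reporting, with flags; raw
values are retained.  The total flux splits as NO₃⁻-derived =
f_PN2O × total and NH₄⁺-derived = remainder (the components always sum
to the total), under the recorded assumption that labeled-pool
emission grows linearly over the chamber closure like the total.  The
combined nitrifier-denitrification/coupled fraction is
f_nD/cND = f_bD − f_PN2O; negative values are returned flagged (they
signal a violated equal-pool assumption, not an arithmetic error).

## Mass balance

The total solution volume is estimated from label dilution,
V = c_label·v_label / c_measured(T4) with defaults 73 mg NH₄⁺-N L⁻¹ in
15 l, assuming pre-existing NH₄⁺ negligible (a correction for measured
pre-label NH₄⁺ exists but is off by default to reproduce the stated
assumption; at the observed 1.6–5.9 mg L⁻¹ it is a ≤ 2 % effect).
Pool N amounts: concentration × V for dissolved pools, dry weight ×
N content for shoots/roots/fruits, and the per-unit cumulative N₂O
emission for the gas pool, interval-wise (0–4 and 4–24 h, each with
its own APE; a single-mean mode exists as an alternative).  Excess ¹⁵N
per pool is APE/100 × N_pool; the ledger total is the exact sum and
the recovery rate is 100 × total / label (115 mg ¹⁵N for ¹⁵NH₄⁺
units, 120 mg for ¹⁵NO₃⁻ units).  Note an accounting subtlety: APE
measures *excess* over natural abundance, so even a closed system
recovers only the label's excess ¹⁵N (≈ 96.5 % of the label's total
¹⁵N at 10.5 atom-%); the synthetic recovery tests therefore use the
excess amount as the denominator when asserting 100 %.  Per-unit
exclusions (e.g. spillover between neighbouring units) are a
configuration flag, not hardcoded.

## Synthetic experiments

The generator emulates the statistical structure the inference
assumes, with one seeded `numpy` generator and bit-exact
regeneration:

* emitted isotope signatures by the chosen mixing case applied to the
  endmember table (the minor endmember is the fraction-weighted mean
  of the fD/nD/Ni signatures);
* headspace samples by exact forward mixing into ambient air
  (ambient defaults: 272 ppb, SP 18.7 ‰, bulk δ¹⁵N 6.3 ‰, δ¹⁸O
  44.5 ‰ — tropospheric literature values, configurable per campaign,
  since the campaign ambient deltas are not published);
* chamber series as linear accumulation from the ambient baseline,
  four points at 0/20/40/60 min, iid Gaussian ppb noise;
* 24 h of label dynamics in hourly steps with exact ¹⁵N bookkeeping:
  15 l of labeled solution mixed into a hidden residual volume
  (default 15 l, making the dilution-based volume estimate's truth
  30 l), first-order nitrification moving NH₄⁺ at its current
  enrichment into NO₃⁻, constant plant uptake, N₂O emission drawing
  from the two pools at the truth split f_PN2O (default 0.7), and an
  optional unmeasured sink that removes a configured percentage of the
  label's excess ¹⁵N (for loss-injection tests: recovery shifts by
  exactly −s).  Mass is conserved exactly in the no-loss
  configuration.

Default truth values sit at the campaign magnitudes: f_bD = 0.87,
r = 0.10, label strengths 10.5/11 atom-%, pool concentrations of
~73 mg NH₄⁺-N L⁻¹ labeled into ~160–250 mg NO₃⁻-N L⁻¹ background,
measurement noise 0.5 ‰ / 2 ppb / 2–3 % relative on pool assays.
Noise-free datasets are inverted exactly (solver round-trips to 10⁻⁶,
two-pool algebra to 10⁻¹⁰); noisy campaigns of 8 units recover f_bD
within ±0.05, r within ±0.02, f_PN2O within ±0.03, the solution
volume within 5 % and recovery within the ~5-point per-unit noise that
real campaign tables also show.

What this does *not* demonstrate: the generator contains no microbial
kinetics (no Monod/pH response, no temporal emission peaks), assumes
the active pools equal the bulk pools, uses a single effective minor
endmember rather than three independently varying ones, and draws all
noise Gaussian and independent.  Passing recovery tests therefore
validate the *inference algebra and its numerical implementation*, not
the biological assumptions; on real data the endmember and
process-order choices remain structural uncertainties that the
scenario × case grid is designed to bracket, and known inconsistencies
(f_PN2O > f_bD) surface as flags rather than being absorbed.

## Numerical choices

* Root bracket r ∈ [10⁻⁴, 1]; Brent tolerance ~10⁻¹⁴ on ln r; 801-point
  bracket scan; pole-crossing brackets excluded.
* Singular geometry (endmember segment parallel to the reduction line,
  or coincident endmembers) raises, it is not silently clipped.
* Threshold boundary inclusive; exclusion reasons recorded verbatim in
  the run log, each excluded record exactly once.
* Float-edge clips (|overshoot| ≤ 10⁻⁹) are not flagged; genuine domain
  violations are.
* All randomness flows from one `numpy.random.default_rng(seed)`; no
  global seeding.
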