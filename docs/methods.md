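# Methods

`opetk` implements a liver-based probabilistic risk assessment for two
organophosphate ester flame retardants — triphenyl phosphate (TPHP) and
tris(1,3-dichloro-2-propyl) phosphate (TDCPP) — exposed via indoor dust
ingestion.  The chain is: in vitro hepatocyte bioactivity (AC50, μM) →
population liver steady-state concentration (Css, μM) from a toxicokinetic
model over a Monte Carlo virtual population → reverse-dosimetry human
equivalent doses (HED, mg/kg/day) → margin of exposure (MOE) against
region-specific estimated daily intakes (EDI, ng/kg-bw/day), classified
into three concern tiers.

## Toxicokinetic model

Seven flow-limited compartments: gut, liver, lung, arterial blood, venous
blood, kidney, rest of body.  Chronic oral dosing is modelled as a
constant-rate infusion into the gut (the daily dose averaged over 24 h),
so the steady state is a true fixed point rather than a periodic orbit and
each individual's Css is a single number.  The model is linear,
`dx/dt = A x + b` in amounts; the steady state solves `A x* = −b` after an
eigenvalue stability check.  Css scales linearly with dose, which is what
licenses the reverse-dosimetry identity below.

Chemical-specific disposition:

* whole-liver intrinsic clearance `CLint_whole = Clint × hepatocellularity ×
  liver mass` (μL/min/10⁶ cells × 10⁶ cells/g × g, converted to L/h);
* hepatic elimination acts on the liver's plasma-equivalent concentration
  at rate `fub × CLint_whole`, which reproduces the well-stirred clearance
  `CL_h = Q_h·fub·CLint_whole / (Q_h + fub·CLint_whole)` at steady state
  (`Q_h` = hepatic artery + portal flow);
* renal elimination is glomerular filtration of unbound chemical,
  `CL_r = GFR × fub`, applied to the kidney's plasma-equivalent
  concentration (a well-stirred kidney analog; this guarantees positive
  steady states for any `CL_r`, at the cost of an effective renal
  clearance `Q_k·CL_r/(Q_k + CL_r)` marginally below `GFR × fub`);
* tissue:plasma partition coefficients are supplied as inputs (no
  prediction from logKow); blood pools have coefficient 1 and plasma is
  identified with blood;
* oral absorption is complete (`fabs = 1`) absent evidence otherwise.

Liver Css is reported as **total tissue concentration** (amount / liver
volume), converted to μM via the molecular weight.  Total vs. unbound
tissue concentration was a genuinely open choice; total is recorded here
and absorbed by the calibration diagnostic below.

An independent ODE route (`integrate_to_steady_state`, stiff Radau
integration of hand-written per-compartment balance equations, day-by-day
until the liver concentration settles) cross-checks the analytic solve;
the suite holds them to 0.1% relative agreement over random parameter
draws and verifies mass conservation (input − hepatic − renal sinks) to
1e-8 relative residual.

## Virtual population

Survey-derived population samplers are not reproducible from summary
statistics, so the sampler here is parametric: lognormal body weight,
liver fraction, hepatocellularity, cardiac output, GFR, fub and Clint,
independent except for allometry — liver mass ∝ BW, flows and GFR ∝
BW^0.75 (reference 70 kg).  Rest-of-body flow is the residual of cardiac
output, so flow balance holds by construction.  Draws outside validity
bounds (nonpositive, or fub > 1) are redrawn up to 100 times, then error.

Two groups: children 0–18 y (geometric-mean body weight 27 kg, GSD 1.6;
liver 3.4% of BW) and adults 18–79 y (70 kg, GSD 1.2; liver 2.6%).
Children carry a ×2 multiplier on intrinsic clearance, expressing the
higher per-kg metabolic capacity of the young; together with the larger
relative liver this gives children ≈2.5× the per-kg hepatic clearance and
correspondingly lower Css at a per-kg dose — the ordering the analysis is
designed to propagate.  Default n = 1000 per population; all sampling is a
pure function of (spec, seed).

Chemical fixture values (molecular weights 326.3 / 430.9 g/mol; partition
coefficients; TPHP Clint 10 μL/min/10⁶ cells, fub 0.05; TDCPP Clint 3,
fub 0.02) are standard-reference or plausible stand-ins, tagged
`fixture` in the provenance map.  TPHP gets the higher intrinsic clearance
and stronger tissue partitioning (the more lipophilic aryl ester); TDCPP's
low fub keeps hepatic elimination dominant over renal, the physically
sensible regime for a liver-cleared ester and the regime in which the
child/adult Css ratio is governed by metabolic capacity rather than
filtration.

**Calibration diagnostic.**  `make_fixture_bundle(calibrate=True)`
rescales each chemical's Clint by a single scalar (Brent root-find on the
geometric-mean log error, calibration populations of n = 500) so that
median liver Css at 1 mg/kg/day lands within ±25% of the published
medians (TPHP 8.17 child / 24.1 adult μM; TDCPP 25.34 child / 58.66 adult
μM).  This anchors medians only; percentile spreads remain emergent from
the population spec and are *not* expected to match the published spreads,
which encode survey-based variance and unpublished chemical parameters.
Passing tests therefore demonstrate the pipeline's structure and
qualitative orderings, not quantitative reproduction of tails.

## Reverse dosimetry

By linearity, `HED = AC50 × dose_ref / Css` per Monte Carlo sample; the
HED percentile at rank p equals the transform of the Css percentile at
rank 100 − p.  Percentiles use linear interpolation between order
statistics; a warning flags P0.1/P99.9 requests below 5000 samples, where
the estimator dominates.  Per-assay HEDs are merged into the "overall"
distribution by pooling samples with equal weight per assay (equal counts
enforced) — the simplest merge whose median can land between assay
clusters; a median-of-ranks alternative exists behind
`merge_assays(..., method="median_of_ranks")` and is not the default.
A summary-level pathway (`hed_from_css_percentiles`) computes HEDs
directly from printed Css percentile summaries; the animal route is
`HED = POD × DAF`.

## Risk characterisation

`MOE = HED / EDI` with HED converted mg → ng (×10⁶) so both tables can be
used in their native units.  EDI is a point median per (region, age
group); variability enters only through the HED distribution, so the MOE
percentile at rank p pairs with the HED percentile at rank p.  Tiers:
high concern MOE ≤ 1, moderate 1 < MOE < 100, low MOE ≥ 100, honoured at
machine precision at the boundaries.  Three interval bands are reported:
P2.5–P97.5, P1–P99 and P0.1–P99.9.

One population Css draw per (chemical, age group) feeds every assay and
every region, so all percentile tables of a pair are deterministic
transforms of the same Monte Carlo sample.

## Numerical choices and limitations

* Steady-state solves are batched 7×7 dense solves; stability is checked
  by eigenvalue sign per individual.
* ODE convergence: relative liver-concentration change < rel_tol over one
  simulated day, horizon 10 000 days.
* Cytotoxicity filtering is strict (`AC50 < limit`); ties drop.  The
  shipped cytotoxicity limit (1000 μM) is a fixture chosen above all
  surviving assays' AC50s, since the underlying limits are not public in
  summary form.
* Children's MOE medians fall below adults' wherever children's intake
  clearly exceeds adults' (the typical pattern, driven by higher dust
  ingestion per kg).  This is *not* universal: a few surveyed regions
  report adult intakes at or above children's (e.g. Brazil, Nepal TDCPP),
  and there the ordering reverses because children's HEDs are ~2.5× higher.
  The regression suite asserts the majority pattern, not a universal law.
* The EDI table treats each survey median as a point value with no
  uncertainty, and AC50s are point values; only toxicokinetic variability
  is propagated.  Dermal and inhalation routes, metabolite tracking and
  partition-coefficient prediction are out of scope.
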