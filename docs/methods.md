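# Methods

## The model

`emsurv` estimates how many out-of-hospital cardiac arrest (OHCA) patients an
EMS system saves per year in a region, and how that number responds to design
changes — parallel dispatch of fire services as first responders, or trimming
the static intervals of the alarm process. The chain is three quantities for
a region *i* and a resource set *j*:

1. **Eligible patients.** `R = I · (1 − P_A)`, where *I* is the annual OHCA
   incidence with resuscitation attempted and *P_A* the probability the
   arrest occurred after ambulance arrival (those cases cannot benefit from
   faster dispatch). Defaults: *I* = 816/yr, *P_A* = 0.15, giving
   R = 693.6/yr.
2. **Survival probability.**
   `S = Σ_{t=1}^{N} (b_t / POP) · VF_t · s_t`, with *N* = 31 minute bins.
   `b_t` is the population newly reached at total time-to-defibrillation bin
   *t* (so `b_t / POP` is the probability a uniformly-located patient is
   treated in bin *t*), `VF_t` the probability of still being in ventricular
   fibrillation — the only defibrillatable rhythm — at *t*, and `s_t` the
   probability of 1-month survival given VF and defibrillation at *t*.
3. **Expected survivors.** `β = R · S`.

Because survivor percentages can be quoted against either denominator,
results report both `S` (among eligible patients) and `β / I` (among all
arrests with resuscitation attempted); neither is privileged.

### Time composition

Total time to defibrillation = static alarm-process overhead + simulated
response time. The statics are geography-independent: incident-to-call
(default 2 min), emergency call handling (1.5 min) and on-scene preparation
(1.5 min) — 5 minutes in all. The simulated part is station reaction time
plus shortest-path drive time. With the 1.5-minute minimum reaction time, no
patient can be treated in under 6.5 minutes under the defaults.

Static design changes (e.g. one minute less call handling) are evaluated as
integer-bin translations of the reach curve along the composed time axis:
the geography is untouched, every home is simply treated that much earlier
or later. Mass pushed below bin 1 accumulates in bin 1, mass pushed past the
last bin accumulates there. The shift-0 row of a marginal-effects table
reproduces the unshifted scenario exactly.

### Binning

Bin *t* covers continuous times in (t−1, t] minutes (ceil binning; τ = 0
maps to bin 1). Ceil is conservative: a home is never credited with an
earlier arrival than simulated. Bin 31 is the open-ended "31+" bin; by
default, population treated beyond 31 minutes receives the bin-31 curve
values (matching the curves' own terminal-bin convention), with a `tail=
"zero"` sensitivity option that grants no survival past 31 minutes instead.
Homes with no road connection to any station count as unreached: they earn
zero survival but remain in the POP denominator.

## Drive-time simulation

Edge traversal time is `60 · length / speed` minutes at the speed limit,
with the speed reduced by 20% on locality edges (congestion in built-up
areas), i.e. a factor 1/0.8 = 1.25 on the pure drive time. The per-home
response time for one resource kind is the minimum over that kind's stations
of (reaction time + shortest-path drive time). Implementation: a virtual
alarm node is connected to every station with edge weight equal to the
station's reaction time, and one Dijkstra run from it yields the
min-over-stations directly; this is provably equivalent to per-station
single-source runs and is cross-checked in the test suite against exhaustive
simple-path enumeration on small random networks. Dual dispatch is the
per-home elementwise minimum of the single-kind fields — the patient is
treated by whichever defibrillator-carrying vehicle arrives first — which
makes the dominance property (dual ≥ ambulance-only, bin by cumulative bin)
structural rather than empirical.

Roads are undirected, vehicles are assumed at their stations at alarm time,
and there is no queueing, turn penalty, one-way handling, time-of-day
variation or vertical (floor-level) delay. These are model simplifications,
not calibrated features.

## Treatment-probability curves

`VF_t` and `s_t` exist in registries only as published figures, so the
package never ships eyeballed figure readings as ground truth. Curves are
either loaded from a user CSV (`minute_bin, vf, surv`, bins 1..31, validated
strictly — missing/duplicate bins and out-of-range probabilities are errors,
never clipped) or generated from a parametric family: per-curve exponential
decay `c_t = c0 · exp(−rate·(t−1))` or clamped linear decay
`c_t = max(0, c0 − rate·(t−1))`.

**Default calibration** (linear): `vf` from 0.65 falling 0.0145/min (0.215
at bin 31, mirroring the register-like decline of VF prevalence with delay)
and `surv` from 0.946 falling 0.0845/min (zero from bin 13). The combined
treatable product `VF_t · s_t` then starts at ≈0.615, loses ≈0.055 in
absolute terms per minute on average, and is exactly zero from bin 13 — the
canonical clinical decline figures (~67% survival with immediate treatment,
−5.5 percentage points per minute, no survival past ~12 minutes of delay).

The generator optionally elevates VF bins 1–2 (arrests witnessed by EMS
crews already on scene inflate the earliest registry bins) and enforces a
non-increasing product from bin `monotone_from` (default 3) onward, scaling
survival down where seeded noise or the early-bin override would break it.
Whether the early elevation should be included at all is genuinely open —
the eligible-patient step already removes the after-arrival fraction `P_A`,
so elevated early VF bins may double-count EMS-witnessed cases; both
behaviours are config options (`vf_early_bins`), neither labelled correct,
and the default omits the elevation.

## Synthetic regions

The generator emulates the data layer of a regional GIS platform:

* **Network**: *n* nodes uniform on a square (defaults: 900 nodes, 80 km
  side), joined when closer than the radius giving a target mean degree of
  3.5; disconnected components are bridged through their nearest node pairs,
  so connectivity is guaranteed by construction. Edge lengths are Euclidean
  (floored at 50 m); speed limits are drawn from {50, 70} km/h on locality
  edges and {70, 90, 110} km/h elsewhere, weighted toward the lower values.
* **Localities**: 35% of nodes, grown as contiguous BFS clusters from random
  seeds (≈60 nodes per cluster) — an approximation of the census settlement
  concept (groups of buildings ≤200 m apart housing ≥200 people), which a
  point-process generator cannot reproduce literally.
* **Homes**: 3000 home sites, drawn with 4× weight on locality nodes (urban
  concentration); the regional population is spread over homes as one person
  each plus a uniform multinomial, so Σ inhabitants = POP exactly and every
  home has ≥1 inhabitant. Homes are used as the arrest locations, with
  identical risk everywhere — the standard at-home-arrest assumption
  (65–74% of OHCAs occur at home).
* **Stations**: placed with the same locality preference. All ambulance
  stations share a 1.5-minute reaction time. Fire stations are 50% full-time
  (1.5 min) and 50% part-time with reaction times uniform on 3–7 minutes
  ("longer and varied" is all that is documented about them; the uniform
  interval is a generator choice).

The Stockholm-like default carries the study-region facts — population
1 949 516, 43 fire stations, incidence 816/yr, P_A = 0.15 — while the
network size (900 nodes / 3000 homes) and the ambulance-station count (30,
never published for the region) are generator choices, sized so a large
share of the population is reached within a handful of simulated minutes.

### What the synthetic regions do and do not show

Passing tests on synthetic regions demonstrate the model's internal laws —
conservation, dominance of dual dispatch, monotone loss under delay,
diminishing dual-dispatch advantage with growing overhead — and that the
pipeline's magnitudes are plausible (a few-per-cent baseline survival, a
positive dual-dispatch increment of the order of ten survivors/year). They
do not reproduce any real region's exact survivor counts: those depend on
the true road network, the true population distribution and register-exact
curves, none of which the generator knows. Absolute β values from synthetic
runs should be read as demonstrations, not predictions.

## Numerical choices

* Inhabitants are integers throughout; reach-curve conservation
  (Σ b_t + unreached = POP) is integer-exact.
* β = R·S holds to full floating precision by construction (it is computed
  as that product), and Σ per-bin contributions = S up to float summation.
* Shortest-path ties are measure-zero (continuous travel times); Dijkstra's
  distance value is unique regardless of path choice, so no tie-break can
  affect results.
* Region/curve CSVs are written with 17 significant digits and read with
  round-trip float parsing, so write→read is bit-exact.
* Curve generation is deterministic when noiseless; all stochastic steps run
  through one `numpy` generator seeded explicitly. Region generation is a
  pure function of (config, seed).

## Known limitations

Uniform at-home arrest risk (no demographic or diurnal structure); undirected
roads with flat locality slowdown; vehicles always at their stations; no
asystole/PEA benefit from earlier CPR (excluded deliberately — only VF
responds to defibrillation in this model); no benefit model for stationary
public-access defibrillators (the reach-curve formulation assumes the
defibrillator travels to the patient); point estimates everywhere, so
parameter uncertainty must be explored by scenario sensitivity (the CLI's
shift grid and the call-handling analysis script) rather than by internal
error propagation.
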