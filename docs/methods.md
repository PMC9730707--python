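# Methods

## The measurement model

A pot on a gravimetric phenotyping platform is a closed water ledger: system
weight W = tare + soil water + plant fresh mass. Between irrigation events,
−dW/dt is whole-plant transpiration. Everything the package derives rests on
that identity.

**Transpiration rate.** Tr(t) = −dW/dt is estimated as the slope of a
centered local linear regression over 2h+1 samples (default half-width h = 5,
≈ 33 min at the 3-minute cadence). Raw first differences of a 3-minute weight
stream are dominated by balance noise (±0.1 g on a ~1 kg load); the local
regression is the mildest smoother that keeps the estimator linear and
offset-invariant. Regression windows never cross an irrigation pulse:
flagged samples are excluded and windows are confined to the contiguous
segment between pulses, because a window straddling a pulse would see a level
shift, not a slope. With h = 0 the estimator degrades to signed forward
differences, whose daily integral telescopes exactly to the day's weight loss
— the form used in the mass-balance checks. Negative estimates are clipped to
zero (transpiration is non-negative; small negatives are noise or
condensation) and the clip count is reported.

**Daily aggregates.** E = mean predawn weight (04:00–04:30) − mean evening
weight (19:00–19:30), same day. PG = predawn(d+1) − predawn(d), defined only
when nightly irrigation returns the pot to capacity (otherwise the predawn
difference mixes soil water with plant mass; requesting PG in a drought phase
raises an error). WUE = ΣPG/ΣE over a fixed window (5 days in the reference
protocol). All windows are half-open [start, end) and a window mean is
declared missing below 75% sample coverage — deterministic handling of edge
samples and data gaps.

**VPD.** The Magnus/Tetens form es(T) = 0.6108·exp(17.27 T/(T+237.3)) kPa,
VPD = es·(1−RH/100) — the standard micrometeorological parameterisation; the
constants live in a config record so an alternative calibration can be
swapped. The air-saturation deficit is used (not leaf-to-air). Midday
normalisation Tr_m,VPD = Tr_m/VPD_m is suppressed when VPD_m ≤ 0.05 kPa to
avoid blow-up on near-saturated days.

## The two-segment drydown response

The response of y = Tr_m,VPD to x = VWC is modelled as a continuous hinge:
y = a for x ≥ θ_cri and y = a − k(θ_cri − x) below, with k ≥ 0 under the
decline-positive sign convention (the slope of y against VWC below the
breakpoint; steeper decline = larger k). Conditional on θ the model is linear
in (a, k) through the basis x' = min(x − θ, 0), so the fit profiles RSS(θ):

1. candidates = a uniform grid (default 200 points) between the 2nd-smallest
   and 2nd-largest observed VWC, **plus** candidates inside every interval
   between consecutive observed VWC values. The RSS profile is smooth only
   within such intervals (the hinge assignment changes at each data point),
   and with irregular spacing a narrow RSS dip can fall between uniform grid
   points — the per-interval candidates keep the search equivalent to
   exhaustive enumeration (verified against a 10⁴-candidate brute force);
2. candidates that leave fewer than two points on either side are skipped;
3. the best cell is refined by bounded golden-section search; RSS ties break
   toward the smaller (more conservative) θ.

R² = 1 − RSS/TSS. `se_a`/`se_k` are conditional OLS errors (θ treated as
known); `se_theta` comes from a case-resampling bootstrap (refits that fail
on degenerate resamples are dropped and counted; >50% failures flags the fit
unstable). Replicate ± values are the between-pot mean ± sd across converged
fits — the spread a multi-pot experiment actually reports — with the
bootstrap SE available as the within-plant alternative.

**Which plant-days enter the fit.** One (VWC, Tr_m,VPD) point per plant-day
during the progressive-drought phase, while the pot is still drying
*dynamically*: a day qualifies if its midday VWC fell by at least
0.0015 m³ m⁻³ since the previous day. Once transpiration has collapsed, VWC
flattens at its terminal value θ_cri − a/k; those quasi-static days would
pile replicate points at a single location without carrying response
information, and in a real experiment the plant would have been rewatered
(wilting) before reaching them. The cutoff corresponds to midday
transpiration ≈ 15% of the plateau under default conditions.

## The pot simulator

The simulator emulates the platform's streams with complete ground truth.
Euler stepping at the 3-minute cadence:

- Tr = g_ref · PAR/(PAR+p50) · VPD · f(VWC), with f = 1 above θ_true and
  f = max(0, 1 − (k/a_eff)(θ_true − VWC)) below. Because transpiration is
  multiplicative in VPD, dividing the midday mean Tr by the midday mean VPD
  recovers a clean two-segment relation in VWC — the property the VPD
  normalisation assumes. The plateau a_eff = g_ref·Σ(s·VPD)/ΣVPD over the
  midday window of the deterministic forcing, so the *emitted* midday
  response is exactly the hinge with parameters (a_eff, k_true, θ_true)
  (noiseless deviation < 10⁻³·a_eff, discretisation only).
- Water balance: W(t+Δ) = W(t) − TrΔ + irrigation − drainage + growth, with
  nightly fertigation pulses (240 s at 00:00, 01:00, 02:00, 03:00) and
  drainage as an instantaneous clip at pot capacity — predawn weights sit at
  capacity under the well-watered schedule, which is what makes PG
  well-defined. Conservation closes to float precision and is asserted to
  10⁻⁶ g in tests.
- Growth (default 0.79 g d⁻¹ fresh mass) is credited during the 00:00–04:00
  irrigation window, so plant mass is constant across the predawn→evening
  span and E equals the day's transpiration integral exactly in noiseless
  runs; growth applied during daylight would contaminate E by the daytime
  mass gain, an artefact real platforms also carry but which would obscure
  the exact identities the tests rely on. Growth pauses while VWC < θ_true
  (stress–growth coupling).
- The pot surface is treated as covered (standard on these platforms): no
  soil-evaporation term, and Tr = 0 at night (PAR = 0). Daylight runs
  07:00–19:00 with solar noon at 13:00, making the forcing symmetric about
  the midday window and placing all transpiration inside the predawn→evening
  weight window.
- Balance noise is Gaussian observation noise on the emitted weights (the
  internal ledger stays exact). VWC = (W − tare − plant mass)/(1.5 L),
  emitted per pot in the environment stream.

**Scale of the default conditions.** Pot volume is 1.5 L (container capacity
VWC 0.30). For a multi-week progressive drydown on that volume — the regime
that yields ~one response point per day for 20+ days — mass balance forces a
daily demand of only ~15–20 g. The default drydown climate is therefore a
humid protected-cultivation (plastic-tunnel) profile: T 12–20 °C, RH 82–97%,
PAR peaking at 1000 µmol m⁻² s⁻¹, giving midday VPD ≈ 0.4 kPa, plateau
a_eff ≈ 0.083 g min⁻¹ kPa⁻¹ and E ≈ 17 g d⁻¹. The generic bright-greenhouse
preset (T 12–32 °C, RH 35–90%, PAR ~1200) remains the default for standalone
environment simulation. The absolute plateau is an order-of-magnitude choice
— published drydown analyses report (θ_cri, k) but not absolute Tr scales —
and the recovery results depend only on (θ_cri, k), not on a_eff. The default
growth rate is scaled to the default demand so that 5-day WUE lands near
0.045 g g⁻¹, the magnitude observed for recovering strawberry.

**Variety presets.** Hongyan (θ 0.1944, k 2.3915), Xiangye (0.1410, 4.6011),
Zhangji (0.1327, 2.7851) — the published per-variety estimates used as
generative truth, with the shared plateau-scale defaults.

**Rewatering policies.** `ck` (nightly irrigation throughout), `none`
(drought to the end), `rewater_at_theta` (resume once VWC ≤ θ_true) and
`rewater_at_wilting` (resume once f ≤ 0.10, a wilting proxy), checked at
each midnight. Phase boundaries (well-irrigated → progressive drought →
water recovery) are emitted in the truth record.

**What the simulator does not emulate.** Soil hydraulic retention curves
(VWC maps linearly to stored water), root growth, nutrient dynamics,
evaporative losses from the substrate surface, sensor drift, and diurnal
hysteresis in the Tr–VWC relation. Passing recovery tests therefore shows
that the estimator chain is correct and well-calibrated under the stated
noise — not that real strawberry data are this clean; on real data the
residual structure around the hinge would be wider and the "dynamic period"
selection more consequential.

## The parameter-recovery protocol

For each variety: 4 replicate pots, 26 simulated days (one well-watered
night, then irrigation withheld), pipeline extraction of the midday response
(~15–20 dynamic plant-days per pot), Gaussian noise with sd = 5% of the
plateau added to the extracted Tr_m,VPD values (clipped at zero; the points
retained by the dynamic-period rule sit ≥ 2.8 sd above zero, so clipping is
negligible), per-pot fits, between-pot aggregation. The balance itself runs
noiseless in this protocol so the injected 5% is the *total* measurement
noise, exactly as stated. Per-pot seeds derive from one root seed.

## Statistical components

- **Two-way ANOVA**: fixed-effects treatment × day with interaction, type II
  sums of squares from least-squares model comparisons (SS_A = RSS(B) −
  RSS(A+B), etc.); p-values from the F distribution; the all-values-equal
  degenerate case returns F = 0, p = 1. Day is a plain fixed factor —
  repeated measures on the same pot are deliberately not modelled. Verified
  against an independent implementation on unbalanced layouts and calibrated
  (uniform null p-values) by simulation.
- **Post-hoc**: Tukey's honestly-significant-difference from the
  studentized-range definition (Tukey–Kramer SE for unequal n), the classic
  "q" companion to ANOVA; family-wise error verified ≤ nominal under a
  simulated null. The method slot is pluggable should a different pairwise
  procedure be preferred.
- **BH-FDR**: the step-up procedure implemented from its definition and
  checked against both a brute-force step-up and an independent library
  implementation.
- **DEG rules**: expression floor FPKM ≥ 1 in ≥ 3 of 6 samples; replicate
  CV < 0.2 (sample sd / mean) applied per condition, only to conditions whose
  replicate mean reaches the floor — a condition where the gene is off may be
  noisy. The alternative reading (one CV across all 6 samples) is available
  via `cv_scope="all"`. The test is a Welch t on log2(FPKM+1) (FPKM is a
  normalised abundance, not a count; no test was prescribed upstream, so the
  default is documented and pluggable). Fold changes use ε = 0.1 pseudo-FPKM;
  DEG status requires |log2FC| ≥ 1 and q ≤ 0.05 within the filtered family.

## Numerical and policy choices, collected

| choice | value | why |
|---|---|---|
| derivative half-width | 5 samples (~33 min) | mildest smoother that tames ±0.1 g balance noise |
| window convention | half-open, 75% coverage | deterministic edges and gap handling |
| VPD guard | 0.05 kPa | avoids normalisation blow-up near saturation |
| breakpoint grid | 200 + per-interval candidates + golden refine | exhaustive-equivalent, globally robust |
| RSS tie-break | smaller θ | conservative irrigation trigger |
| dynamic-period cutoff | ΔVWC ≥ 0.0015 d⁻¹ | excludes the uninformative terminal plateau |
| irrigation jump threshold | 5 g per 3-min interval | far above noise, far below pulse size |
| alignment tolerance | step/2, max gap 9 min | no interpolation across gaps |
| bootstrap | 200 case resamples | within-plant SE complement to replicate sd |
| ε pseudo-FPKM | 0.1 | finite ratios without moving 2-fold calls at the floor |

## Known limitations

Single-timezone clock-time windows (no DST); no mixed-effects or
autocorrelation-aware treatment modelling; the hinge model is the only
response form offered (no spline/logistic alternatives); the simulator's
stomatal response is exactly the fitted model family, so recovery tests probe
estimation error, not model misspecification; FPKM-level DEG calling is
intentionally simple and is not a substitute for count-based models when raw
counts are available.
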