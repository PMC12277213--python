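# Methods

`berryflux` simulates the growth of a highbush blueberry (*Vaccinium
corymbosum* 'Bluecrop') fruit as a biophysical single compartment exchanging
water and sugar with the plant, with the phytohormone abscisic acid (ABA)
acting as the ripening signal that re-tunes the exchange coefficients over
the season.  This note records the model equations as implemented, the
reasoning behind every genuinely open design choice, the defaults and what
they mean, and the limits of what the synthetic-data tests demonstrate.

## State variables and bookkeeping

The state is the dry mass *s* (mg) and water mass *w* (mg) of one fruit;
fresh mass is *s* + *w* by definition (seed mass is negligible in blueberry
and is not tracked).  Time runs in hours from anthesis (t = 0; DAA = days
after anthesis).  The balances

    ds/dt = U_s − R_f            (sugar uptake − respiration)
    dw/dt = U_x + U_p − T_f      (xylem + phloem inflow − transpiration)

are enforced as exact identities at every step: the integrator returns the
flux decomposition alongside the state, and the tests check both identities
to 1e−12 relative over the whole packaged season.

## Thermal time and the ABA signal

Cumulative growing degree hours, cGDH = Σ max(0, min(T, T_o) − T_b),
accumulate hourly from anthesis (base T_b = 5 °C, optimum cap T_o = 30 °C).
The convention is that cGDH at a timestamp counts the hours already
elapsed, so cGDH(anthesis) = 0.

ABA concentration (µg per g dry mass) follows a beta-growth curve of
thermal time with four parameters — initial ABA_0, peak ABA_f, inflection
abscissa ABA_m and peak abscissa ABA_e (both in K·h):

    g(x) = max(0, (1 + (ABA_e − x)/(ABA_e − ABA_m)) · (x/ABA_e)^(ABA_e/(ABA_e − ABA_m)))
    ABA(x) = ABA_0 + (ABA_f − ABA_0) · g(x)

g(0) = 0, g(ABA_e) = 1 and g declines beyond the peak, reproducing the
rise–surge–decline pattern of non-climacteric fruit; the raw form would go
negative at very large thermal times and is clamped at zero.  The
normalised signal ABA_norm = (ABA − ABA_0)/(ABA_f − ABA_0) ∈ [0, 1] is the
single channel through which ABA modulates the fluxes.  ABA_m is treated as
the inflection of the accumulation curve rather than a hard onset
threshold; "onset" in this shape is simply where the curve becomes
appreciable.  Accumulation is hourly, not a daily aggregate.  ABA_0 and
ABA_f are cultivar constants: warming shifts the curve in time but never
changes its endpoints, and the tests assert exactly that.

## Carbon flux

Sugar uptake has three routes.  Concentrations on the carbon side are mass
fractions (mg sugar per mg water); the mM phloem driver is converted with
the sucrose molar mass (342.3 g mol⁻¹).

* **Active uptake**: U_a = ABA_sugar(u) · v_m · s · C_p/(K_m + C_p) · I(t),
  Michaelis–Menten in the phloem sugar, proportional to dry mass (sink
  size), gated by a logistic inhibitor I(t) = 1/(1 + exp((t − t*)/τ)) of
  fruit age, and scaled by the ABA factor ABA_sugar(u) = k_ABA · B(u) where
  B is the same beta shape in the normalised signal, peaking (at k_ABA)
  when u = STP_e and negligible below STP_m.  ABA stimulates transporter
  activity up to an optimum and suppresses it beyond — this is what lets
  simulated dry mass peak and then decline late in the season.  The
  inhibitor clock runs on hours since anthesis, not thermal time; this
  keeps the uptake shutdown anchored to fruit age while the ABA window
  shifts with climate, which is what produces the earlier-but-smaller dry
  mass peaks under warming.
* **Mass flow**: U_mf = max(0, U_p) · C_p — sugar advected with phloem
  water; a reverse phloem water flux carries no sugar out.
* **Diffusion**: U_diff = max(0, p_s · A_m · (C_p − C_f)) with the fruit
  sugar concentration C_f = ssr · s/w; likewise one-way into the fruit.

Respiration is R_f = q_g·max(0, ds/dt) + q_m(T)·s + q_r·ABA_norm with Q10
maintenance kinetics q_m(T) = q_m_ref · Q10^((T − T_ref)/10).  The growth
term applies only to positive growth, so the late-season dry-mass decline
does not manufacture negative respiration.  Because growth respiration
depends on ds/dt itself, the pair (ds/dt, R_f) is solved in closed form:
ds/dt = (U_s − q_m s − q_r·ABA_norm)/(1 + q_g) when that is non-negative,
otherwise the ungrown branch; either way ds/dt + R_f = U_s exactly.  The
ripening term is q_r · ABA_norm (units mg h⁻¹, matching the coefficient's
stated unit), not scaled by s.

## Water flux

Geometry: V = w/ρ_water + s/ρ_dry; surface area A_f = c_area·(fresh/1000)^(2/3)
(c_area = 4.84 cm² g^(−2/3) is an exact sphere at unit density); the
composite membrane area is A_m = a_mem·A_f, and both vascular pathways see
the full A_m (the usual equal-area convention).

Osmotic pressures close via van't Hoff, π = RTC·10⁻⁶ MPa (C in mol m⁻³);
the fruit side adds a fixed non-sugar contribution `osm_other` for organic
acids and ions.  Boundary conditions: the xylem is at stem water potential
with negligible osmolarity (P_x = Ψ_stem, π_x = 0); the phloem is in local
water-potential equilibrium with the stem, P_p = Ψ_stem + π_p(C_p).

ABA enters the water side twice, both as exponential decays in the
normalised signal:

    L(u) = L_max · exp(−k_L·u)            hydraulic conductivity, both pathways
    ρ(u) = ρ_min + ρ_0 · exp(−k_p·u)      skin permeability (floor ρ_min)

The exponential form for L mirrors the stated exponential for ρ; a ripening
fruit hydraulically uncouples from the plant and seals its skin.
Transpiration is T_f = A_f · α(T) · ρ(u) · max(0, H_f − H_a) · 1000 with
α(T) the saturated vapour density from the Magnus formula
(P_sat = 610.94·exp(17.625·T_C/(T_C+243.04)) Pa, Alduchov–Eskridge
constants) and H_f = 0.996 the internal air-space humidity; condensation is
clamped to zero.

Growth is plastic (Lockhart) only — elastic storage is neglected, standard
in this framework.  Cell-wall extensibility decays logistically with age,
φ(t) = φ_max/(1 + exp((t − t_φ)/s_φ)), so expansion shuts down as walls
stiffen.  Each step solves the linear turgor closure

    [G·(a_x − P_f) + G·(a_p − P_f) − T_f]/ρ_water = V·φ·(P_f − Y)

with G = A_m·L and a_j = P_j − σ_j(π_j − π_f).  If the solution exceeds the
yield threshold Y the fruit grows at V·φ·(P_f − Y); otherwise P_f is
re-solved with the growth term removed (hydraulic equilibrium) and clamped
at ≥ 0 — only then can the fruit lose water on net, which is what happens
on hot afternoons when Ψ_stem is near −1.8 MPa.  The two branches agree at
P_f = Y.  A residual of the solved balance is carried through to the output
table and checked to 1e−10 every step.

## Integration

Fixed-step explicit Euler at the weather resolution with integer substeps
(default 2 per hour; drivers held constant within the hour).  The dynamics
are smooth and the scheme's adequacy is measured, not assumed: halving the
substep changes the final fresh mass by ~0.5% on the default
configuration, checked in the tests.  If a degenerate parameterisation
drives a mass negative it is clamped at zero and the run logs one summary
warning; calibration searches routinely visit such corners and must not
crash there.

## Environmental drivers and the synthetic season

Runs are forced by hourly temperature and relative humidity plus two
boundary profiles whose ranges are fixed study conditions: stem water
potential oscillates diurnally between −0.10 and −1.8 MPa, and phloem
sucrose lies between 15 and 100 mM.  Their within-range shapes are declared
package defaults, not facts inherited from data: Ψ_stem is a sinusoid
peaking (least negative) pre-dawn at 04:00 and bottoming at 16:00; C_p is a
raised cosine over the season, low at anthesis, peaking mid-season.  The
synthetic weather generator produces a Suwon-like temperate season (May–
August): a seasonal half-sine warming trend, a diurnal cosine peaking at
14:00, anti-phase relative humidity, Gaussian noise, all reproducible from
a seed.

What the generator does *not* emulate: weather fronts and multi-day
autocorrelation, rain events, heat spikes (except via the temperature-offset
scenario), vapour-pressure-deficit asymmetries, or any coupling between
Ψ_stem and the atmosphere.  Passing tests therefore demonstrate internal
consistency and the qualitative climate responses of the model, not
predictive skill on real orchard data — that requires observed weather and
harvest series supplied as CSV.

## Parameters

The registry carries every constant with units, bounds and a provenance
flag.  Thirteen parameters are flagged `calibrated` — the set a field
calibration would tune (ABA_m, ABA_e, a_mem, ρ_0, ρ_min, k_p, k_L, Y, v_m,
k_ABA, STP_m, STP_e, q_r) — and the sensitivity analysis covers exactly
this set.  Values flagged `placeholder` are defaults chosen once inside
literature ranges to make the packaged season realistic for a ~2 g
blueberry (final dry fraction ~11%, ABA peak 32.3 µg g⁻¹ near 60 DAA, dry
mass peaking ~52 DAA and declining a few percent by 80 DAA); they are not
measurements and must be recalibrated for any real dataset.

## Evaluation toolkit

Goodness of fit uses MAE, RMSE, range-normalised RMSE, Nash–Sutcliffe
efficiency EF = 1 − SSE/SST, and Willmott's refined index of agreement d_r
(the bounded two-branch form).  Metrics are computed on paired observation
times only — each harvest at d DAA is matched to the simulated hour nearest
24·d — and ABA observations at or below the 0.01 µg mg⁻¹ detection floor
are censored out of the ABA metrics.

Local sensitivity is one-at-a-time: each parameter is raised 10% with the
others fixed and the coefficient S = 10·(ΔW/W)/(ΔP/P) (percent per
standardised 10% increase) is reported for the final dry, water and fresh
mass; n + 1 simulations total.  Because active uptake is proportional to s,
its parameters act multiplicatively on an exponential growth phase, and
their coefficients are large (tens of percent); the identity-pathway and
disconnected-parameter cases are exact (10% and 0%) and tested.

Calibration is two-stage, mirroring how the model would meet data: the ABA
curve's thermal-time parameters (ABA_m, ABA_e) are fitted first against ABA
observations — cheap, since ABA depends only on weather — then frozen while
the remaining free parameters are fitted to fresh-mass observations through
full simulations.  The optimiser is differential evolution over the
registry bounds, seeded and with deterministic polish (L-BFGS-B on a
unit-cube rescaling of the bounds; the internal objective is the MSE, which
is smooth at the optimum where the RMSE is conical, and the reported
objective is its square root).  One identifiability fact matters: v_m and
k_ABA enter U_a strictly as a product, so they cannot be identified
jointly; recovery studies fit one with the other held fixed, and a joint
fit of both should be interpreted as fitting their product.

## Known limitations

* ABA is empirical (thermal-time beta growth), not a biosynthesis/
  degradation/transport model; it cannot respond to water stress.
* No whole-plant coupling: Ψ_stem and C_p are imposed, so source limitation
  and competition between fruits are outside the model.
* Skin permeability follows ABA_norm instantaneously; since ABA declines
  after its peak, permeability partially rebounds late in the season,
  whereas real cuticular wax deposition is irreversible.  With the default
  k_p the effect on late water mass is a few percent.
* Fruit temperature equals air temperature; no radiation balance.
* Growth sensitivity to the uptake parameters is exponential in character;
  calibration of v_m/k_ABA against noisy data is well behaved, but
  extrapolating far outside the fitted climate should be done with care.
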