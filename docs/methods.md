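# Methods

## Virtual population

Each virtual patient is a vector (body weight, Vd/kg, f_u, CL_NR, SA at
Qd 300/100/50 mL/min, SC at Quf 5 mL/min) drawn independently per
parameter from a log-normal distribution and truncated to the published
plausible range. The published summaries are arithmetic mean ± SD, so
the underlying normal parameters are moment-matched:

    σ² = ln(1 + (sd/mean)²),  μ = ln(mean) − σ²/2.

Truncation is by rejection resampling, not clipping: no probability mass
piles up at the bounds, at the cost of post-truncation moments deviating
slightly from the nominal mean/SD (documented, not corrected — for
heavily left-truncated parameters such as cefepime Vd/kg, where ~19% of
the untruncated mass lies below the 0.25 L/kg bound, the realised mean
sits a few percent above the nominal one). A range lower bound of 0 is
treated as "no lower truncation" since the log-normal support already
excludes 0. Fractions (f_u, SA, SC) are truncated to [0, 1]; a window
capturing < 10⁻⁶ of the mass raises an error rather than looping
forever. With sd = 0 the sampler degenerates to the constant mean.

No parameter correlations, covariate models or inter-occasion
variability are modelled; body weight is log-normal with the published
moments. Patients are anuric adults with no residual renal function, so
between KRT sessions the only elimination route is CL_NR.

Sampling is reproducible: one seed spawns a fixed-order substream per
parameter, so cohorts are bit-identical under the same seed and adding a
parameter would not perturb existing draws. The study runner derives an
independent substream per (drug, setting) cell from its global seed.

## KRT schedules and clock conventions

Five settings are modelled (see README). Internally all computation is
in litres and hours; effluent rates in mL/min convert by 0.06 (L/h per
mL/min). t = 0 is the start of the first KRT session of the week;
sessions recur at the same clock time daily (Mon/Wed/Fri pattern every
48 h for setting 1). For the late-PIKRT variant the origin is the first
dose and the first session starts at t = 15 h.

Dosing anchors: settings 1–3 give the first dose immediately after the
first 4-h HD session (t = 4 h); early PIKRT at session start; late PIKRT
15 h before the session; extended PIKRT at t = 0. Maintenance doses
follow at fixed multiples of the interval — no re-anchoring to later
sessions, which the daily same-clock sessions make unambiguous for the
studied regimens. For setting 1 a q24h "post-HD" regimen therefore doses
at the same clock time on non-HD days.

Therapy days are anchored at the first dose: day d is
[first dose + 24(d−1), first dose + 24d]. For settings 1–3 day 7 ends
at t = 172 h, a few hours into the next weekly KRT cycle, so schedules
extend session recurrence past 168 h (default horizon 180 h). This is
what produces the alternating high/low end-of-day toxicity pattern under
thrice-weekly HD: days whose end falls right after an HD session (days
2, 4 and 7) are low, HD-gap days high.

## PK engine

The one-compartment model is solved event-by-event: segment boundaries
are the union of infusion starts/ends, session starts/ends and the seven
day boundaries, and concentration is advanced with the analytic
constant-coefficient solution (the (1 − e^(−x))/x form is used so the
ke → 0 limit is numerically exact). The model state is total
concentration; free concentration is f_u × total per patient. Total
drug is dosed and cleared — PK parameters are treated as total-drug
parameters — while PD targets compare free concentration and toxicity
thresholds compare total (the piperacillin threshold can be switched to
the free scale via `toxicity_scale="free"`, since published wording for
that threshold is ambiguous; total is the default).

Time above a threshold is computed per segment from the closed-form
crossing time of the monotone segment solution, making %fT>MIC exact
rather than grid-sampled. End-of-day troughs are instantaneous
concentrations at 24-h multiples after the first dose (concentration is
continuous at dose starts, so the value at a dose time is the trough).
Attainment and exceedance comparisons are non-strict (≥).

The test suite cross-checks the engine against an independent fixed-step
RK4 integrator (relative error < 10⁻⁵ over full weekly profiles across
all settings) and the crossing-time algebra against dense midpoint
sampling at 5×10⁻⁴ h resolution (agreement within 2×10⁻³ h).

## Regimen evaluation and selection

A candidate regimen's report contains per-day PTA (share of the cohort
attaining the day's fT target), per-day toxicity exceedance, and the
average daily dose (total mg over the week / 7, amortising any loading
dose). For piperacillin, attainment is joint: the piperacillin target
and the tazobactam 50% fT>4 mg/L target must both hold, with tazobactam
simulated as an independent drug dosed at 1/8 of the piperacillin dose.
For the 9-h PIKRT setting both timing variants are evaluated and the
reported PTA is the elementwise worst of the two, so a selected regimen
works regardless of administration timing.

Selection: among candidates whose weekly-minimum PTA ≥ 90%, the smallest
daily dose wins; ties break toward fewer administrations per day. When
no compliant candidate fits under the drug's maximal conventional daily
dose (a config table; only cefepime's 6 g/day is established), a
concession branch accepts regimens holding days 2–7 near the floor
(default ≥ 87%) with day-1 PTA above a relaxation floor (default 75%,
chosen so that day-1 values in the mid-70s are acceptable while clearly
failing regimens are not; both floors are configurable, as the clinical
concessions they encode are qualitative judgments). The built-in
candidate grids span conventional dose/interval combinations per drug
and can be replaced from a YAML config.

## What the simulation does and does not show

The generator reproduces the published between-patient variability of
each parameter but, by design, nothing the publications did not report:
no within-patient variation over the week, no parameter correlations
(e.g. weight–Vd), no residual renal function, no KRT interruptions.
Passing checks therefore validate the arithmetic of the model under the
stated population assumptions — they do not validate those assumptions
against real patients, and reported percentages are sensitive to the
open distributional choices (log-normal parameterisation, truncation
handling) at the level of a few percentage points.

Monte Carlo sizes: published percentages are reproduced with n = 5,000
patients (matching the source cohorts; standard error ≤ ~0.7 pp);
fast unit checks use cohorts of a few hundred.

## Known limitations

- One-compartment kinetics: no post-dialysis rebound/redistribution,
  which for some β-lactams inflates apparent intra-dialytic clearance.
- Extraction coefficients are flow-specific constants; intradialytic
  variation of Qd/Quf is not modelled.
- The neurotoxicity metric is a threshold exceedance at a single daily
  time point, not an exposure–toxicity model.
- Selection concessions ("slightly below 90%", "substantial toxicity")
  are encoded as configurable thresholds; they are judgment calls, not
  estimated quantities.
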