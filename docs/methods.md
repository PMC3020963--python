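# Methods

This note documents the generative model behind the synthetic recordings,
the estimation procedures, the numerical choices, and the limits of what
the test suite can establish about real data.

## Generative model of a TEVC recording

A recording is simulated per oocyte and per protocol as a sequence of
constant-voltage epochs. Within an epoch at voltage *V* the channel open
fraction *p* relaxes from its value at the end of the previous epoch toward
the Boltzmann steady state

    p_inf(V) = 1 / (1 + exp((V0.5 − V)/k)).

Deactivating relaxations (target below the current open fraction) are
bi-exponential with weights (a_f, 1−a_f) and voltage-dependent time
constants

    τ_fast(V) = τ_fast(−120 mV) · exp((V + 120)/V_e),
    τ_slow(V) = τ_slow(−120 mV) · exp((V + 120)/V_e),

a single-exponential law in voltage with one shared e-fold parameter
V_e. Activating relaxations use a single fixed time constant τ_act
(default 150 ms): channel opening at depolarized potentials is fast and is
not the object of study, and extrapolating the deactivation e-fold law to
+40 mV would be unphysical. The measured current is

    I = g_max · p · (V − E_rev)/1000 + g_leak · (V − V_hold)/1000   [µA]

(conductances in µS, voltages in mV, K⁺ reversal E_rev = −90 mV by
default), plus a capacitive transient at every step edge (decaying
exponential, τ = 1 ms, amplitude 5× the peak ionic current of the epoch
that follows the edge, signed by the voltage step) and additive Gaussian
sample noise. Noise is scaled per epoch: sd = noise_sd_frac × that epoch's
peak ionic current, so a noise fraction of 1% means a signal-to-noise
ratio of 100 on every analyzed segment. Between-oocyte variability
multiplies V0.5, both τ anchors and a_f by independent lognormal factors
of unit mean and CV `oocyte_cv` (default 0.10); the slope factor k is held
fixed, so ΔG0 co-varies with V0.5 at constant gating charge. All draws are
reproducible from (seed, oocyte id), with per-protocol noise streams.

### Protocols

* Activation: hold −90 mV; +20 mV leak-check step; 4-s steps from −70 to
  +40 mV in 10 mV increments; 1-s tail at −70 mV; 1 ms sampling. The top
  step is +40 mV (not +50) because the linear-leak model is only valid on
  −160..+40 mV and the simulator rejects levels outside it; the Boltzmann
  is already >99.9% saturated at +40 mV for every encoded construct.
* Deactivation: hold −90 mV; leak check; 1 s at +40 mV to open the
  channels; 2-s repolarizations from −50 to −160 mV in 10 mV decrements;
  0.5 ms sampling. The 2-s tail spans >10 slow time constants at −120 mV;
  a 1-s tail lets the offset and the slow component trade against each
  other and biases τ_fast by about −2%.

### Reference construct library

Generator parameters are anchored to the reported measurements. Activation:
WT V0.5 = −23.2 mV with ΔG0 = −6.8 kJ/mol (implying z_g ≈ 3.04 and
k ≈ 8.37 mV at 295.15 K); Δ2–9 V0.5 = −5.6 mV with ΔG0 = −1.9 kJ/mol; GGS
V0.5 = −18.5 mV at the WT slope; all other constructs carry WT activation
values. Deactivation: constructs with a reported τ_fast at −120 mV (WT
33.7 ms, Δ2–9 11.4 ms, Δ2–25 8.7 ms, GGS 7.5 ms) are anchored there;
constructs reported only at the −30 kJ/mol driving force (R5A 16.5, G6A
12.7, P10A 44.4, T13A 38.2, D16A 54.2, I19A 19.2, R20A 20.4 ms) are
anchored at the voltage where their own driving force equals −30 kJ/mol.
The shared e-fold parameter V_e = 33.13 mV is calibrated once so the WT
law passes through both WT anchors. τ_slow is five times τ_fast at the
anchor (the WT ratio); the fast fraction a_f defaults to 0.85, with an
optional linear-in-V variant for studying amplitude redistribution.
Constructs with no reported values (the remaining alanine mutants, all
classified unchanged) carry WT kinetics. Absolute current scale is
arbitrary (all analyses are normalized or ratio-based); g_max = 30 µS
gives oocyte-realistic µA-scale currents, g_leak = 0.3 µS.

## Estimation procedures

**Leak subtraction.** The +20 mV check step from holding measures the leak
conductance: plateau currents are averaged over the trailing 50% of the
holding and check epochs (≥10 samples, pooled across sweeps), and
g_leak = ΔI/ΔV. Every sample is then corrected by baseline +
g_leak·(V − V_rev,leak); the leak reversal defaults to the holding
potential and is configurable. On noiseless linear-leak data the
subtraction is exact; the only systematic residue is the (vanishing)
channel current flowing during the check step.

**Decay window.** Tail fits start at the largest-|I| sample after a blank
period (default 8 ms) and run to the end of the epoch. The blank is eight
capacitive time constants: the residual step transient is then <0.05% of
its amplitude, whereas a 5 ms blank leaves ~3% of the tail amplitude as
contamination and measurably biases the fastest constructs. Traces that
are flat, or whose extremum leaves less than a quarter of the post-blank
epoch, are flagged and fall back to the blank boundary.

**Bi-exponential fitting.** Trust-region least squares in an
amplitude-linear / log-τ parameterization, bounds τ ∈ [0.5·Δt, 10·window],
three starts with τ pairs (w/10, w/2), (w/30, w/3), (w/100, w/5) and
amplitudes from linear least squares given the τs; analytic Jacobian;
best-of-starts by residual sum of squares; components relabeled so
τ_fast < τ_slow. Two components are only reported when τ_slow/τ_fast ≥ 1.5,
each carries ≥0.1% of the summed amplitude, and the two-component fit
beats the nested single-exponential fit in an extra-sum-of-squares F-test
(α = 10⁻³); otherwise a single-exponential fallback is reported
(τ_slow = NaN, fast fraction 1). The F-test matters when the true tail is
effectively single-exponential (a fast fraction at 1): without it a noise
blip can be fitted as a second, faster component and steal the τ_fast
label.
Non-convergence yields NaN parameters and a cleared flag, never an
exception. The offset C is estimated, not pinned at zero, to tolerate
residual leak.

**Activation curves.** The tail amplitude per sweep is the mean current
over a fixed 50 ms window after the blank. Because the tail kinetics at
the fixed tail voltage are identical across sweeps, this window mean is
exactly proportional to the instantaneous tail amplitude; the raw
extremum of a few thousand noisy samples is also available
(`method="extremum"`) but is a max-statistic with a positive bias of a
few σ. Curves are normalized to the largest sweep and fitted with the
Boltzmann in either parameterization; the saturating amplitude is
co-estimated by default, because the normalizing point is itself noisy
and pinning the amplitude at 1 converts that noise into a systematic
slope bias (measured: +4% on k at 2% noise). A fit whose midpoint falls
outside the sampled voltage range is marked non-converged. Every fit is
reported in both (V0.5, k) and (ΔG0, z_g) form; the two are linked by
exact identities, so they are one fit, not two.

**Driving-force comparison.** Voltages in −160..−60 mV are converted with
DF = −(ΔG0 − z_g·E·F) and τ_fast is interpolated at −30 kJ/mol linearly in
log τ versus DF (τ is positive and near-exponential in voltage; for the
generator's law the interpolation is exact). Each oocyte is converted with
its own fitted energetics by default: per-oocyte conversion errors are
independent and average out across the cohort, whereas a pooled-fit error
is common to all oocytes and does not (measured at n = 40: per-oocyte
measurement scatter 2.2% versus 8% under pooled conversion). Pooled
conversion (`per_oocyte_conversion=False`) matches plotting all oocytes on
one shared driving-force axis. Fits entering the curve must be converged,
unflagged, and carry at least 2% of the set's largest tail amplitude —
the last guard removes sweeps near the K⁺ reversal potential, where no
tail current exists and a fit is meaningless. Extrapolation beyond the
measured span is refused unless explicitly enabled.

**Statistics.** Construct summaries are mean ± SEM (SD/√n) of the
per-oocyte τ at the target driving force. Mutants are compared to wild
type by one-way ANOVA across all constructs followed by Dunnett's
many-to-one test at α = 0.05, and classified faster/slower from the sign
of the difference when significant. The Dunnett p-value integrates a
multivariate t distribution numerically; the integrator is seeded so
summaries are byte-reproducible. Groups with n < 2 are reported but not
tested (classification "unchanged", with a warning).

**Helix annotation.** Residues advance 100° per turn on the wheel. The
hydrophilic face direction is the circular mean of the charged + polar
side-chain angles; residues within ±90° of it form face A. For the hERG
segment T13–E23 this puts T13, D16, T17, R20, K21 and E23 on one face and
F14, L15, I18, F22 on the other. I19 (at 240° when T13 is at 0°) is a
genuinely borderline residue: the six hydrophilic residues span a 200°
arc, so no half-plane can contain all of them plus I19, and the geometric
rule assigns it to the hydrophobic face. NOE restraints are classified
purely by sequence separation (short |i−j| ≤ 1, medium 1 < |i−j| < 5,
long ≥ 5; i = j records rejected and reported); per-residue density is
reported both exactly and floored to an integer.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes:
bi-exponential voltage-dependent tails, Boltzmann activation, linear leak
over −160..+40 mV, capacitive edges, signal-scaled Gaussian noise, and
lognormal oocyte-to-oocyte variability. It does **not** model
recovery-from-inactivation (the "hook" at the start of real hERG tails),
Markov-state gating with microscopic rates, series-resistance or
clamp-speed artifacts, temperature drift, non-Gaussian or correlated
noise, or endogenous oocyte conductances. Passing recovery tests
therefore shows the estimation chain is correct and well-conditioned for
this data class; on real recordings the fit window must additionally
clear the inactivation hook, and leak may be imperfectly linear.

## Problem sizes and determinism

Recovery experiments use the reported replicate counts (n = 5–14 per
construct) with 10% between-oocyte CV and 1–2% sample noise; Monte-Carlo
property tests use 200 replicate traces (fitting bias) and 1000 simulated
cohorts at reduced n (ANOVA type-I rate). The cohort mean of n jittered
oocytes carries an intrinsic sampling standard error of 10%/√n ≈ 3–3.5%,
which dominates the measurement error of the pipeline (≤1–2%); recovered
cohort means should be read against that spread. All randomness derives
from user-supplied seeds; identical inputs give bit-identical sweep sets
and byte-identical summary files.

## Known limitations

* τ_fast below ~3 ms is not measurable with the default blank: the fast
  component has largely decayed within 8 ms (e.g. the GGS construct at
  −160 mV). The blank is configurable, but shortening it trades transient
  contamination for coverage.
* The sweep at the K⁺ reversal potential carries no tail current; it is
  excluded from driving-force curves by the amplitude guard rather than
  fitted.
* Slow time constants at the least negative voltages (τ_slow ≈ 1.4 s at
  −50 mV) approach the epoch length and are reported with poor precision.
* Dunnett's test assumes approximately normal, equal-variance groups; the
  generator's lognormal jitter at CV 0.10 is close enough, but heavier
  between-oocyte variability would warrant the Welch/Holm alternative.
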