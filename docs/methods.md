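# Methods

## Spectral model

A measured spectrum is modelled as

y(ν) = b(ν) + Σ_i A₀ᵢ · Fᵢ²Wᵢν / ((Fᵢ² − ν²)² + (Wᵢν)²) + ε(ν)

where b is a smooth background and each term is the spectral response of a
damped harmonic oscillator (DHO) with natural frequency F (cm⁻¹) and
damping width W (cm⁻¹).  The DHO profile is the standard physically
motivated Raman lineshape: it vanishes at ν = 0 and ν → ∞, reduces to a
near-Lorentzian for W ≪ F, and its maximum shifts below F as damping
grows.  Two documentation points matter for interpreting outputs:

- the reported **F is the natural frequency Ω**, not the profile argmax;
- the reported **W is the damping constant Γ**, not the FWHM (they agree to
  first order in the near-Lorentzian regime).

The band **area A** is obtained by numerical integration (trapezoid,
0.5 cm⁻¹ grid) of the fitted profile over the fit window rather than an
analytic formula; this is robust for all W/F ratios including the broad
O–H stretches.

### Background

The joint fit uses a Chebyshev polynomial background of degree 3 (default;
configurable).  For seeding — both the polynomial initialisation and peak
detection — an asymmetric-least-squares baseline is computed (second-
difference penalty λ = 10⁶, asymmetry p = 0.01, 10 reweighting
iterations): points above the current baseline are down-weighted so the
solution hugs the lower envelope.  On a constant spectrum it returns the
constant; under an isolated band it deviates from the true baseline by a
few percent of the band amplitude, which the joint fit subsequently
absorbs.

### Peak seeding

Two detectors are combined on the background-subtracted, Savitzky–Golay
smoothed signal (window 11, order 3):

1. local maxima with prominence > 5 × the robust noise scale (MAD of first
   differences / √2);
2. maxima of the negative second derivative (window 21) with prominence
   > 10 × its own noise scale **and** signal height above the same 5σ
   floor — this resolves shoulders of strongly overlapped neighbours
   (e.g. bands 24 cm⁻¹ apart with Γ ≈ 26 cm⁻¹) that appear as a single
   summit.

Candidates closer than 6 cm⁻¹ are deduplicated (taller kept).  Width seeds
come from the half-height width (floored at 5 cm⁻¹), amplitude seeds from
the on-resonance identity height = A₀F/W.

### Optimisation

Bounded trust-region least squares (scipy `least_squares`, TRF) jointly
over background coefficients and all (F, W, A₀), with the analytic
Jacobian; ftol = xtol = 1e-8.  Bounds: F within ±25 cm⁻¹ of its seed and
inside the window, W ∈ [0.5, 300], A₀ ≥ 0.  After the first solve,
components whose amplitude falls below `min_amplitude` or whose
on-resonance height falls below 2 noise sigmas are pruned and the fit
re-run once.  Components closer than 5 cm⁻¹ are merged (areas summed,
amplitude-weighted F and W) — this threshold sits below the band-matching
tolerance so genuine neighbours are never merged.  Optimizer failure is
reported as `converged=False`, never an exception; up to 3 restarts with
seeded jitter are attempted, so the fit is a deterministic function of
(spectrum, seeds, config).

## Band registry

All fitted component frequencies are pooled and clustered by 1-D single
linkage: sort, cut every gap > δ.  δ defaults to 10 cm⁻¹ — the closest
distinct canonical bands (1584 and 1603 cm⁻¹) are 19 cm⁻¹ apart, so
δ = 10 separates all 24 while absorbing fit jitter (empirically
< 1 cm⁻¹).  Single linkage is deliberately simple and order-invariant, but
it chains: a single stray component mid-gap can bridge two bands, which is
why the seeding works hard to avoid fitting blended pairs as one broad
component.  Cluster labels are the rounded median frequency; with
asymmetric stage trends the observed median can shift the label by
±1–2 cm⁻¹ relative to a band's nominal frequency, so comparisons against
nominal frequencies should use a small tolerance.

**Presence** is counted at the animal level: an animal presents a band for
an (organ, stage) if any of its replicate spectra contains a member
component; replicate multiplicity never inflates the fraction.  **Retention**
follows the strict rule: a band is kept for an organ iff at least one time
window has presence fraction strictly greater than 0.60 — a fraction of
exactly 0.60 does not retain.  The time window defaults to a single
sampling stage; `window_size > 1` pools consecutive stages.  The retained
set per organ feeds the feature matrix; spurious low-presence clusters
(fit artifacts, noise peaks) are eliminated here, mirroring how a large
pool of identified bands collapses to a small well-represented set.

## Feature matrix and scaling

Observation unit: (animal, stage) — replicate spectra are collapsed by
taking, per band, the component with the largest area (strongest
detection; a mean-over-replicates mode is available).  Columns are named
A\<band\>, W\<band\>, F\<band\> in band-then-variable order.  Because A
(thousands of counts·cm⁻¹), W (tens of cm⁻¹) and F (hundreds to thousands
of cm⁻¹) differ by orders of magnitude, the matrix is autoscaled (mean 0,
sample sd 1, computed over non-missing entries) before modelling;
zero-variance columns are dropped with a warning.  Missing descriptors are
imputed at the column mean (zero after scaling), which is neutral under
centred PLS.  The scaler exposes the inverse transform.

## PLS-DA and the fingerprint statistics

Stages are encoded as a centred one-column-per-stage indicator matrix
(PLS2/PLS-DA).  A PLS1 mode (single numeric response = hpf) is provided
for comparison, since a purely monotone reading of development is also
defensible; the default follows the per-stage structure visible in the
fingerprint tables.  NIPALS runs to a 1e-12 convergence tolerance with the
sign convention that each weight vector's largest-magnitude element is
positive, making loadings reproducible across implementations.

**Q²** uses leave-one-animal-out cross-validation — all rows of an animal
are held out together, because within-animal rows share random effects —
with Q²(a) = 1 − PRESS(a)/SS, PRESS accumulated over held-out indicator
predictions and SS the total centred-Y sum of squares.  **Component
selection**: A\* is the largest a such that every component up to a raises
Q² by strictly more than `q2_gain` (default 0.01), with a floor of one
component.

**Scalar projections.**  The projection couples stage k's Y-loading row
q_k with descriptor j's X-loading row p_j over the first A\* components.
Three readings are implemented because the precise formula is not
recoverable from the available description:

- `covariance` (default): s_kj = Σ_a q_ka p_ja ‖t_a‖² / n — the
  model-reconstructed covariance between descriptor j and the stage-k
  indicator.  This is the reading under which the statistic behaves as an
  "integrated measure of covariation between descriptors and stages" and
  under which the vector module ranks descriptors by importance.
- `loading`: s_kj = (q_k·p_j)/‖p_j‖ — the signed length of q_k projected
  onto the descriptor's loading *direction*.  Geometrically clean, but
  direction-only: with one significant component every descriptor gets the
  same module, and in simulation its module ranking is uncorrelated with
  VIP, so it cannot serve as an importance measure.
- `raw`: s_kj = q_k·p_j.

**Vector module.**  Default m_j = √(Σ_k s_kj²) (the Euclidean length of
descriptor j's stage-projection vector).  The literal "length of the sum"
|Σ_k s_kj| and the absolute sum Σ_k|s_kj| are selectable; the literal
reading lets bipolar descriptors (high early, low late) cancel to ≈ 0,
which would contradict the module's use as a discrimination score.  An
optional normalisation rescales so the largest module is 1.  Under the
default (covariance projections + Euclidean module), the module ranking
correlates with VIP at Spearman ρ ≈ 0.9 in simulation, and a descriptor
carrying all class separation attains the maximum module.

## Synthetic data generator

The generator emulates the reference experimental design: six animals (three from each of
two clutches), spectra on a 100–4000 cm⁻¹ grid at 1 cm⁻¹, sampled every
24 h inside each organ's observation window (iris and forebrain from
24 hpf, melanocytes/heart/muscle from 48 hpf, swim bladder from 96 hpf),
giving 216 spectra.

**Band library.**  24 canonical bands (223–3431 cm⁻¹) with per-organ
membership: 1603/2929/3431 in every organ; 1307/1375/1639 heart-only;
223/621/796/845/1199/1450/1584/2852/2978/3002 muscle-only; 980/1409 only
in iris, melanocytes and swim bladder; organ set sizes 6 (iris),
8 (swim bladder), 9 (melanocytes), 9 (forebrain), 12 (heart), 17 (muscle).
Membership slots not fixed by those constraints are filled with fixed,
documented choices from the non-exclusive pool, biased toward the bands
whose descriptors dominate each organ's fingerprint (e.g. 1002 and 1156
for the swim bladder); care is taken that no filler band ends up in all
six organs, which would break the three-common-bands structure.  Default
damping widths are 16 cm⁻¹ below 1800 cm⁻¹, 26 cm⁻¹ in the CH-stretch
region and 40 cm⁻¹ for the O–H bands; peak heights are fixed per band
(80–180 counts).  All magnitudes are plausible stand-ins for 532 nm
acquisitions, not estimates of real tissue values.

**Trajectories.**  Each (organ, band, variable) follows
base × (1 + effect·g(u)) × animal-effect + residual (multiplicative for A
and W) or base + effect·g(u) + shift + residual (additive, cm⁻¹, for F),
with u the window-normalised stage and g either a linear ramp or a
mid-window pulse rescaled to the ramp's RMS contrast (so equal effects
produce comparable stage separation).  Defaults: every descriptor gets a
weak trend near its noise floor (areas ±20%, widths ±9%, frequencies
±0.65 cm⁻¹; kind and sign cycle deterministically with the band's
position), reflecting that in real developing tissue nearly every band
parameter oscillates over time; each organ's headline descriptors — the
ones its fingerprint should rank on top — get the full effects (areas
±80%, widths ±35%, frequencies ±3 cm⁻¹, i.e. 3–5× their noise).  Animal
random effects are log-normal sd 0.15 (A), 0.05 (W) and Gaussian
0.4 cm⁻¹ (F); residuals 5% (A), 4% (W), 0.25 cm⁻¹ (F).  Frequency
effects are specified absolutely so that the closest canonical bands stay
separable under δ = 10 clustering.  Noise is white Gaussian with
sd = median planted peak height / SNR, SNR 20 by default.  A null variant
sets every trend flat.  Presence probabilities (default 1) allow planting
partially-present bands for retention tests.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: melanin and fluorescence physics beyond a
smooth cubic background, cosmic-ray spikes, detector etaloning, wavelength
drift between sessions, non-Gaussian noise, correlated band parameters
within a spectrum, and any real biochemical coupling between organs.
Real-data band counts additionally depend on instrument settings and the
original fitting software's conventions, so agreement is expected at the
level of structure (which bands, which organs, which descriptors
discriminate), not of raw counts of identified bands.

## Problem sizes and numerical choices

The default test suite and the acceptance script run the full 216-spectrum
design once (≈ 20 s of fitting), 50-replicate Monte-Carlo studies at the
parameter level for the chemometrics properties, and reduced
(one-organ) datasets for determinism checks — sizes chosen so the whole
chain is exercised end to end while iterating quickly.  Determinism is
exact: one global seed drives simulation, fit restarts and everything
downstream, and repeat runs are hash-identical.  Ties in module sorting
are broken stably by descriptor order; degenerate inputs (zero spectra,
empty seed lists, single-stage organs, zero-variance columns) return
defined results or raise named errors as documented per function.

## Known limitations

- Single-linkage band matching can chain through stray mid-gap components;
  the seeding minimises but cannot eliminate this on pathological data.
- The >60% retention rule with six animals means presence 4/6 retains and
  3/6 does not; with so few animals the rule is sensitive to single
  detection failures, which is faithful to the design it implements.
- Q² with leave-one-animal-out on six animals is a six-fold estimate and
  noisy; the component-selection gain threshold (0.01) is a pragmatic
  default, not an inference procedure.
- With one significant component the fingerprint degenerates under the
  `loading` projection (all modules equal); the default `covariance`
  projection does not have this failure mode but still reflects shared
  (correlated) descriptor structure rather than unique contributions.
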