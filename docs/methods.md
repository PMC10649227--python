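# Methods

## Kinetic model

Continuous ²H₂O labeling replaces a protein pool at first-order rate k
(day⁻¹). At labeling time t (days) the fraction of newly synthesised
(labeled) protein is f(t) = 1 − e^(−kt), and the monoisotopic relative
isotope abundance (RIA) of a peptide,
I₀(t) = A₀(t)/Σᵢ₌₀⁵Aᵢ(t), decays as

I₀(t) = I₀ᵃˢʸᵐᵖ + (I₀(0) − I₀ᵃˢʸᵐᵖ)·e^(−kt).

The model assumes a single precursor enrichment reached instantly at
t = 0 and held constant (no rise kinetics of body water, no precursor
recycling), one exponential per peptide (no multi-compartment pools),
and RIAs measured over exactly six mass isotopomers.

Two fitting modes minimise the residual sum of squares with BFGS:

- **one-parameter**: the plateau is fixed from theory and only k is
  fitted through k = e^(−θ);
- **two-parameter**: θ and α are fitted jointly with
  I₀ᵃˢʸᵐᵖ = I₀(0)/(1 + e^(−α)).

The transforms make every real (θ, α) admissible: rates cannot go
negative and the plateau cannot exceed the natural RIA. Optimization
controls: at most 500 iterations; convergence is declared when the
optimizer reports success, when the SSE change between the final two
iterates falls below 1e-10, or when the final gradient is numerically
zero (BFGS often exits with a precision-loss status at an effectively
exact optimum). Gradients are central differences with step 1e-6.
Initialisation: k₀ = 0.05 day⁻¹ (a physically typical rate) and α₀
chosen so the plateau starts at its theoretical value when an
enrichment model is supplied, else at the smallest observed RIA.
Non-converged fits are returned flagged, never silently.

## Plateau conventions

The closed-form plateau is I₀ᵃˢʸᵐᵖ = I₀(0)·(1 − p_W/(1 − p_H))^N_EH:
each of the N_EH exchangeable hydrogens independently escapes
deuterium with probability 1 − p_X, p_X = (p_W − p_H)/(1 − p_H).
Because labeling also pushes intensity beyond M5 while the RIA is
normalized over six peaks only, the six-peak plateau of the *labeled
pattern* exceeds this closed form by ~1–2% at p_W = 4.6% and
N_EH ≈ 20. The quantify pipeline therefore pins the one-parameter
plateau to the pattern-derived six-peak value (consistent with how the
data themselves are normalized), scaled by the measured day-0 anchor;
`fit_one_parameter` called directly defaults to the closed form. The
two-parameter fit estimates the plateau from the data and sidesteps
the issue.

## Isotope patterns

Natural patterns come from iterated truncated convolution of
per-element isotope distributions (exponentiation-by-squaring), using
IUPAC 2013 representative abundances frozen in `constants.py` for
reproducibility. Patterns carry 10 internal peaks and are
renormalized; all RIAs are defined over the first 6. The labeled
pattern is the natural pattern convolved with the label-count
distribution over N_EH exchangeable hydrogens. The packaged N_EH table
(Commerford-style per-residue averages) is fractional, so the label
count mixes the two adjacent integer binomials with the weight chosen
so the zero-label probability equals (1 − p_X)^N_EH exactly — this
keeps the binomial model and the closed-form plateau consistent at the
monoisotope, which is the quantity everything downstream uses. The
table is an organism-average convention and can be overridden per
call.

## Two-isotopomer (partial-profile) RIA

When a co-eluting contaminant corrupts some isotopomer channels, the
complete-profile RIA is biased but the ratio A_i/A_j of two clean
channels still determines the labeled fraction. The estimator inverts
the mixture model in six-peak-normalized space: it verifies on a grid
that the model ratio is strictly monotone in f (else the pair is
rejected as unsupported), brackets, solves to 1e-10 by Brent's method,
and returns I₀ = (1−f)·nat₆[0] + f·lab₆[0]. Working in six-peak space
makes the estimator agree with the complete-profile RIA *exactly* on
undistorted data (verified to ~1e-12 in the tests); an observed ratio
outside the attainable range raises an interference error rather than
extrapolating.

## Filtering and aggregation

Default filter (strict senses, matching its printed form): peptides
with k < 0.01 day⁻¹ pass iff RMSE < 0.01 — R² is uninformative when
the RIA barely moves; all others need R² > 0.9, r > 0.9, RMSE < 0.05.
User thresholds (R², r, RMSE, SD, NDP, abundance, isotope deviation,
number of experiments) use inclusive senses by default, switchable to
strict; a disabled threshold always passes; a missing metric fails an
enabled threshold.

GOF definitions: R² = 1 − SSE/SStot; r = Pearson correlation of
observed vs predicted; RMSE = √(SSE/NDP); SD = √(SSE/(NDP−p)) with p
fitted parameters — the RMSE/SD distinction is a documented package
convention (SD is the residual standard deviation, not the rate's
standard error). Zero-variance observations report R² = 0 and r as
missing.

Protein aggregation: iterative two-sided Grubbs at α = 0.05 (n ≥ 3,
critical value from the Student-t formula), then median of surviving
rates; protein SD is the harmonic mean of surviving peptide SDs
(zero/missing SDs are excluded from the harmonic mean — it is
undefined at zero — but still count toward the median); the 95% CI is
k ± t₀.₉₇₅,ₙ₋₁·SD/√n clamped at zero, with single-peptide proteins
inheriting the peptide's own interval. If Grubbs removes everything,
the pre-removal median is emitted with a warning flag. Peptides are
keyed by (sequence, charge); charge states are independent
observations. Shared peptides are razor-assigned to the first-listed
protein.

Rate confidence intervals are Wald/delta-method: the SSE Hessian in
natural parameters is differenced at the optimum, the covariance is
2σ̂²H⁻¹ with σ̂² = SSE/(NDP−p), and the quantile is Student-t with
NDP−p degrees of freedom; the lower bound clamps at zero and a
singular Hessian yields a flagged unbounded interval. Empirical
coverage at nominal 95% measures 94–96% over 500 simulated fits.

## Retention-time alignment and MBR

Alignment operates on base-peak chromatograms restricted to a
peptide's elution neighborhood (not the global TIC). A whole-window
cross-correlation first estimates the bulk shift; the COW dynamic
program then places each segment boundary (nominal length 25 scans)
on any reference scan within ±slack of its coarse-registered nominal
position, with stretch lengths constrained to ±slack (correlation on
degenerate stretches is meaningless). The benefit is the sum of
per-segment Pearson correlations weighted by each target segment's
share of total intensity — unweighted sums let baseline-only segments
outvote the elution peak with noise correlations. Ties break toward
the smallest cumulative shift, making the output deterministic and the
identity map the result for equal inputs. Endpoints map to endpoints;
windows shorter than one segment fall back to a single global shift.
Slack should cover the largest expected inter-run drift (shifts around
a minute are realistic; at 3 s scan spacing that is ~22 scans).

MBR transfers a peptide identified in a source run (earliest labeling
time preferred, day 0 first) into runs lacking the identification,
centered at the warped retention time; transferred points are flagged
`mbr_transferred` and never overwrite identified ones. Warped
positions outside the target run are skipped with a logged reason.

## Extraction

XICs for M0..M5 are drawn at mz + i·1.003355/z within a ppm tolerance
(default 10 ppm, ±120 s window); deuterium-induced spacing differences
are ignored at MS1 tolerance scale. Elution bounds come from the
3-point-smoothed M0+M1 trace: apex plus the contiguous region above 5%
of apex — a documented convention of this package. All isotopomers are
trapezoid-integrated over those *shared* bounds so the isotopomer
ratios (hence the RIA) are unbiased by boundary choice. Only
centroided MS1 data are accepted; profile spectra are rejected with an
explicit message. The mzML reader/writer pair is a minimal standalone
implementation (lxml) covering centroided spectra with 32/64-bit
float arrays, plain or zlib-compressed; files written by the generator
are cross-checked against an independent mzML implementation in the
test suite.

## Synthetic data: what it emulates, what it does not

The generator draws proteins with log-uniform rates (default
0.005–1.0 day⁻¹, all peptides of a protein sharing its k), tryptic-like
sequences, charges 2–3, and simulates the *six quantified channels*
directly: the observed profile is the six-peak-normalized
natural/labeled mixture at f(t), times abundance, times multiplicative
Gaussian channel noise (default σ = 0.5% relative). Defaults mirror a
murine labeling design: schedule 0,1,2,3,4,5,6,14,21 days and
p_W = 0.046 — a plausible steady-state body-water enrichment under 8%
(v/v) enriched drinking water after a loading bolus; both are
configurable. Contamination is modeled as an additive bump on chosen
channels at a chosen fraction of the base peak, varying between
samples (uniform ×0.5–1.5) as a co-eluting foreign species would.
Spectral runs add Gaussian elution peaks (σ = 6 s, 3 s scan spacing),
per-run rigid RT shifts, and per-run missing identifications (day 0 is
always identified, anchoring the natural profile). All randomness
flows through one seeded generator; equal seeds give byte-identical
outputs.

Deliberate simplifications — passing tests demonstrate correctness of
the machinery under the stated model, not instrument realism: no
signal beyond M5 (so the noiseless RIA is exactly exponential; real
profiles leak ~1–2% past M5 at these enrichments), rigid rather than
smoothly drifting RT shifts, no chimeric spectra, no detector
saturation or missingness-by-intensity, noise independent across
channels and time points.

## Validation scenario sizes

The self-validation suite uses desk-scale problem sizes chosen to make
the Monte-Carlo statements stable: 200 replicates per rate for noisy
recovery (rates 0.005, 0.05, 0.3, 1.0 day⁻¹), 100 contaminated
peptides (rates 0.05–0.5 day⁻¹, the regime where a clean fit reaches
R² ≥ 0.95 — slower peptides fail GOF for identifiability, not
interference, reasons), 1000 random vectors for the Grubbs
cross-check, 500 fits for CI coverage, 60 peptide windows with shifts
up to ±66 s for alignment, and a 4-protein/12-peptide experiment at
40% missing identifications for MBR. The plateau-recovery check is
asserted only for k ≥ 0.05 day⁻¹: at k = 0.005 the pool turns over
~10% in 21 days, the plateau is never approached, and its estimate is
unidentifiable in principle.

## Known limitations

- p_W is config-supplied, never estimated from the spectra.
- The exponential model ignores precursor rise time; very fast
  turnover (k ≳ 2 day⁻¹) is poorly constrained by a 0–21 d schedule.
- Peak detection is deliberately simple (smoothed apex + 5% bounds);
  heavily overlapping elution profiles are out of scope.
- Isotope patterns are aggregated nominal-mass isotopomers; no
  fine structure.
- The Wald CI is symmetric in k and can be anti-conservative for
  rates near zero.
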