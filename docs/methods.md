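# Methods

## Exchange model and quantities

Saturation transfer treats each observed ³¹P pool (Pi or PCr) exchanging
with γATP as a two-site system. Under complete, continuous saturation of
γATP the longitudinal Bloch–McConnell equations reduce to

    dMz/dt = (M0 − Mz)/T1 − κf · Mz ,

whose steady state is M_sat = M0 · T1obs/T1 with 1/T1obs = 1/T1 + κf.
Hence ΔM/M₀ = 1 − M_sat/M0 = κf·T1obs ∈ [0, 1), κf = (ΔM/M₀)/T1obs, and
the unidirectional flux is κf·[substrate]. Inversion recovery acquired
while the partner stays saturated relaxes with the *observed* rate, fitted
as y = A1·[1 − A2·e^(−t/T1obs)]; A2 = 2 is a perfect inversion and is left
free in the fit (imperfect inversion changes A2, not T1obs). The null
point of a perfect-inversion recovery sits at t = T1obs·ln 2.

Assumptions: complete γATP saturation with no off-resonance spillover on
the control acquisition (the "mirror" control is modeled as a no-op);
single-exponential intrinsic relaxation; one reaction quantified at a time
(Pi→γATP and PCr→γATP independently).

## Synthetic data

The MRS generator emulates a resting-muscle ³¹P acquisition at 162.1 MHz:
4000 complex points over a 10 kHz sweep, five resonances at PCr 0 (the ppm
reference), Pi +4.9, γATP −2.4, αATP −7.5, βATP −16.0 ppm. Each peak is a
pseudo-Voigt line realized in the time domain as the matching mix of an
exponentially and a Gaussian-damped sinusoid, so its half-line Fourier
transform has exactly the configured height and FWHM. Peaks default to
pure Lorentzian (in vivo ³¹P lines are Lorentzian-dominated); the Gaussian
fraction is a free parameter. Receiver noise is i.i.d. complex circular
Gaussian per time point. Saturated members scale each exchanging pool to
its steady state and remove the γATP peak.

Inversion-recovery series are generated directly as magnetization-vs-time
values (the quantity a peak fit would deliver), with their own noise scale
`ir_noise_sd`, since fitted-area noise lives on a different scale than
per-point receiver noise. Pi and γATP/control saturation offsets are
conventions, not measured values; they are configurable.

What the generator does *not* emulate: B0 inhomogeneity, eddy currents,
chemical-shift anisotropy, J-coupling multiplets of the ATP resonances
(each ATP line is a single mixed line), partial saturation spillover, and
baseline rolls from acquisition dead time. Passing tests therefore show
correctness of the estimation chain under the stated model, not robustness
to every in vivo artifact.

The expression generator plants a two-group (default n = 4 vs 4) log2-
normal study: gene baselines ~ N(9, 1.5) on the log2 scale (linear ≈ 500,
the conventional scaling target), within-group noise 0.25 log2 units, 5%
of genes shifted by 2 log2 units (60% up), probe sets ≥ genes with a
3′-rank annotation, and 3 of 25 categories stacked with 80% planted genes.

## Processing chain

Zero-fill (default to 8000 points) → exponential multiplication (default
30 Hz; point k is multiplied by e^(−π·LB·k·dt), which adds LB to a
Lorentzian FWHM) → FFT with the first point halved and dwell-time scaling,
so intensities approximate the continuous half-line transform → phasing →
optional polynomial baseline correction. Because appended points are zero,
zero-fill and apodization commute; the literal order is kept and tested.

Automatic phasing replaces interactive phasing: the criterion is the
summed squared negative real intensity plus a term preferring the maximal
absorption integral. The second term matters: a noiseless, correctly
phased spectrum has *no* negative intensity over a ~1° plateau of
rotations, and the absorption integral Re[s(0)·e^(iφ)] peaks exactly at
the correct zero-order phase, making the optimum well defined. Chosen
angles are logged as ordinary phase corrections, so replaying a processing
log is bit-exact.

Baseline correction fits a Chebyshev polynomial (default degree 3) to
peak-masked regions. It is off by default in the pipeline: the synthetic
baseline is flat, and subtracting a polynomial fitted to Lorentzian far
tails biases areas more than it helps.

## Lineshape fitting

The model is a sum of pseudo-Voigt lines, PV = η·G + (1−η)·L with common
center, height and FWHM, plus one constant intensity offset per spectrum.
Minimization is bounded damped least squares (lmfit's `least_squares`,
trust-region reflective; tolerances 1e-12, centers confined to ±0.5 ppm
windows around their table-driven, peak-picked starting values so
overlapping peaks cannot swap labels). Areas use the closed forms
A_G = a·w·sqrt(π/(4 ln2)), A_L = a·w·π/2 (intensity·Hz; units cancel in
every downstream ratio).

The constant offset absorbs the flat pedestal that discrete sampling and
Lorentzian-tail aliasing leave on a digitized spectrum (≈1e-4 of the PCr
height at the default settings). Without it, the area *ratio* between the
control and saturated spectra carries a ~0.1% bias that is negligible for
large ΔM/M₀ but dominates small ones; with it, noiseless end-to-end κf
recovery is within 0.25% across κf ∈ [0.05, 0.5] s⁻¹, T1obs ∈ [0.5, 3] s.

## Quantification

ΔM/M₀ = (area_control − area_saturated)/area_control from the two fits of
the same resonance. Negative values on noisy data are reported (with a
warning), not clipped, so group means stay unbiased. The T1obs fit
initializes A1 from the longest delay, T1obs from the zero-crossing
heuristic t_null/ln 2 when the series changes sign (else a third of the
sampled range), and rejects series that a constant fits as well as the
model. Substrate concentrations enter either directly or by the standard
internal-reference scaling [pool] = [ATP]·area_pool/area_βATP, with [ATP]
from an external assay; βATP is the reference because it is overlap-free.

One unit note: the study tables this mirrors print the Pi→γATP block in
mmol/g and the PCr block in μmol/g while the numbers are commensurate; the
package carries each block in the units it is given and does not resolve
the discrepancy.

## Group statistics

Tables report mean ± SEM and 100·(treated−control)/control. Comparisons
are unpaired t-tests; both the pooled-variance (Student) and Welch
variants are provided because the flux tables name Student's t while the
microarray methods use Welch. One-tailed p-values halve the two-tailed p
in the observed direction. Exactly constant samples (a noiseless
simulation artifact) short-circuit to p = 1 (equal means) or p = 0, with a
flag.

## Expression statistics

Probe sets collapse to genes by keeping the 3′-most (rank 1) probe set;
unannotated probe sets are dropped with a logged count. Per-gene Welch
t-tests run on log2 abundances; Benjamini–Hochberg adjustment spans all
tested genes; a gene passes with adjusted p ≤ 0.05 and ≥ 2-fold change.
Fold change defaults to the ratio of linear group means (a config switch
selects geometric means). Over-representation uses the upper-tail
hypergeometric probability P(X ≥ k) per category over a universe that
defaults to the collapsed gene set (switchable to all annotated genes);
categories with fewer than two selected genes are removed, and kept
categories need p ≤ 0.05.

## Numerical and design choices

* All randomness flows from one top-level seed through
  `numpy.random.SeedSequence` spawning; reports embed config and seed and
  reruns are bit-identical.
* The Monte-Carlo robustness study uses 2048-point FIDs (zero-filled to
  4096) over 100 seeds; the noiseless table reproduction uses the
  protocol-sized 4000 → 8000 chain. Inversion delays default to eight
  log-spaced points over 0.152–7.651 s.
* Inter-animal variability is off by default (group means are the object
  of interest for table reproduction) and available as a multiplicative
  CV on κf and concentrations.
* Degenerate inputs fail loudly: zero-variance genes are flagged at p = 1,
  constant IR series raise, non-converged fits refuse to quantify.

## Known limitations

Single-quantification model only (no multi-site exchange, no correction
for incomplete saturation, no reverse flux); frequency-domain fitting only
(no prior-knowledge time-domain fitting); JCAMP-DX and vendor raw formats
are not read — the TSV + JSON-sidecar format is the interchange format.
The published per-animal raw data are not available, so spectrum-level
agreement is demonstrated on simulation ground truth, and agreement with
the published tables is at the level of their printed group-mean inputs.
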