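# satflux

Quantification of skeletal-muscle ATP synthesis flux from in vivo ³¹P
saturation-transfer NMR, paired with the two-group transcriptome statistics
used alongside such measurements — built as a fully testable pipeline driven
by synthetic data with known ground truth.

## The problem

In resting muscle the reaction Pi → γATP (mitochondrial ATP synthase) and
PCr → γATP (creatine kinase) exchange magnetization between ³¹P pools.
Selectively saturating the γATP resonance drains the observed pool (Pi or
PCr) to a steady state; the fractional loss ΔM/M₀ together with the
apparent relaxation time T1obs (measured by inversion recovery during
continued saturation) gives the forward pseudo-first-order rate constant

    κ_f = (ΔM/M₀) / T1obs,        1/T1obs = 1/T1 + κ_f,

and the unidirectional synthesis flux

    V = κ_f · [substrate]     ([Pi] or [PCr], per gram wet tissue).

The package implements every stage of that measurement —

* **`satflux.synthetic`** — ground-truth generators: ³¹P FIDs (PCr, Pi,
  γ/α/β-ATP as pseudo-Voigt lines), control/saturated acquisition pairs
  under two-site Bloch–McConnell steady-state exchange, inversion-recovery
  series, and two-group expression matrices with planted fold changes and
  planted enriched categories;
* **`satflux.processing`** — zero-filling, exponential apodization, FFT with
  a PCr-referenced ppm axis, automatic/manual phasing, polynomial baseline
  correction, with a replayable processing log;
* **`satflux.fitting`** — multi-peak mixed Gaussian/Lorentzian
  (pseudo-Voigt) fits by bounded damped least squares, with closed-form
  areas;
* **`satflux.quantify`** — ΔM/M₀ from fitted areas, the three-parameter
  inversion-recovery fit y = A1·[1 − A2·e^(−t/T1obs)], κ_f and flux;
* **`satflux.stats`** — mean ± SEM summaries, percent change, pooled/Welch
  unpaired t-tests;
* **`satflux.enrichment`** — 3′-most probe-set collapse, per-gene Welch
  t-tests on log₂ abundances with Benjamini–Hochberg FDR and a 2-fold cut,
  and upper-tail hypergeometric category over-representation with a
  ≥ 2-gene category filter;
* **`satflux.pipeline`** — end-to-end orchestration with seeded
  reproducibility, plus a thin `satflux` CLI.

## Worked example

The numbered drivers under `analysis/` run the study end to end (from the
repository root). `analysis/02_flux_table.py` simulates noiseless control
(n = 10) and tumor-bearing (n = 6) groups from group-mean truth, pushes
every animal through processing → fitting → quantification, and prints:

```
group comparison (noiseless group-mean truth):
  Pi->gammaATP flux: C 0.085 vs TB 0.045 mmol/g/s (-47.1%)
  PCr->gammaATP flux: C 0.620 vs TB 0.451 umol/g/s (-27.3%)
  Pi dM/M0: C 0.484 vs TB 0.305 (-37.0%)
  Pi kf:    C 0.304 vs TB 0.203 1/s (-33.2%)
```

i.e. the cachectic (tumor-bearing) group's Pi → γATP ATP synthesis rate is
roughly halved, driven by a ~37% drop in ΔM/M₀ and a ~21% drop in [Pi].
`analysis/03_noise_robustness.py` repeats the chain 100 times at 5%
receiver noise (median |κ_f error| ≈ 5%), and `analysis/04_expression.py`
runs the transcriptome branch on a planted n = 4 vs 4 study (47/50 planted
genes and all 3 planted categories recovered at 5% FDR with a 2-fold cut).
Tables are written under `results/`.

A minimal library session:

```python
import satflux as sf

kf = sf.compute_rate_constant(0.484, 1.59)   # 0.3044 1/s
flux = sf.compute_flux(kf, 0.280)            # 0.0852 mmol/g/s
```

## Layout

```
src/satflux/    library (all computation lives here)
analysis/       numbered narrative drivers (01 simulate ... 04 expression)
tests/          pytest suite, including acceptance-level checks
scripts/        acceptance.py
docs/methods.md model, assumptions, numerical choices, limitations
```
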