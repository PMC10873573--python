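# Methods

## Mixing model

An acquisition with `n` detection channels over an `i×j` field of view is
flattened to a matrix `X (m×n)`, `m = i·j`, in row-major pixel order: row
`p` is pixel `p`'s intensity across channels. With `r` fluorophores the
linear mixing model is `X ≈ W H`, `W (m×r) ≥ 0` the per-pixel abundances,
`H (r×n) ≥ 0` the channel-binned emission spectra. Blind unmixing estimates
both factors; `r ≤ min(m, n)` (the determined system at `r = n`) is
required for a well-posed solution. The flattening convention is frozen
because the abundance columns must be folded back into images with the
identical order.

## Why plain NMF is not enough

For high-overlap spectra the minimum of `‖X − WH‖_F²` is degenerate: if
`(W, H)` is exact, so is `(W A, A⁻¹H)` for a continuum of invertible `A`
keeping both factors nonnegative. Moving along this continuum trades
spectrum sparseness against image crosstalk — the spurious solutions have
*sparser* spectra and dirtier images, and the crosstalk-free solution is
the *least sparse* exact factorization, the endpoint where the
nonnegativity of `W` becomes active. Random-initialization NMF lands
anywhere on (or off) this set, which is what the reproducibility and
crosstalk failures of naive NMF look like in practice.

## The solver

Objective: `f(W, H) = ‖X − WH‖_F² + α·J1(H)` with the per-row Hoyer
sparseness `s(h) = (√n − ‖h‖₁/‖h‖₂)/(√n − 1)` and
`J1(H) = Σ_rows (s(row) − spH)` ("linear" form; a symmetric squared form is
available). Matrix sparseness is reported as the mean over rows — rows are
the per-fluorophore spectra, which is the physically meaningful unit here.

Pipeline (all deterministic):

1. **Normalization.** `X` is divided by its maximum (optional,
   default on) so every default below is scale-free.
2. **NNDSVD initialization.** The leading singular triplet is nonnegative
   up to sign and used directly; each later triplet is split into positive
   and negative sections, the pair with the larger norm product is kept and
   rescaled to preserve its singular value. Sign indeterminacy is fixed by
   flipping each pair so its positive section dominates (exact ties break
   positive). Triplets below `1e-12·σ₁` are left zero; an optional
   `zero_fill="mean"` variant fills exact zeros with `mean(X)/100`.
3. **Constraint phase** (default 400 iterations). Every row of `H` is held
   at sparseness *exactly* `spH` by two-sided Hoyer projection (alternating
   hyperplane/sphere projection with zeroing of negatives, preserving the
   row's Euclidean norm). `H` is updated by projected gradient descent —
   step `1/L` with `L = 2‖WᵀW‖₂`, backtracking halvings, candidate
   projected *before* the acceptance test — and `W` by the Lee–Seung
   multiplicative rule. The exact constraint is what collapses the
   rotation/crosstalk continuum: spurious solutions need rows sparser than
   the target and become unreachable.
4. **Release and drift.** The projection relaxes to a one-sided floor
   (rows may become less sparse, not more). The linear penalty's
   subgradient now enters the descent direction, exerting a constant
   downward pressure on row sparseness that drifts the factors along the
   near-exact continuum toward its least-sparse endpoint — the
   crosstalk-free solution. The weight `α` defaults to `0.5·m` (per-pixel
   scale): the squared-Frobenius term grows with `m`, so a fixed O(1)
   weight would be invisible.
5. **Anneal and polish.** After 800 further iterations `α` decays by 0.95
   per iteration, releasing the bias so the fidelity term converges cleanly
   (relative objective change below `1e-8`). Convergence is only monitored
   once `α` has fallen below `1e-4` of its initial value — a plateau under
   an active penalty is an equilibrium, not convergence.
6. **Split/merge rescue.** Occasionally the constraint phase locks a basin
   in which one fluorophore is estimated twice while a neighbor pair is
   merged. Physically distinct fluorophores in these designs are ≥ 0.7 rad
   apart in spectral angle, so two estimated spectra closer than 0.35 rad
   are treated as twins: the lower-abundance twin is dropped, the survivors
   refit briefly, the freed component is reseeded from the leading
   nonnegative NNDSVD direction of the unexplained residual
   `max(X − WH, 0)`, and a half-length schedule reruns. Up to 4 rounds; the
   candidate with the lowest final objective wins. The rescue is fully
   deterministic.
7. **Canonical output.** Each `H` row is max-normalized to 1 with the
   compensating scale folded into `W`; components are ordered by ascending
   peak channel, ties by descending total abundance. Output is therefore
   unique and reproducible bit-for-bit.

**Monotone objective.** The recorded trace is `fidelity + α_t·J1` at the
current weight. Each `H` step is accepted only if it does not increase that
value (with a stall fallback that leaves `H` unchanged), the `W` update
cannot increase the fidelity term and does not touch the penalty, the
weight `α_t` never increases, and the floored penalty is clamped at ≥ 0 —
so the trace is non-increasing by construction. After a rescue the reported
trace is that of the winning run.

**Choosing `spH`.** The target must lie below the true spectra's
sparseness (forcing extra sparseness distorts the solution — visible as
the degradation of SAD/Dice when sweeping `spH` past the reference
sparseness) but close enough to exclude the spurious continuum. Blind
default: the median Hoyer sparseness of the nonzero pixel spectra minus a
0.2 margin — in highly multiplexed images most pixels are dominated by few
fluorophores, so pixel spectra are a serviceable proxy for the unknown
references. With a reference mixing matrix at hand, `suggest_sp_h` returns
its mean row sparseness minus 0.05.

### Key parameters

| parameter | default | meaning |
|---|---|---|
| `sp_h` | auto (pixel estimate − 0.2) | target row sparseness in [0, 1] |
| `alpha` | auto (`0.5·m`) | initial sparsity-penalty weight |
| `constraint_iter` | 400 | iterations with the exact two-sided projection |
| `anneal_iter` / `anneal_decay` | 800 / 0.95 | penalty hold length, then geometric decay per iteration |
| `max_iter` / `rel_tol` | 1600 / 1e-8 | iteration cap and relative-change stop |
| `rescue_sad` | 0.35 rad | spectral angle below which two components count as twins |
| `normalize_input` | true | divide `X` by its max before factorizing |

## Baselines

* **Linear unmixing (LU):** per-pixel nonnegative least squares against the
  rows of a supplied reference mixing matrix (identical pixel spectra share
  one solve). The supervised gold standard; errors on rank-deficient
  references, naming the dependent rows.
* **Random-init NMF (nNMF):** scikit-learn's multiplicative-update
  Frobenius NMF with random initialization and no sparsity term, wrapped
  with the same normalization and component ordering as the main solver.
* **Crosstalk subtraction:** the post-hoc step used on real acquisitions —
  NNLS coefficients of donor components regressed onto a target image,
  subtracted and clipped at zero.

## Synthetic data

The generator emulates a prism/PMT-array spectral acquisition:

* **Spectra:** unit-peak symmetric Gaussians, σ = FWHM/(2√(2 ln 2)),
  default FWHM 50 nm, on a 1-nm grid. Real emission spectra are red-tailed;
  asymmetry is deliberately out of scope.
* **Channel binning:** the mixing matrix integrates the piecewise-linear
  spectrum over each half-open band (band edges inserted as breakpoints, so
  a spectrum symmetric about a shared edge splits exactly); rows are
  max-normalized then multiplied by per-fluorophore brightness factors.
* **Default design:** peaks at 430 + 25k nm, `n = r` equal bands spanning
  [370 nm, last peak + 40 nm]. For r = 3 this is three 50-nm bands over
  370–520 nm with 25-nm peak separation (neighbor min-integral overlap
  0.556); r = 11 spans 370–720 nm — the visible-range, one-channel-per-
  fluorophore regime.
* **Perturbations:** per-fluorophore spectral shift drawn uniformly from
  ±3 nm (the scene is synthesized from the shifted spectra while the
  *unshifted* reference matrix is returned, as when a baseline is handed a
  stale reference), then additive i.i.d. Gaussian noise with
  σ = 0.02 × max(clean signal), clipped at zero since detectors report
  nonnegative counts. The clipping slightly biases the noise moments; the
  moment check in the tests restricts itself to unclipped pixels.
* **Phantom:** `r` disjoint vertical strips of equal width (±1 px),
  intensity 1 (optional linear ramp). Strips make support overlap exactly
  zero, so any off-diagonal image correlation is crosstalk.

Everything flows through one seeded generator; a dataset is a pure function
of its config.

What the generator does *not* emulate: Poisson photon statistics, detector
offsets, textured specimens, spatially varying spectra within one
fluorophore, excitation effects. Consequences for interpreting scores:

* Flat strips plus additive noise are close to a worst case for windowed
  SSIM — in flat regions the structure term compares pure noise against
  zero variance. At the default noise, even supervised LU given the true
  mixing matrix scores SSIM⁻ ≈ 0.4–0.8 on noisy strips; absolute SSIM under
  noise therefore measures the noise floor, not unmixing quality, and the
  noisy benchmarks are scored primarily by Dice (binarized masks, noise-
  robust) and by dominance over the baselines.
* Because noise scales with the *global* signal maximum, brightening one
  fluorophore 10× raises every other fluorophore's absolute noise floor
  10×. The intensity-ratio experiment would then measure noise robustness
  rather than intensity robustness — so its default design is noiseless,
  isolating the factor it is about; the noisy variant remains available
  and is reported alongside.

## Evaluation choices

* Components are matched to references before scoring (Hungarian
  assignment on spectral angle, or on image correlation when no reference
  spectra exist); all metrics are invariant to the solver's output
  permutation and to per-row positive rescaling of spectra.
* Matched images and truths are normalized to unit peak before SSIM/Dice —
  abundances are defined only up to scale.
* SSIM: 11×11 Gaussian window, σ 1.5, K1 = 0.01, K2 = 0.03, dynamic range
  1 after rescaling the pair by its joint maximum; images smaller than the
  window fall back to one global window (logged).
* Dice: per-image Otsu threshold (parameter-free, deterministic; constant
  images binarize by positivity); a fixed-threshold override exists. Two
  empty masks score 1.
* RMSE is computed on the solver's own (normalized) input so values are
  comparable across datasets. SAD is reported in radians.
* Spectral overlap between two spectra is the integral of the pointwise
  minimum of their unit-area forms — isolated in one function since other
  definitions exist in the literature.

## Problem sizes

The shipped benchmarks run at 60×60 (3-color) and 96×96 (11-color, 5
seeds) with 1600-iteration schedules — sizes chosen so the full suite and
the acceptance run each complete in minutes on a single CPU while leaving
every qualitative effect (exact recovery, crosstalk collapse, baseline
gaps) intact.

## Known limitations

* The sparseness mechanism assumes the true spectra are roughly equally
  sparse and sparser than the blind target; exotic mixtures of very narrow
  and very broad emitters would need per-row targets.
* The rescue heuristic keys on a 0.35 rad twin threshold, appropriate for
  designs whose distinct fluorophores are ≥ 0.5 rad apart; tighter peak
  spacing than ~15 nm at FWHM 50 would need a smaller threshold.
* Recovery degrades gracefully with noise but the method includes no
  denoising; heavy shot noise should be handled upstream.
* `r` is an input, not estimated; requesting the wrong component count
  yields split or merged components by construction.
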