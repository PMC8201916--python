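# Methods

## The measure

A functional connectivity (FC) matrix `C` — Pearson correlations between
regional BOLD series, negatives clipped to zero, unit diagonal — is
decomposed into eigenmodes `C = U Λ Uᵀ`.  For a correlation matrix the raw
eigenvalues always sum to `N`, so the raw spectrum cannot register how
synchronised the network is; the *squared* eigenvalue `Λᵢ²` does grow with
synchronisation and is used as each mode's contribution.  The rare negative
eigenvalues (clipping makes `C` only approximately positive semidefinite)
are set to zero after sorting, so the zeroed modes sit at the tail and
contribute nothing.

Modules are read off the eigenvector signs, nested across levels.  Regions
sharing a sign in a mode are taken to co-activate; regions of opposite sign
oppose each other.  The first mode of a positive FC matrix is sign-uniform
(Perron–Frobenius), giving one whole-network module; mode `i` splits every
level-`(i−1)` module into its positive-sign and negative-sign subsets.
Level `i` is scored by a size-corrected, eigenvalue-weighted module count

    Hᵢ = Λᵢ² Mᵢ (1 − pᵢ) / N,     pᵢ = Σⱼ |mⱼ − N/Mᵢ| / N ,

where `Mᵢ` is the module count and `mⱼ` the module sizes.  The correction
`pᵢ` penalises heterogeneous sizes: a two-module level with sizes `(1, N−1)`
is nearly global integration, not genuine segregation, and `1 − p` shrinks
its score accordingly.  Global integration is the level-1 component
normalised once more by `N`, `H_In = H₁/N = Λ₁²/N² ∈ [0, 1]`; segregation
accumulates all deeper levels, `H_Se = Σᵢ₌₂..N Hᵢ / N`; the balance is
`H_B = H_In − H_Se`, zero at the balanced operating point.

### Sign conventions and degeneracies

Three choices are open in the sign-split procedure and are fixed as follows:

* **Orientation.** An eigenvector is defined only up to sign.  Each vector
  is oriented so its largest-magnitude component is positive before its
  signs are read (the first vector is additionally oriented to a positive
  component sum during decomposition, which agrees with the Perron vector).
  Without this, a vector whose nonzero entries all share one sign — which
  happens in clipped FC matrices when a region decorrelates from the rest —
  would partition differently under the solver's arbitrary sign choice.
  With it, module counts, sizes and all components are exactly invariant to
  eigenvector sign flips.
* **Zeros.** Components within `1e-12` of zero (relative to the vector's
  largest component) join the non-negative group.  This absorbs solver
  rounding of analytically-zero entries; the worked four-region example
  exercises it.
* **Degenerate eigenvalues.** Equal eigenvalues are kept in the solver's
  stable sorted order.  Partitions inside a degenerate eigenspace are
  basis-dependent; the summary components are still well defined, but
  per-level labels should not be interpreted there.  Test fixtures avoid
  exact degeneracy except where only the summary is asserted.

Once every module is a singleton, the remaining levels keep `Mᵢ = N` and
`pᵢ = 0`, contributing `Λᵢ²/N` each — nonzero only while `Λᵢ > 0`.

## FC construction and sliding windows

Static FC is computed over all frames with sessions concatenated; the only
post-processing is clipping negative correlations to zero and forcing the
diagonal to one.  The sliding-window count convention is
`floor((n_frames − width)/step)` — deliberately one less than the usual
`n − w + 1` at step 1 — so that the reference four-session resting-state
protocol (4 × 1200 frames, TR 0.72 s, width 83 frames, step 1 frame) yields
4,717 windows of 59.76 s and 3,396.24 s of total analysis time.  Each
window applies the identical FC construction to its 83 frames.

## Gaussian linear diffusion model

On a structural connectivity (SC) matrix `A` (symmetric, non-negative, zero
diagonal; from directed tract probabilities via `w = (pᵢⱼ + pⱼᵢ)/2`), with
Laplacian `H = D − A` and global coupling `c ≥ 0`, regional activity obeys
the linear stochastic dynamics `dx/dt = −(I + cH)x + noise`.  Writing
`Q = (I + cH)⁻¹`, the ensemble covariance is `Cov = 2QQᵀ` and the model FC
is its correlation matrix.  For connected non-negative SC and `c > 0` the
analytic FC is strictly positive (`I + cH` is an M-matrix), identity at
`c = 0`, and all-ones in the strong-coupling limit.

**Simulation.** The sampler integrates the dynamics by Euler–Maruyama, one
recorded frame per step of `dt` model-time units.  The noise covariance is
chosen per eigenmode of `I + cH` (amplitude `2·sqrt(dt/λ)` along each
eigenvector) so that the stationary covariance of the simulated process is
the analytic `2QQᵀ`; a unit-amplitude noise would instead equilibrate to
`(I + cH)⁻¹`, whose correlations are systematically weaker than the
ensemble covariance the analytic route uses, and the two routes would never
agree.  Defaults: `dt = 0.05` (stability requires `dt·λ_max(I+cH) < 2`,
checked with an informative error; the Euler discretisation bias on
correlations is O(dt), about 0.01 at the two-node test point), burn-in of
10 model-time units (the slowest mode relaxes on 1 unit), and one
integer seed controlling all noise.

**Balanced coupling.** Sweeping `c` over a grid, `H_In(c)` rises and
`H_Se(c)` falls monotonically on the tested synthetic SCs, so `H_B(c)`
crosses zero exactly once.  The crossing `c*` is located by linear
interpolation between the bracketing grid points, or by Brent's method
inside that bracket when refinement is requested.

## Calibration

Short series inflate segregation, so raw components are length-biased.  The
static correction rescales each cohort stream proportionally,
`HSe'ᵢ = HSeᵢ·H_In^S/⟨HSe⟩` and `HIn'ᵢ = HInᵢ·H_In^S/⟨HIn⟩`, to a reference
integration level `H_In^S` (default 0.18, the long-run stable-FC value of
the reference young-adult cohort, which coincides with the model's
integration at its balanced coupling; any other dataset needs its own
reference, so the parameter is always visible).  Both cohort means then
equal `H_In^S` exactly, the mean balance is zero, and ranks within each
stream are untouched; the map is idempotent.  Per-window streams are then
rescaled per subject to that subject's calibrated static values.
Single-subject calibration is allowed but warned about — the factors are
then estimated from one observation.

## Dynamic state measures

Given the calibrated per-window balance `H_B^t`, with every window
contributing `tr` seconds (`t_all` = window count × tr): dwell times
`T_In = t(H_B^t ≥ 0)/t_all` and `T_Se = 1 − T_In` (zero counts as
integrated, matching the `≥` in the definition); switching frequency
`f_IS = n/t_all` with `n` the number of adjacent pairs whose product is
`≤ 0` (a run of exact zeros therefore counts one crossing per adjacent
pair); deviation amplitudes `D_In`/`D_Se` as the mean (absolute) balance on
each side, an unvisited side contributing 0 with a warning, and
`D_IS = D_In + D_Se`.  The duration-vs-count ambiguity in the deviation
denominators is moot — both readings give the same ratio — so per-window
means are used.

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes, not
anatomical realism (no distance-dependent wiring, no hemispheres):

* **SC**: 10 regions in two equal blocks, within-block mean weight 1.0,
  between-block 0.2, Gaussian weight noise with sd 0.1 clipped at zero,
  symmetrised, connectivity enforced by seeded resampling.  Small enough
  that a full coupling sweep and a 20-subject dynamic pipeline run on one
  CPU in well under a minute, large enough for a clear modular hierarchy.
* **Cohort**: 20 subjects, each simulated at a coupling `c_k` on a linear
  grid over `(0.25·c*, 2.5·c*)` around the SC's own balanced coupling —
  individual variation enters through the model's only physiological dial,
  placing subjects along the segregation→integration axis with several
  near balance, mirroring how an empirical cohort straddles its group
  operating point.  Each subject gets 2×10⁴ frames at TR 0.72 s; per-window
  analysis uses width 83 frames and step 10 frames (the reference window
  duration with a coarser stride, keeping ~2,000 windows per subject).
* **Seeding**: one master seed; subject seeds are spawned from it (and
  domain-separated from the SC draw), so any subject is reproducible alone.

What passing on these conditions shows — and does not.  The synthetic
series are stationary, Gaussian, and generated by the very model used for
the sweep, so they validate the estimators and the internal consistency of
the pipeline (ordering recovery, dwell/switching/deviation patterns around
balance), not robustness to haemodynamics, motion, measurement noise, or
non-stationarity of real BOLD data.

## Numerical notes

* Asymmetry tolerance on input matrices: `1e-8` (inputs are symmetrised
  by averaging before decomposition); FC invariant checks at `1e-10`.
* The worked four-region fixture’s expected values are closed forms (2×2
  block eigenvalues `1.85 ± √0.0425`, within-pair modes `0.2` and `0.1`),
  kept independent of the eigensolver.
* Modularity uses the ordered-pair double sum including `i = j` (the
  `−kᵢ²/l` self-terms), matching the printed formula and the standard
  toolbox convention; participation treats isolated nodes as PC = 0 with a
  warning.  Weighted global metrics take distance = 1/weight, path length
  as the mean finite pairwise distance, efficiency as the mean inverse
  distance with disconnected pairs contributing zero, and Onnela
  geometric-mean clustering — conventions chosen here, isolated in one
  function so they can be swapped.
* JSON results store floats at full double precision; matrices are written
  with 12 significant digits.

## Known limitations

* Partitions within exactly degenerate eigenspaces are basis-dependent
  (see above).
* The balanced-coupling search assumes a single crossing; multiple
  crossings are reported (`n_sign_changes`) but only the first is refined.
* The sampler's Euler discretisation biases correlations by O(dt); for
  precision work at strong coupling reduce `dt` (the stability bound is
  checked, the bias is not).
* No empirical-data preprocessing of any kind is included; inputs are
  assumed to be cleaned region × time or region × region tables.
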