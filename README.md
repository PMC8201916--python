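# nspbalance

Quantify the balance between **segregation** and **integration** in
functional brain networks with the nested-spectral-partition (NSP)
eigenmode framework, locate the balanced operating point of a Gaussian
linear diffusion model on a structural connectome, and track dynamic
switching between segregated and integrated states through sliding
windows.

Intended for researchers analysing region × region functional connectivity
(FC) or region × time BOLD-like series who want an explicit, hierarchical
balance measure rather than single-level graph statistics.

## The measure

An FC matrix `C` (Pearson correlations, negatives clipped to zero) is
decomposed into eigenmodes `C = UΛUᵀ`; `Λᵢ²` is mode *i*'s contribution.
Modules are detected hierarchically by eigenvector sign — mode 1 gives one
whole-network module, mode *i* splits every existing module into its
positive- and negative-sign subsets — and each level is scored by a
size-corrected, eigenvalue-weighted module count:

    Hᵢ = Λᵢ² Mᵢ (1 − pᵢ) / N ,   pᵢ = Σⱼ |mⱼ − N/Mᵢ| / N

with `Mᵢ` the module count and `mⱼ` the module sizes at level *i*.  Then

* `H_In = H₁/N ∈ [0, 1]` — global integration,
* `H_Se = Σᵢ₌₂..N Hᵢ/N` — total hierarchical segregation,
* `H_B = H_In − H_Se` — the balance; `H_B = 0` marks the balanced state.

On a structural connectome the package's linear diffusion model
`dx/dt = −(I + cH)x + noise` (Laplacian `H = D − A`, coupling `c`) has
analytic FC `corr(2QQᵀ)`, `Q = (I + cH)⁻¹`; sweeping `c` locates the
critical coupling `c*` where `H_B` crosses zero.  Sliding-window
trajectories of `H_B^t` yield dwell times `T_In`/`T_Se`, switching
frequency `f_IS`, and deviation amplitudes `D_In`/`D_Se`.

## Worked example

```python
import nspbalance as nb

fc, _ = nb.worked_example_fixture()   # two tight pairs, weakly coupled
spectrum  = nb.decompose_fc(fc)
partition = nb.nested_partition(spectrum)
profile   = nb.component_profile(spectrum, partition)
print(spectrum.eigenvalues.round(5))  # [2.05616 1.64384 0.2  0.1]
print(partition.module_counts)        # [1 2 3 4]
print(f"{profile.integration:.5f} {profile.segregation:.5f} {profile.balance:.5f}")
# 0.26424 0.34528 -0.08104
```

The four regions form two strongly correlated pairs (r = 0.9 and 0.8) with
weak cross-pair correlation (0.1).  Level 2 of the partition recovers the
two pairs; the balance `H_B ≈ −0.081` is negative because most eigenmode
contribution sits in the segregated levels — the network is
segregation-dominated.  Running `python examples/coupling_sweep.py` prints
the model sweep on a synthetic 10-region connectome, ending in

```
H_B sign changes: 1
balanced coupling c* = 0.3235 (H_In(c*) = H_Se(c*): segregation-integration balance)
```

More narrative scripts live in `examples/` (dynamic state measures,
cohort calibration).  A thin CLI mirrors the library:

```bash
nsp compute --fc FC.csv --out profile.json
nsp sweep --sc SC.csv --c-min 0 --c-max 1.2 --steps 31 --out sweep.json
nsp dynamics --bold BOLD.csv --tr 0.72 --width 83 --step 1 --out dyn.json
nsp calibrate --cohort cohort.csv --hins 0.18 --out calib.json
nsp synth sc --seed 0 --out sc.csv
```

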