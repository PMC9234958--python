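# ccrelax

Spin dynamics of hyperpolarized ¹³CH₂ and ¹³CH₃ groups after dissolution-DNP
sample transfer: cross-correlated cross-relaxation (CCR), symmetry manifolds,
multiplet analysis and field-dependent solvent paramagnetic relaxation
enhancement (sPRE).

## The problem

In dissolution dynamic nuclear polarization (DDNP), a sample is hyperpolarized
near 1 K, dissolved, and shot through a varying magnetic field into an NMR
spectrometer. During that transfer, proton-carrying ¹³C groups (the CH₂ of
ethylene glycol, the CH₃ of methanol) can come out with *inverted* ¹³C signals:
cross-relaxation driven by the interference of the C–H dipolar couplings
converts the near-unity proton polarization into carbon polarization of
opposite sign. The package simulates and analyzes this effect quantitatively:

- **Symmetry manifolds.** Two equivalent protons split into triplet (T) and
  singlet (S) states; three methyl protons into the A/Eₐ/E_b irreducible
  representations of the C₃ permutation group (sizes 4/2/2). Population
  imbalances between manifolds (T–S, A–E) are long-lived because in-pair
  dipolar and symmetric random-field relaxation cannot mix them.
- **Redfield relaxation.** The semi-classical relaxation superoperator is
  assembled from dipole–dipole (auto- and cross-correlated), chemical-shift
  anisotropy (CSA), CSA–DD interference and random-field mechanisms, each
  toggleable, with the spectral density J(ω) = (2/5)τc/(1+ω²τc²) and an
  optional Woessner rotating-top model for internal methyl rotation.
  The heteronuclear two-spin limit reproduces the Solomon equations
  ρ_I = (b²/4)[J(ω_I−ω_S) + 3J(ω_I) + 6J(ω_I+ω_S)],
  σ_IS = (b²/4)[6J(ω_I+ω_S) − J(ω_I−ω_S)] to machine precision.
- **Propagation and detection.** dρ/dt = −i[H,ρ] − R(ρ−ρ_eq) is solved by
  exact matrix exponentiation; the detection pulse train (small flip angles,
  one scan per second) yields per-line multiplet intensities, which decompose
  exactly into the Cz, CzHz, CzHzHz, CzHzHzHz spin-order contributions.
- **Back-fitting.** `InitialCombinationModel` fits the hyperpolarized initial
  combination (Hz, Cz, manifold imbalance) to measured or synthetic decay
  curves; because the forward model is affine in the initial state the fit is
  exact linear least squares with classical inference
  (`fit()` → results with `params`, `bse`, `conf_int()`, `summary()`).
- **sPRE.** The outer-sphere translational model with the Hwang–Freed
  spectral density gives the strongly field-dependent proton relaxation
  enhancement of dissolved TEMPOL, the quantity that makes low-field transfer
  passages so destructive.

## Worked example

Simulate the methanol scenario (hyperpolarized ¹³CH₃ with the negative-DNP
combination ¹Hz:¹³Cz:A–E = −1:−0.01:3 applied 12 s before detection), generate
a noisy synthetic dataset from it, and fit the combination back:

```python
import ccrelax as cx
out = cx.run_scenario("methanol_ch3", "run1", seed=1)
print(out["log"]["first_scan_normalized"])
print(out["fit"].summary())
```

prints (numbers produced by this exact code):

```
{'line1': -4.436725767569525, 'line2': -1.9566646921765727,
 'line3': -4.203160214910041, 'line4': 1.0}

Initial-combination fit (linear least squares)
==============================================================
observations: 240   residual dof: 237   R^2: 0.994738
condition number: 7.8   identifiable: True
--------------------------------------------------------------
component     estimate     std err        [95% conf. int.]
Hz            -0.98477     0.03824    -1.06011    -0.90943
Cz            -0.00550     0.00877    -0.02277     0.01177
AE             3.00044     0.01576     2.96938     3.03149
==============================================================
```

The first line shows the ¹³C quartet at the start of detection normalized to
its fourth line: the signal is no longer the thermal +1:+3:+3:+1 pattern — the
negative proton polarization has been converted into carbon polarization of
opposite sign and the long-lived A–E imbalance contributes anti-phase orders
that make the multiplet asymmetric. The fit recovers the generating
combination (−1, −0.01, 3) from the 2%-noise synthetic data within its 95%
confidence intervals.

The same machinery runs from the shell:

```bash
ccrelax simulate methanol_ch3 --out run1 --seed 1
ccrelax spre --b0-min 1e-4 --b0-max 12 --out spre.csv
ccrelax graph ch2_eg --out pathways.graphml
```

## Layout

| module | contents |
| --- | --- |
| `ccrelax.spinsys` | spin systems, Hamiltonians, T/S and A/E manifolds, level labeling |
| `ccrelax.relaxation` | Redfield superoperators per mechanism, population matrices, pathway graphs, calibration |
| `ccrelax.dynamics` | initial combinations, propagation, detection trains, transfer field profiles |
| `ccrelax.spectra` | multiplet intensities, spin-order decomposition, Lorentzian synthesis and fitting |
| `ccrelax.fitting` | `InitialCombinationModel` / `InitialCombinationResults` |
| `ccrelax.spre` | field-dependent solvent PRE of nitroxide radicals |
| `ccrelax.synthetic` | synthetic decay-curve datasets with ground truth, field-profile fixtures |
| `ccrelax.config` | YAML config dialect, bundled fixtures, scenario runner |
| `ccrelax.cli` | `ccrelax` command (`simulate`, `spectrum`, `fit`, `spre`, `synth`, `graph`) |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
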