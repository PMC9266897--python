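# larex

Quantitative CEST MRI analysis with Lorentzian-corrected Ω-plots.

Chemical exchange saturation transfer (CEST) imaging detects dilute labile
protons — such as the hydroxyl protons of glycosaminoglycan (GAG) in
intervertebral disc — through their exchange with water under selective RF
saturation. Quantitative CEST goes beyond contrast: from Z-spectra acquired
at several saturation amplitudes B₁ it estimates the labile-proton fraction
f_b and the exchange rate k_ba. The classical route is the
relaxation-compensated Ω-plot: the spillover-corrected inverse metric
MTR_Rex = 1/Z(+δ) − 1/Z(−δ), scaled by R₁ into AREX (apparent
exchange-dependent relaxation), obeys

    AREX / DC = f_b · k_ba · ω₁² / (ω₁² + k_ba (k_ba + R_2b))

at the steady state of a pulsed train with duty cycle DC, so 1/(AREX/DC) is
linear in 1/ω₁² with intercept p = 1/(f_b k_ba) and slope q such that
q/p = k_ba (k_ba + R_2b); ordinary least squares over ≥ 3 B₁ levels inverts
for both parameters.

That inversion assumes a two-pool system. Real tissue is not: in disc, the
amide, NOE and semisolid MT pools distort Z(±1 ppm) and drive the raw AREX
Ω-plot into biased or outright non-physiological estimates. The
Lorentzian-corrected variant (LAREX) implemented here fixes this by
(1) normalizing the Z-spectra, (2) decomposing each spectrum into six
Lorentzian lines (water, amide, hydroxyl, NOE at −1.6 and −3.5 ppm, MT)
under box constraints with an arctangent loss, (3) re-centering the fitted
lines to their nominal offsets and synthesizing a clean two-pool spectrum
from the water and target lines only, and (4) running the same Ω-plot
inversion on the corrected spectra.

The package provides:

- `larex.bm_sim` — pulsed-saturation Bloch–McConnell simulator for
  star-topology multi-pool systems (matrix-exponential propagation,
  vectorized over offsets and pulse segments), with presets for the 3 T
  six-pool disc model (`ivd6`), the ideal two-pool system (`ideal2`) and
  the acquisition scheme (`scheme_3t`: Gaussian pulses, t_p = t_d = 100 ms,
  n_p = 40, 64 offsets in ±5 ppm plus a 300-ppm reference).
- `larex.zproc` — reference normalization, WASSR B₀ mapping and spectral
  shift correction, non-local-means denoising, T₁ (inversion-recovery) and
  T₂ (spin-echo) fitting.
- `larex.lorentz` — the constrained six-pool Lorentzian decomposition,
  arctangent loss variants, re-centering and two-pool synthesis.
- `larex.omega` — MTR_asym / MTR_Rex / AREX metrics, the Ω-plot inversion
  with Gaussian-pulse form factors, the AREX and LAREX pipelines, and the
  GAG concentration conversion.
- `larex.experiments` — the in-silico accuracy grid, synthetic voxelwise
  phantoms, the worked single-point example, and voxelwise map estimation.
- a `larex` command-line interface (`simulate`, `fit-lorentz`, `qcest`,
  `grid`, `phantom`, `fig5`).

## Worked example

Simulate the six-pool disc system at its reference operating point
(f_b = 1.8 ‰, k_ba = 400 Hz), then quantify it with both pipelines:

```python
from larex import (ivd6, scheme_3t, qcest_arex, qcest_larex,
                   ArexConfig, gag_concentration)
from larex.experiments import simulate_stack

stack = simulate_stack(ivd6(f_b=1.8e-3, k_ba=400.0))   # 7 B1 levels, 64 offsets
config = ArexConfig.from_scheme(scheme_3t(0.6))

arex = qcest_arex(stack, 1.306, config)
larex = qcest_larex(stack, 1.306, config)
print(f"AREX : admissible={arex.admissible}  flags={arex.flags}")
print(f"LAREX: f_b = {larex.f_b_permil:.2f} permil, "
      f"k_ba = {larex.k_ba_Hz:.0f} Hz (R^2 = {larex.r_squared:.2f})")
print(f"GAG  : {gag_concentration(larex.f_b):.0f} mM")
```

prints

```
AREX : admissible=False  flags=('inadmissible_regression',)
LAREX: f_b = 2.35 permil, k_ba = 358 Hz (R^2 = 0.71)
GAG  : 70 mM
```

The raw AREX Ω-plot collapses on the multi-pool system (negative intercept,
flagged non-physiological — the interfering pools dominate the ±1 ppm
asymmetry), while the Lorentzian-corrected inversion recovers the ground
truth within the study's error bounds (|Δf_b| ≤ 1 ‰, |Δk_ba| ≤ 300 Hz).
The last line converts the recovered fraction to a GAG concentration
assuming 80 % tissue water and three exchanging OH protons per
disaccharide.

The same comparison over a parameter grid:

```sh
larex grid --n 4 --out grid.tsv       # physiological box, ~6 min on one CPU
larex fig5 --seed 0 --out fig5.json   # the worked single-point report
```

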