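# t1rho-infarct

Non-contrast characterization of chronic myocardial infarction from
T1ρ-weighted cardiovascular MR, built and validated on a digital
left-ventricle phantom.

Late gadolinium enhancement (LGE) is the reference standard for imaging
myocardial scar, but it needs a contrast agent that is contraindicated in
renal failure. Spin-lock (T1ρ) imaging offers an endogenous alternative:
chronic scar has a rotating-frame relaxation time nearly twice that of
healthy myocardium (≈92 ms vs ≈47 ms at 3 T in swine), so T1ρ-weighted
images at long spin-lock durations show scar bright without any agent.
This package implements the complete quantification pipeline around that
contrast mechanism, for researchers developing or evaluating non-contrast
scar imaging:

- **phantom** — a seeded synthetic short-axis LV: annular myocardium,
  blood pool, and a sectoral infarct of configurable angular extent and
  transmural depth, rasterized with supersampled partial-volume mixing.
  Signal follows mono-exponential spin-lock decay
  `S(TSL) = Σ_t f_t · S0_t · exp(−TSL/T1ρ_t)` over the spin-lock schedule
  TSL = 6, 18, 30, 42, 48 ms (ν₁ = 500 Hz carried as metadata), with
  Rician magnitude noise. Every downstream quantity has an analytic
  ground-truth value computed from the configuration, not the raster.
- **relaxometry** — pixelwise `T1ρ` mapping by bounded nonlinear least
  squares seeded from the log-linear estimate, with validity masking and
  region statistics.
- **chords** — the chord segmentation used for regional analysis: 20
  circumferential wedges × 5 radial sections about the cardiac centroid,
  with mid-myocardial (sections 2–4) signal profiles normalized to the
  maximum.
- **metrics** — infarct classification (remote mean + k·SD, FWHM, or fixed
  threshold), infarct size as the infarct-adjacent fraction of the
  endocardial perimeter, chord-based transmurality, tissue mass at
  1.06 g/mL, and CNR = (S_infarct − S_remote)/σ_noise.
- **agreement** — Bland–Altman bias and 1.96·SD limits of agreement,
  OLS correlation, and balanced two-way ANOVA for method comparison.
- **pipeline / cli** — one reproducible run per `RunConfig` (`t1rho-mi`
  subcommands: `simulate`, `fit`, `chords`, `quantify`, `agree`,
  `run-all`), NIfTI-1 rasters with JSON sidecars, YAML configs.

The `analysis/` scripts walk the study end to end: `01` simulates the
phantom, `02` fits relaxation maps, `03` chord-segments, `04` quantifies
the infarct, `05` compares methods across a seeded cohort.

## Worked example

```python
from t1rho_infarct import PhantomConfig, RunConfig, run_study

run = RunConfig(phantom=PhantomConfig(n_slices=10, seed=4))
result = run_study(run)
r = result.report
print(f"infarct size {r.infarct_size_percent:.1f}%  "
      f"mass {r.infarct_mass:.1f} g  CNR {r.cnr:.2f}")
```

prints

```
infarct size 21.1%  mass 9.4 g  CNR 11.19
```

The phantom was built with a transmural infarct sector covering 21.1% of
the endocardial perimeter; the pipeline (Rician noise at SNR 50 →
pixelwise T1ρ fit → remote mean + 5·SD classification → perimeter ratio)
recovers it exactly to the printed precision. The mass is the classified
infarct volume times 1.06 g/mL, and the CNR is measured on the 48 ms
spin-lock image against the background-estimated noise level. Running
`python analysis/05_method_agreement.py` compares T1ρ-measured sizes with
the simulated reference modality and the analytic truth over a 7-subject
cohort (bias −0.4 and −0.1 points, R² ≈ 0.998).

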