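# neuroquant

Quantification and statistics for longitudinal multimodal PET/MRI brain
studies in small animals. The package turns raw acquisition series into
parametric maps, regional statistics and longitudinal inference:

* **SUV** from static FDG-PET: SUV = A_conc / (A_inj / BW), with optional
  F-18 decay correction of the injected activity to scan start;
* **ADC** from multi-b-value DWI: voxel-wise monoexponential fits
  S(b) = S0·e^(−b·ADC) in three orthogonal directions, averaged;
* **K1** (perfusion uptake rate ≈ cerebral blood flow) from FAIR
  arterial-spin-labeling: voxel-wise inversion-recovery fits
  S(TI) = c + S0·(1 − 2·e^(−TI·R1)) of the selective and non-selective
  series, combined through the one-compartment model
  K1 = V_d·R1,a·(R1,s − R1,ns)/R1,ns with V_d = 0.95 mL/mL, T1,a = 2 s;
* **regional statistics** over an atlas label volume: per-region means,
  relative left–right hemispheric differences d = (L − R)/L, and left-vs-
  right region-by-region Pearson correlation heat maps pooled over time;
* **trend analysis**: a linear mixed model with per-subject random
  intercept and slope, fixed quadratic time effect and dose covariate,
  fitted by REML, with Wald tests of the quadratic and dose terms.

The intended study design is hemispheric irradiation follow-up (5 vs 20 Gy,
six subjects per group, scans before and 3, 7, 30 and 60 days after
exposure), but every stage works on any pre-registered NIfTI volumes that
share a grid with the atlas.

Because such animal datasets are rarely public, the package ships a
first-class synthetic-phantom module: mirror-symmetric labeled brain
phantoms, forward simulators for all three modalities with Rician (MRI) or
Gaussian (PET) noise and known ground truth, and a longitudinal cohort
generator that draws from exactly the mixed model the trend stage fits.
Every estimator is validated by parameter recovery against this generator.

## Worked example

```python
import neuroquant as nq
from neuroquant.phantom import GroundTruth

atlas = nq.make_label_phantom((32, 32, 16), rng_seed=1)
truth = GroundTruth()                      # SNR-40 defaults, known values
brain = atlas.brain_mask

# diffusion: three directions, fitted and averaged
dwi = nq.simulate_dwi(atlas, truth, rng_seed=7)
adc = nq.mean_adc([nq.fit_adc_direction(s, mask=brain) for s in dwi])

# perfusion: selective/non-selective FAIR pair -> K1
sel, nsel = nq.simulate_fair(atlas, truth, rng_seed=7)
k1 = nq.compute_k1(
    nq.fit_inversion_recovery(sel, mask=brain).r1_map(),
    nq.fit_inversion_recovery(nsel, mask=brain).r1_map(),
)

table = nq.extract_regions(adc, atlas, subject="s01", timepoint="pre")
print(table[table.hemisphere == "left"][["region", "mean_value", "voxel_count"]])
```

```
         region  mean_value  voxel_count
0      thalamus    0.000707          254
1        cortex    0.000726          254
2  hypothalamus    0.000719          254
3   hippocampus    0.000750          254
4      amygdala    0.000736          254
5    ventricles    0.002171          254
```

The fitted regional ADC means reproduce the simulated ground truth
(0.71, 0.73, 0.72, 0.75, 0.74 and 2.2 ×10⁻³ mm²/s) to within the Monte-
Carlo noise of ~250-voxel averages at SNR 40; the cerebellum is absent
because the diffusion analysis excludes it by default, and the ventricles
sit at the CSF value.

The one-command demonstration simulates the full two-dose cohort (60
scans), fits every map, and runs all analyses:

```
neuroquant demo --seed 7 --out demo_out
```

```
SUV: p_quadratic=7.917e-27 p_dose=0.005405
ADC: p_quadratic=1.26e-19 p_dose=0.8878
K1: p_quadratic=0.3566 p_dose=0.9111
```

Under the default generator the glucose-uptake and diffusion trajectories
carry a real quadratic time effect (recovered with p ≪ 0.05) while
perfusion carries none. The generator encodes *no* mean dose difference;
the small SUV dose p-value at this particular seed is the kind of
finite-sample false positive an uncorrected Wald z-test on 12 subjects
produces occasionally, which is why the test suite measures the test's
empirical type-I error over many simulated cohorts rather than trusting a
single draw. `demo_out/` contains the region table,
hemispheric-difference table, per-dose correlation heat maps (CSV + PNG),
trend fits (JSON) with fitted curves, example parametric maps (NIfTI), and
a provenance record.

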