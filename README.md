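# lgequant

Infarct-size quantification for late gadolinium enhancement (LGE)
cardiac MR, and the reproducibility analysis that decides which method a
multicenter trial should use — driven entirely by synthetic short-axis
phantoms, so the whole pipeline runs with no patient data.

## Who this is for

Acute-infarct size on LGE CMR is an attractive surrogate endpoint for
cardioprotection trials, but every sizing method begins with a human
tracing the endocardial/epicardial borders, and methods differ in how
they treat partially bright ("grey", intermediate-signal-intensity)
tissue at the infarct rim. This package is for people studying that
measurement chain: it simulates a multi-reader core-laboratory study on
phantoms with known ground truth, quantifies every phantom with eight
standard methods, and computes the reproducibility statistics (CV, ICC,
Bland–Altman, variance components) and the trial sample sizes they imply.

## The eight methods

| tag | description |
|---|---|
| `AUTO_SEGMENT` | weighted-threshold algorithm: voxels above a remote-myocardium threshold t = μ_r + k·σ_r get weight min(1, (SI−t)/(F−t)) up to the plateau level F, so intermediate-signal voxels count fractionally |
| `AUTO_UC_SEGMENT` | the same plus simulated user corrections (add no-reflow, remove blood-pool/artifact blobs) |
| `AUTO_FWHM` | full-width-at-half-maximum: dichotomous classification above half the maximal infarct signal |
| `AUTO_UC_FWHM` | FWHM with user corrections |
| `MANUAL` | planimetry including all hyperenhanced tissue, bright or grey |
| `MANUAL_ISI` | planimetry including 100% of bright and 50% of grey tissue |
| `VISUAL` | 17-segment extent scoring, size = Σ midpoint(score)/17 with midpoints 13/38/63/88% |
| `VISUAL_ISI` | extent score additionally weighted by a 4-level signal-intensity score |

No-reflow (microvascular obstruction) zones count as 100% infarcted in
all methods.

The statistics stage implements the core-laboratory reproducibility
analysis: per-patient averaged absolute between-reader differences;
CV = 100·SD(differences)/mean size; ICC(2,1) with F-based CI;
Bland–Altman bias ± 1.96·SD; one-way variance components σ_T² (between
patients) and σ_e² (method); and the two-arm sample size
n = 2σ²(z_{α/2}+z_β)²/δ² with σ² = σ_T² + σ_e².

## Worked example

Simulate a 30-patient cohort read by three simulated core laboratories
(smooth radial contour-tracing error of 1 mm SD), quantify with all
eight methods, and summarize:

```python
from lgequant.pipeline import PipelineConfig, run_pipeline
from lgequant.phantom import CohortSpec, PhantomSpec, ReaderModel
from lgequant import reprostats

readers = [ReaderModel(reader_id=f"lab{i+1}", contour_error_sd=1.0) for i in range(3)]
config = PipelineConfig(
    cohort=CohortSpec(n_patients=30, n_readers=3, reader_models=readers,
                      master_seed=7, phantom_template=PhantomSpec(grid=(96, 96, 8))),
)
result = run_pipeline(config)
frame = reprostats.report_frame(result.reports)
print(len(result.measurements), "measurements")
print(frame[["method", "mean_size", "cv_percent", "icc", "within_share", "n_delta_5"]]
      .round(2).to_string(index=False))
```

prints

```
720 measurements
         method  mean_size  cv_percent  icc  within_share  n_delta_5
      AUTO_FWHM      21.11        2.20 0.99          0.01         48
   AUTO_SEGMENT      16.81        2.04 0.99          0.01         33
   AUTO_UC_FWHM      20.13        2.23 0.99          0.01         50
AUTO_UC_SEGMENT      16.10        2.68 0.99          0.01         34
         MANUAL      26.15        7.39 0.92          0.08         78
     MANUAL_ISI      21.17        3.16 0.98          0.02         52
         VISUAL      26.61        8.78 0.91          0.09         77
     VISUAL_ISI      16.66        5.61 0.97          0.03         35
```

Reading the table: 720 = 30 patients × 3 readers × 8 methods. The
automated methods show nonzero CV even though their border algorithms
are deterministic — the variability enters through the contour tracing
that precedes them. MANUAL and VISUAL carry the largest between-reader
CV because readers disagree on how much of the grey rim "appears
hyperenhanced"; their ISI variants, which weight grey tissue by an
explicit rule, cut the CV roughly in half and also report smaller mean
sizes (grey counted at half weight). `within_share` is
σ_e²/(σ_T²+σ_e²): for the well-behaved methods the sizing method
contributes under 10% of total variance, so the per-arm sample size to
detect a 5 %LV treatment effect (`n_delta_5`) varies mainly with the
method's between-patient spread.

The same pipeline is available from the shell:

```bash
lgequant run --n-patients 30 --n-readers 3 --seed 7 --out out/
lgequant samplesize --sigma 10 --delta 5        # -> 63
```

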