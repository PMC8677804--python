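# dnctest

Analysis pipeline for the **Dopamine Neuron Challenge (DNC) Test** — a
candidate laboratory test for detecting Parkinson's disease before
symptom onset. Parkinsonian motor signs only appear after more than 60%
of substantia nigra dopamine neurons are lost, because the surviving
neurons compensate by releasing more dopamine at rest. The DNC Test
defeats this compensation: a drug challenge (methylphenidate +
haloperidol) evokes maximal dopamine release, and the resulting surge of
dopamine metabolites in CSF and plasma scales with the number of
surviving neurons. Diseased subjects show a blunted surge even when
fewer than 30% of their neurons are gone.

The package implements every quantitative stage of that analysis for
researchers working with the mouse-model data or planning similar
studies:

- **photometry** — spectral linear unmixing of two-fluorophore
  (dLight1.1 / tdTomato) emission spectra, linear photobleaching
  correction with ΔF/F₀%, and the ratio-increase metric used to rank
  challenge agents;
- **hplc** — chromatogram peak integration, the HVA standard curve
  (0.5–50 ng/ml), absolute plasma HVA, and the CSF DOPAC/5-HIAA and
  HVA/5-HIAA internal-control ratios;
- **histology** — TH⁺ cell counting (opening → blur → rolling-ball →
  isodata threshold → watershed → area filter), terminal optical
  density, and percent-loss summaries;
- **dnc** — the diagnostic core: midpoint threshold
  T = (mean_challenged_control + mean_challenged_PD)/2, per-subject
  calls (positive iff value < T), sensitivity = N_true+/N_PD × 100%,
  specificity = N_true−/N_control × 100%, plus the closed-form normal
  prediction of both;
- **synthetic** — seeded generators for every input (emission-frame
  series, chromatograms, cohort tables at the published mean ± SEM × n,
  DAB-like section images), each returning its latent ground truth;
- **pipeline / cli** — a schema-validated, fully seeded end-to-end run
  with manifest and Markdown report.

No raw animal data were deposited; the published group summaries
(collected in `dnctest.studyparams`) are the quantitative inputs, and
synthetic data stand in for the measurement streams.

## Worked example

```sh
dnc run --config configs/demo.yaml --seed 1 --out runs/demo
```

runs every stage on synthetic inputs and writes `report.md`,
per-stage CSVs, classification plots and a `manifest.json` of parameter
values and output digests. From an actual run:

```
| stage       | analyte     | threshold |
|-------------|-------------|-----------|
| early       | DOPAC_5HIAA | 0.1107    |
| early       | HVA_ng_ml   | 13.65     |
| ultra_early | HVA_5HIAA   | 0.1535    |
| ultra_early | HVA_ng_ml   | 14.29     |

Simulated cohort (early stage), state=challenged:
| analyte     | threshold | sensitivity    | specificity    |
|-------------|-----------|----------------|----------------|
| DOPAC_5HIAA | 0.1129    | 100% (12/12)   | 93% (13/14)    |
| HVA_ng_ml   | 13.756    | 100% (13/13)   | 82% (18/22)    |

Photometry: injected transient amplitude 50.0% -> recovered peak dF/F0 48.0%
HPLC: plasma HVA 17.91 ng/ml (constructed 17.91); CSF DOPAC/5-HIAA 0.1518 (constructed 0.1520)
```

The first table is computed from the published challenged-state group
means — the midpoint thresholds that define a positive diagnosis per
analyte and disease stage. The second shows the same classifier applied
to one simulated cohort drawn at the published group parameters: the
20-week ("early", ~28% neuron loss) CSF analytes separate essentially
perfectly, while plasma HVA trades a little specificity for an easier
sample to collect. The photometry and HPLC lines demonstrate that each
measurement stage recovers the ground truth its synthetic input was
built from.

Library use mirrors the CLI:

```python
from dnctest import synthetic, dnc

table = synthetic.simulate_cohort(synthetic.CohortSpec.from_study("early", seed=1))
result = dnc.evaluate_dnc(table, "HVA_ng_ml")
print(result.threshold, result.sensitivity_rounded, result.specificity_rounded)
```

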