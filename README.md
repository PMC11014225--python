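# breathpanel

Breath-test chromatogram analysis for case/control VOC (volatile organic
compound) studies: from raw micro-GC detector traces to a validated
three-compound diagnostic biomarker panel.

Screening colorectal cancer (CRC) through exhaled breath rests on a simple
observation: tumour metabolism shifts the pattern of VOCs reaching the
lungs. A portable gas chromatograph turns one breath sample into one
chromatogram — a detector-intensity trace over retention time — and the
diagnostic question becomes a signal-processing and feature-selection
problem. `breathpanel` implements that pipeline end to end, for
breathomics researchers who want a reproducible, testable reference
implementation:

1. **Simulation** — a generator of synthetic breath cohorts with known
   ground truth (exponentially modified Gaussian peaks at the retention
   times of a 61-compound breath VOC library plus unannotated compounds,
   log-normal abundances, planted case-elevated biomarkers, baseline
   drift, detector noise, retention-time jitter, and optional
   "technically inadequate" runs).
2. **Pre-processing & QC** — Savitzky–Golay de-noising, asymmetric
   least-squares baseline subtraction, and adequacy checks (signal floor,
   detector saturation, missing landmark peaks).
3. **Peak extraction** — prominence-gated peak picking,
   valley-referenced trapezoidal integration, anchor-based retention-time
   alignment, consensus-feature clustering, and library annotation,
   yielding a samples × ~100-VOC abundance matrix
   (log10, standardized on training rows only).
4. **Panel discovery** — a two-class Fisher linear discriminant built from
   first principles, `w = S_λ⁻¹(μ₊ − μ₋)` with covariance shrinkage
   `S_λ = (1−λ)S + λ(tr S/p)I`, scored by leave-one-out cross-validation
   over **every** k-feature subset of the candidate pool
   (C(100, 3) = 161,700 discriminants for a 3-peak panel).
5. **Evaluation** — confusion counts and sensitivity / specificity /
   PPV / NPV / accuracy on training, testing and combined sets, plus PCA
   projections of the selected panel.

The matrix-facing estimators (`FisherLDA`, `PanelSelector`, `PanelPCA`)
follow scikit-learn conventions (`fit`/`predict`/`transform`,
`get_params`, trailing-underscore fitted attributes) and compose with
scikit-learn tooling.

## Worked example

```python
from breathpanel.config import RunConfig
from breathpanel.pipeline import run_pipeline

report = run_pipeline(RunConfig(seed=1), "runs/demo")
print(report.table_frame())
```

This simulates the default cohort (36 CRC + 32 healthy controls, 18+18
training / 18+14 testing split, biomarker effect size 1.5), extracts 83
consensus VOC features, exhaustively scores 91,881 three-feature panels on
the training rows, and evaluates the winner:

```
                           Training Set  Testing Set  Training + Testing Set
Subject number                     36.0         32.0                    68.0
Positive                           19.0         19.0                    38.0
Negative                           17.0         13.0                    30.0
Specificity                        94.4         64.3                    81.3
Sensitivity                       100.0         77.8                    88.9
Positive predictive value          94.7         73.7                    84.2
Negative predictive value         100.0         69.2                    86.7
Total accuracy                     97.2         71.9                    85.3
```

Reading the table: of the 32 held-out samples, 77.8% of cancer cases and
64.3% of controls are called correctly by the selected panel, for a
combined accuracy of 85.3%. The gap between training (97.2%) and testing
(71.9%) accuracy is the selection optimism inherent in searching ~92,000
panels on 36 samples — a caveat discussed in `docs/methods.md`. The
selected panel (`runs/demo/discover/best_panel.json`) contains the planted
2,5-dimethylheptane peak at 341 s plus two unannotated features; at the
default effect size the search recovers the full planted triple only part
of the time, which is itself a faithful property of small-cohort panel
selection.

The same pipeline is scriptable stage by stage:

```bash
breathpanel simulate   --seed 1 --out runs/demo
breathpanel preprocess --seed 1 --out runs/demo
breathpanel features   --seed 1 --out runs/demo
breathpanel discover   --seed 1 --out runs/demo
breathpanel evaluate   --seed 1 --out runs/demo
```

Running the subcommands separately is byte-identical to `breathpanel run`.
Real chromatograms can be analysed by pointing `input_dir` at a directory
of `time_s,intensity` CSVs plus a `manifest.csv`
(`sample_id,group,role`).

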