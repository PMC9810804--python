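# bddkit

Entropy-based measurement of depression severity from video-derived
behavioral streams.

Clinical assessment of major depressive disorder (MDD) leans on rating
scales and interviews — slow, labor-intensive, and partly subjective.  Two
observable signatures of depressive severity are a flattened, monotonous
facial affect and a reduced, less varied range of body movement.  `bddkit`
turns those two signatures into a single longitudinal severity score, the
**behavioral depression degree (BDD)**, for researchers in computational
psychiatry who already have (or can mock) a perception front end producing
per-frame expression probabilities and body keypoints.

## The model

For each therapy session, two per-frame streams are condensed into two
Shannon entropies:

* **Expression entropy** — the perception front end emits a probability
  vector over the seven basic expressions (angry, disgust, fear, happy, sad,
  surprise, neutral) for every video frame.  The per-frame vectors are
  averaged into one session distribution *p*, and

  H(X) = − Σᵢ p(xᵢ) log p(xᵢ) / log 7 ∈ [0, 1].

  Lively, varied affect gives H near 1; mass piled on one class (typically
  "sad") gives H near 0.

* **Action entropy** — a pose estimator tracks 18 body keypoints (COCO-18
  layout) in normalized image coordinates.  Each joint *j* gets a motion
  amplitude D(yⱼ): the mean Euclidean displacement between consecutive
  frames, computed only over frames where the joint was detected.  With
  D_z = Σⱼ D(yⱼ) and qⱼ = D(yⱼ)/D_z,

  G(Y) = − Σⱼ qⱼ log qⱼ / log 18 ∈ [0, 1].

  Whole-body movement gives G near 1; movement frozen into a few joints —
  or no movement at all (D_z = 0 ⇒ G = 0) — gives G near 0.

The two entropies are mixed by a convex weight λ into the behavioral
entropy F(X, Y) = λ·H(X) + (1 − λ)·G(Y), and the severity score is its
complement:

  **B(X, Y) = 1 − F(X, Y)**  (higher BDD = more severe).

λ is fitted by scanning a grid over [0, 1] and maximizing the mean sample
Pearson correlation between the pooled per-session BDD values and three
clinical scale series — Zung's self-rating depression and anxiety scales
(SDS, SAS) and the Hamilton depression scale (HAMD).

The package also ships scale scoring and severity banding for SDS/SAS/HAMD,
longitudinal per-patient reports, a shape-checked specification of the
48×48-grayscale expression-recognition CNN (for validating externally
trained weights), and a deterministic synthetic-cohort generator in which a
latent severity variable drives all three data modalities with a *known*
generating λ — so the whole pipeline is testable end to end without any
video data or trained model.

## Worked example

Generate a synthetic 40-patient, 7-session cohort, fit λ, score BDD and
report:

```sh
bddkit simulate --patients 40 --sessions 7 --seed 7 --out-dir data
echo '{"in_dir": "data", "out_dir": "out"}' > config.json
bddkit pipeline --config config.json
bddkit report --scales data/scales.csv --bdd out/bdd.csv --out reports.json --text
```

The cohort was generated with λ* = 0.94; the fit recovers

```
best_lambda = 0.95  best mean similarity = 0.965  n = 280
```

i.e. a 96.5 % mean Pearson similarity between BDD and the three scales at
the fitted λ, and the per-patient report shows BDD falling together with
the clinical scales over treatment:

```
patient p001 (7 sessions)
  SDS    68.1 ->   36.8  decrease  46.0%   [moderate to severe depression -> no depression]
  SAS    60.7 ->   34.3  decrease  43.5%   [moderate to severe anxiety -> no anxiety]
  HAMD   38.1 ->   10.2  decrease  73.2%   [severe depression -> mild depression]
  BDD   0.825 ->  0.173  decrease  79.0%
```

Each line gives the baseline → end scale total, the percent decrease
(positive = improvement), and the severity bands the totals fall in.

The same stages are available individually (`extract`, `features`,
`fit-lambda`, `score`, `report`), and everything is importable as a
library:

```python
import bddkit as bk

cohort = bk.generate_cohort(bk.CohortSpec(seed=7))
fit = bk.fit_lambda(cohort.features_list(), cohort.scale_records())
print(fit.best_lambda, fit.best_mean_similarity)
```

## Documentation

See `docs/methods.md` for the model assumptions, the synthetic generator's
construction and calibration, numerical conventions and known limitations.
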