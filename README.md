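# phenotree

Phenomapping of broad-QRS electrocardiograms: an unsupervised pipeline
that learns a compact latent representation of ECG median beats, embeds a
cohort as a low-dimensional **tree** whose branches are data-driven
*phenogroups* of abnormal ventricular depolarization, projects external
cohorts onto the frozen tree, and quantifies how position on the tree
relates to prevalent disease, incident disease (with death as a competing
risk) and response to cardiac resynchronization therapy (CRT).

It is written for cardiac electrophysiology and biostatistics researchers
who want to run, extend, or stress-test this kind of analysis without
access to protected clinical ECG datasets: a synthetic-cohort generator
produces 8-lead median beats and 10 s rhythm strips at 400 Hz with the
classic LBBB / RBBB / NSIVCD morphology signatures, together with linked
survival, prevalence and CRT-response outcomes whose generating
parameters are known — so every stage of the pipeline can be tested
against ground truth.

## The method

1. **Preprocessing** — bandpass 0.5–100 Hz, 60 Hz notch, resample to
   400 Hz (all zero-phase); R peaks detected on lead II; per-sample,
   per-lead median across beats gives one median beat on the 8
   informative leads (I, II, V1–V6). Records enter the broad-QRS cohort
   only if QRS duration > 120 ms and no pacing / CIED / complete-heart-
   block flag is set.
2. **Latent representation** — a convolutional variational autoencoder
   encodes each median beat as z ∈ R^51 (posterior mean). Implemented in
   numpy with seeded training, so results are bitwise reproducible.
3. **Tree embedding** — reversed graph embedding: alternating
   minimization of

   ‖X − WZ‖²_F + λ Σ_{(k,k')∈B} ‖y_k − y_k'‖² + γ Σ_i softmin_σ,k ‖z_i − y_k‖²

   over an orthonormal basis W (d×2), sample coordinates Z, K centroids
   Y, a spanning tree B (minimum spanning tree each iteration) and soft
   assignments R. Sub-branches are maximal paths between branch points;
   Ward clustering of sub-branch positions (adjacency-constrained) merges
   them into phenogroups (default 6); pseudotime is geodesic distance
   along the tree from its center.
4. **External projection** — gradient-boosted regressors map latent
   features to tree coordinates, predictions are snapped to the nearest
   point on any tree edge, and phenogroups are assigned by k-NN among
   reference samples (k chosen by 10-fold CV over 1–200). The tree is
   never refit.
5. **Outcome models** — logistic / linear models for prevalent disease,
   Cox proportional hazards for fatal outcomes, Fine–Gray subdistribution
   hazards for nonfatal outcomes with death competing (IPCW risk-set
   expansion + weighted partial likelihood), per-sample risk surfaces on
   (dim1, dim2, pseudotime), global Moran's I for spatial autocorrelation
   on the tree, elastic-net explainability of phenogroups, bootstrapped
   Harrell C-index comparison of prognostic models, and Benjamini–
   Hochberg multiple-testing adjustment.
6. **CRT analysis** — response endpoints from pre/post-implant echo pairs
   (LVEF +10 points absolute; LVESD/LVESV −15% relative; missing pairs
   stay undefined), echo-to-ECG linkage within ±60 days, and logistic
   response models on tree position adjusted for age, sex and QRS
   duration (LBBB records by default).

## Worked example

```python
import warnings
import numpy as np
from phenotree.synthetic import generate_cohort
from phenotree.vae import VaeConfig, train_vae, encode
from phenotree.tree import (fit_ddrtree, assign_branches, merge_branches,
                            compute_pseudotime)
from phenotree.outcomes import fit_adjusted_model

warnings.filterwarnings("ignore")

# 1. synthetic broad-QRS cohort: 8-lead median beats + linked outcomes
beats, outcomes = generate_cohort(800, seed=1)
eligible = outcomes["eligible"].to_numpy()
print(f"cohort: {len(beats)} records, {eligible.sum()} broad-QRS eligible")

# 2. 51-dim latent representation of each median beat
vae = train_vae(np.stack([b.beats for b in beats]),
                VaeConfig(n_blocks=4, epochs=12, seed=1))
latents = encode(vae, [b for b, e in zip(beats, eligible) if e])

# 3. tree embedding, phenogroups, pseudotime
tree = fit_ddrtree(latents, n_centroids=60, seed=1)
tree = compute_pseudotime(merge_branches(assign_branches(tree), n_groups=6))
print(f"sub-branches: {tree.hyperparams['n_subbranches']}, "
      f"phenogroup sizes: {np.bincount(tree.phenogroup)[1:].tolist()}")

# 4. incident disease ~ phenogroup: Fine-Gray subdistribution hazards
#    (death competing), adjusted for age, sex and ECG measures
df = outcomes[eligible].reset_index(drop=True).copy()
df["phenogroup"] = tree.phenogroup
res = fit_adjusted_model(
    df, "incident_event", ["phenogroup"],
    ["age", "sex", "heart_rate", "qtc_ms", "qrs_ms"],
    kind="fine_gray", reference_phenogroup=int(df.phenogroup.mode()[0]))
for _, row in res.table.iterrows():
    if row["term"].startswith("phenogroup"):
        print(f"{row['term']}: SHR {row['exp_estimate']:.2f} "
              f"({row['ci_low']:.2f}-{row['ci_high']:.2f}), p={row['p']:.3f}")
```

which prints:

```
cohort: 800 records, 682 broad-QRS eligible
sub-branches: 9, phenogroup sizes: [71, 105, 34, 258, 103, 111]
phenogroup=1: SHR 0.89 (0.55-1.45), p=0.645
phenogroup=2: SHR 1.12 (0.75-1.67), p=0.570
phenogroup=3: SHR 0.73 (0.33-1.59), p=0.427
phenogroup=5: SHR 1.14 (0.70-1.84), p=0.595
phenogroup=6: SHR 0.97 (0.64-1.45), p=0.871
```

The 682 eligible records fall into 6 phenogroups (phenogroup 4, the
largest/most central, is the reference). Each subdistribution hazard
ratio (SHR) compares a phenogroup's incident-event risk against the
reference, accounting for the competing risk of death; on this small
synthetic cohort, whose event risk is driven by a continuous severity
latent rather than by group membership, none of the group contrasts is
individually significant — exactly what the generator implies.

The same analysis runs end-to-end from one config via the CLI:

```bash
phenotree run --config pipeline.yaml --seed 7
```

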