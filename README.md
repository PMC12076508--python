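# ohecc — chirality classification from raw Cartesian coordinates

`ohecc` is a Python toolkit for studying whether simple machine-learning
classifiers can read *stereochemistry* — the handedness of molecules — out of
nothing more than atom positions and atom types.  It is aimed at
computational chemists and ML practitioners who want a small, fully
reproducible test bed for chirality-aware molecular representations.

## The representation

A molecule with up to 27 atoms over the vocabulary {H, C, N, O, F} is encoded
as a **one-hot encoded Cartesian coordinate (OHECC)** matrix: row *i* is

```
( x_i, y_i, z_i, 1[el_i=H], 1[el_i=C], 1[el_i=N], 1[el_i=O], 1[el_i=F] )
```

zero-padded to 27 rows (27 × 8 = a flat 216-vector).  Because the raw
coordinates enter untouched, a molecule and its mirror image get *different*
feature vectors — unlike the classical **Coulomb matrix**

```
M_ii = 0.5 Z_i^2.4        M_ij = Z_i Z_j / |R_i − R_j|
```

which depends only on interatomic distances and is therefore identical for
the two enantiomers of a chiral molecule.  The package implements both, the
Coulomb matrix serving as the provably chirality-blind counterexample.

Around the representation sit:

* a geometric **R/S labeler** (`ohecc.stereo`): breadth-first sphere ranking
  of substituents plus the signed volume u₁·(u₂×u₃) of the priority-ordered
  neighbors (negative = R), cross-validated against RDKit's CIP perception;
* a seeded **generator of labeled chiral toy molecules**
  (`ohecc.synthetic`): 0–4 tetrahedral stereocenters with construction-known
  labels, exact enantiomer pairs, and a signed surrogate "optical rotation"
  α̃ = Σₖ sₖwₖ + ε whose sign is determined by the configuration;
* builders for six balanced, seeded **classification tasks**
  (`ohecc.datasets`): chiral-center existence, 0-vs-1 centers, (R)-vs-(S),
  rotation sign for one-center molecules, rotation sign for all molecules,
  and 0–4 center counting — plus a reader for OR-QM9-style NPZ archives;
* **model wrappers** (`ohecc.models`) for random forests, gradient-boosted
  trees and a 216→500→200→softmax feed-forward network, all seed-deterministic;
* **confusion matrices and metrics** (`ohecc.metrics`) in the
  predicted-rows-by-true-columns orientation with the first-listed class as
  the positive class;
* **distribution statistics** (`ohecc.stats`): z-filtered moment summaries,
  an extreme-rotation census, and the R/S-vs-sign Pearson correlation.

## Worked example

```python
import numpy as np
from ohecc import (GeneratorConfig, make_enantiomer_pair, encode_coulomb,
                   encode_ohecc)

cfg = GeneratorConfig(center_distribution={1: 1.0}, noise_sd=0.0)
a, b = make_enantiomer_pair(cfg, seed=1)
print("labels:", a.labels, "vs mirror:", b.labels)
d_cm = np.abs(encode_coulomb(a.molecule).values
              - encode_coulomb(b.molecule).values).max()
d_oh = np.abs(encode_ohecc(a.molecule).values
              - encode_ohecc(b.molecule).values).max()
print(f"max |Coulomb difference| = {d_cm:.2e};  max |OHECC difference| = {d_oh:.2f}")
```

```
labels: ['S'] vs mirror: ['R']
max |Coulomb difference| = 0.00e+00;  max |OHECC difference| = 3.72
```

The Coulomb matrices of the two mirror images agree to the last bit — no
classifier could ever separate them — while the OHECC matrices differ.
Training a random forest on the OHECC features of a noiseless single-center
rotation-sign task shows the sign is learnable from geometry alone:

```python
from ohecc import (make_dataset, records_from_dataset, TaskSpec, build_task,
                   ModelConfig, train, predict, confusion, metrics)
from ohecc.metrics import round_metrics

ds = make_dataset(GeneratorConfig(n_molecules=1500, noise_sd=0.0,
                                  center_distribution={1: 1.0}), seed=0)
data = build_task(records_from_dataset(ds),
                  TaskSpec(task="sign_one_center", per_class=600, seed=0))
model = train(data.X_train, data.y_train,
              ModelConfig("rf", {"n_estimators": 300, "max_depth": 50,
                                 "min_samples_leaf": 2, "max_features": "sqrt"},
                          seed=0))
cm = confusion(data.y_test, predict(model, data.X_test), data.classes)
print(cm.to_frame());  print(round_metrics(metrics(cm)))
```

```
true         -    +
predicted
-          120    2
+            0  118
{'accuracy': 0.992, 'precision': 0.984, 'recall': 1.0, 'f1': 0.992}
```

240 held-out molecules, 238 correctly signed.  Here precision is the
fraction of "−" predictions that are truly "−" (120/122) and recall the
fraction of true "−" molecules found (120/120); the positive class is always
the first-listed one.

The same pipeline is available from the shell:

```bash
ohecc simulate --n 1000 --centers mixed --seed 1 --out-dir out/sim
ohecc experiment --task zero_vs_one --model rf --n-per-class 500 --seed 1 \
      --out-dir out/exp
ohecc stats --labels-csv out/sim/labels.csv --out-dir out/stats
```

Every command writes a `manifest.json` (arguments, seed, library versions);
identical invocations produce byte-identical outputs.

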