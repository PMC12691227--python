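# wsiprog

Dual-branch survival modeling for whole-slide histopathology images (WSIs),
with a fully synthetic test bed.

## What problem this solves

Prognosis from a resection slide depends on two kinds of information that
live at different scales: the *architecture* of the lesion (how much
necrosis, where the fibrosis sits relative to the tumor) and the
*morphology of the cells* (nuclear staining, texture, pleomorphism). A
gigapixel WSI cannot be modeled directly, and patch-bag approaches discard
the spatial layout. `wsiprog` implements a structure-aware compression of
the slide in both directions and trains censored-survival models on each:

* **Macro branch** — the slide is tiled, every patch is labeled with one of
  eight tissue categories `z ∈ {0..7}`, and the label grid becomes an
  8-channel indicator map `M ∈ R^{H×W×8}` (channel `z` is 1 where the patch
  is category `z`). A CNN encoder maps `M` to a 2048-dim feature, a
  FC+BN+ReLU projection compresses it to a 32-dim embedding, and a linear
  head emits a macro risk score.
* **Micro branch** — slide-level category proportions
  `r_z = Σ 1(z_{ij}=z) / Σ 1` apportion a budget of `N = 27` patches
  (`n_z ≈ r_z·N`, largest-remainder rounding, shortfalls compensated from
  dominant categories); the sampled RGB tiles are stacked into a
  `27×3`-channel input and encoded the same way into a 32-dim embedding
  and a micro risk score.
* **Fused model** — both branch heads are dropped; the concatenated 64-dim
  embedding passes through an MLP to a patient-level risk score.

All models optimize the Cox negative log partial likelihood

```
L = − Σ_{i: δ_i=1} [ s_i − log Σ_{j: t_j ≥ t_i} exp(s_j) ]
```

(Breslow ties), and are evaluated with Harrell's C-index, the IPCW
integrated Brier score and the IPCW mean absolute error under stratified
5-fold cross-validation, with median-split Kaplan–Meier stratification and
log-rank testing. Interpretability tooling covers occlusion sensitivity
maps on the tissue map, slide-level structural parameters (N-ratio,
FIB-center, FIB-edge) with a multivariable proportional-hazards fit, and
nuclear morphometrics with Lasso ∩ Mann–Whitney feature selection.

Because clinical WSIs cannot ship with a package, a synthetic-cohort
generator produces label grids, textured tiles and proportional-hazards
survival outcomes with *known* ground truth, so every stage is testable
end to end. It is intended for method developers working on WSI survival
models who need a controlled, fully reproducible substrate.

## Worked example

```python
import numpy as np
from wsiprog.synthetic import SyntheticCohortConfig, generate_cohort
from wsiprog.tissue_map import build_tissue_map, resize_tissue_map, stack_maps
from wsiprog.models import MacroNet, EncoderSpec
from wsiprog.survival import TrainConfig, train_branch, stratify_km

cfg = SyntheticCohortConfig(n_patients=120, rng_seed=0, censoring_rate=0.0,
                            necrosis_beta=(2.0, 10.0),
                            hazard_coefficients={"n_ratio": 16.0})
cohort = generate_cohort(cfg)                      # grids + survival table
x = stack_maps([resize_tissue_map(build_tissue_map(g), (32, 32))
                for g in cohort.grids])            # (120, 8, 32, 32)
t = cohort.survival["time"].to_numpy()
d = cohort.survival["event"].to_numpy()

idx = np.random.default_rng(0).permutation(120)
net = MacroNet(EncoderSpec(backbone="tiny_test", in_channels=8), seed=0)
hist = train_branch(net, x, t, d,
                    TrainConfig(learning_rate=1e-2, max_epochs=30, seed=0),
                    train_idx=idx[40:], val_idx=idx[:40])
print(f"validation C-index: {hist['best_val_c_index']:.3f}")

strat = stratify_km(t, d, net.predict_risk(x))
print(f"log-rank chi2 = {strat['chi2']:.1f}, p = {strat['p_value']:.2e}")
```

Output:

```
validation C-index: 0.753
log-rank chi2 = 49.3, p = 2.22e-12
```

The cohort's hazard is driven by the necrosis fraction of each synthetic
slide, so a validation C-index far above 0.5 (the generator's oracle
C-index is ~0.75 here) means the macro branch has read the planted
architectural signal out of the tissue map, and the median risk split
separates survival sharply.

There is also a CLI for the same recipes:

```bash
wsiprog synth --n 40 --grid 64 --seed 7 --out cohort_dir/
wsiprog mtop  --grid cohort_dir/grids/patient_0000.tif --target 32 32 --out map.npz
wsiprog fst   --grid cohort_dir/grids/patient_0000.tif --n 27 --strategy category --seed 7 --out fst.npz
wsiprog run   --branch macro --n 60 --folds 3 --seed 7 --out run_dir/
```

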