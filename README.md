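# robustpet

Robust PET image reconstruction when the system model itself is uncertain.

Iterative PET reconstruction recovers a nonnegative activity map `x` from
coincidence counts `y ≈ D x`, where the system matrix `D` holds the
detection sensitivities.  Classical estimators — MLEM and penalized weighted
least squares (PWLS) — assume `D` is known exactly; real scanners never
satisfy that, and model error degrades the image.  `robustpet` implements an
**uncertainty-penalized weighted least squares (UPWLS)** reconstructor: a
min–max estimator that minimizes the worst-case weighted residual over
norm-bounded perturbations of both the system matrix and the data,

    min_x  max_{‖Δ‖≤φ}  xᵀQx + ‖(D + MfΔEf)x − (y + MfΔEg)‖²_W ,

solved in closed form through corrected penalty/weighting matrices
`Q̂ = Q + λEfᵀEf`, `Ŵ = W + WMf(λI − MfᵀWMf)†MfᵀW` with a regularization
scalar `λ ≥ ‖MfᵀWMf‖`, and iterated as a state-space (Kalman-style)
recursion for the static imaging case.  The package also provides the MLEM
and PWLS+CG baselines, a single-ray (intersection-length) parallel-beam
projector, an analytic Shepp-Logan phantom, a Poisson prompt/delayed scan
simulator with uniform randoms/scatter, controlled system-matrix
perturbation, and a Monte-Carlo bias/variance evaluation harness.

Intended users: image-reconstruction researchers who want a reproducible,
desk-scale testbed for estimators under system-model uncertainty.

## Worked example

Simulate one noisy scan, perturb the system matrix to a 6% mean relative
error, and reconstruct with all three methods:

```python
import numpy as np
import robustpet as rp
from robustpet.pwls import default_beta

geom = rp.ScanGeometry(grid_nx=32, grid_ny=32, n_angles=30, n_bins=47)
D = rp.build_system_matrix(geom)
truth = rp.shepp_logan_phantom(geom)

proto = rp.ScanProtocol(total_counts=20_000, n_realizations=1, seed=0)
prompt, delayed = rp.simulate_scan(truth, D, proto, realization=0)
y = rp.correct_sinogram(prompt, delayed, proto)
scale = y.meta["scale"]                      # activity -> expected counts

pert = rp.perturb_system_matrix(D, 0.06, seed=0)
D_noisy = rp.apply_perturbation(D, pert)     # reconstruct with the wrong D
print(f"measured matrix error: {rp.relative_error(D, D_noisy):.4f}")

truth_counts = rp.ActivityImage(geom, truth.values * scale)
em = rp.mlem_reconstruct(y, D_noisy, n_iter=200, x_true=truth_counts)

pen = rp.PenaltyModel(geom, beta=1.0)
w = 1.0 / np.maximum(prompt.values, 1.0)     # plug-in Poisson weights
pen.beta = default_beta(D_noisy, w, pen)
pw = rp.pwls_cg_reconstruct(y, D_noisy, w, pen, n_iter=200, x_true=truth_counts)

ssm = rp.StateSpaceModel(R=np.maximum(prompt.values, 1.0))
U = rp.make_norm_bounded_model(D_noisy, 0.06)  # assumed uncertainty budget
up = rp.upwls_reconstruct(y, D_noisy, rp.PenaltyModel(geom, beta=1.0), ssm, U,
                          stop=rp.ConvergenceConfig(epsilon=1e-4, max_iter=15),
                          x_true=truth_counts, x0_mode="fbp")

for name, res in (("MLEM", em), ("PWLS+CG", pw), ("UPWLS", up)):
    img = rp.ActivityImage(geom, res.image.values / scale)
    b, s = rp.bias_std(img, truth)
    print(f"{name:8s} error={rp.normalized_error(img, truth):.3f}"
          f"  bias={b:.3f}  std={s:.3f}")
```

Output:

```
measured matrix error: 0.0600
MLEM     error=0.673  bias=0.789  std=1.348
PWLS+CG  error=0.798  bias=1.066  std=1.524
UPWLS    error=0.666  bias=0.617  std=1.324
```

`error` is the relative L2 distance to the ground truth; `bias`/`std` are
the mean absolute and standard deviation of ground-truth-normalized pixel
residuals.  With a 6% matrix error the robust estimator gives the lowest
bias and spread of the three — it is the only one that budgets for the
model being wrong.

## Command line

A thin CLI wraps the library:

```sh
robustpet simulate --grid 64 --angles 60 --bins 95 --counts 100000 \
          --randoms 0.6 --scatter 0.2 --matrix-error 0.06 \
          --realizations 50 --seed 0 --out scan.h5
robustpet reconstruct --method upwls --input scan.h5 --realization 0 \
          --iters 15 --out recon.nii --trace trace.csv
robustpet evaluate --scan scan.h5 --methods em,pwls,upwls \
          --noise-levels 0,0.06,0.12 --realizations 20 --out table.csv
robustpet fixture --size tiny --seed 0 --out fixtures/
```

Scan containers are HDF5 (phantom, sparse `D`, perturbation, per-realization
sinograms, geometry/protocol metadata); images are 2-D NIfTI; traces and
evaluation tables are CSV.  YAML config files (see `robustpet.config`) can
preset any parameter; flags override.

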