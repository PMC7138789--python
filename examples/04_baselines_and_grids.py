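"""Compare reducers (none / PCA / random projection) and inspect grids.

PCA keeps the components explaining 99% of training variance; Gaussian
random projection targets the Johnson-Lindenstrauss dimension at
eps = 0.5. Both are fitted on training rows only.
"""

from microrep import (
    RunConfig,
    SyntheticSpec,
    enumerate_ae_grid,
    enumerate_classifier_grid,
    generate_synthetic,
    run_once,
)

for kind in ("SAE", "DAE", "VAE", "CAE"):
    print(f"{kind} architecture grid: {len(enumerate_ae_grid(kind, 10_000))} designs")
for algorithm in ("SVM", "RF", "MLP"):
    print(f"{algorithm} hyper-parameter grid: "
          f"{len(enumerate_classifier_grid(algorithm))} combinations")

profile, labels = generate_synthetic(
    SyntheticSpec(n_samples=200, n_features=500, latent_dim=8,
                  effect_size=3.0, kind="marker", seed=3)
)
for reducer in ("none", "PCA", "RP"):
    result = run_once(profile, labels,
                      RunConfig(reducer=reducer, classifier="SVM"), seed=0)
    print(f"reducer={reducer:4s}  test AUC {result.auc:.3f}  "
          f"(chosen: {result.best_spec.to_text()})")
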