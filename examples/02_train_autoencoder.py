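"""Train a shallow autoencoder and inspect its latent representation.

The encoder maps 1000-dimensional binary marker profiles to 32 latent
dimensions by minimizing reconstruction MSE with Adam; training stops
once validation loss has not improved for 20 epochs and the best
epoch's weights are restored.
"""

from microrep import AEArchitecture, SyntheticSpec, generate_synthetic, train_autoencoder

profile, labels = generate_synthetic(
    SyntheticSpec(n_samples=200, n_features=1000, latent_dim=8,
                  effect_size=3.0, kind="marker", seed=1)
)
x = profile.values

arch = AEArchitecture("SAE", input_dim=1000, latent_dim=32)
encoder = train_autoencoder(arch, x[:140], x[140:180], seed=0)

log = encoder.training_log
print(f"architecture: {arch.describe()}")
print(f"trained for {log.n_epochs} epochs; best validation loss "
      f"{log.val_loss[encoder.best_epoch]:.5f} at epoch {encoder.best_epoch}")

z = encoder.transform(x)
print(f"latent matrix: {z.shape[0]} x {z.shape[1]} "
      "(each row is the low-dimensional embedding of one sample)")
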