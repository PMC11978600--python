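"""Clean the cognitive battery and compress it with the autoencoder.

Cleaning applies, in order: the per-visit coverage filter (>= 75 participants),
the constancy filter (5th-95th percentile band all equal), the 5x IQR outlier
filter, and removal of participants left with no data. The surviving battery
is z-scored and reduced to a latent vector per visit (65% of the input width).
"""

from cogtraj import autoencode, generate_cohort, preprocess
from cogtraj.cohort import CohortConfig

cohort = generate_cohort(CohortConfig(seed=1))
clean, report = preprocess.preprocess_cognitive(cohort.cognitive)
print(f"rows {report.n_rows_before} -> {report.n_rows_after}; "
      f"removed variables: {report.variables_removed or 'none'}; "
      f"removed values: {report.values_removed}")

Z, params, meta = autoencode.standardize_features(clean)
spec = autoencode.AutoencoderSpec(input_dim=Z.shape[1], latent_fraction=0.65, seed=0)
model = autoencode.train_autoencoder(Z, spec)
latent = autoencode.encode_table(model, Z, meta)

print(f"latent dimension: {spec.latent_dim} (from {Z.shape[1]} scores)")
print(f"masked reconstruction MSE: {model.final_loss:.4f} "
      "(fraction of unit input variance left unexplained)")
print(latent.iloc[:3, :6].to_string(index=False))
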