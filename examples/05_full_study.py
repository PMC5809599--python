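"""End-to-end three-population study on synthetic data.

Reproduces the study design: three populations of axial profiles (China
n=19, Siberia n=18, USA n=16) with population-specific furrow-depth and
sharpness regimes, automatic landmarking (effaced specimens are flagged and
skipped), and the full statistical battery, written to results/ with a
reproducibility manifest.
"""

import json

from trilomorph import RunConfig, run_pipeline

config = RunConfig(out_dir="scratch/example_study", seed=42,
                   n_permutations=999)
manifest = run_pipeline(config)

lm = manifest["stages"]["landmarks"]
print(f"landmarked {lm['n_landmarked']} of 53 specimens; "
      f"effaced (insufficient relief): {len(lm['effaced'])}")
print(f"artifacts written: {len(manifest['artifacts'])}")
print("\nkey outputs under scratch/example_study/:")
for name in ("relief_by_population.csv", "pca_variance.csv",
             "goodall_tests.csv", "cva_mahalanobis.csv", "manifest.json"):
    print(f"  {name}")

with open("scratch/example_study/goodall_tests.csv") as fh:
    print("\ngoodall_tests.csv:")
    print(fh.read())
print("Low p-values here reflect the planted between-population differences")
print("in furrow depth and sharpness; the manifest's checksums make the run")
print("bit-reproducible for a fixed seed.")
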