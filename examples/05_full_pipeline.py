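"""Run the whole analysis end to end and write the report bundle.

simulate -> validate -> derive pCO2 -> effect sizes -> per-bin and
subgroup meta-analyses -> sensitivity -> Ca-Mg regressions, all into one
output directory of plot-ready CSVs plus a JSON manifest.
"""

from pathlib import Path

import pandas as pd

from oa_crust_meta import (
    RunConfig, SyntheticConfig, generate_dataset, run_full_analysis,
    write_extraction_table,
)

workdir = Path("scratch/example_run")
workdir.mkdir(parents=True, exist_ok=True)
csv_path = workdir / "extraction.csv"
write_extraction_table(generate_dataset(SyntheticConfig(rng_seed=1)), csv_path)

written = run_full_analysis(RunConfig(
    input_path=str(csv_path),
    output_dir=str(workdir / "bundle"),
    exclude_articles_sensitivity=("art_1500-1999_000",),
))
print("bundle files:")
for name in sorted(written):
    print(f"  {name:20s} {written[name]}")

print("\ncalcium bin summaries:")
print(pd.read_csv(written["bins_calcium"])[
    ["pco2_bin", "k", "mu_hat", "ci_low", "ci_high", "tau2", "Q", "significant"]
].to_string(index=False))

# Every number in the bundle is reproducible by calling the module
# functions directly with the manifest's configuration; rerunning with the
# same seed reproduces the bundle bit for bit.
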