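"""Generate a study-shaped synthetic dataset and run the analysis stages.

Builds the default 48-sample, 24-locus dataset (wild group neutral at
theta=0.01/site; domesticated groups bottlenecked at their configured
intensities), then prints the per-locus polymorphism table and the AMOVA
summary.
"""

import tempfile
from pathlib import Path

from flaxpopgen import pipeline
from flaxpopgen.synthetic_data import StudyConfig, generate_study

dataset = generate_study(StudyConfig(seed=42))
out = Path(tempfile.mkdtemp(prefix="flaxpopgen_"))

results = pipeline.run_pipeline(
    dataset, out, stages=("stats", "amova"), seed=42, n_perm=1000
)

stats = results["stats"]
print(stats[["locus_id", "n", "L", "S", "Nh", "pi"]].tail(5).to_string(index=False))
amova = results["amova"]["overall"]
print(
    f"\nAMOVA over the 5 panel groups: {amova.pct_among:.1f}% of variation "
    f"among groups (phi_st={amova.phi_st:.3f}, p={amova.p_perm:.4g})"
)
print(f"reports written under {out}")
print(
    "The Total row mirrors the survey's concatenated summary; the AMOVA\n"
    "percentage is the share of molecular variance separating the groups."
)
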