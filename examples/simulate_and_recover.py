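"""Full pipeline on synthetic data: can the planted drivers be found again?

Generates a 14-condition, 200-feature-per-layer dual-omics dataset in
which eight proteins jointly set the growth rate, runs the whole
analysis (growth-curve fitting, layer matching, standardization,
three-regressor benchmark, ANN permutation importance, cross-layer
combination, reduced-panel retraining), and reports how many of the
planted drivers appear in the combined top-20.
"""

import logging
import tempfile

from omigrow import RunConfig, SimulateSpec, run_pipeline

logging.basicConfig(level=logging.ERROR)
logging.getLogger("omigrow").setLevel(logging.ERROR)

outdir = tempfile.mkdtemp(prefix="omigrow_run_")
config = RunConfig(
    outdir=outdir,
    seed=7,
    k=20,
    n_repeats=30,
    simulate=SimulateSpec(n_conditions=14, n_features=200, n_planted=8),
)
report = run_pipeline(config)

print("Benchmark (in-sample, training on the full dataset):")
print(report.benchmark.round(6).to_string(index=False))
print()
print(f"Combined cross-layer top-20: {report.top_features['combined'][:10]} ...")
print(f"Planted drivers:             {sorted(report.truth.planted_features)}")
print(f"Recovery of planted truth by combined top-20: {report.recovery:.3f}")
print()
print("Reduced-panel comparison (panel = combined top-8):")
print(report.reduced.round(4).to_string(index=False))
print()
print(
    "Reading the numbers: accuracy is 100*(1 - mean relative error) of the\n"
    "in-sample growth-rate predictions; recovery is the fraction of the 8\n"
    "planted drivers present in the combined top-20. A recovery well above\n"
    "the ~0.10 chance level shows the selection tracks real signal, while a\n"
    "value below 1.0 shows how diffusely an overparameterized network\n"
    "spreads its reliance across correlated features."
)
print(f"\nAll tables were written to {outdir}")
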