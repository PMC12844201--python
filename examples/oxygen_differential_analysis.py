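"""Aerobic vs anaerobic differential abundance and CV ranking.

Generates proteomics data in which six background proteins carry a
planted between-oxygen abundance shift, tests every protein with
Welch's t-test under Benjamini-Hochberg FDR control, and ranks the
significant ones by coefficient of variation — most variable first.
"""

from omigrow import diff_abundance, generate_design, generate_omics

design = generate_design(14, seed=4)
_, prot, _, truth = generate_omics(
    design, n_features=80, n_planted=4,
    oxygen_shift=400.0, n_oxygen_shifted=6, noise_sd=0.0, seed=4,
)

res = diff_abundance(prot, design, alpha=0.05)
hits = res[res.significant].sort_values("cv_rank")
print(f"{int(res.significant.sum())} of {len(res)} proteins significant at FDR 0.05")
print(f"planted oxygen-shifted proteins: {sorted(truth.oxygen_shifted_features)}")
print()
cols = ["mean_aerobic", "mean_anaerobic", "t_stat", "q_value", "cv", "cv_rank"]
print(hits[cols].round(4).to_string())
print(
    "\nEvery flagged protein is one of the planted oxygen-responders. cv is\n"
    "the sample sd over mean across all 14 conditions: cv_rank 1 marks the\n"
    "protein whose abundance swings hardest between oxygen regimes, while\n"
    "the highest consistency_rank (not shown) marks the most stable one."
)
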