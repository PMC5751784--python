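"""How much does mis-judged PCR efficiency hurt the caller?

The coverage estimate assumes perfect amplification. If the real
per-cycle efficiency was lower, the fragment population was smaller and
the true coverage higher than assumed. This study generates data at the
true coverage, re-runs the caller under each efficiency assumption, and
compares ROC AUCs over the standard cut-off sweep.
"""

import warnings

from cornas import run_pcr_efficiency_study

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)  # >1 coverage cells skip
    summary, _ = run_pcr_efficiency_study(
        expected_coverages=(0.5, 0.25, 0.1, 0.01),
        efficiencies=(1.0, 0.95, 0.90, 0.85, 0.80),
        population_N=3_000_000,
        iterations=50,
        seed=7,
    )

print(summary.round(4).to_string(index=False))

base = summary[summary.efficiency == 1.0].set_index("expected_coverage")["auc"]
worst = (
    summary[~summary.skipped]
    .assign(rel=lambda d: abs(d.auc - d.expected_coverage.map(base)) / d.expected_coverage.map(base))
    ["rel"].max()
)
print(f"\nworst relative AUC change vs perfect efficiency: {worst:.1%}")

# Cells where the assumed coverage would reach 1 (e.g. expected coverage
# 0.5 at 80% efficiency) are skipped: the method is not recommended
# there. Elsewhere the AUC moves by only a few percent — the caller is
# robust to moderate over-estimation of the fragment population.
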