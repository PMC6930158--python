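"""Exhaustive mean-expression signature search over candidate genes.

Every gene subset (size >= 2) is scored as the per-sample mean of its
members' log2 expression and ranked by responder AUC — the same
construction as the published combination table.
"""
import dataclasses

from immunoscreen import (
    combination_table,
    derive_responder_labels,
    enumerate_combinations,
    reference_scenarios,
    simulate_cohort,
)

config = dataclasses.replace(reference_scenarios()["combo-recovery"], seed=1)
expr, clin = simulate_cohort(config)
labels = derive_responder_labels(clin.survival())

records = enumerate_combinations(list(expr.genes), expr, labels, mode="exhaustive")
print(f"evaluated {len(records)} gene-set combinations "
      f"({expr.n_genes} genes, sizes 2-{expr.n_genes})")
print(combination_table(records).head(8).to_string(index=False))
print(f"\nplanted signature: {'+'.join(sorted(config.planted_signature))}")
# Nested sets share most of their genes, so AUCs near the top differ by well
# under their sampling error: many near-equivalent signatures is the expected
# outcome, not a failure of the search.
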