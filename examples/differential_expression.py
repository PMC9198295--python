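"""Moderated-t differential expression on a synthetic two-arm cohort.

Generates a 1000-gene cohort (6 normal vs 10 tumor samples) with 25 genes
planted up and 25 down at |log2 fold change| = 3, runs the empirical-Bayes
moderated t-test, and filters DEGs at |logFC| >= 2 and FDR < 0.05.
"""

import blcanet as b

spec = b.SyntheticExpressionSpec(
    n_genes=1000, n_control=6, n_treatment=10, n_de_up=25, n_de_down=25, seed=7
)
matrix, labels, truth = b.generate_expression(spec)

det = b.moderated_t_table(matrix, labels)
degs = b.filter_degs(det)

planted = set(truth.index[truth != "none"])
found = {g for g, _ in degs}
print(f"genes tested: {len(det)}")
print(f"DEGs at |logFC|>=2, FDR<0.05: {len(degs)} "
      f"({sum(1 for _, d in degs if d == 'up')} up, "
      f"{sum(1 for _, d in degs if d == 'down')} down)")
print(f"planted genes recovered: {len(found & planted)}/{len(planted)}; "
      f"false discoveries: {len(found - planted)}")
print("\ntop 5 by |moderated t|:")
print(det.loc[[g for g, _ in degs[:5]]].round(3))
# The moderated t shrinks per-gene variances toward a common prior, which
# stabilizes the ranking at these small arm sizes; with a planted effect of
# 3 log2 units nearly all 50 planted genes should be recovered with no
# false discoveries.
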