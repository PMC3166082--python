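"""Descriptor-combination selection by bootstrap-scored beam search.

Runs the feature-weighting union, redundancy pruning and beam search on the
default synthetic panel (scaled scoring for speed) and prints the winning
combination per size -- the analysis that identifies which descriptor axes
jointly predict functional inhibition.
"""

from fiasma import GeneratorConfig, beam_search, candidate_pool, generate_experimental_set

exp = generate_experimental_set(GeneratorConfig(seed=1))
matrix, labels = exp.labeled_matrix()
pool = candidate_pool(matrix, labels, top_q=8)
print("candidate pool after weighting union + redundancy pruning:")
print("  ", ", ".join(pool))

results = beam_search(
    matrix, labels, pool, beam_width=4, max_size=4, seed=1,
    score_resamples=30, final_resamples=200, refine_top=4,
)
print()
print("best combination per size (200-fold bootstrap Youden, mean +/- SD):")
for size, res in results.items():
    rep = res.report
    print(f"  n={size}: {', '.join(res.combination)}")
    print(f"        J = {rep.youden_mean:.3f} +/- {rep.youden_sd:.3f}, "
          f"accuracy = {rep.accuracy_mean:.3f} +/- {rep.accuracy_sd:.3f}")
print()
print("Performance rises with combination size and plateaus once the four")
print("mechanistic axes (lipophilicity, summed basic pKa, most-acidic pKa,")
print("size-intensive polar surface) are all present.")
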