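"""Score similarity between rank lists and rank perturbations against a query.

Builds a disease-like rank list plus three perturbation lists — one sharing
the disease's top/bottom probes, one unrelated, one inverted — computes the
bidirectional GSEA distance matrix and ranks the perturbations.
"""

import numpy as np

from sigmatch import ProbeRankList, distance_matrix, prl_distance, rank_perturbations

rng = np.random.default_rng(0)
probes = np.array([f"P{i:03d}" for i in range(200)])

disease = ProbeRankList(rng.permutation(probes))
# "similar": keeps the disease's 60 most up- and downregulated probes inside
# the same extreme windows (shuffled within), shuffles the middle
similar = ProbeRankList(
    np.concatenate(
        [
            rng.permutation(disease.ordering[:60]),
            rng.permutation(disease.ordering[60:-60]),
            rng.permutation(disease.ordering[-60:]),
        ]
    )
)
unrelated = ProbeRankList(rng.permutation(probes))
inverted = disease.reverse()

prls = {"disease": disease, "similar": similar, "unrelated": unrelated, "inverted": inverted}
dm = distance_matrix(prls, n=30)

print("pairwise distances (0 = identical regulation, 2 = opposite):")
print(dm.to_frame().round(3))

print("\nperturbations ranked by distance to the disease profile:")
print(rank_perturbations(dm, "disease").round(3).to_string(index=False))

print(f"\nself distance: {prl_distance(disease, disease, 30):.3f}")
print(f"inverted distance: {prl_distance(disease, inverted, 30):.3f}")
# A shared signature pulls the distance well below 1 (the expectation for
# unrelated lists); inversion pushes it toward the maximum of 2.
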