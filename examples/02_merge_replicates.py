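"""Merge replicate rank lists into one consensus list.

Three noisy replicate orderings of eight probes are combined by hierarchical
majority voting: the two closest lists (Spearman footrule) merge first via
Borda mean ranks, then the result absorbs the remaining list.
"""

from sigmatch import ProbeRankList, footrule_distance, merge_condition_prls

replicates = [
    ProbeRankList(["P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8"]),
    ProbeRankList(["P2", "P1", "P3", "P4", "P5", "P6", "P8", "P7"]),
    ProbeRankList(["P8", "P7", "P5", "P6", "P3", "P4", "P1", "P2"]),
]

for i, a in enumerate(replicates):
    for j, b in enumerate(replicates[i + 1 :], start=i + 1):
        print(f"footrule(replicate {i}, replicate {j}) = {footrule_distance(a, b):.0f}")

consensus, trace = merge_condition_prls(replicates)
print("consensus order:", " ".join(consensus.ordering))
for step in trace.steps:
    print(f"merged members {step.left} + {step.right} at footrule {step.distance:.0f}")

# The two near-identical replicates merge first (small footrule distance);
# the discordant third list joins last, so it cannot dominate the consensus.
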