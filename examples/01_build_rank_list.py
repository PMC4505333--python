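"""Build a probe rank list from one experiment/control pair.

Constructs a tiny four-probe intensity pair, applies the lower-quartile
threshold-and-sort procedure and prints the resulting ranking alongside the
thresholds used.
"""

from sigmatch import build_prl, primary_threshold

control = [10.0, 2.0, 50.0, 8.0]
experiment = [5.0, 2.0, 100.0, 1.0]
probes = ["P1", "P2", "P3", "P4"]

thr = primary_threshold(experiment, control)
print(f"primary threshold (pooled lower quartile): {thr.primary}")
print(f"secondary threshold (primary / 10):        {thr.secondary}")

prl = build_prl(experiment, control, probes)
for rank, probe in enumerate(prl.ordering, start=1):
    print(f"rank {rank}: {probe}")

# Rank 1 is the most upregulated probe (largest clamped experiment/control
# ratio); clamping at the lower quartile keeps probes with tiny intensities
# from dominating the list through unstable fold changes.
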