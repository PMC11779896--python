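"""Temporal binning of dated archaeobotanical contexts.

Shows the midpoint rule, the wide-interval exclusion, and per-bin mean
crop percentages on a handful of hand-made contexts.
"""

from buffercrops import (
    ArchContext,
    BinSpec,
    aggregate_bins,
    assign_bin,
    crop_trajectory,
    midpoint,
)

# a radiocarbon-dated buckwheat grain: interval 1286-1387 AD
grain = ArchContext("Vilnius_Arsenalo5", "FTMC-DW62-1", 1286, 1387,
                    {"buckwheat": 1.0})
spec = BinSpec()  # [100,1800) in 100-year bins, exclude spans > 200 years
print(f"midpoint {midpoint(grain)} -> bin starting {assign_bin(grain, spec)}")

contexts = [
    grain,
    ArchContext("SiteA", "c1", 1300, 1400, {"rye": 30, "oat": 10}),
    ArchContext("SiteA", "c2", 1320, 1360, {"rye": 5, "millet": 5}),
    ArchContext("SiteB", "c3", 1100, 1600, {"rye": 8}),   # span 500 -> excluded
    ArchContext("SiteC", "c4", 1450, 1500, {"hemp": 2, "rye": 2}),
]
series = aggregate_bins(contexts, spec)
for b in series.bins:
    shares = ", ".join(f"{c}={v:.1f}%" for c, v in b.mean_percent.items() if v > 0)
    print(f"bin {b.bin_start}-{b.bin_start + 100}: n={b.n_contexts}  {shares}")

print("rye trajectory:", crop_trajectory(series, "rye"))

# each context is first converted to a five-crop percentage composition;
# the bin value is the unweighted mean of those compositions ("mean
# presence").  The 1100-1600 context is dropped: its 500-year dating span
# cannot be trusted to a single 100-year bin.
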