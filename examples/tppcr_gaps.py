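"""Predict TP-PCR ladder gaps for interrupted alleles.

Simulates 3' triplet-primed PCR traces for the three expanded alleles of an
interrupted family and for the 37-unit hexamer allele, printing the gap
intervals the interruptions punch into the peak ladder.
"""

from repeatlens import parse_pattern
from repeatlens.tppcr import interruption_clusters, simulate_trace

ALLELES = {
    "E1 (pure)": ("(CTG)n", 440),
    "E2.1 (2x CCG)": ("(CTG)n(CCGCTG)(CTG)7(CCGCTG)(CTG)11", 350),
    "E3 (6x CCG)": (
        "(CTG)n(CCGCTG)2(CTG)3(CCGCTG)2(CTG)5(CCGCTG)(CTG)7(CCGCTG)(CTG)11",
        140,
    ),
    "G3.1 (hexamer)": ("(CTG)6(CCGCTG)13(CTG)5", None),
}

for name, (text, n) in ALLELES.items():
    pattern = parse_pattern(text, n_value=n)
    trace = simulate_trace(pattern)
    clusters = interruption_clusters(pattern, orientation="three_prime")
    gaps = ", ".join(f"units {a}-{b}" for a, b in trace.gaps) or "none"
    print(f"{name:>15}: {len(trace.peaks):3d} peaks, gaps: {gaps}")
    print(f"{'':>15}  interruption clusters (3'-anchored): {clusters}")

# A pure repeat yields a contiguous ladder (no gaps).  Each gap corresponds
# to one cluster of interruptions near the assayed 3' end: the parent-child
# pair shows two vs three gaps (the extra 3' interruptions arose de novo),
# and the hexamer allele collapses the ladder into one large gap.
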