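"""Call the DM1-locus haplotype from a seven-marker genotype panel.

Builds the homozygous marker panel of an individual carrying the
hexamer-interrupted 37-unit allele and calls it against the haplotype-A
reference, then shows how a single mismatching marker flips the call.
"""

from repeatlens import call_haplotype
from repeatlens.haplotype import genotypes_from_mapping

g22 = {
    "RS2070736": ("T", "T"),
    "RS572634": ("T", "T"),
    "RS1799894": ("T", "T"),
    "RS4646995": ("Ins", "Ins"),  # the Alu element insertion
    "RS16939": ("G", "G"),
    "RS527221": ("C", "C"),
    "RS915915": ("T", "T"),
}

call = call_haplotype(genotypes_from_mapping(g22))
print(f"G2.2 panel      : {call.label} ({call.matched_markers}/7 markers match)")

flipped = dict(g22, RS4646995=("Del", "Del"))
call = call_haplotype(genotypes_from_mapping(flipped))
print(f"Alu deletion    : {call.label} ({call.matched_markers}/7 markers match)")

partial = {k: v for k, v in g22.items() if k != "RS915915"}
call = call_haplotype(genotypes_from_mapping(partial))
print(f"missing marker  : {call.label} (missing: {', '.join(call.missing_markers)})")

# "A" means every marker carries at least one haplotype-A allele — the
# combination shared by most European DM1 expansions, here linking the
# interrupted intermediate allele to the same chromosomal background.
# Calls are unphased: heterozygous compatibility suffices.
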