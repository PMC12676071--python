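"""Integer encoding of genotype calls used throughout the package.

Haploid gamete calls are one of the two parental array alleles or missing;
diploid sporophyte calls may additionally be heterozygous.
"""

ALLELE_A = 0
ALLELE_B = 1
HET = 2
MISSING = -1

#: default token alphabet for delimited genotype tables
DEFAULT_ALPHABET = {"A": ALLELE_A, "B": ALLELE_B, "AB": HET, "NA": MISSING}

#: origin codes for haplotype-of-origin tracks (A/B parental haplotype)
ORIGIN_A = 0
ORIGIN_B = 1
ORIGIN_MISSING = -1
ORIGIN_TOKENS = {ORIGIN_A: "A", ORIGIN_B: "B", ORIGIN_MISSING: "."}
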