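"""Design CAPS markers from SNPs that create or destroy restriction sites.

Takes a SNP with its flanking sequence, screens the packaged enzyme
catalogue for recognition sites present in exactly one allele, and
prints the predicted digestion fragment patterns per genotype class —
what the bands of the three genotypes would look like on a gel.
"""

from nilscan import differential_digest, load_enzymes

enzymes = load_enzymes()
print(f"catalogue: {len(enzymes)} enzymes, e.g. "
      + ", ".join(e.name for e in enzymes[:6]) + ", ...")

# a G>A SNP whose reference allele completes an EcoRI site (GAATTC)
flank = ("ACGTACCGTTAGGCATCCTGAACCGTTACGGATTTACCGGTAT"
         "GAATTC"
         "GGTTACCAGGTTAACCGGTTAACCGGATCCTTGGAACCGTAAT")
snp_offset = 43  # the G of GAATTC
assert flank[snp_offset] == "G"

candidates = differential_digest(
    flank, snp_offset, ref_allele="G", alt_allele="A",
    enzymes=enzymes, chrom="chr6", pos=24_120_345, amplicon_halfwidth=40,
)

for c in candidates:
    print(f"\n{c.enzyme.name} ({c.enzyme.recognition}) — site on the "
          f"{c.allele_with_site} allele")
    print(f"  hh (donor homozygote):     {c.fragments_alt} bp")
    print(f"  ll (recurrent homozygote): {c.fragments_ref} bp")
    print(f"  hl (heterozygote):         {c.fragments_het} bp")
print()
print("Fragment sizes per allele always sum to the amplicon length; the")
print("heterozygote shows the union of both allele patterns, so all three")
print("genotype classes are distinguishable on a gel (a codominant marker).")
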