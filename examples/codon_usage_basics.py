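"""RSCU, relative adaptiveness and CAI on a toy gene set.

Builds a handful of in-frame coding sequences with contrasting codon usage
in the Lys (AAA/AAG) and Gln (CAA/CAG) families, derives an RSCU profile
from the biased genes, and scores every gene's codon adaptation index
against it.
"""

from codonsel import compute_cai, compute_rscu, count_codons, pool_counts

# two "highly expressed" genes using AAA and CAG heavily, two balanced ones
genes = {
    "rpl_like_1": "AAA" * 70 + "AAG" * 10 + "CAG" * 15 + "CAA" * 5,
    "rpl_like_2": "AAA" * 65 + "AAG" * 15 + "CAG" * 18 + "CAA" * 2,
    "average_1": "AAA" * 40 + "AAG" * 40 + "CAG" * 10 + "CAA" * 10,
    "average_2": "AAA" * 20 + "AAG" * 60 + "CAG" * 5 + "CAA" * 15,
}
counts = {g: count_codons(seq, g) for g, seq in genes.items()}

reference = compute_rscu(
    pool_counts([counts["rpl_like_1"], counts["rpl_like_2"]]),
    source="highly_expressed",
)
print("reference RSCU (highly expressed genes):")
for codon in ("AAA", "AAG", "CAA", "CAG"):
    print(f"  {codon}: RSCU = {reference.rscu[codon]:.3f}, "
          f"w = {reference.w[codon]:.3f}")

print("\nper-gene CAI against that reference:")
for g, cc in counts.items():
    print(f"  {g}: CAI = {compute_cai(cc, reference).cai:.3f}")

print("\nAn RSCU above 1 marks a codon used more than expected under equal "
      "synonymous use; CAI near 1 means a gene uses the reference set's "
      "preferred codons almost exclusively.")
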