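"""Sequencing-error misassignment in an uneven doped pool.

A read of one sequence can be misassigned to a Hamming-1 neighbor.  In a
doped pool the wild-type outweighs each single mutant ~30:1, so even a 1%
per-base error rate sends a noticeable stream of wild-type reads into every
single mutant's count.  Print the expected observed/true abundance ratio
and the spurious-read fraction per mutant order at two error rates:
ordinary single-read accuracy (1%) and the compounded accuracy of strictly
overlapped paired-end joining (0.01%).
"""

from kseqtools import DopedPoolDesign, ErrorModel, error_table

design = DopedPoolDesign(length=21, eta=0.09, n_families=4)

for xi in (0.01, 0.0001):
    df = error_table(ErrorModel(xi), design, max_order=4)
    print(f"per-base error rate xi = {xi:g}")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print()

print(
    "At xi = 1%, more than 10% of a single mutant's reads are really its\n"
    "neighbors' reads (spurious fraction > 0.10) — a systematic bias that\n"
    "replicates cannot fix.  At xi = 0.01% the worst contamination through\n"
    "quadruple mutants is below 0.5%."
)
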