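"""Validating the swap sampler against exhaustive enumeration.

For margins small enough, every binary matrix with the given row and
column totals can be listed outright; the swap chain must then visit them
uniformly. This is the package's internal correctness oracle, exposed so
users can re-verify it for margin families of their choice.
"""

from nullcooc import enumerate_fixed_margin_matrices, exact_null_distribution
from nullcooc.calibration import compare_sampler_to_oracle

rows, cols = (3, 2, 2, 1), (2, 2, 2, 1, 1)
mats = enumerate_fixed_margin_matrices(rows, cols)
print(f"margins {rows} x {cols}: {len(mats)} distinct matrices")

dist = exact_null_distribution((rows, cols))
print("exact C-score distribution under the uniform fixed-margin law:")
for value, prob in sorted(dist.items()):
    print(f"  C = {value:5.2f}   P = {prob:.4f}")

cmp = compare_sampler_to_oracle(rows, cols, n_samples=20_000, seed=0)
print(f"\nswap sampler vs oracle at {cmp.n_samples} samples: "
      f"total-variation distance = {cmp.total_variation:.4f}, "
      f"chi-square GOF p = {cmp.chi2_p_value:.3f}")
print("TV near 0 and a non-significant GOF mean the chain samples the"
      "\nfixed-margin family uniformly, as the permutation test assumes.")
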