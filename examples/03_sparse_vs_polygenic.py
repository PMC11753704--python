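"""Use E(k) to distinguish sparse from polygenic regional architectures.

Simulates regions with 3 vs 50 causal variants at the same total
heritability and shows that the posterior expected number of causal
variants separates the two regimes.
"""

import numpy as np

from regfine import fine_map_region, simulate_sparse_region

for m_causal in (3, 50):
    ek = []
    for rep in range(5):
        region, _ = simulate_sparse_region(
            m=200, n=300_000, h2=0.05, m_causal=m_causal,
            seed=1000 * m_causal + rep)
        res = fine_map_region(region, max_causal=10, seed=rep, draws=1000,
                              compute_summaries=False)
        ek.append(res.expected_k)
    label = "sparse (3 causal)" if m_causal == 3 else "polygenic (50 causal)"
    print(f"{label:>22}: E(k) = {np.round(ek, 2).tolist()}")

print("\nWith ample sample size, E(k) stays near the true count for sparse "
      "regions and\nclimbs toward the K cap for polygenic ones - a cheap "
      "architecture diagnostic.")
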