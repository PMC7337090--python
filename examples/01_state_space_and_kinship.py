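"""IBD state space of a hexaploid cross and worked kinship entries.

A hexaploid parent transmits 3 of its 6 homologs per gamete, so a cross
segregates 20 x 20 = 400 genotype classes; the Pi matrix records the
proportion of alleles two classes share identical by descent.
"""

import numpy as np

import polyqtl as pq

space = pq.build_state_space(6)
print(f"gametes per parent: {space.gametes_per_parent}")
print(f"genotype classes:   {space.n_states}")

pi = pq.build_pi_matrix(space)
values = np.unique(np.round(pi.values, 12))
print(f"distinct IBD proportions: {len(values)} -> {values * 6} sixths")

# two individuals observed with certainty: abc|ghi shares 5 of 6 alleles
# with abc|ghj (all but i/j)
Z = np.zeros((3, space.n_states))
Z[0, space.state_from_label("abc|ghi")] = 1.0
Z[1, space.state_from_label("abc|ghj")] = 1.0
# a third individual whose genotype is split 50:50 between the two states
Z[2, space.state_from_label("abc|ghi")] = 0.5
Z[2, space.state_from_label("abc|ghj")] = 0.5

G = pq.kinship_from_probs(Z, pi)
print(f"certain abc|ghi vs abc|ghj : {G[0, 1]:.4f}  (= 5/6)")
print(f"50:50 split vs abc|ghj     : {G[2, 1]:.4f}  (= 5.5/6)")
print("Larger entries mean more alleles shared IBD, hence stronger")
print("expected phenotypic resemblance at a QTL located here.")
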