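"""Round trip: generate two-epoch activation labels, recover the overlap.

Populations of 1000 neurons are drawn from the bivariate Bernoulli model
at several overlap settings (kappa); tallying each population and scoring
it shows the mean similarity score tracking kappa.
"""

import numpy as np

from arcfish import SimConfig, counts_from_truth, similarity_score, simulate_labels

for kappa in (0.0, 0.25, 0.5, 0.75, 1.0):
    scores = []
    for rep in range(100):
        cfg = SimConfig(n_cells=1000, p1=0.3, p2=0.3, kappa=kappa,
                        glia_fraction=0.0, seed=rep)
        truth = simulate_labels(cfg, place=False)
        scores.append(similarity_score(counts_from_truth(truth)).sisc)
    scores = np.asarray(scores)
    print(f"kappa={kappa:4.2f}  mean SiSc={scores.mean():.3f} "
          f"(sd {scores.std(ddof=1):.3f} over {len(scores)} populations)")

print("\nThe mean score tracks the generative overlap; the small upward")
print("offset at intermediate kappa is the finite-sample bias of the")
print("plug-in estimator when the two epoch proportions are equal.")
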