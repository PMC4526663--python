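"""Similarity score from classification tallies.

Three benchmark populations of 100 neurons: one where every Arc-positive
cell is double-labeled (perfect ensemble reuse), one where the double
fraction sits exactly at the product of the epoch proportions (independent
ensembles), and one intermediate tally evaluated through the full chain.
"""

from arcfish import CellCounts, similarity_score

tallies = {
    "perfect overlap": CellCounts(neg=50, nuc=0, cyt=0, dob=50),
    "independence": CellCounts(neg=49, nuc=21, cyt=21, dob=9),
    "intermediate": CellCounts(neg=50, nuc=10, cyt=15, dob=25),
}

for name, counts in tallies.items():
    r = similarity_score(counts)
    print(f"{name:16s} epoch1={r.epoch1:.2f} epoch2={r.epoch2:.2f} "
          f"p(E1E2)={r.p_e1e2:.3f} diff={r.diff_e1e2:+.3f} SiSc={r.sisc:.4f}")

print("\nSiSc 1 = one population active in both epochs; 0 = two independent")
print("populations; intermediate values grade the degree of ensemble reuse.")
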