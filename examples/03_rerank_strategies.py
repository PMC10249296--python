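"""The two re-ranking strategies on a hand-sized example.

S1(p, k) moves the bottom-p-scored candidates to the end of the list
(re-ordered by score) while preserving the top-k original positions.
S2(p, k) sorts by the sum of the original rank and the S1 rank, giving
the original ranking more weight — an ensemble of both rankers.
"""

from retroranker import apply_s1, apply_s2

original_ranks = [1, 2, 3, 4, 5, 6]
rr_scores = [0.9, 0.1, 0.8, 0.2, 0.7, 0.3]

print("original order:", original_ranks)
print("ranker scores: ", rr_scores)
print("S1(0.5, 0):    ", apply_s1(original_ranks, rr_scores, p=0.5, k=0).tolist())
print("S2(0.5, 0):    ", apply_s2(original_ranks, rr_scores, p=0.5, k=0).tolist())
print("S1(1.0, 2):    ", apply_s1(original_ranks, rr_scores, p=1.0, k=2).tolist())
print("S2(0.0, 0):    ", apply_s2(original_ranks, rr_scores, p=0.0, k=0).tolist())

# S1(0.5, 0) demotes the three lowest-scored candidates (2, 4, 6) to the
# tail in score order; S2 blends that with the original ranking, so
# candidate 2 (originally second) recovers ground. p = 0 is the identity,
# and k = 2 pins the first two original positions.
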