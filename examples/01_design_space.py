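"""Build the synthetic design space and inspect its structure.

10 templates x 64 primers differing only at three priming-site positions
(-14/-8/-2 from the primer 3' end), each template tagged by a unique
12-base recognition sequence.
"""

from collections import Counter

from depcrsim import default_design

design = default_design()
space = design.space

print(f"templates: {len(design.templates)}  primers: {len(design.primers)}  "
      f"interactions: {len(space.pairs())}")
print(f"ST0 forward priming site: {design.templates[0].forward_site}")
print(f"V0 core (perfect match):  {design.primers[0].core}")

dist = Counter(p.n_mismatches for p in space.profiles.values())
print("pairs by mismatch count:", dict(sorted(dist.items())))
# 10 perfect-match pairs (Vi x STi); everything else has 1-3 variant-position
# mismatches, so every read can be scored as perfect-match or mismatch annealing.

recs = [t.recognition_seq for t in design.templates]
from depcrsim.design import hamming
import itertools
min_d = min(hamming(a, b) for a, b in itertools.combinations(recs, 2))
print(f"minimum pairwise Hamming distance between recognition sequences: {min_d}")
# >= 4 guarantees exact-match template identification is unambiguous.
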