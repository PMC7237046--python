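"""Effect of a central substitution on binding, as a function of distance.

Scans a small ensemble of uniform-random 101-nt RNAs: the central base is
substituted (all six unordered nucleotide pairs) and the change in footprint
opening free energy, ddG, is computed for every footprint start position.
Printed: the pair-averaged mean and standard deviation of ddG near the
substitution and 30 nt away.  The mean is near zero away from the
substitution, but the standard deviation stays clearly positive — single
substitutions act on protein binding at a distance through structure, with
a symmetric average effect.
"""

import numpy as np

from snpfold import run_random_scan
from snpfold.scan import PAIRS

profile = run_random_scan(n_sequences=10, length=101, footprint=7, seed=7)
center = profile.center
mean = np.mean([profile.mean[p] for p in PAIRS], axis=0)
std = profile.pooled_std()

print(f"{profile.n_sequences} random sequences, length {profile.sequence_length} nt, "
      f"footprint {profile.footprint} nt, seed {profile.seed}")
print("footprint start    mean ddG (kcal/mol)   std ddG (kcal/mol)")
for d in (0, -10, -30, 30):
    pos = center + d
    print(f"  center{d:+4d} nt     {mean[pos]:+.4f}               {std[pos]:.4f}")
print("Mean ~0 at a distance, std > 0: individual substitutions still matter.")
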