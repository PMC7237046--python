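"""Independent oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths: the
structure counter is its own recursion over pairability only, and the
effective-K_D oracle works from an explicit enumeration of (structure,
bound-protein) states, extracting K_eff from the dilute-limit bound
fraction.
"""

from __future__ import annotations

import math
from functools import lru_cache

from snpfold.binding import AffinityTable, BindingMode
from snpfold.fold import EnergyModel, enumerate_structures, normalize_sequence

_PAIRABLE = {"GC", "CG", "AU", "UA", "GU", "UG"}


def count_structures(seq: str, min_loop: int = 3) -> int:
    """Number of admissible structures by an independent counting recurrence.

    C(i, j) = C(i, j-1) + sum over pairable (p, j-1) of C(i, p) * C(p+1, j-1),
    counting only pairability and the hairpin-loop minimum.
    """
    s = normalize_sequence(seq)

    @lru_cache(maxsize=None)
    def c(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 1
        total = c(i, j - 1)
        q = j - 1
        for p in range(i, q - min_loop):
            if s[p] + s[q] in _PAIRABLE:
                total += c(i, p) * c(p + 1, q)
        return total

    return c(0, len(s))


def kd_eff_bound_states(
    seq: str,
    table: AffinityTable,
    model: EnergyModel,
    mode: BindingMode | None = None,
) -> float:
    """Effective K_D from explicit enumeration of protein-bound states.

    States are (structure, binding position or none).  A protein bound at
    footprint [i, i+k) requires all footprint bases unpaired in the
    structure and carries statistical weight exp(-E/kT) * c / K_D(w_i) at
    free protein concentration c.  The dilute-limit bound fraction gives
    theta / c -> Z_bound_coeff / Z, i.e. 1/K_eff = Z_bound_coeff / Z.
    """
    s = normalize_sequence(seq)
    k = table.k
    structures = enumerate_structures(s, model)
    kT = model.kT
    if mode is not None and mode.kind == "single_site":
        starts = [mode.interval[0]]
    else:
        starts = range(len(s) - k + 1)
    z = 0.0
    z_bound_coeff = 0.0
    for pairs, energy in structures:
        w = math.exp(-energy / kT)
        z += w
        paired = set()
        for p, q in pairs:
            paired.add(p)
            paired.add(q)
        for i in starts:
            if any(pos in paired for pos in range(i, i + k)):
                continue
            kd = table.kd[s[i : i + k]]
            if math.isinf(kd):
                continue
            z_bound_coeff += w / kd
    if z_bound_coeff == 0.0:
        return math.inf
    return z / z_bound_coeff
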