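"""Boltzmann-ensemble folding of RNA secondary structures with hard constraints.

The partition function is computed over all pseudoknot-free secondary
structures built from canonical pairs (GC, AU, GU wobble) with a minimum
hairpin-loop length, by the standard O(N^3) interval recursion.  Hard
constraints force chosen bases to remain unpaired, which is how a bound
single-stranded-RNA-binding protein footprint is modelled: the probability
that a footprint is entirely unpaired is the ratio of the constrained to
the unconstrained partition function.

Two energy backends are available:

* ``builtin`` — a self-contained simplified nearest-neighbour model with one
  energy per pair type and an optional bonus per stacked pair.  Everything
  in this package is exact and testable under this model.
* ``vienna`` — an adapter onto the ViennaRNA Python bindings (full Turner
  parameters), if installed.  Ensemble free-energy differences and unpaired
  probabilities are comparable across backends; absolute partition values
  are not (ViennaRNA applies its own internal rescaling).

An exhaustive structure enumerator for short sequences serves as the
ground-truth oracle for the recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "BASES",
    "KB",
    "EnergyModel",
    "EnsembleResult",
    "normalize_sequence",
    "partition_function",
    "prob_interval_unpaired",
    "enumerate_structures",
    "structure_energy",
]

#: Boltzmann constant in kcal/(mol*K).
KB = 0.0019872

BASES = "ACGU"

_CANONICAL = {
    ("G", "C"): "GC",
    ("C", "G"): "GC",
    ("A", "U"): "AU",
    ("U", "A"): "AU",
    ("G", "U"): "GU",
    ("U", "G"): "GU",
}

_ENC = {b: i for i, b in enumerate(BASES)}


class SequenceError(ValueError):
    """Raised for sequences outside the {A,C,G,U/T} alphabet."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, map T to U, and reject anything outside {A,C,G,U}."""
    s = str(seq).strip().upper().replace("T", "U")
    if not s:
        raise SequenceError("empty sequence")
    bad = set(s) - set(BASES)
    if bad:
        raise SequenceError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


@dataclass(frozen=True)
class EnergyModel:
    """Energy parameters for the built-in nearest-neighbour model.

    Parameters
    ----------
    temperature
        Folding temperature in kelvin (default 37 C).
    pair_energies
        Free energy in kcal/mol per canonical pair type.
    stack_bonus
        Extra free energy (kcal/mol) added for each pair whose inner
        neighbour is also paired (helix stacking).  0 disables stacking.
    min_hairpin_loop
        Minimum number of unpaired bases enclosed by a hairpin-closing pair.
    scale_energy
        Per-nucleotide rescaling free energy (kcal/mol) applied internally
        so that partition values stay inside float64 range for sequences up
        to roughly 600 nt; it cancels exactly in every reported quantity.
    backend
        ``"builtin"`` or ``"vienna"`` (Turner parameters via the ViennaRNA
        Python bindings, which must be importable).
    """

    temperature: float = 310.15
    pair_energies: Mapping[str, float] = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    stack_bonus: float = 0.0
    min_hairpin_loop: int = 3
    scale_energy: float = 0.7
    backend: str = "builtin"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")
        for k, v in self.pair_energies.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite energy for pair {k}")
        if self.backend not in ("builtin", "vienna"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T in kcal/mol (~0.6163 at 310.15 K)."""
        return KB * self.temperature

    def pair_energy(self, a: str, b: str) -> float | None:
        """Energy of pairing bases ``a``/``b``; None if not canonical."""
        key = _CANONICAL.get((a, b))
        if key is None:
            return None
        return self.pair_energies[key]


DEFAULT_MODEL = EnergyModel()


@dataclass(frozen=True)
class EnsembleResult:
    """Partition value and ensemble free energy of a folding ensemble.

    ``Z`` is dimensionless with the open chain carrying weight 1, so under
    the built-in model Z >= 1 and ``G = -kT ln Z <= 0``.  ``log_Z`` is the
    primary stored quantity (``Z`` itself may overflow for long sequences).
    """

    log_Z: float
    kT: float

    @property
    def Z(self) -> float:
        try:
            return math.exp(self.log_Z)
        except OverflowError:
            return math.inf

    @property
    def G(self) -> float:
        return -self.kT * self.log_Z


def _check_constraints(n: int, constraints: Iterable[int]) -> np.ndarray:
    pos = sorted(set(int(p) for p in constraints))
    if pos and (pos[0] < 0 or pos[-1] >= n):
        raise IndexError(f"constraint position out of range for length {n}")
    mask = np.zeros(n, dtype=bool)
    mask[pos] = True
    return mask


def _pair_weight_matrix(seq: str, model: EnergyModel, forced: np.ndarray) -> np.ndarray:
    """w[p, q] = exp(-E(p,q)/kT) for admissible pairs, else 0 (upper triangle)."""
    n = len(seq)
    kT = model.kT
    w44 = np.zeros((4, 4))
    for (a, b), key in _CANONICAL.items():
        w44[_ENC[a], _ENC[b]] = math.exp(-model.pair_energies[key] / kT)
    enc = np.fromiter((_ENC[c] for c in seq), dtype=np.intp, count=n)
    w = w44[enc[:, None], enc[None, :]]
    w *= np.triu(np.ones((n, n), dtype=bool), k=model.min_hairpin_loop + 1)
    w[forced, :] = 0.0
    w[:, forced] = 0.0
    return w


def _log_partition_builtin(seq: str, model: EnergyModel, forced: np.ndarray) -> float:
    """log Z by the interval recursion.

    State: Z[i, j] is the partition value of the half-open interval [i, j);
    Zb[p, q] is the weight of all structures on [p, q] in which p pairs
    with q.  Appending base q = j-1 either leaves it unpaired or closes a
    pair (p, q), giving a triangular matrix-vector product per column,
    O(N^3) overall.

    A first pass runs unscaled (exact, open chain at weight 1); if the
    partition value overflows float64 — long and/or pairing-rich sequences
    — the pass is repeated with a per-base Boltzmann rescaling of
    ``scale_energy`` kcal/mol, which cancels exactly in the returned log.
    """
    for scale_energy in (0.0, model.scale_energy):
        log_z = _interval_recursion(seq, model, forced, scale_energy)
        if log_z is not None:
            return log_z
        if scale_energy == model.scale_energy:
            break
    raise OverflowError(
        "partition value left float64 range; adjust EnergyModel.scale_energy"
    )


def _interval_recursion(
    seq: str, model: EnergyModel, forced: np.ndarray, scale_energy: float
) -> float | None:
    n = len(seq)
    kT = model.kT
    u = math.exp(-scale_energy / kT)  # rescaling factor per base
    s = math.exp(-model.stack_bonus / kT)
    w = _pair_weight_matrix(seq, model, forced) * (u * u)
    ml = model.min_hairpin_loop

    Z = np.zeros((n + 1, n + 1))
    np.fill_diagonal(Z, 1.0)
    Zb = np.zeros((n, n))
    with np.errstate(over="ignore", invalid="ignore"):
        for j in range(1, n + 1):
            q = j - 1
            pmax = q - ml  # pair starts p in [0, pmax)
            if pmax > 0:
                inner = Z[1 : pmax + 1, q].copy()  # Z[p+1, q] for p < pmax
                if s != 1.0:
                    # add stacking credit for structures where (p+1, q-1) pair
                    inner += (s - 1.0) * Zb[1 : pmax + 1, q - 1]
                Zb[:pmax, q] = w[:pmax, q] * inner
                Z[:j, j] = Z[:j, j - 1] * u + Z[:j, :pmax] @ Zb[:pmax, q]
            else:
                Z[:j, j] = Z[:j, j - 1] * u
    zf = Z[0, n]
    if not (zf > 0.0) or not math.isfinite(zf):
        return None  # over-/underflow at this scaling
    return math.log(zf) + n * scale_energy / kT


def _log_partition_vienna(seq: str, model: EnergyModel, forced: np.ndarray) -> float:
    import RNA  # deferred: optional backend

    md = RNA.md()
    md.temperature = model.temperature - 273.15
    fc = RNA.fold_compound(seq, md)
    for p in np.flatnonzero(forced):
        fc.hc_add_up(int(p) + 1)  # 1-based
    _, g = fc.pf()  # kcal/mol
    return -g / model.kT


def partition_function(
    seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    constraints: Iterable[int] = (),
) -> EnsembleResult:
    """Partition function with the given bases forced to stay unpaired.

    Returns an :class:`EnsembleResult` whose ``Z`` sums ``exp(-E/kT)`` over
    every admissible structure (open chain included at weight 1 under the
    built-in model) and whose ``G = -kT ln Z``.
    """
    s = normalize_sequence(seq)
    forced = _check_constraints(len(s), constraints)
    if model.backend == "vienna":
        log_z = _log_partition_vienna(s, model, forced)
    else:
        log_z = _log_partition_builtin(s, model, forced)
    return EnsembleResult(log_Z=log_z, kT=model.kT)


def prob_interval_unpaired(
    seq: str,
    interval: tuple[int, int],
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Ensemble probability that every base in half-open [i, j) is unpaired.

    Computed as Z(bases in [i, j) forced unpaired) / Z(unconstrained); the
    empty interval has probability 1 by convention.
    """
    s = normalize_sequence(seq)
    i, j = int(interval[0]), int(interval[1])
    if not (0 <= i <= j <= len(s)):
        raise IndexError(f"interval [{i}, {j}) out of range for length {len(s)}")
    if i == j:
        return 1.0
    z0 = partition_function(s, model)
    zc = partition_function(s, model, constraints=range(i, j))
    return math.exp(zc.log_Z - z0.log_Z)


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle (short sequences only)

_ENUM_MAX_N = 25


def structure_energy(pairs: Sequence[tuple[int, int]], seq: str, model: EnergyModel) -> float:
    """Energy of an explicit structure: pair terms plus stacking bonuses."""
    pset = set(pairs)
    e = 0.0
    for p, q in pairs:
        ep = model.pair_energy(seq[p], seq[q])
        if ep is None:
            raise ValueError(f"non-canonical pair ({p},{q}) in structure")
        e += ep
        if (p + 1, q - 1) in pset:
            e += model.stack_bonus
    return e


def _enum_pairs(
    seq: str, i: int, j: int, ok: np.ndarray, ml: int, memo: dict
) -> list[tuple[tuple[int, int], ...]]:
    """All admissible pair sets on half-open [i, j) (nested, no pseudoknots)."""
    if j - i <= ml:
        return [()]
    key = (i, j)
    if key in memo:
        return memo[key]
    out = list(_enum_pairs(seq, i, j - 1, ok, ml, memo))  # j-1 unpaired
    q = j - 1
    for p in range(i, q - ml):
        if not ok[p, q]:
            continue
        for left in _enum_pairs(seq, i, p, ok, ml, memo):
            for inner in _enum_pairs(seq, p + 1, q, ok, ml, memo):
                out.append(left + ((p, q),) + inner)
    memo[key] = out
    return out


def enumerate_structures(
    seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    constraints: Iterable[int] = (),
) -> list[tuple[tuple[tuple[int, int], ...], float]]:
    """Every admissible secondary structure with its energy (N <= 25).

    Each structure is a tuple of (i, j) pairs sorted by opening position;
    the pair-free structure is always present.  Summing ``exp(-E/kT)``
    over the returned list reproduces :func:`partition_function` — this is
    the ground-truth oracle for the recursion.
    """
    s = normalize_sequence(seq)
    n = len(s)
    if n > _ENUM_MAX_N:
        raise ValueError(f"enumeration limited to N <= {_ENUM_MAX_N}, got {n}")
    forced = _check_constraints(n, constraints)
    ok = _pair_weight_matrix(s, model, forced) > 0
    structures = _enum_pairs(s, 0, n, ok, model.min_hairpin_loop, {})
    return [(st, structure_energy(st, s, model)) for st in structures]
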