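"""Protein-binding observables derived from the folding ensemble.

A single-stranded-RNA-binding protein with a footprint of k bases can only
bind where all k bases are unpaired, so its effective affinity for a
structured RNA combines the intrinsic (unstructured-RNA) dissociation
constant of each k-mer with the ensemble probability that the k-mer is
accessible.  In the dilute, single-occupancy limit the effective
dissociation constant of the whole molecule is

    1 / K_eff = sum_i  p_open([i, i+k)) / K_D(w_i)

over footprint start positions i, where w_i is the k-mer starting at i and
p_open is the probability that the footprint is entirely unpaired.  The
``single_site`` mode restricts the sum to one designated footprint — the
hard-constraint analysis that isolates the effect of a variant on the
central binding site.

Opening free energies follow Delta G_open = -kT ln p_open, and the effect
of a point substitution on a fixed footprint is
Delta Delta G = Delta G_open(mut) - Delta G_open(wt); the protein's
intrinsic binding energy is the same for both alleles and cancels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .fold import DEFAULT_MODEL, EnergyModel, normalize_sequence, partition_function

__all__ = [
    "OpeningResult",
    "AffinityTable",
    "BindingMode",
    "opening_free_energy",
    "ddG",
    "effective_kd",
    "affinity_ratio",
]


@dataclass(frozen=True)
class OpeningResult:
    """Probability that a footprint is entirely unpaired, and -kT ln p."""

    p_open: float
    dG_open: float


@dataclass(frozen=True)
class BindingMode:
    """How footprint placements contribute to the effective K_D.

    ``ensemble`` sums over every placement of the footprint in the window;
    ``single_site`` keeps only one designated footprint interval.
    """

    kind: str
    interval: tuple[int, int] | None = None

    @classmethod
    def ensemble(cls) -> "BindingMode":
        return cls("ensemble")

    @classmethod
    def single_site(cls, start: int, k: int) -> "BindingMode":
        return cls("single_site", (int(start), int(start) + int(k)))

    def __post_init__(self) -> None:
        if self.kind not in ("ensemble", "single_site"):
            raise ValueError(f"unknown binding mode {self.kind!r}")
        if self.kind == "single_site" and self.interval is None:
            raise ValueError("single_site mode requires a footprint interval")


class AffinityTable:
    """Complete map from every k-mer to its intrinsic K_D in nM.

    The table represents the protein's sequence preference on unstructured
    RNA (an RNAcompete-style measurement).  Every one of the 4^k k-mers
    must be present with K_D > 0; ``inf`` marks a non-binder and
    contributes exactly zero to effective-K_D sums.
    """

    def __init__(self, kd: Mapping[str, float], k: int = 7):
        self.k = int(k)
        table: dict[str, float] = {}
        for kmer, v in kd.items():
            w = normalize_sequence(kmer)
            if len(w) != self.k:
                raise ValueError(f"k-mer {kmer!r} does not have length {self.k}")
            table[w] = float(v)
        if len(table) != 4**self.k:
            raise ValueError(
                f"affinity table must cover all {4 ** self.k} {self.k}-mers, "
                f"got {len(table)}"
            )
        for w, v in table.items():
            if not v > 0:
                raise ValueError(f"K_D for {w} must be > 0, got {v}")
        self.kd = table

    def __getitem__(self, kmer: str) -> float:
        return self.kd[normalize_sequence(kmer)]

    def __len__(self) -> int:
        return len(self.kd)

    def scaled(self, c: float) -> "AffinityTable":
        """A copy with every K_D multiplied by c > 0."""
        if not c > 0:
            raise ValueError("scale factor must be > 0")
        return AffinityTable({w: v * c for w, v in self.kd.items()}, k=self.k)

    # -- TSV round trip (2 columns: kmer, K_D in nM; 'inf' allowed) --------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("kmer\tkd_nM\n")
            for w in sorted(self.kd):
                fh.write(f"{w}\t{self.kd[w]!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AffinityTable":
        kd: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.lower().startswith("kmer"):
                raise ValueError(f"{path}: expected 'kmer<TAB>kd_nM' header")
            for ln, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                try:
                    w, v = line.rstrip("\n").split("\t")
                    kd[w] = float(v)
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: malformed row") from exc
        if not kd:
            raise ValueError(f"{path}: empty affinity table")
        k = len(next(iter(kd)))
        return cls(kd, k=k)

    @classmethod
    def uniform(cls, kd_value: float, k: int = 7) -> "AffinityTable":
        """Sequence-independent table (every k-mer at the same K_D)."""
        kmers = ("".join(t) for t in itertools.product("ACGU", repeat=k))
        return cls({w: kd_value for w in kmers}, k=k)


def _log_p_open(
    seq: str, interval: tuple[int, int], model: EnergyModel, log_z0: float
) -> float:
    zc = partition_function(seq, model, constraints=range(interval[0], interval[1]))
    return zc.log_Z - log_z0


def opening_free_energy(
    seq: str,
    interval: tuple[int, int],
    model: EnergyModel = DEFAULT_MODEL,
) -> OpeningResult:
    """Opening probability and free energy of one footprint interval."""
    s = normalize_sequence(seq)
    i, j = int(interval[0]), int(interval[1])
    if not (0 <= i <= j <= len(s)):
        raise IndexError(f"interval [{i}, {j}) out of range for length {len(s)}")
    log_z0 = partition_function(s, model).log_Z
    lp = _log_p_open(s, (i, j), model, log_z0)
    return OpeningResult(p_open=math.exp(lp), dG_open=-model.kT * lp)


def _check_single_mismatch(a: str, b: str) -> None:
    if len(a) != len(b):
        raise ValueError("allele sequences differ in length")
    diff = sum(1 for x, y in zip(a, b) if x != y)
    if diff > 1:
        raise ValueError(f"allele sequences differ at {diff} positions (expected <= 1)")


def ddG(
    seq_wt: str,
    seq_mut: str,
    footprint_interval: tuple[int, int],
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Delta Delta G = dG_open(mut) - dG_open(wt) for a fixed footprint (kcal/mol).

    The two sequences must be identical except at (at most) one position.
    Positive values mean the footprint is harder to open — hence harder to
    bind — in the mutant.
    """
    a = normalize_sequence(seq_wt)
    b = normalize_sequence(seq_mut)
    _check_single_mismatch(a, b)
    if a == b:
        return 0.0
    return (
        opening_free_energy(b, footprint_interval, model).dG_open
        - opening_free_energy(a, footprint_interval, model).dG_open
    )


def effective_kd(
    seq: str,
    table: AffinityTable,
    model: EnergyModel = DEFAULT_MODEL,
    mode: BindingMode | None = None,
) -> float:
    """Structure-aware effective dissociation constant of the window (nM).

    Dilute single-occupancy limit: 1/K_eff = sum_i p_open(i) / K_D(w_i)
    over footprint placements (all of them in ensemble mode, the designated
    one in single-site mode).  Footprints overhanging the sequence end are
    skipped; returns ``inf`` when every term vanishes.
    """
    s = normalize_sequence(seq)
    k = table.k
    if len(s) < k:
        raise ValueError(f"sequence shorter than footprint ({len(s)} < {k})")
    mode = mode or BindingMode.ensemble()
    if mode.kind == "single_site":
        i, j = mode.interval
        if j - i != k:
            raise ValueError("single_site interval length must equal the footprint")
        if not (0 <= i and j <= len(s)):
            raise IndexError("single_site interval out of range")
        starts = [i]
    else:
        starts = list(range(len(s) - k + 1))

    log_z0 = partition_function(s, model).log_Z
    inv = 0.0
    for i in starts:
        kd = table.kd[s[i : i + k]]
        if math.isinf(kd):
            continue  # exact 1/inf = 0: non-binders never contribute
        lp = _log_p_open(s, (i, i + k), model, log_z0)
        inv += math.exp(lp) / kd
    if inv == 0.0:
        return math.inf
    return 1.0 / inv


def affinity_ratio(
    seq_ref: str,
    seq_alt: str,
    table: AffinityTable,
    model: EnergyModel = DEFAULT_MODEL,
    mode: BindingMode | None = None,
) -> float:
    """K_eff(alt) / K_eff(ref) for two alleles of the same window.

    A ratio above 1 means the alternate allele makes protein binding
    harder.  The alleles must differ at exactly one position (or none, in
    which case the ratio is exactly 1).
    """
    a = normalize_sequence(seq_ref)
    b = normalize_sequence(seq_alt)
    _check_single_mismatch(a, b)
    if a == b:
        return 1.0
    kd_ref = effective_kd(a, table, model, mode)
    kd_alt = effective_kd(b, table, model, mode)
    if math.isinf(kd_ref) and math.isinf(kd_alt):
        raise ValueError("both alleles are complete non-binders; ratio undefined")
    return kd_alt / kd_ref
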