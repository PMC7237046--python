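"""Synthetic inputs with controlled statistical structure.

Stand-ins for the pipeline's real-world inputs: uniform-random transcripts,
complete k-mer affinity tables with an AU-rich binding preference (as for
HuR-like proteins), transcripts with a planted structural switch in which a
distal variant toggles a stem that sequesters the binding motif, and whole
cohorts with a controllable above/below-1 asymmetry of planted effect
directions.  Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .binding import AffinityTable
from .fold import BASES, normalize_sequence
from .pipeline import BindingSite, SnpRecord

__all__ = [
    "gen_random_sequences",
    "gen_affinity_table",
    "gen_planted_switch",
    "gen_cohort",
    "PlantedSwitch",
    "CohortFixture",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def revcomp(seq: str) -> str:
    """Reverse complement over the RNA alphabet (G-C, A-U)."""
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


def gen_random_sequences(n: int, length: int, seed: int) -> list[str]:
    """n i.i.d. uniform-random RNA sequences (equal base probabilities)."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(BASES))
    return ["".join(letters[rng.integers(0, 4, size=length)]) for _ in range(n)]


def gen_affinity_table(
    k: int = 7,
    K0: float = 5.0,
    beta: float = 6.0,
    jitter_sigma: float = 0.5,
    seed: int = 0,
) -> AffinityTable:
    """Complete 4^k affinity table with an AU-rich binding preference.

    K_D(w) = K0 * exp(beta * GC(w)) * lognormal jitter, with GC(w) the G+C
    fraction of the k-mer.  With beta > 0 AU-rich k-mers bind tightest
    (K_D ~ K0 in nM); the GC-richest k-mers are ~exp(beta) weaker, giving
    the few-orders-of-magnitude dynamic range typical of RNAcompete
    measurements.  jitter_sigma=0 makes the table a pure function of GC
    content.
    """
    if K0 <= 0:
        raise ValueError("K0 must be > 0")
    rng = np.random.default_rng(seed)
    kd = {}
    for t in itertools.product(BASES, repeat=k):
        w = "".join(t)
        gc = (w.count("G") + w.count("C")) / k
        jitter = float(np.exp(rng.normal(0.0, jitter_sigma))) if jitter_sigma > 0 else 1.0
        kd[w] = K0 * float(np.exp(beta * gc)) * jitter
    return AffinityTable(kd, k=k)


# ---------------------------------------------------------------------------
# Planted structural switch

#: AU-rich 7-mer used as the planted binding motif (tightest class under
#: the AU-preference table; also a realistic HuR-like ARE core).
MOTIF = "UAUUUAU"
_EXT5 = "GGC"  # GC-rich helix extensions flanking the motif
_EXT3 = "GCC"
_LOOP = 10  # unpaired spacer between duplex arm and its partner (nt)
_DECOY_LEN = 6  # background runs this long complementary to an arm are scrubbed


def _scrub_decoys(
    seq: list[str], protected: set[int], arms: list[str], rng: np.random.Generator
) -> None:
    """Remove background k-mers complementary to a designed duplex arm.

    A random background can by chance contain a stretch complementary to
    the motif arm (or its partner), offering the stem an alternative
    pairing partner that decouples the variant from motif accessibility.
    Any unprotected window of ``_DECOY_LEN`` whose reverse complement
    occurs in an arm gets one of its bases redrawn; repeated until clean.
    """
    targets = set()
    for arm in arms:
        for i in range(len(arm) - _DECOY_LEN + 1):
            targets.add(arm[i : i + _DECOY_LEN])
    n = len(seq)
    for _ in range(10 * n):  # generous bound; typically a handful of edits
        dirty = False
        s = "".join(seq)
        for i in range(n - _DECOY_LEN + 1):
            if revcomp(s[i : i + _DECOY_LEN]) not in targets:
                continue
            editable = [p for p in range(i, i + _DECOY_LEN) if p not in protected]
            if not editable:
                continue  # the designed duplex itself
            j = editable[len(editable) // 2]
            seq[j] = str(rng.choice([b for b in BASES if b != seq[j]]))
            dirty = True
            break
        if not dirty:
            return
    raise RuntimeError("decoy scrubbing did not converge")


@dataclass(frozen=True)
class PlantedSwitch:
    """One transcript with a designed stem-toggle variant.

    One allele completes a perfect duplex that sequesters the binding motif
    (plus short GC clamps); the other allele breaks the duplex, leaving the
    motif accessible.  ``truth`` is "gt" when the alternate allele
    sequesters (affinity ratio > 1) and "lt" when it liberates (< 1).
    """

    transcript_id: str
    sequence: str
    site: BindingSite
    snp: SnpRecord
    motif_interval: tuple[int, int]
    truth: str

    @property
    def alt_sequence(self) -> str:
        s = self.sequence
        p = self.snp.position
        return s[:p] + self.snp.alt + s[p + 1 :]


def gen_planted_switch(
    seed: int,
    direction: str = "gt",
    L: int = 201,
    transcript_id: str | None = None,
) -> PlantedSwitch:
    """Build a transcript whose variant toggles a motif-sequestering stem.

    Layout (all coordinates 0-based, c = (L-1)//2): the motif sits at
    [c-3, c+4) inside a 13-nt duplex arm [c-6, c+7) (GC clamps on both
    sides); after a 10-nt loop, the reverse complement of the arm is
    planted at [c+17, c+30).  The variant position pairs with the motif
    center, 23 nt downstream of it — well outside the motif itself.  For
    direction "gt" the reference carries a mismatch there (stem broken,
    motif open) and the alternate allele restores the perfect stem.
    """
    if L % 2 == 0 or L < 61:
        raise ValueError("L must be odd and >= 61")
    if direction not in ("gt", "lt"):
        raise ValueError("direction must be 'gt' or 'lt'")
    rng = np.random.default_rng(seed)
    letters = np.array(list(BASES))
    seq = list("".join(letters[rng.integers(0, 4, size=L)]))

    c = (L - 1) // 2
    arm = _EXT5 + MOTIF + _EXT3  # 13 nt
    arm_start = c - 6
    partner = revcomp(arm)
    partner_start = c + 7 + _LOOP
    seq[arm_start : arm_start + 13] = arm
    seq[partner_start : partner_start + 13] = partner
    protected = set(range(arm_start, arm_start + 13)) | set(
        range(partner_start, partner_start + 13)
    )
    _scrub_decoys(seq, protected, [arm, partner], rng)

    # variant position: partner base that pairs with the motif center c
    snp_pos = partner_start + (12 - (c - arm_start))
    paired_base = partner[snp_pos - partner_start]  # completes the stem
    mismatch = paired_base  # any base that cannot pair with the motif center
    motif_center_base = seq[c]
    candidates = [b for b in BASES if b != paired_base]
    rng.shuffle(candidates)
    for b in candidates:
        if b + motif_center_base not in ("GC", "CG", "AU", "UA", "GU", "UG"):
            mismatch = b
            break

    if direction == "gt":
        ref_base, alt_base = mismatch, paired_base  # alt sequesters the motif
    else:
        ref_base, alt_base = paired_base, mismatch  # alt liberates the motif
    seq[snp_pos] = ref_base
    sequence = "".join(seq)

    tid = transcript_id or f"switch{seed}"
    motif_interval = (c - 3, c + 4)
    site = BindingSite(transcript_id=tid, start=c - 10, end=c + 11)
    snp = SnpRecord(transcript_id=tid, position=snp_pos, ref=ref_base, alt=alt_base)
    return PlantedSwitch(
        transcript_id=tid,
        sequence=sequence,
        site=site,
        snp=snp,
        motif_interval=motif_interval,
        truth=direction,
    )


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class CohortFixture:
    """A full synthetic input set with per-variant planted ground truth."""

    transcripts: dict[str, str]
    sites: list[BindingSite]
    snps: list[SnpRecord]
    truth: dict[str, str]  # transcript_id -> "gt" | "lt" | "neutral"
    params: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write transcripts.fa, snps.vcf, sites.bed into ``out_dir``."""
        from . import io as sfio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "transcripts.fa",
            "snps": out / "snps.vcf",
            "sites": out / "sites.bed",
        }
        sfio.write_fasta(paths["fasta"], self.transcripts)
        sfio.write_vcf(paths["snps"], self.snps, self.transcripts)
        sfio.write_bed(paths["sites"], self.sites)
        return paths


def gen_cohort(
    n_sites: int,
    frac_planted: float = 0.7,
    asymmetry: float = 0.5,
    seed: int = 0,
    L: int = 61,
) -> CohortFixture:
    """A cohort mixing planted stem-switch cases with neutral cases.

    Each case is one transcript carrying one binding site and one variant;
    ``L`` is the folding-window length the cohort is meant to be analysed
    with, and transcripts are made 40 nt longer than L so that a window
    centred on any in-site motif fits without running off the transcript
    ends.  A planted case gets a stem-toggle variant whose effect direction
    is "gt" with probability ``asymmetry``; a neutral case gets a random
    variant 11-20 nt from the site middle.  Neutral variants sit outside
    the site interval on purpose: motif selection then sees the same site
    sequence for both alleles, which makes the neutral null exactly
    symmetric (reference and alternate alleles enter exchangeably).  A
    variant inside the site would bias ratios above 1, because the motif
    is chosen to be optimal for the reference allele.
    """
    if not 0.0 <= asymmetry <= 1.0:
        raise ValueError("asymmetry must lie in [0, 1]")
    if not 0.0 <= frac_planted <= 1.0:
        raise ValueError("frac_planted must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    letters = np.array(list(BASES))
    transcripts: dict[str, str] = {}
    sites: list[BindingSite] = []
    snps: list[SnpRecord] = []
    truth: dict[str, str] = {}
    Lt = L + 40  # transcript length: window L plus motif-offset margin
    c = (Lt - 1) // 2
    for i in range(n_sites):
        tid = f"tx{i:05d}"
        if rng.random() < frac_planted:
            direction = "gt" if rng.random() < asymmetry else "lt"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sw = gen_planted_switch(sub_seed, direction, Lt, transcript_id=tid)
            transcripts[tid] = sw.sequence
            sites.append(sw.site)
            snps.append(sw.snp)
            truth[tid] = direction
        else:
            seq = "".join(letters[rng.integers(0, 4, size=Lt)])
            transcripts[tid] = seq
            sites.append(BindingSite(transcript_id=tid, start=c - 10, end=c + 11))
            offset = int(rng.choice([-1, 1])) * int(rng.integers(11, 21))
            pos = c + offset
            ref = seq[pos]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            snps.append(SnpRecord(transcript_id=tid, position=pos, ref=ref, alt=alt))
            truth[tid] = "neutral"
    return CohortFixture(
        transcripts=transcripts,
        sites=sites,
        snps=snps,
        truth=truth,
        params={
            "n_sites": n_sites,
            "frac_planted": frac_planted,
            "asymmetry": asymmetry,
            "seed": seed,
            "L": L,
        },
    )
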