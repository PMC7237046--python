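"""Transcriptome-style analysis of variant effects on protein binding.

Stages: match variants to binding-site intervals on the same transcript,
pick the highest-affinity motif inside each site, fold a window centred on
that motif for both alleles, take the ratio of effective dissociation
constants (alternate over reference), and summarise the cohort — the
above/below-1 asymmetry with its one-sided exact binomial p-value, the
distance distribution of variants stratified by fold change, and cumulative
ratio curves with sub-1 ratios reciprocated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binding import AffinityTable, BindingMode, effective_kd
from .fold import DEFAULT_MODEL, BASES, EnergyModel, normalize_sequence

__all__ = [
    "SnpRecord",
    "BindingSite",
    "SnpEffectRecord",
    "AsymmetrySummary",
    "RunReport",
    "match_snps_to_sites",
    "select_best_motif",
    "extract_window",
    "compute_snp_effects",
    "asymmetry_test",
    "distance_distribution",
    "cumulative_ratio_curves",
    "STRATA",
]

logger = logging.getLogger(__name__)

#: Fold-change strata used throughout (fold change = max(ratio, 1/ratio)):
#: below twofold, two-to-threefold, threefold or greater.
STRATA = ("<2", "2-3", ">=3")


@dataclass(frozen=True)
class SnpRecord:
    """A single-nucleotide variant in 0-based transcript coordinates."""

    transcript_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for allele in (self.ref, self.alt):
            if allele not in BASES:
                raise ValueError(f"allele {allele!r} not a single RNA base")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass(frozen=True)
class BindingSite:
    """A protein binding-site interval [start, end) on a transcript."""

    transcript_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid site interval [{self.start}, {self.end})")

    @property
    def middle(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class SnpEffectRecord:
    """One variant x site evaluation."""

    snp: SnpRecord
    site: BindingSite
    motif_interval: tuple[int, int]
    window_interval: tuple[int, int]
    kd_ref_nM: float
    kd_alt_nM: float
    affinity_ratio: float
    distance_nt: int  # SNP position - motif center; negative = upstream

    @property
    def fold_change(self) -> float:
        r = self.affinity_ratio
        return max(r, 1.0 / r)

    @property
    def stratum(self) -> str:
        fc = self.fold_change
        if fc < 2.0:
            return "<2"
        if fc < 3.0:
            return "2-3"
        return ">=3"


@dataclass(frozen=True)
class AsymmetrySummary:
    """Above/below-1 counts, binomial p-value, and the three ratio means."""

    n_above: int
    n_below: int
    n_equal: int
    p_value: float
    mean_above: float
    mean_below: float
    mean_all: float


@dataclass
class RunReport:
    """Bookkeeping for every record dropped along the way."""

    n_snps: int = 0
    n_sites: int = 0
    n_candidates: int = 0
    n_records: int = 0
    unmatched_snps: int = 0
    unknown_transcript: int = 0
    short_site: int = 0
    window_overruns_end: int = 0
    snp_outside_window: int = 0
    ref_allele_mismatch: int = 0
    parameters: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def match_snps_to_sites(
    snps: Sequence[SnpRecord],
    sites: Sequence[BindingSite],
    radius: int = 40,
    report: RunReport | None = None,
) -> list[tuple[SnpRecord, BindingSite]]:
    """Pair each variant with the nearest site middle within ``radius`` nt.

    The radius is inclusive.  A variant within radius of several sites is
    paired with the nearest one only; ties go to the smaller site start.
    """
    report = report if report is not None else RunReport()
    by_tx: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_tx.setdefault(s.transcript_id, []).append(s)
    out: list[tuple[SnpRecord, BindingSite]] = []
    for snp in snps:
        best: BindingSite | None = None
        best_key: tuple[int, int] | None = None
        for site in by_tx.get(snp.transcript_id, ()):
            d = abs(snp.position - site.middle)
            if d <= radius:
                key = (d, site.start)
                if best_key is None or key < best_key:
                    best, best_key = site, key
        if best is None:
            report.unmatched_snps += 1
        else:
            out.append((snp, best))
    report.n_candidates += len(out)
    return out


def select_best_motif(
    site: BindingSite,
    transcript_seq: str,
    table: AffinityTable,
) -> tuple[int, int] | None:
    """The k-mer window inside the site with minimal intrinsic K_D.

    Ties go to the leftmost window.  Returns None when the site (clipped
    to the transcript) is shorter than the footprint.
    """
    k = table.k
    seq = normalize_sequence(transcript_seq)
    lo = max(site.start, 0)
    hi = min(site.end, len(seq))
    if hi - lo < k:
        return None
    best_start, best_kd = None, math.inf
    for i in range(lo, hi - k + 1):
        kd = table.kd[seq[i : i + k]]
        if kd < best_kd:
            best_start, best_kd = i, kd
    if best_start is None:  # every in-site k-mer is a non-binder
        best_start = lo
    return (best_start, best_start + k)


def extract_window(
    transcript_seq: str,
    motif_center: int,
    L: int,
) -> tuple[str, int] | None:
    """The length-L window centred on the motif, plus its transcript offset.

    Returns None (skip, never truncate) when the window would overrun
    either transcript end.
    """
    if L % 2 == 0:
        raise ValueError("window length L must be odd")
    half = (L - 1) // 2
    lo = motif_center - half
    hi = motif_center + half + 1
    if lo < 0 or hi > len(transcript_seq):
        return None
    return transcript_seq[lo:hi], lo


def compute_snp_effects(
    candidates: Iterable[tuple[SnpRecord, BindingSite]],
    transcripts: Mapping[str, str],
    table: AffinityTable,
    model: EnergyModel = DEFAULT_MODEL,
    L: int = 201,
    mode: str = "ensemble",
    report: RunReport | None = None,
) -> tuple[list[SnpEffectRecord], RunReport]:
    """Affinity ratios (alternate over reference) for matched candidates.

    ``mode`` is "ensemble" (all footprint placements in the window) or
    "single_site" (the selected motif only).  Records are skipped — and
    counted in the report — when the transcript is unknown, the site is
    shorter than the footprint, the window overruns a transcript end, the
    variant falls outside the window, or the stated reference allele does
    not match the transcript sequence.
    """
    if mode not in ("ensemble", "single_site"):
        raise ValueError(f"unknown mode {mode!r}")
    report = report if report is not None else RunReport()
    seqs = {tid: normalize_sequence(s) for tid, s in transcripts.items()}
    records: list[SnpEffectRecord] = []
    for snp, site in candidates:
        seq = seqs.get(snp.transcript_id)
        if seq is None:
            logger.warning("unknown transcript %s; candidate skipped", snp.transcript_id)
            report.unknown_transcript += 1
            continue
        motif = select_best_motif(site, seq, table)
        if motif is None:
            report.short_site += 1
            continue
        motif_center = motif[0] + table.k // 2
        win = extract_window(seq, motif_center, L)
        if win is None:
            report.window_overruns_end += 1
            continue
        window, offset = win
        wpos = snp.position - offset
        if not (0 <= wpos < L):
            report.snp_outside_window += 1
            continue
        if window[wpos] != snp.ref:
            logger.warning(
                "reference allele mismatch at %s:%d (%s != %s); skipped",
                snp.transcript_id, snp.position, window[wpos], snp.ref,
            )
            report.ref_allele_mismatch += 1
            continue
        alt_window = window[:wpos] + snp.alt + window[wpos + 1 :]
        if mode == "single_site":
            bmode = BindingMode.single_site(motif[0] - offset, table.k)
        else:
            bmode = BindingMode.ensemble()
        kd_ref = effective_kd(window, table, model, bmode)
        kd_alt = effective_kd(alt_window, table, model, bmode)
        ratio = kd_alt / kd_ref
        records.append(
            SnpEffectRecord(
                snp=snp,
                site=site,
                motif_interval=motif,
                window_interval=(offset, offset + L),
                kd_ref_nM=kd_ref,
                kd_alt_nM=kd_alt,
                affinity_ratio=ratio,
                distance_nt=snp.position - motif_center,
            )
        )
    report.n_records += len(records)
    return records, report


def _ratios(records: Iterable) -> np.ndarray:
    vals = []
    for r in records:
        vals.append(r.affinity_ratio if hasattr(r, "affinity_ratio") else float(r))
    return np.asarray(vals, dtype=float)


def asymmetry_test(records: Iterable) -> AsymmetrySummary:
    """One-sided exact binomial test for an excess of ratios above 1.

    Ratios exactly 1 (full float equality) are excluded from both counts
    but reported.  The p-value is P(X >= n_above) for X ~ Binomial(n, 1/2)
    with n = n_above + n_below, evaluated exactly via the regularized
    incomplete beta function; under a symmetric null it is uniform at its
    attainable values.  Accepts SnpEffectRecords or raw ratios.
    """
    ratios = _ratios(records)
    if ratios.size == 0:
        raise ValueError("asymmetry_test needs at least one record")
    above = ratios[ratios > 1.0]
    below = ratios[ratios < 1.0]
    n_above, n_below = above.size, below.size
    n = n_above + n_below
    if n == 0:
        raise ValueError("all ratios are exactly 1; no informative records")
    p = float(stats.binom.sf(n_above - 1, n, 0.5))
    return AsymmetrySummary(
        n_above=int(n_above),
        n_below=int(n_below),
        n_equal=int(ratios.size - n),
        p_value=p,
        mean_above=float(above.mean()) if n_above else float("nan"),
        mean_below=float(below.mean()) if n_below else float("nan"),
        mean_all=float(ratios.mean()),
    )


def distance_distribution(
    records: Sequence[SnpEffectRecord],
    strata: Sequence[str] = STRATA,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, dict]:
    """Signed variant-to-motif distances per fold-change stratum.

    For each stratum: the distance values, an integer-bin histogram, the
    population standard deviation, and its bootstrap standard error
    (``n_boot`` resamples, seeded).  Empty strata report std as None.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    for stratum in strata:
        d = np.asarray(
            [r.distance_nt for r in records if r.stratum == stratum], dtype=float
        )
        entry: dict = {"n": int(d.size), "distances": d}
        if d.size == 0:
            entry.update(std=None, std_se=None, hist=None)
        else:
            entry["std"] = float(d.std())
            boots = np.empty(n_boot)
            for b in range(n_boot):
                boots[b] = d[rng.integers(0, d.size, size=d.size)].std()
            entry["std_se"] = float(boots.std())
            lo, hi = int(d.min()), int(d.max())
            edges = np.arange(lo, hi + 2) - 0.5
            counts, _ = np.histogram(d, bins=edges)
            entry["hist"] = pd.DataFrame(
                {"distance_nt": np.arange(lo, hi + 1), "count": counts}
            )
        out[stratum] = entry
    return out


def cumulative_ratio_curves(records: Iterable) -> pd.DataFrame:
    """Cumulative counts over reciprocated ratios, split by direction.

    Ratios below 1 are reciprocated onto [1, inf); each curve reports, at
    every observed value x, how many of its ratios are <= x.  Ratios
    exactly 1 belong to neither curve.
    """
    ratios = _ratios(records)
    frames = []
    for name, vals in (
        ("above", ratios[ratios > 1.0]),
        ("below_reciprocated", 1.0 / ratios[ratios < 1.0]),
    ):
        v = np.sort(vals)
        frames.append(
            pd.DataFrame(
                {
                    "curve": name,
                    "ratio": v,
                    "cumulative_count": np.arange(1, v.size + 1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
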