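"""Readers and writers for the pipeline's standard formats.

Transcripts travel as FASTA (T normalized to U on read), variants as
minimal VCF 4.2 with CHROM holding the transcript id (or as a 4-column
TSV: transcript_id, pos_1based, ref, alt), binding sites as BED3+ in
0-based half-open transcript coordinates.  Output tables are
tab-separated, UTF-8, LF line endings, '.' for absent values, with headers
naming units.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fold import normalize_sequence
from .pipeline import AsymmetrySummary, BindingSite, SnpEffectRecord, SnpRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_snps",
    "read_sites",
    "write_vcf",
    "write_snps_tsv",
    "write_bed",
    "write_effects_tsv",
    "read_effects_tsv",
    "write_summary_tsv",
    "SnpReadResult",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {id: normalized RNA sequence}.

    Duplicate ids and empty files are errors; T/lowercase are normalized.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = normalize_sequence(str(rec.seq))
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 60) -> None:
    records = [
        SeqRecord(Seq(normalize_sequence(s)), id=tid, description="")
        for tid, s in seqs.items()
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass(frozen=True)
class SnpReadResult:
    records: list[SnpRecord]
    n_non_snv_skipped: int


def _read_snps_vcf(path: str | Path) -> SnpReadResult:
    from cyvcf2 import VCF

    records: list[SnpRecord] = []
    skipped = 0
    for v in VCF(str(path)):
        ref = v.REF.upper().replace("T", "U")
        if len(ref) != 1 or ref not in "ACGU":
            skipped += 1
            continue
        for alt in v.ALT:  # multi-allelic records split into biallelic SNVs
            alt = alt.upper().replace("T", "U")
            if len(alt) != 1 or alt not in "ACGU" or alt == ref:
                skipped += 1
                continue
            records.append(
                SnpRecord(
                    transcript_id=v.CHROM,
                    position=v.POS - 1,  # VCF POS is 1-based
                    ref=ref,
                    alt=alt,
                )
            )
    return SnpReadResult(records, skipped)


def _read_snps_tsv(path: str | Path) -> SnpReadResult:
    records: list[SnpRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (
                ln == 1 and line.lower().startswith("transcript")
            ):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated columns")
            tid, pos_s, ref, alt = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: position {pos_s!r} not an integer") from exc
            ref = ref.upper().replace("T", "U")
            alt = alt.upper().replace("T", "U")
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGU" or alt not in "ACGU":
                skipped += 1
                continue
            try:
                records.append(
                    SnpRecord(transcript_id=tid, position=pos - 1, ref=ref, alt=alt)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return SnpReadResult(records, skipped)


def read_snps(path: str | Path) -> SnpReadResult:
    """Variants from minimal VCF 4.x or the 4-column TSV dialect.

    1-based positions are converted to 0-based; multi-allelic VCF records
    are split into biallelic SNVs; non-SNV alleles are skipped and counted.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.suffix.lower() in (".vcf",):
        return _read_snps_vcf(path)
    return _read_snps_tsv(path)


def write_vcf(
    path: str | Path,
    snps: Sequence[SnpRecord],
    transcripts: Mapping[str, str] | None = None,
) -> None:
    """Minimal VCF 4.2 with CHROM = transcript id and 1-based POS."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if transcripts:
            for tid, seq in transcripts.items():
                fh.write(f"##contig=<ID={tid},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(
                f"{s.transcript_id}\t{s.position + 1}\t.\t{s.ref}\t{s.alt}\t.\t.\t.\n"
            )


def write_snps_tsv(path: str | Path, snps: Sequence[SnpRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("transcript_id\tpos_1based\tref\talt\n")
        for s in snps:
            fh.write(f"{s.transcript_id}\t{s.position + 1}\t{s.ref}\t{s.alt}\n")


def read_sites(path: str | Path) -> list[BindingSite]:
    """BED3+ (0-based half-open, transcript coordinates) -> BindingSites."""
    sites: list[BindingSite] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED needs at least 3 columns")
            tid, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{ln}: invalid interval [{start}, {end})")
            sites.append(BindingSite(transcript_id=tid, start=start, end=end))
    return sites


def write_bed(path: str | Path, sites: Sequence[BindingSite]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sites:
            fh.write(f"{s.transcript_id}\t{s.start}\t{s.end}\n")


_EFFECTS_COLUMNS = [
    "transcript_id",
    "snp_pos_nt",
    "ref",
    "alt",
    "site_start_nt",
    "site_end_nt",
    "motif_start_nt",
    "motif_end_nt",
    "window_start_nt",
    "window_end_nt",
    "kd_ref_nM",
    "kd_alt_nM",
    "affinity_ratio",
    "fold_change",
    "distance_nt",
    "stratum",
]


def write_effects_tsv(path: str | Path, records: Sequence[SnpEffectRecord]) -> None:
    rows = [
        {
            "transcript_id": r.snp.transcript_id,
            "snp_pos_nt": r.snp.position,
            "ref": r.snp.ref,
            "alt": r.snp.alt,
            "site_start_nt": r.site.start,
            "site_end_nt": r.site.end,
            "motif_start_nt": r.motif_interval[0],
            "motif_end_nt": r.motif_interval[1],
            "window_start_nt": r.window_interval[0],
            "window_end_nt": r.window_interval[1],
            "kd_ref_nM": repr(r.kd_ref_nM),
            "kd_alt_nM": repr(r.kd_alt_nM),
            "affinity_ratio": repr(r.affinity_ratio),
            "fold_change": repr(r.fold_change),
            "distance_nt": r.distance_nt,
            "stratum": r.stratum,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_EFFECTS_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_effects_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_EFFECTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_summary_tsv(path: str | Path, summary: AsymmetrySummary) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "n_ratios_above_1\tn_ratios_below_1\tn_ratios_equal_1\t"
            "binomial_p_value\tmean_ratio_above_1\tmean_ratio_below_1\tmean_ratio_all\n"
        )
        def fmt(x: float) -> str:
            return "." if x != x else repr(x)  # NaN -> '.'

        fh.write(
            f"{summary.n_above}\t{summary.n_below}\t{summary.n_equal}\t"
            f"{summary.p_value!r}\t{fmt(summary.mean_above)}\t"
            f"{fmt(summary.mean_below)}\t{fmt(summary.mean_all)}\n"
        )
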