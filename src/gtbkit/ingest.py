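"""Parse per-variant prediction scores into a uniform record stream.

Two input routes are supported: dbNSFP-style tab-delimited score tables
(1-based positions, ``;``-separated multi-transcript score cells aligned
with a transcript-id cell, ``.`` for missing) and VCF files whose INFO
fields carry numeric score annotations. Both routes emit
:class:`VariantScore` records — one raw score per (position, ref, alt,
transcript, algorithm) — plus a :class:`ParseReport` tallying skips and
warnings in aggregate, never one log line per record.

Coordinates in the records are 1-based, mirroring the tables they come
from; the single conversion to the internal 0-based half-open convention
happens when records are binned into a region (see
:func:`gtbkit.tolerance.build_profiles`).
"""

from __future__ import annotations

import io
import math
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Optional, Union

from .errors import FormatError
from .registry import Registry

_BASES = frozenset("ACGT")

#: Cap on individually stored warnings; counts keep accumulating past it.
_MAX_STORED_WARNINGS = 100


@dataclass(frozen=True)
class VariantScore:
    """One raw score for one (position, ref, alt, transcript, algorithm)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    algorithm_id: str
    raw: float
    transcript: Optional[str] = None


@dataclass
class ParseReport:
    """Aggregate tally of a parse run."""

    rows_seen: int = 0
    rows_skipped: int = 0
    records_emitted: int = 0
    warnings: list = field(default_factory=list)
    warning_counts: Counter = field(default_factory=Counter)

    def warn(self, line: Optional[int], message: str) -> None:
        self.warning_counts[message] += 1
        if len(self.warnings) < _MAX_STORED_WARNINGS:
            self.warnings.append((line, message))

    def summary(self) -> str:
        parts = [
            f"{self.rows_seen} rows seen",
            f"{self.rows_skipped} rows skipped",
            f"{self.records_emitted} records emitted",
        ]
        for msg, n in self.warning_counts.most_common():
            parts.append(f"{n}x {msg}")
        return "; ".join(parts)


def _open_text(source: Union[str, os.PathLike, IO[str]]):
    """Return (file-like, should_close)."""
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def _parse_float(token: str) -> Optional[float]:
    try:
        return float(token)
    except ValueError:
        return None


def read_dbnsfp_rows(
    source: Union[str, os.PathLike, IO[str]],
    registry: Registry,
    column_map: Mapping[str, str],
    *,
    chrom_col: str = "chr",
    pos_col: str = "pos",
    ref_col: str = "ref",
    alt_col: str = "alt",
    transcript_col: str = "transcript_id",
) -> tuple[list[VariantScore], ParseReport]:
    """Read a dbNSFP-style score table.

    Parameters
    ----------
    source:
        Path or text file-like. The header row may start with ``#``.
    registry:
        Active registry; every key of *column_map* must resolve in it.
    column_map:
        Maps algorithm id → score column name. Only mapped columns are
        read; the real dbNSFP release has hundreds of columns we ignore.

    Returns
    -------
    (records, report):
        One :class:`VariantScore` per non-missing (row, transcript,
        algorithm) score field. A ``;``-separated score cell must align
        field-for-field with the transcript cell; on length mismatch the
        row's fields for that algorithm are skipped with a warning.

    Raises
    ------
    FormatError
        If a required header column (coordinates or a mapped score
        column) is absent.
    """
    for alg_id in column_map:
        if alg_id not in registry:
            raise FormatError(f"column map names unknown algorithm id {alg_id!r}")

    records: list[VariantScore] = []
    report = ParseReport()
    fh, should_close = _open_text(source)
    try:
        header_line = fh.readline()
        if not header_line:
            raise FormatError("empty input: no header row")
        header = header_line.rstrip("\n").lstrip("#").split("\t")
        col_idx = {name: i for i, name in enumerate(header)}

        required = [chrom_col, pos_col, ref_col, alt_col] + list(column_map.values())
        missing = [c for c in required if c not in col_idx]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        tx_idx = col_idx.get(transcript_col)

        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            report.rows_seen += 1
            fields = line.split("\t")
            if len(fields) < len(header):
                report.rows_skipped += 1
                report.warn(lineno, "row has fewer fields than header")
                continue

            chrom = fields[col_idx[chrom_col]]
            pos = _parse_float(fields[col_idx[pos_col]])
            if pos is None or pos != int(pos) or int(pos) < 1:
                report.rows_skipped += 1
                report.warn(lineno, "unmappable position")
                continue
            pos = int(pos)
            ref = fields[col_idx[ref_col]].upper()
            alt = fields[col_idx[alt_col]].upper()
            if ref not in _BASES or alt not in _BASES or ref == alt:
                report.rows_skipped += 1
                report.warn(lineno, "not a SNV (ref/alt)")
                continue

            tx_fields: Optional[list[str]] = None
            if tx_idx is not None:
                tx_cell = fields[tx_idx]
                tx_fields = tx_cell.split(";") if tx_cell not in (".", "") else None

            emitted_any = False
            for alg_id, col in column_map.items():
                cell = fields[col_idx[col]]
                if cell in (".", ""):
                    continue
                values = cell.split(";")
                if len(values) > 1:
                    if tx_fields is None or len(tx_fields) != len(values):
                        report.warn(
                            lineno,
                            f"{col}: multi-value cell not aligned with transcripts",
                        )
                        continue
                    pairs = zip(tx_fields, values)
                elif tx_fields is not None and len(tx_fields) > 1:
                    report.warn(
                        lineno,
                        f"{col}: single value against {len(tx_fields)} transcripts",
                    )
                    continue
                else:
                    tx = tx_fields[0] if tx_fields else None
                    pairs = [(tx, values[0])]

                for tx, token in pairs:
                    if token in (".", ""):
                        continue
                    raw = _parse_float(token)
                    if raw is None:
                        report.warn(lineno, f"{col}: unparseable score field")
                        continue
                    records.append(
                        VariantScore(chrom, pos, ref, alt, alg_id, raw, tx)
                    )
                    report.records_emitted += 1
                    emitted_any = True
            del emitted_any
    finally:
        if should_close:
            fh.close()
    return records, report


def read_vcf_scores(
    path: Union[str, os.PathLike],
    registry: Registry,
    info_map: Mapping[str, str],
) -> tuple[list[VariantScore], ParseReport]:
    """Read numeric score annotations from VCF INFO fields.

    Only SNV alleles are considered; indels and other non-SNV records are
    skipped and tallied. Multi-allelic records expand per ALT allele, with
    multi-valued INFO fields split per allele (``,``-separated, one value
    per ALT). An absent INFO key produces no record and no warning.
    """
    from cyvcf2 import VCF

    for alg_id in info_map:
        if alg_id not in registry:
            raise FormatError(f"info map names unknown algorithm id {alg_id!r}")

    records: list[VariantScore] = []
    report = ParseReport()
    vcf = VCF(os.fspath(path))
    try:
        for variant in vcf:
            report.rows_seen += 1
            alts = variant.ALT or []
            snv_idx = [
                (i, a)
                for i, a in enumerate(alts)
                if len(variant.REF) == 1
                and len(a) == 1
                and variant.REF.upper() in _BASES
                and a.upper() in _BASES
                and a.upper() != variant.REF.upper()
            ]
            if not snv_idx:
                report.rows_skipped += 1
                report.warn(None, "non-SNV record skipped")
                continue

            for alg_id, key in info_map.items():
                value = variant.INFO.get(key)
                if value is None:
                    continue
                if isinstance(value, (tuple, list)):
                    tokens = [str(v) for v in value]
                else:
                    tokens = str(value).split(",")
                if len(tokens) == 1 and len(alts) > 1:
                    per_allele = {i: tokens[0] for i, _ in snv_idx}
                elif len(tokens) == len(alts):
                    per_allele = {i: tokens[i] for i, _ in snv_idx}
                else:
                    report.warn(None, f"{key}: value count does not match ALT count")
                    continue

                for i, alt in snv_idx:
                    raw = _parse_float(per_allele[i])
                    if raw is None or not math.isfinite(raw):
                        report.warn(None, f"{key}: unparseable or non-finite value")
                        continue
                    records.append(
                        VariantScore(
                            variant.CHROM,
                            variant.POS,
                            variant.REF.upper(),
                            alt.upper(),
                            alg_id,
                            raw,
                        )
                    )
                    report.records_emitted += 1
    finally:
        vcf.close()
    return records, report


def validate_stream(
    records: Iterable[VariantScore],
    registry: Registry,
    report: Optional[ParseReport] = None,
) -> Iterator[VariantScore]:
    """Pass through valid records; drop the rest with a warning tally.

    A record is valid when its algorithm id resolves in *registry* and its
    raw value is finite. Filtering, not failing: invalid records never
    raise.
    """
    if report is None:
        report = ParseReport()
    for rec in records:
        if rec.algorithm_id not in registry:
            report.warn(None, f"unknown algorithm id {rec.algorithm_id!r}")
            continue
        if not math.isfinite(rec.raw):
            report.warn(None, "non-finite raw score")
            continue
        yield rec
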