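"""Read and write genome-browser track formats for tolerance profiles.

All track output uses the 0-based half-open convention of BED, BedGraph
and bigWig. Missing bases are represented by the *absence* of intervals,
never by a sentinel value — 0 is a meaningful tolerance score. Adjacent
bases with (numerically) equal values are merged into single intervals on
write; merging is lossless for per-base queries.
"""

from __future__ import annotations

import os
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ConfigError, FormatError, UsageError
from .tolerance import Region, ToleranceProfile, TrackSet

ChromSizes = Mapping[str, int]

#: Values closer than this are considered equal when merging intervals.
MERGE_EPS = 1e-9


def read_chrom_sizes(source: Union[str, os.PathLike, IO[str]]) -> dict[str, int]:
    """Read a UCSC chrom.sizes file (two tab-separated columns)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        name = getattr(source, "name", "<chrom.sizes>")
    else:
        name = str(source)
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{name}:{lineno}: expected 'chrom<TAB>length'")
        try:
            length = int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{name}:{lineno}: non-integer length") from exc
        if length <= 0:
            raise FormatError(f"{name}:{lineno}: non-positive length")
        sizes[fields[0]] = length
    return sizes


def _runs(profile: ToleranceProfile) -> list[tuple[int, int, float]]:
    """Maximal (start, end, value) runs of equal-valued scored bases."""
    values = profile.values
    runs: list[tuple[int, int, float]] = []
    run_start: Optional[int] = None
    run_val = 0.0
    for i, v in enumerate(values):
        if np.isfinite(v):
            if run_start is not None and abs(v - run_val) <= MERGE_EPS:
                continue
            if run_start is not None:
                runs.append((run_start, i, run_val))
            run_start, run_val = i, float(v)
        else:
            if run_start is not None:
                runs.append((run_start, i, run_val))
                run_start = None
    if run_start is not None:
        runs.append((run_start, len(values), run_val))
    return [(profile.start + s, profile.start + e, v) for s, e, v in runs]


def write_bedgraph(profile: ToleranceProfile, sink: IO[str]) -> int:
    """Write a profile as 4-column BedGraph; returns intervals written.

    Adjacent equal values (within ``MERGE_EPS``) merge into one interval;
    missing slots produce no interval; output is sorted by start.
    """
    n = 0
    for s, e, v in _runs(profile):
        sink.write(f"{profile.chrom}\t{s}\t{e}\t{v:.6f}\n")
        n += 1
    return n


def write_bigwig(
    profile: ToleranceProfile,
    chrom_sizes: ChromSizes,
    path: Union[str, os.PathLike],
) -> None:
    """Write a profile as a bigWig file whose per-base values match it."""
    import pyBigWig

    if profile.chrom not in chrom_sizes:
        raise ConfigError(f"chromosome {profile.chrom!r} absent from chrom sizes")
    if profile.end > chrom_sizes[profile.chrom]:
        raise ConfigError(
            f"profile [{profile.start}, {profile.end}) overruns "
            f"{profile.chrom!r} (length {chrom_sizes[profile.chrom]})"
        )
    runs = _runs(profile)
    bw = pyBigWig.open(os.fspath(path), "w")
    try:
        bw.addHeader(sorted(chrom_sizes.items()))
        if runs:
            bw.addEntries(
                [profile.chrom] * len(runs),
                [s for s, _, _ in runs],
                ends=[e for _, e, _ in runs],
                values=[v for _, _, v in runs],
            )
    finally:
        bw.close()


def _read_bedgraph_intervals(
    source: Union[str, os.PathLike, IO[str]], chrom: str
) -> list[tuple[int, int, float]]:
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        name = getattr(source, "name", "<bedgraph>")
    else:
        name = str(source)
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    intervals: list[tuple[int, int, float]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{name}:{lineno}: expected 4 BedGraph columns")
        try:
            s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise FormatError(f"{name}:{lineno}: malformed BedGraph line") from exc
        if e <= s or s < 0:
            raise FormatError(f"{name}:{lineno}: invalid interval [{s}, {e})")
        if fields[0] == chrom:
            intervals.append((s, e, v))
    intervals.sort()
    for (s1, e1, _), (s2, _, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise FormatError(
                f"{name}: overlapping intervals at {chrom}:{s2} (previous ends {e1})"
            )
    return intervals


def read_track(
    source: Union[str, os.PathLike, IO[str]],
    format: str,
    region: Region,
    algorithm_id: Optional[str] = None,
) -> ToleranceProfile:
    """Read a BedGraph or bigWig track over *region* into a profile.

    Bases uncovered by any interval come back missing (NaN). Overlapping
    intervals in a BedGraph are a format error.
    """
    chrom, start, end = region
    if end <= start:
        raise UsageError("region end must exceed start")
    if algorithm_id is None:
        name = getattr(source, "name", None) or str(source)
        algorithm_id = os.path.splitext(os.path.basename(name))[0]
    values = np.full(end - start, np.nan)

    if format == "bedgraph":
        for s, e, v in _read_bedgraph_intervals(source, chrom):
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                values[lo - start : hi - start] = v
    elif format == "bigwig":
        import pyBigWig

        if hasattr(source, "read"):
            raise UsageError("bigwig input must be a file path")
        bw = pyBigWig.open(os.fspath(source))
        if bw is None:
            raise FormatError(f"cannot open bigWig file {source}")
        try:
            if chrom in bw.chroms():
                lo, hi = start, min(end, bw.chroms()[chrom])
                if lo < hi:
                    vals = bw.values(chrom, lo, hi, numpy=True)
                    # a bigWig with zero data intervals yields an empty array
                    if vals.size == hi - lo:
                        values[: hi - start] = vals
        except RuntimeError as exc:
            raise FormatError(f"malformed bigWig file {source}: {exc}") from exc
        finally:
            bw.close()
    else:
        raise UsageError(f"unknown track format {format!r}")

    return ToleranceProfile(algorithm_id, chrom, start, values)


def extract_region(tracks: TrackSet, region: Region) -> Optional[TrackSet]:
    """Slice a TrackSet to its intersection with *region*.

    Returns None (the empty-result signal) when the regions are disjoint
    or on different chromosomes; this is not an error.
    """
    chrom, start, end = region
    t_chrom, t_start, t_end = tracks.region
    if chrom != t_chrom:
        return None
    lo, hi = max(start, t_start), min(end, t_end)
    if lo >= hi:
        return None
    sub_region = (chrom, lo, hi)
    profiles = {
        key: ToleranceProfile(
            prof.algorithm_id,
            chrom,
            lo,
            prof.values[lo - t_start : hi - t_start].copy(),
        )
        for key, prof in tracks.profiles.items()
    }
    return TrackSet(region=sub_region, profiles=profiles)


def write_regions_bed(regions: Iterable, sink: IO[str]) -> int:
    """Write detected regions as BED6, sorted by (chrom, start).

    The BED score column is ``round(1000 * mean tolerance)``; names are
    ``roi_1``, ``roi_2``, … in output order.
    """
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    n = 0
    for k, r in enumerate(ordered, start=1):
        score = int(round(1000 * r.mean_score))
        sink.write(
            f"{r.chrom}\t{r.start}\t{r.end}\troi_{k}\t{score}\t.\n"
        )
        n += 1
    return n
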