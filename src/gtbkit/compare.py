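"""Compare tolerance tracks across algorithms and flag intolerant regions.

Reported inter-algorithm agreement in the literature spans the whole
range from near zero to near perfect correlation, so this module
quantifies it per region: Pearson and Spearman correlations plus mean
absolute difference over the bases both tracks score. Spearman is the
headline statistic in our docs because native score scales are non-linear
across methods — rank agreement is the fairer comparison.

A consensus profile (unweighted per-base mean across methods) feeds a
deliberately simple threshold/run-length detector for candidate
intolerant regions — long stretches of predicted intolerance supported by
multiple methods. The detector is a plain run scanner, not a statistical
caller: no significance is attached to its output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Optional

import numpy as np
from scipy import stats

from .errors import DomainError, UsageError
from .tolerance import ToleranceProfile, TrackSet


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement statistics between two profiles over shared scored bases.

    Correlations are None (undefined) when fewer than two bases are
    shared or either restricted vector is constant; ``mean_abs_diff`` is
    None only when no base is shared.
    """

    algorithm_a: str
    algorithm_b: str
    n_shared: int
    pearson_r: Optional[float]
    spearman_rho: Optional[float]
    mean_abs_diff: Optional[float]


@dataclass(frozen=True)
class IntolerantRegion:
    """A candidate intolerant interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    mean_score: float
    n_supporting_methods: int

    @property
    def length(self) -> int:
        return self.end - self.start


def pairwise_concordance(
    a: ToleranceProfile, b: ToleranceProfile
) -> ConcordanceResult:
    """Concordance between two profiles over the same region."""
    if a.region != b.region:
        raise UsageError(
            f"profiles cover different regions: {a.region} vs {b.region}"
        )
    mask = np.isfinite(a.values) & np.isfinite(b.values)
    n = int(mask.sum())
    va, vb = a.values[mask], b.values[mask]

    pearson = spearman = mad = None
    if n >= 1:
        mad = float(np.mean(np.abs(va - vb)))
    if n >= 2 and va.std() > 0 and vb.std() > 0:
        pearson = float(stats.pearsonr(va, vb).statistic)
        spearman = float(stats.spearmanr(va, vb).statistic)
    return ConcordanceResult(a.algorithm_id, b.algorithm_id, n, pearson, spearman, mad)


def concordance_matrix(
    tracks: TrackSet,
) -> dict[tuple[str, str], ConcordanceResult]:
    """All pairwise concordances, keyed by (id_a, id_b); symmetric."""
    ids = list(tracks.profiles)
    if len(ids) < 2:
        raise UsageError("concordance matrix needs at least 2 profiles")
    matrix: dict[tuple[str, str], ConcordanceResult] = {}
    for i, a in enumerate(ids):
        for b in ids[i:]:
            res = pairwise_concordance(tracks[a], tracks[b])
            matrix[(a, b)] = res
            if a != b:
                matrix[(b, a)] = ConcordanceResult(
                    b, a, res.n_shared, res.pearson_r, res.spearman_rho,
                    res.mean_abs_diff,
                )
    return matrix


def concordance_to_tsv(
    matrix: dict[tuple[str, str], ConcordanceResult], sink: IO[str]
) -> None:
    """Export a concordance matrix as long-form TSV."""
    sink.write(
        "algorithm_a\talgorithm_b\tn_shared\tpearson_r\tspearman_rho\tmean_abs_diff\n"
    )
    def fmt(x: Optional[float]) -> str:
        return "NA" if x is None else f"{x:.6f}"

    for (a, b), res in sorted(matrix.items()):
        sink.write(
            f"{a}\t{b}\t{res.n_shared}\t{fmt(res.pearson_r)}\t"
            f"{fmt(res.spearman_rho)}\t{fmt(res.mean_abs_diff)}\n"
        )


def consensus_profile(tracks: TrackSet, min_methods: int = 1) -> ToleranceProfile:
    """Unweighted per-base mean across the methods scoring each base.

    Bases scored by fewer than *min_methods* methods are missing in the
    output. The result is labelled ``"consensus"``; it is a convenience
    aggregate of this package, not a score defined by any single method.
    """
    if min_methods < 1:
        raise DomainError("min_methods must be >= 1")
    chrom, start, end = tracks.region
    span = end - start
    if not tracks.profiles:
        return ToleranceProfile("consensus", chrom, start, np.full(span, np.nan))
    stack = np.vstack([p.values for p in tracks])
    counts = np.isfinite(stack).sum(axis=0)
    sums = np.nansum(stack, axis=0)
    means = np.where(counts >= min_methods, sums / np.maximum(counts, 1), np.nan)
    return ToleranceProfile("consensus", chrom, start, means)


def method_counts(tracks: TrackSet) -> np.ndarray:
    """Number of methods scoring each base of the track set's region."""
    if not tracks.profiles:
        chrom, start, end = tracks.region
        return np.zeros(end - start, dtype=int)
    return np.isfinite(np.vstack([p.values for p in tracks])).sum(axis=0)


def detect_intolerant_regions(
    tracks: TrackSet,
    threshold: float,
    min_length: int,
    min_methods: int = 1,
    max_gap: int = 0,
) -> list[IntolerantRegion]:
    """Scan the consensus profile for runs of sustained intolerance.

    A base qualifies when its consensus value (over >= *min_methods*
    methods) is at least *threshold*. Maximal runs of qualifying bases —
    allowing interruptions of at most *max_gap* consecutive
    sub-threshold-or-missing bases — are kept when their total span is at
    least *min_length*. Regions are trimmed to qualifying bases at both
    ends, sorted, and non-overlapping.

    ``mean_score`` averages the qualifying (supra-threshold) bases only;
    ``n_supporting_methods`` is the minimum per-base method count over
    those bases.
    """
    if not 0.0 <= threshold <= 1.0:
        raise UsageError("threshold must lie in [0, 1]")
    if min_length < 1:
        raise UsageError("min_length must be >= 1")
    if max_gap < 0:
        raise UsageError("max_gap must be >= 0")

    consensus = consensus_profile(tracks, min_methods)
    counts = method_counts(tracks)
    chrom, start, _ = tracks.region
    values = consensus.values
    hits = np.flatnonzero(np.isfinite(values) & (values >= threshold))

    regions: list[IntolerantRegion] = []

    def close(run: list[int]) -> None:
        s, e = run[0], run[-1] + 1
        if e - s < min_length:
            return
        idx = np.asarray(run)
        regions.append(
            IntolerantRegion(
                chrom=chrom,
                start=start + s,
                end=start + e,
                mean_score=float(values[idx].mean()),
                n_supporting_methods=int(counts[idx].min()),
            )
        )

    run: list[int] = []
    for i in hits:
        if run and i - run[-1] - 1 > max_gap:
            close(run)
            run = []
        run.append(int(i))
    if run:
        close(run)
    return regions
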