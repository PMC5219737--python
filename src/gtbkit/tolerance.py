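"""Per-base genome tolerance from raw variant-effect scores.

The tolerance of a genomic base summarizes how damaging the substitutions
at that base are predicted to be. For each base we consider its three
possible single-nucleotide substitutions ("permutations" of the base);
each substitution may carry several raw scores, one per overlapping
transcript. Raw scores on an algorithm's native scale are min–max
normalized,

    u = (x - min) / (max - min),

clamped into the configured bounds beforehand, and flipped (``1 - u``)
for algorithms that report damage with *low* scores, so every normalized
value lies in [0, 1] with higher = less tolerant to mutation. Scores are
then averaged in two stages — across transcripts within a substitution,
then across the substitutions present — to give the per-base tolerance.
Substitutions with no score are excluded from the mean, never imputed.

Missing per-base values are represented as NaN throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .errors import DomainError, UsageError
from .ingest import ParseReport, VariantScore
from .registry import AlgorithmSpec, Registry

Region = tuple[str, int, int]  # chrom, start, end — 0-based half-open


@dataclass(frozen=True)
class PermutationGroup:
    """All raw scores for one substitution (one alt allele) at one base."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    algorithm_id: str
    raws: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.raws:
            raise DomainError("PermutationGroup needs at least one raw score")
        if self.alt == self.ref:
            raise DomainError("alt allele equals ref")
        if not all(math.isfinite(r) for r in self.raws):
            raise DomainError("non-finite raw score in permutation group")


@dataclass(eq=False)
class ToleranceProfile:
    """Per-base normalized tolerance over one contiguous region.

    ``values`` has one slot per base of the region (0-based half-open
    ``[start, start + len(values))``); missing slots are NaN, scored slots
    lie in [0, 1].
    """

    algorithm_id: str
    chrom: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        scored = self.values[np.isfinite(self.values)]
        if scored.size and (scored.min() < 0.0 or scored.max() > 1.0):
            raise DomainError(
                f"profile {self.algorithm_id!r} has values outside [0, 1]"
            )

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    @property
    def region(self) -> Region:
        return (self.chrom, self.start, self.end)

    @property
    def n_scored(self) -> int:
        return int(np.isfinite(self.values).sum())


@dataclass(eq=False)
class TrackSet:
    """Tolerance profiles for several algorithms over a common region."""

    region: Region
    profiles: dict[str, ToleranceProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        chrom, start, end = self.region
        if end <= start:
            raise DomainError("region end must exceed start")
        for key, prof in self.profiles.items():
            if prof.region != self.region:
                raise DomainError(
                    f"profile {key!r} region {prof.region} does not match "
                    f"track set region {self.region}"
                )

    def __iter__(self):
        return iter(self.profiles.values())

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, algorithm_id: str) -> ToleranceProfile:
        return self.profiles[algorithm_id]


def normalize_score(
    raw: Union[float, np.ndarray], spec: AlgorithmSpec
) -> Union[float, np.ndarray]:
    """Min–max normalize *raw* onto [0, 1], oriented higher = less tolerant.

    Values outside ``[spec.score_min, spec.score_max]`` are clamped first
    (relevant for empirical bounds). For ``lower_is_damaging`` algorithms
    the result is inverted so the orientation is uniform across tracks.

    Accepts a scalar or an ndarray; raises :class:`DomainError` on
    non-finite input.
    """
    arr = np.asarray(raw, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise DomainError("normalize_score requires finite raw input")
    clamped = np.clip(arr, spec.score_min, spec.score_max)
    u = (clamped - spec.score_min) / (spec.score_max - spec.score_min)
    if spec.direction == "lower_is_damaging":
        u = 1.0 - u
    if np.isscalar(raw) or arr.ndim == 0:
        return float(u)
    return u


def denormalize_score(
    value: Union[float, np.ndarray], spec: AlgorithmSpec
) -> Union[float, np.ndarray]:
    """Inverse of :func:`normalize_score` for values already in [0, 1]."""
    arr = np.asarray(value, dtype=np.float64)
    if ((arr < 0) | (arr > 1)).any():
        raise DomainError("denormalize_score requires values in [0, 1]")
    u = 1.0 - arr if spec.direction == "lower_is_damaging" else arr
    raw = spec.score_min + u * (spec.score_max - spec.score_min)
    if np.isscalar(value) or arr.ndim == 0:
        return float(raw)
    return raw


def site_tolerance(
    groups: Sequence[PermutationGroup], spec: AlgorithmSpec
) -> float:
    """Two-stage mean tolerance of one base for one algorithm.

    For each substitution, the mean of its normalized transcript scores;
    then the unweighted mean over the substitutions present. Substitutions
    absent from *groups* are excluded from the average.
    """
    if not groups:
        raise DomainError("site_tolerance requires at least one group")
    per_perm = [
        float(np.mean([normalize_score(r, spec) for r in g.raws])) for g in groups
    ]
    return float(np.mean(per_perm))


def build_profiles(
    records: Iterable[VariantScore],
    region: Region,
    registry: Registry,
    algorithms: Optional[Sequence[str]] = None,
    *,
    min_permutations: int = 1,
    report: Optional[ParseReport] = None,
) -> TrackSet:
    """Bin score records over *region* into per-algorithm tolerance profiles.

    Parameters
    ----------
    records:
        :class:`VariantScore` stream, in any order. Records outside the
        region (or for algorithms not requested) are ignored. Duplicate
        (pos, alt, transcript) records for an algorithm: last one wins,
        tallied as a warning in *report*.
    region:
        ``(chrom, start, end)``, 0-based half-open; record positions are
        1-based and converted here.
    algorithms:
        Algorithm ids to profile. Default: every id seen in the records
        within the region. Unknown ids raise :class:`UsageError`.
    min_permutations:
        Bases scored for fewer than this many of their 3 substitutions are
        masked as missing (default 1, i.e. keep everything scored).
    """
    chrom, start, end = region
    if end <= start:
        raise DomainError("region end must exceed start")
    if algorithms is not None:
        unknown = [a for a in algorithms if a not in registry]
        if unknown:
            raise UsageError(f"unknown algorithm id(s): {', '.join(unknown)}")
    if report is None:
        report = ParseReport()

    wanted = set(algorithms) if algorithms is not None else None
    span = end - start
    # per algorithm: {offset: {alt: {transcript: raw}}} — last write wins
    bins: dict[str, dict[int, dict[str, dict[Optional[str], float]]]] = {}

    for rec in records:
        if rec.chrom != chrom:
            continue
        offset = rec.pos - 1 - start  # the single 1-based -> 0-based conversion
        if not 0 <= offset < span:
            continue
        if wanted is not None and rec.algorithm_id not in wanted:
            continue
        if rec.algorithm_id not in registry:
            report.warn(None, f"unknown algorithm id {rec.algorithm_id!r}")
            continue
        alts = bins.setdefault(rec.algorithm_id, {}).setdefault(offset, {})
        txs = alts.setdefault(rec.alt, {})
        if rec.transcript in txs:
            report.warn(None, "duplicate record (pos, alt, transcript); last wins")
        txs[rec.transcript] = rec.raw

    ids = list(algorithms) if algorithms is not None else sorted(bins)
    profiles: dict[str, ToleranceProfile] = {}
    for alg_id in ids:
        spec = registry[alg_id]
        values = np.full(span, np.nan)
        for offset, alts in bins.get(alg_id, {}).items():
            if len(alts) < min_permutations:
                continue
            per_perm = [
                float(np.mean(normalize_score(np.array(list(txs.values())), spec)))
                for txs in alts.values()
            ]
            values[offset] = float(np.mean(per_perm))
        profiles[alg_id] = ToleranceProfile(alg_id, chrom, start, values)

    return TrackSet(region=region, profiles=profiles)
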