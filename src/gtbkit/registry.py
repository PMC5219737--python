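"""Catalogue of variant-effect prediction algorithms and conservation scores.

Every score that feeds a tolerance track needs three pieces of metadata
before it can be min–max normalized onto a common [0, 1] scale: the lower
and upper bounds of its native scale, and the direction in which damage is
reported (SIFT calls low scores damaging, PolyPhen-2 calls high scores
damaging). Bounds are either *theoretical* (the algorithm's scale is
defined on a closed interval, e.g. probabilities on [0, 1]) or *empirical*
(open-ended scores such as GERP++ or PhyloP, for which we ship published
observed ranges). Empirical bounds are honest defaults, not facts about
the algorithms; every field here can be overridden from a user-supplied
registry file via :func:`load_registry`.

Algorithms fall into four categories: generic non-synonymous predictors,
cancer-specific predictors, genome-wide predictors, and conservation
scores computed from multi-species alignments.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Optional, Union

from .errors import ConfigError, FormatError, UsageError

CATEGORIES = (
    "nonsynonymous_generic",
    "cancer_specific",
    "genome_wide",
    "conservation",
)

#: CLI-friendly shorthands for the category tokens.
CATEGORY_ALIASES = {
    "nonsynonymous": "nonsynonymous_generic",
    "generic": "nonsynonymous_generic",
    "cancer": "cancer_specific",
    "genome": "genome_wide",
    "genomewide": "genome_wide",
}

DIRECTIONS = ("higher_is_damaging", "lower_is_damaging")
BOUNDS_KINDS = ("theoretical", "empirical")

#: Default browser view: two popular non-synonymous predictors and two
#: genome-wide predictors.
DEFAULT_TRACK_IDS = ("sift", "polyphen2_humdiv", "fathmm_mkl_coding", "cadd")

_REGISTRY_COLUMNS = (
    "id",
    "display_name",
    "category",
    "score_min",
    "score_max",
    "direction",
    "bounds_kind",
    "notes",
)


@dataclass(frozen=True)
class AlgorithmSpec:
    """Metadata for one prediction algorithm or conservation score.

    Parameters
    ----------
    id:
        Short unique token, e.g. ``"sift"``.
    display_name:
        Human-readable name as printed in track legends.
    category:
        One of :data:`CATEGORIES`.
    score_min, score_max:
        Lower and upper bounds of the native score scale — the *min* and
        *max* of the normalization formula. ``score_min < score_max`` is
        required.
    direction:
        ``"higher_is_damaging"`` or ``"lower_is_damaging"``; decides
        whether normalization inverts the scale so that the output is
        always oriented "higher = less tolerant".
    bounds_kind:
        ``"theoretical"`` for closed native scales, ``"empirical"`` for
        observed ranges of unbounded scores.
    """

    id: str
    display_name: str
    category: str
    score_min: float
    score_max: float
    direction: str
    bounds_kind: str = "theoretical"
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ConfigError("algorithm id must be non-empty")
        if self.category not in CATEGORIES:
            raise ConfigError(
                f"unknown category {self.category!r} for {self.id!r}; "
                f"expected one of {', '.join(CATEGORIES)}"
            )
        if self.direction not in DIRECTIONS:
            raise ConfigError(
                f"unknown direction {self.direction!r} for {self.id!r}"
            )
        if self.bounds_kind not in BOUNDS_KINDS:
            raise ConfigError(
                f"unknown bounds_kind {self.bounds_kind!r} for {self.id!r}"
            )
        if not (math.isfinite(self.score_min) and math.isfinite(self.score_max)):
            raise ConfigError(f"non-finite bounds for {self.id!r}")
        if not self.score_min < self.score_max:
            raise ConfigError(
                f"score_min must be strictly below score_max for {self.id!r} "
                f"(got [{self.score_min}, {self.score_max}])"
            )


class Registry:
    """Ordered, id-unique collection of :class:`AlgorithmSpec` entries."""

    def __init__(self, entries: Iterable[AlgorithmSpec], source: str = "builtin"):
        self._entries: dict[str, AlgorithmSpec] = {}
        self.source = source
        for spec in entries:
            if spec.id in self._entries:
                raise ConfigError(f"duplicate algorithm id {spec.id!r}")
            self._entries[spec.id] = spec

    def __iter__(self) -> Iterator[AlgorithmSpec]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, algorithm_id: str) -> bool:
        return algorithm_id in self._entries

    def __getitem__(self, algorithm_id: str) -> AlgorithmSpec:
        try:
            return self._entries[algorithm_id]
        except KeyError:
            raise KeyError(f"unknown algorithm id {algorithm_id!r}") from None

    def get(self, algorithm_id: str) -> Optional[AlgorithmSpec]:
        """Return the entry for *algorithm_id*, or None if absent."""
        return self._entries.get(algorithm_id)

    def ids(self) -> list[str]:
        return list(self._entries)

    def extended(self, entries: Iterable[AlgorithmSpec], source: str) -> "Registry":
        """A new registry where *entries* override/extend this one by id."""
        merged = dict(self._entries)
        for spec in entries:
            merged[spec.id] = spec
        return Registry(merged.values(), source=source)

    def to_tsv(self, sink: IO[str]) -> None:
        """Serialize to the registry TSV dialect (round-trips exactly)."""
        sink.write("\t".join(_REGISTRY_COLUMNS) + "\n")
        for spec in self:
            sink.write(
                "\t".join(
                    [
                        spec.id,
                        spec.display_name,
                        spec.category,
                        repr(spec.score_min),
                        repr(spec.score_max),
                        spec.direction,
                        spec.bounds_kind,
                        spec.notes,
                    ]
                )
                + "\n"
            )


def _entry(
    id: str,
    display_name: str,
    category: str,
    lo: float,
    hi: float,
    direction: str,
    bounds_kind: str = "theoretical",
    notes: str = "",
) -> AlgorithmSpec:
    return AlgorithmSpec(id, display_name, category, lo, hi, direction, bounds_kind, notes)


def builtin_registry() -> Registry:
    """The built-in catalogue of supported algorithms and scores.

    Bounds and directions are package defaults (see the module docstring);
    empirical ranges follow the values published with each score's
    distribution. PolyPhen-2's two models, FATHMM's two weightings and each
    PhyloP lineage are separate entries because the browser displays them
    as distinct tracks.
    """
    g, c, w, v = CATEGORIES
    entries = [
        # Non-synonymous, generic
        _entry("sift", "SIFT", g, 0.0, 1.0, "lower_is_damaging"),
        _entry("polyphen2_humdiv", "PolyPhen-2 (HumDiv)", g, 0.0, 1.0, "higher_is_damaging"),
        _entry("polyphen2_humvar", "PolyPhen-2 (HumVar)", g, 0.0, 1.0, "higher_is_damaging"),
        _entry("mutation_assessor", "MutationAssessor", g, -5.14, 6.49, "higher_is_damaging", "empirical"),
        _entry("fathmm_unweighted", "FATHMM (Unweighted)", g, -16.13, 10.64, "lower_is_damaging", "empirical"),
        _entry("fathmm_weighted", "FATHMM (Weighted)", g, -16.13, 10.64, "lower_is_damaging", "empirical"),
        _entry("fathmm_mkl_coding", "FATHMM-MKL (Coding)", g, 0.0, 1.0, "higher_is_damaging"),
        _entry("mutationtaster2", "MutationTaster2", g, 0.0, 1.0, "higher_is_damaging", "theoretical",
               "continuous converted score; categorical labels ignored"),
        _entry("provean", "PROVEAN", g, -14.0, 14.0, "lower_is_damaging", "empirical"),
        _entry("vest", "VEST", g, 0.0, 1.0, "higher_is_damaging"),
        _entry("lrt", "LRT", g, 0.0, 1.0, "higher_is_damaging", "theoretical",
               "converted score; higher = more likely deleterious"),
        _entry("metalr", "MetaLR", g, 0.0, 1.0, "higher_is_damaging"),
        _entry("metasvm", "MetaSVM", g, -2.0, 3.0, "higher_is_damaging", "empirical"),
        # Cancer-specific
        _entry("transfic_sift", "TransFIC (SIFT)", c, -6.0, 6.0, "higher_is_damaging", "empirical"),
        _entry("transfic_polyphen2", "TransFIC (PolyPhen-2)", c, -6.0, 6.0, "higher_is_damaging", "empirical"),
        _entry("transfic_mutation_assessor", "TransFIC (MutationAssessor)", c, -6.0, 6.0, "higher_is_damaging", "empirical"),
        _entry("fathmm_cancer", "FATHMM (Cancer)", c, -16.13, 10.64, "lower_is_damaging", "empirical"),
        # Genome-wide
        _entry("cadd", "CADD", w, 0.0, 99.0, "higher_is_damaging", "empirical",
               "phred-scaled C-score clamped to an empirical range"),
        _entry("dann", "DANN", w, 0.0, 1.0, "higher_is_damaging"),
        _entry("fathmm_mkl_noncoding", "FATHMM-MKL (Non-coding)", w, 0.0, 1.0, "higher_is_damaging"),
        _entry("fitcons", "fitCons", w, 0.0, 1.0, "higher_is_damaging"),
        # Conservation scores
        _entry("phastcons_46way", "PhastCons (46-Way)", v, 0.0, 1.0, "higher_is_damaging"),
        _entry("phylop_46way_vertebrate", "PhyloP (46-Way, vertebrate)", v, -20.0, 10.0, "higher_is_damaging", "empirical"),
        _entry("phylop_46way_primate", "PhyloP (46-Way, primates)", v, -20.0, 10.0, "higher_is_damaging", "empirical"),
        _entry("phylop_46way_placental", "PhyloP (46-Way, placental mammals)", v, -20.0, 10.0, "higher_is_damaging", "empirical"),
        _entry("phastcons_100way", "PhastCons (100-Way)", v, 0.0, 1.0, "higher_is_damaging"),
        _entry("phylop_100way_vertebrate", "PhyloP (100-Way, vertebrate)", v, -20.0, 10.0, "higher_is_damaging", "empirical"),
        _entry("phylop_100way_primate", "PhyloP (100-Way, primates)", v, -20.0, 10.0, "higher_is_damaging", "empirical"),
        _entry("phylop_100way_placental", "PhyloP (100-Way, placental mammals)", v, -20.0, 10.0, "higher_is_damaging", "empirical"),
        _entry("gerp_pp", "GERP++", v, -12.3, 6.17, "higher_is_damaging", "empirical"),
        _entry("siphy", "SiPhy", v, 0.0, 37.9, "higher_is_damaging", "empirical"),
    ]
    return Registry(entries, source="builtin")


def _spec_from_mapping(obj: dict, where: str) -> AlgorithmSpec:
    missing = [k for k in _REGISTRY_COLUMNS[:7] if k not in obj]
    if missing:
        raise FormatError(f"{where}: missing field(s) {', '.join(missing)}")
    try:
        lo = float(obj["score_min"])
        hi = float(obj["score_max"])
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{where}: non-numeric bounds") from exc
    return AlgorithmSpec(
        id=str(obj["id"]),
        display_name=str(obj["display_name"]),
        category=str(obj["category"]),
        score_min=lo,
        score_max=hi,
        direction=str(obj["direction"]),
        bounds_kind=str(obj.get("bounds_kind", "theoretical")),
        notes=str(obj.get("notes", "")),
    )


def _parse_registry_text(text: str, name: str) -> list[AlgorithmSpec]:
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{name}: invalid JSON: {exc}") from exc
        if isinstance(data, dict):
            data = [data]
        return [_spec_from_mapping(obj, f"{name}: entry {i}") for i, obj in enumerate(data)]

    entries: list[AlgorithmSpec] = []
    header: Optional[list[str]] = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            unknown = [h for h in header if h not in _REGISTRY_COLUMNS]
            if unknown or "id" not in header:
                raise FormatError(
                    f"{name}:{lineno}: bad registry header; expected columns "
                    f"from {', '.join(_REGISTRY_COLUMNS)}"
                )
            continue
        if len(fields) < len(header) and len(fields) == len(header) - 1 and header[-1] == "notes":
            fields = fields + [""]
        if len(fields) != len(header):
            raise FormatError(
                f"{name}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        entries.append(_spec_from_mapping(dict(zip(header, fields)), f"{name}:{lineno}"))
    if header is None and not entries:
        return []
    return entries


def load_registry(
    source: Union[str, os.PathLike, IO[str]],
    base: Optional[Registry] = None,
) -> Registry:
    """Load a registry file (TSV or JSON), overriding/extending *base* by id.

    The TSV dialect has a header line ``id display_name category score_min
    score_max direction bounds_kind [notes]`` (tab-separated) and ``#``
    comment lines; the JSON form is an array of objects with the same keys.

    Raises
    ------
    FormatError
        On a malformed row (the message names the line).
    ConfigError
        On a duplicate id within *source* or invalid bounds/category.
    """
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
        name = getattr(source, "name", "<registry>")
    else:
        name = str(source)
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()

    entries = _parse_registry_text(text, name)
    seen: set[str] = set()
    for spec in entries:
        if spec.id in seen:
            raise ConfigError(f"{name}: duplicate algorithm id {spec.id!r}")
        seen.add(spec.id)

    if base is None:
        return Registry(entries, source=name)
    return base.extended(entries, source=name)


def normalize_category(token: str) -> str:
    """Resolve a category token or alias; raise UsageError if unknown."""
    if token in CATEGORIES:
        return token
    if token in CATEGORY_ALIASES:
        return CATEGORY_ALIASES[token]
    raise UsageError(
        f"unknown category {token!r}; expected one of "
        f"{', '.join(CATEGORIES)} (aliases: {', '.join(CATEGORY_ALIASES)})"
    )


def list_algorithms(
    registry: Registry, category: Optional[str] = None
) -> list[AlgorithmSpec]:
    """Entries of *registry*, optionally filtered by category, in order."""
    if category is None:
        return list(registry)
    cat = normalize_category(category)
    return [spec for spec in registry if spec.category == cat]
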