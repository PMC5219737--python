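"""Synthetic dbNSFP-style score tables with a planted tolerance signal.

The generator emulates the structure of a per-SNV score table: for every
base of a region it emits the three possible substitutions, each scored
by every simulated algorithm for every overlapping transcript. Scores are
built backwards from a known per-base latent intolerance profile
(background level plus rectangular "intolerant blocks"): Gaussian noise
is added on the normalized [0, 1] scale, the result clamped to [0, 1]
exactly as the analysis pipeline clamps, then mapped to each algorithm's
native scale by inverting the min–max normalization (including direction
inversion for lower-is-damaging scores). One shared noise draw per
(base, substitution, transcript) across methods — mixed with
method-private noise in proportion ``c : (1 - c)`` of the variance —
controls the expected inter-method correlation ``c``.

With zero noise and zero missingness the pipeline recovers the latent
profile exactly, which is the generator's core design invariant. What the
generator deliberately does not emulate: real gene structure, codon
effects, the behaviour of any actual predictor, or dbNSFP's full column
schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Optional, Sequence

import numpy as np

from .errors import ConfigError
from .registry import Registry
from .tolerance import denormalize_score

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic score table.

    Coordinates are 0-based half-open; latent ``blocks`` are
    ``(start, end, level)`` triples in absolute coordinates with levels in
    [0, 1]. ``blocks=None`` plants one default block of level 0.9 over the
    middle fifth of the region. ``noise_sd`` is the noise standard
    deviation on the normalized scale; ``inter_method_correlation`` is the
    fraction ``c`` of noise variance shared across methods.
    """

    chrom: str = "chr1"
    start: int = 0
    end: int = 1000
    algorithms: tuple[str, ...] = ("sift", "polyphen2_humdiv", "fathmm_mkl_coding", "cadd")
    background: float = 0.1
    blocks: Optional[tuple[tuple[int, int, float], ...]] = None
    noise_sd: float = 0.05
    inter_method_correlation: float = 0.8
    transcripts_per_site: int = 1
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigError("region end must exceed start")
        if not 0.0 <= self.background <= 1.0:
            raise ConfigError("background level must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0.0 <= self.inter_method_correlation <= 1.0:
            raise ConfigError("inter_method_correlation must lie in [0, 1]")
        if self.transcripts_per_site < 1:
            raise ConfigError("transcripts_per_site must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.blocks is None:
            span = self.end - self.start
            block = (self.start + (2 * span) // 5, self.start + (3 * span) // 5, 0.9)
            default = (block,) if block[1] > block[0] else ()
            object.__setattr__(self, "blocks", default)
        for s, e, level in self.blocks:
            if not (self.start <= s < e <= self.end):
                raise ConfigError(f"block [{s}, {e}) outside region")
            if not 0.0 <= level <= 1.0:
                raise ConfigError(f"block level {level} outside [0, 1]")


@dataclass
class SynthTruth:
    """Ground truth accompanying a generated table."""

    chrom: str
    start: int
    latent: np.ndarray
    planted_regions: list[tuple[int, int, float]]
    records: list[tuple] = field(default_factory=list)
    # (chrom, pos_1based, ref, alt, transcript, algorithm_id, raw)


def simulate_latent(config: SynthConfig) -> SynthTruth:
    """Build the per-base latent intolerance profile from the block spec."""
    span = config.end - config.start
    latent = np.full(span, config.background)
    occupied = np.zeros(span, dtype=bool)
    for s, e, level in config.blocks:
        sl = slice(s - config.start, e - config.start)
        if occupied[sl].any():
            raise ConfigError("latent blocks overlap")
        occupied[sl] = True
        latent[sl] = level
    return SynthTruth(
        chrom=config.chrom,
        start=config.start,
        latent=latent,
        planted_regions=[tuple(b) for b in config.blocks],
    )


def default_column_map(algorithms: Sequence[str]) -> dict[str, str]:
    """The column naming the generator uses: ``<id>_score``."""
    return {a: f"{a}_score" for a in algorithms}


def simulate_table(config: SynthConfig, registry: Registry) -> tuple[str, SynthTruth]:
    """Generate a dbNSFP-style table and its ground truth.

    The emitted text uses the ingest dialect: tab-separated, header
    ``#chr pos ref alt transcript_id <id>_score …``, 1-based positions,
    ``;``-joined multi-transcript cells aligned with ``transcript_id``,
    ``.`` for missing fields. Fully reproducible from ``config.seed``.
    """
    unknown = [a for a in config.algorithms if a not in registry]
    if unknown:
        raise ConfigError(f"unknown algorithm id(s): {', '.join(unknown)}")

    truth = simulate_latent(config)
    span = config.end - config.start
    n_alg = len(config.algorithms)
    n_tx = config.transcripts_per_site
    rng = np.random.default_rng(config.seed)

    ref_idx = rng.integers(0, 4, size=span)
    # normalized-scale targets, shape (alg, base, substitution, transcript)
    c = config.inter_method_correlation
    shared = rng.standard_normal((span, 3, n_tx))
    private = rng.standard_normal((n_alg, span, 3, n_tx))
    noise = config.noise_sd * (np.sqrt(c) * shared + np.sqrt(1.0 - c) * private)
    targets = np.clip(truth.latent[None, :, None, None] + noise, 0.0, 1.0)
    missing = rng.random((n_alg, span, 3, n_tx)) < config.missing_rate

    raws = np.empty_like(targets)
    for k, alg_id in enumerate(config.algorithms):
        raws[k] = denormalize_score(targets[k], registry[alg_id])

    tx_names = [f"T{t + 1}" for t in range(n_tx)]
    tx_cell = ";".join(tx_names)
    header = ["#chr", "pos", "ref", "alt", "transcript_id"] + [
        f"{a}_score" for a in config.algorithms
    ]
    lines = ["\t".join(header)]

    for i in range(span):
        ref = _BASES[ref_idx[i]]
        pos = config.start + i + 1  # 1-based output convention
        alts = [b for b in _BASES if b != ref]
        for j, alt in enumerate(alts):
            row = [config.chrom, str(pos), ref, alt, tx_cell]
            for k, alg_id in enumerate(config.algorithms):
                fields = []
                for t in range(n_tx):
                    if missing[k, i, j, t]:
                        fields.append(".")
                        continue
                    raw = float(raws[k, i, j, t])
                    fields.append(repr(raw))
                    truth.records.append(
                        (config.chrom, pos, str(ref), str(alt), tx_names[t], alg_id, raw)
                    )
                if all(f == "." for f in fields):
                    row.append(".")
                else:
                    row.append(";".join(fields))
            lines.append("\t".join(row))

    return "\n".join(lines) + "\n", truth


def write_truth_json(truth: SynthTruth, sink: IO[str]) -> None:
    """Write the truth sidecar (latent profile + planted blocks) as JSON."""
    json.dump(
        {
            "chrom": truth.chrom,
            "start": truth.start,
            "latent": [float(v) for v in truth.latent],
            "planted_regions": [
                {"start": s, "end": e, "level": level}
                for s, e, level in truth.planted_regions
            ],
        },
        sink,
        indent=0,
    )
    sink.write("\n")


# ---------------------------------------------------------------------------
# Small frozen fixture: 12 bases, 2 algorithms, no noise, no missingness.
# Generated once with simulate_table(FIXTURE_CONFIG, builtin_registry()) and
# frozen here so docs and smoke tests have a byte-stable input.

FIXTURE_CONFIG = SynthConfig(
    chrom="chrF",
    start=0,
    end=12,
    algorithms=("sift", "cadd"),
    background=0.2,
    blocks=((4, 8, 0.9),),
    noise_sd=0.0,
    inter_method_correlation=0.0,
    transcripts_per_site=2,
    missing_rate=0.0,
    seed=20170106,
)

# Frozen row data: (pos, ref, sift_cell_value, cadd_cell_value); each score
# cell repeats its value for the two transcripts T1;T2. The raw values are
# the exact denormalized images of latent 0.2 / 0.9 on each native scale
# (SIFT inverted: 1 - 0.2 = 0.8; CADD: 0.9 * 99 = 89.10000000000001).
_FIXTURE_ROWS: list[tuple[int, str, str, str]] = [
    (1, "G", "0.8", "19.8"),
    (2, "A", "0.8", "19.8"),
    (3, "G", "0.8", "19.8"),
    (4, "C", "0.8", "19.8"),
    (5, "G", "0.09999999999999998", "89.10000000000001"),
    (6, "C", "0.09999999999999998", "89.10000000000001"),
    (7, "C", "0.09999999999999998", "89.10000000000001"),
    (8, "G", "0.09999999999999998", "89.10000000000001"),
    (9, "T", "0.8", "19.8"),
    (10, "G", "0.8", "19.8"),
    (11, "C", "0.8", "19.8"),
    (12, "T", "0.8", "19.8"),
]

FIXTURE_TABLE = "\t".join(
    ["#chr", "pos", "ref", "alt", "transcript_id", "sift_score", "cadd_score"]
) + "\n" + "".join(
    f"chrF\t{pos}\t{ref}\t{alt}\tT1;T2\t{s};{s}\t{c};{c}\n"
    for pos, ref, s, c in _FIXTURE_ROWS
    for alt in "ACGT"
    if alt != ref
)

#: Expected per-base tolerance: both algorithms recover the latent exactly.
FIXTURE_EXPECTED = {
    "sift": [0.2] * 4 + [0.9] * 4 + [0.2] * 4,
    "cadd": [0.2] * 4 + [0.9] * 4 + [0.2] * 4,
}


def fixture_small() -> tuple[str, SynthTruth]:
    """A deterministic 12-base, 2-algorithm fixture for docs and smoke tests."""
    truth = simulate_latent(FIXTURE_CONFIG)
    return FIXTURE_TABLE, truth
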