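"""Core tolerance computation: normalization, two-stage means, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtbkit import (
    AlgorithmSpec,
    DomainError,
    PermutationGroup,
    UsageError,
    VariantScore,
    build_profiles,
    denormalize_score,
    normalize_score,
    site_tolerance,
)

UNIT_HI = AlgorithmSpec("hi", "Hi", "genome_wide", 0.0, 1.0, "higher_is_damaging")
UNIT_LO = AlgorithmSpec("lo", "Lo", "genome_wide", 0.0, 1.0, "lower_is_damaging")

spec_strategy = st.builds(
    lambda lo, width, direction: AlgorithmSpec(
        "s", "S", "genome_wide", lo, lo + width, direction, "empirical"
    ),
    lo=st.floats(-100, 100),
    width=st.floats(1e-3, 200),
    direction=st.sampled_from(["higher_is_damaging", "lower_is_damaging"]),
)


class TestNormalizeScore:
    @pytest.mark.parametrize(
        "raw,lo,hi,direction,expected",
        [
            (0.0, 0.0, 1.0, "lower_is_damaging", 1.0),   # SIFT most damaging
            (1.0, 0.0, 1.0, "higher_is_damaging", 1.0),  # PolyPhen-2 max
            (10.0, -10.0, 30.0, "higher_is_damaging", 0.5),
            (45.0, -10.0, 30.0, "higher_is_damaging", 1.0),  # clamped above max
            (-99.0, -10.0, 30.0, "higher_is_damaging", 0.0),  # clamped below min
        ],
    )
    def test_pinned_values(self, raw, lo, hi, direction, expected):
        spec = AlgorithmSpec("s", "S", "genome_wide", lo, hi, direction, "empirical")
        assert normalize_score(raw, spec) == pytest.approx(expected)

    def test_nonfinite_raw_rejected(self):
        with pytest.raises(DomainError):
            normalize_score(float("nan"), UNIT_HI)

    @settings(max_examples=200, derandomize=True)
    @given(raw=st.floats(-1e6, 1e6), spec=spec_strategy)
    def test_output_always_in_unit_interval(self, raw, spec):
        assert 0.0 <= normalize_score(raw, spec) <= 1.0

    @settings(max_examples=200, derandomize=True)
    @given(a=st.floats(-1e3, 1e3), b=st.floats(-1e3, 1e3), spec=spec_strategy)
    def test_monotone_in_declared_direction(self, a, b, spec):
        lo_raw, hi_raw = min(a, b), max(a, b)
        lo_n, hi_n = normalize_score(lo_raw, spec), normalize_score(hi_raw, spec)
        if spec.direction == "higher_is_damaging":
            assert lo_n <= hi_n
        else:
            assert lo_n >= hi_n

    @settings(max_examples=100, derandomize=True)
    @given(spec=spec_strategy)
    def test_endpoints_map_to_exact_zero_and_one(self, spec):
        at_min = normalize_score(spec.score_min, spec)
        at_max = normalize_score(spec.score_max, spec)
        if spec.direction == "higher_is_damaging":
            assert (at_min, at_max) == (0.0, 1.0)
        else:
            assert (at_min, at_max) == (1.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(value=st.floats(0, 1), spec=spec_strategy)
    def test_denormalize_is_right_inverse(self, value, spec):
        assert normalize_score(denormalize_score(value, spec), spec) == pytest.approx(
            value, abs=1e-9
        )


def _group(alt, raws):
    return PermutationGroup("chr1", 10, "A", alt, "hi", tuple(raws))


class TestSiteTolerance:
    def test_mean_of_three_substitutions(self):
        groups = [_group("C", [0.2]), _group("G", [0.4]), _group("T", [0.9])]
        assert site_tolerance(groups, UNIT_HI) == pytest.approx(0.5)

    def test_two_stage_mean_weights_substitutions_equally(self):
        # transcripts average first: (mean(0.2, 0.4) + 0.6) / 2 = 0.45
        groups = [_group("C", [0.2, 0.4]), _group("T", [0.6])]
        assert site_tolerance(groups, UNIT_HI) == pytest.approx(0.45)

    def test_single_score_is_identity(self):
        assert site_tolerance([_group("C", [0.7])], UNIT_HI) == pytest.approx(0.7)

    def test_empty_input_is_domain_error(self):
        with pytest.raises(DomainError):
            site_tolerance([], UNIT_HI)

    @settings(max_examples=100, derandomize=True)
    @given(
        raws=st.lists(
            st.lists(st.floats(0, 1), min_size=1, max_size=4), min_size=1, max_size=3
        ),
        data=st.data(),
    )
    def test_invariant_under_reordering(self, raws, data):
        alts = ["C", "G", "T"][: len(raws)]
        groups = [_group(a, r) for a, r in zip(alts, raws)]
        shuffled = data.draw(st.permutations(groups))
        shuffled = [
            PermutationGroup(g.chrom, g.pos, g.ref, g.alt, g.algorithm_id,
                             tuple(data.draw(st.permutations(list(g.raws)))))
            for g in shuffled
        ]
        assert site_tolerance(groups, UNIT_HI) == pytest.approx(
            site_tolerance(shuffled, UNIT_HI)
        )


def brute_force_profiles(records, region, registry, algorithms):
    """Independent flat re-implementation: group by (algorithm, pos, alt),
    min-max normalize inline, nested means, one value per scored base."""
    chrom, start, end = region
    out = {}
    for alg in algorithms:
        spec = registry[alg]
        by_pos = {}
        for r in records:
            if r.chrom != chrom or r.algorithm_id != alg:
                continue
            if not (start < r.pos <= end):
                continue
            by_pos.setdefault(r.pos, {}).setdefault(r.alt, {})[r.transcript] = r.raw
        values = np.full(end - start, np.nan)
        for pos, alts in by_pos.items():
            perm_means = []
            for txs in alts.values():
                normed = []
                for raw in txs.values():
                    x = min(max(raw, spec.score_min), spec.score_max)
                    u = (x - spec.score_min) / (spec.score_max - spec.score_min)
                    if spec.direction == "lower_is_damaging":
                        u = 1.0 - u
                    normed.append(u)
                perm_means.append(sum(normed) / len(normed))
            values[pos - 1 - start] = sum(perm_means) / len(perm_means)
        out[alg] = values
    return out


class TestBuildProfiles:
    def test_empty_stream_gives_all_missing_profiles(self, registry):
        ts = build_profiles([], ("chr1", 0, 50), registry, ["sift", "cadd"])
        assert set(ts.profiles) == {"sift", "cadd"}
        assert all(p.n_scored == 0 for p in ts)

    def test_single_sift_record_composes_with_normalization(self, registry):
        rec = VariantScore("chr1", 10, "A", "C", "sift", 0.0)
        ts = build_profiles([rec], ("chr1", 0, 20), registry, ["sift"])
        prof = ts["sift"]
        assert prof.n_scored == 1
        assert prof.values[9] == pytest.approx(1.0)  # SIFT 0.0 = most damaging

    def test_records_outside_region_ignored(self, registry):
        recs = [
            VariantScore("chr1", 5, "A", "C", "sift", 0.5),
            VariantScore("chr1", 500, "A", "C", "sift", 0.5),
            VariantScore("chr2", 5, "A", "C", "sift", 0.5),
        ]
        ts = build_profiles(recs, ("chr1", 0, 10), registry, ["sift"])
        assert ts["sift"].n_scored == 1

    def test_unknown_algorithm_filter_is_usage_error(self, registry):
        with pytest.raises(UsageError):
            build_profiles([], ("chr1", 0, 10), registry, ["mystery"])

    def test_min_permutations_masks_thin_positions(self, registry):
        recs = [
            VariantScore("chr1", 3, "A", "C", "cadd", 10.0),
            VariantScore("chr1", 7, "A", "C", "cadd", 10.0),
            VariantScore("chr1", 7, "A", "G", "cadd", 20.0),
        ]
        ts = build_profiles(recs, ("chr1", 0, 10), registry, ["cadd"],
                            min_permutations=2)
        assert np.isnan(ts["cadd"].values[2])
        assert np.isfinite(ts["cadd"].values[6])

    def test_duplicate_record_last_wins_with_warning(self, registry):
        from gtbkit.ingest import ParseReport

        recs = [
            VariantScore("chr1", 3, "A", "C", "cadd", 10.0, "T1"),
            VariantScore("chr1", 3, "A", "C", "cadd", 99.0, "T1"),
        ]
        report = ParseReport()
        ts = build_profiles(recs, ("chr1", 0, 10), registry, ["cadd"], report=report)
        assert ts["cadd"].values[2] == pytest.approx(1.0)
        assert sum(report.warning_counts.values()) == 1

    def test_matches_brute_force_on_random_instances(self, registry):
        rng = np.random.default_rng(42)
        algorithms = ["sift", "cadd", "gerp_pp"]
        for _ in range(20):
            n = int(rng.integers(1, 400))
            region = ("chr1", 0, 100)
            records = []
            for _ in range(n):
                alg = algorithms[rng.integers(0, 3)]
                spec = registry[alg]
                pos = int(rng.integers(1, 101))
                alt = "CGT"[rng.integers(0, 3)]
                tx = f"T{rng.integers(1, 4)}"
                width = spec.score_max - spec.score_min
                raw = float(spec.score_min + rng.uniform(-0.2, 1.2) * width)
                records.append(VariantScore("chr1", pos, "A", alt, alg, raw, tx))
            ts = build_profiles(records, region, registry, algorithms)
            expected = brute_force_profiles(records, region, registry, algorithms)
            for alg in algorithms:
                np.testing.assert_allclose(
                    ts[alg].values, expected[alg], atol=1e-12, equal_nan=True
                )

    def test_scored_slots_stay_in_unit_interval(self, registry):
        rng = np.random.default_rng(7)
        records = [
            VariantScore("chr1", int(rng.integers(1, 51)), "A", "C", "gerp_pp",
                         float(rng.normal(0, 30)))
            for _ in range(200)
        ]
        ts = build_profiles(records, ("chr1", 0, 50), registry, ["gerp_pp"])
        vals = ts["gerp_pp"].values
        scored = vals[np.isfinite(vals)]
        assert scored.size > 0
        assert scored.min() >= 0.0 and scored.max() <= 1.0
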