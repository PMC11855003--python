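"""Grand sums, the methylation z-score, its bands, and the gate search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylhit.io import GateRegion
from methylhit.mzs import (
    DegenerateCohortError,
    MethylationZScoreModel,
    build_cohort,
    classify_band,
    compute_mzs,
    optimize_gate,
    region_sum,
)
from conftest import make_profile


def brute_force_gate_search(profiles, positions, objective, min_cpg, max_cpg):
    """Independent oracle: double loop over every contiguous CpG window."""
    ratios = {
        p.sample_id: {s.pos: s.ratio for s in p.sites} for p in profiles
    }
    normals = [p.sample_id for p in profiles if p.group == "normal"]
    tumors = [p.sample_id for p in profiles if p.group == "tumor"]
    best = None
    n = len(positions)
    for length in range(min_cpg, max_cpg + 1):
        for start in range(n - length + 1):
            window = positions[start : start + length]
            nd = np.array([sum(ratios[s][p] for p in window) for s in normals])
            sd = nd.std(ddof=1)
            if sd < 1e-9:
                continue
            z = [(sum(ratios[t][p] for p in window) - nd.mean()) / sd for t in tumors]
            value = float(np.mean(z)) if objective == "mean_tumor_mzs" else float(max(z))
            key = (-value, length, start)
            if best is None or key < best[0]:
                best = (key, (start, length, value))
    return best[1]


class TestRegionSum:
    def test_empty_common_set_is_zero(self, profile_factory, wide_gate):
        p = profile_factory("s", "normal", [0.5] * 3)
        assert region_sum(p, wide_gate, []) == 0.0

    def test_all_ones_hits_upper_bound(self, profile_factory, wide_gate):
        p = profile_factory("s", "tumor", [1.0] * 10)
        positions = [s.pos for s in p.sites]
        assert region_sum(p, wide_gate, positions) == 10.0

    def test_matches_brute_force_addition(self, profile_factory, wide_gate):
        p = profile_factory("s", "tumor", [0.2, 0.5, 0.8])
        positions = [s.pos for s in p.sites]
        assert region_sum(p, wide_gate, positions) == pytest.approx(1.5)

    def test_missing_position_names_it(self, profile_factory, wide_gate):
        p = profile_factory("s", "tumor", [0.2, 0.5])
        with pytest.raises(KeyError, match="999"):
            region_sum(p, wide_gate, [100, 999])


class TestBuildCohort:
    def test_identical_coverage(self, profile_factory, wide_gate):
        profiles = [profile_factory(f"n{i}", "normal", [0.1 * i] * 5) for i in range(3)]
        cohort = build_cohort(profiles, wide_gate)
        assert cohort.n_cpg == 5

    def test_intersection_drops_uncovered_site(self, profile_factory, wide_gate):
        full = [profile_factory(f"n{i}", "normal", [0.5] * 5) for i in range(2)]
        partial = make_profile("n2", "normal", [0.5] * 4)  # misses the 5th site
        cohort = build_cohort(full + [partial], wide_gate)
        assert cohort.n_cpg == 4

    def test_staggered_coverage_equals_explicit_set_intersection(self, wide_gate):
        rng = np.random.default_rng(7)
        all_pos = list(range(100, 400, 10))
        profiles, kept_sets = [], []
        for i in range(4):
            keep = sorted(rng.choice(len(all_pos), size=24, replace=False))
            pos = [all_pos[k] for k in keep]
            from methylhit.io import CpGSite, MethylationProfile

            sites = [CpGSite("chr1", p, 0.5) for p in pos]
            profiles.append(MethylationProfile(f"n{i}", "normal", sites))
            kept_sets.append(set(pos))
        cohort = build_cohort(profiles, wide_gate)
        assert set(cohort.common_positions) == set.intersection(*kept_sets)

    def test_fewer_than_two_normals_rejected(self, profile_factory, wide_gate):
        p = profile_factory("n0", "normal", [0.5] * 3)
        t = profile_factory("t0", "tumor", [0.5] * 3)
        with pytest.raises(ValueError, match="normal"):
            build_cohort([p, t], wide_gate)

    def test_min_fraction_drops_incomplete_sample_with_warning(self, profile_factory, wide_gate):
        full = [profile_factory(f"n{i}", "normal", [0.5] * 10) for i in range(9)]
        partial = make_profile("n9", "normal", [0.5] * 8)
        with pytest.warns(UserWarning, match="n9"):
            cohort = build_cohort(full + [partial], wide_gate,
                                  site_policy="min_fraction", min_fraction=0.9)
        assert "n9" not in cohort.sample_ids
        assert cohort.n_cpg == 10


class TestComputeMzs:
    def test_tumor_at_normal_mean_scores_zero(self):
        res = compute_mzs(12.0, [10.0, 12.0, 14.0])
        assert res.mzs == pytest.approx(0.0)
        assert res.band == "none"

    def test_hand_computed_example(self):
        # normals (10, 12, 14): mean 12, sample sd 2; tumor 20 -> z = 4
        res = compute_mzs(20.0, [10.0, 12.0, 14.0])
        assert res.nd_mean == pytest.approx(12.0)
        assert res.nd_sd == pytest.approx(2.0)
        assert res.mzs == pytest.approx(4.0)
        assert res.band == "H"

    def test_constant_normals_degenerate(self):
        with pytest.raises(DegenerateCohortError):
            compute_mzs(5.0, [3.0, 3.0, 3.0])


class TestBands:
    @pytest.mark.parametrize(
        "mzs,band",
        [(-3.0, "none"), (0.0, "none"), (1.99, "none"), (2.0, "H"), (4.0, "H"),
         (4.999, "H"), (5.0, "VH"), (9.9, "VH"), (10.0, "EH"), (40.0, "EH")],
    )
    def test_half_open_boundaries(self, mzs, band):
        assert classify_band(mzs) == band

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_band(float("nan"))


class TestModel:
    def _cohort(self, rng, n_cpg=30, n_normal=8, n_tumor=4, shift=None):
        profiles = []
        for i in range(n_normal):
            profiles.append(make_profile(f"n{i}", "normal", rng.beta(5, 5, n_cpg)))
        for i in range(n_tumor):
            r = rng.beta(5, 5, n_cpg)
            if shift is not None:
                r = np.clip(r + shift, 0, 1)
            profiles.append(make_profile(f"t{i}", "tumor", r))
        return profiles

    def test_normal_cohort_self_scores_standardized(self, wide_gate):
        """Scoring each normal against the full cohort gives mean 0, sample sd 1."""
        rng = np.random.default_rng(3)
        res = MethylationZScoreModel(self._cohort(rng), wide_gate).fit()
        z = res.normal_zscores()
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_grand_sums_bounded_by_n_cpg(self, wide_gate):
        rng = np.random.default_rng(4)
        res = MethylationZScoreModel(self._cohort(rng), wide_gate).fit()
        assert all(0.0 <= r.td_sum <= r.n_cpg for r in res.results)

    def test_monotonicity_raising_a_tumor_cpg_never_lowers_its_mzs(self, wide_gate):
        rng = np.random.default_rng(5)
        profiles = self._cohort(rng)
        base = MethylationZScoreModel(profiles, wide_gate).fit()
        target = profiles[-1]
        for idx in (0, 7, 29):
            bumped_ratios = [
                min(1.0, s.ratio + 0.3) if i == idx else s.ratio
                for i, s in enumerate(target.sites)
            ]
            bumped = profiles[:-1] + [make_profile(target.sample_id, "tumor", bumped_ratios)]
            res = MethylationZScoreModel(bumped, wide_gate).fit()
            assert res.results[-1].mzs >= base.results[-1].mzs

    def test_summary_mentions_gate_and_samples(self, wide_gate):
        rng = np.random.default_rng(6)
        res = MethylationZScoreModel(self._cohort(rng), wide_gate).fit()
        text = res.summary()
        assert "wide" in text and "t0" in text and "band" in text.lower()


class TestOptimizeGate:
    def test_planted_signal_recovered_exactly(self):
        rng = np.random.default_rng(11)
        n_cpg = 100
        # normal cohort large enough that sd-estimation noise cannot move the
        # argmax off the planted window
        profiles = [
            make_profile(f"n{i}", "normal", rng.uniform(0.08, 0.12, n_cpg))
            for i in range(64)
        ]
        for i in range(3):
            r = rng.uniform(0.08, 0.12, n_cpg)
            r[10:20] += 0.6
            profiles.append(make_profile(f"t{i}", "tumor", r))
        region = GateRegion("search", "chr1", 0, 10_000)
        gate, value = optimize_gate(profiles, region, min_cpg=5, max_cpg=30)
        positions = [s.pos for s in profiles[0].sites]
        assert gate.start == positions[10]
        assert gate.end == positions[19] + 1
        assert value > 5

    @pytest.mark.parametrize("objective", ["mean_tumor_mzs", "max_tumor_mzs"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, objective, seed):
        rng = np.random.default_rng(seed)
        n_cpg = 40
        profiles = [
            make_profile(f"n{i}", "normal", rng.beta(3, 3, n_cpg)) for i in range(5)
        ] + [
            make_profile(f"t{i}", "tumor", rng.beta(3, 3, n_cpg)) for i in range(3)
        ]
        region = GateRegion("search", "chr1", 0, 10_000)
        min_cpg, max_cpg = 3, 15
        gate, value = optimize_gate(profiles, region, objective, min_cpg, max_cpg)
        positions = [s.pos for s in profiles[0].sites]
        start, length, expected = brute_force_gate_search(
            profiles, positions, objective, min_cpg, max_cpg
        )
        assert gate.start == positions[start]
        assert gate.end == positions[start + length - 1] + 1
        assert value == pytest.approx(expected, abs=1e-9)

    def test_exact_tie_returns_smallest_leftmost_window(self):
        # dyadic ratios make float sums exact: tumors sit exactly at the
        # normal mean everywhere, so every window scores exactly 0
        pattern_a = [0.25, 0.75] * 10
        pattern_b = [0.75, 0.25] * 10
        mean = [0.5] * 20
        profiles = [
            make_profile("n0", "normal", pattern_a),
            make_profile("n1", "normal", pattern_b),
            make_profile("t0", "tumor", mean),
        ]
        region = GateRegion("search", "chr1", 0, 10_000)
        gate, value = optimize_gate(profiles, region, min_cpg=3, max_cpg=10)
        positions = [s.pos for s in profiles[0].sites]
        assert value == 0.0
        assert gate.start == positions[0]
        assert gate.end == positions[2] + 1  # smallest admissible window, leftmost

    def test_large_normal_cohort_localizes_planted_event_precisely(self):
        """Window jitter is a cohort-size effect: with 128 normals the
        optimizer pins the planted window almost exactly."""
        from methylhit.synthdata import MethylSimConfig, simulate_methylation_cohort

        hits = 0
        for rep in range(10):
            cfg = MethylSimConfig(n_normal=128, seed=500 + rep)
            profiles, truth = simulate_methylation_cohort(cfg)
            gate, _ = optimize_gate(profiles, cfg.search_gate(), min_cpg=5, max_cpg=60)
            positions = cfg.positions()
            lo, hi = truth.event_window
            planted = set(range(lo, hi))
            recovered = {
                i for i, p in enumerate(positions) if gate.start <= p < gate.end
            }
            hits += len(planted & recovered) / len(planted | recovered) >= 0.8
        assert hits >= 9

    def test_no_admissible_window_errors(self):
        profiles = [
            make_profile("n0", "normal", [0.5] * 10),
            make_profile("n1", "normal", [0.5] * 10),
            make_profile("t0", "tumor", [0.9] * 10),
        ]
        region = GateRegion("search", "chr1", 0, 10_000)
        with pytest.raises(ValueError, match="admissible"):
            optimize_gate(profiles, region, min_cpg=3)
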