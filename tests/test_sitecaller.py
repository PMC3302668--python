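"""Kernel-density classification, extension, merging and the full caller."""

from __future__ import annotations

import math

import numpy as np
import pytest

from parclip.ingest import ReadGroup, build_read_groups
from parclip.sitecaller import (
    build_profile,
    call_sites,
    classify_positions,
    estimate_densities,
    extend_site,
    merge_spans,
    signal_runs,
)
from parclip.simulate import SimConfig, simulate_reads, simulate_reference

from conftest import make_read, random_profile


def naive_signal_offsets(x_tc, x_tt, depth, lam=3.0, min_depth=5):
    """Independent double-loop evaluation of the density classifier."""
    L = len(x_tc)

    def density(x):
        n = sum(x)
        if n == 0:
            return [0.0] * L
        f = [
            sum(x[i] / n * math.exp(-((i - j) ** 2) / (2 * lam * lam)) for i in range(L))
            for j in range(L)
        ]
        total = sum(f)
        return [v / total for v in f]

    if sum(x_tc) == 0:
        return set()
    if sum(x_tt) == 0:
        return {j for j in range(L) if depth[j] >= min_depth}
    k_tc, k_tt = density(x_tc), density(x_tt)
    return {j for j in range(L) if depth[j] >= min_depth and k_tc[j] > k_tt[j]}


class TestProfile:
    def test_hand_tallied_counts(self, flat_reference):
        # five identical reads over ACGT-repeat; one converts the T at 7
        reads = [make_read(f"r{i}", 0, 20, flat_reference,
                           conversions=[7] if i == 0 else [])
                 for i in range(5)]
        group = build_read_groups(reads)[0]
        profile = build_profile(group, flat_reference)
        assert profile.x_tc[7] == 1
        assert profile.x_tt[7] == 4
        assert profile.depth[7] == 5
        assert profile.x_tt[3] == 5  # unconverted T covered by all reads

    def test_no_reference_t_positions(self):
        reference = {"chr1": "ACG" * 20 + "AAAA"}
        reference = {"chr1": reference["chr1"].replace("T", "A")}
        reads = [make_read(f"r{i}", 0, 20, reference) for i in range(3)]
        profile = build_profile(build_read_groups(reads)[0], reference)
        assert profile.n_tc == 0 and profile.n_tt == 0

    def test_recurrent_conversion_single_location(self, flat_reference):
        reads = [make_read(f"r{i}", 0, 20, flat_reference, conversions=[11])
                 for i in range(5)]
        profile = build_profile(build_read_groups(reads)[0], flat_reference)
        assert profile.x_tc[11] == 5
        assert profile.n_conversion_locations == 1

    def test_counts_bounded_by_depth(self, flat_reference):
        reads = [make_read(f"r{i}", i, i + 20, flat_reference,
                           conversions=[7] if i < 3 else [])
                 for i in range(5)]
        profile = build_profile(build_read_groups(reads)[0], flat_reference)
        assert np.all(profile.x_tc + profile.x_tt <= profile.depth)
        assert np.all((profile.x_tc + profile.x_tt == 0) | profile.is_t)

    def test_empty_group_rejected(self):
        group = ReadGroup("chr1", "+", 0, 10, reads=[])
        with pytest.raises(ValueError):
            build_profile(group, {"chr1": "A" * 10})


class TestDensities:
    def _single_event_profile(self, L=11, at=5):
        import conftest

        rng = np.random.default_rng(0)
        profile = conftest.random_profile(rng, max_len=20)
        profile.x_tc = np.zeros(L, dtype=np.int64)
        profile.x_tt = np.zeros(L, dtype=np.int64)
        profile.depth = np.full(L, 5, dtype=np.int64)
        profile.is_t = np.ones(L, dtype=bool)
        profile.x_tc[at] = 1
        profile.group = ReadGroup("fix", "+", 0, L, reads=[])
        return profile

    def test_single_kernel_peak_and_symmetry(self):
        profile = self._single_event_profile()
        dens = estimate_densities(profile, lam=3.0)
        assert int(np.argmax(dens.k_tc)) == 5
        np.testing.assert_allclose(dens.k_tc[5 - 3: 5], dens.k_tc[6: 9][::-1])

    def test_kernel_ratio_is_gaussian(self):
        # normalization cancels: k(5)/k(2) = exp(3^2 / (2*3^2)) = exp(1/2)
        profile = self._single_event_profile()
        dens = estimate_densities(profile, lam=3.0)
        assert dens.k_tc[5] / dens.k_tc[2] == pytest.approx(math.exp(0.5), rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_densities_normalized(self, seed):
        profile = random_profile(np.random.default_rng(seed))
        dens = estimate_densities(profile)
        assert abs(dens.k_tc.sum() - 1.0) < 1e-9
        if profile.n_tt > 0:
            assert abs(dens.k_tt.sum() - 1.0) < 1e-9
        assert (dens.k_tc >= 0).all() and (dens.k_tt >= 0).all()

    def test_zero_length_rejected(self):
        profile = self._single_event_profile()
        profile.x_tc = np.zeros(0, dtype=np.int64)
        profile.x_tt = np.zeros(0, dtype=np.int64)
        with pytest.raises(ValueError):
            estimate_densities(profile)


class TestClassify:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_oracle(self, seed):
        profile = random_profile(np.random.default_rng(seed), max_len=120)
        dens = estimate_densities(profile)
        ours = set(classify_positions(profile, dens).tolist())
        oracle = naive_signal_offsets(profile.x_tc.tolist(), profile.x_tt.tolist(),
                                      profile.depth.tolist())
        assert ours == oracle

    def test_all_signal_when_no_nonconversions(self):
        profile = random_profile(np.random.default_rng(3))
        profile.x_tt = np.zeros_like(profile.x_tt)
        dens = estimate_densities(profile)
        expected = np.flatnonzero(profile.depth >= 5)
        np.testing.assert_array_equal(classify_positions(profile, dens), expected)

    def test_low_depth_excluded(self):
        profile = random_profile(np.random.default_rng(4))
        profile.depth = np.full(profile.length, 4, dtype=np.int64)
        dens = estimate_densities(profile)
        assert len(classify_positions(profile, dens, min_depth=5)) == 0

    def test_separated_signal_blocks(self):
        # conversion mass at the left end, non-conversions at the right:
        # signal must be one left-anchored run with a single crossover
        L = 40
        group = ReadGroup("fix", "+", 0, L, reads=[])
        x_tc = np.zeros(L, dtype=np.int64)
        x_tt = np.zeros(L, dtype=np.int64)
        x_tc[2:5] = 4
        x_tt[32:38] = 4
        profile_depth = np.full(L, 10, dtype=np.int64)
        from parclip.sitecaller import ConversionProfile

        profile = ConversionProfile(group, x_tc, x_tt, profile_depth,
                                    np.ones(L, dtype=bool))
        dens = estimate_densities(profile)
        offsets = classify_positions(profile, dens)
        runs = signal_runs(offsets)
        assert len(runs) == 1
        assert runs[0][0] == 0  # left-anchored
        assert runs[0][1] < L  # crossover before the right end


class TestExtension:
    def _uniform_profile(self, L=30, depth=10):
        group = ReadGroup("fix", "+", 0, L, reads=[])
        from parclip.sitecaller import ConversionProfile

        return ConversionProfile(
            group,
            np.zeros(L, dtype=np.int64), np.zeros(L, dtype=np.int64),
            np.full(L, depth, dtype=np.int64), np.ones(L, dtype=bool),
        )

    def test_fixed5_full_extension(self):
        profile = self._uniform_profile()
        assert extend_site((10, 15), profile, "fixed5") == (5, 20)

    def test_fixed5_depth_cliff(self):
        profile = self._uniform_profile()
        profile.depth[:8] = 4  # depth failure left of offset 8
        profile.depth[15:] = 4  # and right of the core
        assert extend_site((10, 15), profile, "fixed5") == (8, 15)

    def test_by_read_reaches_distal_read_end(self, flat_reference):
        reads = [make_read(f"r{i}", 8, 28, flat_reference, conversions=[15])
                 for i in range(5)]
        reads.append(make_read("long", 2, 30, flat_reference, conversions=[15]))
        group = build_read_groups(reads)[0]
        profile = build_profile(group, flat_reference)
        lo, hi = extend_site((10, 16), profile, "by_read", min_depth=1,
                             reference=flat_reference)
        assert (group.start + lo, group.start + hi) == (2, 30)

    def test_by_read_ignores_conversionless_reads(self, flat_reference):
        reads = [make_read(f"r{i}", 8, 28, flat_reference, conversions=[15])
                 for i in range(5)]
        reads.append(make_read("long", 2, 30, flat_reference))  # no conversion
        group = build_read_groups(reads)[0]
        profile = build_profile(group, flat_reference)
        lo, hi = extend_site((10, 16), profile, "by_read", min_depth=1,
                             reference=flat_reference)
        assert (group.start + lo, group.start + hi) == (8, 28)

    def test_merge_overlapping_and_disjoint(self):
        assert merge_spans([(0, 10), (9, 20)]) == [(0, 20)]
        assert merge_spans([(0, 10), (10, 20)]) == [(0, 10), (10, 20)]
        assert merge_spans([(0, 10), (8, 15), (14, 30)]) == [(0, 30)]


class TestCallSites:
    def _simulated(self, seed=1, **kw):
        config = SimConfig(seed=seed, **kw)
        reference, _, truth = simulate_reference(config)
        reads = simulate_reads(reference, truth, config)
        return build_read_groups(reads), reference, truth

    def test_group_filters(self, flat_reference):
        # four reads: below the five-read floor
        reads4 = [make_read(f"a{i}", 0, 20, flat_reference, conversions=[7, 11])
                  for i in range(4)]
        assert call_sites(build_read_groups(reads4), flat_reference) == []
        # five reads but a single conversion location
        reads5 = [make_read(f"b{i}", 0, 20, flat_reference, conversions=[7])
                  for i in range(5)]
        assert call_sites(build_read_groups(reads5), flat_reference) == []

    def test_two_hotspots_give_two_sites(self, flat_reference):
        # hotspots at 7 and 47, 40 nt apart, inside one group
        reads = []
        for i in range(6):
            reads.append(make_read(f"l{i}", 0, 30, flat_reference, conversions=[7]))
            reads.append(make_read(f"r{i}", 28, 58, flat_reference, conversions=[47]))
            reads.append(make_read(f"m{i}", 10, 48, flat_reference))
        groups = build_read_groups(reads)
        assert len(groups) == 1
        sites = call_sites(groups, flat_reference)
        assert len(sites) == 2
        assert abs(sites[0].midpoint - 7) <= 3
        assert abs(sites[1].midpoint - 47) <= 3

    def test_sites_stay_inside_group_span(self):
        groups, reference, _ = self._simulated()
        sites = call_sites(groups, reference)
        for site in sites:
            assert site.group.start <= site.start < site.end <= site.group.end
            profile_depth = build_profile(site.group, reference).depth
            lo, hi = site.start - site.group.start, site.end - site.group.start
            assert (profile_depth[lo:hi] >= 1).all()

    def test_evidence_is_log2_conversions(self):
        groups, reference, _ = self._simulated()
        for site in call_sites(groups, reference):
            assert site.evidence == pytest.approx(math.log2(site.n_conversions))
            assert site.n_conversions >= 1

    def test_monotonic_in_thresholds(self):
        groups, reference, _ = self._simulated(seed=6)
        base = len(call_sites(groups, reference, min_reads=5,
                              min_conversion_locations=2))
        for min_reads, min_locs in [(8, 2), (5, 3), (10, 4)]:
            stricter = len(call_sites(groups, reference, min_reads=min_reads,
                                      min_conversion_locations=min_locs))
            assert stricter <= base

    @pytest.mark.parametrize("lam", [2.0, 3.0, 4.0, 5.0])
    def test_bandwidth_robustness(self, lam):
        """Planted-site recovery is stable across kernel bandwidths."""
        from parclip.simulate import recovery_metrics

        groups, reference, truth = self._simulated(seed=9)
        sites = call_sites(groups, reference, lam=lam)
        metrics = recovery_metrics(sites, truth, midpoint_tolerance=2)
        assert metrics["recall"] >= 0.85

    def test_relaxed_depth_mode_calls_superset(self, flat_reference):
        reads = [make_read(f"r{i}", i * 2, i * 2 + 20, flat_reference,
                           conversions=[11, 15]) for i in range(5)]
        groups = build_read_groups(reads)
        strict = call_sites(groups, flat_reference)
        relaxed = call_sites(groups, flat_reference, per_position_depth=False)
        assert len(relaxed) >= len(strict)
        assert len(relaxed) >= 1
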