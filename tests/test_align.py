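import pytest
from hypothesis import given, strategies as st

from trflptools import (
    align_profiles,
    correct_ambiguous,
    generate_synthetic_dataset,
    round_sizes,
    summarize_and_flag,
    SyntheticSpec,
)

from conftest import (
    TABLE4_PROFILES,
    TABLE5_PROFILES,
    TABLE6_PROFILES,
    TABLE7_PROFILES,
    make_profile,
    profiles_from,
)


def bin_sizes(alignment):
    return [sorted(b.sizes) for b in alignment.bins]


class TestMovingAverageAlignment:
    def test_two_profile_example_automatic(self):
        al = align_profiles(profiles_from(TABLE4_PROFILES), 1.0, 0.5)
        assert bin_sizes(al) == [
            [207.43, 208.26], [208.52], [432.71, 433.69], [433.84]
        ]

    def test_single_fragment_profiles_merge_into_two_bins(self):
        al = align_profiles(profiles_from(TABLE6_PROFILES), 1.0, 0.5)
        assert bin_sizes(al) == [[309.30, 309.61, 310.29], [310.31, 310.46, 311.18]]
        assert [round_sizes(b.mean_size) for b in al] == [309.73, 310.65]

    def test_single_profile_gets_one_bin_per_fragment(self):
        al = align_profiles([make_profile("only", [100, 100.4, 101])], 1.0, 0.5)
        assert bin_sizes(al) == [[100], [100.4], [101]]

    def test_z_extension_pulls_in_fragment_beyond_seed_range(self):
        # 100.0 and 100.9 seed the bin (within Y=1); the mean 100.45 brings
        # 101.3 (0.85 over the seed range but < Z=1 over the mean) inside
        profs = [make_profile("a", [100.0]), make_profile("b", [100.9]),
                 make_profile("c", [101.3])]
        al = align_profiles(profs, 1.0, 1.0)
        assert bin_sizes(al) == [[100.0, 100.9, 101.3]]
        # with no Z extension the third fragment opens its own bin
        al0 = align_profiles(profs, 1.0, 0.0)
        assert bin_sizes(al0) == [[100.0, 100.9], [101.3]]

    def test_one_fragment_per_profile_rule(self):
        profs = [make_profile("a", [100.0, 100.5]), make_profile("b", [100.2])]
        al = align_profiles(profs, 1.0, 0.5)
        assert bin_sizes(al) == [[100.0, 100.2], [100.5]]


class TestAmbiguityCorrection:
    def test_two_profile_example_corrected(self):
        al = align_profiles(profiles_from(TABLE4_PROFILES), 1.0, 0.5)
        cor, report = correct_ambiguous(al)
        assert bin_sizes(cor) == [
            [207.43], [208.26, 208.52], [432.71], [433.69, 433.84]
        ]
        assert report.n_moved == 2

    def test_four_profile_example_corrected(self):
        al = align_profiles(profiles_from(TABLE5_PROFILES), 1.0, 0.5)
        cor, _ = correct_ambiguous(al)
        assert bin_sizes(cor) == [[253.81, 254.11], [254.66, 254.87]]

    def test_well_separated_bins_untouched(self):
        profs = [make_profile("a", [100, 200]), make_profile("b", [100.1, 200.1])]
        al = align_profiles(profs, 1.0, 0.5)
        cor, report = correct_ambiguous(al)
        assert bin_sizes(cor) == bin_sizes(al)
        assert (report.n_flagged, report.n_moved) == (0, 0)

    def test_correction_preserves_fragment_count(self):
        al = align_profiles(profiles_from(TABLE4_PROFILES), 1.0, 0.5)
        cor, _ = correct_ambiguous(al)
        assert cor.n_peaks == al.n_peaks


class TestBinSummary:
    def test_close_bins_both_flagged(self):
        al = summarize_and_flag(align_profiles(profiles_from(TABLE6_PROFILES), 1.0, 0.5))
        assert [b.ambiguous for b in al] == [True, True]

    def test_correct_alignment_still_flagged(self):
        al = summarize_and_flag(align_profiles(profiles_from(TABLE7_PROFILES), 1.0, 0.5))
        stats = [
            (b.n_members, round_sizes(b.min_size), round_sizes(b.max_size),
             round_sizes(b.mean_size), b.ambiguous)
            for b in al
        ]
        assert stats == [
            (4, 162.99, 163.32, 163.16, True),
            (4, 164.10, 164.88, 164.48, True),
            (2, 166.18, 166.95, 166.57, True),
            (4, 167.77, 168.25, 168.05, True),
        ]

    def test_gap_exactly_y_not_flagged(self):
        profs = [make_profile("a", [100.0, 101.0])]
        al = summarize_and_flag(align_profiles(profs, 1.0, 0.5), y=1.0)
        assert [b.ambiguous for b in al] == [False, False]


@st.composite
def random_profiles(draw):
    profiles = []
    for i in range(draw(st.integers(1, 5))):
        n = draw(st.integers(0, 10))
        sizes = draw(st.sets(st.floats(50, 150, allow_nan=False), min_size=n, max_size=n))
        profiles.append(make_profile(f"p{i}", sorted(sizes)))
    return profiles


@given(random_profiles(), st.floats(0.1, 3), st.floats(0, 2))
def test_partition_and_multiplicity_invariants(profiles, y, z):
    al = align_profiles(profiles, y, z)
    seen = set()
    for b in al.bins:
        assert len(b.members) == len(set(b.members))  # <=1 per profile by key
        for name, peak in b.members.items():
            key = (name, peak.size)
            assert key not in seen
            seen.add(key)
    assert seen == {(p.name, q.size) for p in profiles for q in p}
    cor, _ = correct_ambiguous(al)
    assert cor.n_peaks == al.n_peaks
    # determinism
    again = align_profiles(profiles, y, z)
    assert bin_sizes(again) == bin_sizes(al)


def test_synthetic_recovery_one_bin_per_true_fragment():
    # fragments spaced > Y + Z with jitter well under Y/2 must come back as
    # exactly one full-membership bin each
    spec = SyntheticSpec(
        true_fragments=tuple((100.0 + 5 * k, 500.0) for k in range(12)),
        n_samples=3, n_replicates=2, size_jitter_sd=0.08, n_noise_peaks=0, seed=11,
    )
    ds = generate_synthetic_dataset(spec)
    al = align_profiles(list(ds), 1.0, 0.5)
    assert len(al) == 12
    assert all(b.n_members == len(ds) for b in al)
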