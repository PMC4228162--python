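import numpy as np
import pytest
from hypothesis import given, strategies as st

from trflptools import (
    ConsistencyError,
    SyntheticSpec,
    align_profiles,
    compare_alignments,
    correct_ambiguous,
    detect_systematic_shifts,
    generate_synthetic_dataset,
    recompute_sizes_with_reference,
)
from trflptools.align import Alignment, Bin
from trflptools.model import Peak

from conftest import make_profile


def aligned(profile_sizes, y=1.0, z=0.5):
    return align_profiles(
        [make_profile(name, sizes) for name, sizes in profile_sizes.items()], y, z
    )


class TestShiftDetection:
    def test_uniform_offset_is_systematic(self):
        al = aligned({"A": [100.0, 200.0, 300.0], "B": [100.3, 200.3, 300.3]})
        direction, report = detect_systematic_shifts(al)
        assert direction.loc["A", "B"] == -1
        assert direction.loc["B", "A"] == 1
        assert report.loc[0, "n_shared_bins"] == 3

    def test_mixed_signs_is_not_systematic(self):
        al = aligned({"A": [100.0, 200.0], "B": [100.2, 199.9]})
        direction, _ = detect_systematic_shifts(al)
        assert direction.loc["A", "B"] == 0

    def test_any_tie_is_not_systematic(self):
        al = aligned({"A": [100.0, 200.0], "B": [100.0, 200.3]})
        direction, _ = detect_systematic_shifts(al)
        assert direction.loc["A", "B"] == 0

    def test_grouping_limits_pairs(self):
        al = aligned({"A": [100.0], "B": [100.3], "C": [100.6]})
        direction, report = detect_systematic_shifts(al, groups=[["A", "B"]])
        assert direction.loc["A", "C"] == 0  # out of scope
        assert len(report) == 1

    def test_ambiguous_bins_excluded_on_request(self):
        al = aligned({"A": [100.0, 200.0], "B": [100.3, 199.9]})
        al.bins[1].ambiguous = True
        direction, _ = detect_systematic_shifts(al, exclude_ambiguous=True)
        assert direction.loc["A", "B"] == -1  # only the first bin counts

    @given(st.lists(st.lists(st.floats(50, 60), min_size=2, max_size=2),
                    min_size=2, max_size=5))
    def test_matrix_antisymmetric_zero_diagonal(self, size_rows):
        profiles = {}
        for i, (a, b) in enumerate(size_rows):
            lo, hi = sorted({round(a, 3), round(b, 3) + 20})
            profiles[f"p{i}"] = [lo, hi]
        al = aligned(profiles, y=100.0, z=0.0)
        direction, _ = detect_systematic_shifts(al)
        m = direction.to_numpy()
        assert (np.diag(m) == 0).all()
        assert (m == -m.T).all()


class TestReferenceResizing:
    def test_candidate_scores_hand_computed(self):
        # two replicates, three bins; only the third bin's relative sizes vary:
        # candidates 1 and 2 tie at sd({x, x+0.2}) = 0.2/sqrt(2), candidate 3
        # pays that twice; the tie breaks to the shortest mean size
        al = aligned({"R1": [100.0, 200.0, 300.0], "R2": [100.2, 200.2, 300.4]})
        profiles, choice = recompute_sizes_with_reference(al)
        scores = choice.candidates["sd_sum"].tolist()
        assert scores[0] == pytest.approx(0.2 / np.sqrt(2), rel=1e-9)
        assert scores[1] == pytest.approx(0.2 / np.sqrt(2), rel=1e-9)
        assert scores[2] == pytest.approx(0.4 / np.sqrt(2), rel=1e-9)
        assert choice.reference_bin == 0
        # anchor = mean(100.0, 100.2) = 100.1
        assert [p.size for p in profiles[0]] == pytest.approx([100.1, 200.1, 300.1])
        assert [p.size for p in profiles[1]] == pytest.approx([100.1, 200.1, 300.3])

    def test_identical_profiles_unchanged(self):
        al = aligned({"R1": [100.0, 200.0], "R2": [100.0, 200.0]})
        profiles, choice = recompute_sizes_with_reference(al)
        assert choice.sd_sum == 0
        for prof in profiles:
            assert [p.size for p in prof] == [100.0, 200.0]

    def test_uniform_shift_fully_absorbed(self):
        delta = 0.37
        al = aligned({"R1": [100.0, 200.0, 300.0],
                      "R2": [100.0 + delta, 200.0 + delta, 300.0 + delta]})
        profiles, _ = recompute_sizes_with_reference(al)
        for a, b in zip(profiles[0], profiles[1]):
            assert a.size == pytest.approx(b.size, abs=1e-9)

    def test_no_common_bin_is_an_error(self):
        al = aligned({"R1": [100.0], "R2": [300.0]})
        with pytest.raises(ConsistencyError, match="common"):
            recompute_sizes_with_reference(al)

    def test_source_size_preserves_identity(self):
        al = aligned({"R1": [100.0, 200.0], "R2": [100.4, 200.4]})
        profiles, _ = recompute_sizes_with_reference(al)
        assert [p.source_size for p in profiles[1]] == [100.4, 200.4]


class TestAlignmentComparison:
    def test_identical_alignments_no_differences(self):
        al = aligned({"A": [100.0, 200.0], "B": [100.2, 200.2]})
        n, _ = compare_alignments(al, al)
        assert n == 0

    def test_single_move_flags_mover_and_neighbours(self):
        a = Peak(100.0, 1, 1)
        b = Peak(100.3, 1, 1)
        c = Peak(101.0, 1, 1)
        orig = Alignment([Bin({"p1": a, "p2": b}), Bin({"p3": c})], ("p1", "p2", "p3"), 1, 0.5)
        moved = Alignment([Bin({"p1": a}), Bin({"p2": b, "p3": c})], ("p1", "p2", "p3"), 1, 0.5)
        n, flags = compare_alignments(orig, moved)
        assert n == 3
        assert flags["differs"].all()

    def test_mismatched_coverage_rejected(self):
        al1 = aligned({"A": [100.0]})
        al2 = aligned({"A": [100.0, 200.0]})
        with pytest.raises(ConsistencyError):
            compare_alignments(al1, al2)

    def test_resizing_unshifted_data_reproduces_alignment(self):
        # jitter < Y/2, spacing > Y + Z: the shift-corrected re-alignment must
        # equal the original corrected alignment bin for bin
        spec = SyntheticSpec(
            true_fragments=tuple((80.0 + 4 * k, 400.0) for k in range(10)),
            n_samples=2, n_replicates=2, size_jitter_sd=0.1,
            n_noise_peaks=0, seed=5,
        )
        ds = generate_synthetic_dataset(spec)
        al, _ = correct_ambiguous(align_profiles(list(ds), 1.0, 0.5))
        profiles, _ = recompute_sizes_with_reference(al)
        realigned, _ = correct_ambiguous(align_profiles(profiles, 1.0, 0.5))
        n, _ = compare_alignments(al, realigned)
        assert n == 0
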