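import math

import pytest
from hypothesis import given, strategies as st

from trflptools import (
    Dataset,
    Peak,
    fpt_normalize,
    tfn_normalize,
    tfn_normalize_replicates,
)
from trflptools.normalize import TFN_TOLERANCE, average_states

from conftest import make_profile


def heights_dataset(*profiles, n_replicates=None):
    made = [make_profile(f"p{i}", [100 * (j + 1) for j in range(len(h))], heights=h)
            for i, h in enumerate(profiles)]
    return Dataset(tuple(made), n_replicates=n_replicates)


class TestTFN:
    def test_single_scale_convergence(self):
        ds = heights_dataset([600, 400], [300, 200])
        out = tfn_normalize(ds, "height", pdt=50)
        assert [p.height for p in out.profiles[0]] == [300, 200]
        assert [p.height for p in out.profiles[1]] == [300, 200]

    def test_iteration_with_removal_terminates_below_tfmin(self):
        # Hand-stepped oracle: TF 1000 scaled by 0.5 -> {30, 470}; the peak at
        # 30 falls under the threshold of 50 and is removed; the new TF 470
        # undershoots TFmin 500, and the profile is never scaled back up.
        ds = heights_dataset([60, 940], [300, 200])
        out = tfn_normalize(ds, "height", pdt=50)
        assert [p.height for p in out.profiles[0]] == [470]
        assert [p.height for p in out.profiles[1]] == [300, 200]

    @pytest.mark.parametrize("variant", ["tfn-heights", "tfn-areas", "tfn-areas-lt",
                                         "fpt-heights", "fpt-areas"])
    def test_equal_totals_are_identity(self, variant):
        ds = heights_dataset([600, 400], [500, 500], [999, 1], n_replicates=1)
        # equal heights totals; make areas equal too (conftest default 1000 each)
        if variant == "tfn-heights":
            out = tfn_normalize(ds, "height", pdt=50)
        elif variant == "tfn-areas":
            out = tfn_normalize(ds, "area")
        elif variant == "tfn-areas-lt":
            out = tfn_normalize_replicates(ds, "area", area_scope="local")
        elif variant == "fpt-heights":
            out = fpt_normalize(ds, "height", 0.0)
        else:
            out = fpt_normalize(ds, "area", 0.0)
        for a, b in zip(out, ds):
            assert [(p.size, p.height, p.area) for p in a] == [
                (p.size, p.height, p.area) for p in b
            ]

    def test_scaling_keeps_height_area_proportional(self):
        ds = Dataset((
            make_profile("a", [100, 200], heights=[600, 400], areas=[6000, 4000]),
            make_profile("b", [100], heights=[500], areas=[5000]),
        ))
        out = tfn_normalize(ds, "height", pdt=50)
        peak = out.profiles[0].peaks[0]
        assert peak.area / peak.height == pytest.approx(10.0)

    def test_local_vs_global_area_threshold(self):
        # group 1 holds the dataset-wide smallest area; in group 2 the local
        # minimum is larger, so the LT variant spares a peak that the global
        # variant would also spare but judges against a smaller floor
        ds = Dataset((
            make_profile("s1.1", [100, 200], areas=[50, 1000], heights=[10, 10]),
            make_profile("s1.2", [100], areas=[800], heights=[10]),
            make_profile("s2.1", [100, 200], areas=[300, 2100], heights=[10, 10]),
            make_profile("s2.2", [100], areas=[1200], heights=[10]),
        ), n_samples=2, n_replicates=2)
        global_out = tfn_normalize_replicates(ds, "area", area_scope="global")
        local_out = tfn_normalize_replicates(ds, "area", area_scope="local")
        # s2.1 scales by 1200/2400 = 0.5 -> areas {150, 1050}; 150 >= 50
        # (global floor) but < 300 (local floor)
        assert [p.area for p in global_out["s2.1"]] == [150, 1050]
        assert [p.area for p in local_out["s2.1"]] == [1050]

    @given(st.lists(st.lists(st.floats(60, 5000), min_size=1, max_size=6),
                    min_size=2, max_size=5))
    def test_termination_invariants(self, height_lists):
        ds = heights_dataset(*height_lists)
        out = tfn_normalize(ds, "height", pdt=50)
        tf_min = min(p.total("height") for p in ds)
        argmin = min(ds, key=lambda p: p.total("height")).name
        for before, after in zip(ds, out):
            assert after.total("height") <= tf_min * (1 + TFN_TOLERANCE)
            assert all(p.height >= 50 for p in after)
            # scaling never increases any peak value
            before_by_size = {p.size: p for p in before}
            assert all(p.height <= before_by_size[p.size].height + 1e-9 for p in after)
        assert [p.height for p in out[argmin]] == [
            p.height for p in ds[argmin]
        ]

    def test_empty_profile_rejected(self):
        ds = Dataset((make_profile("a", []), make_profile("b", [100])))
        with pytest.raises(ValueError, match="no peaks"):
            tfn_normalize(ds, "height", pdt=50)


def test_average_states_matches_peaks_by_size():
    a = [Peak(100.0, 60.0, 600.0), Peak(200.0, 40.0, 400.0)]
    b = [Peak(100.0, 50.0, 500.0)]
    merged = average_states(a, b)
    assert [(p.size, p.height, p.area) for p in merged] == [
        (100.0, 55.0, 550.0),
        (200.0, 20.0, 200.0),  # present in one state: half its value, kept
    ]


class TestFPT:
    def test_removes_strictly_below_threshold_keeping_raw_values(self):
        ds = heights_dataset([980, 15, 5])
        out = fpt_normalize(ds, "height", 0.01)
        assert [p.height for p in out.profiles[0]] == [980, 15]

    def test_zero_threshold_is_identity(self):
        ds = heights_dataset([980, 15, 5])
        out = fpt_normalize(ds, "height", 0.0)
        assert [p.height for p in out.profiles[0]] == [980, 15, 5]

    def test_peak_exactly_at_threshold_kept(self):
        ds = heights_dataset([99, 1])
        out = fpt_normalize(ds, "height", 0.01)
        assert [p.height for p in out.profiles[0]] == [99, 1]

    @given(st.lists(st.lists(st.floats(1, 5000), min_size=1, max_size=8),
                    min_size=1, max_size=4),
           st.floats(0, 0.2))
    def test_idempotent(self, height_lists, fpt):
        ds = heights_dataset(*height_lists)
        try:
            once = fpt_normalize(ds, "height", fpt)
        except ValueError:
            return  # a profile lost every peak mid-way is out of scope here
        if any(len(p) == 0 for p in once):
            return
        twice = fpt_normalize(once, "height", fpt)
        assert [[p.height for p in pr] for pr in twice] == [
            [p.height for p in pr] for pr in once
        ]
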