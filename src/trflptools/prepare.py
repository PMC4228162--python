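"""Noise-threshold and analysis-range preparation of a raw dataset.

Peaks survive when their height is at or above the peak detection threshold
(PDT) and their size lies within the closed analysis range.  Filtering is
judged on height only — the parameter is a *height* detection threshold — and
a surviving peak keeps its area untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Dataset, ParameterError


@dataclass(frozen=True)
class PrepareReport:
    """Summary of the preparation step."""

    max_trfs_per_profile: int
    removed_below_pdt: int
    removed_out_of_range: int


def apply_threshold_and_range(
    dataset: Dataset, pdt: float, size_min: float, size_max: float
) -> tuple[Dataset, PrepareReport]:
    """Apply the peak detection threshold and size-range restriction.

    Keeps peaks with ``height >= pdt`` and ``size_min <= size <= size_max``
    (both bounds inclusive).  Profile order and names are preserved; profiles
    may come out empty.
    """
    if pdt < 0:
        raise ParameterError("pdt must be >= 0")
    if size_min >= size_max:
        raise ParameterError(f"size_min ({size_min}) must be < size_max ({size_max})")

    removed_pdt = 0
    removed_range = 0
    profiles = []
    for profile in dataset:
        kept = []
        for peak in profile:
            if peak.height < pdt:
                removed_pdt += 1
            elif not size_min <= peak.size <= size_max:
                removed_range += 1
            else:
                kept.append(peak)
        profiles.append(profile.with_peaks(kept))
    report = PrepareReport(
        max_trfs_per_profile=max((len(p) for p in profiles), default=0),
        removed_below_pdt=removed_pdt,
        removed_out_of_range=removed_range,
    )
    return dataset.with_profiles(profiles), report
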