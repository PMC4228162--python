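"""Collapse aligned replicate profiles into one consensus profile per sample.

A fragment enters the consensus when it is present in at least ``x_min`` of
the sample's replicates.  Its consensus size is the mean of the member
sizes; height and area are either the mean or the sum over the replicates in
which it is present (summing emulates pooling replicates before loading).
Averages are taken over the replicates holding the fragment, not zero-filled
over all replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

from .align import Alignment
from .model import Dataset, ParameterError, Peak, Profile, sample_stem

_COMBINES = ("average", "sum")


@dataclass(frozen=True)
class ConsensusRule:
    """Occurrence filter and combination rule for consensus building."""

    x_min: int = 2
    combine: str = "average"

    def __post_init__(self) -> None:
        if self.x_min < 1:
            raise ParameterError("X must be >= 1")
        if self.combine not in _COMBINES:
            raise ParameterError(f"combine must be one of {_COMBINES}")


def groups_from_names(
    names: Sequence[str], n_replicates: int | None = None
) -> list[tuple[str, list[str]]]:
    """Replicate groups from profile names.

    Uses the ``<sample>.<replicate>`` naming convention when every name
    follows it; otherwise falls back to consecutive chunks of
    ``n_replicates``.
    """
    stems = [sample_stem(n) for n in names]
    if all(s is not None for s in stems):
        groups: list[tuple[str, list[str]]] = []
        for name, stem in zip(names, stems):
            if groups and groups[-1][0] == stem:
                groups[-1][1].append(name)
            else:
                groups.append((stem, [name]))
        return groups
    if n_replicates is None:
        raise ParameterError(
            "profile names do not follow the '<sample>.<replicate>' convention; "
            "n_replicates is required"
        )
    if len(names) % n_replicates:
        raise ParameterError(
            f"{len(names)} profiles not divisible by n_replicates={n_replicates}"
        )
    return [
        (f"Sample {i // n_replicates + 1}", list(names[i : i + n_replicates]))
        for i in range(0, len(names), n_replicates)
    ]


def build_consensus(
    alignment: Alignment,
    groups: Sequence[tuple[str, Sequence[str]]],
    rule: ConsensusRule,
) -> Dataset:
    """One consensus profile per sample from an aligned replicate set."""
    known = set(alignment.profile_names)
    for sample, members in groups:
        missing = set(members) - known
        if missing:
            raise ParameterError(
                f"group {sample!r} names profiles absent from the alignment: {sorted(missing)}"
            )
        if rule.x_min > len(members):
            raise ParameterError(
                f"X={rule.x_min} exceeds the {len(members)} replicates of {sample!r}"
            )

    profiles = []
    for sample, members in groups:
        peaks = []
        for b in alignment.bins:
            present = [b.members[n] for n in members if n in b.members]
            if len(present) < rule.x_min:
                continue
            sizes = [p.size for p in present]
            heights = [p.height for p in present]
            areas = [p.area for p in present]
            if rule.combine == "average":
                height, area = fmean(heights), fmean(areas)
            else:
                height, area = sum(heights), sum(areas)
            peaks.append(Peak(fmean(sizes), height, area))
        profiles.append(Profile(sample, tuple(sorted(peaks, key=lambda p: p.size))))
    return Dataset(tuple(profiles), n_samples=len(profiles), n_replicates=1)
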