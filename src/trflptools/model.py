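"""Core domain types for T-RFLP fingerprint analysis.

A terminal restriction fragment (T-RF) appears in an electropherogram as a
peak characterised by its estimated size in bases, its height and its area
(both in fluorescence units).  A profile is the ordered set of peaks detected
in one sample loading; a dataset groups profiles, optionally into consecutive
replicate groups (all samples are assumed to have the same number of
replicates).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator, Sequence


class FormatError(ValueError):
    """Raised when an input table violates the expected block layout."""


class ParameterError(ValueError):
    """Raised when an analysis parameter violates its constraints."""


class ConsistencyError(ValueError):
    """Raised when two artifacts that must describe the same data disagree."""


def round_sizes(value: float, ndigits: int = 2) -> float:
    """Round half away from zero on the decimal representation.

    Reported fragment sizes are conventionally printed with two decimals.
    Plain ``round`` applies binary round-half-to-even, which turns e.g.
    166.565 into 166.56; decimal-aware rounding keeps 166.57.  Internal
    computation always uses full precision — this is display rounding only.
    """
    return float(Decimal(repr(value)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Peak:
    """One detected fragment: size in bases, height and area in fluorescence units.

    ``source_size`` carries the original size through size-recalculation steps
    so that a fragment keeps its identity after its size has been replaced by
    a reference-relative estimate.
    """

    size: float
    height: float
    area: float
    source_size: float | None = None

    def __post_init__(self) -> None:
        if not self.size > 0:
            raise ValueError(f"peak size must be positive, got {self.size}")
        if self.height < 0 or self.area < 0:
            raise ValueError("peak height and area must be non-negative")
        if self.height == 0 and self.area == 0:
            raise ValueError("a present peak must have height > 0 or area > 0")

    @property
    def identity(self) -> float:
        """Size under which this peak was originally observed."""
        return self.size if self.source_size is None else self.source_size

    def value(self, signal: str) -> float:
        if signal == "height":
            return self.height
        if signal == "area":
            return self.area
        raise ParameterError(f"signal must be 'height' or 'area', got {signal!r}")

    def scaled(self, factor: float) -> "Peak":
        """Scale both fluorescence signals by the same factor; size untouched."""
        return replace(self, height=self.height * factor, area=self.area * factor)


@dataclass(frozen=True)
class Profile:
    """One sample loading's peak list, ordered by strictly increasing size."""

    name: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("profile name must be non-empty")
        sizes = [p.size for p in self.peaks]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError(f"peak sizes of profile {self.name!r} must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def total(self, signal: str) -> float:
        """Total fluorescence: the sum of all peak heights (or areas)."""
        return sum(p.value(signal) for p in self.peaks)

    def with_peaks(self, peaks: Sequence[Peak]) -> "Profile":
        return Profile(self.name, tuple(sorted(peaks, key=lambda p: p.size)))


_REPLICATE_SUFFIX = re.compile(r"^(?P<stem>.*\S)\s*\.\s*\d+$")


def sample_stem(profile_name: str) -> str | None:
    """Sample name for a ``<sample>.<replicate>`` style profile name, else None."""
    m = _REPLICATE_SUFFIX.match(profile_name)
    return m.group("stem") if m else None


@dataclass(frozen=True)
class Dataset:
    """Ordered profiles with optional consecutive replicate grouping."""

    profiles: tuple[Profile, ...]
    n_samples: int | None = None
    n_replicates: int | None = None

    def __post_init__(self) -> None:
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate profile names: {dupes}")
        if self.n_replicates is not None:
            if self.n_replicates < 1:
                raise ValueError("n_replicates must be >= 1")
            if self.n_samples is not None and self.n_samples * self.n_replicates != len(names):
                raise ValueError(
                    f"{self.n_samples} samples x {self.n_replicates} replicates "
                    f"!= {len(names)} profiles"
                )

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[Profile]:
        return iter(self.profiles)

    def __getitem__(self, name: str) -> Profile:
        for p in self.profiles:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.profiles]

    def replicate_groups(self) -> list[tuple[str, tuple[Profile, ...]]]:
        """Consecutive replicate groups as (sample name, profiles).

        Sample names follow the ``<sample>.<replicate>`` convention when every
        member of a group shares the same stem; otherwise ``Sample <i>``.
        """
        if self.n_replicates is None:
            raise ParameterError("dataset has no replicate structure defined")
        if len(self.profiles) % self.n_replicates:
            raise ParameterError(
                f"{len(self.profiles)} profiles not divisible by n_replicates={self.n_replicates}"
            )
        groups = []
        for i in range(0, len(self.profiles), self.n_replicates):
            chunk = self.profiles[i : i + self.n_replicates]
            stems = {sample_stem(p.name) for p in chunk}
            stem = stems.pop() if len(stems) == 1 and None not in stems else None
            groups.append((stem or f"Sample {i // self.n_replicates + 1}", chunk))
        return groups

    def with_profiles(self, profiles: Sequence[Profile]) -> "Dataset":
        return Dataset(tuple(profiles), self.n_samples, self.n_replicates)


@dataclass(frozen=True)
class Params:
    """Analysis parameters.

    pdt
        Peak height detection threshold in fluorescence units; peaks with
        height below it are discarded during preparation and act as the
        minimum allowed height during total-fluorescence normalization.
    size_min, size_max
        Analysis range in bases, inclusive at both ends.
    y
        Alignment seed range: a fragment joins a fresh bin when it is less
        than ``y`` bases longer than the bin's seed.
    z
        Moving-average extension range: a fragment joins an existing bin when
        it is less than ``z`` bases longer than the bin's current mean size.
    x_min
        Minimum number of replicates a fragment must appear in to enter the
        consensus profile.
    fpt
        Fixed percentage threshold, as a fraction of total profile signal
        (0.01 means 1%).
    """

    pdt: float = 50.0
    size_min: float = 50.0
    size_max: float = 1020.0
    y: float = 1.0
    z: float = 0.5
    x_min: int = 2
    fpt: float = 0.01

    def __post_init__(self) -> None:
        if self.pdt < 0:
            raise ParameterError("pdt must be >= 0")
        if not (0 < self.size_min < self.size_max):
            raise ParameterError("need 0 < size_min < size_max")
        if not self.y > 0:
            raise ParameterError("Y must be > 0")
        if self.z < 0:
            raise ParameterError("Z must be >= 0")
        if self.x_min < 1:
            raise ParameterError("X must be >= 1")
        if not 0 <= self.fpt < 1:
            raise ParameterError("FPT must be in [0, 1)")
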