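"""Moving-average alignment of T-RFs across profiles.

Fragment size estimates vary between loadings, so deciding which peaks in
different profiles represent the same fragment is the central step of the
analysis.  The binning procedure is greedy and works from short fragments to
long:

1. The globally shortest unassigned fragment seeds a new bin.
2. Every unassigned fragment less than ``Y`` bases longer than the seed
   joins the bin — at most one per profile, shortest first.
3. The bin's mean size is computed and any unassigned fragment (from a
   profile not yet in the bin) less than ``Z`` bases longer than the mean is
   added, one at a time in ascending size order, recomputing the mean after
   each addition, until nothing more qualifies.
4. The next bin is seeded from the remaining fragments.

Because the procedure never looks ahead, a fragment lying between two
near-coincident fragments of other profiles can end up with the wrong
partner; :func:`correct_ambiguous` re-assigns such fragments to their
nearest neighbour.  :func:`summarize_and_flag` marks bins whose extremes
encroach on the neighbouring bin's alignment range, where a pairwise or
subset analysis could bin differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterator, Sequence

import pandas as pd

from .model import ConsistencyError, Dataset, ParameterError, Peak, Profile, round_sizes


@dataclass
class Bin:
    """One alignment bin: at most one fragment per profile."""

    members: dict[str, Peak]
    ambiguous: bool = False

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def sizes(self) -> list[float]:
        return [p.size for p in self.members.values()]

    @property
    def min_size(self) -> float:
        return min(self.sizes)

    @property
    def max_size(self) -> float:
        return max(self.sizes)

    @property
    def mean_size(self) -> float:
        return fmean(self.sizes)


@dataclass
class Alignment:
    """Ordered alignment bins over a fixed set of profiles."""

    bins: list[Bin]
    profile_names: tuple[str, ...]
    y: float
    z: float

    def __post_init__(self) -> None:
        for b in self.bins:
            unknown = set(b.members) - set(self.profile_names)
            if unknown:
                raise ValueError(f"bin members from unknown profiles: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self) -> Iterator[Bin]:
        return iter(self.bins)

    @property
    def n_peaks(self) -> int:
        return sum(b.n_members for b in self.bins)

    def peaks_of(self, profile_name: str) -> list[Peak]:
        return [b.members[profile_name] for b in self.bins if profile_name in b.members]

    def size_frame(self) -> pd.DataFrame:
        """Bin x profile matrix of member sizes (NaN where absent)."""
        data = {
            name: [b.members[name].size if name in b.members else float("nan") for b in self.bins]
            for name in self.profile_names
        }
        return pd.DataFrame(data, index=[f"T-RF {i + 1}" for i in range(len(self.bins))])

    def stats_frame(self) -> pd.DataFrame:
        """Per-bin summary table: member sizes, count, min/max/mean, ambiguity.

        Sizes are reported rounded to two decimals (half away from zero);
        internal values keep full precision.
        """
        rows = []
        for b in self.bins:
            row = {
                name: round_sizes(b.members[name].size) if name in b.members else None
                for name in self.profile_names
            }
            row["No of T-RFs"] = b.n_members
            row["Min size"] = round_sizes(b.min_size)
            row["Max size"] = round_sizes(b.max_size)
            row["Mean size"] = round_sizes(b.mean_size)
            row["Ambiguous"] = "Yes" if b.ambiguous else "No"
            rows.append(row)
        return pd.DataFrame(rows, index=[f"T-RF {i + 1}" for i in range(len(self.bins))])

    def to_dataset(self) -> Dataset:
        """Reassemble the member peaks into per-profile peak lists."""
        profiles = [Profile(n, tuple(sorted(self.peaks_of(n), key=lambda p: p.size)))
                    for n in self.profile_names]
        return Dataset(tuple(profiles))


def align_profiles(profiles: Sequence[Profile], y: float, z: float) -> Alignment:
    """Greedy moving-average binning of all fragments across profiles."""
    if not y > 0:
        raise ParameterError("Y must be > 0")
    if z < 0:
        raise ParameterError("Z must be >= 0")
    names = tuple(p.name for p in profiles)
    if len(set(names)) != len(names):
        raise ValueError("profile names must be unique")

    records: list[tuple[float, int, Peak]] = []
    for pi, prof in enumerate(profiles):
        for peak in prof.peaks:
            records.append((peak.size, pi, peak))
    records.sort(key=lambda r: (r[0], r[1]))

    assigned = [False] * len(records)
    bins: list[Bin] = []
    cursor = 0
    n_left = len(records)
    while n_left:
        while assigned[cursor]:
            cursor += 1
        seed_size, seed_pi, _ = records[cursor]
        member_idx = [cursor]
        represented = {seed_pi}
        assigned[cursor] = True
        # seed range: strictly less than Y longer than the seed, one fragment
        # per profile — the shortest wins, later ones seed subsequent bins
        for j in range(cursor + 1, len(records)):
            size, pi, _ = records[j]
            if size - seed_size >= y:
                break
            if assigned[j] or pi in represented:
                continue
            member_idx.append(j)
            represented.add(pi)
            assigned[j] = True
        # moving-average extension: strictly less than Z longer than the
        # current mean, one at a time, mean recomputed after each addition
        while True:
            mean = fmean(records[j][0] for j in member_idx)
            added = False
            for j in range(cursor + 1, len(records)):
                if assigned[j]:
                    continue
                size, pi, _ = records[j]
                if size - mean >= z:
                    break
                if pi in represented:
                    continue
                member_idx.append(j)
                represented.add(pi)
                assigned[j] = True
                added = True
                break
            if not added:
                break
        bins.append(
            Bin({names[records[j][1]]: records[j][2]
                 for j in sorted(member_idx, key=lambda j: records[j][1])})
        )
        n_left -= len(member_idx)

    bins.sort(key=lambda b: b.mean_size)
    return Alignment(bins, names, y, z)


@dataclass(frozen=True)
class CorrectionReport:
    """Outcome of the ambiguous-alignment correction."""

    n_flagged: int
    n_moved: int
    flagged: tuple[tuple[str, float], ...] = ()
    moved: tuple[tuple[str, float], ...] = ()


def correct_ambiguous(alignment: Alignment, y: float | None = None) -> tuple[Alignment, CorrectionReport]:
    """Re-assign fragments caught between two close fragments of other profiles.

    A fragment is flagged when it lies strictly within ``y`` bases of both a
    shorter and a longer fragment belonging to other profiles.  Each flagged
    fragment is re-assigned to the bin holding its nearest neighbour (by
    absolute size difference) unless its own profile is already represented
    there; size, height and area move together.  Correction is single-pass:
    flags are determined on the input alignment.
    """
    if y is None:
        y = alignment.y
    entries = [
        (name, peak, bi)
        for bi, b in enumerate(alignment.bins)
        for name, peak in b.members.items()
    ]
    all_sorted = sorted(entries, key=lambda e: (e[1].size, e[0]))

    flagged = []
    for name, peak, bi in all_sorted:
        has_shorter = any(
            o_name != name and o_peak.size < peak.size and peak.size - o_peak.size < y
            for o_name, o_peak, _ in all_sorted
        )
        has_longer = any(
            o_name != name and o_peak.size > peak.size and o_peak.size - peak.size < y
            for o_name, o_peak, _ in all_sorted
        )
        if has_shorter and has_longer:
            flagged.append((name, peak, bi))

    members = [dict(b.members) for b in alignment.bins]
    current_bin = {(name, peak.size): bi for name, peak, bi in entries}
    moved = []
    for name, peak, _ in flagged:
        neighbours = [
            (abs(o_peak.size - peak.size), o_peak.size, o_name)
            for o_name, o_peak, _ in all_sorted
            if o_name != name
        ]
        _, n_size, n_name = min(neighbours)
        target = current_bin[(n_name, n_size)]
        source = current_bin[(name, peak.size)]
        if target != source and name not in members[target]:
            del members[source][name]
            members[target][name] = peak
            current_bin[(name, peak.size)] = target
            moved.append((name, peak.size))

    bins = [Bin(m) for m in members if m]
    bins.sort(key=lambda b: b.mean_size)
    report = CorrectionReport(
        n_flagged=len(flagged),
        n_moved=len(moved),
        flagged=tuple((name, p.size) for name, p, _ in flagged),
        moved=tuple(moved),
    )
    return Alignment(bins, alignment.profile_names, alignment.y, alignment.z), report


def summarize_and_flag(alignment: Alignment, y: float | None = None) -> Alignment:
    """Flag adjacent bin pairs whose ranges encroach within ``y`` bases.

    A bin pair is ambiguous when the shortest fragment of the following bin
    is strictly less than ``y`` bases longer than the longest fragment of the
    current bin; both bins of an offending pair are flagged.
    """
    if y is None:
        y = alignment.y
    bins = sorted(
        (Bin(dict(b.members), ambiguous=False) for b in alignment.bins),
        key=lambda b: b.mean_size,
    )
    for cur, nxt in zip(bins, bins[1:]):
        if nxt.min_size - cur.max_size < y:
            cur.ambiguous = True
            nxt.ambiguous = True
    return Alignment(bins, alignment.profile_names, alignment.y, alignment.z)
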