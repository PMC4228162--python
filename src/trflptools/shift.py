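"""Detection and correction of systematic size-estimation shifts.

Size calling drifts between capillary loadings: one loading may report every
fragment slightly shorter than another.  Over the bins two profiles share, a
*systematic shift* is declared when every size difference has the same sign.
The correction re-expresses every profile's sizes relative to a reference
fragment common to all profiles — the candidate minimizing the summed
within-bin standard deviation of relative sizes — which absorbs any constant
per-profile offset.  The shift-corrected sizes are then re-aligned and the
re-alignment compared with the original; applying a correction to the
original alignment is left to the analyst.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

import numpy as np
import pandas as pd

from .align import Alignment, Bin
from .model import ConsistencyError, Peak, Profile

#: Relative slack under which two candidate reference scores count as tied.
_TIE_RTOL = 1e-9


def detect_systematic_shifts(
    alignment: Alignment,
    groups: Sequence[Sequence[str]] | None = None,
    exclude_ambiguous: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise systematic-shift directions between profiles.

    ``groups`` limits comparison to pairs within each group (e.g. replicates
    of the same sample); ``None`` compares all pairs.  With
    ``exclude_ambiguous`` bins flagged ambiguous are disregarded.

    Returns the direction matrix — entry (a, b) is -1 when every shared-bin
    fragment of ``a`` is shorter than ``b``'s, +1 when longer, else 0 (mixed
    signs, a tie, no shared bins, or out of scope) — and a per-pair report.
    """
    names = list(alignment.profile_names)
    if groups is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    else:
        pairs = []
        for group in groups:
            members = [n for n in group if n in names]
            pairs.extend((a, b) for i, a in enumerate(members) for b in members[i + 1 :])

    direction = pd.DataFrame(0, index=names, columns=names, dtype=int)
    rows = []
    for a, b in pairs:
        diffs = [
            bin_.members[a].size - bin_.members[b].size
            for bin_ in alignment.bins
            if a in bin_.members and b in bin_.members
            and not (exclude_ambiguous and bin_.ambiguous)
        ]
        if diffs and all(d < 0 for d in diffs):
            sign = -1
        elif diffs and all(d > 0 for d in diffs):
            sign = 1
        else:
            sign = 0
        direction.loc[a, b] = sign
        direction.loc[b, a] = -sign
        rows.append(
            {
                "profile_a": a,
                "profile_b": b,
                "n_shared_bins": len(diffs),
                "n_a_shorter": sum(d < 0 for d in diffs),
                "n_a_longer": sum(d > 0 for d in diffs),
                "direction": sign,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=["profile_a", "profile_b", "n_shared_bins",
                 "n_a_shorter", "n_a_longer", "direction"],
    )
    return direction, report


@dataclass(frozen=True)
class ReferenceChoice:
    """The reference bin minimizing summed within-bin spread of relative sizes."""

    reference_bin: int
    sd_sum: float
    candidates: pd.DataFrame


def recompute_sizes_with_reference(
    alignment: Alignment, exclude_ambiguous: bool = False
) -> tuple[list[Profile], ReferenceChoice]:
    """Shift-corrected sizes relative to the best common reference fragment.

    Every bin holding a fragment from all profiles is tested as a reference:
    per profile, each fragment's relative size is its size minus that
    profile's size in the candidate bin, and the candidate's score is the sum
    over bins of the sample standard deviation (n-1 denominator) of relative
    sizes; single-member bins contribute 0.  The candidate with the lowest
    score wins (ties broken by smallest mean size).  New sizes anchor the
    reference at the mean of its original sizes.  With ``exclude_ambiguous``
    (consensus mode) ambiguous bins are excluded both from candidacy and from
    the score.

    The returned profiles carry only re-computed size data (heights and
    areas travel along unchanged); each peak's ``source_size`` preserves its
    original identity for later comparison.
    """
    names = alignment.profile_names
    usable = [
        (bi, b) for bi, b in enumerate(alignment.bins)
        if not (exclude_ambiguous and b.ambiguous)
    ]
    candidates = [(bi, b) for bi, b in usable if set(b.members) == set(names)]
    if not candidates:
        raise ConsistencyError(
            "no alignment bin is common to all profiles; relative sizing impossible"
        )

    scored = []
    for ci, cbin in candidates:
        ref = {n: cbin.members[n].size for n in names}
        sd_sum = 0.0
        for _, b in usable:
            rel = [p.size - ref[n] for n, p in b.members.items()]
            if len(rel) >= 2:
                sd_sum += float(np.std(rel, ddof=1))
        scored.append({"bin": ci, "mean_size": cbin.mean_size, "sd_sum": sd_sum})
    table = pd.DataFrame(scored, columns=["bin", "mean_size", "sd_sum"])

    best = min(s["sd_sum"] for s in scored)
    tol = _TIE_RTOL * max(1.0, best)
    tied = [s for s in scored if s["sd_sum"] <= best + tol]
    chosen = min(tied, key=lambda s: s["mean_size"])
    cbin = alignment.bins[chosen["bin"]]
    ref = {n: cbin.members[n].size for n in names}
    anchor = fmean(ref.values())

    profiles = []
    for name in names:
        peaks = [
            Peak(
                size=anchor + (p.size - ref[name]),
                height=p.height,
                area=p.area,
                source_size=p.identity,
            )
            for b in alignment.bins
            for n, p in b.members.items()
            if n == name
        ]
        profiles.append(Profile(name, tuple(sorted(peaks, key=lambda p: p.size))))
    choice = ReferenceChoice(chosen["bin"], chosen["sd_sum"], table)
    return profiles, choice


def compare_alignments(
    original: Alignment, realigned: Alignment
) -> tuple[int, pd.DataFrame]:
    """Count fragments whose co-binned companions changed between alignments.

    Fragments are identified by (profile, original size); a fragment counts
    as differing when the set of fragments sharing its bin is not the same in
    both alignments.
    """

    def comember_sets(alignment: Alignment) -> dict[tuple[str, float], frozenset]:
        out = {}
        for b in alignment.bins:
            keys = {(n, p.identity) for n, p in b.members.items()}
            for key in keys:
                out[key] = frozenset(keys - {key})
        return out

    orig = comember_sets(original)
    new = comember_sets(realigned)
    if set(orig) != set(new):
        raise ConsistencyError(
            "alignments do not cover the same fragments; cannot compare"
        )
    rows = [
        {
            "profile": name,
            "size": size,
            "differs": orig[(name, size)] != new[(name, size)],
        }
        for name, size in sorted(orig, key=lambda k: (k[1], k[0]))
    ]
    flags = pd.DataFrame(rows, columns=["profile", "size", "differs"])
    return int(flags["differs"].sum()), flags
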