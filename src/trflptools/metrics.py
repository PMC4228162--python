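"""Community comparison: relative abundance, Bray-Curtis, Jaccard, Shannon.

All metrics operate on a bin x profile relative-abundance table derived from
an alignment, so that the i-th entry of two profiles refers to the same
fragment.  The Shannon index uses the base-10 logarithm; base-10 values are
not comparable with the natural-log convention used by some other tools, nor
across datasets analysed with different thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .align import Alignment
from .model import ParameterError, Profile, round_sizes

_SIGNALS = ("height", "area")


def profile_relative_abundance(profile: Profile, signal: str = "height") -> list[float]:
    """Per-peak share of the profile's total signal (sums to 1)."""
    if signal not in _SIGNALS:
        raise ParameterError(f"signal must be one of {_SIGNALS}, got {signal!r}")
    total = profile.total(signal)
    if total <= 0:
        raise ValueError(f"profile {profile.name!r} has zero total {signal} signal")
    return [p.value(signal) / total for p in profile]


def relative_abundance(alignment: Alignment, signal: str = "height") -> pd.DataFrame:
    """Bin x profile table of relative abundances.

    Each column sums to 1; absent bins hold 0.  Rows are labelled with the
    bin's mean size (two decimals, deduplicated where rounding collides).
    """
    if signal not in _SIGNALS:
        raise ParameterError(f"signal must be one of {_SIGNALS}, got {signal!r}")
    labels = []
    for b in alignment.bins:
        label = f"{round_sizes(b.mean_size):.2f}"
        while label in labels:
            label += "'"
        labels.append(label)
    table = pd.DataFrame(0.0, index=labels, columns=list(alignment.profile_names))
    for label, b in zip(labels, alignment.bins):
        for name, peak in b.members.items():
            table.loc[label, name] = peak.value(signal)
    totals = table.sum(axis=0)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise ValueError(f"profiles with zero total signal: {zero}")
    return table / totals


def bray_curtis_matrix(abundances: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances: sum|x_i - y_i| / sum(x_i + y_i).

    The denominator is evaluated literally, so the distance is defined for
    un-normalized columns too.
    """
    values = abundances.to_numpy(dtype=float)
    names = list(abundances.columns)
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = values[:, i], values[:, j]
            denom = float(np.sum(x + y))
            if denom == 0:
                raise ValueError(
                    f"Bray-Curtis undefined for the empty pair ({names[i]!r}, {names[j]!r})"
                )
            out[i, j] = out[j, i] = float(np.sum(np.abs(x - y))) / denom
    return pd.DataFrame(out, index=names, columns=names)


def jaccard_matrix(abundances: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard similarities: shared occupied bins / union of occupied bins."""
    presence = abundances.to_numpy(dtype=float) > 0
    names = list(abundances.columns)
    n = len(names)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = int(np.sum(presence[:, i] | presence[:, j]))
            if union == 0:
                raise ValueError(
                    f"Jaccard undefined for the empty pair ({names[i]!r}, {names[j]!r})"
                )
            inter = int(np.sum(presence[:, i] & presence[:, j]))
            out[i, j] = out[j, i] = inter / union
    return pd.DataFrame(out, index=names, columns=names)


def shannon_index(abundances: pd.DataFrame) -> pd.Series:
    """Per-profile Shannon diversity H = -sum x_i log10 x_i over x_i > 0."""
    out = {}
    for name in abundances.columns:
        x = abundances[name].to_numpy(dtype=float)
        x = x[x > 0]
        if x.size == 0:
            raise ValueError(f"profile {name!r} is empty; Shannon index undefined")
        out[name] = float(-np.sum(x * np.log10(x)))
    return pd.Series(out, name="Shannon index")
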