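"""Profile normalization.

Two families of procedures remove loading-amount differences between
profiles:

* Total fluorescence normalization (TFN): every profile whose total signal
  TF exceeds the dataset minimum TFmin is scaled by TFmin/TF; peaks that
  fall below the minimum allowed value after scaling are removed and the
  scaling is reiterated on the remainder until TF reaches (or undershoots)
  TFmin.  For height-based TFN the minimum allowed value is the peak height
  detection threshold; for area-based TFN it is the minimum observed peak
  area, taken over the whole dataset or — in the "local threshold" variant —
  over the replicate group being normalized.

* Fixed percentage threshold (FPT): peaks whose share of the profile's total
  signal falls below a fixed fraction are removed; survivors keep their raw
  values (rescaling to relative abundance is a separate, later step).

Scaling multiplies height and area by the same factor, so the two signals
stay proportional and either remains usable downstream.
"""

from __future__ import annotations

from typing import Sequence

from .model import Dataset, ParameterError, Peak, Profile

#: Relative tolerance on |TF - TFmin| for declaring convergence.
TFN_TOLERANCE = 1e-6

_SIGNALS = ("height", "area")


def _check_signal(signal: str) -> None:
    if signal not in _SIGNALS:
        raise ParameterError(f"signal must be one of {_SIGNALS}, got {signal!r}")


def _min_observed_area(profiles: Sequence[Profile]) -> float:
    areas = [p.area for prof in profiles for p in prof.peaks]
    if not areas:
        raise ValueError("no peaks present; cannot derive minimum observed area")
    return min(areas)


def _states_equal(a: Sequence[Peak], b: Sequence[Peak], tol: float) -> bool:
    if len(a) != len(b):
        return False
    for pa, pb in zip(a, b):
        if pa.size != pb.size:
            return False
        scale = max(abs(pa.height), abs(pb.height), abs(pa.area), abs(pb.area), 1.0)
        if abs(pa.height - pb.height) > tol * scale or abs(pa.area - pb.area) > tol * scale:
            return False
    return True


def average_states(a: Sequence[Peak], b: Sequence[Peak]) -> list[Peak]:
    """Per-peak arithmetic mean of two iteration states.

    Peaks are matched by size.  A peak present in only one state contributes
    half its value and is kept.
    """
    by_size_a = {p.size: p for p in a}
    by_size_b = {p.size: p for p in b}
    merged = []
    for size in sorted(set(by_size_a) | set(by_size_b)):
        pa, pb = by_size_a.get(size), by_size_b.get(size)
        height = ((pa.height if pa else 0.0) + (pb.height if pb else 0.0)) / 2
        area = ((pa.area if pa else 0.0) + (pb.area if pb else 0.0)) / 2
        src = (pa or pb).source_size
        merged.append(Peak(size, height, area, source_size=src))
    return merged


def _tfn_profile(
    profile: Profile, tf_min: float, min_peak: float, signal: str
) -> Profile:
    if not profile.peaks:
        raise ValueError(f"profile {profile.name!r} has no peaks")
    if profile.total(signal) <= 0:
        raise ValueError(f"profile {profile.name!r} has zero total {signal} signal")

    peaks: list[Peak] = list(profile.peaks)
    history: list[tuple[Peak, ...]] = [tuple(peaks)]
    while peaks:
        tf = sum(p.value(signal) for p in peaks)
        if tf <= tf_min or abs(tf - tf_min) <= TFN_TOLERANCE * tf_min:
            break
        factor = tf_min / tf
        peaks = [p.scaled(factor) for p in peaks]
        peaks = [p for p in peaks if p.value(signal) >= min_peak]
        history.append(tuple(peaks))
        # A period-2 cycle around TFmin (a peak hopping in and out at the
        # threshold) resolves to the per-peak average of the two states.
        if len(history) >= 3 and _states_equal(history[-1], history[-3], TFN_TOLERANCE):
            peaks = average_states(history[-1], history[-2])
            break
    return profile.with_peaks(peaks)


def tfn_normalize(
    dataset: Dataset,
    signal: str = "height",
    pdt: float | None = None,
    min_area: float | None = None,
) -> Dataset:
    """Iterative total-fluorescence normalization over all profiles passed in.

    TFmin is the lowest total fluorescence among ``dataset``'s profiles at
    entry.  Profiles already at (or below) TFmin are returned unchanged; no
    profile is ever scaled up.
    """
    _check_signal(signal)
    if signal == "height":
        if pdt is None:
            raise ParameterError("height-based TFN requires the peak detection threshold")
        min_peak = pdt
    else:
        min_peak = _min_observed_area(dataset.profiles) if min_area is None else min_area
    for profile in dataset:
        if not profile.peaks:
            raise ValueError(f"profile {profile.name!r} has no peaks")
    tf_min = min(p.total(signal) for p in dataset)
    if tf_min <= 0:
        raise ValueError("a profile has zero total signal")
    return dataset.with_profiles(
        [_tfn_profile(p, tf_min, min_peak, signal) for p in dataset]
    )


def tfn_normalize_replicates(
    dataset: Dataset,
    signal: str = "height",
    pdt: float | None = None,
    area_scope: str = "global",
) -> Dataset:
    """TFN applied within each replicate group.

    Each group is normalized to its own minimum total fluorescence.  For
    area-based TFN the minimum allowed peak area comes from the whole dataset
    (``area_scope="global"``) or from the group itself (``"local"``, the
    local-threshold variant).  Height-based TFN always uses the detection
    threshold, so the scope does not apply.
    """
    _check_signal(signal)
    if area_scope not in ("global", "local"):
        raise ParameterError("area_scope must be 'global' or 'local'")
    global_min_area = _min_observed_area(dataset.profiles) if signal == "area" else None
    out: list[Profile] = []
    for _, group in dataset.replicate_groups():
        sub = Dataset(tuple(group))
        min_area = None
        if signal == "area":
            min_area = (
                _min_observed_area(group) if area_scope == "local" else global_min_area
            )
        out.extend(tfn_normalize(sub, signal, pdt=pdt, min_area=min_area).profiles)
    return dataset.with_profiles(out)


def fpt_normalize(dataset: Dataset, signal: str = "height", fpt: float = 0.01) -> Dataset:
    """Remove peaks whose relative abundance falls below a fixed fraction.

    Relative abundances are computed once, on the input profile; peaks
    strictly below ``fpt`` are dropped and survivors keep their raw height
    and area.  Each profile is treated independently, so the same procedure
    serves replicate and consensus profiles alike.
    """
    _check_signal(signal)
    if not 0 <= fpt < 1:
        raise ParameterError("fpt must be in [0, 1)")
    profiles = []
    for profile in dataset:
        if not profile.peaks:
            raise ValueError(f"profile {profile.name!r} has no peaks")
        total = profile.total(signal)
        if total <= 0:
            raise ValueError(f"profile {profile.name!r} has zero total {signal} signal")
        profiles.append(
            profile.with_peaks([p for p in profile if p.value(signal) / total >= fpt])
        )
    return dataset.with_profiles(profiles)
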