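"""Orchestration of analysis chains.

A chain is a sequence of named steps through the fixed stage order

    prepare -> normalize replicates -> align replicates -> correct ->
    [shift check/correct] -> consensus -> normalize consensus ->
    align consensus -> check bins -> [shift check/correct] ->
    relative abundance -> metrics

Any contiguous-order subsequence is valid (normalization or shift handling
may be skipped entirely), but a step may never precede an earlier stage.
Each executed step appends one record to the run history, and every step is
also callable on its own through the library or CLI, so any intermediate
artifact can be substituted by a user-provided file.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import align as _align
from . import consensus as _consensus
from . import metrics as _metrics
from . import normalize as _normalize
from . import prepare as _prepare
from . import shift as _shift
from .io import RunRecord, append_run_record, write_alignment, write_dataset, write_matrix
from .model import Dataset, ParameterError, Params


class ChainError(ValueError):
    """Raised when a step list violates the stage order or names an unknown step."""


#: Stage rank of every step; metric steps share the final rank and may be
#: combined freely once relative abundances exist.
_STAGES: dict[str, int] = {
    "prepare": 1,
    "normalize-replicates": 2,
    "align-replicates": 3,
    "correct-alignment": 4,
    "shift-check-replicates": 5,
    "shift-correct-replicates": 6,
    "consensus": 7,
    "normalize-consensus": 8,
    "align-consensus": 9,
    "check-bins": 10,
    "shift-check-consensus": 11,
    "shift-correct-consensus": 12,
    "relative-abundance": 13,
    "bray-curtis": 14,
    "jaccard": 14,
    "shannon": 14,
}

_VARIANTS: dict[str, tuple[str, ...]] = {
    "normalize-replicates": ("tfn-heights", "tfn-areas", "tfn-areas-lt",
                             "fpt-heights", "fpt-areas"),
    "normalize-consensus": ("tfn-heights", "tfn-areas", "fpt-heights", "fpt-areas"),
    "consensus": ("average", "sum"),
    "relative-abundance": ("heights", "areas"),
}


def _parse_step(step: str) -> tuple[str, str | None]:
    name, _, variant = step.partition(":")
    if name not in _STAGES:
        raise ChainError(f"unknown step {name!r}")
    allowed = _VARIANTS.get(name)
    if allowed is None:
        if variant:
            raise ChainError(f"step {name!r} takes no variant, got {variant!r}")
        return name, None
    if not variant:
        raise ChainError(f"step {name!r} requires a variant from {allowed}")
    if variant not in allowed:
        raise ChainError(f"unknown variant {variant!r} for {name!r}; choose from {allowed}")
    return name, variant


def validate_steps(steps: Sequence[str]) -> list[tuple[str, str | None]]:
    """Check step names, variants and stage precedence; return parsed steps."""
    if not steps:
        raise ChainError("empty step list")
    parsed = [_parse_step(s) for s in steps]
    for (a, _), (b, _) in zip(parsed, parsed[1:]):
        ra, rb = _STAGES[a], _STAGES[b]
        if rb < ra or (rb == ra and not (ra == 14 and a != b)):
            raise ChainError(
                f"step {b!r} cannot follow {a!r}: "
                f"the {b!r} stage precedes (or repeats) the {a!r} stage"
            )
    return parsed


def run_chain(
    dataset: Dataset,
    params: Params,
    steps: Sequence[str],
    out_dir: str | Path | None = None,
    history_path: str | Path | None = None,
) -> dict[str, Any]:
    """Execute a validated chain; return artifacts keyed by step name.

    With ``out_dir`` every tabular artifact is written as TSV; with
    ``history_path`` one JSON-lines run record per step is appended, each
    record's input id matching the previous record's output id.
    """
    parsed = validate_steps(steps)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    if history_path is None and out is not None:
        history_path = out / "run_history.jsonl"

    state: Any = dataset
    groups: list[tuple[str, list[str]]] | None = None
    if dataset.n_replicates is not None:
        groups = [(s, [p.name for p in ps]) for s, ps in dataset.replicate_groups()]
    artifacts: dict[str, Any] = {}
    prev_id = "input-data"

    for step, (name, variant) in zip(steps, parsed):
        if name == "prepare":
            state, report = _prepare.apply_threshold_and_range(
                state, params.pdt, params.size_min, params.size_max
            )
            artifacts[step] = state
            artifacts["prepare-report"] = report
            _persist_dataset(out, "prepared", state)
        elif name in ("normalize-replicates", "normalize-consensus"):
            state = _run_normalize(state, name, variant, params)
            artifacts[step] = state
            _persist_dataset(out, f"normalized-{variant}", state)
        elif name in ("align-replicates", "align-consensus"):
            if isinstance(state, Dataset) and state.n_replicates is not None:
                groups = [(s, [p.name for p in ps]) for s, ps in state.replicate_groups()]
            state = _align.align_profiles(list(state), params.y, params.z)
            artifacts[step] = state
            _persist_alignment(out, name, state)
        elif name == "correct-alignment":
            state, report = _align.correct_ambiguous(_require_alignment(state, name))
            artifacts[step] = state
            artifacts["correction-report"] = report
            _persist_alignment(out, "corrected-alignment", state)
        elif name == "check-bins":
            state = _align.summarize_and_flag(_require_alignment(state, name))
            artifacts[step] = state
            if out is not None:
                write_matrix(state.stats_frame().fillna(""), out / "bin-stats.tsv")
        elif name in ("shift-check-replicates", "shift-check-consensus"):
            alignment = _require_alignment(state, name)
            scope_groups = (
                [g for _, g in groups] if name.endswith("replicates") and groups else None
            )
            direction, report = _shift.detect_systematic_shifts(
                alignment,
                groups=scope_groups,
                exclude_ambiguous=name.endswith("consensus"),
            )
            artifacts[step] = direction
            artifacts[f"{name}-report"] = report
            if out is not None:
                write_matrix(direction, out / f"{name}-matrix.tsv")
                write_matrix(report.set_axis(report.index.astype(str)), out / f"{name}-report.tsv")
        elif name in ("shift-correct-replicates", "shift-correct-consensus"):
            alignment = _require_alignment(state, name)
            consensus_mode = name.endswith("consensus")
            profiles, choice = _shift.recompute_sizes_with_reference(
                alignment, exclude_ambiguous=consensus_mode
            )
            realigned = _align.align_profiles(profiles, params.y, params.z)
            if consensus_mode:
                realigned = _align.summarize_and_flag(realigned)
            else:
                realigned, _ = _align.correct_ambiguous(realigned)
            n_diff, flags = _shift.compare_alignments(alignment, realigned)
            artifacts[step] = {
                "reference": choice,
                "realigned": realigned,
                "n_differing": n_diff,
                "flags": flags,
            }
            if out is not None:
                write_matrix(choice.candidates.set_axis(
                    choice.candidates.index.astype(str)), out / f"{name}-candidates.tsv")
                write_alignment(realigned, out / f"{name}-realigned.tsv")
                write_matrix(flags.set_axis(flags.index.astype(str)),
                             out / f"{name}-flags.tsv")
        elif name == "consensus":
            alignment = _require_alignment(state, name)
            if groups is None:
                raise ChainError("consensus requires a replicate-grouped input dataset")
            rule = _consensus.ConsensusRule(x_min=params.x_min, combine=variant)
            state = _consensus.build_consensus(alignment, groups, rule)
            groups = None
            artifacts[step] = state
            _persist_dataset(out, f"consensus-{variant}", state)
        elif name == "relative-abundance":
            alignment = _require_alignment(state, name)
            signal = "height" if variant == "heights" else "area"
            state = _metrics.relative_abundance(alignment, signal)
            artifacts[step] = state
            if out is not None:
                write_matrix(state, out / f"relative-abundance-{variant}.tsv")
        elif name in ("bray-curtis", "jaccard", "shannon"):
            table = _require_abundance(state, name)
            if name == "bray-curtis":
                result: Any = _metrics.bray_curtis_matrix(table)
            elif name == "jaccard":
                result = _metrics.jaccard_matrix(table)
            else:
                result = _metrics.shannon_index(table)
            artifacts[step] = result
            if out is not None:
                frame = result.to_frame() if isinstance(result, pd.Series) else result
                write_matrix(frame, out / f"{name}.tsv")

        if history_path is not None:
            append_run_record(
                history_path,
                RunRecord(
                    operation=step,
                    params=dataclasses.asdict(params),
                    input_id=prev_id,
                    output_id=step,
                ),
            )
        prev_id = step

    return artifacts


def _run_normalize(state: Any, name: str, variant: str, params: Params) -> Dataset:
    if not isinstance(state, Dataset):
        raise ChainError(f"{name} expects profile data, got {type(state).__name__}")
    replicate_scope = name == "normalize-replicates" and state.n_replicates is not None
    if variant == "tfn-heights":
        if replicate_scope:
            return _normalize.tfn_normalize_replicates(state, "height", pdt=params.pdt)
        return _normalize.tfn_normalize(state, "height", pdt=params.pdt)
    if variant == "tfn-areas":
        if replicate_scope:
            return _normalize.tfn_normalize_replicates(state, "area", area_scope="global")
        return _normalize.tfn_normalize(state, "area")
    if variant == "tfn-areas-lt":
        if not replicate_scope:
            raise ChainError("tfn-areas-lt requires replicate-grouped data")
        return _normalize.tfn_normalize_replicates(state, "area", area_scope="local")
    signal = "height" if variant == "fpt-heights" else "area"
    return _normalize.fpt_normalize(state, signal, params.fpt)


def _require_alignment(state: Any, step: str) -> _align.Alignment:
    if not isinstance(state, _align.Alignment):
        raise ChainError(f"step {step!r} expects an alignment, got {type(state).__name__}")
    return state


def _require_abundance(state: Any, step: str) -> pd.DataFrame:
    if not isinstance(state, pd.DataFrame):
        raise ChainError(
            f"step {step!r} expects a relative-abundance table, got {type(state).__name__}"
        )
    return state


def _persist_dataset(out: Path | None, stem: str, dataset: Dataset) -> None:
    if out is not None:
        write_dataset(dataset, out / f"{stem}.tsv")


def _persist_alignment(out: Path | None, stem: str, alignment: _align.Alignment) -> None:
    if out is not None:
        write_alignment(alignment, out / f"{stem}.tsv")
        write_matrix(alignment.stats_frame().fillna(""), out / f"{stem}-stats.tsv")
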