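"""Reading and writing of the block-layout peak table and result matrices.

The canonical on-disk format is delimited text (TSV, or CSV by extension) in
the layout produced by fragment-analysis report tools: one row of sample
names, then a block of presence/absence rows (one per fragment slot, values
0/1 with blank equivalent to 0), then size rows, height rows and area rows.
Columns are profiles; the first column holds row labels.

Presence rows are authoritative: a stored peak exists exactly where the
presence cell is 1.  A presence of 1 with a blank size cell is a format
error — the reader fails loud rather than guessing.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .model import Dataset, FormatError, Params, Peak, Profile

_BLOCKS = ("presence", "size", "height", "area")
_BLOCK_PREFIXES = {"t-rf": "presence", "trf": "presence", "size": "size",
                   "height": "height", "area": "area"}


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _classify(label: str) -> str | None:
    head = label.strip().lower()
    for prefix, block in _BLOCK_PREFIXES.items():
        if head.startswith(prefix):
            return block
    return None


def _parse_cell(raw: str, row_label: str, col_label: str) -> float | None:
    text = raw.strip()
    if text in ("", "0"):
        return None  # the value 0 and blank are equivalent to absent
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"non-numeric value {raw!r} in row {row_label!r}, column {col_label!r}"
        ) from None


def read_dataset(
    path: str | Path,
    names_row: int = 1,
    n_samples: int | None = None,
    n_replicates: int | None = None,
) -> Dataset:
    """Parse a block-layout peak table into a :class:`Dataset`.

    ``names_row`` is the 1-based row holding the sample names (layout
    parameter 5).  Rows above it are ignored.  The rows below must form four
    equally long blocks: presence, size, height, area.
    """
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False,
                      skip_blank_lines=False)
    if names_row < 1 or names_row > len(raw):
        raise FormatError(f"names_row={names_row} outside table with {len(raw)} rows")
    names = [str(v).strip() for v in raw.iloc[names_row - 1, 1:]]
    names = [n for n in names if n != ""]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"duplicate profile names: {dupes}")
    body = raw.iloc[names_row:, : 1 + len(names)]
    body = body[body.apply(lambda r: any(str(v).strip() for v in r), axis=1)]
    labels = [str(v).strip() for v in body.iloc[:, 0]]

    # When labels follow the T-RF/Size/Height/Area convention, use them to
    # name the offending row of an uneven block; otherwise rely on row count.
    kinds = [_classify(lab) for lab in labels]
    if all(k is not None for k in kinds) and len(set(kinds)) == len(_BLOCKS):
        counts = {b: kinds.count(b) for b in _BLOCKS}
        if len(set(counts.values())) != 1:
            n_trf = min(counts.values())
            offender = next(
                labels[i] for i, k in enumerate(kinds) if kinds[: i + 1].count(k) > n_trf
            )
            raise FormatError(
                f"row blocks have unequal lengths {counts}; offending row {offender!r}"
            )
        n_trf = counts["presence"]
    else:
        if len(labels) % len(_BLOCKS):
            raise FormatError(
                f"{len(labels)} data rows do not divide into presence/size/height/area "
                f"blocks; last row {labels[-1] if labels else '?'!r}"
            )
        n_trf = len(labels) // len(_BLOCKS)

    blocks = {
        block: body.iloc[i * n_trf : (i + 1) * n_trf, 1:]
        for i, block in enumerate(_BLOCKS)
    }
    block_labels = {
        block: labels[i * n_trf : (i + 1) * n_trf] for i, block in enumerate(_BLOCKS)
    }

    profiles = []
    for j, name in enumerate(names):
        peaks = []
        for i in range(n_trf):
            pres_raw = str(blocks["presence"].iloc[i, j]).strip()
            if pres_raw in ("", "0", "0.0"):
                continue
            if pres_raw not in ("1", "1.0"):
                raise FormatError(
                    f"presence value must be 0, 1 or blank; got {pres_raw!r} in row "
                    f"{block_labels['presence'][i]!r}, column {name!r}"
                )
            values = {}
            for block in ("size", "height", "area"):
                cell = str(blocks[block].iloc[i, j])
                values[block] = _parse_cell(cell, block_labels[block][i], name)
            if values["size"] is None:
                raise FormatError(
                    f"presence is 1 but size is blank in row "
                    f"{block_labels['size'][i]!r}, column {name!r}"
                )
            peaks.append(
                Peak(values["size"], values["height"] or 0.0, values["area"] or 0.0)
            )
        profiles.append(Profile(name, tuple(sorted(peaks, key=lambda p: p.size))))
    return Dataset(tuple(profiles), n_samples=n_samples, n_replicates=n_replicates)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset back to the block layout at full precision."""
    sep = _sep_for(path)
    n_trf = max((len(p) for p in dataset), default=0)
    rows: list[list[str]] = [["Sample Name"] + dataset.names]
    grids = {block: [] for block in _BLOCKS}
    for i in range(n_trf):
        grids["presence"].append(
            [f"T-RF {i + 1}"] + ["1" if i < len(p) else "0" for p in dataset]
        )
        for block, attr in (("size", "size"), ("height", "height"), ("area", "area")):
            grids[block].append(
                [f"{block.capitalize()} {i + 1}"]
                + [repr(getattr(p.peaks[i], attr)) if i < len(p) else "" for p in dataset]
            )
    for block in _BLOCKS:
        rows.extend(grids[block])
    Path(path).write_text("\n".join(sep.join(r) for r in rows) + "\n")


def write_matrix(table: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled numeric matrix as round-trippable delimited text."""
    for axis, labels in (("row", table.index), ("column", table.columns)):
        labels = [str(v) for v in labels]
        if any(lab == "" for lab in labels):
            raise ValueError(f"empty {axis} label")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate {axis} labels")
    table.to_csv(path, sep=_sep_for(path), float_format=None)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


# --- alignment serialization ----------------------------------------------

def write_alignment(alignment, path: str | Path) -> None:
    """Write an alignment as a bin x profile TSV of size|height|area triplets.

    Cells are ``size|height|area`` (``size|height|area|source_size`` when a
    fragment carries a re-computed size), blank where a profile has no
    fragment in the bin.  A trailing ``Ambiguous`` column holds Yes/No.
    """
    sep = _sep_for(path)
    rows = [["Bin"] + list(alignment.profile_names) + ["Ambiguous"]]
    for i, b in enumerate(alignment.bins):
        cells = []
        for name in alignment.profile_names:
            peak = b.members.get(name)
            if peak is None:
                cells.append("")
            else:
                parts = [repr(peak.size), repr(peak.height), repr(peak.area)]
                if peak.source_size is not None:
                    parts.append(repr(peak.source_size))
                cells.append("|".join(parts))
        rows.append([f"T-RF {i + 1}"] + cells + ["Yes" if b.ambiguous else "No"])
    Path(path).write_text("\n".join(sep.join(r) for r in rows) + "\n")


def read_alignment(path: str | Path, y: float, z: float):
    """Read an alignment written by :func:`write_alignment`."""
    from .align import Alignment, Bin
    from .model import Peak

    sep = _sep_for(path)
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split(sep)
    if header[-1] != "Ambiguous":
        raise FormatError("alignment table must end with an 'Ambiguous' column")
    names = tuple(header[1:-1])
    bins = []
    for ln in lines[1:]:
        cells = ln.split(sep)
        members = {}
        for name, cell in zip(names, cells[1:-1]):
            if not cell.strip():
                continue
            parts = cell.split("|")
            if len(parts) not in (3, 4):
                raise FormatError(f"malformed alignment cell {cell!r} in row {cells[0]!r}")
            src = float(parts[3]) if len(parts) == 4 else None
            members[name] = Peak(float(parts[0]), float(parts[1]), float(parts[2]),
                                 source_size=src)
        bins.append(Bin(members, ambiguous=cells[-1].strip() == "Yes"))
    return Alignment(bins, names, y, z)


# --- run history -----------------------------------------------------------

@dataclass(frozen=True)
class RunRecord:
    """One analysis step: what ran, with which parameters, on what."""

    operation: str
    params: dict[str, Any] = field(default_factory=dict)
    input_id: str = ""
    output_id: str = ""
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )


def append_run_record(path: str | Path, record: RunRecord) -> None:
    """Append one structured JSON line; prior lines are never modified."""
    with open(path, "a") as fh:
        fh.write(json.dumps(dataclasses.asdict(record), sort_keys=True) + "\n")


def read_run_history(path: str | Path) -> list[RunRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(RunRecord(**json.loads(line)))
    return records


# --- parameter config ------------------------------------------------------

# Verbatim long-form parameter names as they appear in the analysis template,
# with snake_case aliases.
_PARAM_KEYS = {
    "Total number of profiles": "n_profiles",
    "Number of samples": "n_samples",
    "Number of replicates per sample": "n_replicates",
    "Number of T-RFs": "n_trfs",
    "Sample names on row": "names_row",
    "Consider T-RF if present in X replicates. X=": "x_min",
    "Align T-RFs with a size difference shorter than Y bases. Y=": "y",
    "Add T-RFs less than Z bases longer than the average size of the alignment. Z=": "z",
    "Peak height detection threshold. PDT =": "pdt",
    "Lower T-RF Size Limit": "size_min",
    "Upper T-RF Size Limit": "size_max",
    "Fixed percentage threshold. FPT=": "fpt",
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML parameter file keyed by the template's parameter names.

    Returns a flat dict with canonical snake_case keys plus any extra keys
    (e.g. a step list) passed through untouched.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, Any] = {}
    for key, value in raw.items():
        out[_PARAM_KEYS.get(str(key).strip(), str(key).strip())] = value
    return out


def params_from_config(config: dict[str, Any]) -> Params:
    fields = {f.name for f in dataclasses.fields(Params)}
    return Params(**{k: v for k, v in config.items() if k in fields})
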