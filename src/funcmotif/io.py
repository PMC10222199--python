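"""Reading and writing the tabular inputs and all result artifacts.

Tables are TSV by default (CSV via ``delimiter=","``), decimal point only.
Sample alignment is always by identifier, never by row order; a missing
identifier is an error, not a silent reindex.  Result floats are serialized
with 12 significant digits so re-runs with identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable, PropertyVector
from .discretize import ClassDescriptor, ClassEncoding
from .clustering import FunctionalPartition
from .effects import GroupEffects
from .exceptions import ParseError, ValidationError
from .model import ModelFit, SelectionTrace

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_property_table",
    "read_class_encoding",
    "write_class_encoding",
    "write_results",
]

#: significant digits for serialized floats
FLOAT_DIGITS = 12


def _fmt(x: float) -> float:
    return float(f"{x:.{FLOAT_DIGITS}g}")


def _read_frame(path, delimiter: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=delimiter, index_col=0)
    except FileNotFoundError:
        raise
    except Exception as err:  # malformed file
        raise ParseError(f"cannot parse {path}: {err}") from err


def read_abundance_table(
    path,
    delimiter: str = "\t",
    orientation: str = "samples_rows",
    community_label: str = "",
) -> AbundanceTable:
    """Read a count table; first column holds identifiers, first row the header.

    ``orientation="samples_rows"`` expects samples as rows and families as
    columns; ``"families_rows"`` reads the transpose.  Counts must be
    non-negative and exactly representable as integers.
    """
    if orientation not in ("samples_rows", "families_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    # pandas silently mangles duplicate header names, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate identifier in header: {dup}")
    frame = _read_frame(path, delimiter)
    if orientation == "families_rows":
        frame = frame.T
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
    return AbundanceTable.from_frame(frame, community_label=community_label)


def write_abundance_table(table: AbundanceTable, path, delimiter: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=delimiter)


def read_property_table(
    path,
    delimiter: str = "\t",
    column: str | None = None,
    sample_order: list[str] | None = None,
):
    """Read per-sample property values.

    Two-column files yield a single :class:`PropertyVector`; wide files with
    several labeled columns yield a dict of vectors keyed by column label
    (pass ``column`` to select one).  When ``sample_order`` is given, vectors
    are aligned to it and missing samples are an alignment error.
    """
    frame = _read_frame(path, delimiter)
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise ParseError(f"non-numeric property column {col!r} in {path}")

    def build(col: str) -> PropertyVector:
        vec = PropertyVector(
            sample_ids=list(map(str, frame.index)),
            values=frame[col].to_numpy(dtype=float),
            label=str(col),
        )
        if sample_order is not None:
            vec = vec.align_to(list(sample_order))
        return vec

    if column is not None:
        if column not in frame.columns:
            raise ParseError(f"column {column!r} not found in {path}")
        return build(column)
    if frame.shape[1] == 1:
        return build(frame.columns[0])
    return {str(col): build(col) for col in frame.columns}


def write_class_encoding(encoding: ClassEncoding, path, delimiter: str = "\t") -> None:
    """Write the 0/1 encoding table; a thresholds sidecar goes next to it."""
    path = Path(path)
    encoding.to_frame().to_csv(path, sep=delimiter)
    sidecar = path.with_suffix(path.suffix + ".classes.json")
    meta = [
        {
            "name": c.name,
            "family_id": c.family_id,
            "class_index": c.class_index,
            "n_classes": c.n_classes,
            "lower": _fmt(c.lower),
            "upper": _fmt(c.upper),
            "frequency": _fmt(c.frequency),
        }
        for c in encoding.classes
    ]
    sidecar.write_text(json.dumps(meta, indent=1))


def read_class_encoding(path, delimiter: str = "\t") -> ClassEncoding:
    path = Path(path)
    frame = _read_frame(path, delimiter)
    sidecar = path.with_suffix(path.suffix + ".classes.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        classes = [
            ClassDescriptor(
                family_id=m["family_id"],
                class_index=int(m["class_index"]),
                n_classes=int(m["n_classes"]),
                lower=float(m["lower"]),
                upper=float(m["upper"]),
                frequency=float(m["frequency"]),
            )
            for m in meta
        ]
        if [c.name for c in classes] != list(map(str, frame.columns)):
            raise ParseError(f"sidecar classes do not match columns of {path}")
    else:  # reconstruct descriptors from "family|c/k" column names
        classes = []
        for name in map(str, frame.columns):
            try:
                family, ck = name.rsplit("|", 1)
                c, k = ck.split("/")
            except ValueError as err:
                raise ParseError(f"cannot parse class name {name!r}") from err
            col = frame[name].to_numpy()
            classes.append(
                ClassDescriptor(
                    family_id=family,
                    class_index=int(c),
                    n_classes=int(k),
                    lower=float("nan"),
                    upper=float("nan"),
                    frequency=float(col.mean()),
                )
            )
    return ClassEncoding(
        sample_ids=list(map(str, frame.index)),
        classes=classes,
        indicators=frame.to_numpy(),
    )


def _partition_dict(partition: FunctionalPartition) -> dict:
    return {
        "assignment": dict(partition.assignment),
        "group_order": list(partition.group_order),
        "residual": partition.residual,
        "member_order": partition.member_order,
    }


def _fit_dict(fit: ModelFit) -> dict:
    out = fit.summary_dict()
    for key in ("r2", "f_ratio", "aicc"):
        if np.isfinite(out[key]):
            out[key] = _fmt(out[key])
    if fit.coefficients is not None and len(fit.coefficients):
        out["intercept"] = _fmt(fit.intercept)
        out["coefficients"] = {k: _fmt(v) for k, v in fit.coefficients.items()}
    return out


def write_results(
    out_dir,
    encoding: ClassEncoding | None = None,
    fits: list[ModelFit] = (),
    traces: list[SelectionTrace] = (),
    effects: GroupEffects | None = None,
    partition: FunctionalPartition | None = None,
) -> dict[str, str]:
    """Write run artifacts to a directory; returns a manifest {kind: path}.

    File kinds: ``encoding`` (TSV), ``selection_trace`` (TSV),
    ``partition`` (JSON), ``effects`` (TSV), ``model_summary`` (JSON).
    Passing no artifacts yields an empty manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    if encoding is not None:
        p = out / "encoding.tsv"
        write_class_encoding(encoding, p)
        manifest["encoding"] = str(p)
    if traces:
        p = out / "selection_trace.tsv"
        frames = []
        for i, tr in enumerate(traces):
            f = tr.to_frame()
            f.insert(0, "trace", f"{tr.final.route}_{i}")
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(
            p, sep="\t", index=False, float_format=f"%.{FLOAT_DIGITS}g"
        )
        manifest["selection_trace"] = str(p)
    if partition is not None:
        p = out / "partition.json"
        p.write_text(json.dumps(_partition_dict(partition), indent=1))
        manifest["partition"] = str(p)
    if effects is not None:
        p = out / "effects.tsv"
        effects.to_frame().to_csv(
            p, sep="\t", index=False, float_format=f"%.{FLOAT_DIGITS}g"
        )
        manifest["effects"] = str(p)
    all_fits = list(fits) + [tr.final for tr in traces]
    if all_fits:
        p = out / "model_summary.json"
        p.write_text(json.dumps([_fit_dict(f) for f in all_fits], indent=1))
        manifest["model_summary"] = str(p)
    return manifest
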