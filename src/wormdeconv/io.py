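"""Tab-separated text I/O for every table the pipeline exchanges.

All files are TSV with optional '#'-prefixed comment/provenance header
lines. Readers validate structure (unique ids, numeric cells, rectangular
rows) and report offending line numbers; writers round-trip values at
full precision (repr-precision floats).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    BulkMatrix,
    ProportionMatrix,
    SignatureMatrix,
    ValidationError,
    validate_ground_truth,
    validate_marker_table,
)

__all__ = [
    "read_matrix", "write_matrix",
    "read_marker_table", "write_marker_table",
    "read_signature", "write_signature",
    "read_bulk", "write_bulk",
    "read_proportions", "write_proportions",
    "read_ground_truth", "write_ground_truth",
    "read_mapping", "write_mapping",
    "read_config", "write_config",
]


class ParseError(ValidationError):
    """A file failed structural validation; message carries line numbers."""


def _read_table_lines(path: Path) -> tuple[list[str], list[int]]:
    """Non-comment lines of a TSV file with their 1-based line numbers."""
    lines, numbers = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            if line.strip() == "":
                continue
            lines.append(line.rstrip("\n"))
            numbers.append(lineno)
    if not lines:
        raise ParseError(f"{path}: no data lines")
    return lines, numbers


def _parse_matrix(path: Path, index_name: str) -> pd.DataFrame:
    """Strictly rectangular numeric TSV with a header row of column ids."""
    lines, numbers = _read_table_lines(Path(path))
    header = lines[0].split("\t")
    ncol = len(header)
    columns = header[1:]
    if len(set(columns)) != len(columns):
        dups = sorted({c for c in columns if columns.count(c) > 1})
        raise ParseError(f"{path}:{numbers[0]}: duplicate column ids {dups}")
    index, rows = [], []
    seen: set[str] = set()
    for line, lineno in zip(lines[1:], numbers[1:]):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ParseError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                f"expected {ncol})"
            )
        rid = fields[0]
        if rid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate row id '{rid}'")
        seen.add(rid)
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        index.append(rid)
    return pd.DataFrame(
        rows, index=pd.Index(index, name=index_name), columns=columns
    )


def _comment_block(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_matrix(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_block(provenance))
        fh.write("\t".join([df.index.name or "id", *map(str, df.columns)]) + "\n")
        for rid, row in zip(df.index, df.to_numpy()):
            fh.write("\t".join([str(rid), *[repr(float(v)) for v in row]]) + "\n")


def read_matrix(path, index_name: str = "id") -> pd.DataFrame:
    return _parse_matrix(Path(path), index_name)


def write_marker_table(markers: pd.DataFrame, path,
                       provenance: dict | None = None) -> None:
    validate_marker_table(markers)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_block(provenance))
        fh.write("feature_id\tcell_type\tmarker_score\n")
        for _, rec in markers.iterrows():
            fh.write(
                f"{rec['feature_id']}\t{rec['cell_type']}\t"
                f"{repr(float(rec['marker_score']))}\n"
            )


def read_marker_table(path) -> pd.DataFrame:
    path = Path(path)
    lines, numbers = _read_table_lines(path)
    header = lines[0].split("\t")
    if header != ["feature_id", "cell_type", "marker_score"]:
        raise ParseError(
            f"{path}:{numbers[0]}: expected header "
            f"'feature_id\\tcell_type\\tmarker_score', got {header}"
        )
    records = []
    for line, lineno in zip(lines[1:], numbers[1:]):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields")
        try:
            score = float(fields[2])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric marker_score '{fields[2]}'"
            ) from None
        records.append((fields[0], fields[1], score))
    markers = pd.DataFrame(
        records, columns=["feature_id", "cell_type", "marker_score"]
    )
    try:
        return validate_marker_table(markers)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_signature(signature: SignatureMatrix, path) -> None:
    write_matrix(signature.values, path,
                 provenance={"table": "signature", **signature.provenance})


def read_signature(path) -> SignatureMatrix:
    return SignatureMatrix(values=read_matrix(path, "feature_id"))


def write_bulk(bulk: BulkMatrix, path, provenance: dict | None = None) -> None:
    """Write values to ``path`` and sample metadata to ``path + '.meta.tsv'``."""
    path = Path(path)
    write_matrix(bulk.values, path, provenance)
    meta = bulk.metadata.reset_index()
    meta.columns = ["sample", *bulk.metadata.columns]
    meta.to_csv(path.with_suffix(path.suffix + ".meta.tsv"), sep="\t",
                index=False)


def read_bulk(path) -> BulkMatrix:
    path = Path(path)
    values = read_matrix(path, "feature_id")
    meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    if not meta_path.exists():
        raise ParseError(f"missing metadata file {meta_path}")
    metadata = pd.read_csv(meta_path, sep="\t", dtype={"sample": str})
    metadata = metadata.set_index("sample")
    metadata["day"] = metadata["day"].astype(int)
    return BulkMatrix(values=values, metadata=metadata)


def write_proportions(proportions: ProportionMatrix, path,
                      provenance: dict | None = None) -> None:
    df = proportions.values.copy()
    df.insert(0, "day", proportions.day)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_block(provenance))
        fh.write("\t".join(["sample", *map(str, df.columns)]) + "\n")
        for rid, row in df.iterrows():
            cells = [str(rid), str(int(row["day"]))]
            cells += [repr(float(v)) for v in row.drop("day")]
            fh.write("\t".join(cells) + "\n")


def read_proportions(path) -> ProportionMatrix:
    df = read_matrix(path, "sample")
    if "day" not in df.columns:
        raise ParseError(f"{path}: proportions table missing 'day' column")
    day = df["day"].astype(int)
    return ProportionMatrix(values=df.drop(columns="day"), day=day)


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    validate_ground_truth(truth)
    truth.to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> pd.DataFrame:
    path = Path(path)
    lines, numbers = _read_table_lines(path)
    header = lines[0].split("\t")
    required = ["tissue", "nuclei_count", "total_cell_volume"]
    if header[: len(required)] != required:
        raise ParseError(f"{path}:{numbers[0]}: expected header {required}")
    records = []
    for line, lineno in zip(lines[1:], numbers[1:]):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 fields")
        try:
            records.append((fields[0], int(fields[1]), float(fields[2])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    truth = pd.DataFrame(
        records, columns=["tissue", "nuclei_count", "total_cell_volume"]
    )
    try:
        return validate_ground_truth(truth)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_mapping(mapping: dict[str, str], path) -> None:
    """Cell-type -> tissue mapping as 'cell_type = tissue' lines."""
    with open(path, "w") as fh:
        fh.write("# cell_type = curated tissue\n")
        for k, v in mapping.items():
            fh.write(f"{k} = {v}\n")


def read_mapping(path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'cell_type = tissue'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in mapping:
                raise ParseError(f"{path}:{lineno}: duplicate cell type '{key}'")
            mapping[key] = value
    if not mapping:
        raise ParseError(f"{path}: empty mapping")
    return mapping


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return out
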