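"""Readers and writers for the pipeline's plain-text table formats.

Everything is delimited text (CSV/TSV inferred from the extension), standard
GMT, or JSON; schemas are checked on read so downstream code can trust column
names and dtypes.  All writers produce files the corresponding readers
round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import ValidationError

# column -> required dtype kind ('n' numeric, 's' string, 'b' bool, 'i' integer)
BEHAVIOR_SCHEMA = {
    "subject_id": "s",
    "group": "s",
    "rotations_per_min": "n",
    "latency_s": "n",
    "crossings": "n",
    "mnss": "n",
    "emg_area": "n",
}
CHANGE_SCHEMA = {"feature_id": "s", "contrast": "s", "log2fc": "n", "p_value": "n"}
DRUG_SCHEMA = {
    "gene_id": "s",
    "drug_name": "s",
    "interaction_type": "s",
    "pd_effect_reported": "b",
}
RTPCR_SCHEMA = {"gene_id": "s", "rtpcr_direction": "s", "rnaseq_direction": "s"}


def _delimiter(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in {".tsv", ".txt", ".gmt"}:
        return "\t"
    raise ValidationError(f"cannot infer delimiter from extension {suffix!r}")


def read_table(path, schema: dict[str, str] | None = None, index_col=None) -> pd.DataFrame:
    """Read a delimited table, checking required columns and dtypes.

    Error messages carry the offending column and 1-based data row number.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=_delimiter(path), index_col=index_col)
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValidationError(f"{path.name}: missing column(s) {missing}")
        for col, kind in schema.items():
            series = df[col]
            if kind == "n" and not pd.api.types.is_numeric_dtype(series):
                coerced = pd.to_numeric(series, errors="coerce")
                bad = coerced.isna() & series.notna()
                if bad.any():
                    row = int(bad.idxmax()) + 1
                    raise ValidationError(
                        f"{path.name}: column {col!r} not numeric at data row {row}"
                    )
                df[col] = coerced
            if kind == "b":
                df[col] = series.map(
                    {True: True, False: False, "True": True, "False": False,
                     "true": True, "false": False, 1: True, 0: False}
                )
                if df[col].isna().any():
                    raise ValidationError(f"{path.name}: column {col!r} not boolean")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delimiter(path), index=index)
    return path


def read_counts(path) -> pd.DataFrame:
    """Genes x samples integer count matrix from TSV (first column = gene_id)."""
    df = read_table(path, index_col=0)
    if not all(pd.api.types.is_numeric_dtype(df[c]) for c in df.columns):
        raise ValidationError(f"{Path(path).name}: count matrix has non-numeric columns")
    return df


def read_gmt(path) -> tuple[dict[str, set[str]], list[str]]:
    """Standard GMT: name <tab> description <tab> member...

    Returns ``(sets, warnings)``.  Duplicate members are deduplicated and
    empty sets dropped, each with a warning; a line with fewer than two tab
    fields is a format error naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"GMT file not found: {path}")
    sets: dict[str, set[str]] = {}
    warnings: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValidationError(f"{path.name}:{lineno}: GMT line needs >= 2 tab fields")
        name, _desc, *members = fields
        if len(members) != len(set(members)):
            warnings.append(f"set {name!r}: duplicate members deduplicated")
        members = set(members)
        if not members:
            warnings.append(f"set {name!r}: empty, dropped")
            continue
        sets[name] = members
    return sets, warnings


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "\t".join([name, description, *sorted(members)])
        for name, members in sorted(sets.items())
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_gene_list(path) -> list[str]:
    """One gene per line; blank lines ignored."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"gene list not found: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(genes) + ("\n" if len(genes) else ""))
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, set):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
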