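"""Readers and writers for the tab-separated table dialects.

PSM tables follow the MaxQuant msms.txt/evidence.txt column dialect
(``Reporter intensity 1..n``, ``Reporter intensity corrected 1..n``,
``Precursor intensity``, ``Ion injection time``, ``PIF``, ``Base peak
ratio``, ``Proteins``, ``Experiment`` and a configurable plex column).
Quantification matrices are written both wide (proteinGroups-style
``Reporter intensity corrected <k> <experiment>`` columns) and tidy long.
Channel indices in file headers are 1-based, matching the dialect; all
internal indices are 0-based — the conversion lives here and only here.

Floats are written in Python's shortest round-trip representation, so a
write/read cycle is bit-exact.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .batch_eval import Embedding
from .label_model import LabelSet, load_label_set
from .quant import ExperimentalDesign, PSMTable, QuantMatrix
from .simulate import GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "read_psm_table",
    "write_psm_table",
    "read_design",
    "write_design",
    "write_quant_matrix",
    "read_quant_matrix",
    "read_embedding",
    "write_embedding",
    "write_ground_truth",
]

def _float_repr(v: float) -> str:
    """Shortest representation that round-trips bit-exactly; NaN -> empty."""
    return str(float(v)) if v == v else ""


def _to_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_float_repr,
              quoting=csv.QUOTE_NONE)


_META_MAP = {
    "Precursor intensity": "precursor_intensity",
    "Ion injection time": "fill_time",
    "PIF": "pif",
    "Base peak ratio": "base_peak_ratio",
}


def _reporter_columns(columns: list[str], prefix: str) -> list[str]:
    """Contiguous 1-based ``<prefix> k`` columns; determines the channel count."""
    pat = re.compile(rf"^{re.escape(prefix)} (\d+)$")
    found = {int(m.group(1)): c for c in columns if (m := pat.match(c))}
    if not found:
        return []
    n = max(found)
    missing = [k for k in range(1, n + 1) if k not in found]
    if missing:
        raise ValueError(f"non-contiguous {prefix!r} columns; missing indices {missing}")
    return [found[k] for k in range(1, n + 1)]


def read_psm_table(
    path: str | Path,
    label_set: LabelSet | None = None,
    plex_column: str = "Plex",
) -> PSMTable:
    """Read a MaxQuant-dialect PSM table.

    The channel count is inferred from the contiguous ``Reporter intensity
    k`` columns and checked against ``label_set`` when one is given (without
    one, a generic label set with numbered channels is used).  If the plex
    column is absent, ``Experiment`` doubles as the plex identifier.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype_backend="numpy_nullable",
                     float_precision="round_trip")
    raw_cols = _reporter_columns(list(df.columns), "Reporter intensity")
    missing = [c for c in ["Proteins", "Experiment"] if c not in df.columns]
    if not raw_cols:
        missing.append("Reporter intensity 1..n")
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")
    n = len(raw_cols)
    if label_set is None:
        label_set = load_label_set([str(k) for k in range(1, n + 1)])
    elif label_set.n != n:
        raise ValueError(
            f"{path}: {n} reporter columns but label set {label_set.name!r} has {label_set.n}"
        )
    corr_cols = _reporter_columns(list(df.columns), "Reporter intensity corrected")
    if corr_cols and len(corr_cols) != n:
        raise ValueError(f"{path}: corrected reporter column count {len(corr_cols)} != {n}")

    def _numeric(col: pd.Series) -> np.ndarray:
        out = pd.to_numeric(col, errors="coerce")
        bad = int(out.isna().sum() - col.isna().sum())
        if bad:
            logger.warning("%s: %d unparseable values in column %r set to missing", path, bad, col.name)
        return out.to_numpy(dtype=float, na_value=np.nan)

    raw = np.column_stack([_numeric(df[c]) for c in raw_cols])
    corrected = np.column_stack([_numeric(df[c]) for c in corr_cols]) if corr_cols else None
    plex = df[plex_column] if plex_column in df.columns else df["Experiment"]
    meta = pd.DataFrame(
        {
            "psm_id": df["id"].astype(str) if "id" in df.columns else df.index.astype(str),
            "protein_group": df["Proteins"].astype(str),
            "plex": plex.astype(str),
            "experiment": df["Experiment"].astype(str),
        }
    )
    for src, dst in _META_MAP.items():
        meta[dst] = _numeric(df[src]) if src in df.columns else np.nan
    table = PSMTable(label_set=label_set, meta=meta, raw=raw, corrected=corrected)
    logger.info("read %d PSMs x %d channels from %s", len(table), n, path)
    return table


def write_psm_table(table: PSMTable, path: str | Path, plex_column: str = "Plex") -> None:
    """Write a PSM table in the MaxQuant column dialect."""
    n = table.label_set.n
    out = pd.DataFrame({"id": table.meta["psm_id"]})
    out["Proteins"] = table.meta["protein_group"]
    out["Experiment"] = table.meta["experiment"]
    out[plex_column] = table.meta["plex"]
    for src, dst in _META_MAP.items():
        out[src] = table.meta[dst]
    for k in range(n):
        out[f"Reporter intensity {k + 1}"] = table.raw[:, k]
    if table.corrected is not None:
        for k in range(n):
            out[f"Reporter intensity corrected {k + 1}"] = table.corrected[:, k]
    _to_tsv(out, path)
    logger.info("wrote %d PSMs to %s", len(table), path)


def read_design(path: str | Path, label_set: LabelSet) -> ExperimentalDesign:
    """Read a design TSV with columns plex, channel, role, sample, group."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("plex", "channel", "role") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: design file missing columns {missing}")
    df = df.replace("", pd.NA)
    return ExperimentalDesign(label_set=label_set, table=df)


def write_design(design: ExperimentalDesign, path: str | Path) -> None:
    _to_tsv(design.table, path)


def _wide_columns(design: ExperimentalDesign) -> dict[str, str]:
    """sample name -> proteinGroups-style wide column header."""
    cols = {}
    sub = design.table[design.table["role"] == "sample"]
    for _, row in sub.iterrows():
        k = design.label_set.index(row["channel"]) + 1
        cols[row["sample"]] = f"Reporter intensity corrected {k} {row['plex']}"
    return cols


def write_quant_matrix(qm: QuantMatrix, path: str | Path, design: ExperimentalDesign) -> None:
    """Write wide (proteinGroups dialect) and tidy long quantification tables.

    The long variant goes to ``<path stem>.long.tsv`` next to the wide file;
    missing cells are empty fields in the wide table and omitted rows in the
    long one.
    """
    path = Path(path)
    colmap = _wide_columns(design)
    wide = qm.values.rename(columns=colmap)
    wide.index.name = "Protein group"
    _to_tsv(wide, path, index=True)
    long = (
        qm.values.stack()
        .rename("value")
        .reset_index()
        .rename(columns={"level_0": "protein_group", "level_1": "sample"})
    )
    long.columns = ["protein_group", "sample", "value"]
    support = qm.support.stack().rename("n_psms").reset_index()
    support.columns = ["protein_group", "sample", "n_psms"]
    long = long.merge(support, on=["protein_group", "sample"], how="left")
    long_path = path.with_suffix(".long.tsv")
    _to_tsv(long, long_path)
    logger.info(
        "wrote %s quant matrix (%d groups x %d samples) to %s (+ %s)",
        qm.kind, qm.values.shape[0], qm.values.shape[1], path, long_path,
    )


def read_quant_matrix(path: str | Path, design: ExperimentalDesign, kind: str = "wm_normalized") -> QuantMatrix:
    """Read a wide quantification table back into a QuantMatrix."""
    df = pd.read_csv(path, sep="\t", index_col="Protein group",
                     float_precision="round_trip")
    inverse = {v: k for k, v in _wide_columns(design).items()}
    unknown = [c for c in df.columns if c not in inverse]
    if unknown:
        raise ValueError(f"{path}: columns not in design: {unknown}")
    values = df.rename(columns=inverse).reindex(columns=design.samples)
    values.index.name = "protein_group"
    support = values.notna().astype(int)
    return QuantMatrix(values=values, kind=kind, support=support, config={"source": str(path)})


def write_embedding(emb: Embedding, path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample": emb.sample_names, "dim1": emb.coordinates[:, 0], "dim2": emb.coordinates[:, 1]}
    )
    _to_tsv(df, path)


def read_embedding(path: str | Path, method: str = "external") -> Embedding:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in ("sample", "dim1", "dim2") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: embedding file missing columns {missing}")
    return Embedding(
        coordinates=df[["dim1", "dim2"]].to_numpy(dtype=float),
        sample_names=df["sample"].astype(str).tolist(),
        method=method,  # type: ignore[arg-type]
    )


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """PSM-level ground-truth sidecar: species, abundance and true PIF per PSM."""
    out = gt.psm.merge(gt.proteins[["protein_id", "abundance"]],
                       left_on="protein_group", right_on="protein_id", how="left")
    _to_tsv(out.drop(columns=["protein_id"]), path)
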