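"""Tabular I/O for the pipeline's artifacts.

The universal in-memory container is :class:`LabelledMatrix`: a cells x genes
table of non-negative expression values (TPM-like units) with one class label
per cell.  On disk, matrices are delimited text (TSV or CSV, inferred from the
extension) with row and column headers, optionally MatrixMarket triplets with
separate id files.  Ranked lists are TSV, IFS curves CSV, rule sets JSON plus
a human-readable text rendering.  All writers and readers are inverse pairs on
valid data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "LabelledMatrix",
    "load_matrix",
    "load_matrix_mtx",
    "write_matrix",
    "read_labels",
    "write_ranked_list",
    "read_ranked_list",
    "write_ifs_curve",
    "read_ifs_curve",
    "write_rules",
    "read_rules",
]

#: reserved column name under which labels may be embedded in a cells x genes table
LABEL_COLUMN = "__label__"


@dataclass
class LabelledMatrix:
    """Cells x genes expression matrix with one class label per cell.

    Parameters
    ----------
    values
        2-D float array, cells in rows, genes in columns; non-negative, finite.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    labels
        One class-label string per cell, aligned with ``cell_ids``.
    """

    values: np.ndarray
    cell_ids: list[str] = field(repr=False)
    gene_ids: list[str] = field(repr=False)
    labels: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = [str(l) for l in self.labels]
        if self.values.ndim != 2:
            raise ValidationError("expression values must form a 2-D table")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValidationError(
                f"id counts ({len(self.cell_ids)} cells, {len(self.gene_ids)} genes) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(self.labels) != n:
            raise ValidationError(f"{len(self.labels)} labels for {n} cells")
        if len(set(self.cell_ids)) != n:
            raise FormatError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise FormatError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            bad = [self.cell_ids[i] for i in np.unique(np.where(~np.isfinite(self.values))[0])]
            raise ValidationError(f"non-finite expression values in cells: {bad[:10]}")
        if np.any(self.values < 0):
            bad = [self.cell_ids[i] for i in np.unique(np.where(self.values < 0)[0])]
            raise ValidationError(f"negative expression values in cells: {bad[:10]}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for l in self.labels:
            counts[l] = counts.get(l, 0) + 1
        return counts

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Column indices of ``gene_ids``; raises on unknown ids."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise ValidationError(f"unknown gene ids: {missing[:10]}")
        return np.asarray([pos[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids: Sequence[str]) -> "LabelledMatrix":
        idx = self.gene_index(gene_ids)
        return LabelledMatrix(
            self.values[:, idx], list(self.cell_ids), [self.gene_ids[i] for i in idx], list(self.labels)
        )

    def subset_cells(self, index: Sequence[int]) -> "LabelledMatrix":
        idx = np.asarray(index, dtype=int)
        return LabelledMatrix(
            self.values[idx],
            [self.cell_ids[i] for i in idx],
            list(self.gene_ids),
            [self.labels[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def require_trainable(self) -> None:
        """Check the invariants any classifier-training stage needs."""
        counts = self.class_counts()
        if len(counts) < 2:
            raise ValidationError("training requires at least 2 distinct class labels")
        small = {c: n for c, n in counts.items() if n < 2}
        if small:
            raise ValidationError(f"training requires >=2 cells per class; too small: {small}")


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (cell_id, label) table into a mapping."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"label table {path} needs two columns (cell_id, label)")
    cells, labels = df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist()
    if len(set(cells)) != len(cells):
        raise FormatError(f"duplicate cell ids in label table {path}")
    return dict(zip(cells, labels))


def load_matrix(
    path: str | Path,
    orientation: str = "genes_by_cells",
    labels: str | Path | dict[str, str] | None = None,
) -> LabelledMatrix:
    """Load a delimited expression table into canonical cells x genes orientation.

    Parameters
    ----------
    path
        TSV or CSV file with row and column headers.
    orientation
        ``"genes_by_cells"`` (the common GEO deposit layout, default) or
        ``"cells_by_genes"``.
    labels
        Path to a two-column (cell_id, label) table, or an explicit mapping.
        May be omitted only when labels are embedded as the reserved
        ``__label__`` column of a cells x genes table.
    """
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path) as fh:  # pandas mangles duplicate header names, so check raw
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    if len(set(header)) != len(header):
        raise FormatError(f"duplicate column ids in {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    embedded: dict[str, str] | None = None
    if orientation == "cells_by_genes" and LABEL_COLUMN in df.columns:
        embedded = {str(c): str(l) for c, l in df[LABEL_COLUMN].items()}
        df = df.drop(columns=[LABEL_COLUMN])
    if orientation == "genes_by_cells":
        df = df.T
    # now cells x genes
    if df.index.duplicated().any():
        raise FormatError(f"duplicate cell ids in {path}")
    if df.columns.duplicated().any():
        raise FormatError(f"duplicate gene ids in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric expression values in {path}: {exc}") from exc

    if isinstance(labels, (str, Path)):
        label_map = read_labels(labels)
    elif isinstance(labels, dict):
        label_map = {str(k): str(v) for k, v in labels.items()}
    else:
        label_map = embedded
    if label_map is None:
        raise ValidationError("no labels supplied and none embedded in the matrix")
    cell_ids = [str(c) for c in df.index]
    missing = [c for c in cell_ids if c not in label_map]
    if missing:
        raise ValidationError(f"label table missing cells: {missing[:10]}")
    return LabelledMatrix(values, cell_ids, [str(g) for g in df.columns], [label_map[c] for c in cell_ids])


def load_matrix_mtx(
    mtx_path: str | Path,
    gene_ids_path: str | Path,
    cell_ids_path: str | Path,
    labels: str | Path | dict[str, str],
    orientation: str = "genes_by_cells",
) -> LabelledMatrix:
    """Load a sparse MatrixMarket triplet file with separate gene/cell id lists."""
    from scipy.io import mmread

    dense = np.asarray(mmread(str(mtx_path)).todense(), dtype=float)
    gene_ids = Path(gene_ids_path).read_text().split()
    cell_ids = Path(cell_ids_path).read_text().split()
    if orientation == "genes_by_cells":
        dense = dense.T
    elif orientation != "cells_by_genes":
        raise ValidationError(f"unknown orientation {orientation!r}")
    label_map = read_labels(labels) if isinstance(labels, (str, Path)) else dict(labels)
    missing = [c for c in cell_ids if c not in label_map]
    if missing:
        raise ValidationError(f"label table missing cells: {missing[:10]}")
    return LabelledMatrix(dense, cell_ids, gene_ids, [label_map[c] for c in cell_ids])


def write_matrix(
    data: LabelledMatrix,
    path: str | Path,
    labels_path: str | Path | None = None,
    orientation: str = "cells_by_genes",
) -> None:
    """Write the expression table (full precision) and, optionally, a label table."""
    path = Path(path)
    df = data.to_frame()
    if orientation == "genes_by_cells":
        df = df.T
    elif orientation != "cells_by_genes":
        raise ValidationError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")
    if labels_path is not None:
        labels_path = Path(labels_path)
        pd.DataFrame({"cell_id": data.cell_ids, "label": data.labels}).to_csv(
            labels_path, sep=_sep_for(labels_path), index=False
        )


# ---------------------------------------------------------------------------
# ranked list / IFS curve / rules
# ---------------------------------------------------------------------------

def write_ranked_list(ranked, path: str | Path) -> None:
    """Write a ranked feature list as TSV with columns rank, gene_id, score."""
    path = Path(path)
    rows = [(i + 1, gid, score) for i, (gid, score) in enumerate(ranked.entries)]
    pd.DataFrame(rows, columns=["rank", "gene_id", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_ranked_list(path: str | Path):
    from .mrmr import RankedList

    df = pd.read_csv(Path(path), sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    if list(df.columns) != ["rank", "gene_id", "score"]:
        raise FormatError(f"unexpected ranked-list header in {path}: {list(df.columns)}")
    return RankedList(entries=list(zip(df["gene_id"], df["score"].astype(float))))


def write_ifs_curve(curve, path: str | Path) -> None:
    """Write an IFS curve as CSV: algorithm, n_features, mcc, acc, one per-class column."""
    classes = sorted({c for rec in curve.records for c in rec.evaluation.per_class_acc})
    rows = []
    for rec in curve.records:
        row = {
            "algorithm": curve.algorithm.algorithm,
            "n_features": rec.n_features,
            "mcc": rec.evaluation.mcc,
            "acc": rec.evaluation.acc,
        }
        for c in classes:
            row[f"acc_{c}"] = rec.evaluation.per_class_acc.get(c, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), sep=",", index=False, float_format="%.17g")


def read_ifs_curve(path: str | Path) -> pd.DataFrame:
    """Read an IFS-curve CSV back as the tabular view written by :func:`write_ifs_curve`."""
    return pd.read_csv(Path(path), sep=",", float_precision="round_trip")


def _rule_to_dict(rule) -> dict:
    return {
        "conditions": [
            {"gene_id": g, "comparator": op, "threshold": float(t)} for g, op, t in rule.conditions
        ],
        "class": rule.predicted_class,
        "support": int(rule.support),
        "purity": float(rule.purity),
    }


def write_rules(rules, path: str | Path, text_path: str | Path | None = None) -> None:
    """Write a rule set as JSON; optionally also a human-readable text rendering."""
    path = Path(path)
    payload = {
        "feature_ids": list(rules.feature_ids),
        "rules": [_rule_to_dict(r) for r in rules.rules],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    if text_path is not None:
        Path(text_path).write_text(render_rules_text(rules))


def render_rules_text(rules) -> str:
    lines = [f"{len(rules.rules)} classification rules over {len(rules.feature_ids)} features", ""]
    for i, r in enumerate(rules.rules, 1):
        conds = " AND ".join(f"{g} {op} {t:.6g}" for g, op, t in r.conditions) or "(always)"
        lines.append(
            f"Rule {i}: IF {conds} THEN class = {r.predicted_class} "
            f"[support={r.support}, purity={r.purity:.3f}]"
        )
    return "\n".join(lines) + "\n"


def read_rules(path: str | Path):
    from .rules import Rule, RuleSet

    payload = json.loads(Path(path).read_text())
    rules = [
        Rule(
            conditions=[(c["gene_id"], c["comparator"], float(c["threshold"])) for c in r["conditions"]],
            predicted_class=r["class"],
            support=int(r["support"]),
            purity=float(r["purity"]),
        )
        for r in payload["rules"]
    ]
    return RuleSet(rules=rules, feature_ids=list(payload["feature_ids"]))
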