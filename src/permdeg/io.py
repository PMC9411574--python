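"""Reading and writing count matrices, group designs, panels and result tables.

All tabular formats are plain tab-separated UTF-8 text with a ``.`` decimal
separator and unquoted identifiers.  Count matrices can also be exchanged as
MatrixMarket coordinate files with ``.genes.txt`` / ``.samples.txt`` sidecars.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    CountsFormatError,
    DesignError,
    DuplicateRecordError,
    MismatchError,
)

__all__ = [
    "CountMatrix",
    "GenePanel",
    "read_counts",
    "write_counts",
    "read_groups",
    "read_panel",
    "write_deg_table",
    "read_deg_table",
    "DEG_TABLE_COLUMNS",
]

#: Column order of a serialized DEG table.
DEG_TABLE_COLUMNS = [
    "gene_id",
    "mean_cpm_control",
    "mean_cpm_treated",
    "log2fc",
    "t_stat",
    "p_adj",
    "call",
]


@dataclasses.dataclass
class CountMatrix:
    """A gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column; order matches ``counts``.
    counts
        Integer array of shape ``(len(gene_ids), len(sample_ids))``.
    groups
        Optional map from sample id to group label.  When present there must
        be exactly two distinct labels and each group needs at least two
        members.
    control_label
        Which of the two labels plays the role of the untreated/control
        group.  Required whenever ``groups`` is set.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    groups: dict[str, str] | None = None
    control_label: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise CountsFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise DuplicateRecordError(f"duplicate gene ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise DuplicateRecordError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)) or np.any(
                self.counts != np.round(self.counts)
            ):
                bad = np.argwhere(self.counts != np.round(self.counts))
                loc = ""
                if bad.size:
                    g, s = bad[0]
                    loc = f" (first at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r})"
                raise CountsFormatError(f"counts must be integral{loc}")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise CountsFormatError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.groups is not None:
            self.set_groups(self.groups, self.control_label)

    # -- design ---------------------------------------------------------

    def set_groups(self, groups: Mapping[str, str], control_label: str | None) -> None:
        """Attach and validate a two-group design."""
        missing = [s for s in self.sample_ids if s not in groups]
        if missing:
            raise MismatchError(f"samples without a group label: {missing}")
        extra = [s for s in groups if s not in self.sample_ids]
        if extra:
            raise MismatchError(f"group file samples absent from counts: {extra}")
        labels = sorted(set(groups.values()))
        if len(labels) != 2:
            raise DesignError(f"need exactly 2 group labels, got {labels}")
        if control_label is None:
            raise DesignError("control_label must name one of the two groups")
        if control_label not in labels:
            raise DesignError(
                f"control label {control_label!r} not among group labels {labels}"
            )
        for lab in labels:
            n = sum(1 for v in groups.values() if v == lab)
            if n < 2:
                raise DesignError(f"group {lab!r} has {n} samples; need >= 2")
        self.groups = dict(groups)
        self.control_label = control_label

    @property
    def treated_label(self) -> str:
        if self.groups is None:
            raise DesignError("no groups attached")
        labels = set(self.groups.values())
        labels.discard(self.control_label)
        return labels.pop()

    def group_mask(self) -> np.ndarray:
        """Boolean vector over sample order; True marks treated samples."""
        if self.groups is None:
            raise DesignError("no groups attached")
        return np.array(
            [self.groups[s] != self.control_label for s in self.sample_ids]
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclasses.dataclass
class GenePanel:
    """An ordered, named list of genes to screen, with optional role tags."""

    name: str
    gene_ids: list[str]
    role_tags: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise DesignError(f"panel {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DuplicateRecordError(
                f"panel {self.name!r} has duplicate gene ids"
            )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


# ---------------------------------------------------------------------------
# count matrices


def read_counts(
    path: str | Path,
    format: str = "tsv",
    allow_noninteger: bool = False,
) -> CountMatrix:
    """Read a count matrix from a TSV or MatrixMarket file.

    TSV layout: first column gene ids, header row of sample ids, integer
    cells.  MTX layout: a coordinate MatrixMarket file ``X.mtx`` with sidecar
    files ``X.genes.txt`` and ``X.samples.txt`` (one id per line).

    With ``allow_noninteger`` fractional cells (e.g. estimated counts) are
    rounded half-to-even instead of rejected.
    """
    path = Path(path)
    if format == "tsv":
        return _read_counts_tsv(path, allow_noninteger)
    if format == "mtx":
        return _read_counts_mtx(path, allow_noninteger)
    raise CountsFormatError(f"unknown counts format {format!r}")


def _coerce_integral(values: np.ndarray, allow_noninteger: bool, where: str) -> np.ndarray:
    if np.issubdtype(values.dtype, np.integer):
        return values.astype(np.int64)
    if not np.all(np.isfinite(values)):
        raise CountsFormatError(f"non-finite count in {where}")
    rounded = np.rint(values)  # rint rounds half to even
    if not allow_noninteger and np.any(values != rounded):
        bad = np.argwhere(np.atleast_2d(values != rounded))[0]
        raise CountsFormatError(
            f"non-integer count {np.atleast_2d(values)[tuple(bad)]!r} in {where} "
            f"at row {bad[0] + 1}, column {bad[1] + 1} "
            "(use allow_noninteger to round estimated counts)"
        )
    return rounded.astype(np.int64)


def _read_counts_tsv(path: Path, allow_noninteger: bool) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise CountsFormatError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateRecordError(f"duplicate gene ids in {path}: {dupes[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise CountsFormatError(f"non-numeric cell in {path}: {exc}") from exc
    values = _coerce_integral(values, allow_noninteger, str(path))
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=values,
    )


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")  # strips the trailing .mtx
    return (
        stem.with_suffix(".genes.txt"),
        stem.with_suffix(".samples.txt"),
    )


def _read_counts_mtx(path: Path, allow_noninteger: bool) -> CountMatrix:
    genes_path, samples_path = _sidecar_paths(path)
    for p in (genes_path, samples_path):
        if not p.exists():
            raise FileNotFoundError(f"missing sidecar file {p} for {path}")
    mat = scipy.io.mmread(path)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    values = _coerce_integral(dense, allow_noninteger, str(path))
    gene_ids = genes_path.read_text().split()
    sample_ids = samples_path.read_text().split()
    if len(gene_ids) != values.shape[0] or len(sample_ids) != values.shape[1]:
        raise CountsFormatError(
            f"sidecar lengths ({len(gene_ids)} genes, {len(sample_ids)} samples) "
            f"do not match matrix shape {values.shape}"
        )
    return CountMatrix(gene_ids=gene_ids, sample_ids=sample_ids, counts=values)


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a count matrix as TSV or MatrixMarket (+ id sidecars)."""
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")
    elif format == "mtx":
        genes_path, samples_path = _sidecar_paths(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts))
        genes_path.write_text("\n".join(cm.gene_ids) + "\n")
        samples_path.write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise CountsFormatError(f"unknown counts format {format!r}")


# ---------------------------------------------------------------------------
# designs and panels


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV into an ordered mapping.

    A header line ``sample\\tgroup`` is permitted and skipped.  Exactly two
    distinct labels are required; which one is the control group is decided
    by configuration, not by this file.
    """
    path = Path(path)
    groups: dict[str, str] = {}
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if lines and lines[0].lower().split("\t")[:2] == ["sample", "group"]:
        lines = lines[1:]
    for i, ln in enumerate(lines, start=1):
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise DesignError(f"{path}:{i}: expected 2 tab-separated columns")
        sample, label = parts[0].strip(), parts[1].strip()
        if sample in groups:
            raise DuplicateRecordError(f"{path}: duplicate sample id {sample!r}")
        groups[sample] = label
    labels = set(groups.values())
    if len(labels) != 2:
        raise DesignError(
            f"{path}: need exactly 2 distinct group labels, got {sorted(labels)}"
        )
    return groups


def read_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Read a gene panel: two-column TSV (gene_id, tag) or one gene per line."""
    path = Path(path)
    gene_ids: list[str] = []
    tags: dict[str, str] = {}
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        gene_ids.append(parts[0])
        if len(parts) > 1 and parts[1]:
            tags[parts[0]] = parts[1]
    return GenePanel(
        name=name or path.stem, gene_ids=gene_ids, role_tags=tags or None
    )


# ---------------------------------------------------------------------------
# result tables


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DEG table as TSV with >= 6 significant digits on floats.

    Columns are ``gene_id, mean_cpm_control, mean_cpm_treated, log2fc,
    t_stat, p_adj, call`` in the table's row order.
    """
    out = table.reset_index() if "gene_id" not in table.columns else table
    missing = [c for c in DEG_TABLE_COLUMNS if c not in out.columns]
    if missing:
        raise MismatchError(f"DEG table missing columns {missing}")
    out[DEG_TABLE_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a DEG table written by :func:`write_deg_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "call": str})
    missing = [c for c in DEG_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MismatchError(f"{path} missing columns {missing}")
    return df
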