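"""Readers and writers for the pipeline's tabular artifacts.

Canonical dialect: tab-separated UTF-8 with ``#`` comment lines.  Gene
identifiers are opaque, case-sensitive strings (real annotations mix
styles such as ``Y65B4BR.6`` and ``Contig60-snapTAU.52``).  All paths may
be gzip-compressed (detected by a ``.gz`` suffix).

Library sizes are explicit metadata — carried in ``#library_size_*=``
header comments or passed as arguments — never inferred from column
sums, because multi-mapped reads make column sums unreliable.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTable",
    "OrthologMap",
    "DomainAnnotation",
    "TermAnnotation",
    "GeneSetCollection",
    "ValidationError",
    "read_expression_table",
    "write_expression_table",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_domain_annotation",
    "read_term_annotation",
    "write_annotation",
    "read_gene_sets",
    "write_gene_sets_gmt",
    "write_tsv_report",
    "write_json_summary",
]


class ValidationError(ValueError):
    """Raised when an input file violates a format invariant."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# expression tables


@dataclass
class ExpressionTable:
    """Per-gene expression for one species: a tissue library paired with a
    whole-organism library.

    ``data`` columns: gene_id, length_bp, count_tissue, count_whole and,
    optionally, fpkm_tissue / fpkm_whole.  Missing FPKM columns are
    recomputed on demand from counts, gene length and library size.
    """

    species_label: str
    data: pd.DataFrame
    library_size_tissue: int
    library_size_whole: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = ["gene_id", "length_bp", "count_tissue", "count_whole"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"expression table missing columns: {missing}")
        if self.library_size_tissue <= 0 or self.library_size_whole <= 0:
            raise ValidationError("library sizes must be positive")
        dup = self.data["gene_id"][self.data["gene_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene_id: {dup.iloc[0]!r}")
        for col in ("count_tissue", "count_whole"):
            bad = np.flatnonzero(self.data[col].to_numpy() < 0)
            if bad.size:
                raise ValidationError(
                    f"negative {col} at row {int(bad[0]) + 1} "
                    f"(gene {self.data['gene_id'].iloc[bad[0]]!r})"
                )
        if np.any(self.data["length_bp"].to_numpy() <= 0):
            raise ValidationError("length_bp must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> list[str]:
        return self.data["gene_id"].tolist()

    def _fpkm(self, which: str) -> np.ndarray:
        col = f"fpkm_{which}"
        if col in self.data.columns:
            return self.data[col].to_numpy(dtype=float)
        lib = getattr(self, f"library_size_{which}")
        counts = self.data[f"count_{which}"].to_numpy(dtype=float)
        length = self.data["length_bp"].to_numpy(dtype=float)
        return counts * 1e9 / (length * lib)

    @property
    def fpkm_tissue(self) -> np.ndarray:
        return self._fpkm("tissue")

    @property
    def fpkm_whole(self) -> np.ndarray:
        return self._fpkm("whole")

    def fpkm_series(self, which: str) -> pd.Series:
        if which not in ("tissue", "whole"):
            raise ValueError("which must be 'tissue' or 'whole'")
        return pd.Series(self._fpkm(which), index=self.data["gene_id"].to_numpy())

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionTable":
        keep = set(gene_ids)
        sub = self.data[self.data["gene_id"].isin(keep)].reset_index(drop=True)
        return ExpressionTable(
            species_label=self.species_label,
            data=sub,
            library_size_tissue=self.library_size_tissue,
            library_size_whole=self.library_size_whole,
        )


def read_expression_table(
    path: str | Path,
    species_label: str,
    library_size_tissue: int | None = None,
    library_size_whole: int | None = None,
) -> ExpressionTable:
    """Read a per-species expression TSV.

    Library sizes come from ``#library_size_tissue=``/``#library_size_whole=``
    comment lines unless overridden by the keyword arguments.
    """
    meta: dict[str, int] = {}
    lines: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    key = key.strip()
                    if key in ("library_size_tissue", "library_size_whole"):
                        meta[key] = int(val.strip())
                continue
            lines.append(line)
    if not lines:
        raise ValidationError(f"{path}: no data rows")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", dtype={"gene_id": str})
    lt = library_size_tissue if library_size_tissue is not None else meta.get(
        "library_size_tissue"
    )
    lw = library_size_whole if library_size_whole is not None else meta.get(
        "library_size_whole"
    )
    if lt is None or lw is None:
        raise ValidationError(
            f"{path}: library sizes not found in header comments and not supplied"
        )
    return ExpressionTable(
        species_label=species_label,
        data=df,
        library_size_tissue=int(lt),
        library_size_whole=int(lw),
    )


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    df = table.data.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    with _open_text(path, "wt") as fh:
        fh.write(f"#library_size_tissue={table.library_size_tissue}\n")
        fh.write(f"#library_size_whole={table.library_size_whole}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# ortholog map


@dataclass
class OrthologMap:
    """Strictly one-to-one ortholog pairs between species A and B."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b

    def __post_init__(self) -> None:
        if list(self.pairs.columns) != ["gene_a", "gene_b"]:
            self.pairs = self.pairs.rename(
                columns=dict(zip(self.pairs.columns, ["gene_a", "gene_b"]))
            )
        for side in ("gene_a", "gene_b"):
            col = self.pairs[side]
            if col.isna().any() or (col.astype(str).str.len() == 0).any():
                raise ValidationError(f"empty id on side {side}")
            dup = col[col.duplicated()]
            if len(dup):
                raise ValidationError(
                    f"ortholog map is not one-to-one: {dup.iloc[0]!r} repeated"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ids_a(self) -> set[str]:
        return set(self.pairs["gene_a"])

    @property
    def ids_b(self) -> set[str]:
        return set(self.pairs["gene_b"])

    @property
    def a_to_b(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    @property
    def b_to_a(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_b"], self.pairs["gene_a"]))

    def swapped(self) -> "OrthologMap":
        return OrthologMap(
            pd.DataFrame(
                {"gene_a": self.pairs["gene_b"], "gene_b": self.pairs["gene_a"]}
            )
        )


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of one-to-one ortholog pairs (no header needed)."""
    rows: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[:2] == ["gene_a", "gene_b"]:
                continue
            if len(parts) < 2:
                raise ValidationError(f"{path}:{ln}: expected two columns")
            rows.append((parts[0].strip(), parts[1].strip()))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b"], dtype=str)
    return OrthologMap(df)


def write_ortholog_map(orthomap: OrthologMap, path: str | Path) -> None:
    df = orthomap.pairs.sort_values("gene_a", kind="mergesort")
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, header=True)


# ---------------------------------------------------------------------------
# many-to-many annotations


@dataclass
class DomainAnnotation:
    """Gene -> protein-domain (family) assignments, many-to-many."""

    assignments: pd.DataFrame  # columns: gene_id, family_id

    def __post_init__(self) -> None:
        self.assignments = self.assignments.drop_duplicates().reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.assignments)

    def families_of(self, gene_id: str) -> set[str]:
        df = self.assignments
        return set(df.loc[df["gene_id"] == gene_id, "family_id"])

    @property
    def family_ids(self) -> set[str]:
        return set(self.assignments["family_id"])


@dataclass
class TermAnnotation:
    """Gene -> functional term assignments (e.g. GO), many-to-many."""

    assignments: pd.DataFrame  # columns: gene_id, term_id[, term_label]

    def __post_init__(self) -> None:
        subset = ["gene_id", "term_id"]
        self.assignments = self.assignments.drop_duplicates(
            subset=subset
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.assignments)


def _read_pairs(path: str | Path, col2: str, extra: tuple[str, ...] = ()) -> pd.DataFrame:
    rows = []
    expected = 2 + len(extra)
    warned = False
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if ln == 1 and parts[0] == "gene_id":
                continue
            if len(parts) < 2:
                raise ValidationError(f"{path}:{ln}: expected at least two columns")
            if len(parts) > expected and not warned:
                logger.warning("%s: ignoring extra columns beyond %d", path, expected)
                warned = True
            row = [parts[0].strip(), parts[1].strip()]
            for i in range(len(extra)):
                row.append(parts[2 + i].strip() if len(parts) > 2 + i else "")
            rows.append(row)
    return pd.DataFrame(rows, columns=["gene_id", col2, *extra], dtype=str)


def read_domain_annotation(path: str | Path) -> DomainAnnotation:
    """Read gene→family TSV (duplicate rows collapsed silently)."""
    return DomainAnnotation(_read_pairs(path, "family_id"))


def read_term_annotation(path: str | Path) -> TermAnnotation:
    """Read gene→term TSV with optional third term_label column."""
    return TermAnnotation(_read_pairs(path, "term_id", ("term_label",)))


def write_annotation(ann: DomainAnnotation | TermAnnotation, path: str | Path) -> None:
    df = ann.assignments.sort_values(
        list(ann.assignments.columns), kind="mergesort"
    )
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene-set collections


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally tagged with a species label per set."""

    sets: dict[str, frozenset[str]]
    species_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


def read_gene_sets(
    path: str | Path, format: str = "plain", species_label: str | None = None
) -> GeneSetCollection:
    """Read gene sets from a plain list (one id per line, set named after
    the file stem) or a GMT file (name, description, ids...)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    if format == "plain":
        ids: list[str] = []
        with _open_text(path) as fh:
            for line in fh:
                tok = line.strip()
                if tok and not tok.startswith("#"):
                    ids.append(tok)
        name = path.name
        for suffix in (".gz", ".txt", ".tsv", ".list"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        if not ids:
            raise ValidationError(f"{path}: empty gene set")
        sets[name] = frozenset(ids)
    elif format == "gmt":
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = [p.strip() for p in line.rstrip("\n").split("\t")]
                if len(parts) < 3:
                    raise ValidationError(f"{path}:{ln}: GMT needs name, desc, ids")
                name, _desc, *ids = parts
                ids = [i for i in ids if i]
                if name in sets:
                    raise ValidationError(f"{path}:{ln}: duplicate set name {name!r}")
                if not ids:
                    raise ValidationError(f"{path}:{ln}: set {name!r} is empty")
                sets[name] = frozenset(ids)
    else:
        raise ValueError(f"unknown format {format!r}")
    if species_label is not None:
        labels = {name: species_label for name in sets}
    return GeneSetCollection(sets=sets, species_labels=labels)


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for name in sorted(collection.sets):
            desc = collection.species_labels.get(name, "na")
            ids = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{ids}\n")


# ---------------------------------------------------------------------------
# generic report output


def write_tsv_report(report: pd.DataFrame, path: str | Path, sort_by: str | None = None) -> None:
    """Write a result table deterministically: rows sorted by the primary
    key (first column unless given), floats at 6 significant digits."""
    df = report.copy()
    key = sort_by if sort_by is not None else (df.columns[0] if len(df.columns) else None)
    if key is not None and len(df):
        df = df.sort_values(key, kind="mergesort")
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _jsonable(obj):
    if hasattr(obj, "to_dict") and not isinstance(obj, (pd.DataFrame, pd.Series)):
        return _jsonable(obj.to_dict())
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj)
        if isinstance(obj, (set, frozenset)):
            items = sorted(items)
        return [_jsonable(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_json_summary(run: Mapping, path: str | Path) -> None:
    """Serialise a pipeline run summary (must carry a 'thresholds' block)."""
    payload = _jsonable(run)
    if "thresholds" not in payload:
        raise ValidationError("run summary must contain a 'thresholds' block")
    with _open_text(path, "wt") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
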