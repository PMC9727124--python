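"""Domain types and text-format readers/writers.

Every downstream stage consumes only the containers defined here:

* :class:`ExpressionMatrix` — a gene × sample numeric matrix with a declared
  scale (raw ``counts`` or ``log2norm`` log2-normalised values),
* :class:`GeneSignature` / :class:`SignatureCollection` — named gene sets with
  a category tag (immune cell-type markers, functional signatures, an
  ESTIMATE-style immune gene set, hallmark sets, pathways),
* :class:`SampleAnnotations` — per-sample clinical covariates (PD-L1 combined
  positive score, molecular subtype, progression-free survival, checkpoint
  inhibitor response, batch, plasma IL-18).

File formats are plain delimited text (TSV/CSV, delimiter auto-detected) and
the Broad GMT dialect for gene sets.  Gene identifiers are matched by exact,
case-sensitive string equality throughout the package; callers are expected to
pre-harmonise aliases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "SignatureCollection",
    "SampleAnnotations",
    "SIGNATURE_CATEGORIES",
    "SUBTYPES",
    "RESPONSES",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "read_sample_annotations",
    "write_sample_annotations",
    "annotations_to_frame",
]

SIGNATURE_CATEGORIES = ("cell_type", "function", "immune_estimate", "hallmark", "pathway")
SUBTYPES = ("CIN", "GS", "EBV", "MSI", "unknown")
RESPONSES = ("responder", "non_responder", "unknown")

EXPRESSION_SCALES = ("counts", "log2norm")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class ExpressionMatrix:
    """Gene × sample expression matrix with a declared scale.

    Parameters
    ----------
    values
        DataFrame with genes in rows (index = gene ids) and samples in
        columns (columns = sample ids).  No missing values allowed.
    scale
        ``"counts"`` for raw non-negative counts, ``"log2norm"`` for
        log2-transformed normalised values.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise ValueError(f"scale must be one of {EXPRESSION_SCALES}, got {self.scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy(dtype=float, copy=False)
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "counts" and (arr < 0).any():
            raise ValueError("counts matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Submatrix restricted to ``genes`` present in the matrix (matrix order)."""
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.scale)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with a category tag."""

    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in SIGNATURE_CATEGORIES:
            raise ValueError(
                f"category must be one of {SIGNATURE_CATEGORIES}, got {self.category!r}"
            )
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")

    def matched(self, gene_ids: Iterable[str]) -> list[str]:
        """Genes of this set present among ``gene_ids``, in ``gene_ids`` order."""
        return [g for g in gene_ids if g in self.genes]


@dataclass
class SignatureCollection:
    """A list of gene signatures; names are unique within each category."""

    signatures: list[GeneSignature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for sig in self.signatures:
            key = (sig.category, sig.name)
            if key in seen:
                raise ValueError(f"duplicate signature name {sig.name!r} in category {sig.category!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    def by_category(self, category: str) -> "SignatureCollection":
        return SignatureCollection([s for s in self.signatures if s.category == category])

    def get(self, name: str, category: str | None = None) -> GeneSignature:
        for s in self.signatures:
            if s.name == name and (category is None or s.category == category):
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signatures]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.signatures:
            out |= s.genes
        return out

    def extend(self, other: "SignatureCollection") -> "SignatureCollection":
        return SignatureCollection(self.signatures + list(other.signatures))


@dataclass
class SampleAnnotations:
    """Clinical covariates for one sample.

    ``cps`` is the PD-L1 combined positive score; ``pfs_time`` is
    progression-free survival in months with ``pfs_event`` True for a
    progression/death event; ``il18`` is the plasma IL-18 level in pg/mL.
    Unknown columns from the source table are kept in ``extras``.
    """

    sample_id: str
    cps: float | None = None
    subtype: str = "unknown"
    pfs_time: float | None = None
    pfs_event: bool | None = None
    response: str = "unknown"
    batch: str | None = None
    il18: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"subtype must be one of {SUBTYPES}, got {self.subtype!r}")
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}, got {self.response!r}")
        if self.cps is not None and self.cps < 0:
            raise ValueError("cps must be non-negative")
        if self.pfs_time is not None and self.pfs_time <= 0:
            raise ValueError("pfs_time must be positive")
        if self.pfs_event is not None and self.pfs_time is None:
            raise ValueError(f"sample {self.sample_id!r}: pfs_event given without pfs_time")
        if self.il18 is not None and self.il18 < 0:
            raise ValueError("il18 must be non-negative")


# ---------------------------------------------------------------------------
# delimited-text helpers
# ---------------------------------------------------------------------------

def _detect_delimiter(path: Path) -> str:
    """Pick tab or comma from the header line; ties go to tab."""
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file")
    return "," if header.count(",") > header.count("\t") else "\t"


def read_expression_table(
    path: str | Path,
    scale_hint: str = "log2norm",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a delimited gene × sample expression table.

    First column holds gene ids, header row holds sample ids.  Duplicate gene
    rows are collapsed — summed on the counts scale, averaged on the log2
    scale — with a warning.  ``transpose=True`` accepts sample-in-rows files.
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty and df.shape[1] == 0:
        raise FormatError(f"{path}: no data columns")
    df.index = df.index.astype(str)
    def _to_float(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    numeric = df.map(_to_float)  # float() parses exactly; bad cells become NaN
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(f"{path}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}")
    if transpose:
        numeric = numeric.T
    if numeric.index.has_duplicates:
        dups = numeric.index[numeric.index.duplicated()].unique().tolist()
        warnings.warn(
            f"collapsing duplicate gene rows {dups} by "
            f"{'sum' if scale_hint == 'counts' else 'mean'}",
            stacklevel=2,
        )
        agg = "sum" if scale_hint == "counts" else "mean"
        numeric = numeric.groupby(level=0, sort=False).agg(agg)
    numeric.index.name = "gene_id"
    return ExpressionMatrix(numeric.astype(float), scale_hint)


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV, full precision (round-trips exactly through repr)."""
    df = expr.values
    if expr.scale == "counts" and np.allclose(df.to_numpy() % 1, 0):
        df = df.astype(int)
        df.to_csv(Path(path), sep="\t", index_label="gene_id")
    else:
        # %.17g round-trips float64 exactly
        df.to_csv(Path(path), sep="\t", index_label="gene_id", float_format="%.17g")


def read_gmt(path: str | Path, category: str) -> SignatureCollection:
    """Read a Broad-dialect GMT file: name, description, then gene ids, tab-separated."""
    path = Path(path)
    sigs: list[GeneSignature] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\t")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in names:
                raise FormatError(f"{path}:{lineno}: duplicate signature name {name!r}")
            names.add(name)
            sigs.append(GeneSignature(name=name, category=category, genes=frozenset(genes)))
    return SignatureCollection(sigs)


def write_gmt(collection: SignatureCollection, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for sig in collection:
            fh.write("\t".join([sig.name, sig.category] + sorted(sig.genes)) + "\n")


_ANNOT_COLUMNS = ("sample_id", "cps", "subtype", "pfs_time", "pfs_event", "response", "batch", "il18")

_TRUTHY = {"1", "true", "True", "TRUE", "yes"}
_FALSY = {"0", "false", "False", "FALSE", "no"}


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "NaN", "nan"):
        return None
    return float(value)


def _opt_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip()
    if s in ("", "NA", "NaN", "nan"):
        return None
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    return bool(float(s))


def read_sample_annotations(path: str | Path) -> list[SampleAnnotations]:
    """Read a delimited annotation table with a required ``sample_id`` column.

    Recognised columns: cps, subtype, pfs_time, pfs_event, response, batch,
    il18.  Other columns are preserved verbatim in ``extras``.  Missing
    optional fields become None / "unknown".
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample_id(s): {dups}")
    extras_cols = [c for c in df.columns if c not in _ANNOT_COLUMNS]
    records: list[SampleAnnotations] = []
    for _, row in df.iterrows():
        def col(name):
            return row[name] if name in df.columns else None

        subtype = col("subtype")
        subtype = subtype if isinstance(subtype, str) and subtype.strip() else "unknown"
        response = col("response")
        response = response if isinstance(response, str) and response.strip() else "unknown"
        batch = col("batch")
        batch = batch if isinstance(batch, str) and batch.strip() else None
        records.append(
            SampleAnnotations(
                sample_id=str(row["sample_id"]),
                cps=_opt_float(col("cps")),
                subtype=subtype,
                pfs_time=_opt_float(col("pfs_time")),
                pfs_event=_opt_bool(col("pfs_event")),
                response=response,
                batch=batch,
                il18=_opt_float(col("il18")),
                extras={c: row[c] for c in extras_cols},
            )
        )
    return records


def annotations_to_frame(annotations: Sequence[SampleAnnotations]) -> pd.DataFrame:
    """Tabular view of annotation records, indexed by sample_id."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "sample_id": a.sample_id,
                "cps": a.cps,
                "subtype": a.subtype,
                "pfs_time": a.pfs_time,
                "pfs_event": a.pfs_event,
                "response": a.response,
                "batch": a.batch,
                "il18": a.il18,
                **a.extras,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def write_sample_annotations(annotations: Sequence[SampleAnnotations], path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(Path(path), sep="\t")
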