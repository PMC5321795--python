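"""Reading and writing expression matrices, sample sheets and result tables.

The canonical on-disk formats are plain UTF-8 TSV files:

* expression matrix — first column ``gene_id``, remaining columns sample ids,
  values in FPKM-like units (non-negative reals);
* sample sheet — columns ``sample_id``, ``condition``, ``replicate``, ``zt``
  (Zeitgeber Time in hours);
* result tables — one row per gene, ``NA`` for missing values.

Validation is strict: the reader rejects anything violating the
:class:`TimeCourseMatrix` invariants instead of silently coercing, because the
downstream Z-scoring assumes every gene shares one balanced sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "TimeCourseMatrix",
    "read_matrix",
    "write_matrix",
    "write_table",
    "read_table",
]

PathLike = Union[str, Path]

SAMPLESHEET_COLUMNS = ["sample_id", "condition", "replicate", "zt"]


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: condition label, biological replicate, ZT (h)."""

    sample_id: str
    condition: str
    replicate: int
    zt: float


@dataclass
class TimeCourseMatrix:
    """Gene x sample expression matrix with per-sample design metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative expression values, index = gene ids,
        columns = sample ids.
    samples
        DataFrame indexed by sample id with columns ``condition``,
        ``replicate`` and ``zt``, aligned to ``values.columns``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.samples["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def condition_samples(self, condition: str) -> pd.DataFrame:
        """Sample sheet rows for one condition, sorted by (replicate, zt)."""
        sub = self.samples[self.samples["condition"] == condition]
        if sub.empty:
            raise ValueError(f"condition {condition!r} not present in matrix")
        return sub.sort_values(["replicate", "zt"])

    def sample_meta(self) -> list[SampleMeta]:
        return [
            SampleMeta(str(sid), str(row["condition"]), int(row["replicate"]), float(row["zt"]))
            for sid, row in self.samples.iterrows()
        ]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        vals = self.values
        meta = self.samples

        if vals.index.duplicated().any():
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if list(vals.columns) != list(meta.index):
            missing = set(vals.columns) ^ set(meta.index)
            raise ValueError(
                "matrix columns and sample sheet disagree; mismatched sample ids: "
                f"{sorted(missing) or 'order differs'}"
            )

        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(vals)
            raise ValueError(f"non-numeric expression value at {bad}")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value for gene {vals.index[g]!r}, sample {vals.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value {arr[g, s]} for gene "
                f"{vals.index[g]!r}, sample {vals.columns[s]!r}"
            )

        trip = meta[["condition", "replicate", "zt"]]
        if trip.duplicated().any():
            dup = trip[trip.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate (condition, replicate, zt) triple: {tuple(dup)}"
            )
        _check_balanced(meta)


def _first_non_numeric(vals: pd.DataFrame) -> str:
    for g, row in vals.iterrows():
        for s, v in row.items():
            try:
                float(v)
            except (TypeError, ValueError):
                return f"gene {g!r}, sample {s!r} (value {v!r})"
    return "unknown position"


def _check_balanced(meta: pd.DataFrame) -> None:
    """Every condition must carry the same set of (replicate, zt) cells."""
    cells = {
        cond: set(zip(sub["replicate"], sub["zt"]))
        for cond, sub in meta.groupby("condition", sort=False)
    }
    union: set = set().union(*cells.values())
    missing = {
        cond: sorted(union - have) for cond, have in cells.items() if union - have
    }
    if missing:
        desc = "; ".join(
            f"{cond} missing (replicate, zt) cells {cells_}" for cond, cells_ in missing.items()
        )
        raise ValueError(f"unbalanced design: {desc}")


def read_matrix(matrix_path: PathLike, samplesheet_path: PathLike) -> TimeCourseMatrix:
    """Read and validate an expression matrix plus its sample sheet.

    The matrix sample order is reconciled against the sample sheet by
    ``sample_id``; any id present in only one of the two files is a hard
    error naming the id.
    """
    vals = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if vals.columns[0] != "gene_id":
        raise ValueError(
            f"matrix file must start with a 'gene_id' column, got {vals.columns[0]!r}"
        )
    vals = vals.set_index("gene_id")

    meta = pd.read_csv(samplesheet_path, sep="\t", dtype={"sample_id": str, "condition": str})
    missing_cols = [c for c in SAMPLESHEET_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"sample sheet missing columns {missing_cols}")
    meta = meta.set_index("sample_id")

    only_matrix = [s for s in vals.columns if s not in meta.index]
    only_sheet = [s for s in meta.index if s not in vals.columns]
    if only_matrix or only_sheet:
        parts = []
        if only_matrix:
            parts.append(f"in matrix but not sample sheet: {only_matrix}")
        if only_sheet:
            parts.append(f"in sample sheet but not matrix: {only_sheet}")
        raise ValueError("sample id mismatch; " + "; ".join(parts))

    # coerce to float column-wise so a bad cell can be named
    for col in vals.columns:
        try:
            vals[col] = pd.to_numeric(vals[col], errors="raise")
        except (TypeError, ValueError):
            bad_gene = next(
                g for g, v in vals[col].items() if not _is_number(v)
            )
            raise ValueError(
                f"non-numeric expression value for gene {bad_gene!r}, sample {col!r}: "
                f"{vals.at[bad_gene, col]!r}"
            ) from None

    vals = vals[list(meta.index)]  # reconcile column order with sheet
    return TimeCourseMatrix(values=vals.astype(float), samples=meta)


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def write_matrix(tcm: TimeCourseMatrix, matrix_path: PathLike, samplesheet_path: PathLike) -> None:
    """Write a TimeCourseMatrix as matrix TSV + sample sheet TSV."""
    out = tcm.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.9g")
    meta = tcm.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(samplesheet_path, sep="\t")


def write_table(rows: Union[pd.DataFrame, Iterable[dict]], path: PathLike) -> None:
    """Write result records as a TSV with header.

    Floats are serialized with 9 significant digits; missing values as "NA".
    An empty record list yields a header-only file (requires a DataFrame so
    the schema is known).
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.9g")


def read_table(path: PathLike) -> pd.DataFrame:
    """Read a result table written by :func:`write_table` ("NA" -> missing)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
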