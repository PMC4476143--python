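"""Data model and I/O for OTU count tables and sample metadata.

Orientation convention used throughout the package: samples are rows,
OTUs are columns.  This matches the mothur ``.shared`` layout.

Two table dialects are supported:

``shared``
    mothur-style TSV with header ``label<TAB>Group<TAB>numOtus<TAB>Otu0001 ...``
    and one row per sample.
``matrix_tsv``
    plain TSV whose first column holds sample ids and whose remaining
    columns are OTU counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "OtuTableFormatError",
    "OtuTableValidationError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "relative_abundance",
    "subset",
]

#: calendar months accepted in metadata (full names, case preserved on output)
VALID_MONTHS = frozenset(
    [
        "January", "February", "March", "April", "May", "June",
        "July", "August", "September", "October", "November", "December",
    ]
)

#: covariate cell values parsed as missing, with the stored reason
MISSING_CODES = {"": "empty", "na": "na", "nan": "na", "n.d.": "no data",
                 "nd": "no data", "bdl": "below detection limit"}


class OtuTableFormatError(ValueError):
    """Raised when a table file cannot be parsed in the requested dialect."""


class OtuTableValidationError(ValueError):
    """Raised when parsed values violate the count-table contract."""


@dataclass
class OtuTable:
    """Samples x OTUs non-negative integer count matrix.

    Parameters
    ----------
    sample_ids :
        Ordered, unique sample labels (rows).
    otu_ids :
        Ordered, unique OTU labels (columns).
    counts :
        ``(n_samples, n_otus)`` array of non-negative integers.
    label :
        Free-text note on the OTU definition (e.g. ``"0.03"`` for 97%%
        identity clusters).
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    label: str = "0.03"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise OtuTableValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise OtuTableValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size and not np.all(np.isfinite(counts.astype(float))):
            raise OtuTableValidationError("counts contain non-finite values")
        if counts.size and np.any(counts.astype(float) != np.round(counts.astype(float))):
            i, j = np.argwhere(counts.astype(float) != np.round(counts.astype(float)))[0]
            raise OtuTableValidationError(
                f"non-integer count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise OtuTableValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise OtuTableValidationError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise OtuTableValidationError("duplicate OTU ids")
        if counts.size and np.any(counts.sum(axis=1) == 0):
            bad = [s for s, t in zip(self.sample_ids, counts.sum(axis=1)) if t == 0]
            raise OtuTableValidationError(f"zero-sum sample rows: {bad}")
        self.counts = counts

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        """Per-sample sequence totals (row sums)."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    # -- derived views ---------------------------------------------------

    def relative_abundance(self) -> pd.DataFrame:
        return relative_abundance(self)

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        otu_ids: Sequence[str] | None = None,
    ) -> "OtuTable":
        return subset(self, sample_ids=sample_ids, otu_ids=otu_ids)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Row-normalize counts to fractions; each row sums to 1.

    Zeros are preserved as exact zeros.  Zero-sum rows are a contract
    violation (they are dropped at read time) and raise.
    """
    totals = table.counts.sum(axis=1)
    if np.any(totals == 0):
        raise OtuTableValidationError("zero-sum sample row present")
    frac = table.counts / totals[:, None]
    return pd.DataFrame(frac, index=table.sample_ids, columns=table.otu_ids)


def subset(
    table: OtuTable,
    sample_ids: Sequence[str] | None = None,
    otu_ids: Sequence[str] | None = None,
) -> OtuTable:
    """Restrict a table to the requested samples and/or OTUs.

    Order of retained identifiers follows the request; counts are
    unchanged.  Unknown or empty id lists raise.
    """
    if sample_ids is None and otu_ids is None:
        raise ValueError("nothing to subset: give sample_ids and/or otu_ids")
    rows = np.arange(table.n_samples)
    cols = np.arange(table.n_otus)
    keep_samples = table.sample_ids
    keep_otus = table.otu_ids
    if sample_ids is not None:
        sample_ids = list(sample_ids)
        if not sample_ids:
            raise ValueError("empty sample id list")
        unknown = [s for s in sample_ids if s not in set(table.sample_ids)]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown}")
        index = {s: i for i, s in enumerate(table.sample_ids)}
        rows = np.array([index[s] for s in sample_ids])
        keep_samples = sample_ids
    if otu_ids is not None:
        otu_ids = list(otu_ids)
        if not otu_ids:
            raise ValueError("empty OTU id list")
        unknown = [o for o in otu_ids if o not in set(table.otu_ids)]
        if unknown:
            raise KeyError(f"unknown OTU ids: {unknown}")
        index = {o: j for j, o in enumerate(table.otu_ids)}
        cols = np.array([index[o] for o in otu_ids])
        keep_otus = otu_ids
    return OtuTable(
        sample_ids=list(keep_samples),
        otu_ids=list(keep_otus),
        counts=table.counts[np.ix_(rows, cols)],
        label=table.label,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_count_cell(value: str, sample: str, otu: str) -> int:
    try:
        x = float(value)
    except ValueError:
        raise OtuTableValidationError(
            f"non-numeric count {value!r} at sample {sample!r}, OTU {otu!r}"
        ) from None
    if x != round(x):
        raise OtuTableValidationError(
            f"non-integer count {value!r} at sample {sample!r}, OTU {otu!r}"
        )
    if x < 0:
        raise OtuTableValidationError(
            f"negative count {value!r} at sample {sample!r}, OTU {otu!r}"
        )
    return int(round(x))


def read_otu_table(path: str | Path, dialect: str = "shared") -> OtuTable:
    """Read an OTU count table.

    Zero-sum sample rows are dropped with a warning; all-zero OTU
    columns are retained.
    """
    path = Path(path)
    if dialect not in ("shared", "matrix_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise OtuTableFormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if dialect == "shared":
        if len(header) < 3 or header[0] != "label" or header[2] != "numOtus":
            raise OtuTableFormatError(
                f"{path}:1: malformed shared header {lines[0]!r} "
                "(expected 'label<TAB>Group<TAB>numOtus<TAB>...')"
            )
        otu_ids = header[3:]
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        label = "0.03"
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3 + len(otu_ids):
                raise OtuTableFormatError(
                    f"{path}:{ln}: expected {3 + len(otu_ids)} fields, "
                    f"got {len(parts)}: {line!r}"
                )
            label, sample = parts[0], parts[1]
            sample_ids.append(sample)
            rows.append(
                [_parse_count_cell(v, sample, o) for v, o in zip(parts[3:], otu_ids)]
            )
        counts = np.array(rows, dtype=np.int64).reshape(len(sample_ids), len(otu_ids))
    else:
        otu_ids = header[1:]
        if not otu_ids:
            raise OtuTableFormatError(f"{path}:1: matrix header has no OTU columns")
        sample_ids = []
        rows = []
        label = "matrix"
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 1 + len(otu_ids):
                raise OtuTableFormatError(
                    f"{path}:{ln}: expected {1 + len(otu_ids)} fields, "
                    f"got {len(parts)}: {line!r}"
                )
            sample = parts[0]
            sample_ids.append(sample)
            rows.append(
                [_parse_count_cell(v, sample, o) for v, o in zip(parts[1:], otu_ids)]
            )
        counts = np.array(rows, dtype=np.int64).reshape(len(sample_ids), len(otu_ids))

    totals = counts.sum(axis=1) if counts.size else np.zeros(len(sample_ids), int)
    keep = totals > 0
    dropped = [s for s, k in zip(sample_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-sum samples: {dropped}", UserWarning)
    return OtuTable(
        sample_ids=[s for s, k in zip(sample_ids, keep) if k],
        otu_ids=otu_ids,
        counts=counts[keep],
        label=label,
    )


def write_otu_table(table: OtuTable, path: str | Path, dialect: str = "shared") -> None:
    """Write a table in the named dialect (UTF-8, tab-separated)."""
    path = Path(path)
    if dialect == "shared":
        lines = ["\t".join(["label", "Group", "numOtus", *table.otu_ids])]
        for sid, row in zip(table.sample_ids, table.counts):
            lines.append(
                "\t".join([table.label, sid, str(table.n_otus), *map(str, row)])
            )
    elif dialect == "matrix_tsv":
        lines = ["\t".join(["sample_id", *table.otu_ids])]
        for sid, row in zip(table.sample_ids, table.counts):
            lines.append("\t".join([sid, *map(str, row)]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

REQUIRED_METADATA_COLUMNS = ("sample_id", "month", "year", "depth_m")


@dataclass
class SampleMetadata:
    """Per-sample collection metadata plus optional numeric covariates.

    ``covariates`` holds numeric values with NaN for missing entries;
    ``missing_reasons`` records why a covariate cell is missing (e.g.
    ``"below detection limit"`` for a "BDL" cell) keyed by
    ``(sample_id, column)``.
    """

    table: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    missing_reasons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in REQUIRED_METADATA_COLUMNS:
            if col not in self.table.columns:
                raise ValueError(f"missing required metadata column {col!r}")
        ids = self.table["sample_id"].astype(str)
        dupes = ids[ids.duplicated()].tolist()
        if dupes:
            raise ValueError(f"duplicate sample_id values: {sorted(set(dupes))}")
        bad_month = sorted(set(self.table["month"]) - VALID_MONTHS)
        if bad_month:
            raise ValueError(f"invalid month values: {bad_month}")
        if (self.table["depth_m"].astype(float) < 0).any():
            raise ValueError("negative depth_m")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].astype(str).tolist()

    def factor(self, name: str) -> pd.Series:
        """Return a grouping column (metadata or covariate) indexed by sample id."""
        if name in self.table.columns:
            return self.table.set_index("sample_id")[name]
        if name in self.covariates.columns:
            return self.covariates[name]
        raise KeyError(f"unknown metadata column {name!r}")

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        for col in self.covariates.columns:
            vals = self.covariates[col].reindex(out["sample_id"].astype(str))
            cells = []
            for sid, v in zip(out["sample_id"].astype(str), vals):
                reason = self.missing_reasons.get((sid, col))
                if reason == "below detection limit":
                    cells.append("BDL")
                elif reason == "no data":
                    cells.append("n.d.")
                elif pd.isna(v):
                    cells.append("")
                else:
                    cells.append(repr(float(v)))
            out[col] = cells
        out.to_csv(path, index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata CSV.

    Required columns: ``sample_id, month, year, depth_m``.  Any extra
    column is kept as a numeric covariate; the codes ``BDL`` and
    ``n.d.`` (and blanks) parse as missing values with a recorded
    reason — never as 0.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    core = raw[list(REQUIRED_METADATA_COLUMNS)].copy()
    core["sample_id"] = core["sample_id"].astype(str)
    core["year"] = core["year"].astype(int)
    core["depth_m"] = core["depth_m"].astype(float)

    extra_cols = [c for c in raw.columns if c not in REQUIRED_METADATA_COLUMNS]
    cov = pd.DataFrame(index=core["sample_id"])
    reasons: dict = {}
    for col in extra_cols:
        vals = []
        for sid, cell in zip(core["sample_id"], raw[col]):
            code = cell.strip().lower()
            if code in MISSING_CODES:
                vals.append(np.nan)
                reasons[(sid, col)] = MISSING_CODES[code]
            else:
                try:
                    vals.append(float(cell))
                except ValueError:
                    vals.append(np.nan)
                    reasons[(sid, col)] = f"unparseable: {cell!r}"
        cov[col] = vals
    return SampleMetadata(table=core, covariates=cov, missing_reasons=reasons)
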