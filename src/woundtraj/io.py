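"""Core data containers and file formats for the wound-trajectory pipeline.

Counts travel as genes x samples tables (TSV or MatrixMarket with row/column
sidecars), sample metadata as CSV, functional-category gene sets as GMT, and
cell-type signatures as TSV.  All readers validate rather than coerce: duplicate
identifiers, negative counts and malformed lines raise :class:`FormatError`
naming the offending entry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("woundtraj")

# Canonical ordering of the four colonization-status x outcome wound groups.
WOUND_GROUPS = (
    "colonized/healed",
    "non-colonized/healed",
    "colonized/failed",
    "non-colonized/failed",
)

OUTCOMES = ("healed", "failed")
COLONIZATION = ("colonized", "non-colonized")

#: Metadata columns every sample record must carry.
META_COLUMNS = ("sample_id", "wound_id", "patient_id", "days_post_injury",
                "outcome", "colonization")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

@dataclass
class CountsMatrix:
    """Raw gene-level counts (genes x samples) with per-gene lengths in bp.

    ``values`` is an integer DataFrame indexed by gene id with sample-id
    columns; ``gene_lengths`` (optional) is a Series over the same gene index,
    required by :func:`woundtraj.normalize.tpm`.
    """

    values: pd.DataFrame
    gene_lengths: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise FormatError("counts contain non-finite values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {v.index[g]!r}, sample {v.columns[s]!r}")
        if self.gene_lengths is not None:
            gl = self.gene_lengths.reindex(v.index)
            if gl.isna().any():
                missing = gl.index[gl.isna()][0]
                raise FormatError(f"missing length for gene {missing!r}")
            if (gl <= 0).any():
                bad = gl.index[gl <= 0][0]
                raise FormatError(f"non-positive length for gene {bad!r}")
            self.gene_lengths = gl.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _read_lengths_sidecar(path: Path) -> Optional[pd.Series]:
    sidecar = path.with_suffix(path.suffix + ".lengths.tsv")
    if not sidecar.exists():
        return None
    df = pd.read_csv(sidecar, sep="\t", index_col=0, comment="#")
    return df.iloc[:, 0].astype(float)


def read_counts(path: str | Path, format: str = "tsv") -> CountsMatrix:
    """Read a genes x samples count matrix from TSV or MatrixMarket.

    The TSV dialect is tab-separated, UTF-8, no quoting, header row of sample
    ids, first column gene id.  MTX requires ``<path>.rows.txt`` and
    ``<path>.cols.txt`` sidecars carrying gene and sample ids.  A
    ``<path>.lengths.tsv`` sidecar, when present, supplies gene lengths.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
    elif format == "mtx":
        rows = path.with_suffix(path.suffix + ".rows.txt")
        cols = path.with_suffix(path.suffix + ".cols.txt")
        for sidecar in (rows, cols):
            if not sidecar.exists():
                raise FormatError(f"missing MTX sidecar: {sidecar}")
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        gene_ids = rows.read_text().splitlines()
        sample_ids = cols.read_text().splitlines()
        if mat.shape != (len(gene_ids), len(sample_ids)):
            raise FormatError(
                f"MTX shape {mat.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(sample_ids)} samples)")
        df = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
    else:
        raise ValueError(f"unknown counts format: {format!r}")
    if np.allclose(df.to_numpy(), np.round(df.to_numpy())):
        df = df.round().astype(np.int64)
    return CountsMatrix(values=df, gene_lengths=_read_lengths_sidecar(path))


def write_counts(counts: CountsMatrix, path: str | Path,
                 format: str = "tsv") -> None:
    """Write counts in a form :func:`read_counts` round-trips bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        counts.values.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        sparse = scipy.sparse.csr_matrix(counts.values.to_numpy())
        scipy.io.mmwrite(str(path), sparse, field="integer")
        path.with_suffix(path.suffix + ".rows.txt").write_text(
            "\n".join(counts.gene_ids) + "\n")
        path.with_suffix(path.suffix + ".cols.txt").write_text(
            "\n".join(counts.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown counts format: {format!r}")
    if counts.gene_lengths is not None:
        counts.gene_lengths.rename("length_bp").to_csv(
            path.with_suffix(path.suffix + ".lengths.tsv"),
            sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def wound_group(outcome: str, colonization: str) -> str:
    """Canonical group label, e.g. ``colonized/healed``."""
    if outcome not in OUTCOMES:
        raise FormatError(f"unknown outcome: {outcome!r}")
    if colonization not in COLONIZATION:
        raise FormatError(f"unknown colonization status: {colonization!r}")
    return f"{colonization}/{outcome}"


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate per-sample metadata and attach the derived ``group`` column.

    Expects one row per sample with columns ``sample_id, wound_id, patient_id,
    days_post_injury, outcome, colonization`` (``cfu_per_gram`` optional).
    """
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"metadata missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id: {dup!r}")
    days = meta["days_post_injury"]
    if (days < 0).any() or not np.allclose(days, days.astype(int)):
        raise FormatError("days_post_injury must be non-negative integers")
    meta = meta.copy()
    meta["days_post_injury"] = days.astype(int)
    meta["group"] = [wound_group(o, c)
                     for o, c in zip(meta["outcome"], meta["colonization"])]
    return meta.set_index("sample_id", drop=False)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str,
                                               "wound_id": str,
                                               "patient_id": str})
    return validate_sample_meta(df)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in meta.columns if c != "group"]
    meta[cols].to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCatalog:
    """Ordered mapping of functional-category name -> member gene ids."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gene_sets(path: str | Path) -> GeneSetCatalog:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, members...)")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCatalog(sets=sets, descriptions=descriptions)


def write_gene_sets(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in catalog.items():
            desc = catalog.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Cell-type signature
# ---------------------------------------------------------------------------

@dataclass
class SignatureMatrix:
    """Genes x cell-types expression signature on the TPM scale."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise FormatError("duplicate gene id in signature")
        if v.columns.duplicated().any():
            raise FormatError("duplicate cell-type id in signature")
        arr = v.to_numpy(dtype=float)
        if (arr < 0).any() or not np.isfinite(arr).all():
            raise FormatError("signature values must be finite and non-negative")
        zero_rows = (arr == 0).all(axis=1)
        if zero_rows.any():
            raise FormatError(
                f"all-zero signature row for gene {v.index[zero_rows][0]!r}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


def read_signature(path: str | Path) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return SignatureMatrix(values=df.astype(float))


def write_signature(sig: SignatureMatrix, path: str | Path) -> None:
    sig.values.to_csv(Path(path), sep="\t", index_label="gene_id",
                      float_format="%.10g")


# ---------------------------------------------------------------------------
# Time bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeBin:
    """Inclusive day span; ``day_hi=None`` means open-ended."""

    label: str
    day_lo: int
    day_hi: Optional[int]

    def contains(self, day: int) -> bool:
        return day >= self.day_lo and (self.day_hi is None or day <= self.day_hi)


#: Study temporal groupings.  "Greater than 17 days" is implemented as
#: day >= 17 so the bins partition every day from 3 upward with no gap
#: after 13-16 (day 17 would otherwise be unassignable).
DEFAULT_TIME_BINS = (
    TimeBin("3-5", 3, 5),
    TimeBin("6", 6, 6),
    TimeBin("7", 7, 7),
    TimeBin("8-10", 8, 10),
    TimeBin("11-12", 11, 12),
    TimeBin("13-16", 13, 16),
    TimeBin("17+", 17, None),
)


def _check_bins(bins: Sequence[TimeBin]) -> None:
    prev_hi = None
    for b in bins:
        if b.day_hi is not None and b.day_hi < b.day_lo:
            raise ValueError(f"bin {b.label!r} has day_hi < day_lo")
        if prev_hi is None and b is not bins[-1] and b.day_hi is None:
            raise ValueError("only the last bin may be open-ended")
        if prev_hi is not None and b.day_lo <= prev_hi:
            raise ValueError(f"bin {b.label!r} overlaps the previous bin")
        prev_hi = b.day_hi if b.day_hi is not None else np.inf


def assign_time_bins(meta: pd.DataFrame,
                     bins: Sequence[TimeBin] = DEFAULT_TIME_BINS,
                     ) -> pd.Series:
    """Map each sample to its temporal grouping label.

    Days below the first bin are recorded as missing (NaN) with a warning and
    are excluded from bin-stratified analyses.
    """
    _check_bins(bins)
    labels = {}
    unbinned = []
    for sid, day in zip(meta["sample_id"], meta["days_post_injury"]):
        for b in bins:
            if b.contains(int(day)):
                labels[sid] = b.label
                break
        else:
            labels[sid] = np.nan
            unbinned.append((sid, int(day)))
    if unbinned:
        warnings.warn(
            f"{len(unbinned)} sample(s) fall outside all time bins and are "
            f"left unbinned: {unbinned[:5]}", stacklevel=2)
    return pd.Series(labels, name="time_bin").reindex(meta["sample_id"])
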