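"""Readers, writers, validation and locus filters for bulk allele-frequency panels.

The central object is the :class:`FrequencyMatrix`: one row per landrace
(a farmer-maintained open-pollinated population genotyped as a single DNA
bulk), one column per biallelic SNP, each cell the frequency of a fixed
reference allele in [0, 1].  Missing calls are stored as NaN and are never
silently treated as zero: a zero is a biological statement (fixation for
the alternate allele), a missing cell is not.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyMatrix",
    "MarkerPanel",
    "PassportTable",
    "FilterReport",
    "read_frequency_matrix",
    "write_frequency_matrix",
    "filter_missing_loci",
    "detect_monomorphic",
    "drop_loci",
    "read_marker_panel",
    "write_marker_panel",
    "read_passport",
    "write_passport",
]

#: Column names of the growing-season climate block (May-October monthly
#: mean temperature and precipitation), in fixed order.
CLIMATE_COLUMNS = tuple(
    f"{var}_{month}"
    for var in ("tmean", "prec")
    for month in ("may", "jun", "jul", "aug", "sep", "oct")
)

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class FrequencyMatrix:
    """Landraces x loci reference-allele frequencies.

    Parameters
    ----------
    landrace_ids : list of str
        Unique row labels.
    locus_ids : list of str
        Unique column labels.
    values : ndarray of shape (n_landraces, n_loci)
        Frequencies in [0, 1]; NaN encodes a missing call.
    """

    landrace_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.landrace_ids = [str(x) for x in self.landrace_ids]
        self.locus_ids = [str(x) for x in self.locus_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.landrace_ids), len(self.locus_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.landrace_ids)} landraces x {len(self.locus_ids)} loci"
            )
        if len(set(self.landrace_ids)) != len(self.landrace_ids):
            raise ValidationError("duplicate landrace ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValidationError("duplicate locus ids")
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0.0) | (self.values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"frequency {self.values[i, j]!r} outside [0, 1] at landrace "
                f"{self.landrace_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )

    @property
    def n_landraces(self) -> int:
        return len(self.landrace_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def row(self, landrace_id: str) -> np.ndarray:
        """Frequency vector of one landrace."""
        try:
            i = self.landrace_ids.index(landrace_id)
        except ValueError:
            raise KeyError(f"unknown landrace id {landrace_id!r}") from None
        return self.values[i]

    def rows(self, landrace_ids) -> np.ndarray:
        """Stacked frequency vectors for several landraces (order preserved)."""
        index = {lid: i for i, lid in enumerate(self.landrace_ids)}
        try:
            idx = [index[lid] for lid in landrace_ids]
        except KeyError as exc:
            raise KeyError(f"unknown landrace id {exc.args[0]!r}") from None
        return self.values[idx]

    def select_loci(self, locus_ids) -> "FrequencyMatrix":
        """Sub-matrix restricted to ``locus_ids`` (order preserved)."""
        index = {lid: j for j, lid in enumerate(self.locus_ids)}
        try:
            idx = [index[lid] for lid in locus_ids]
        except KeyError as exc:
            raise KeyError(f"unknown locus id {exc.args[0]!r}") from None
        return FrequencyMatrix(list(self.landrace_ids), list(locus_ids), self.values[:, idx])

    def select_landraces(self, landrace_ids) -> "FrequencyMatrix":
        return FrequencyMatrix(list(landrace_ids), list(self.locus_ids), self.rows(landrace_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.landrace_ids, columns=self.locus_ids)


@dataclass
class MarkerPanel:
    """Genetic map of the SNP panel: locus id, chromosome, position in cM.

    Rows are kept sorted by (chromosome, position); positions must be
    non-negative.  The table backs map-window SNP thinning and the
    map-ordered block jackknife.
    """

    table: pd.DataFrame  # columns: locus_id, chromosome, position_cM

    def __post_init__(self) -> None:
        required = ["locus_id", "chromosome", "position_cM"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"marker panel missing columns {missing}")
        t = self.table.loc[:, required].copy()
        t["locus_id"] = t["locus_id"].astype(str)
        t["chromosome"] = t["chromosome"].astype(str)
        t["position_cM"] = t["position_cM"].astype(float)
        if (t["position_cM"] < 0).any():
            raise ValidationError("negative genetic map position")
        if t["locus_id"].duplicated().any():
            dup = t.loc[t["locus_id"].duplicated(), "locus_id"].iloc[0]
            raise ValidationError(f"duplicate locus id {dup!r} in marker panel")
        t = t.sort_values(["chromosome", "position_cM"], kind="stable").reset_index(drop=True)
        self.table = t

    @property
    def locus_ids(self) -> list[str]:
        return self.table["locus_id"].tolist()

    @property
    def n_loci(self) -> int:
        return len(self.table)

    def subset(self, locus_ids) -> "MarkerPanel":
        keep = set(locus_ids)
        return MarkerPanel(self.table[self.table["locus_id"].isin(keep)].copy())


@dataclass
class PassportTable:
    """Landrace metadata: group label, collection site and climate covariates.

    Coordinates are optional — germplasm passport records commonly lack
    them for a subset of accessions; rows without coordinates are retained
    and flagged so geographic analyses can exclude them listwise.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "landrace_id" not in self.table.columns:
            raise ValidationError("passport table requires a landrace_id column")
        t = self.table.copy()
        t["landrace_id"] = t["landrace_id"].astype(str)
        if t["landrace_id"].duplicated().any():
            dup = t.loc[t["landrace_id"].duplicated(), "landrace_id"].iloc[0]
            raise ValidationError(f"duplicate landrace id {dup!r} in passport")
        for col, lo, hi in (("latitude", -90.0, 90.0), ("longitude", -180.0, 180.0)):
            if col not in t.columns:
                t[col] = np.nan
            t[col] = pd.to_numeric(t[col], errors="coerce")
            bad = t[col].notna() & ((t[col] < lo) | (t[col] > hi))
            if bad.any():
                row = t.loc[bad].iloc[0]
                raise ValidationError(
                    f"{col} {row[col]} out of range for landrace {row['landrace_id']!r}"
                )
        t["has_coordinates"] = t["latitude"].notna() & t["longitude"].notna()
        self.table = t.reset_index(drop=True)

    @property
    def landrace_ids(self) -> list[str]:
        return self.table["landrace_id"].tolist()

    @property
    def n_with_coordinates(self) -> int:
        return int(self.table["has_coordinates"].sum())

    def coordinates(self) -> pd.DataFrame:
        """Rows with both coordinates present, indexed by landrace id."""
        t = self.table[self.table["has_coordinates"]]
        return t.set_index("landrace_id")[["latitude", "longitude"]]

    def groups(self, column: str = "group") -> dict[str, list[str]]:
        """Mapping group label -> member landrace ids (missing labels skipped)."""
        if column not in self.table.columns:
            raise KeyError(f"no column {column!r} in passport table")
        out: dict[str, list[str]] = {}
        for lid, g in zip(self.table["landrace_id"], self.table[column]):
            if pd.isna(g) or g == "":
                continue
            out.setdefault(str(g), []).append(lid)
        return out

    def climate(self) -> pd.DataFrame:
        """Complete 12-variable climate block indexed by landrace id.

        Rows with any missing climate value are excluded.
        """
        cols = [c for c in CLIMATE_COLUMNS if c in self.table.columns]
        if len(cols) not in (0, 12):
            raise ValidationError(
                f"climate block must have 0 or 12 variables, found {len(cols)}"
            )
        if not cols:
            return pd.DataFrame(index=pd.Index([], name="landrace_id"))
        t = self.table.set_index("landrace_id")[list(CLIMATE_COLUMNS)].apply(
            pd.to_numeric, errors="coerce"
        )
        return t.dropna()


@dataclass
class FilterReport:
    """Bookkeeping for a locus filter: n_input = n_dropped + n_retained."""

    n_input: int
    n_dropped: int
    n_retained: int
    dropped_locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_input != self.n_dropped + self.n_retained:
            raise ValueError("inconsistent filter report counts")


def _read_table(path_or_buf, dialect: str | None = None) -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t", None: None}[dialect]
    return pd.read_csv(
        path_or_buf,
        sep=sep,
        engine="python" if sep is None else "c",
        comment="#",
        dtype=str,
        keep_default_na=False,
    )


def read_frequency_matrix(path, dialect: str | None = None, orientation: str = "landraces") -> FrequencyMatrix:
    """Read a delimited frequency table.

    First column holds landrace ids (``orientation='landraces'``, rows are
    landraces) or locus ids (``orientation='loci'``, rows are loci and the
    table is transposed on read).  Empty cells and ``NA`` are missing.
    Values outside [0, 1] or non-numeric cells are rejected with the
    offending location named.
    """
    raw = _read_table(path, dialect)
    if raw.shape[1] < 2:
        raise ValidationError("frequency table needs an id column plus at least one locus")
    row_ids = raw.iloc[:, 0].astype(str).tolist()
    col_ids = [str(c) for c in raw.columns[1:]]
    values = np.full((len(row_ids), len(col_ids)), np.nan)
    for j, col in enumerate(raw.columns[1:]):
        cells = raw[col]
        for i, cell in enumerate(cells):
            s = cell.strip()
            if s in _MISSING_TOKENS:
                continue
            try:
                v = float(s)
            except ValueError:
                raise ValidationError(
                    f"non-numeric cell {s!r} at row {row_ids[i]!r}, column {col_ids[j]!r}"
                ) from None
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"frequency {v} outside [0, 1] at row {row_ids[i]!r}, column {col_ids[j]!r}"
                )
            values[i, j] = v
    if orientation == "loci":
        return FrequencyMatrix(col_ids, row_ids, values.T)
    if orientation != "landraces":
        raise ValueError(f"orientation must be 'landraces' or 'loci', got {orientation!r}")
    return FrequencyMatrix(row_ids, col_ids, values)


def write_frequency_matrix(fm: FrequencyMatrix, path, dialect: str = "csv",
                           precision: int = 6, metadata: dict | None = None) -> None:
    """Write a frequency matrix with ``# key=value`` metadata header lines.

    Frequencies are printed at ``precision`` decimals; missing as ``NA``.
    """
    sep = "," if dialect == "csv" else "\t"
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("landrace_id" + sep + sep.join(fm.locus_ids) + "\n")
        fmt = f"{{:.{precision}f}}"
        for lid, row in zip(fm.landrace_ids, fm.values):
            cells = ["NA" if math.isnan(v) else fmt.format(v) for v in row]
            fh.write(lid + sep + sep.join(cells) + "\n")


def filter_missing_loci(fm: FrequencyMatrix) -> tuple[FrequencyMatrix, FilterReport]:
    """Drop every locus with at least one missing call.

    E.g. a 23412-SNP panel in which 378 loci show missing data in at
    least one landrace retains 23034.
    """
    keep = ~np.isnan(fm.values).any(axis=0)
    dropped = [lid for lid, k in zip(fm.locus_ids, keep) if not k]
    if not keep.any():
        raise ValidationError("all loci have missing data; nothing retained")
    out = FrequencyMatrix(
        list(fm.landrace_ids),
        [lid for lid, k in zip(fm.locus_ids, keep) if k],
        fm.values[:, keep],
    )
    report = FilterReport(fm.n_loci, len(dropped), out.n_loci, dropped)
    return out, report


def detect_monomorphic(fm: FrequencyMatrix, eps: float = 0.0) -> list[str]:
    """Loci fixed for the same allele in every landrace.

    A locus is monomorphic when all frequencies are <= eps (reference allele
    absent everywhere) or all are >= 1 - eps.  ``eps`` > 0 loosens the
    fixation call to absorb bulk-frequency estimation error; a column such
    as [0.0, 1.0] is polymorphic across landraces and never flagged.
    """
    if fm.has_missing:
        raise ValidationError("detect_monomorphic requires a complete matrix")
    low = (fm.values <= eps).all(axis=0)
    high = (fm.values >= 1.0 - eps).all(axis=0)
    flag = low | high
    return [lid for lid, f in zip(fm.locus_ids, flag) if f]


def drop_loci(fm: FrequencyMatrix, locus_ids) -> tuple[FrequencyMatrix, FilterReport]:
    """Remove the named loci, e.g. monomorphic ones when configured to do so."""
    drop = set(locus_ids)
    unknown = drop - set(fm.locus_ids)
    if unknown:
        raise KeyError(f"unknown locus ids {sorted(unknown)[:3]}")
    keep = [lid for lid in fm.locus_ids if lid not in drop]
    if not keep:
        raise ValidationError("all loci dropped")
    out = fm.select_loci(keep)
    return out, FilterReport(fm.n_loci, len(drop), out.n_loci, sorted(drop))


def read_marker_panel(path) -> MarkerPanel:
    t = _read_table(path, "tsv")
    return MarkerPanel(t)


def write_marker_panel(panel: MarkerPanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_passport(path) -> PassportTable:
    t = _read_table(path, None)
    t = t.replace({tok: np.nan for tok in _MISSING_TOKENS})
    return PassportTable(t)


def write_passport(pp: PassportTable, path) -> None:
    pp.table.drop(columns=["has_coordinates"]).to_csv(path, index=False)
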