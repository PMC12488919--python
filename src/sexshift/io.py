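"""Tabular I/O for expression matrices, sample designs, DEG tables and signed-change tables.

All formats are plain TSV (tab separated, UTF-8, decimal point, no quoting).
Lines starting with ``#`` are header comments and are skipped on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEXES = ("F", "M")
DOSES = ("control", "d0.5", "d50")

#: expected value range of the normalized relative-expression scale
EXPRESSION_RANGE = (0.0, 20.0)

DEG_COLUMNS = [
    "probe_id", "mean_a", "mean_b", "sd_a", "sd_b", "n_a", "n_b",
    "t_stat", "df", "p_value", "direction", "max_group_mean",
]

_DIRECTION_TOKENS = {
    "increased": "increased",
    "reduced": "reduced",
    "ns": "ns",
    "---": "missing",
    "missing": "missing",
}


class FormatError(ValueError):
    """Malformed input file (duplicated ids, bad tokens, non-numeric cells)."""


class ConsistencyError(ValueError):
    """Matrix and design disagree about which samples exist."""


class DesignError(ValueError):
    """A group specification cannot be satisfied by the design."""


@dataclass
class ExpressionMatrix:
    """Probes x samples relative-expression matrix on the normalized 0-20 scale.

    ``values`` is a DataFrame indexed by probe id with one column per sample.
    Values slightly outside [0, 20] only trigger a warning: the bound describes
    the study's normalization, not a mathematical constraint.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicated probe ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample ids: {dups}")
        if self.values.shape[1] < 2:
            raise FormatError("expression matrix needs at least 2 samples")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise FormatError("expression matrix contains non-finite values")
        lo, hi = EXPRESSION_RANGE
        if (arr < lo).any() or (arr > hi).any():
            warnings.warn(
                "expression values outside the nominal [0, 20] relative-expression range",
                stacklevel=2,
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleDesign:
    """Sample annotation: one row per sample with sex in {F, M} and dose in {control, d0.5, d50}."""

    table: pd.DataFrame  # columns: sample_id, sex, dose

    def __post_init__(self) -> None:
        required = {"sample_id", "sex", "dose"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicated sample ids in design: {dups}")
        bad_sex = set(self.table["sex"]) - set(SEXES)
        if bad_sex:
            raise FormatError(f"unknown sex labels: {sorted(bad_sex)}")
        bad_dose = set(self.table["dose"]) - set(DOSES)
        if bad_dose:
            raise FormatError(f"unknown dose labels: {sorted(bad_dose)}")

    def samples_in_cells(self, cells: Iterable[tuple[str, str]]) -> list[str]:
        cells = set(cells)
        mask = [
            (sex, dose) in cells
            for sex, dose in zip(self.table["sex"], self.table["dose"])
        ]
        return self.table.loc[mask, "sample_id"].tolist()


@dataclass(frozen=True)
class GroupSpec:
    """A labelled set of (sex, dose) design cells; pooled groups are unions of cells."""

    label: str
    cells: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.cells:
            raise DesignError(f"group {self.label!r} selects no cells")
        for sex, dose in self.cells:
            if sex not in SEXES or dose not in DOSES:
                raise DesignError(f"group {self.label!r} has invalid cell {(sex, dose)!r}")

    @classmethod
    def parse(cls, expr: str, label: str | None = None) -> "GroupSpec":
        """Parse a cell expression like ``"F:control"`` or ``"F:d0.5+d50"``.

        Several sex segments may be joined with commas, e.g. ``"F:control,M:control"``.
        """
        cells: set[tuple[str, str]] = set()
        for segment in expr.split(","):
            segment = segment.strip()
            if ":" not in segment:
                raise DesignError(f"cannot parse group expression {segment!r}")
            sex, doses = segment.split(":", 1)
            for dose in doses.split("+"):
                cells.add((sex.strip(), dose.strip()))
        return cls(label=label or expr, cells=frozenset(cells))


@dataclass
class SignedChangeTable:
    """Analyte rows with rat and human change directions for concordance scoring.

    ``ns_aligned_override`` marks rows whose non-significant human direction is,
    by an explicit caller judgement, treated as aligned under the permissive policy.
    """

    table: pd.DataFrame  # parameter, rat_direction, human_direction, ns_aligned_override
    stratum: str | None = None

    def __post_init__(self) -> None:
        if "ns_aligned_override" not in self.table.columns:
            self.table = self.table.assign(ns_aligned_override=False)
        if self.table["parameter"].duplicated().any():
            dups = self.table.loc[self.table["parameter"].duplicated(), "parameter"].tolist()
            raise FormatError(f"duplicated parameters in signed-change table: {dups}")

    def __len__(self) -> int:
        return len(self.table)


def _write_with_header(df: pd.DataFrame, path: Path, header_lines: Sequence[str],
                       float_format: str | None = None, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)
    return path


def read_expression(matrix_path: Path, design_path: Path) -> tuple[ExpressionMatrix, SampleDesign]:
    """Read a probes-x-samples TSV and its sample design, reconciling samples by id.

    The matrix header row holds sample ids and the first column probe ids.
    Raises :class:`FormatError` on duplicate ids or non-numeric cells (named by
    row/column) and :class:`ConsistencyError` on a matrix/design sample mismatch.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#", dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric value {raw.iat[r, c]!r} at probe {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r} in {matrix_path}"
        )
    if numeric.isna().to_numpy().any():
        raise FormatError(f"missing values in expression matrix {matrix_path}")
    matrix = ExpressionMatrix(numeric.astype(float))

    design_df = pd.read_csv(design_path, sep="\t", comment="#", dtype=str)
    design = SampleDesign(design_df)

    matrix_ids = set(matrix.sample_ids)
    design_ids = set(design.table["sample_id"])
    if matrix_ids != design_ids:
        raise ConsistencyError(
            f"sample ids differ between matrix and design: "
            f"only in matrix {sorted(matrix_ids - design_ids)}, "
            f"only in design {sorted(design_ids - matrix_ids)}"
        )
    # reconcile by id, not position: design rows follow matrix column order
    design = SampleDesign(
        design.table.set_index("sample_id").loc[matrix.sample_ids].reset_index()
    )
    return matrix, design


def write_expression(matrix: ExpressionMatrix, design: SampleDesign,
                     matrix_path: Path, design_path: Path,
                     header_lines: Sequence[str] = ()) -> tuple[Path, Path]:
    """Write matrix and design TSVs; values at 6 decimals (round-trip precision)."""
    mp = _write_with_header(matrix.values, Path(matrix_path), header_lines,
                            float_format="%.6f", index=True)
    dp = _write_with_header(design.table[["sample_id", "sex", "dose"]],
                            Path(design_path), header_lines)
    return mp, dp


def write_deg_table(records: pd.DataFrame, path: Path,
                    header_lines: Sequence[str] = ()) -> Path:
    """Write a DEG table with fixed column order, sorted by ascending p (ties by probe id)."""
    if len(records) == 0:
        out = pd.DataFrame(columns=DEG_COLUMNS)
    else:
        out = records[DEG_COLUMNS].sort_values(
            ["p_value", "probe_id"], kind="mergesort"
        )
    return _write_with_header(out, Path(path), header_lines, float_format="%.10g")


def read_deg_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"probe_id": str, "direction": str})
    missing = set(DEG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"DEG table missing columns: {sorted(missing)}")
    return df[DEG_COLUMNS]


def read_signed_change_table(path: Path, stratum: str | None = None) -> SignedChangeTable:
    """Read a signed-change TSV (parameter, rat_direction, human_direction[, ns_aligned_override]).

    Direction tokens are case-insensitive; ``---`` means the human value is unavailable.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"parameter", "rat_direction", "human_direction"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"signed-change table missing columns: {sorted(missing)}")

    def parse_direction(token: str, allow_ns: bool) -> str:
        norm = _DIRECTION_TOKENS.get(str(token).strip().lower())
        if norm is None or (not allow_ns and norm not in ("increased", "reduced")):
            raise FormatError(f"unknown direction token {token!r}")
        return norm

    df = df.assign(
        rat_direction=[parse_direction(t, allow_ns=False) for t in df["rat_direction"]],
        human_direction=[parse_direction(t, allow_ns=True) for t in df["human_direction"]],
    )
    if "ns_aligned_override" in df.columns:
        df["ns_aligned_override"] = (
            df["ns_aligned_override"].str.strip().str.lower().isin(("1", "true", "yes"))
        )
    return SignedChangeTable(df, stratum=stratum)


def write_signed_change_table(table: SignedChangeTable, path: Path,
                              header_lines: Sequence[str] = ()) -> Path:
    out = table.table.copy()
    out["human_direction"] = out["human_direction"].replace({"missing": "---"})
    out["ns_aligned_override"] = out["ns_aligned_override"].astype(int)
    return _write_with_header(out, Path(path), header_lines)
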