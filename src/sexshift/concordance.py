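"""Direction concordance between a rat exposure signature and a human disease signature.

Rows of a signed-change table pair an analyte's direction of change in
BPA-exposed rats with its direction in humans with metabolic syndrome. A row is
*comparable* when the human direction was measured (not ``missing``) and
*aligned* when both directions are identical. Under the default ``strict``
policy a non-significant (``ns``) human row is comparable but never aligned;
under ``count_aligned`` an ``ns`` row is counted as aligned only when it
carries an explicit per-row override flag — a judgement call is never a silent
default.

The package ships the study's printed male (11-row) and female (6-row) tables
as TSV data files; :func:`bundled_table` loads them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .deg import _round_half_up
from .io import SignedChangeTable, read_signed_change_table


class EmptyTableError(ValueError):
    """The signed-change table has no rows."""


class InsufficientDataError(ValueError):
    """Fewer than 2 comparable rows; a bootstrap interval is meaningless."""


@dataclass
class ConcordanceResult:
    stratum: str | None
    ns_policy: str
    n_rows: int
    n_comparable: int
    n_aligned: int
    aligned_percent: int | None  # round-half-up; None when nothing is comparable
    verdicts: pd.DataFrame

    def __str__(self) -> str:
        pct = "NA" if self.aligned_percent is None else f"{self.aligned_percent}%"
        return (f"{self.stratum or 'table'}: {self.n_aligned} aligned of "
                f"{self.n_comparable} comparable ({pct}; {self.n_rows} rows, "
                f"policy {self.ns_policy})")


def bundled_table(stratum: str) -> SignedChangeTable:
    """Load the packaged printed signed-change table for ``"male"`` or ``"female"``."""
    if stratum not in ("male", "female"):
        raise ValueError("stratum must be 'male' or 'female'")
    ref = resources.files("sexshift") / "data" / f"signed_changes_{stratum}.tsv"
    with resources.as_file(ref) as path:
        return read_signed_change_table(Path(path), stratum=stratum)


def score_concordance(table: SignedChangeTable,
                      ns_policy: str = "strict") -> ConcordanceResult:
    """Score direction alignment between the rat and human columns of one stratum."""
    if ns_policy not in ("strict", "count_aligned"):
        raise ValueError("ns_policy must be 'strict' or 'count_aligned'")
    df = table.table
    if len(df) == 0:
        raise EmptyTableError("signed-change table is empty")
    comparable = df["human_direction"] != "missing"
    aligned = comparable & (df["rat_direction"] == df["human_direction"])
    if ns_policy == "count_aligned":
        aligned |= comparable & (df["human_direction"] == "ns") & df["ns_aligned_override"]
    verdicts = df.assign(comparable=comparable, aligned=aligned)
    n_comp, n_aln = int(comparable.sum()), int(aligned.sum())
    return ConcordanceResult(
        stratum=table.stratum,
        ns_policy=ns_policy,
        n_rows=len(df),
        n_comparable=n_comp,
        n_aligned=n_aln,
        aligned_percent=_round_half_up(100.0 * n_aln / n_comp) if n_comp else None,
        verdicts=verdicts,
    )


def bootstrap_concordance(table: SignedChangeTable, n_boot: int, seed: int,
                          ns_policy: str = "strict",
                          level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap interval for the aligned percentage (row resampling).

    Deterministic given the seed. Resamples whole rows with replacement;
    resamples with no comparable row are redrawn into the NaN-free percentile.
    """
    base = score_concordance(table, ns_policy)
    if base.n_comparable < 2:
        raise InsufficientDataError(
            f"need >= 2 comparable rows, have {base.n_comparable}"
        )
    df = base.verdicts
    rng = np.random.default_rng(seed)
    n = len(df)
    idx = rng.integers(0, n, size=(n_boot, n))
    comp = df["comparable"].to_numpy()[idx].sum(axis=1)
    aln = df["aligned"].to_numpy()[idx].sum(axis=1)
    with np.errstate(invalid="ignore"):
        pct = np.where(comp > 0, 100.0 * aln / np.maximum(comp, 1), np.nan)
    pct = pct[~np.isnan(pct)]
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(pct, [tail, 100.0 - tail])
    return float(lo), float(hi)
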