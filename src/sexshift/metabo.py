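"""Factorial statistics for metabolite and lipid panels.

Two-way (sex x treatment) ANOVA with Type II sums of squares for the study's
unbalanced 2x2 cells, Tukey-Kramer post-hoc comparisons of the four cell means,
and pooled-variance t-tests computable directly from printed summary statistics
(mean, SD, n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import DesignError

__all__ = [
    "SummaryStats", "AnovaResult", "DegenerateVarianceError",
    "two_way_anova", "two_way_anova_matrix", "tukey_hsd", "t_test_from_summary",
]


class DegenerateVarianceError(ValueError):
    """All within-cell variation is zero; F statistics are undefined."""


@dataclass(frozen=True)
class SummaryStats:
    """Printed summary of one group: mean, standard deviation and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass
class AnovaResult:
    """Type II two-way ANOVA of one analyte on a sex x {control, dose} design."""

    analyte: str
    dose: str
    f_treatment: float
    p_treatment: float
    f_sex: float
    p_sex: float
    f_interaction: float
    p_interaction: float
    df_effect: int
    df_error: int
    cell_means: dict[tuple[str, str], float]


def _design_matrices(sex: np.ndarray, treat: np.ndarray) -> dict[str, np.ndarray]:
    n = sex.size
    one = np.ones(n)
    s = (sex == "M").astype(float)
    t = treat.astype(float)
    return {
        "full": np.column_stack([one, s, t, s * t]),
        "additive": np.column_stack([one, s, t]),
        "sex_only": np.column_stack([one, s]),
        "treat_only": np.column_stack([one, t]),
    }


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of y regressed on x (via QR)."""
    q, _ = np.linalg.qr(x)
    fitted_sq = (q.T @ y) ** 2
    return (y ** 2).sum(axis=0) - fitted_sq.sum(axis=0)


def two_way_anova_matrix(values: np.ndarray, sex: np.ndarray, treated: np.ndarray
                         ) -> pd.DataFrame:
    """Vectorized Type II two-way ANOVA over many analytes sharing one design.

    ``values`` is observations x analytes (no missing values), ``sex`` the per
    observation sex label ('F'/'M') and ``treated`` a boolean/0-1 treatment
    indicator. Returns one row per analyte with F and p for the treatment and
    sex main effects (each adjusted for the other, ignoring the interaction)
    and the sex x treatment interaction.
    """
    y = np.atleast_2d(np.asarray(values, dtype=float))
    if y.ndim != 2:
        raise ValueError("values must be 2-D (observations x analytes)")
    sex = np.asarray(sex)
    treated = np.asarray(treated)
    for s_lab in ("F", "M"):
        for t_lab in (0, 1):
            if ((sex == s_lab) & (treated == t_lab)).sum() < 2:
                raise DesignError(
                    f"cell (sex={s_lab}, treated={bool(t_lab)}) has fewer than 2 observations"
                )
    x = _design_matrices(sex, treated)
    rss_full = _rss(x["full"], y)
    rss_add = _rss(x["additive"], y)
    ss_treat = _rss(x["sex_only"], y) - rss_add
    ss_sex = _rss(x["treat_only"], y) - rss_add
    ss_int = rss_add - rss_full
    df_error = y.shape[0] - 4
    if df_error < 1:
        raise DesignError("not enough observations for the 2x2 model with interaction")
    # QR leaves ~1e-30 residuals on exactly-fitting data; judge degeneracy
    # relative to the response's own scale
    scale = np.maximum((y ** 2).sum(axis=0), 1e-300)
    degenerate = rss_full <= 1e-12 * scale
    if degenerate.all():
        raise DegenerateVarianceError("zero within-cell variance for every analyte")
    mse = np.where(degenerate, np.nan, rss_full / df_error)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_treat = np.clip(ss_treat, 0, None) / mse
        f_sex = np.clip(ss_sex, 0, None) / mse
        f_int = np.clip(ss_int, 0, None) / mse
    return pd.DataFrame({
        "f_treatment": f_treat,
        "p_treatment": stats.f.sf(f_treat, 1, df_error),
        "f_sex": f_sex,
        "p_sex": stats.f.sf(f_sex, 1, df_error),
        "f_interaction": f_int,
        "p_interaction": stats.f.sf(f_int, 1, df_error),
        "df_effect": 1,
        "df_error": df_error,
    })


def _select_panel(panel: pd.DataFrame, analyte: str, dose: str
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if dose not in ("d0.5", "d50"):
        raise DesignError(f"dose must be 'd0.5' or 'd50', got {dose!r}")
    if analyte not in panel.columns:
        raise KeyError(f"analyte {analyte!r} not in panel")
    sub = panel[panel["dose"].isin(["control", dose])]
    sub = sub.dropna(subset=[analyte])  # listwise deletion per analyte
    y = sub[analyte].to_numpy(dtype=float)
    sex = sub["sex"].to_numpy()
    treated = (sub["dose"] == dose).to_numpy().astype(int)
    return y, sex, treated


def two_way_anova(panel: pd.DataFrame, analyte: str, dose: str) -> AnovaResult:
    """Type II two-way ANOVA of one analyte: sex x {control, one selected dose}.

    The panel is a tidy table with columns sample_id, sex, dose and one column
    per analyte; each dose is analyzed separately against the controls.
    Missing analyte values are dropped listwise for that analyte.
    """
    y, sex, treated = _select_panel(panel, analyte, dose)
    res = two_way_anova_matrix(y[:, None], sex, treated)
    row = res.iloc[0]
    if not np.isfinite(row["f_treatment"]):
        raise DegenerateVarianceError(
            f"zero within-cell variance for analyte {analyte!r}"
        )
    cell_means = {
        (s_lab, lab): float(y[(sex == s_lab) & (treated == t_val)].mean())
        for s_lab in ("F", "M")
        for t_val, lab in ((0, "control"), (1, dose))
    }
    return AnovaResult(
        analyte=analyte, dose=dose,
        f_treatment=float(row["f_treatment"]), p_treatment=float(row["p_treatment"]),
        f_sex=float(row["f_sex"]), p_sex=float(row["p_sex"]),
        f_interaction=float(row["f_interaction"]), p_interaction=float(row["p_interaction"]),
        df_effect=1, df_error=int(row["df_error"]),
        cell_means=cell_means,
    )


def tukey_hsd(panel: pd.DataFrame, analyte: str, dose: str,
              alpha: float = 0.05) -> pd.DataFrame:
    """All 6 pairwise comparisons among the four (sex, dose) cell means.

    Adjusted p-values come from the studentized-range distribution with the
    Tukey-Kramer allowance for unequal cell sizes. Cells are labelled
    fCont/fDose/mCont/mDose in the style of the study's post-hoc tables.
    """
    y, sex, treated = _select_panel(panel, analyte, dose)
    labels = np.where(
        sex == "F",
        np.where(treated == 1, f"fBPA{dose[1:]}", "fCont"),
        np.where(treated == 1, f"mBPA{dose[1:]}", "mCont"),
    )
    res = pairwise_tukeyhsd(y, labels, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.replace("-", "_") for c in res.summary().data[0]],
    )
    frame["p_adj"] = res.pvalues
    frame["meandiff"] = res.meandiffs
    return frame[["group1", "group2", "meandiff", "p_adj", "reject"]]


def t_test_from_summary(a: SummaryStats, b: SummaryStats,
                        pooled: bool = True) -> dict:
    """Two-sided two-sample t-test from printed summaries (mean, SD, n).

    Pooled-variance (Student) by default, matching the study; Welch optional.
    Degenerate inputs: both SDs zero with equal means gives t=0, p=1; both SDs
    zero with unequal means is flagged infinite with p=0.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return {"t": 0.0, "df": a.n + b.n - 2, "p": 1.0, "infinite": False}
        return {"t": float(np.sign(a.mean - b.mean)) * float("inf"),
                "df": a.n + b.n - 2, "p": 0.0, "infinite": True}
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=pooled
    )
    if pooled:
        df = a.n + b.n - 2
    else:
        va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return {"t": float(t), "df": float(df), "p": float(p), "infinite": False}
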