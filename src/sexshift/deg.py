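"""Two-group differential expression with an empirical-Bayes moderated t-statistic.

The moderated test shrinks each probe's sample variance toward a prior variance
s0^2 estimated across all probes, assuming the hierarchical model

    s_g^2 | sigma_g^2  ~  sigma_g^2 * chi^2_{d_g} / d_g
    1 / sigma_g^2      ~  (1 / (d0 * s0^2)) * chi^2_{d0}

so that the marginal distribution of s_g^2 is a scaled F. The hyperparameters
(d0, s0^2) are estimated by matching the first two moments of log s_g^2 to that
prior (trigamma inversion), and the posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces the sample variance in a pooled two-sample t with d0 + d_g degrees of
freedom. With d0 = 0 this reduces to the ordinary Student t; with d0 -> infinity
every probe uses the common prior variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import DesignError, ExpressionMatrix, GroupSpec, SampleDesign


class EstimationError(RuntimeError):
    """The variance-prior hyperparameters could not be estimated."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the DEG pipeline.

    alpha
        two-sided significance level; strictly ``p < alpha`` is called
        significant (no multiple-testing adjustment by default).
    expr_filter
        minimum group-mean relative expression required in at least one of the
        two groups (the study's "at least 1.5 in one group" rule).
    fc_cutoff
        optional fold-change threshold used only by the bias diagnostic.
    test
        "moderated" (empirical-Bayes) or "student" (plain pooled t).
    adjust
        None or "bh" for Benjamini-Hochberg adjusted p-values (reuse option;
        off by default, matching the study).
    """

    alpha: float = 0.05
    expr_filter: float = 1.5
    fc_cutoff: float | None = None
    test: str = "moderated"
    adjust: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.expr_filter < 0:
            raise ValueError("expr_filter must be >= 0")
        if self.fc_cutoff is not None and self.fc_cutoff <= 1.0:
            raise ValueError("fc_cutoff must exceed 1")
        if self.test not in ("moderated", "student"):
            raise ValueError("test must be 'moderated' or 'student'")
        if self.adjust not in (None, "bh"):
            raise ValueError("adjust must be None or 'bh'")


@dataclass
class ModeratedVarianceModel:
    """Fitted scaled-F variance prior and per-probe posterior variances."""

    d0: float  # prior degrees of freedom; np.inf when log-variances show no excess spread
    s0_sq: float
    s_tilde_sq: np.ndarray = field(repr=False)

    @property
    def infinite_prior(self) -> bool:
        return math.isinf(self.d0)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by a monotone Newton iteration.

    trigamma is strictly decreasing and convex on (0, inf), so the iteration
    y <- y + trigamma(y) * (1 - trigamma(y)/x) / trigamma'(y) converges
    monotonically from the starting value 0.5 + 1/x.
    """
    if x <= 0:
        raise EstimationError(f"trigamma inverse undefined for {x}")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            return y
    raise EstimationError(
        f"trigamma inversion did not converge (target {x}, last value {y})"
    )


def fit_moderated_model(sample_variances: np.ndarray,
                        residual_df: np.ndarray | float,
                        d0: float | None = None) -> ModeratedVarianceModel:
    """Estimate the scaled-F variance prior by moment matching of log variances.

    Parameters
    ----------
    sample_variances
        per-probe sample variances (>= 0; zeros are offset by the smallest
        positive variance times 1e-6 to keep log moments defined).
    residual_df
        per-probe residual degrees of freedom (scalar broadcast allowed).
    d0
        optionally force the prior degrees of freedom instead of estimating
        them: 0 disables shrinkage, ``np.inf`` collapses every probe onto the
        prior variance.
    """
    s2 = np.asarray(sample_variances, dtype=float).copy()
    df = np.broadcast_to(np.asarray(residual_df, dtype=float), s2.shape)
    if (df <= 0).any():
        raise EstimationError("residual df must be positive")
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise EstimationError("all sample variances are zero")
    s2[s2 == 0] = positive.min() * 1e-6
    if s2.size < 2 and d0 is None:
        raise EstimationError("need at least 2 probes to estimate the variance prior")

    # e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2) is an unbiased estimate of
    # log sigma_g^2 with variance trigamma(d_g/2) under the sampling model.
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) if n > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2.0).mean())

    if d0 is None:
        if excess > 0:
            d0 = 2.0 * trigamma_inverse(excess)
        else:
            d0 = math.inf

    if math.isinf(d0):
        s0_sq = float(s2.mean())  # zero spread: every probe shares one variance
        s_tilde = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s0_sq = float(s2.mean())  # carries zero weight in the posterior
        s_tilde = s2
    else:
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        s_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
    return ModeratedVarianceModel(d0=float(d0), s0_sq=float(s0_sq), s_tilde_sq=s_tilde)


def _resolve_groups(design: SampleDesign, group_a: GroupSpec, group_b: GroupSpec
                    ) -> tuple[list[str], list[str]]:
    samples_a = design.samples_in_cells(group_a.cells)
    samples_b = design.samples_in_cells(group_b.cells)
    if set(samples_a) & set(samples_b):
        raise DesignError(
            f"groups {group_a.label!r} and {group_b.label!r} share samples"
        )
    for spec, samples in ((group_a, samples_a), (group_b, samples_b)):
        if len(samples) < 2:
            raise DesignError(
                f"group {spec.label!r} resolves to {len(samples)} sample(s); need >= 2"
            )
    return samples_a, samples_b


def compare_groups(matrix: ExpressionMatrix, design: SampleDesign,
                   group_a: GroupSpec, group_b: GroupSpec,
                   config: AnalysisConfig = AnalysisConfig(),
                   d0: float | None = None) -> pd.DataFrame:
    """Per-probe two-group comparison; returns every probe (filtering is separate).

    Group A is the comparison's first-named group: ``direction == "up"`` means
    higher mean relative expression in group A. Uses the pooled-variance
    moderated t (df = n_a + n_b - 2 + d0) or a plain Student t per the config.
    ``d0`` forces the prior degrees of freedom of the moderated test.
    """
    samples_a, samples_b = _resolve_groups(design, group_a, group_b)
    a = matrix.values[samples_a].to_numpy()
    b = matrix.values[samples_b].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]
    dg = n_a + n_b - 2

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / dg

    if config.test == "moderated":
        if pooled.size < 2 and d0 is None:
            d0 = 0.0  # a single probe gives the prior nothing to borrow from
        model = fit_moderated_model(pooled, float(dg), d0=d0)
        denom_var = model.s_tilde_sq
        df_total = np.full(pooled.shape, dg + model.d0)
    else:
        denom_var = pooled
        df_total = np.full(pooled.shape, float(dg))

    diff = mean_a - mean_b
    se = np.sqrt(denom_var * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (diff != 0), np.sign(diff) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame({
        "probe_id": matrix.probe_ids,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "sd_a": np.sqrt(var_a),
        "sd_b": np.sqrt(var_b),
        "n_a": n_a,
        "n_b": n_b,
        "t_stat": t,
        "df": df_total,
        "p_value": p,
        "direction": np.where(diff > 0, "up", "down"),
        "max_group_mean": np.maximum(mean_a, mean_b),
    })
    if config.adjust == "bh":
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out.attrs["group_a"] = group_a.label
    out.attrs["group_b"] = group_b.label
    return out


def filter_degs(records: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()
                ) -> pd.DataFrame:
    """Keep probes with p < alpha and group-mean expression >= expr_filter in one group.

    The p threshold is strict (p exactly equal to alpha is excluded). Output is
    ordered by ascending p with ties broken by probe id; the operation is
    idempotent and its output is always a subset of its input.
    """
    p = records["p_adjusted"] if config.adjust == "bh" and "p_adjusted" in records else records["p_value"]
    keep = (p < config.alpha) & (records["max_group_mean"] >= config.expr_filter)
    out = records.loc[keep].sort_values(["p_value", "probe_id"], kind="mergesort")
    out.attrs.update(records.attrs)
    return out.reset_index(drop=True)


def summarize_deg_sets(deg_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per labelled DEG list, total / up / up% / down / down%.

    Percentages are integers, rounded half-up; empty sets report 0% with a flag.
    """
    rows = []
    for label, df in deg_sets.items():
        total = len(df)
        up = int((df["direction"] == "up").sum()) if total else 0
        down = total - up
        rows.append({
            "label": label,
            "total": total,
            "up": up,
            "up_percent": _round_half_up(100.0 * up / total) if total else 0,
            "down": down,
            "down_percent": _round_half_up(100.0 * down / total) if total else 0,
            "empty": total == 0,
        })
    return pd.DataFrame(rows)


def compare_deg_sets(set_a: pd.DataFrame, set_b: pd.DataFrame) -> dict:
    """Probe-id overlap of two DEG lists and direction agreement on the overlap.

    ``direction_match_fraction`` is NaN (not applicable) for disjoint sets.
    """
    a = set_a.set_index("probe_id")["direction"]
    b = set_b.set_index("probe_id")["direction"]
    common = a.index.intersection(b.index)
    n = len(common)
    return {
        "overlap_count": n,
        "overlap_fraction_a": n / len(a) if len(a) else float("nan"),
        "overlap_fraction_b": n / len(b) if len(b) else float("nan"),
        "direction_match_fraction":
            float((a.loc[common] == b.loc[common]).mean()) if n else float("nan"),
    }


def fold_changes(records: pd.DataFrame, scale: str = "ratio") -> pd.Series:
    """Per-probe fold change on the relative-expression scale.

    ``ratio`` (default): larger group mean over smaller group mean — only this
    definition reproduces the cutoff's bias toward low-expression probes, since
    equal absolute shifts give smaller ratios at high levels. ``log2diff`` treats
    the values as log2 units and returns 2**|mean_a - mean_b|.
    Probes whose smaller group mean is <= 0 get NaN (FC undefined).
    """
    hi = np.maximum(records["mean_a"], records["mean_b"])
    lo = np.minimum(records["mean_a"], records["mean_b"])
    if scale == "ratio":
        fc = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0), np.nan)
    elif scale == "log2diff":
        fc = 2.0 ** (hi - lo)
    else:
        raise ValueError("scale must be 'ratio' or 'log2diff'")
    return pd.Series(fc, index=records.index, name="fold_change")


def fc_cutoff_diagnostic(records: pd.DataFrame,
                         config: AnalysisConfig,
                         fc_scale: str = "ratio") -> dict:
    """Quantify the expression-level bias introduced by a fold-change cutoff.

    Applies ``config.fc_cutoff`` to an already-filtered DEG list and reports how
    the mean relative expression (per-probe max group mean) of the retained set
    shrinks: ``expr_ratio = mean_expr_after / mean_expr_before``. Also emits the
    (FC, expression level) pairs used for the diagnostic scatter plot.
    """
    if config.fc_cutoff is None:
        raise ValueError("config.fc_cutoff must be set for the diagnostic")
    fc = fold_changes(records, scale=fc_scale)
    defined = fc.notna()
    expr = records.loc[defined, "max_group_mean"]
    fc_def = fc[defined]
    keep = fc_def >= config.fc_cutoff
    n_before, n_after = int(defined.sum()), int(keep.sum())
    mean_before = float(expr.mean()) if n_before else float("nan")
    mean_after = float(expr[keep].mean()) if n_after else float("nan")
    return {
        "n_before": n_before,
        "n_after": n_after,
        "n_excluded_undefined_fc": int((~defined).sum()),
        "percent_removed": _round_half_up(100.0 * (n_before - n_after) / n_before)
            if n_before else 0,
        "mean_expr_before": mean_before,
        "mean_expr_after": mean_after,
        "expr_ratio": mean_after / mean_before if n_before and n_after else float("nan"),
        "fc_vs_expr": pd.DataFrame({
            "probe_id": records.loc[defined, "probe_id"].to_numpy(),
            "fold_change": fc_def.to_numpy(),
            "max_group_mean": expr.to_numpy(),
        }),
    }
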