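"""Masculinization/feminization classification of exposure-induced expression changes.

A probe is *sex-biased* if it is differentially expressed between control
females and control males. For an exposure DEG that is also sex-biased (matched
by identical probe id, since different probes covering one gene sit at
systematically different levels), the exposed-group mean is classified by

towards
    ``opposite`` when the exposure shift (exposed mean minus same-sex control
    mean) points in the direction of the opposite-sex control mean, ``same``
    when it points away, ``tie`` on an exactly zero shift;
proximity
    ``closer_to_opposite`` when the exposed mean lies nearer the opposite-sex
    control mean than the same-sex control mean, ``closer_to_same`` otherwise,
    ``equidistant`` on an exact tie.

Exact ties are tracked and excluded from "towards opposite" numerators rather
than silently assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

from .deg import AnalysisConfig, _round_half_up, compare_groups, filter_degs
from .io import DesignError, ExpressionMatrix, GroupSpec, SampleDesign


class ShiftClassification(NamedTuple):
    towards: str      # opposite | same | tie
    proximity: str    # closer_to_opposite | closer_to_same | equidistant
    exposure_direction: str  # up | down | none


@dataclass
class ShiftSummary:
    """Counts and integer percentages of an exposed-sex shift analysis.

    The nesting chain
    ``n_closer_to_opposite <= n_towards_opposite <= n_same_probe_id
    <= n_overlap_sex_biased <= n_exposure_degs`` holds by construction.
    ``towards_percent`` is relative to the classified (same-probe-id) overlap;
    ``closer_percent`` is relative to the towards-opposite count.
    """

    exposed_sex: str
    n_exposure_degs: int
    n_overlap_sex_biased: int
    overlap_percent: int
    n_same_probe_id: int
    n_towards_opposite: int
    towards_percent: int | None
    n_closer_to_opposite: int
    closer_percent: int | None
    n_ties: int
    percent_down: int | None
    percent_up: int | None

    def __post_init__(self) -> None:
        chain = (self.n_closer_to_opposite, self.n_towards_opposite,
                 self.n_same_probe_id, self.n_overlap_sex_biased,
                 self.n_exposure_degs)
        if not all(a <= b for a, b in zip(chain, chain[1:])):
            raise AssertionError(f"shift-summary count nesting violated: {chain}")

    def as_dict(self) -> dict:
        return asdict(self)


def identify_sex_biased(matrix: ExpressionMatrix, design: SampleDesign,
                        config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Control-female vs control-male DEGs, annotated with the bias direction.

    Columns: probe_id, mean_ctrl_f, mean_ctrl_m, p_value, bias_direction
    (higher_in_F / higher_in_M) plus the underlying comparison statistics.
    """
    cells = {("F", "control"), ("M", "control")}
    present = {(s, d) for s, d in zip(design.table["sex"], design.table["dose"])}
    if not cells <= present:
        raise DesignError("design lacks control samples of both sexes")
    records = compare_groups(
        matrix, design,
        GroupSpec("control female", frozenset({("F", "control")})),
        GroupSpec("control male", frozenset({("M", "control")})),
        config,
    )
    degs = filter_degs(records, config)
    out = degs.rename(columns={"mean_a": "mean_ctrl_f", "mean_b": "mean_ctrl_m"})
    out["bias_direction"] = np.where(
        out["mean_ctrl_f"] > out["mean_ctrl_m"], "higher_in_F", "higher_in_M"
    )
    return out


def overlap_exposure_with_sex_bias(exposure_degs: pd.DataFrame,
                                   sex_bias: pd.DataFrame) -> tuple[pd.Index, int]:
    """Probe-id intersection and its integer percentage of the exposure DEG count."""
    overlap = pd.Index(exposure_degs["probe_id"]).intersection(
        pd.Index(sex_bias["probe_id"])
    )
    n_exp = len(exposure_degs)
    percent = _round_half_up(100.0 * len(overlap) / n_exp) if n_exp else 0
    return overlap, percent


def classify_shift(mean_exposed: float, mean_same_ctrl: float,
                   mean_opp_ctrl: float) -> ShiftClassification:
    """Classify one probe's exposed-group mean against the two control means."""
    delta_exp = mean_exposed - mean_same_ctrl
    delta_opp = mean_opp_ctrl - mean_same_ctrl
    if delta_exp == 0:
        towards = "tie"
    elif np.sign(delta_exp) == np.sign(delta_opp) and delta_opp != 0:
        towards = "opposite"
    else:
        towards = "same"
    d_opp = abs(mean_exposed - mean_opp_ctrl)
    d_same = abs(mean_exposed - mean_same_ctrl)
    if d_opp < d_same:
        proximity = "closer_to_opposite"
    elif d_opp > d_same:
        proximity = "closer_to_same"
    else:
        proximity = "equidistant"
    direction = "up" if delta_exp > 0 else ("down" if delta_exp < 0 else "none")
    return ShiftClassification(towards, proximity, direction)


def classify_shifts(matrix: ExpressionMatrix, design: SampleDesign,
                    exposed_sex: str, pool_doses: bool = True,
                    config: AnalysisConfig = AnalysisConfig(),
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full shift classification for one exposed sex.

    Compares the exposed group (both doses pooled by default, mirroring the
    combined BPA(0.5+50) analysis) against same-sex controls, intersects the
    resulting DEGs with the sex-biased universe by probe id, and classifies
    each overlapping probe. Returns (classifications, exposure_degs, sex_bias).
    """
    if exposed_sex not in ("F", "M"):
        raise DesignError(f"exposed_sex must be 'F' or 'M', got {exposed_sex!r}")
    doses = ("d0.5", "d50") if pool_doses else ("d0.5",)
    exposed = GroupSpec(
        f"{exposed_sex} exposed", frozenset({(exposed_sex, d) for d in doses})
    )
    ctrl = GroupSpec(
        f"{exposed_sex} control", frozenset({(exposed_sex, "control")})
    )
    exposure_degs = filter_degs(
        compare_groups(matrix, design, exposed, ctrl, config), config
    )
    sex_bias = identify_sex_biased(matrix, design, config)

    overlap, _ = overlap_exposure_with_sex_bias(exposure_degs, sex_bias)
    exp_means = exposure_degs.set_index("probe_id").loc[overlap]
    bias_means = sex_bias.set_index("probe_id").loc[overlap]
    opp_col = "mean_ctrl_m" if exposed_sex == "F" else "mean_ctrl_f"
    same_col = "mean_ctrl_f" if exposed_sex == "F" else "mean_ctrl_m"

    rows = []
    for probe in overlap:
        cls = classify_shift(
            float(exp_means.at[probe, "mean_a"]),
            float(bias_means.at[probe, same_col]),
            float(bias_means.at[probe, opp_col]),
        )
        rows.append({
            "probe_id": probe,
            "exposed_sex": exposed_sex,
            "mean_exposed": float(exp_means.at[probe, "mean_a"]),
            "mean_same_ctrl": float(bias_means.at[probe, same_col]),
            "mean_opp_ctrl": float(bias_means.at[probe, opp_col]),
            "towards": cls.towards,
            "proximity": cls.proximity,
            "exposure_direction": cls.exposure_direction,
        })
    columns = ["probe_id", "exposed_sex", "mean_exposed", "mean_same_ctrl",
               "mean_opp_ctrl", "towards", "proximity", "exposure_direction"]
    classifications = pd.DataFrame(rows, columns=columns)
    return classifications, exposure_degs, sex_bias


def summarize_shift(classifications: pd.DataFrame,
                    exposure_degs: pd.DataFrame,
                    sex_bias: pd.DataFrame) -> ShiftSummary:
    """Aggregate per-probe classifications into masculinization/feminization counts and percentages."""
    overlap, overlap_percent = overlap_exposure_with_sex_bias(exposure_degs, sex_bias)
    n_same = len(classifications)
    towards_opp = classifications["towards"] == "opposite"
    n_towards = int(towards_opp.sum())
    n_closer = int((towards_opp & (classifications["proximity"] == "closer_to_opposite")).sum())
    n_ties = int(((classifications["towards"] == "tie")
                  | (classifications["proximity"] == "equidistant")).sum())
    n_down = int((classifications["exposure_direction"] == "down").sum())
    n_up = int((classifications["exposure_direction"] == "up").sum())
    exposed_sex = (classifications["exposed_sex"].iloc[0]
                   if n_same else "NA")
    return ShiftSummary(
        exposed_sex=exposed_sex,
        n_exposure_degs=len(exposure_degs),
        n_overlap_sex_biased=len(overlap),
        overlap_percent=overlap_percent,
        n_same_probe_id=n_same,
        n_towards_opposite=n_towards,
        towards_percent=_round_half_up(100.0 * n_towards / n_same) if n_same else None,
        n_closer_to_opposite=n_closer,
        closer_percent=_round_half_up(100.0 * n_closer / n_towards) if n_towards else None,
        n_ties=n_ties,
        percent_down=_round_half_up(100.0 * n_down / n_same) if n_same else None,
        percent_up=_round_half_up(100.0 * n_up / n_same) if n_same else None,
    )


def shift_plot_data(classifications: pd.DataFrame) -> pd.DataFrame:
    """Expression-level plot data: probes ranked by opposite-sex control mean."""
    out = classifications.sort_values("mean_opp_ctrl", kind="mergesort").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out[["rank", "probe_id", "mean_exposed", "mean_same_ctrl", "mean_opp_ctrl"]]


def opposite_regulation_table(deg_f: pd.DataFrame, deg_m: pd.DataFrame) -> dict:
    """Probes significant in both sexes with per-sex directions.

    Directions are each sex's exposed-vs-same-sex-control direction; the table
    reports which probes move the same way in both sexes and which move
    oppositely.
    """
    merged = deg_f.merge(deg_m, on="probe_id", suffixes=("_f", "_m"))
    table = merged[["probe_id", "direction_f", "direction_m",
                    "mean_a_f", "mean_b_f", "p_value_f",
                    "mean_a_m", "mean_b_m", "p_value_m"]].copy()
    table["same_direction"] = table["direction_f"] == table["direction_m"]
    n_common = len(table)
    n_same = int(table["same_direction"].sum())
    return {
        "table": table.sort_values("probe_id", kind="mergesort").reset_index(drop=True),
        "n_common": n_common,
        "n_same_direction": n_same,
        "n_opposite_direction": n_common - n_same,
    }
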