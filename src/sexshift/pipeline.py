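"""End-to-end orchestration: simulate/read -> DEG -> shift -> ANOVA -> concordance.

Every output file carries header comments with the tool version, the run seed
and SHA-256 checksums of the inputs, and a run manifest (JSON) records the
whole bundle, so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import bundled_table, score_concordance
from .deg import AnalysisConfig, compare_groups, filter_degs, summarize_deg_sets
from .io import (ExpressionMatrix, GroupSpec, SampleDesign, read_expression,
                 write_deg_table, write_expression)
from .metabo import tukey_hsd, two_way_anova
from .shift import classify_shifts, shift_plot_data, summarize_shift
from .simulate import ExprSimConfig, PanelSimConfig, simulate_expression, \
    simulate_metabolite_panel


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    seed: int = 0
    outdir: Path = Path("sexshift_run")
    matrix_path: Path | None = None   # when None, expression data is simulated
    design_path: Path | None = None
    simulation: dict = field(default_factory=dict)
    panel_simulation: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    pool_doses: bool = True

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        cfg.outdir = Path(cfg.outdir)
        if cfg.matrix_path:
            cfg.matrix_path = Path(cfg.matrix_path)
        if cfg.design_path:
            cfg.design_path = Path(cfg.design_path)
        return cfg

    def validate(self) -> None:
        for p in (self.matrix_path, self.design_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        AnalysisConfig(**self.analysis)  # raises on invalid thresholds


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, header: list[str]) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"sexshift {__version__}", f"seed {config.seed}"]
    analysis = AnalysisConfig(**config.analysis)
    outputs: dict[str, str] = {}

    def emit(df: pd.DataFrame, name: str) -> None:
        path = _write_tsv(df, outdir / name, header)
        outputs[name] = _sha256(path)

    # --- stage: expression data -------------------------------------------
    try:
        if config.matrix_path is not None:
            matrix, design = read_expression(config.matrix_path, config.design_path)
            inputs = {str(config.matrix_path): _sha256(config.matrix_path),
                      str(config.design_path): _sha256(config.design_path)}
        else:
            sim_cfg = ExprSimConfig(**{"seed": config.seed, **config.simulation})
            matrix, design, truth = simulate_expression(sim_cfg)
            mp, dp = write_expression(matrix, design, outdir / "matrix.tsv",
                                      outdir / "design.tsv", header)
            emit(truth.table, "sim_truth.tsv")
            outputs["matrix.tsv"] = _sha256(mp)
            outputs["design.tsv"] = _sha256(dp)
            inputs = {"simulated": f"seed={config.seed}"}
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage 'expression data': {exc}") from exc

    # --- stage: DEG tables and up/down summary ----------------------------
    try:
        comparisons = {
            "ctrlF_vs_ctrlM": (GroupSpec.parse("F:control"), GroupSpec.parse("M:control")),
            "expF_vs_ctrlF": (GroupSpec.parse("F:d0.5+d50"), GroupSpec.parse("F:control")),
            "expM_vs_ctrlM": (GroupSpec.parse("M:d0.5+d50"), GroupSpec.parse("M:control")),
        }
        deg_sets = {}
        for label, (ga, gb) in comparisons.items():
            degs = filter_degs(compare_groups(matrix, design, ga, gb, analysis), analysis)
            deg_sets[label] = degs
            path = write_deg_table(degs, outdir / f"degs_{label}.tsv", header)
            outputs[path.name] = _sha256(path)
        emit(summarize_deg_sets(deg_sets), "deg_summary.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'deg': {exc}") from exc

    # --- stage: shift classification --------------------------------------
    shift_summaries = []
    try:
        for sex in ("F", "M"):
            cls, exp_degs, sex_bias = classify_shifts(
                matrix, design, sex, pool_doses=config.pool_doses, config=analysis
            )
            emit(cls, f"shift_classification_{sex}.tsv")
            emit(shift_plot_data(cls), f"shift_plot_data_{sex}.tsv")
            summary = summarize_shift(cls, exp_degs, sex_bias)
            shift_summaries.append(summary.as_dict())
        emit(pd.DataFrame(shift_summaries), "shift_summary.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'sexshift': {exc}") from exc

    # --- stage: metabolite ANOVA ------------------------------------------
    try:
        panel_cfg = PanelSimConfig(**{
            "analytes": ("analyte_null", "analyte_bpa", "analyte_interaction"),
            "cell_means": {
                "analyte_bpa": {("F", "d0.5"): 1.5, ("M", "d0.5"): 1.5,
                                ("F", "d50"): 1.5, ("M", "d50"): 1.5},
                "analyte_interaction": {("F", "d0.5"): 1.5, ("M", "d0.5"): -1.5,
                                        ("F", "d50"): 1.5, ("M", "d50"): -1.5},
            },
            "seed": config.seed + 1,
            **config.panel_simulation,
        })
        panel, _ = simulate_metabolite_panel(panel_cfg)
        rows = []
        for analyte in panel_cfg.analytes:
            for dose in ("d0.5", "d50"):
                res = two_way_anova(panel, analyte, dose)
                rows.append({"analyte": analyte, "dose": dose,
                             "p_treatment": res.p_treatment,
                             "p_interaction": res.p_interaction,
                             "f_treatment": res.f_treatment,
                             "f_interaction": res.f_interaction})
        emit(pd.DataFrame(rows), "anova.tsv")
        emit(tukey_hsd(panel, panel_cfg.analytes[-1], "d0.5"), "tukey.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'anova': {exc}") from exc

    # --- stage: concordance -----------------------------------------------
    try:
        conc_rows = []
        for stratum in ("female", "male"):
            res = score_concordance(bundled_table(stratum), ns_policy="strict")
            conc_rows.append({"stratum": stratum, "n_rows": res.n_rows,
                              "n_comparable": res.n_comparable,
                              "n_aligned": res.n_aligned,
                              "aligned_percent": res.aligned_percent})
        emit(pd.DataFrame(conc_rows), "concordance.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'concordance': {exc}") from exc

    manifest = {
        "tool": "sexshift",
        "version": __version__,
        "seed": config.seed,
        "inputs": inputs,
        "analysis": dataclasses.asdict(analysis),
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def render_report(outdir: Path) -> str:
    """Human-readable digest of a completed run directory."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines = [f"sexshift {manifest['version']} run (seed {manifest['seed']})", ""]
    for name in ("deg_summary.tsv", "shift_summary.tsv", "concordance.tsv"):
        path = outdir / name
        if path.exists():
            lines.append(f"== {name} ==")
            lines.append(pd.read_csv(path, sep="\t", comment="#").to_string(index=False))
            lines.append("")
    return "\n".join(lines)
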