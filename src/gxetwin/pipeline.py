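"""End-to-end orchestration: simulate -> prep -> score -> associate -> twin.

A single seeded configuration drives the whole analysis and produces a
``ResultsReport`` with five blocks mirroring the study design: phenotypic
correlations, GPS associations (raw and parent-BMI-adjusted), within-family
fixed-effects estimates (combined and same-/opposite-sex DZ), the
correlated-factors twin model, and the MZ-discordance regressions.  Each
block records the sample size it was computed on; identical config + seed
gives a byte-identical JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, prs
from .calibrate import calibrated_model
from .pheno import prepare_phenotypes, cronbach_alpha, RESTRICTION_ITEMS, PRESSURE_ITEMS
from .lms import LmsReference
from .simulate import simulate_cohort, read_cohort, write_cohort
from .twin import (TwinData, fit_correlated_factors, fit_saturated,
                   compare_models, intraclass_correlations, profile_ci)

log = logging.getLogger("gxetwin")

__all__ = ["PipelineConfig", "ResultsReport", "run_pipeline", "render_report"]

TRAIT_COLS = ("bmi_sds", "restriction", "pressure")


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    output_dir: str | None = None
    generating: dict = field(default_factory=dict)
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    p_thresholds: tuple = prs.DEFAULT_P_THRESHOLDS
    analysis_p_threshold: float = 0.001
    n_pcs: int = 10
    adjust_parent_bmi: bool = True
    dz_split: bool = True
    unrelated_twin_order: int = 1
    compute_ci: bool = False
    n_replicates: int = 1
    write_intermediates: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.simulate and not self.input_dir:
            raise ValueError("input_dir is required when not simulating")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("version", None)
        return cls(**raw)


@dataclass
class ResultsReport:
    blocks: dict
    schema_version: str = "1"

    def to_dict(self) -> dict:
        return {"schema_version": self.schema_version, "blocks": self.blocks}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ResultsReport":
        d = json.loads(text)
        return cls(blocks=d["blocks"], schema_version=d.get("schema_version", "1"))


def _assoc_row(res: assoc.AssociationResult) -> dict:
    return {k: (None if v is None or (isinstance(v, float) and not np.isfinite(v))
                else v) for k, v in res.as_row().items()}


def _unrelated_mask(df: pd.DataFrame, twin_order: int) -> np.ndarray:
    unr = (df["zygosity"] == "UNR").to_numpy()
    if unr.any():
        return unr
    return (df["twin_order"] == twin_order).to_numpy()


def _safe(fn, *args, **kw):
    try:
        return _assoc_row(fn(*args, **kw))
    except (assoc.DegenerateVarianceError, assoc.InsufficientDataError) as err:
        return {"error": str(err)}


def run_pipeline(config: PipelineConfig) -> ResultsReport:
    """Execute every enabled stage; aborts with the stage name on failure."""
    stage = "configure"
    try:
        if config.n_replicates > 1:
            return _replicate_study(config)

        stage = "simulate" if config.simulate else "load"
        model = None
        if config.simulate:
            model = calibrated_model(seed=config.seed, **config.generating)
            tables, panel, _ = simulate_cohort(model)
            log.info("simulated cohort: %d individuals, %d SNPs",
                     len(tables.phenotypes), panel.n_snps)
        else:
            tables = read_cohort(config.input_dir)
            panel = None
        if config.output_dir and (config.write_intermediates or not config.simulate):
            write_cohort(tables, Path(config.output_dir) / "cohort")

        stage = "prep"
        ref = LmsReference(tables.lms)
        clean = prepare_phenotypes(tables.phenotypes, ref)
        df = clean.data
        log.info("prep: %d rows, %d exclusion records", len(df),
                 len(clean.exclusions))

        report: dict = {}
        unrel = _unrelated_mask(df, config.unrelated_twin_order)
        du = df[unrel]

        stage = "phenotypic_correlations"
        block = {}
        for a, b in (("bmi_sds", "restriction"), ("bmi_sds", "pressure"),
                     ("restriction", "pressure")):
            block[f"{a}__{b}"] = _safe(assoc.standardized_ols, du[b], du[a])
        raw = tables.phenotypes
        for scale, items in (("restriction", RESTRICTION_ITEMS),
                             ("pressure", PRESSURE_ITEMS)):
            if set(items).issubset(raw.columns) and len(raw) >= 3:
                block[f"alpha_{scale}"] = cronbach_alpha(raw[items])
        report["phenotypic_correlations"] = block

        stage = "polygenic_score"
        clump_cfg = prs.ClumpConfig(r2_threshold=config.clump_r2,
                                    window_kb=config.clump_window_kb,
                                    p_thresholds=tuple(config.p_thresholds))
        retained = prs.clump(tables.sumstats, tables.dosages, clump_cfg)
        gps_raw, k = prs.score(tables.dosages, tables.sumstats,
                               retained["SNP"], config.analysis_p_threshold)
        if config.n_pcs > 0:
            chrom = tables.sumstats.set_index("SNP").loc[
                tables.dosages.columns, "CHR"].to_numpy()
            pos = tables.sumstats.set_index("SNP").loc[
                tables.dosages.columns, "BP"].to_numpy()
            pcs = prs.genotype_pca(tables.dosages, chrom=chrom, pos=pos,
                                   n_components=config.n_pcs,
                                   random_state=config.seed)
            gps = prs.adjust_score(gps_raw, components=pcs.to_numpy())
        else:
            gps = prs.adjust_score(gps_raw)
        gps = gps.reindex(df["individual_id"]).to_numpy()
        df = df.assign(gps=gps)
        du = df[unrel]

        stage = "gps_associations"
        block = {"n_score_snps": int(k), "n_clumped": int(len(retained))}
        for outcome in TRAIT_COLS:
            block[f"gps__{outcome}"] = _safe(assoc.standardized_ols,
                                             du[outcome], du["gps"])
        if "parent_bmi" in du.columns:
            for outcome in TRAIT_COLS:
                block[f"parent_bmi__{outcome}"] = _safe(
                    assoc.standardized_ols, du[outcome], du["parent_bmi"])
            if config.adjust_parent_bmi:
                for outcome in ("restriction", "pressure"):
                    ok = np.isfinite(du["parent_bmi"].to_numpy(float))
                    sub = du[ok]
                    resid = _residual(sub[outcome], sub["parent_bmi"])
                    block[f"gps__{outcome}_parent_adjusted"] = _safe(
                        assoc.standardized_ols, resid, sub["gps"])
        report["gps_associations"] = block

        stage = "within_family"
        block = {}
        dz_sets = {"combined": df["zygosity"].isin(["DZ_ss", "DZ_os"])}
        if config.dz_split:
            dz_sets["same_sex"] = df["zygosity"] == "DZ_ss"
            dz_sets["opposite_sex"] = df["zygosity"] == "DZ_os"
        for label, mask in dz_sets.items():
            sub = df[mask.to_numpy() if hasattr(mask, "to_numpy") else mask]
            for outcome in ("restriction", "pressure"):
                block[f"{label}:gps__{outcome}"] = _safe(
                    assoc.fixed_effects_within_family, sub[outcome],
                    sub["gps"], sub["family_id"])
        report["within_family"] = block

        stage = "twin_model"
        tdata = TwinData.from_phenotypes(df, TRAIT_COLS)
        fit = fit_correlated_factors(tdata, "ACE", seed=config.seed)
        sat = fit_saturated(tdata)
        ae = fit_correlated_factors(tdata, "AE", seed=config.seed)
        icc = intraclass_correlations(tdata)
        block = {
            "n_pairs": {g: int(n) for g, n in fit.n_pairs.items()},
            "standardized": {t: {c: float(fit.std_props.loc[t, c])
                                 for c in ("A", "C", "E")}
                             for t in TRAIT_COLS},
            "correlations": {key: {f"{TRAIT_COLS[i]}__{TRAIT_COLS[j]}":
                                   float(fit.correlations[key][i, j])
                                   for i in range(3) for j in range(i + 1, 3)}
                             for key in ("r_a", "r_c", "r_e")},
            "fit": [{"model": f.model, "ep": f.n_params,
                     "minus2LL": round(f.minus2LL, 6), "df": f.df,
                     "AIC": round(f.aic, 6)} for f in (sat, fit, ae)],
            "ace_vs_saturated": compare_models(sat, fit),
            "ae_vs_ace": compare_models(fit, ae),
            "icc": {g: {t: float(icc.loc[g, t]) for t in TRAIT_COLS}
                    for g in icc.index},
        }
        if config.compute_ci:
            cis = {}
            for t in TRAIT_COLS:
                cis[f"A_{t}"] = list(profile_ci(fit, ("A", t)))
            for i in range(3):
                for j in range(i + 1, 3):
                    cis[f"r_a_{TRAIT_COLS[i]}__{TRAIT_COLS[j]}"] = list(
                        profile_ci(fit, ("r_a", i, j)))
            block["profile_ci_95"] = cis
        report["twin_model"] = block

        stage = "mz_difference"
        mz = df[df["zygosity"] == "MZ"].reset_index(drop=True)
        block = {}
        for outcome in ("restriction", "pressure"):
            block[f"delta_bmi__delta_{outcome}"] = _safe(
                assoc.mz_difference_regression, mz[outcome].to_numpy(),
                mz["bmi_sds"].to_numpy(), mz["family_id"].to_numpy())
        report["mz_difference"] = block

        out = ResultsReport(blocks=_jsonify(report))
        if config.output_dir:
            stage = "write_report"
            outdir = Path(config.output_dir)
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "report.json").write_text(out.to_json())
            (outdir / "report.md").write_text(render_report(out, "markdown"))
        return out
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err


def _residual(y, x):
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    ok = np.isfinite(y) & np.isfinite(x)
    X = np.column_stack([np.ones(ok.sum()), x[ok]])
    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    out = np.full(y.size, np.nan)
    out[ok] = y[ok] - X @ beta
    return out


def _replicate_study(config: PipelineConfig) -> ResultsReport:
    """Replicate mode: repeat the single-cohort run with spawned seeds and
    summarise key estimands with Monte-Carlo standard errors."""
    base = config
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_replicates)
    rows = []
    for r, s in enumerate(seeds):
        cfg = PipelineConfig(**{**asdict(base), "n_replicates": 1,
                                "seed": int(s % (2 ** 31 - 1)),
                                "output_dir": None})
        rep = run_pipeline(cfg).blocks
        row = {}
        for key in ("gps__bmi_sds", "gps__restriction", "gps__pressure"):
            entry = rep["gps_associations"].get(key, {})
            if "beta" in entry:
                row[key] = entry["beta"]
        for t in TRAIT_COLS:
            row[f"A_{t}"] = rep["twin_model"]["standardized"][t]["A"]
        rows.append(row)
    frame = pd.DataFrame(rows)
    summary = {
        col: {"mean": float(frame[col].mean()),
              "mc_se": float(frame[col].std(ddof=1) / np.sqrt(len(frame))),
              "n_replicates": int(frame[col].notna().sum())}
        for col in frame.columns
    }
    return ResultsReport(blocks={"replicate_summary": summary,
                                 "n_replicates": config.n_replicates})


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def render_report(report: ResultsReport, format: str = "json") -> str:
    """Render the report; 'json' round-trips losslessly, 'markdown' mirrors
    the results-table ordering of the analysis blocks."""
    if format == "json":
        return report.to_json()
    if format != "markdown":
        raise ValueError(f"unknown format {format!r}")
    lines = ["# Gene-environment correlation analysis report", ""]
    order = ["phenotypic_correlations", "gps_associations", "within_family",
             "twin_model", "mz_difference", "replicate_summary"]
    blocks = report.blocks
    for name in order + [k for k in blocks if k not in order]:
        if name not in blocks or not blocks[name]:
            continue
        lines.append(f"## {name.replace('_', ' ')}")
        lines.append("")
        lines.extend(_render_block(blocks[name]))
        lines.append("")
    return "\n".join(lines)


def _render_block(block, prefix=""):
    lines = []
    if isinstance(block, dict) and block and all(
            isinstance(v, dict) and "beta" in v for v in block.values()):
        lines.append("| test | beta | t | df | p | r2 | n |")
        lines.append("|---|---|---|---|---|---|---|")
        for key, v in block.items():
            lines.append(
                f"| {prefix}{key} | {v['beta']:.4f} | {v['t']:.2f} | {v['df']} "
                f"| {v['p']:.3g} | {v['r2']:.4f} | {v['n']} |")
        return lines
    if isinstance(block, dict):
        for key, v in block.items():
            if isinstance(v, dict) and "beta" in v:
                lines.append(
                    f"- {prefix}{key}: beta={v['beta']:.4f} (t={v['t']:.2f}, "
                    f"df={v['df']}, p={v['p']:.3g}, n={v['n']})")
            elif isinstance(v, dict):
                lines.append(f"**{prefix}{key}**")
                lines.extend(_render_block(v))
            elif isinstance(v, list):
                lines.append(f"- {key}: {v}")
            else:
                lines.append(f"- {key}: {v}")
        return lines
    return [str(block)]
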