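"""End-to-end analysis pipeline tying the stages together.

Stage order: reader classification and composite scoring, backbone
identification from the reference group, FA-weighted nodal degree and mean
backbone FA, group statistics, region-wise ANCOVA, partial-correlation hub
screening with BH-FDR per behavioral measure, between-group Fisher r-to-z
comparison for each hub, hierarchical regression of phonological awareness
on the hubs over the covariate block, and bootstrap mediation
(hub degree -> phonological awareness -> character reading) per hub.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    ancova_group_effect,
    fisher_z_compare,
    hierarchical_regression,
    partial_correlation,
    screen_hubs,
)
from .behavior import BehavioralRecord, composite_frame, group_compare
from .connectome import (
    BackboneNetwork,
    SubjectConnectome,
    backbone_mean_fa,
    identify_backbone,
    nodal_strength_table,
)
from .io import read_behavior, read_cohort, write_backbone, write_table
from .mediation import mediate, mediation_report

COVARIATES = ["sex", "age", "raven_iq"]
MEASURES = {"pa_z": "PA", "ran_z": "RAN", "character_reading": "reading"}


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    manifest: str = ""
    behavior: str = ""
    out_dir: str = "hubnet_out"
    reference_group: str = "good"  # backbone-defining group, or "all"
    alpha: float = 0.05
    zero_convention: str = "discard_zeros"
    measures: list[str] = field(default_factory=lambda: list(MEASURES))
    covariates: list[str] = field(default_factory=lambda: list(COVARIATES))
    q_threshold: float = 0.05
    n_boot: int = 1000
    level: float = 0.95
    seed: int = 0
    welch: bool = False  # Welch instead of pooled t for group comparisons

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineReport:
    backbone: BackboneNetwork
    composites: pd.DataFrame
    group_stats: pd.DataFrame
    ancova: pd.DataFrame
    screening: dict[str, pd.DataFrame]
    hubs: dict[str, list[str]]
    fisher: pd.DataFrame
    regression: pd.DataFrame | None
    regression_steps: pd.DataFrame | None
    mediation: dict[str, object]
    mean_fa: pd.DataFrame


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:  # annotate with the failing stage
                raise PipelineError(name, e) from e

        return wrapped

    return deco


def analyze_cohort(
    connectomes: Sequence[SubjectConnectome],
    records: Sequence[BehavioralRecord],
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """Run the full in-memory analysis on an already-loaded cohort."""
    cfg = config or PipelineConfig()
    if len(connectomes) != len(records):
        raise PipelineError(
            "input", ValueError("connectome and behavioral subject counts differ")
        )
    ids_c = [s.subject_id for s in connectomes]
    ids_b = [r.subject_id for r in records]
    if ids_c != ids_b:
        raise PipelineError(
            "input", ValueError("subject order differs between manifest and behavior")
        )

    comp = _stage("composites")(composite_frame)(records)
    groups = comp["group"].to_numpy()
    covs = comp[cfg.covariates].to_numpy(float)

    @_stage("backbone")
    def _backbone():
        ref = (
            list(connectomes)
            if cfg.reference_group == "all"
            else [s for s, g in zip(connectomes, groups) if g == cfg.reference_group]
        )
        return identify_backbone(
            ref, alpha=cfg.alpha, zero_convention=cfg.zero_convention
        )

    backbone = _backbone()

    @_stage("nodal_strength")
    def _strengths():
        return nodal_strength_table(connectomes, backbone)

    strengths = _strengths()

    @_stage("mean_fa")
    def _mean_fa():
        vals = [backbone_mean_fa(s, backbone) for s in connectomes]
        return pd.DataFrame(
            {"subject_id": ids_c, "group": groups, "backbone_mean_fa": vals}
        )

    mean_fa = _mean_fa()

    @_stage("group_stats")
    def _group_stats():
        kind = "t_welch" if cfg.welch else "t_pooled"
        rows = []
        by_group = lambda col: (
            comp.loc[comp.group == "good", col].to_numpy(float),
            comp.loc[comp.group == "poor", col].to_numpy(float),
        )
        sex_tab = pd.crosstab(comp["group"], comp["sex"]).to_numpy()
        chi2, df, p = group_compare(sex_tab, "chi_square")
        rows.append(("sex", "chi_square", chi2, df, p))
        for col in ["age", "raven_iq", "character_reading", "pa_z", "ran_z",
                    "phoneme_deletion", "spoonerism1", "spoonerism2",
                    "ran_digits", "ran_objects", "ran_colors"]:
            t, df, p = group_compare(by_group(col), kind)
            rows.append((col, kind, t, df, p))
        t, df, p = group_compare(
            (
                mean_fa.loc[mean_fa.group == "good", "backbone_mean_fa"],
                mean_fa.loc[mean_fa.group == "poor", "backbone_mean_fa"],
            ),
            kind,
        )
        rows.append(("backbone_mean_fa", kind, t, df, p))
        return pd.DataFrame(
            rows, columns=["measure", "test", "statistic", "df", "p"]
        )

    group_stats = _group_stats()

    @_stage("ancova")
    def _ancova():
        indicator = (groups == "poor").astype(int)
        res = ancova_group_effect(strengths, indicator, covs)
        return pd.DataFrame(
            [
                (r.region, r.group_effect, r.t, r.p_raw, r.p_adjusted)
                for r in res
            ],
            columns=["region", "group_effect", "t", "p_raw", "p_adjusted"],
        )

    ancova = _ancova()

    screening: dict[str, pd.DataFrame] = {}
    hubs: dict[str, list[str]] = {}

    @_stage("screening")
    def _screening():
        for col in cfg.measures:
            res = screen_hubs(
                strengths, comp[col].to_numpy(float), covs, q=cfg.q_threshold
            )
            screening[col] = pd.DataFrame(
                [
                    (r.region, r.r, r.df, r.p_raw, r.p_adjusted)
                    for r in res
                ],
                columns=["region", "r", "df", "p_raw", "p_adjusted"],
            )
            hubs[col] = [
                r.region for r in res if r.p_adjusted < cfg.q_threshold
            ]

    _screening()
    pa_hubs = hubs.get("pa_z", [])

    @_stage("fisher")
    def _fisher():
        rows = []
        k = len(cfg.covariates)
        for hub in pa_hubs:
            per_group = {}
            for g in ("good", "poor"):
                mask = groups == g
                per_group[g] = partial_correlation(
                    strengths.region(hub)[mask],
                    comp.loc[mask, "pa_z"].to_numpy(float),
                    covs[mask],
                    region=hub,
                )
            fz = fisher_z_compare(
                per_group["good"].r,
                int(np.sum(groups == "good")),
                per_group["poor"].r,
                int(np.sum(groups == "poor")),
                k=k,
            )
            rows.append(
                (hub, per_group["good"].r, per_group["poor"].r, fz.z, fz.p)
            )
        return pd.DataFrame(
            rows, columns=["region", "r_good", "r_poor", "z", "p"]
        )

    fisher = _fisher()

    regression = regression_steps = None
    if pa_hubs:

        @_stage("regression")
        def _regression():
            blocks = [
                comp[cfg.covariates],
                pd.DataFrame(
                    {h: strengths.region(h) for h in pa_hubs},
                    index=comp.index,
                ),
            ]
            return hierarchical_regression(
                comp["pa_z"].to_numpy(float), blocks
            )

        reg = _regression()
        regression = reg.frame()
        regression_steps = pd.DataFrame([vars(s) for s in reg.steps])

    @_stage("mediation")
    def _mediation():
        out = {}
        for i, hub in enumerate(pa_hubs):
            out[hub] = mediate(
                strengths.region(hub),
                comp["pa_z"].to_numpy(float),
                comp["character_reading"].to_numpy(float),
                covs,
                n_boot=cfg.n_boot,
                level=cfg.level,
                seed=cfg.seed + i,
                covariate_names=list(cfg.covariates),
            )
        return out

    mediation = _mediation()

    return PipelineReport(
        backbone=backbone,
        composites=comp,
        group_stats=group_stats,
        ancova=ancova,
        screening=screening,
        hubs=hubs,
        fisher=fisher,
        regression=regression,
        regression_steps=regression_steps,
        mediation=mediation,
        mean_fa=mean_fa,
    )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Load a cohort from disk, analyze it, and write the report bundle."""
    try:
        connectomes = read_cohort(config.manifest)
        records = read_behavior(config.behavior)
    except Exception as e:
        raise PipelineError("load", e) from e

    report = analyze_cohort(connectomes, records, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_backbone(report.backbone, out)
    write_table(report.composites, out / "composites.tsv")
    write_table(report.group_stats, out / "group_stats.tsv")
    write_table(report.ancova, out / "ancova.tsv")
    write_table(report.mean_fa, out / "backbone_mean_fa.tsv")
    for col, frame in report.screening.items():
        write_table(frame, out / f"screening_{col}.tsv")
    write_table(report.fisher, out / "fisher_z.tsv")
    if report.regression is not None:
        write_table(report.regression, out / "regression_coefficients.tsv")
        write_table(report.regression_steps, out / "regression_steps.tsv")
    with open(out / "mediation.txt", "w") as fh:
        for hub, res in report.mediation.items():
            fh.write(mediation_report(res, label=hub) + "\n\n")

    b = report.backbone
    log = {
        "hubnet_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "zero_convention": b.zero_convention,
        "corrected_threshold": b.corrected_threshold,
        "reference_group": config.reference_group,
        "reference_n": b.reference_n,
        "n_edges": b.n_edges,
        "sparsity": b.sparsity,
        "alt_densities": b.alt_densities,
        "q_threshold": config.q_threshold,
        "measures": list(config.measures),
        "covariates": list(config.covariates),
        "n_boot": config.n_boot,
        "level": config.level,
        "welch": config.welch,
        "hubs": report.hubs,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    return report
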