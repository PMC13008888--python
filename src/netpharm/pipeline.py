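"""End-to-end orchestration and candidate prioritization.

One config drives the whole decision procedure: descriptor screening →
per-target decoy-controlled thresholds → interaction classification →
ubiquity flags → merged network with centralities → prioritized candidate
tables. The two candidate tables mirror the usual reporting layout: the
first lists probable binders with high gastrointestinal absorption
(grouped by target, strongest affinity first) and the second its
non-ubiquitous subset.

Inputs either come from TSV files (the ``inputs`` mapping) or are produced
by the synthetic generators; in both cases the same stages run. All
artifacts are plain text (TSV/JSON/SIF/GraphML) written into a caller-named
output directory with no timestamps, so a rerun with the same config and
seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .adme import (
    PhytochemicalRecord,
    bioavailability_tier,
    lipophilicity_flag,
    screen_phytochemicals,
)
from .classifier import (
    LabeledScoreSet,
    ThresholdResult,
    classify_interactions,
    export_distribution_summary,
    roc_curve,
    screen_diagnostics,
)
from .io import read_interactions, read_scores, read_table, write_table
from .network import build_network, centralities, write_graphml, write_sif
from .synthetic import (
    CohortSimConfig,
    ScoreSimConfig,
    generate_interactions,
    generate_phytochemicals,
    generate_ppi,
    generate_score_sets,
    generate_targets,
)
from .ubiquity import MissingReferenceError, UbiquityTable, flag_ubiquitous

logger = logging.getLogger("netpharm")

# which subcellular locations demand membrane permeation by the ligand
DEFAULT_LOCATION_RULES: dict[str, str] = {
    "secreted": "any",
    "extracellular": "any",
    "cell_membrane": "permeation",
    "membrane": "permeation",
    "cell_surface": "permeation",
    "cytoplasm": "permeation",
    "intracellular": "permeation",
    "nucleus": "permeation",
    "endoplasmic_reticulum": "permeation",
    "mitochondrion": "permeation",
}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from a nested YAML file."""

    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)  # paths; empty → synthetic
    score_sim: ScoreSimConfig = field(default_factory=ScoreSimConfig)
    cohort_sim: CohortSimConfig = field(default_factory=CohortSimConfig)
    threshold_criterion: str = "youden"  # or "best_accuracy"
    ef_fractions: tuple[float, ...] = (0.2,)
    reference_compound: str = "quinic acid"
    require_high_gi: bool = True
    require_non_ubiquity: bool = True
    location_rules: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LOCATION_RULES)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "score_sim" in kwargs:
            kwargs["score_sim"] = ScoreSimConfig(**kwargs["score_sim"])
        if "cohort_sim" in kwargs:
            kwargs["cohort_sim"] = CohortSimConfig(**kwargs["cohort_sim"])
        if "ef_fractions" in kwargs:
            kwargs["ef_fractions"] = tuple(kwargs["ef_fractions"])
        cfg = cls(**kwargs)
        for p in cfg.inputs.values():
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input path does not exist: {p}")
        return cfg

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(
            self,
            seed=seed,
            score_sim=replace(self.score_sim, seed=seed),
            cohort_sim=replace(self.cohort_sim, seed=seed),
        )


@dataclass
class PipelineResult:
    compounds: pd.DataFrame
    retained: pd.DataFrame
    exclusion_log: pd.DataFrame
    targets: pd.DataFrame
    score_sets: list[LabeledScoreSet]
    thresholds: dict[str, ThresholdResult]
    diagnostics: pd.DataFrame
    classified: pd.DataFrame
    ubiquity_flags: dict[str, str]
    network: nx.Graph
    centrality: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    stage_counts: dict[str, int]


def location_compatible(
    compound: PhytochemicalRecord,
    target_location: str,
    rules: dict[str, str] | None = None,
) -> tuple[bool, str]:
    """Can this compound plausibly reach a target at this location?

    Secreted/extracellular targets are reachable for any finite log P.
    Targets behind a membrane (cell surface inward) additionally require
    predicted high gastrointestinal absorption and a consensus log P that
    is neither too lipophilic nor too hydrophilic to cross the bilayer.
    The location → policy matrix is overridable via ``rules``.
    """
    rules = rules if rules is not None else DEFAULT_LOCATION_RULES
    loc = str(target_location).strip().lower()
    if loc not in rules:
        raise ValueError(f"unknown subcellular location class: {target_location!r}")
    if rules[loc] == "any":
        if not np.isfinite(compound.consensus_logp):
            raise ValueError(f"{compound.compound_id}: non-finite consensus log P")
        return True, "secreted_target"
    flag = lipophilicity_flag(compound.consensus_logp)
    if flag in ("too_lipophilic", "too_hydrophilic"):
        return False, flag
    if str(compound.gi_absorption).lower() != "high":
        return False, "low_gi_absorption"
    return True, "permeation_ok"


def prioritize_candidates(
    classified: pd.DataFrame,
    screened: pd.DataFrame,
    ubiquity_flags: dict[str, str],
    targets: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the two candidate tables from classified interactions.

    Rows are probable binders of screened compounds, annotated with class,
    log P, ubiquity flag, GI class, bioavailability tier and the
    location-compatibility verdict; sorted by target then ascending mean
    affinity (strongest first). The first table keeps (by default) only
    high-GI compounds; the second additionally drops ubiquitous ones.
    """
    binders = classified[classified["classification"] == "probable_binder"]
    comp = screened.set_index("compound_id")
    targ = targets.set_index("target_id") if not targets.empty else pd.DataFrame()
    rows = []
    for _, row in binders.iterrows():
        cid, tid = row["compound_id"], row["target_id"]
        if cid not in comp.index:
            continue  # excluded upstream by the descriptor screen
        c = comp.loc[cid]
        rec = PhytochemicalRecord.from_mapping({"compound_id": cid, **c.to_dict()})
        loc = (
            str(targ.loc[tid, "subcellular_location"])
            if not targ.empty and tid in targ.index
            else "secreted"
        )
        compatible, reason = location_compatible(rec, loc, config.location_rules)
        rows.append(
            {
                "compound_id": cid,
                "name": c.get("name", ""),
                "phytochemical_class": c.get("phytochemical_class", ""),
                "consensus_logp": float(c["consensus_logp"]),
                "target_id": tid,
                "subcellular_location": loc,
                "mean_affinity_kcal_mol": float(row["mean_score"]),
                "ubiquity": ubiquity_flags.get(cid, "unknown"),
                "gi_absorption": c.get("gi_absorption", ""),
                "bioavailability_score": float(c["bioavailability_score"]),
                "bioavailability_tier": bioavailability_tier(
                    float(c["bioavailability_score"])
                ),
                "location_compatible": bool(compatible),
                "location_reason": reason,
            }
        )
    table3 = pd.DataFrame(
        rows,
        columns=[
            "compound_id", "name", "phytochemical_class", "consensus_logp",
            "target_id", "subcellular_location", "mean_affinity_kcal_mol",
            "ubiquity", "gi_absorption", "bioavailability_score",
            "bioavailability_tier", "location_compatible", "location_reason",
        ],
    )
    if config.require_high_gi and not table3.empty:
        table3 = table3[table3["gi_absorption"].str.lower() == "high"]
    table3 = table3.sort_values(
        ["target_id", "mean_affinity_kcal_mol", "compound_id"]
    ).reset_index(drop=True)
    if config.require_non_ubiquity and not table3.empty:
        table4 = table3[table3["ubiquity"] != "ubiquitous"].reset_index(drop=True)
    else:
        table4 = table3.copy()
    return table3, table4


def _load_or_generate(config: PipelineConfig):
    inp = config.inputs
    if inp:
        compounds = read_table(inp["compounds"])
        targets = read_table(inp["targets"]) if "targets" in inp else pd.DataFrame(
            columns=["target_id", "subcellular_location"]
        )
        scores = read_scores(inp["scores"])
        score_sets = [
            LabeledScoreSet.from_table(scores, tid)
            for tid in scores["target_id"].unique()
        ]
        interactions = read_interactions(inp["interactions"])
        ppi = read_table(inp["ppi"]) if "ppi" in inp else pd.DataFrame(
            columns=["target_a", "target_b"]
        )
        if "occurrences" in inp:
            occ = read_table(inp["occurrences"])
            compounds = compounds.drop(columns=["occurrence_count"], errors="ignore")
            compounds = compounds.merge(occ, on="compound_id", how="left")
    else:
        compounds = generate_phytochemicals(config.cohort_sim)
        targets = generate_targets(config.cohort_sim)
        score_sets = generate_score_sets(config.cohort_sim, config.score_sim)
        interactions = generate_interactions(
            compounds, targets, config.cohort_sim, config.score_sim
        )
        ppi = generate_ppi(targets, config.cohort_sim)
    return compounds, targets, score_sets, interactions, ppi


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage; optionally write the artifact bundle to ``out_dir``."""
    counts: dict[str, int] = {}

    stage = "inputs"
    try:
        compounds, targets, score_sets, interactions, ppi = _load_or_generate(config)
        counts["compounds_in"] = len(compounds)
        counts["targets"] = len(targets)
        counts["interactions_in"] = len(interactions)
        counts["ppi_edges"] = len(ppi)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "screen"
    try:
        retained, exclusion_log = screen_phytochemicals(compounds)
        counts["compounds_retained"] = len(retained)
        counts["compounds_excluded"] = len(exclusion_log)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "thresholds"
    try:
        thresholds = {
            s.target_id: roc_curve(s, criterion=config.threshold_criterion)
            for s in score_sets
        }
        diag_rows = []
        for s in score_sets:
            d = screen_diagnostics(s, ef_fractions=config.ef_fractions)
            row = {
                "target_id": d.target_id,
                "auc": thresholds[d.target_id].auc,
                "youden_j": thresholds[d.target_id].youden_j,
                "optimal_threshold": thresholds[d.target_id].optimal_threshold,
                "mannwhitney_u": d.mannwhitney_u,
                "mannwhitney_p": d.mannwhitney_p,
                "cohens_d": d.cohens_d,
            }
            for f, ef in d.ef_at_fraction.items():
                row[f"ef_at_{int(round(f * 100))}pct"] = ef
            diag_rows.append(row)
        diagnostics = pd.DataFrame(diag_rows)
        counts["targets_with_threshold"] = len(thresholds)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "classify"
    try:
        retained_ids = set(retained["compound_id"])
        eligible = interactions[interactions["compound_id"].isin(retained_ids)]
        classified = classify_interactions(eligible, thresholds)
        counts["interactions_classified"] = len(classified)
        counts["probable_binders"] = int(
            (classified["classification"] == "probable_binder").sum()
        )
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "ubiquity"
    try:
        if "occurrence_count" not in compounds.columns:
            if config.require_non_ubiquity:
                raise MissingReferenceError("no occurrence counts supplied")
            ubiq_flags = {cid: "unknown" for cid in compounds["compound_id"]}
        else:
            table = UbiquityTable.from_frame(
                compounds[["compound_id", "occurrence_count"]],
                reference_compound_id=config.reference_compound,
            )
            ubiq_flags = flag_ubiquitous(table)
        counts["ubiquitous"] = sum(1 for v in ubiq_flags.values() if v == "ubiquitous")
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "network"
    try:
        net = build_network(
            classified,
            ppi,
            compound_attributes=retained[
                [c for c in ("compound_id", "phytochemical_class", "gi_absorption",
                             "bioavailability_score", "consensus_logp")
                 if c in retained.columns]
            ],
            target_attributes=targets,
        )
        for cid, flag in ubiq_flags.items():
            if cid in net:
                net.nodes[cid]["ubiquity"] = flag
        cent = centralities(net)
        counts["network_nodes"] = net.number_of_nodes()
        counts["network_edges"] = net.number_of_edges()
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "report"
    try:
        table3, table4 = prioritize_candidates(
            classified, retained, ubiq_flags, targets, config
        )
        counts["candidates_high_gi"] = len(table3)
        counts["candidates_non_ubiquitous"] = len(table4)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    result = PipelineResult(
        compounds=compounds,
        retained=retained,
        exclusion_log=exclusion_log,
        targets=targets,
        score_sets=score_sets,
        thresholds=thresholds,
        diagnostics=diagnostics,
        classified=classified,
        ubiquity_flags=ubiq_flags,
        network=net,
        centrality=cent,
        table3=table3,
        table4=table4,
        stage_counts=counts,
    )
    if out_dir is not None:
        write_artifacts(result, config, Path(out_dir))
    return result


def write_artifacts(result: PipelineResult, config: PipelineConfig, out_dir: Path) -> None:
    """Write the full plain-text artifact bundle (no timestamps anywhere, so
    bundles are byte-identical across reruns of the same config+seed)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    write_table(result.compounds, out_dir / "compounds.tsv")
    write_table(result.retained, out_dir / "compounds_retained.tsv")
    write_table(result.exclusion_log, out_dir / "exclusion_log.tsv")
    write_table(result.targets, out_dir / "targets.tsv")

    score_frames = [s.trial_scores for s in result.score_sets if s.trial_scores is not None]
    if score_frames:
        write_table(pd.concat(score_frames, ignore_index=True), out_dir / "scores.tsv")
    write_table(result.diagnostics, out_dir / "threshold_diagnostics.tsv")
    thr_json = {
        tid: {
            "auc": t.auc,
            "youden_j": t.youden_j,
            "optimal_threshold": t.optimal_threshold,
            "criterion": t.criterion,
            "direction": t.direction,
        }
        for tid, t in result.thresholds.items()
    }
    (out_dir / "thresholds.json").write_text(
        json.dumps(thr_json, indent=2, sort_keys=True) + "\n"
    )

    write_table(result.classified, out_dir / "interactions_classified.tsv")
    ubiq = pd.DataFrame(
        sorted(result.ubiquity_flags.items()), columns=["compound_id", "ubiquity"]
    )
    write_table(ubiq, out_dir / "ubiquity_flags.tsv")

    write_sif(result.network, out_dir / "network.sif")
    write_graphml(result.network, out_dir / "network.graphml")
    write_table(result.centrality, out_dir / "centrality.tsv")

    write_table(result.table3, out_dir / "candidates_high_gi.tsv")
    write_table(result.table4, out_dir / "candidates_non_ubiquitous.tsv")

    long, summary = export_distribution_summary(result.score_sets, result.thresholds)
    write_table(long, out_dir / "score_distributions_long.tsv")
    write_table(summary, out_dir / "score_distributions_summary.tsv")

    log_lines = [
        f"netpharm {__version__}",
        f"numpy {np.__version__}; pandas {pd.__version__}; "
        f"scipy {scipy.__version__}; networkx {nx.__version__}",
        f"seed {config.seed}",
        f"threshold_criterion {config.threshold_criterion}",
        "stage counts:",
    ]
    log_lines += [f"  {k} = {v}" for k, v in result.stage_counts.items()]
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
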