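"""Synthetic generators for every pipeline input.

No docking runs, ADME predictor exports, target-prediction tables or PPI
downloads ship with this package, so each input is emulated with the
statistical structure the analysis assumes:

* per-target docking scores for labeled binders and decoys, as two
  populations with a controlled standardized separation (Cohen's d) and
  per-trial replicate noise;
* a phytochemical descriptor table shaped like an ADME predictor export,
  with configurable fractions engineered to fail every drug-likeness rule,
  to carry ≥2 PAINS alerts, or to have missing descriptors;
* a compound–target interaction table with latent binder/nonbinder labels
  retained for recovery tests;
* an Erdős–Rényi protein–protein interaction edge list;
* geometric (heavy-right-tail) species occurrence counts with a named
  reference compound inserted at a fixed count.

Determinism: one global seed is fanned out to stable per-table child seeds
(CRC32 of a table tag), so any single table can be regenerated
independently and the same seed reproduces every table bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import LabeledScoreSet
from .ubiquity import DEFAULT_REFERENCE

SUBCELLULAR_LOCATIONS = (
    "secreted",
    "cell_membrane",
    "cytoplasm",
    "nucleus",
    "endoplasmic_reticulum",
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreSimConfig:
    """Two-population docking-score model for one target.

    Scores are binding affinities in kcal/mol (lower = stronger). Each
    docked ligand gets a latent population value drawn from its class
    distribution plus independent per-trial replicate noise; the recorded
    score is the mean over ``n_trials`` replicates. Defaults give a
    standardized separation d = (mu_binder − mu_decoy)/sigma = −2.0,
    inside the −0.842…−3.652 band a well-behaved decoy-controlled screen
    produces, with 25 ligands per class (the design floor is 20).
    """

    n_binders: int = 25
    n_decoys: int = 25
    mu_binder: float = -8.5
    mu_decoy: float = -6.5
    sigma: float = 1.0
    trial_noise_sd: float = 0.25
    n_trials: int = 2
    seed: int = 0
    family: str = "gaussian"  # or "shifted_lognormal" for skewed populations

    def validate(self) -> None:
        if self.n_binders < 2 or self.n_decoys < 2:
            raise ConfigurationError("need at least 2 ligands per class")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.trial_noise_sd < 0:
            raise ConfigurationError("trial_noise_sd must be >= 0")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.family not in ("gaussian", "shifted_lognormal"):
            raise ConfigurationError(f"unknown score family {self.family!r}")


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort-level shape of the synthetic study.

    Defaults emulate the scale of a single-plant network-pharmacology
    screen: 150 phytochemicals (including the reference compound) against
    9 targets, with roughly 30% of sampled compound–target pairs drawn from
    the binder score population and enough pair sampling to yield ≈170
    interactions. Occurrence counts are geometric on {1, 2, …} with success
    probability ``ubiquity_tail_param`` (0.2 → mean 5 species, heavy right
    tail); the reference compound is inserted exactly once at
    ``reference_count`` occurrences.
    """

    n_compounds: int = 150
    n_targets: int = 9
    binder_fraction: float = 0.3
    interaction_prob: float = 0.13
    ppi_edge_prob: float = 0.5
    ubiquity_tail_param: float = 0.2
    reference_count: int = 6
    reference_compound_id: str = DEFAULT_REFERENCE
    fraction_fail_all: float = 0.25
    fraction_pains: float = 0.05
    fraction_missing: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 1:
            raise ConfigurationError("n_compounds must be >= 1")
        if self.n_targets < 1:
            raise ConfigurationError("n_targets must be >= 1")
        for name in (
            "binder_fraction",
            "interaction_prob",
            "ppi_edge_prob",
            "ubiquity_tail_param",
            "fraction_fail_all",
            "fraction_pains",
            "fraction_missing",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_fail_all + self.fraction_pains + self.fraction_missing > 1:
            raise ConfigurationError("engineered fractions must sum to <= 1")
        if self.reference_count < 1:
            raise ConfigurationError("reference_count must be >= 1")


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Stable per-table child generator: one global seed, CRC32 of a tag."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(tag.encode())])


def _draw_population(rng, mu, sigma, n, family):
    if family == "gaussian":
        return rng.normal(mu, sigma, size=n)
    # shifted lognormal with matched mean/SD, right-skewed; fixed shape 0.75
    s = 0.75
    raw = rng.lognormal(mean=0.0, sigma=s, size=n)
    mean = np.exp(s**2 / 2)
    sd = np.sqrt((np.exp(s**2) - 1) * np.exp(s**2))
    return mu + sigma * (raw - mean) / sd


def generate_labeled_scores(cfg: ScoreSimConfig, target_id: str) -> LabeledScoreSet:
    """Simulate a binder/decoy docking-score set for one target.

    Each of the n_binders + n_decoys ligands gets ``n_trials`` trial scores
    (population value + independent replicate noise); the stored mean score
    is exactly the arithmetic mean of its trials.
    """
    cfg.validate()
    rng = child_rng(cfg.seed, f"scores:{target_id}")
    rows = []
    for label, n, mu in (
        ("binder", cfg.n_binders, cfg.mu_binder),
        ("decoy", cfg.n_decoys, cfg.mu_decoy),
    ):
        pop = _draw_population(rng, mu, cfg.sigma, n, cfg.family)
        noise = rng.normal(0.0, cfg.trial_noise_sd, size=(n, cfg.n_trials)) if cfg.trial_noise_sd > 0 else np.zeros((n, cfg.n_trials))
        trials = pop[:, None] + noise
        for i in range(n):
            rows.append(
                {
                    "target_id": target_id,
                    "ligand_id": f"{target_id}_{label}_{i:03d}",
                    "label": label,
                    **{f"trial_{t + 1}": trials[i, t] for t in range(cfg.n_trials)},
                }
            )
    frame = pd.DataFrame(rows)
    return LabeledScoreSet.from_table(frame, target_id)


def generate_targets(cfg: CohortSimConfig) -> pd.DataFrame:
    """Target table: gene-like symbol, UniProt-like accession, subcellular
    location, and a 2-cluster label."""
    cfg.validate()
    rng = child_rng(cfg.seed, "targets")
    rows = []
    for i in range(cfg.n_targets):
        rows.append(
            {
                "target_id": f"TGT{i + 1:02d}",
                "uniprot_id": f"P{rng.integers(10000, 99999)}",
                "subcellular_location": SUBCELLULAR_LOCATIONS[
                    int(rng.integers(0, len(SUBCELLULAR_LOCATIONS)))
                ],
                "cluster": f"cluster_{1 + i % 2}",
            }
        )
    return pd.DataFrame(rows)


_PHYTO_CLASSES = (
    "flavonoid", "phenolic_acid", "thiocarbamate", "sterol", "triterpene",
    "sesquiterpene", "fatty_acid_derivative", "peptide_derivative", "steroid",
    "glucosinolate",
)
_BA_SCORES = np.array([0.55, 0.56, 0.85, 0.17, 0.11])
_BA_WEIGHTS = np.array([0.55, 0.2, 0.1, 0.1, 0.05])


def generate_phytochemicals(cfg: CohortSimConfig) -> pd.DataFrame:
    """Descriptor table shaped like an ADME predictor export.

    Disjoint engineered subsets (sized by the config fractions) fail all
    five drug-likeness rule sets, carry ≥2 PAINS alerts, or have missing
    descriptors; the rest are drawn from drug-like descriptor ranges.
    Occurrence counts are geometric; the reference compound is inserted
    exactly once (replacing one generated row) with ``reference_count``.
    """
    cfg.validate()
    rng = child_rng(cfg.seed, "phytochemicals")
    n = cfg.n_compounds
    rows = []
    for i in range(n):
        mw = float(rng.uniform(160, 620))
        logp = float(rng.normal(2.0, 1.5))
        wlogp = logp + float(rng.normal(0, 0.4))
        xlogp = logp + float(rng.normal(0, 0.4))
        tpsa = float(rng.uniform(20, 180))
        heavy = int(max(8, round(mw / 13.5 + rng.normal(0, 2))))
        carbon = int(max(5, round(heavy * 0.75)))
        rows.append(
            {
                "compound_id": f"CPD{i + 1:03d}",
                "name": f"phytochemical {i + 1}",
                "phytochemical_class": _PHYTO_CLASSES[int(rng.integers(0, len(_PHYTO_CLASSES)))],
                "mw": mw,
                "consensus_logp": logp,
                "wlogp": wlogp,
                "xlogp": xlogp,
                "tpsa": tpsa,
                "hbd": int(rng.poisson(2)),
                "hba": int(rng.poisson(5)),
                "rotatable_bonds": int(rng.poisson(4)),
                "molar_refractivity": float(rng.uniform(40, 140)),
                "heavy_atoms": heavy,
                "carbon_atoms": carbon,
                "heteroatoms": heavy - carbon,
                "rings": int(min(8, rng.poisson(3))),
                "pains_alerts": 0,
                # crude permeation-style rule for the absorption class
                "gi_absorption": "high" if (tpsa <= 131.6 and wlogp <= 5.88) else "low",
                "bioavailability_score": float(rng.choice(_BA_SCORES, p=_BA_WEIGHTS)),
                "occurrence_count": int(rng.geometric(cfg.ubiquity_tail_param)),
                "missing_descriptors": False,
            }
        )
    table = pd.DataFrame(rows)

    # a non-engineered compound must pass at least one rule set; the rare
    # random draw that fails all five is nudged into the Egan window
    from .adme import PhytochemicalRecord, evaluate_druglikeness

    for i in range(n):
        rec = PhytochemicalRecord.from_mapping(table.loc[i])
        if not any(v.passed for v in evaluate_druglikeness(rec)):
            table.loc[i, "wlogp"] = min(table.loc[i, "wlogp"], 5.88)
            table.loc[i, "tpsa"] = min(table.loc[i, "tpsa"], 131.6)

    order = rng.permutation(n)
    n_fail = round(cfg.fraction_fail_all * n)
    n_pains = round(cfg.fraction_pains * n)
    n_missing = round(cfg.fraction_missing * n)
    fail_idx = order[:n_fail]
    pains_idx = order[n_fail : n_fail + n_pains]
    missing_idx = order[n_fail + n_pains : n_fail + n_pains + n_missing]

    # violates every sub-criterion family of all five rule sets at once
    table.loc[fail_idx, ["mw", "consensus_logp", "wlogp", "xlogp", "tpsa"]] = [
        750.0, 8.0, 8.0, 8.0, 250.0,
    ]
    table.loc[fail_idx, ["hbd", "hba", "rotatable_bonds", "rings"]] = [8, 14, 18, 9]
    table.loc[fail_idx, ["molar_refractivity", "heavy_atoms"]] = [150.0, 80]
    table.loc[fail_idx, "gi_absorption"] = "low"

    table.loc[pains_idx, "pains_alerts"] = 2 + (
        np.asarray(rng.integers(0, 2, size=len(pains_idx))) if len(pains_idx) else 0
    )
    table.loc[missing_idx, "missing_descriptors"] = True
    table.loc[missing_idx, ["mw", "consensus_logp", "wlogp", "xlogp", "tpsa", "molar_refractivity"]] = np.nan

    # the reference compound replaces the last generated row, exactly once
    ref_i = n - 1
    table.loc[ref_i, :] = _reference_row(cfg)
    table = table.astype({"hbd": int, "hba": int, "rotatable_bonds": int,
                          "heavy_atoms": int, "carbon_atoms": int,
                          "heteroatoms": int, "rings": int, "pains_alerts": int})
    return table


def _reference_row(cfg: CohortSimConfig) -> dict:
    # quinic-acid-like descriptor vector: small, polar, rule-passing
    return {
        "compound_id": cfg.reference_compound_id,
        "name": cfg.reference_compound_id,
        "phytochemical_class": "phenolic_acid",
        "mw": 192.17,
        "consensus_logp": -1.7,
        "wlogp": -2.3,
        "xlogp": -1.9,
        "tpsa": 118.2,
        "hbd": 5,
        "hba": 6,
        "rotatable_bonds": 1,
        "molar_refractivity": 41.4,
        "heavy_atoms": 13,
        "carbon_atoms": 7,
        "heteroatoms": 6,
        "rings": 1,
        "pains_alerts": 0,
        "gi_absorption": "high",
        "bioavailability_score": 0.56,
        "occurrence_count": int(cfg.reference_count),
        "missing_descriptors": False,
    }


def generate_interactions(
    compounds: pd.DataFrame,
    targets: pd.DataFrame,
    cfg: CohortSimConfig,
    score_cfg: ScoreSimConfig,
) -> pd.DataFrame:
    """Sample a compound–target interaction table with latent labels.

    Each (compound, target) pair enters with probability
    ``cfg.interaction_prob``; a sampled pair is latently a binder with
    probability ``cfg.binder_fraction`` and its trial scores are drawn from
    the corresponding score population. The latent label is retained so
    recovery against the decoy-derived thresholds can be measured.
    """
    cfg.validate()
    score_cfg.validate()
    if compounds.empty or targets.empty:
        raise ConfigurationError("compound and target tables must be non-empty")
    rng = child_rng(cfg.seed, "interactions")
    rows = []
    for cid in compounds["compound_id"]:
        for tid in targets["target_id"]:
            if rng.random() >= cfg.interaction_prob:
                continue
            is_binder = rng.random() < cfg.binder_fraction
            mu = score_cfg.mu_binder if is_binder else score_cfg.mu_decoy
            pop = float(_draw_population(rng, mu, score_cfg.sigma, 1, score_cfg.family)[0])
            trials = pop + (
                rng.normal(0.0, score_cfg.trial_noise_sd, size=score_cfg.n_trials)
                if score_cfg.trial_noise_sd > 0
                else np.zeros(score_cfg.n_trials)
            )
            rows.append(
                {
                    "compound_id": cid,
                    "target_id": tid,
                    **{f"trial_{t + 1}": trials[t] for t in range(score_cfg.n_trials)},
                    "mean_score": float(np.mean(trials)),
                    "latent_label": "binder" if is_binder else "nonbinder",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["compound_id", "target_id"]
        + [f"trial_{t + 1}" for t in range(score_cfg.n_trials)]
        + ["mean_score", "latent_label"],
    )


def generate_ppi(targets: pd.DataFrame, cfg: CohortSimConfig) -> pd.DataFrame:
    """Erdős–Rényi PPI edge list over the targets: undirected, no self-loops,
    no duplicate edges."""
    cfg.validate()
    if targets.empty:
        raise ConfigurationError("target table must be non-empty")
    rng = child_rng(cfg.seed, "ppi")
    ids = list(targets["target_id"])
    rows = [
        {"target_a": ids[i], "target_b": ids[j]}
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if rng.random() < cfg.ppi_edge_prob
    ]
    return pd.DataFrame(rows, columns=["target_a", "target_b"])


def generate_score_sets(
    cfg: CohortSimConfig, score_cfg: ScoreSimConfig
) -> list[LabeledScoreSet]:
    """One labeled binder/decoy score set per target, with per-target child
    seeds derived from the cohort seed."""
    cfg.validate()
    sets = []
    for i in range(cfg.n_targets):
        tid = f"TGT{i + 1:02d}"
        per_target = ScoreSimConfig(
            **{**score_cfg.__dict__, "seed": cfg.seed}
        )
        sets.append(generate_labeled_scores(per_target, tid))
    return sets
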