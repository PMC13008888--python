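"""Rule-based drug-likeness and PAINS screening of phytochemical tables.

A compound enters the downstream pipeline when it (a) has a complete
descriptor vector, (b) passes at least one of the five drug-likeness rule
sets (Lipinski, Ghose, Veber, Egan, Muegge), and (c) carries at most one
PAINS alert. Descriptors are precomputed inputs (the tables an ADME
predictor emits); this module never computes descriptors from structures,
and PAINS matching itself is out of scope — only the alert counts are used.

Rule constants live in ``data/druglikeness_rules.yaml`` so they can be
re-pinned without touching code.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable

import pandas as pd
import yaml

RULE_NAMES = ("lipinski", "ghose", "veber", "egan", "muegge")

with importlib.resources.files("netpharm.data").joinpath(
    "druglikeness_rules.yaml"
).open() as _fh:
    RULE_CONSTANTS: dict = yaml.safe_load(_fh)


class DescriptorError(ValueError):
    """Raised when a rule is evaluated on a record with missing descriptors."""


@dataclass
class PhytochemicalRecord:
    """One compound's descriptor vector plus screening-relevant annotations.

    Descriptor semantics follow the usual ADME predictor outputs:
    ``consensus_logp`` is the arithmetic mean of several computed log P
    estimates, ``tpsa`` is the topological polar surface area in Å²,
    ``gi_absorption`` is the predicted passive gastrointestinal absorption
    class, and ``bioavailability_score`` is the probability-like oral
    bioavailability score in (0, 1]. ``occurrence_count`` (species count) is
    filled in by the ubiquity stage and may be absent (None).
    """

    compound_id: str
    name: str = ""
    phytochemical_class: str = ""
    mw: float = float("nan")
    consensus_logp: float = float("nan")
    wlogp: float = float("nan")
    xlogp: float = float("nan")
    tpsa: float = float("nan")
    hbd: int = 0
    hba: int = 0
    rotatable_bonds: int = 0
    molar_refractivity: float = float("nan")
    heavy_atoms: int = 0
    carbon_atoms: int = 0
    heteroatoms: int = 0
    rings: int = 0
    pains_alerts: int = 0
    gi_absorption: str = "high"
    bioavailability_score: float = 0.55
    occurrence_count: int | None = None
    missing_descriptors: bool = False

    @classmethod
    def from_mapping(cls, row) -> "PhytochemicalRecord":
        known = {f.name for f in dc_fields(cls)}
        return cls(**{k: v for k, v in dict(row).items() if k in known})


@dataclass
class RuleVerdict:
    rule_name: str
    passed: bool
    violations: list[str] = field(default_factory=list)


def _check(value, lo=None, hi=None, lo_exclusive=False) -> bool:
    if lo is not None:
        if lo_exclusive and not value > lo:
            return False
        if not lo_exclusive and not value >= lo:
            return False
    if hi is not None and not value <= hi:
        return False
    return True


def evaluate_druglikeness(record: PhytochemicalRecord) -> list[RuleVerdict]:
    """Evaluate all five rule sets on one record.

    Returns exactly five verdicts (Lipinski, Ghose, Veber, Egan, Muegge in
    that order). Lipinski tolerates one violated sub-criterion; the others
    require all of theirs. Raises :class:`DescriptorError` for records
    flagged ``missing_descriptors`` — callers must exclude those instead.
    """
    if record.missing_descriptors:
        raise DescriptorError(
            f"{record.compound_id}: descriptors missing; record must be excluded"
        )
    c = RULE_CONSTANTS
    verdicts = []

    lip = c["lipinski"]["criteria"]
    lip_viol = []
    if not _check(record.mw, hi=lip["mw_max"]):
        lip_viol.append(f"mw>{lip['mw_max']}")
    if not _check(record.consensus_logp, hi=lip["logp_max"]):
        lip_viol.append(f"logp>{lip['logp_max']}")
    if not _check(record.hbd, hi=lip["hbd_max"]):
        lip_viol.append(f"hbd>{lip['hbd_max']}")
    if not _check(record.hba, hi=lip["hba_max"]):
        lip_viol.append(f"hba>{lip['hba_max']}")
    verdicts.append(
        RuleVerdict("lipinski", len(lip_viol) <= c["lipinski"]["max_violations"], lip_viol)
    )

    gh = c["ghose"]["criteria"]
    gh_viol = []
    if not _check(record.mw, lo=gh["mw_min"], hi=gh["mw_max"]):
        gh_viol.append("mw")
    if not _check(record.wlogp, lo=gh["wlogp_min"], hi=gh["wlogp_max"]):
        gh_viol.append("wlogp")
    if not _check(record.molar_refractivity, lo=gh["mr_min"], hi=gh["mr_max"]):
        gh_viol.append("molar_refractivity")
    if not _check(record.heavy_atoms, lo=gh["atoms_min"], hi=gh["atoms_max"]):
        gh_viol.append("atoms")
    verdicts.append(RuleVerdict("ghose", not gh_viol, gh_viol))

    vb = c["veber"]["criteria"]
    vb_viol = []
    if not _check(record.rotatable_bonds, hi=vb["rotb_max"]):
        vb_viol.append("rotatable_bonds")
    if not _check(record.tpsa, hi=vb["tpsa_max"]):
        vb_viol.append("tpsa")
    verdicts.append(RuleVerdict("veber", not vb_viol, vb_viol))

    eg = c["egan"]["criteria"]
    eg_viol = []
    if not _check(record.wlogp, hi=eg["wlogp_max"]):
        eg_viol.append("wlogp")
    if not _check(record.tpsa, hi=eg["tpsa_max"]):
        eg_viol.append("tpsa")
    verdicts.append(RuleVerdict("egan", not eg_viol, eg_viol))

    mg = c["muegge"]["criteria"]
    mg_viol = []
    if not _check(record.mw, lo=mg["mw_min"], hi=mg["mw_max"]):
        mg_viol.append("mw")
    if not _check(record.xlogp, lo=mg["xlogp_min"], hi=mg["xlogp_max"]):
        mg_viol.append("xlogp")
    if not _check(record.tpsa, hi=mg["tpsa_max"]):
        mg_viol.append("tpsa")
    if not _check(record.rings, hi=mg["rings_max"]):
        mg_viol.append("rings")
    if not _check(record.carbon_atoms, lo=mg["carbon_min_exclusive"], lo_exclusive=True):
        mg_viol.append("carbon_atoms")
    if not _check(record.heteroatoms, lo=mg["heteroatom_min_exclusive"], lo_exclusive=True):
        mg_viol.append("heteroatoms")
    if not _check(record.rotatable_bonds, hi=mg["rotb_max"]):
        mg_viol.append("rotatable_bonds")
    if not _check(record.hba, hi=mg["hba_max"]):
        mg_viol.append("hba")
    if not _check(record.hbd, hi=mg["hbd_max"]):
        mg_viol.append("hbd")
    verdicts.append(RuleVerdict("muegge", not mg_viol, mg_viol))

    return verdicts


def passes_any_rule(record: PhytochemicalRecord) -> bool:
    return any(v.passed for v in evaluate_druglikeness(record))


def screen_phytochemicals(
    table: pd.DataFrame, max_pains: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion logic to a compound table.

    Retained ⇔ descriptors complete AND at least one rule set passed AND at
    most ``max_pains`` PAINS alerts. Returns ``(retained, exclusion_log)``;
    the log has one row per excluded compound with the first failing
    condition (checked in order missing → druglikeness → pains) and a
    human-readable detail.
    """
    if table.empty:
        raise ValueError("compound table is empty")
    keep_mask = []
    log_rows = []
    for _, row in table.iterrows():
        rec = PhytochemicalRecord.from_mapping(row)
        if rec.missing_descriptors or _has_null_descriptor(rec):
            keep_mask.append(False)
            log_rows.append((rec.compound_id, "missing", "null descriptor values"))
            continue
        verdicts = evaluate_druglikeness(rec)
        if not any(v.passed for v in verdicts):
            failed = "; ".join(f"{v.rule_name}:{','.join(v.violations)}" for v in verdicts)
            keep_mask.append(False)
            log_rows.append((rec.compound_id, "druglikeness", failed))
            continue
        if rec.pains_alerts > max_pains:
            keep_mask.append(False)
            log_rows.append(
                (rec.compound_id, "pains", f"{rec.pains_alerts} alerts > {max_pains}")
            )
            continue
        keep_mask.append(True)
    retained = table.loc[keep_mask].reset_index(drop=True)
    exclusion_log = pd.DataFrame(log_rows, columns=["compound_id", "reason", "detail"])
    return retained, exclusion_log


_NUMERIC_DESCRIPTORS = (
    "mw", "consensus_logp", "wlogp", "xlogp", "tpsa", "molar_refractivity",
)


def _has_null_descriptor(rec: PhytochemicalRecord) -> bool:
    return any(
        getattr(rec, name) is None or math.isnan(float(getattr(rec, name)))
        for name in _NUMERIC_DESCRIPTORS
    )


def lipophilicity_flag(consensus_logp: float) -> str:
    """Bin consensus log P for membrane-permeation assessment.

    The optimal window for crossing biological membranes is taken as
    [−1.0, 2.0]; values above 5 are flagged too lipophilic (likely retained
    in the bilayer), values below −1 too hydrophilic to partition into it.
    """
    if consensus_logp is None or not math.isfinite(consensus_logp):
        raise ValueError(f"consensus log P must be finite, got {consensus_logp}")
    if consensus_logp < -1.0:
        return "too_hydrophilic"
    if consensus_logp <= 2.0:
        return "optimal"
    if consensus_logp <= 5.0:
        return "moderate"
    return "too_lipophilic"


def bioavailability_tier(score: float) -> str:
    """Display binning of the oral bioavailability score: high (>0.55),
    moderate [0.17–0.55], low (<0.17)."""
    if not math.isfinite(score):
        raise ValueError("bioavailability score must be finite")
    if score > 0.55:
        return "high"
    if score >= 0.17:
        return "moderate"
    return "low"


def records_from_table(table: pd.DataFrame) -> Iterable[PhytochemicalRecord]:
    for _, row in table.iterrows():
        yield PhytochemicalRecord.from_mapping(row)
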