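"""TSV readers/writers for the pipeline's tabular interfaces.

Column schemas (all tab-separated, header row, UTF-8):

* scores:       target_id, ligand_id, label ∈ {binder, decoy}, trial_1..trial_k
* interactions: compound_id, target_id, trial_1..trial_k, mean_score
                [, latent_label, predicted_probability]
* compounds:    compound_id, name, phytochemical_class, mw, consensus_logp,
                wlogp, xlogp, tpsa, hbd, hba, rotatable_bonds,
                molar_refractivity, heavy_atoms, carbon_atoms, heteroatoms,
                rings, pains_alerts, gi_absorption, bioavailability_score,
                occurrence_count, missing_descriptors
* targets:      target_id, uniprot_id, subcellular_location, cluster
* ppi:          target_a, target_b
* occurrences:  compound_id, occurrence_count
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    frame = read_table(path)
    required = {"target_id", "ligand_id", "label"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    if not frame["label"].isin(["binder", "decoy"]).all():
        raise ValueError("score table labels must be 'binder' or 'decoy'")
    if not any(c.startswith("trial_") for c in frame.columns):
        raise ValueError("score table needs at least one trial_* column")
    return frame


def read_interactions(path: str | Path) -> pd.DataFrame:
    frame = read_table(path)
    required = {"compound_id", "target_id"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    trial_cols = [c for c in frame.columns if c.startswith("trial_")]
    if "mean_score" not in frame.columns:
        if not trial_cols:
            raise ValueError("interaction table needs mean_score or trial_* columns")
        frame["mean_score"] = frame[trial_cols].mean(axis=1)
    return frame
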