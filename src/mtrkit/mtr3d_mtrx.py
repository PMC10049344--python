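"""Spatial missense tolerance (MTR3D) and the MTRX consensus combiner.

MTR3D applies the observed/expected missense ratio not to a sequence
window but to the set of codons whose residues fall within a distance
radius of the focal residue in the protein's tertiary structure.  Codons
without a structural mapping get no score; unmapped spatial neighbours
contribute to neither the observed nor the expected sums, keeping the
ratio internally consistent.

MTRX is a random-forest consensus over four per-position features — MTR
v1 (41-codon window), MTR v2 (21-codon window), MTR3D and relative
solvent accessibility — emitting a probability-like score in [0, 1]
where values approaching 1 indicate likely-deleterious positions.  No
published model weights are shipped: the combiner is trained on labels
the caller supplies (synthetic planted truth in the bundled generators,
or curated labels on real data), and the training provenance (seed,
feature list, out-of-bag estimate) is carried on the model object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split

from .mtr_sequence import IntoleranceTrack
from .structure_tools import SeqStructMap, StructureModel, all_neighborhoods
from .variant_model import GeneModel, VariantSet
from . import mtr_sequence

MTRX_FEATURES = ["mtr_v1", "mtr_v2", "mtr3d", "rsa"]
DEFAULT_SEED = 20230307
DEFAULT_N_TREES = 500

DELETERIOUS = "deleterious"
BENIGN = "benign"


def compute_mtr3d(
    gene: GeneModel,
    population_variants: VariantSet,
    mapping: SeqStructMap,
    structure: StructureModel,
    radius: float,
) -> IntoleranceTrack:
    """Spatial MTR over structure neighborhoods, one value per codon.

    For each codon with a mapped residue, the scoring window is the set of
    codons mapped to residues within ``radius`` Å (representative-atom
    distance) of that residue.  Unmapped codons are missing; windows with
    no observed variants are missing.
    """
    L = len(gene)
    values = np.full(L, np.nan)
    obs_mis_out = np.zeros(L, dtype=np.int64)
    obs_syn_out = np.zeros(L, dtype=np.int64)
    exp_prop_out = np.full(L, np.nan)

    r2c = mapping.residue_to_codon
    if not r2c:
        import warnings

        warnings.warn(f"{gene.gene_id}: no mapped codons; MTR3D track all-missing")
        return IntoleranceTrack(gene.gene_id, "MTR3D", values)

    n_mis, n_syn = mtr_sequence.possibility_counts(gene)
    obs_mis, obs_syn = mtr_sequence._per_codon_observed(population_variants, gene)
    hoods = all_neighborhoods(structure, radius)

    for residue_number, codon_index in r2c.items():
        members = hoods.get(residue_number)
        if members is None:  # residue lacks a representative atom
            continue
        codon_set = [r2c[m] - 1 for m in members if m in r2c]
        idx = np.array(codon_set, dtype=np.intp)
        w_nmis = int(n_mis[idx].sum())
        w_nsyn = int(n_syn[idx].sum())
        w_omis = int(obs_mis[idx].sum())
        w_osyn = int(obs_syn[idx].sum())
        i = codon_index - 1
        obs_mis_out[i] = w_omis
        obs_syn_out[i] = w_osyn
        exp_prop = w_nmis / (w_nmis + w_nsyn)
        exp_prop_out[i] = exp_prop
        if w_omis + w_osyn > 0:
            values[i] = (w_omis / (w_omis + w_osyn)) / exp_prop
    return IntoleranceTrack(
        gene_id=gene.gene_id,
        score_name="MTR3D",
        values=values,
        obs_missense=obs_mis_out,
        obs_synonymous=obs_syn_out,
        exp_missense_prop=exp_prop_out,
    )


# ---------------------------------------------------------------------------
# MTRX

@dataclass
class MTRXFeatureRow:
    gene_id: str
    codon_index: int
    mtr_v1: float = np.nan
    mtr_v2: float = np.nan
    mtr3d: float = np.nan
    rsa: float = np.nan
    label: str | None = None  # deleterious | benign (training only)


def rows_to_frame(rows: Iterable[MTRXFeatureRow] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "codon_index": r.codon_index,
                "mtr_v1": r.mtr_v1,
                "mtr_v2": r.mtr_v2,
                "mtr3d": r.mtr3d,
                "rsa": r.rsa,
                "label": r.label,
            }
            for r in rows
        ]
    )


@dataclass
class MTRXModel:
    """A trained random-forest consensus with its training provenance."""

    forest: RandomForestClassifier
    features: list[str]
    seed: int
    oob_score: float | None
    holdout_accuracy: float | None
    n_training_rows: int

    def provenance(self) -> dict:
        return {
            "features": self.features,
            "seed": self.seed,
            "n_trees": self.forest.n_estimators,
            "oob_score": self.oob_score,
            "holdout_accuracy": self.holdout_accuracy,
            "n_training_rows": self.n_training_rows,
        }


def train_mtrx(
    rows: Iterable[MTRXFeatureRow] | pd.DataFrame,
    seed: int = DEFAULT_SEED,
    n_trees: int = DEFAULT_N_TREES,
    features: Sequence[str] = MTRX_FEATURES,
    holdout: float = 0.2,
) -> MTRXModel:
    """Train the MTRX random-forest combiner on labelled feature rows.

    Rows with any missing feature or without a label are excluded from
    training.  A stratified holdout (default 20%) provides a self-test
    accuracy; the returned model is refit on all complete labelled rows.
    """
    df = rows_to_frame(rows)
    features = list(features)
    labelled = df.dropna(subset=features).loc[df["label"].notna()]
    if labelled.empty:
        raise ValueError("no complete labelled rows to train on")
    y = (labelled["label"] == DELETERIOUS).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = labelled[features].to_numpy(dtype=float)

    holdout_accuracy = None
    if holdout and 0.0 < holdout < 1.0:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=holdout, stratify=y, random_state=seed
        )
        probe = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        probe.fit(X_tr, y_tr)
        holdout_accuracy = float(accuracy_score(y_te, probe.predict(X_te)))

    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True
    )
    forest.fit(X, y)
    return MTRXModel(
        forest=forest,
        features=features,
        seed=seed,
        oob_score=float(forest.oob_score_),
        holdout_accuracy=holdout_accuracy,
        n_training_rows=len(labelled),
    )


def score_mtrx(
    model: MTRXModel, rows: Iterable[MTRXFeatureRow] | pd.DataFrame
) -> np.ndarray:
    """P(deleterious) per row, in [0, 1]; NaN where any feature is missing."""
    df = rows_to_frame(rows)
    missing_cols = [f for f in model.features if f not in df.columns]
    if missing_cols:
        raise ValueError(f"feature column(s) {missing_cols} absent from rows")
    X = df[model.features].to_numpy(dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    scores = np.full(len(df), np.nan)
    if complete.any():
        deleterious_col = list(model.forest.classes_).index(True)
        scores[complete] = model.forest.predict_proba(X[complete])[:, deleterious_col]
    return scores


def mtrx_track(
    model: MTRXModel, rows: Iterable[MTRXFeatureRow] | pd.DataFrame, gene_length: int
) -> IntoleranceTrack:
    """Arrange per-row MTRX scores as a per-codon track for one gene."""
    df = rows_to_frame(rows)
    scores = score_mtrx(model, df)
    values = np.full(gene_length, np.nan)
    for pos, s in zip(df["codon_index"].to_numpy(), scores):
        if 1 <= pos <= gene_length:
            values[pos - 1] = s
    gene_ids = df["gene_id"].unique()
    return IntoleranceTrack(
        gene_id=str(gene_ids[0]) if len(gene_ids) else "", score_name="MTRX", values=values
    )
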