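"""Spatial MTR3D scoring and the MTRX random-forest consensus."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mtrkit import synthetic_data as sd
from mtrkit.mtr3d_mtrx import (
    BENIGN,
    DELETERIOUS,
    MTRX_FEATURES,
    MTRXFeatureRow,
    compute_mtr3d,
    mtrx_track,
    score_mtrx,
    train_mtrx,
)
from mtrkit.mtr_sequence import compute_mtr
from mtrkit.variant_model import MISSENSE, Variant, VariantSet

EXTENDED_RADIUS_10 = 10 * 3.8 + 0.05  # spatial radius equal to +/-10 codons


def test_extended_chain_collapses_to_sequence_window():
    """On a straight chain, a radius of +/-10 codons makes the spatial
    neighborhood identical to the 21-codon sequence window, so MTR3D must
    equal MTR v2 exactly at every position."""
    gene = sd.generate_gene(150, seed=1, gene_id="G")
    pop = sd.generate_population_variants(gene, density=1.0, seed=2)
    structure, mapping = sd.generate_structure(gene, topology="extended")
    spatial = compute_mtr3d(gene, pop, mapping, structure, EXTENDED_RADIUS_10)
    sequential = compute_mtr(gene, pop, 21)
    assert np.array_equal(spatial.values, sequential.values, equal_nan=True)


def test_folded_structure_sees_spatial_depletion_sequence_window_misses():
    """A hairpin brings codons 80-85 next to 10-15; depletion planted only
    at 80-85 lowers MTR3D at codon 12 below the sequence-window score."""
    gene = sd.generate_gene(100, seed=4, gene_id="G")
    pairs = [(a, 95 - a) for a in range(10, 16)]  # (10,85) .. (15,80)
    structure, mapping = sd.generate_structure(
        gene, topology="folded_contact_pairs", contact_pairs=pairs, contact_distance=5.0
    )
    pop = sd.generate_population_variants(
        gene, density=4.0, depletion_regions=[(70, 95)], depletion_multiplier=0.05,
        seed=5,
    )
    mtr3d = compute_mtr3d(gene, pop, mapping, structure, 12.0)
    mtr_v2 = compute_mtr(gene, pop, 21)
    assert mtr3d.values[11] < mtr_v2.values[11]


def test_radius_zero_is_single_position_ratio():
    gene = sd.generate_gene(50, seed=6, gene_id="G")
    structure, mapping = sd.generate_structure(gene, topology="extended")
    ref = gene.protein_seq[9]
    alt = "A" if ref != "A" else "G"
    pop = VariantSet("p", [Variant("G", 10, ref, alt, consequence=MISSENSE)])
    track = compute_mtr3d(gene, pop, mapping, structure, 0.0)
    # only codon 10 has an observed variant: all-missense observation there
    from mtrkit.variant_model import enumerate_codon_snvs

    counts = enumerate_codon_snvs(gene.codons[9])
    exp = counts["n_missense"] / (counts["n_missense"] + counts["n_synonymous"])
    assert track.values[9] == pytest.approx(1.0 / exp)
    assert np.isnan(track.values[20])


def test_unmapped_codons_are_missing():
    gene = sd.generate_gene(60, seed=7, gene_id="G")
    structure, mapping = sd.generate_structure(gene, topology="extended")
    mapping.pairs = [(c, r) for c, r in mapping.pairs if c > 20]  # N-term unmapped
    pop = sd.generate_population_variants(gene, density=2.0, seed=8)
    track = compute_mtr3d(gene, pop, mapping, structure, 8.0)
    assert np.isnan(track.values[:20]).all()
    assert not np.isnan(track.values[30:50]).all()


def test_empty_mapping_warns_all_missing():
    gene = sd.generate_gene(30, seed=9, gene_id="G")
    structure, mapping = sd.generate_structure(gene, topology="extended")
    mapping.pairs = []
    with pytest.warns(UserWarning):
        track = compute_mtr3d(gene, VariantSet("e"), mapping, structure, 8.0)
    assert np.isnan(track.values).all()


# ---------------------------------------------------------------------------
# MTRX

def _synthetic_rows(n, seed, label_rule="mtr_v2", noise=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "gene_id": "G",
            "codon_index": np.arange(1, n + 1),
            "mtr_v1": rng.uniform(0, 1.5, n),
            "mtr_v2": rng.uniform(0, 1.5, n),
            "mtr3d": rng.uniform(0, 1.5, n),
            "rsa": rng.uniform(0, 1, n),
        }
    )
    if label_rule == "mtr_v2":
        y = df["mtr_v2"] < 0.5
    elif label_rule == "logit":
        z = (
            -2.0 * df["mtr_v1"] - 2.0 * df["mtr_v2"] - 2.0 * df["mtr3d"]
            - 1.5 * df["rsa"] + 4.0
        )
        y = rng.random(n) < 1 / (1 + np.exp(-z))
    else:
        y = rng.random(n) < 0.5  # labels independent of features
    df["label"] = np.where(y, DELETERIOUS, BENIGN)
    return df


def test_separable_labels_high_holdout_accuracy():
    model = train_mtrx(_synthetic_rows(2000, seed=10), seed=1)
    assert model.holdout_accuracy >= 0.95
    assert model.oob_score is not None


def test_label_shuffled_auc_near_half():
    df = _synthetic_rows(1500, seed=11, label_rule="independent")
    train, held_out = df.iloc[:1000], df.iloc[1000:]
    model = train_mtrx(train, seed=2, holdout=0.0)
    scores = score_mtrx(model, held_out)
    auc = roc_auc_score((held_out["label"] == DELETERIOUS).to_numpy(), scores)
    assert abs(auc - 0.5) <= 0.1


def test_monotone_logit_all_features_important():
    from sklearn.inspection import permutation_importance

    df = _synthetic_rows(3000, seed=12, label_rule="logit")
    model = train_mtrx(df, seed=3)
    X = df[MTRX_FEATURES].to_numpy()
    y = (df["label"] == DELETERIOUS).to_numpy()
    imp = permutation_importance(
        model.forest, X, y, n_repeats=5, random_state=0
    ).importances_mean
    assert (imp > 0).all()


def test_scores_deterministic_and_bounded():
    df = _synthetic_rows(500, seed=13)
    model_a = train_mtrx(df, seed=7)
    model_b = train_mtrx(df, seed=7)
    s_a = score_mtrx(model_a, df)
    s_b = score_mtrx(model_b, df)
    assert np.array_equal(s_a, s_b)
    assert (s_a >= 0).all() and (s_a <= 1).all()
    # repeat scoring with the same model is bit-identical
    assert np.array_equal(s_a, score_mtrx(model_a, df))


def test_missing_features_yield_missing_scores():
    df = _synthetic_rows(200, seed=14)
    model = train_mtrx(df, seed=4)
    df2 = df.copy()
    df2.loc[0, "mtr3d"] = np.nan
    df2.loc[1, MTRX_FEATURES] = np.nan
    scores = score_mtrx(model, df2)
    assert np.isnan(scores[0]) and np.isnan(scores[1])
    assert not np.isnan(scores[2:]).any()


def test_training_input_validation():
    df = _synthetic_rows(100, seed=15)
    df["label"] = DELETERIOUS
    with pytest.raises(ValueError):
        train_mtrx(df, seed=1)  # single class
    with pytest.raises(ValueError):
        train_mtrx(df.iloc[0:0], seed=1)  # empty
    good = _synthetic_rows(100, seed=16)
    model = train_mtrx(good, seed=1)
    with pytest.raises(ValueError):
        score_mtrx(model, good.drop(columns=["rsa"]))


def test_feature_row_dataclass_interface():
    rows = [
        MTRXFeatureRow("G", 1, 0.2, 0.1, 0.3, 0.4, DELETERIOUS),
        MTRXFeatureRow("G", 2, 1.2, 1.1, 1.3, 0.6, BENIGN),
    ] * 20
    model = train_mtrx(rows, seed=5, holdout=0.0)
    track = mtrx_track(model, rows[:2], gene_length=5)
    assert not np.isnan(track.values[0]) and not np.isnan(track.values[1])
    assert np.isnan(track.values[2:]).all()
    assert track.values[0] > track.values[1]  # intolerant row scores higher


def test_planted_deleterious_positions_score_higher():
    """Directional separation: case-like positions drawn from planted
    intolerant regions get lower MTR3D and higher MTRX than the rest."""
    gene = sd.generate_gene(200, seed=17, gene_id="G")
    region = [(81, 130)]
    pop = sd.generate_population_variants(
        gene, density=1.5, depletion_regions=region, depletion_multiplier=0.2, seed=18
    )
    structure, mapping = sd.generate_structure(gene, topology="helix")
    mtr3d = compute_mtr3d(gene, pop, mapping, structure, 8.0)
    inside = np.nanmean(mtr3d.values[80:130])
    outside = np.nanmean(np.concatenate([mtr3d.values[:80], mtr3d.values[130:]]))
    assert inside < outside

    df = pd.DataFrame(
        {
            "gene_id": "G",
            "codon_index": np.arange(1, 201),
            "mtr_v1": compute_mtr(gene, pop, 41).values,
            "mtr_v2": compute_mtr(gene, pop, 21).values,
            "mtr3d": mtr3d.values,
            "rsa": 0.5,
            "label": [
                DELETERIOUS if 81 <= i <= 130 else BENIGN for i in range(1, 201)
            ],
        }
    )
    model = train_mtrx(df, seed=6, holdout=0.0)
    scores = score_mtrx(model, df)
    assert np.nanmean(scores[80:130]) > np.nanmean(
        np.concatenate([scores[:80], scores[130:]])
    )
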