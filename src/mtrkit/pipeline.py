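"""End-to-end analysis: score, map, classify, compare, report.

``run_analysis`` sequences the full study on a synthetic cohort (or any
:class:`~mtrkit.synthetic_data.SyntheticStudy`-shaped bundle built from
user data): per-gene MTR v1/v2 tracks from population variation, toy (or
supplied) structures for MTR3D and relative solvent accessibility, an
MTRX consensus trained on planted truth, alignment-based conservation,
then cohort-level enrichment at every configured threshold, rank-based
group tests, predictor correlation matrices and a lollipop-plot data
export.  Every stage logs variant counts read/scored so availability
filters are auditable, and the report is stamped with the config hash
and seed so a rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import conservation as conservation_mod
from . import enrichment_stats as es
from . import mtr3d_mtrx, mtr_sequence, synthetic_data
from .mtr_sequence import IntoleranceTrack, WindowSpec
from .structure_tools import compute_rsa
from .synthetic_data import SyntheticCohortSpec, SyntheticStudy

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "mtr": 0.78,  # exome-wide top-25% intolerance cutoff for MTR
    "mtr3d": 0.75,
    "mtr3d_strong": 0.5,
    "mtrx": 0.75,  # MTRX scores above this are called intolerant
}


@dataclass
class AnalysisConfig:
    spec: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    window_sizes: tuple[int, int] = (41, 21)
    spatial_radius: float = 8.0
    percentile: float = 25.0
    test_kind: str = "ranksum"
    alternative: str = "two-sided"
    structure_topology: str = "helix"
    alignment_depth: int = 30
    mtrx_seed: int = mtr3d_mtrx.DEFAULT_SEED
    mtrx_trees: int = 500
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {**asdict(self), "spec": asdict(self.spec)}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


SCORE_NAMES = ["MTR_v1", "MTR_v2", "MTR3D", "MTRX", "conservation"]


def _variant_scores(
    cohort, tracks: Mapping[str, Mapping[str, IntoleranceTrack]], score: str
) -> np.ndarray:
    """Per-variant track value at each variant's codon (NaN if unscored)."""
    out = []
    for v in cohort:
        track = tracks.get(score, {}).get(v.gene_id)
        if track is None or v.codon_index > len(track):
            out.append(np.nan)
        else:
            out.append(track.values[v.codon_index - 1])
    return np.array(out, dtype=float)


def region_recovery(
    study: SyntheticStudy, tracks: Mapping[str, IntoleranceTrack], cutoff: float
) -> dict:
    """Precision/recall of planted-region recovery by score < cutoff."""
    tp = fp = fn = tn = 0
    for gene in study.genes:
        track = tracks[gene.gene_id]
        for i, value in enumerate(track.values):
            if np.isnan(value):
                continue
            predicted = value < cutoff
            actual = study.in_region(gene.gene_id, i + 1)
            if predicted and actual:
                tp += 1
            elif predicted:
                fp += 1
            elif actual:
                fn += 1
            else:
                tn += 1
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"precision": precision, "recall": recall, "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def compute_all_tracks(study: SyntheticStudy, config: AnalysisConfig) -> dict:
    """All per-gene score tracks plus the structures and MTRX model used."""
    rng = np.random.default_rng(config.seed + 1)
    w1, w2 = config.window_sizes
    tracks: dict[str, dict[str, IntoleranceTrack]] = {name: {} for name in SCORE_NAMES}
    rsa_values: dict[str, dict[str, float]] = {}

    for gene in study.genes:
        pop = study.population[gene.gene_id]
        tracks["MTR_v1"][gene.gene_id] = mtr_sequence.compute_mtr(gene, pop, WindowSpec(w1))
        tracks["MTR_v2"][gene.gene_id] = mtr_sequence.compute_mtr(gene, pop, WindowSpec(w2))

        structure, mapping = synthetic_data.generate_structure(
            gene, topology=config.structure_topology, seed=int(rng.integers(2**31))
        )
        tracks["MTR3D"][gene.gene_id] = mtr3d_mtrx.compute_mtr3d(
            gene, pop, mapping, structure, config.spatial_radius
        )
        rsa_values[gene.gene_id] = compute_rsa(structure)

        alignment = synthetic_data.generate_alignment(
            gene,
            conserved_blocks=study.regions.get(gene.gene_id, ()),
            n_sequences=config.alignment_depth,
            seed=int(rng.integers(2**31)),
        )
        tracks["conservation"][gene.gene_id] = conservation_mod.windowed_conservation(
            alignment, gene_id=gene.gene_id
        )

    # MTRX: train the consensus on planted truth from alternate genes,
    # score every position everywhere
    feature_frames = []
    for gene in study.genes:
        L = len(gene)
        rsa_track = np.array(
            [rsa_values[gene.gene_id].get(str(i + 1), np.nan) for i in range(L)]
        )
        feature_frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene.gene_id,
                    "codon_index": np.arange(1, L + 1),
                    "mtr_v1": tracks["MTR_v1"][gene.gene_id].values,
                    "mtr_v2": tracks["MTR_v2"][gene.gene_id].values,
                    "mtr3d": tracks["MTR3D"][gene.gene_id].values,
                    "rsa": rsa_track,
                    "label": [
                        mtr3d_mtrx.DELETERIOUS
                        if study.in_region(gene.gene_id, i + 1)
                        else mtr3d_mtrx.BENIGN
                        for i in range(L)
                    ],
                }
            )
        )
    features = pd.concat(feature_frames, ignore_index=True)
    train_genes = {g.gene_id for g in study.genes[::2]}
    train_rows = features[features["gene_id"].isin(train_genes)]
    model = mtr3d_mtrx.train_mtrx(
        train_rows, seed=config.mtrx_seed, n_trees=config.mtrx_trees
    )
    for gene in study.genes:
        rows = features[features["gene_id"] == gene.gene_id]
        tracks["MTRX"][gene.gene_id] = mtr3d_mtrx.mtrx_track(model, rows, len(gene))
    return {"tracks": tracks, "mtrx_model": model, "features": features}


def run_analysis(
    config: AnalysisConfig | None = None,
    study: SyntheticStudy | None = None,
) -> dict:
    """Run the full analysis and return a JSON-serializable report bundle."""
    config = config or AnalysisConfig()
    if study is None:
        study = synthetic_data.generate_study(config.spec, seed=config.seed)
    logger.info(
        "study: %d genes, cohorts %s",
        len(study.genes),
        {k: len(v) for k, v in study.cohorts.items()},
    )
    computed = compute_all_tracks(study, config)
    tracks = computed["tracks"]

    pooled_cutoff = mtr_sequence.percentile_threshold(
        tracks["MTR_v1"].values(), config.percentile
    )

    # enrichment blocks at every configured threshold
    threshold_blocks = {
        "mtr": ("MTR_v1", config.thresholds["mtr"], es.BELOW),
        "mtr3d": ("MTR3D", config.thresholds["mtr3d"], es.BELOW),
        "mtr3d_strong": ("MTR3D", config.thresholds["mtr3d_strong"], es.BELOW),
        "mtrx": ("MTRX", config.thresholds["mtrx"], es.ABOVE),
        "mtr_pooled_percentile": ("MTR_v1", pooled_cutoff, es.BELOW),
    }
    enrichment: dict[str, dict] = {}
    for block, (score, cutoff, direction) in threshold_blocks.items():
        enrichment[block] = {}
        for label, cohort in study.cohorts.items():
            scores = _variant_scores(cohort, tracks, score)
            result = es.fraction_intolerant(
                scores, cutoff, direction, group=label, score_name=score
            )
            enrichment[block][label] = asdict(result)
            logger.info(
                "%s / %s: %d of %d variants scored, %s intolerant",
                block,
                label,
                result.n_scored,
                len(cohort),
                result.n_intolerant,
            )

    # rank scores pooled across all cohort variants, then group tests
    comparisons: dict[str, dict] = {}
    cohort_sizes = {label: len(c) for label, c in study.cohorts.items()}
    for score in SCORE_NAMES:
        pooled = {
            label: _variant_scores(cohort, tracks, score)
            for label, cohort in study.cohorts.items()
        }
        concat = np.concatenate([pooled[l] for l in ("case", "control1", "control2")])
        if np.isnan(concat).all():
            continue
        invert = score in es.LOW_IS_DAMAGING
        ranks = es.rank_scores(-concat if invert else concat)
        offsets = np.cumsum([0] + [len(pooled[l]) for l in ("case", "control1", "control2")])
        rank_groups = {
            label: ranks[offsets[i] : offsets[i + 1]]
            for i, label in enumerate(("case", "control1", "control2"))
        }
        comparisons[score] = {}
        for control in ("control1", "control2"):
            try:
                cmp = es.compare_groups(
                    rank_groups["case"],
                    rank_groups[control],
                    test=config.test_kind,
                    alternative=config.alternative,
                    score_name=score,
                )
            except ValueError:
                continue
            comparisons[score][control] = asdict(cmp)

    # pairwise predictor correlations, all genes and disease-panel subset
    variant_rows = []
    for label, cohort in study.cohorts.items():
        for v in cohort:
            row = {"key": v.key, "gene_id": v.gene_id, "cohort": label}
            for score in SCORE_NAMES:
                track = tracks[score].get(v.gene_id)
                row[score] = (
                    track.values[v.codon_index - 1]
                    if track is not None and v.codon_index <= len(track)
                    else np.nan
                )
            variant_rows.append(row)
    vdf = pd.DataFrame(variant_rows).drop_duplicates(subset="key").set_index("key")
    dee_genes = {g.gene_id for g in study.genes if g.is_dee_gene}
    corr_all, n_all = es.pairwise_correlations(vdf[SCORE_NAMES])
    correlations = {
        "all_genes": {"matrix": corr_all.round(6).to_dict(), "n": n_all.to_dict()}
    }
    dee_df = vdf[vdf["gene_id"].isin(dee_genes)][SCORE_NAMES]
    if len(dee_df) >= 3:
        corr_dee, n_dee = es.pairwise_correlations(dee_df)
        correlations["dee_genes"] = {
            "matrix": corr_dee.round(6).to_dict(),
            "n": n_dee.to_dict(),
        }

    # conservation vs MTR, pooled over gene positions
    cons_concat = np.concatenate(
        [tracks["conservation"][g.gene_id].values for g in study.genes]
    )
    mtr_concat = np.concatenate([tracks["MTR_v1"][g.gene_id].values for g in study.genes])
    cons_vs_mtr = conservation_mod.correlate_tracks(cons_concat, mtr_concat, "pearson")

    recovery = region_recovery(study, tracks["MTR_v1"], pooled_cutoff)

    lollipop = lollipop_export(study)

    report = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "thresholds": {**config.thresholds, "mtr_pooled_percentile": pooled_cutoff},
        "cohort_sizes": cohort_sizes,
        "enrichment": enrichment,
        "group_comparisons": comparisons,
        "correlations": correlations,
        "conservation_vs_mtr": cons_vs_mtr,
        "region_recovery": recovery,
        "mtrx_provenance": computed["mtrx_model"].provenance(),
        "lollipop": lollipop,
    }
    return report


def lollipop_export(study: SyntheticStudy) -> list[dict]:
    """Per (gene, position, cohort) variant counts for external lollipop plots."""
    counts: dict[tuple, int] = {}
    for label, cohort in study.cohorts.items():
        for v in cohort:
            key = (v.gene_id, v.codon_index, label)
            counts[key] = counts.get(key, 0) + 1
    return [
        {"gene": g, "position": p, "cohort": c, "count": n}
        for (g, p, c), n in sorted(counts.items())
    ]


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the JSON report plus human-readable TSVs; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")

    rows = []
    for block, groups in report["enrichment"].items():
        for label, result in groups.items():
            rows.append({"block": block, **result})
    pd.DataFrame(rows).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)

    rows = []
    for score, controls in report["group_comparisons"].items():
        for control, cmp in controls.items():
            rows.append({"control": control, **cmp})
    pd.DataFrame(rows).to_csv(out_dir / "group_comparisons.tsv", sep="\t", index=False)

    with open(out_dir / "lollipop.json", "w") as fh:
        json.dump(report["lollipop"], fh, indent=2)
        fh.write("\n")
    return json_path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
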