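"""Sliding-window Missense Tolerance Ratio (MTR) over gene codons.

The MTR at focal codon *i* is the observed missense proportion divided by
the expected missense proportion over a symmetric window of codons::

    MTR_i = [obs_mis / (obs_mis + obs_syn)] / [exp_mis / (exp_mis + exp_syn)]

where the expected counts enumerate all single-nucleotide substitutions of
the window's codons (nonsense possibilities excluded from both sides) and
the observed counts are distinct missense/synonymous variant keys seen in a
reference population.  Values near 1 indicate tolerance; values below 1,
depletion of missense variation (regional intolerance).  Two window widths
are conventional: 41 codons (v1) and 21 codons (v2).

Windows are clipped to the gene at the termini (asymmetric near the ends)
so terminal codons still receive scores.  Focal codons whose window holds
no observed variants get a missing value — the ratio is undefined there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_model import (
    MISSENSE,
    SYNONYMOUS,
    GeneModel,
    VariantSet,
    enumerate_codon_snvs,
)

MTR_V1_WINDOW = 41
MTR_V2_WINDOW = 21


@dataclass
class WindowSpec:
    """A symmetric sliding window of ``size`` codons, clipped at gene ends."""

    size: int = MTR_V1_WINDOW
    truncation_rule: str = "clip"

    def __post_init__(self) -> None:
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError("window size must be an odd positive integer")
        if self.truncation_rule != "clip":
            raise ValueError("only the 'clip' truncation rule is supported")

    @property
    def half(self) -> int:
        return self.size // 2

    def bounds(self, focal: int, length: int) -> tuple[int, int]:
        """Inclusive 1-based window bounds around ``focal`` for a gene of ``length``."""
        return max(1, focal - self.half), min(length, focal + self.half)


@dataclass
class IntoleranceTrack:
    """Per-codon score vector for one gene.

    ``values`` has one entry per codon (NaN = missing).  For MTR-family
    tracks the per-position window bookkeeping (observed missense and
    synonymous counts, expected missense proportion) is retained so reports
    can audit every score.
    """

    gene_id: str
    score_name: str
    values: np.ndarray
    obs_missense: np.ndarray | None = None
    obs_synonymous: np.ndarray | None = None
    exp_missense_prop: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.values)

    @property
    def non_missing(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]


def possibility_counts(gene: GeneModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-codon counts of possible missense and synonymous SNVs."""
    n_mis = np.empty(len(gene), dtype=np.int64)
    n_syn = np.empty(len(gene), dtype=np.int64)
    for i, codon in enumerate(gene.codons):
        counts = enumerate_codon_snvs(codon)
        n_mis[i] = counts["n_missense"]
        n_syn[i] = counts["n_synonymous"]
    return n_mis, n_syn


def expected_missense_proportion(gene: GeneModel, window: Sequence[int]) -> float:
    """Expected missense proportion over a 1-based inclusive codon range.

    ``window`` is ``(start, stop)``; the proportion is the number of
    possible missense SNVs over possible missense+synonymous SNVs summed
    across the window's codons.
    """
    start, stop = window
    if not (1 <= start <= stop <= len(gene)):
        raise ValueError(f"window {window} outside gene of length {len(gene)}")
    n_mis, n_syn = possibility_counts(gene)
    mis = int(n_mis[start - 1 : stop].sum())
    syn = int(n_syn[start - 1 : stop].sum())
    assert mis + syn > 0, "sense codons always admit missense possibilities"
    return mis / (mis + syn)


def observed_window_counts(
    variants: VariantSet, gene: GeneModel, window: Sequence[int]
) -> dict[str, int]:
    """Distinct observed missense/synonymous variants within a codon range."""
    start, stop = window
    obs = {"obs_missense": 0, "obs_synonymous": 0}
    for v in variants:
        if v.gene_id != gene.gene_id or not (start <= v.codon_index <= stop):
            continue
        if v.consequence == MISSENSE:
            obs["obs_missense"] += 1
        elif v.consequence == SYNONYMOUS:
            obs["obs_synonymous"] += 1
    return obs


def _per_codon_observed(variants: VariantSet, gene: GeneModel) -> tuple[np.ndarray, np.ndarray]:
    obs_mis = np.zeros(len(gene), dtype=np.int64)
    obs_syn = np.zeros(len(gene), dtype=np.int64)
    for v in variants:
        if v.gene_id != gene.gene_id or v.codon_index > len(gene):
            continue
        if v.consequence == MISSENSE:
            obs_mis[v.codon_index - 1] += 1
        elif v.consequence == SYNONYMOUS:
            obs_syn[v.codon_index - 1] += 1
    return obs_mis, obs_syn


def _window_sums(per_codon: np.ndarray, half: int) -> np.ndarray:
    """Clipped sliding-window sums: out[i] = sum(x[max(0,i-h) : i+h+1])."""
    c = np.concatenate(([0], np.cumsum(per_codon)))
    n = len(per_codon)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return c[hi] - c[lo]


def compute_mtr(
    gene: GeneModel,
    population_variants: VariantSet,
    spec: WindowSpec | int = MTR_V1_WINDOW,
) -> IntoleranceTrack:
    """Compute the sliding-window MTR track for one gene.

    Parameters
    ----------
    gene : GeneModel
    population_variants : VariantSet
        Reference (standing) variation; only missense and synonymous
        records contribute, counted once per distinct variant key.
    spec : WindowSpec or int
        Window width in codons (odd); 41 for v1, 21 for v2.
    """
    if isinstance(spec, int):
        spec = WindowSpec(spec)
    if spec.size > 2 * len(gene) - 1:
        raise ValueError(
            f"window of {spec.size} codons exceeds 2L-1 for gene length {len(gene)}"
        )
    n_mis, n_syn = possibility_counts(gene)
    obs_mis, obs_syn = _per_codon_observed(population_variants, gene)

    w_nmis = _window_sums(n_mis, spec.half)
    w_nsyn = _window_sums(n_syn, spec.half)
    w_omis = _window_sums(obs_mis, spec.half)
    w_osyn = _window_sums(obs_syn, spec.half)

    exp_prop = w_nmis / (w_nmis + w_nsyn)
    obs_total = w_omis + w_osyn
    with np.errstate(invalid="ignore"):
        obs_prop = np.where(obs_total > 0, w_omis / np.maximum(obs_total, 1), np.nan)
    values = obs_prop / exp_prop

    name = {MTR_V1_WINDOW: "MTR_v1", MTR_V2_WINDOW: "MTR_v2"}.get(
        spec.size, f"MTR_w{spec.size}"
    )
    return IntoleranceTrack(
        gene_id=gene.gene_id,
        score_name=name,
        values=values,
        obs_missense=w_omis,
        obs_synonymous=w_osyn,
        exp_missense_prop=exp_prop,
    )


def percentile_threshold(tracks: Iterable[IntoleranceTrack], q: float) -> float:
    """Pooled q-th percentile of all non-missing track values.

    Uses the lower-interpolation convention; downstream classification
    treats values strictly below the returned cutoff as intolerant, so
    ``q=0`` classifies nothing and ``q=100`` classifies everything below
    the pooled maximum.
    """
    pooled = np.concatenate([t.non_missing for t in tracks])
    if pooled.size == 0:
        raise ValueError("no non-missing values to pool")
    return float(np.percentile(pooled, q, method="lower"))


# ---------------------------------------------------------------------------
# Track IO

TRACK_COLUMNS = ["gene", "position", "score", "obs_mis", "obs_syn", "exp_prop"]


def track_to_frame(track: IntoleranceTrack) -> pd.DataFrame:
    n = len(track)
    none = np.full(n, np.nan)
    return pd.DataFrame(
        {
            "gene": track.gene_id,
            "position": np.arange(1, n + 1),
            "score": track.values,
            "obs_mis": track.obs_missense if track.obs_missense is not None else none,
            "obs_syn": track.obs_synonymous if track.obs_synonymous is not None else none,
            "exp_prop": track.exp_missense_prop
            if track.exp_missense_prop is not None
            else none,
        }
    )


def write_track(track: IntoleranceTrack, path: str | Path) -> None:
    """Write a track as TSV (gene, position, score, obs_mis, obs_syn, exp_prop)."""
    with open(path, "w") as fh:
        fh.write(f"# score: {track.score_name}\n")
        track_to_frame(track).to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_track(path: str | Path, score_name: str = "score") -> IntoleranceTrack:
    df = pd.read_csv(path, sep="\t", comment="#", na_values="NA")
    df = df.sort_values("position")
    return IntoleranceTrack(
        gene_id=str(df["gene"].iloc[0]),
        score_name=score_name,
        values=df["score"].to_numpy(dtype=float),
        obs_missense=df["obs_mis"].to_numpy(),
        obs_synonymous=df["obs_syn"].to_numpy(),
        exp_missense_prop=df["exp_prop"].to_numpy(),
    )


def write_track_bed(
    track: IntoleranceTrack, path: str | Path, threshold: float | None = None
) -> None:
    """BED-like export: 0-based half-open codon intervals, one row per codon.

    When ``threshold`` is given, only codons scoring strictly below it
    (intolerant codons) are written.
    """
    with open(path, "w") as fh:
        for i, score in enumerate(track.values):
            if np.isnan(score):
                continue
            if threshold is not None and not score < threshold:
                continue
            fh.write(f"{track.gene_id}\t{i}\t{i + 1}\t{track.score_name}\t{score:.6g}\n")
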