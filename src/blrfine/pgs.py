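"""Polygenic scores from fine-mapped effects and predictive-ability metrics.

The polygenic score of an individual is the allele-dosage-weighted sum of
estimated effects, PGS = sum_i x_i b_hat_i.  Effects estimated on the
centered-and-scaled genotype scale are applied on that same scale by
default; ``scale="dosage"`` converts them to the raw-dosage scale via
b_raw = b_scaled / sqrt(2 p (1 - p)) first (an affine change that leaves
R^2 and AUC unchanged).

Predictive ability is the squared Pearson correlation (R^2 of the simple
regression of the validation phenotype on the score) for quantitative
traits, and the rank AUC for binary traits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evalmetrics import pip_auc
from .synthgeno import GenotypeMatrix

__all__ = ["compute_pgs", "predictive_r2", "predictive_auc", "write_scores_tsv"]


def compute_pgs(G_validation: GenotypeMatrix, weight_ids, weights,
                scale: str = "scaled") -> np.ndarray:
    """Per-sample polygenic score from estimated effects.

    ``weight_ids``/``weights`` are the variants carrying non-zero estimated
    effects; every weight id must exist in the validation genotypes.
    ``scale``: "scaled" (weights on the centered-and-scaled genotype scale,
    the estimation scale) or "dosage" (weights applied to raw allele counts).
    """
    weight_ids = np.asarray(weight_ids, dtype=object)
    weights = np.asarray(weights, dtype=np.float64)
    if len(weight_ids) != len(weights):
        raise ValueError("weight_ids and weights must have equal length")
    lookup = {v: j for j, v in enumerate(G_validation.ids)}
    missing = [v for v in weight_ids if v not in lookup]
    if missing:
        raise ValueError(f"weight variants absent from genotypes: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    cols = np.array([lookup[v] for v in weight_ids], dtype=int)
    x = G_validation.counts[:, cols].astype(np.float64)
    if scale == "scaled":
        p = np.asarray(G_validation.freqs, dtype=np.float64)[cols]
        x = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    elif scale != "dosage":
        raise ValueError(f"scale must be 'scaled' or 'dosage', got {scale!r}")
    return x @ weights


def predictive_r2(y_validation: np.ndarray, scores: np.ndarray) -> float:
    """R^2 of regressing the (adjusted, scaled) validation phenotype on the
    score — the squared Pearson correlation for a simple regression."""
    y = np.asarray(y_validation, dtype=np.float64)
    s = np.asarray(scores, dtype=np.float64)
    if np.var(s) == 0.0:
        raise ValueError("predictive R^2 is undefined for a constant score")
    r = np.corrcoef(y, s)[0, 1]
    return float(r * r)


def predictive_auc(labels_validation: np.ndarray, scores: np.ndarray) -> float:
    """Rank AUC of the score for discriminating cases from controls."""
    return pip_auc(scores, labels_validation)


def write_scores_tsv(scores: np.ndarray, path, sample_ids=None) -> None:
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(scores))]
    pd.DataFrame({"sample_id": sample_ids, "score": scores}).to_csv(
        path, sep="\t", index=False)
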