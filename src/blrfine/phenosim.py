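"""Phenotype simulation under polygenic genetic architectures.

Quantitative phenotypes follow

    y = sum_i w_i b_i + e,    e ~ N(0, sigma_e^2),

on centered-and-scaled genotypes w, with the genetic variance sigma_g^2 set
equal to the target SNP heritability h2 and the residual variance
sigma_e^2 = sigma_g^2 (1/h2 - 1), so that Var(y) = 1 in expectation.

Two architectures are provided:

* GA1 — all causal effects from one normal, b ~ N(0, sigma_g^2 / m_C).
* GA2 — a three-class mixture: 93% of causal SNPs are small-effect, 5%
  moderate and 2% large, with per-SNP effect variances
  (0.6 sigma_g^2)/(0.93 m_C), (0.2 sigma_g^2)/(0.05 m_C) and
  (0.2 sigma_g^2)/(0.02 m_C), so the three classes contribute 60/20/20% of
  the genetic variance in expectation.

A separate two-causal design places exactly two causal variants with fixed
effects (large L = 0.05, small S = 0.01) in a region and a residual variance
fixed at 1.0 (phenotypes are not rescaled), giving per-SNP heritabilities of
~0.0025 (L) and ~0.001 (S).

Binary traits are produced by liability-style dichotomization: the top
``prevalence`` fraction of the quantitative values become cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .synthgeno import ScaledDesign

__all__ = [
    "CausalSpec",
    "SimulatedPhenotype",
    "simulate_ga1",
    "simulate_ga2",
    "simulate_two_causal",
    "dichotomize",
    "write_phenotype_tsv",
    "write_truth_tsv",
]

# GA2 mixture: class membership proportions and genetic-variance shares.
GA2_PROPORTIONS = (0.93, 0.05, 0.02)
GA2_VARIANCE_SHARES = (0.6, 0.2, 0.2)
GA2_CLASS_LABELS = ("small", "moderate", "large")

# Two-causal design: fixed effects on the scaled-genotype scale.
TWO_CAUSAL_EFFECTS = {"L": 0.05, "S": 0.01}
TWO_CAUSAL_CONFIGS = {"LL": ("L", "L"), "LS": ("L", "S"), "SS": ("S", "S")}


@dataclass
class CausalSpec:
    """Ground truth of a simulation: which variants are causal and how big."""

    indices: np.ndarray          # variant indices, unique
    effects: np.ndarray          # effect sizes on the scaled-genotype scale
    class_labels: np.ndarray     # per-causal effect-size class

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=np.float64)
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("causal indices must be unique")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("causal effects must be finite")


@dataclass
class SimulatedPhenotype:
    y: np.ndarray
    h2: float
    sigma_g2: float
    sigma_e2: float
    causal: CausalSpec
    binary: Optional[np.ndarray] = None
    prevalence: Optional[float] = None


def _check_h2(h2):
    if not (0.0 < h2 < 1.0):
        raise ValueError(f"h2 must be in (0, 1), got {h2}")


def simulate_ga1(W: ScaledDesign, m_causal: int, h2: float, seed: int = 0) -> SimulatedPhenotype:
    """Single-normal architecture: b ~ N(0, sigma_g^2 / m_causal)."""
    _check_h2(h2)
    if not (1 <= m_causal <= W.m):
        raise ValueError(f"m_causal must be in [1, m={W.m}], got {m_causal}")
    rng = np.random.default_rng(seed)
    sigma_g2 = h2
    sigma_e2 = sigma_g2 * (1.0 / h2 - 1.0)
    idx = np.sort(rng.choice(W.m, size=m_causal, replace=False))
    b = rng.normal(0.0, np.sqrt(sigma_g2 / m_causal), size=m_causal)
    y = W.W[:, idx].astype(np.float64) @ b + rng.normal(0.0, np.sqrt(sigma_e2), size=W.n)
    causal = CausalSpec(idx, b, np.full(m_causal, "ga1", dtype=object))
    return SimulatedPhenotype(y=y, h2=h2, sigma_g2=sigma_g2, sigma_e2=sigma_e2, causal=causal)


def _largest_remainder_counts(m_causal: int, proportions) -> np.ndarray:
    """Integer class counts summing to m_causal, hitting proportions exactly
    where possible (largest-remainder apportionment, ties to earlier class)."""
    target = np.asarray(proportions) * m_causal
    counts = np.floor(target).astype(int)
    rem = target - counts
    short = m_causal - counts.sum()
    for c in np.argsort(-rem, kind="stable")[:short]:
        counts[c] += 1
    return counts


def simulate_ga2(W: ScaledDesign, m_causal: int, h2: float, seed: int = 0) -> SimulatedPhenotype:
    """Three-class mixture architecture (93/5/2% membership, 60/20/20% variance)."""
    _check_h2(h2)
    if not (1 <= m_causal <= W.m):
        raise ValueError(f"m_causal must be in [1, m={W.m}], got {m_causal}")
    counts = _largest_remainder_counts(m_causal, GA2_PROPORTIONS)
    if np.any(counts == 0):
        raise ValueError(
            f"m_causal={m_causal} leaves an empty effect-size class "
            f"(counts {tuple(counts)}); increase m_causal so every class has >= 1 SNP"
        )
    rng = np.random.default_rng(seed)
    sigma_g2 = h2
    sigma_e2 = sigma_g2 * (1.0 / h2 - 1.0)
    idx = rng.choice(W.m, size=m_causal, replace=False)  # random order -> random class assignment
    labels = np.repeat(np.array(GA2_CLASS_LABELS, dtype=object), counts)
    effects = np.empty(m_causal)
    start = 0
    for share, prop, cnt in zip(GA2_VARIANCE_SHARES, GA2_PROPORTIONS, counts):
        # per-SNP variance (share * sigma_g2) / (prop * m_causal); with exact
        # proportions the denominator equals the class count
        var_c = share * sigma_g2 / (prop * m_causal)
        effects[start:start + cnt] = rng.normal(0.0, np.sqrt(var_c), size=cnt)
        start += cnt
    order = np.argsort(idx)
    causal = CausalSpec(idx[order], effects[order], labels[order])
    y = W.W[:, causal.indices].astype(np.float64) @ causal.effects
    y += rng.normal(0.0, np.sqrt(sigma_e2), size=W.n)
    return SimulatedPhenotype(y=y, h2=h2, sigma_g2=sigma_g2, sigma_e2=sigma_e2, causal=causal)


def simulate_two_causal(W_region: ScaledDesign, config: str, seed: int = 0) -> SimulatedPhenotype:
    """Two causal variants with fixed effects; residual variance fixed at 1.0.

    ``config`` is one of "LL", "LS", "SS" (L = 0.05, S = 0.01 on scaled
    genotypes).  Phenotypes are NOT rescaled to unit variance.
    """
    if config not in TWO_CAUSAL_CONFIGS:
        raise ValueError(f"unknown two-causal config {config!r}; expected one of "
                         f"{sorted(TWO_CAUSAL_CONFIGS)}")
    if W_region.m < 2:
        raise ValueError("two-causal design needs a region of >= 2 variants")
    rng = np.random.default_rng(seed)
    labels = np.array(TWO_CAUSAL_CONFIGS[config], dtype=object)
    effects = np.array([TWO_CAUSAL_EFFECTS[l] for l in labels])
    idx = rng.choice(W_region.m, size=2, replace=False)
    order = np.argsort(idx)
    causal = CausalSpec(idx[order], effects[order], labels[order])
    sigma_e2 = 1.0
    sigma_g2 = float(np.sum(causal.effects**2))
    y = W_region.W[:, causal.indices].astype(np.float64) @ causal.effects
    y += rng.normal(0.0, 1.0, size=W_region.n)
    h2 = sigma_g2 / (sigma_g2 + sigma_e2)
    return SimulatedPhenotype(y=y, h2=h2, sigma_g2=sigma_g2, sigma_e2=sigma_e2, causal=causal)


def dichotomize(y: np.ndarray, prevalence: float) -> np.ndarray:
    """Top-quantile case/control labels: exactly round(n * prevalence) cases.

    The individuals with the largest phenotype values become cases; ties are
    broken deterministically by ascending sample index.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    k = int(round(n * prevalence))
    if k < 1:
        raise ValueError(f"n * prevalence = {n * prevalence:g} < 1: no cases")
    order = np.lexsort((np.arange(n), -y))  # descending y, index tie-break
    labels = np.zeros(n, dtype=np.int8)
    labels[order[:k]] = 1
    return labels


# ---------------------------------------------------------------------------
# I/O

def write_phenotype_tsv(pheno: SimulatedPhenotype, path, sample_ids=None) -> None:
    n = len(pheno.y)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    df = pd.DataFrame({"sample_id": sample_ids, "y": pheno.y})
    if pheno.binary is not None:
        df["case"] = pheno.binary
    df.to_csv(path, sep="\t", index=False)


def write_truth_tsv(causal: CausalSpec, variant_ids, path) -> None:
    ids = np.asarray(variant_ids, dtype=object)
    pd.DataFrame({
        "id": ids[causal.indices],
        "index": causal.indices,
        "effect": causal.effects,
        "class": causal.class_labels,
    }).to_csv(path, sep="\t", index=False)
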