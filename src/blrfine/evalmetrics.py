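"""Evaluation of fine-mapping output: confusion rules, F1, PIP AUC, and
MCMC convergence diagnostics.

Region classification.  Each credible set containing a simulated causal
(index) SNP is a true positive, unless it has more than 10 SNPs, in which
case it is penalized as a false negative (overly large sets are
uninformative).  A set containing no causal SNP is a false positive.  A
region that emitted no set, or whose sampler failed to converge, is a false
negative.  Causal variants are scored independently, so in a two-causal
region a single set containing both causals contributes two true positives.

F1 = 2 p r / (p + r) with precision p = TP/(TP+FP), recall r = TP/(TP+FN);
zero denominators yield 0 so empty-output methods score worst.

PIP AUC is the midrank Mann-Whitney statistic of PIPs against the causal
indicator.

Convergence uses the Geweke diagnostic: the difference of the means of the
first 10% and last 50% of a chain, scaled by an autocorrelation-robust
(spectral-density-at-zero) standard error; |Z| > 3 flags non-convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .credsets import CredibleSet, RegionSpec

__all__ = [
    "ConfusionCounts",
    "GewekeResult",
    "classify_regions",
    "f1",
    "pip_auc",
    "geweke_z",
    "assess_convergence",
    "rank_methods",
]

MAX_TP_SIZE = 10
GEWEKE_THRESHOLD = 3.0


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    region_labels: Dict[str, str] = field(default_factory=dict)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        labels = dict(self.region_labels)
        labels.update(other.region_labels)
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, labels)


def classify_regions(regions: Sequence[RegionSpec],
                     credsets: Dict[str, List[CredibleSet]],
                     max_tp_size: int = MAX_TP_SIZE,
                     converged: Optional[Dict[str, bool]] = None) -> ConfusionCounts:
    """Apply the TP/FP/FN rules per region.

    ``credsets`` maps region_id -> list of emitted credible sets (empty list
    if none); ``converged`` maps region_id -> bool (missing = converged).
    Region truth comes from ``RegionSpec.causal_idx``.
    """
    out = ConfusionCounts()
    converged = converged or {}
    for reg in regions:
        if reg.region_id not in credsets:
            raise ValueError(f"no credible-set entry for region {reg.region_id!r}")
        causals = set(int(c) for c in reg.causal_idx)
        n_causal = max(1, len(causals))
        if not converged.get(reg.region_id, True):
            out.fn += n_causal
            out.region_labels[reg.region_id] = "FN(non-converged)"
            continue
        sets = credsets[reg.region_id]
        if len(sets) == 0:
            out.fn += n_causal
            out.region_labels[reg.region_id] = "FN(no credible set)"
            continue
        tp = fp = fn = 0
        for cs in sets:
            hit = causals & set(int(v) for v in cs.variant_idx)
            if not hit:
                fp += 1
            elif cs.size > max_tp_size:
                fn += len(hit)    # oversized TP set penalized as FN
            else:
                tp += len(hit)
        out.tp += tp
        out.fp += fp
        out.fn += fn
        out.region_labels[reg.region_id] = f"TP={tp},FP={fp},FN={fn}"
    return out


def f1(counts: ConfusionCounts) -> tuple:
    """(precision, recall, F1); zero denominators give 0 by convention."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else 0.0
    score = 2.0 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, score


def pip_auc(pips: np.ndarray, causal_indicator: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of PIPs for discriminating causal
    variants, with midrank tie handling."""
    pips = np.asarray(pips, dtype=np.float64)
    ind = np.asarray(causal_indicator).astype(bool)
    n1 = int(ind.sum())
    n0 = len(ind) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC is undefined with a single class "
                         f"(n_causal={n1}, n_null={n0})")
    ranks = stats.rankdata(pips, method="average")
    u = ranks[ind].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class GewekeResult:
    z: Dict[str, float]
    frac_first: float
    frac_last: float
    converged: bool
    assessable: Dict[str, bool] = field(default_factory=dict)


def _spectral0(x: np.ndarray) -> float:
    """Long-run variance (spectral density at zero) via a Bartlett window.

    The window spans 4% of the segment (the diagnostic's classic choice);
    slowly mixing chains need a bandwidth that grows proportionally with
    the segment, or the standard error is underestimated and stationary
    chains are over-flagged.
    """
    n = len(x)
    x = x - x.mean()
    lag = min(n - 1, max(1, int(np.floor(0.04 * n))))
    g0 = float(x @ x) / n
    s = g0
    for k in range(1, lag + 1):
        gk = float(x[:-k] @ x[k:]) / n
        s += 2.0 * (1.0 - k / (lag + 1.0)) * gk
    return max(s, 0.0)


def geweke_z(chain: np.ndarray, frac_first: float = 0.10,
             frac_last: float = 0.50) -> tuple:
    """Geweke Z for one chain: (z, assessable).

    z = (mean_first - mean_last)/sqrt(se1^2 + se2^2) with spectral
    standard errors; ``assessable`` is False for (near-)constant segments,
    whose z is returned as NaN.
    """
    chain = np.asarray(chain, dtype=np.float64)
    n = len(chain)
    if n < 20:
        raise ValueError(f"chain too short for the diagnostic (length {n} < 20)")
    n1 = max(2, int(np.floor(frac_first * n)))
    n2 = max(2, int(np.floor(frac_last * n)))
    a, b = chain[:n1], chain[n - n2:]
    s1 = _spectral0(a) / n1
    s2 = _spectral0(b) / n2
    denom = s1 + s2
    if denom <= 0.0 or not np.isfinite(denom):
        return float("nan"), False
    return float((a.mean() - b.mean()) / np.sqrt(denom)), True


def assess_convergence(chains: Dict[str, np.ndarray], frac_first: float = 0.10,
                       frac_last: float = 0.50,
                       threshold: float = GEWEKE_THRESHOLD) -> GewekeResult:
    """Geweke diagnostic over the monitored parameter chains.

    ``converged`` is False iff any assessable |z| exceeds the threshold.
    Non-assessable (constant) chains do not trigger the flag.
    """
    zs, ok = {}, {}
    converged = True
    for name, chain in chains.items():
        z, assessable = geweke_z(chain, frac_first, frac_last)
        zs[name] = z
        ok[name] = assessable
        if assessable and abs(z) > threshold:
            converged = False
    return GewekeResult(z=zs, frac_first=frac_first, frac_last=frac_last,
                        converged=converged, assessable=ok)


def rank_methods(metric_table: pd.DataFrame, higher_is_better: bool = True) -> pd.DataFrame:
    """Mean rank (+- SE) per method across scenarios.

    ``metric_table``: rows = scenarios, columns = methods, cells = scores.
    Methods are ranked within each scenario (rank 1 = best; ties get the
    average rank), then averaged across scenarios.
    """
    if metric_table.isna().any().any():
        missing = [f"{r}/{c}" for r, c in
                   zip(*np.nonzero(metric_table.isna().to_numpy()))]
        missing = [f"{metric_table.index[int(i.split('/')[0])]}:"
                   f"{metric_table.columns[int(i.split('/')[1])]}" for i in missing]
        raise ValueError(f"metric table has missing cells: {missing}")
    ranks = metric_table.rank(axis=1, ascending=not higher_is_better, method="average")
    n = len(ranks)
    out = pd.DataFrame({
        "mean_rank": ranks.mean(axis=0),
        "se": ranks.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else 0.0,
    })
    return out.sort_values("mean_rank")
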