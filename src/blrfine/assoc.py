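"""GWAS summary statistics, LD matrices, and sufficient-statistic reconstruction.

The fine-mapping samplers never see individual-level data: they operate on
the cross-products X'X and X'y reconstructed from per-variant marginal GWAS
effects and an LD correlation matrix B via

    X'X = D^{1/2} B D^{1/2},    X'y = D b~,

where for genotypes centered and scaled to unit variance the per-variant
weight is simply the sample size, D_i = n_i, and for merely centered
genotypes D_i = 1/(se_i^2 + b~_i^2 / n_i).  With in-sample LD and exact
in-sample scaling the reconstruction is an algebraic identity.

B stores SIGNED Pearson correlations r (the identity above requires signs);
r^2 is derived from it where squared LD is needed (credible-set grouping,
purity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .synthgeno import ScaledDesign

__all__ = [
    "SummaryStats",
    "LDMatrix",
    "SuffStats",
    "gwas_linear",
    "gwas_logistic",
    "compute_ld",
    "reconstruct_suffstats",
]

SUMSTATS_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "freq", "beta", "se", "n", "p"]


@dataclass
class SummaryStats:
    """Per-variant marginal GWAS results (arrays aligned by variant)."""

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    freq: np.ndarray
    beta: np.ndarray        # marginal effect b~_i
    se: np.ndarray          # standard error of b~_i
    n: np.ndarray           # per-variant sample size
    p: np.ndarray           # two-sided p-value
    converged: Optional[np.ndarray] = None   # logistic fits only

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.se = np.asarray(self.se, dtype=np.float64)
        self.n = np.asarray(self.n, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")
        if np.any(self.n < 2):
            raise ValueError("per-variant sample sizes must be >= 2")

    @property
    def m(self) -> int:
        return len(self.ids)

    def subset(self, idx) -> "SummaryStats":
        idx = np.asarray(idx)
        kw = {}
        if self.converged is not None:
            kw["converged"] = self.converged[idx]
        return SummaryStats(self.ids[idx], self.chrom[idx], self.pos[idx],
                            self.a1[idx], self.a2[idx], self.freq[idx],
                            self.beta[idx], self.se[idx], self.n[idx],
                            self.p[idx], **kw)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "id": self.ids, "chrom": self.chrom, "pos": self.pos,
            "a1": self.a1, "a2": self.a2, "freq": self.freq,
            "beta": self.beta, "se": self.se, "n": self.n, "p": self.p,
        })
        if self.converged is not None:
            df["converged"] = self.converged.astype(int)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SummaryStats":
        missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"summary-statistic table is missing columns {missing}")
        kw = {}
        if "converged" in df.columns:
            kw["converged"] = df["converged"].to_numpy(dtype=bool)
        return cls(
            ids=df["id"].to_numpy(dtype=object),
            chrom=df["chrom"].astype(str).to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            a1=df["a1"].astype(str).to_numpy(dtype=object),
            a2=df["a2"].astype(str).to_numpy(dtype=object),
            freq=df["freq"].to_numpy(dtype=np.float64),
            beta=df["beta"].to_numpy(dtype=np.float64),
            se=df["se"].to_numpy(dtype=np.float64),
            n=df["n"].to_numpy(dtype=np.float64),
            p=df["p"].to_numpy(dtype=np.float64),
            **kw,
        )

    @classmethod
    def read_tsv(cls, path) -> "SummaryStats":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class LDMatrix:
    """Signed Pearson correlation matrix, dense (per region) or banded.

    Banded layout: ``values[i, half_bandwidth + (j - i)] = r_ij`` for
    ``|j - i| <= half_bandwidth``; entries beyond the band are implicitly 0.
    """

    ids: np.ndarray
    values: np.ndarray
    half_bandwidth: Optional[int] = None   # None => dense m x m

    @property
    def m(self) -> int:
        return len(self.ids)

    @property
    def is_banded(self) -> bool:
        return self.half_bandwidth is not None

    def dense(self) -> np.ndarray:
        """Materialize the full m x m matrix (use only for modest m)."""
        if not self.is_banded:
            return self.values
        m, hb = self.m, self.half_bandwidth
        out = np.zeros((m, m))
        for d in range(-hb, hb + 1):
            col = hb + d
            i = np.arange(max(0, -d), min(m, m - d))
            out[i, i + d] = self.values[i, col]
        return out

    def subset(self, idx) -> "LDMatrix":
        if self.is_banded:
            raise ValueError("subset of a banded LD matrix is not supported; "
                             "slice a dense region instead")
        idx = np.asarray(idx)
        return LDMatrix(ids=self.ids[idx], values=self.values[np.ix_(idx, idx)])

    def write_tsv(self, path) -> None:
        if self.is_banded:
            m, hb = self.m, self.half_bandwidth
            rows = []
            for d in range(0, hb + 1):
                i = np.arange(0, m - d)
                r = self.values[i, hb + d]
                rows.append(pd.DataFrame({"id_i": self.ids[i], "id_j": self.ids[i + d], "r": r}))
            pd.concat(rows).to_csv(path, sep="\t", index=False)
        else:
            pd.DataFrame(self.values, columns=list(self.ids)).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        """Read a dense LD TSV written by :meth:`write_tsv`."""
        df = pd.read_csv(path, sep="\t")
        return cls(ids=np.array(df.columns, dtype=object), values=df.to_numpy(dtype=np.float64))


@dataclass
class SuffStats:
    """Reconstructed cross-products for the joint model (dense or banded XtX)."""

    XtX: np.ndarray
    Xty: np.ndarray
    D: np.ndarray
    n_effective: float
    half_bandwidth: Optional[int] = None

    @property
    def m(self) -> int:
        return len(self.Xty)


# ---------------------------------------------------------------------------
# GWAS

def gwas_linear(W: ScaledDesign, y: np.ndarray) -> SummaryStats:
    """Single-SNP ordinary least squares of y on each scaled genotype column.

    No covariates; an intercept is implicit (y is centered internally, the
    columns of W are centered by construction).  Returns the marginal slope,
    its standard error and a two-sided p-value from the t distribution with
    n - 2 degrees of freedom.
    """
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    n, m = W.n, W.m
    yc = y - y.mean()
    # keep W's dtype in the products (a float32 design stays float32-sized)
    wtw = np.einsum("ij,ij->j", W.W, W.W).astype(np.float64)
    if np.any(wtw == 0.0):
        j = int(np.nonzero(wtw == 0.0)[0][0])
        raise ValueError(f"zero-variance genotype column {W.ids[j]!r} (index {j})")
    wty = (W.W.T @ yc.astype(W.W.dtype, copy=False)).astype(np.float64)
    beta = wty / wtw
    yty = yc @ yc
    # per-variant residual variance of the single-SNP fit
    rss = np.maximum(yty - beta * wty, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(np.maximum(sigma2 / wtw, np.finfo(float).tiny))
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return SummaryStats(ids=W.ids, chrom=W.chrom, pos=W.positions, a1=W.a1, a2=W.a2,
                        freq=W.freqs, beta=beta, se=se,
                        n=np.full(m, float(n)), p=p)


def gwas_logistic(W: ScaledDesign, labels: np.ndarray, max_iter: int = 30,
                  tol: float = 1e-8, chunk: int = 512) -> SummaryStats:
    """Single-SNP logistic regression (intercept + slope) per variant.

    Newton-Raphson on the two-parameter model, vectorized across variants in
    chunks.  Effects are on the log-odds scale per scaled dosage.  Variants
    whose fit does not converge, or that show quasi-separation (diverging
    slope), are flagged via ``converged`` rather than raising.
    """
    yb = np.asarray(labels, dtype=np.float64)
    if set(np.unique(yb)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if yb.min() == yb.max():
        raise ValueError("both classes must be present")
    n, m = W.n, W.m
    beta = np.empty(m)
    se = np.empty(m)
    conv = np.ones(m, dtype=bool)
    base = np.log(yb.mean() / (1.0 - yb.mean()))
    for s in range(0, m, chunk):
        X = W.W[:, s:s + chunk].astype(np.float64)
        c = X.shape[1]
        b0 = np.full(c, base)
        b1 = np.zeros(c)
        active = np.ones(c, dtype=bool)
        for _ in range(max_iter):
            eta = b0 + X * b1
            mu = 1.0 / (1.0 + np.exp(-eta))
            wgt = mu * (1.0 - mu)
            g0 = (yb[:, None] - mu).sum(axis=0)
            g1 = (X * (yb[:, None] - mu)).sum(axis=0)
            s0 = wgt.sum(axis=0)
            s1 = (wgt * X).sum(axis=0)
            s2 = (wgt * X * X).sum(axis=0)
            det = s0 * s2 - s1 * s1
            bad = det <= 1e-12
            det = np.where(bad, 1.0, det)
            d0 = (s2 * g0 - s1 * g1) / det
            d1 = (-s1 * g0 + s0 * g1) / det
            d0 = np.where(bad | ~active, 0.0, d0)
            d1 = np.where(bad | ~active, 0.0, d1)
            b0 += d0
            b1 += d1
            active &= np.maximum(np.abs(d0), np.abs(d1)) > tol
            if not active.any():
                break
        eta = b0 + X * b1
        mu = 1.0 / (1.0 + np.exp(-eta))
        wgt = mu * (1.0 - mu)
        s0 = wgt.sum(axis=0)
        s1 = (wgt * X).sum(axis=0)
        s2 = (wgt * X * X).sum(axis=0)
        det = np.maximum(s0 * s2 - s1 * s1, 1e-300)
        var1 = s0 / det
        ok = ~active & (np.abs(b1) < 20.0) & np.isfinite(var1) & (var1 > 0)
        beta[s:s + c] = b1
        se[s:s + c] = np.sqrt(np.where(var1 > 0, var1, np.nan))
        conv[s:s + c] = ok
    se = np.where(np.isfinite(se) & (se > 0), se, 1e6)  # flagged variants get inert SE
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return SummaryStats(ids=W.ids, chrom=W.chrom, pos=W.positions, a1=W.a1, a2=W.a2,
                        freq=W.freqs, beta=beta, se=se,
                        n=np.full(m, float(n)), p=p, converged=conv)


# ---------------------------------------------------------------------------
# LD

def compute_ld(W: ScaledDesign, half_bandwidth: Optional[int] = None,
               subsample_n: Optional[int] = None, seed: int = 0) -> LDMatrix:
    """Signed Pearson LD among the columns of W.

    Dense by default; with ``half_bandwidth`` only correlations within the
    band are stored (genome-wide sliding-window layout: a window of
    2 * hb + 1 SNPs shifting one SNP at a time corresponds to hb = 1999 for
    the conventional 2000-SNP window).  ``subsample_n`` computes LD on a
    seeded random subset of individuals, as is common for reference panels.
    """
    if W.n < 2:
        raise ValueError("need at least 2 samples to compute LD")
    X = W.W
    if subsample_n is not None and subsample_n < W.n:
        rows = np.random.default_rng(seed).choice(W.n, size=subsample_n, replace=False)
        X = X[rows]
    n = X.shape[0]
    mu = X.mean(axis=0, dtype=np.float64)
    sd = np.sqrt(np.einsum("ij,ij->j", X, X).astype(np.float64) / n - mu**2)
    if np.any(sd == 0):
        j = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"zero-variance column {W.ids[j]!r} in LD computation")
    if half_bandwidth is None:
        # blockwise over rows: avoids a full standardized copy of X
        m = X.shape[1]
        B = np.zeros((m, m))
        blk = max(1, int(2**26 // max(m, 1)))
        for s in range(0, n, blk):
            Xc = (X[s:s + blk] - mu.astype(X.dtype)) / sd.astype(X.dtype)
            B += Xc.T @ Xc
        B /= n
        np.fill_diagonal(B, 1.0)
        B = np.clip((B + B.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(B, 1.0)
        return LDMatrix(ids=W.ids, values=B)
    hb = int(half_bandwidth)
    m = X.shape[1]
    Xc = (X - mu) / sd
    band = np.zeros((m, 2 * hb + 1))
    band[:, hb] = 1.0
    for d in range(1, hb + 1):
        if d >= m:
            break
        r = np.einsum("ij,ij->j", Xc[:, :-d], Xc[:, d:]) / n
        r = np.clip(r, -1.0, 1.0)
        band[: m - d, hb + d] = r
        band[d:, hb - d] = r
    return LDMatrix(ids=W.ids, values=band, half_bandwidth=hb)


# ---------------------------------------------------------------------------
# Eq. X'X = D^0.5 B D^0.5, X'y = D b~

def reconstruct_suffstats(ss: SummaryStats, B: LDMatrix, scaled: bool = True) -> SuffStats:
    """Rebuild X'X and X'y from marginal effects and LD.

    ``scaled=True`` assumes genotypes centered AND scaled to unit variance
    (D_i = n_i); ``scaled=False`` assumes centered only
    (D_i = 1 / (se_i^2 + b~_i^2 / n_i)).
    """
    if len(ss.ids) != len(B.ids) or not np.array_equal(np.asarray(ss.ids), np.asarray(B.ids)):
        mism = _first_mismatch(ss.ids, B.ids)
        raise ValueError(f"summary statistics and LD matrix are misaligned: {mism}")
    if scaled:
        D = ss.n.astype(np.float64)
    else:
        D = 1.0 / (ss.se**2 + ss.beta**2 / ss.n)
    sqrtD = np.sqrt(D)
    Xty = D * ss.beta
    if B.is_banded:
        hb = B.half_bandwidth
        m = B.m
        XtX = np.zeros_like(B.values)
        for d in range(-hb, hb + 1):
            col = hb + d
            i = np.arange(max(0, -d), min(m, m - d))
            XtX[i, col] = sqrtD[i] * B.values[i, col] * sqrtD[i + d]
        return SuffStats(XtX=XtX, Xty=Xty, D=D,
                         n_effective=float(np.median(ss.n)), half_bandwidth=hb)
    XtX = (sqrtD[:, None] * B.values) * sqrtD[None, :]
    return SuffStats(XtX=XtX, Xty=Xty, D=D, n_effective=float(np.median(ss.n)))


def _first_mismatch(a, b):
    a, b = np.asarray(a), np.asarray(b)
    if len(a) != len(b):
        return f"lengths differ ({len(a)} vs {len(b)})"
    bad = np.nonzero(a != b)[0]
    j = int(bad[0])
    return f"first mismatch at index {j}: {a[j]!r} vs {b[j]!r}"
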