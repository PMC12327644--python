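"""Genotype simulation with tunable banded LD, and genotype scaling.

Genotypes are simulated as two haplotypes per individual.  Each haplotype is
a first-order autoregressive Gaussian latent process along the chromosome,
thresholded at the per-variant effect-allele frequency, so the allele at
variant ``j`` is ``1`` with probability ``p_j`` and adjacent variants are
positively correlated with a strength controlled by ``ld_rho``.  This yields
the blocky, banded LD structure that region-wide and banded genome-wide
fine-mapping operate on.  It is an emulator of real cohort LD, not a
population-genetic model.

Scaling follows the standard centered-and-scaled coding

    w_i = (x_i - 2 p_i) / sqrt(2 p_i (1 - p_i))

where ``x_i`` is the effect-allele count (0, 1 or 2) and ``p_i`` the
effect-allele frequency.  With in-sample frequencies and population-variance
normalisation each column of W has mean 0 and variance 1 exactly, which makes
the summary-statistic reconstruction of X'X and X'y exact (see ``assoc``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "ScaledDesign",
    "simulate_genotypes",
    "scale_genotypes",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_variant_table",
]

#: Default lower bound of the simulated minor-allele-frequency spectrum,
#: mirroring the common QC exclusion of variants with MAF < 0.01.
DEFAULT_MAF_FLOOR = 0.01


@dataclass
class GenotypeMatrix:
    """n x m matrix of effect-allele counts with variant metadata.

    Attributes
    ----------
    counts : ndarray of int8, shape (n, m)
        Allele dosages in {0, 1, 2}.
    ids : ndarray of str, shape (m,)
        Variant identifiers.
    chrom : ndarray of str, shape (m,)
        Chromosome label per variant.
    positions : ndarray of int, shape (m,)
        1-based basepair coordinates, strictly increasing within a chromosome.
    freqs : ndarray of float, shape (m,)
        Effect-allele frequency in (0, 1) (generating frequency for simulated
        data, or an external estimate for loaded data).
    a1, a2 : ndarray of str
        Effect and other allele labels.
    """

    counts: np.ndarray
    ids: np.ndarray
    chrom: np.ndarray
    positions: np.ndarray
    freqs: np.ndarray
    a1: np.ndarray = None
    a2: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        m = self.counts.shape[1]
        if self.a1 is None:
            self.a1 = np.full(m, "A", dtype=object)
        if self.a2 is None:
            self.a2 = np.full(m, "G", dtype=object)

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def sample_freqs(self) -> np.ndarray:
        """In-sample effect-allele frequencies, mean(x)/2 per column."""
        return self.counts.mean(axis=0, dtype=np.float64) / 2.0


@dataclass
class ScaledDesign:
    """Centered-and-scaled genotype design matrix W (columns mean 0, var 1)."""

    W: np.ndarray
    ids: np.ndarray
    chrom: np.ndarray
    positions: np.ndarray
    freqs: np.ndarray
    a1: np.ndarray = None
    a2: np.ndarray = None

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.W.shape[1]

    def subset(self, idx) -> "ScaledDesign":
        """Column subset; contiguous index windows are returned as views."""
        idx = np.asarray(idx)
        if len(idx) > 0 and np.all(np.diff(idx) == 1):
            idx = slice(int(idx[0]), int(idx[-1]) + 1)
            return ScaledDesign(
                W=self.W[:, idx],
                ids=self.ids[idx],
                chrom=self.chrom[idx],
                positions=self.positions[idx],
                freqs=self.freqs[idx],
                a1=self.a1[idx] if self.a1 is not None else None,
                a2=self.a2[idx] if self.a2 is not None else None,
            )
        return ScaledDesign(
            W=self.W[:, idx],
            ids=self.ids[idx],
            chrom=self.chrom[idx],
            positions=self.positions[idx],
            freqs=self.freqs[idx],
            a1=self.a1[idx] if self.a1 is not None else None,
            a2=self.a2[idx] if self.a2 is not None else None,
        )


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple = (DEFAULT_MAF_FLOOR, 0.49),
    ld_rho: float = 0.0,
    seed: int = 0,
    chrom: str = "1",
    bp_spacing: int = 1000,
) -> GenotypeMatrix:
    """Simulate an LD-structured genotype matrix.

    Two haplotypes per individual are drawn from an AR(1) latent Gaussian
    process along variants (lag-one correlation ``ld_rho``) and thresholded at
    ``Phi^{-1}(p_j)``, so each haplotype carries the effect allele at variant
    ``j`` with probability ``p_j`` and adjacent-variant genotype correlation
    increases monotonically with ``ld_rho``.

    Parameters
    ----------
    n, m : int
        Sample and variant counts (n >= 2, m >= 1).
    maf_range : (lo, hi)
        Effect-allele frequencies are drawn uniformly in [lo, hi];
        requires 0 < lo <= hi < 0.5.
    ld_rho : float in [0, 1)
        Latent autoregressive correlation; 0 gives independent variants.
    seed : int
        Reproducibility seed.
    """
    if n < 2 or m < 1:
        raise ValueError(f"need n >= 2 and m >= 1, got n={n}, m={m}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi < 0.5, got {maf_range}")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError(f"ld_rho must be in [0, 1), got {ld_rho}")

    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=m)
    thresh = stats.norm.ppf(freqs)

    counts = np.empty((n, m), dtype=np.int8)
    innov = np.sqrt(1.0 - ld_rho**2)
    # Sequential AR(1) over variants; only the previous latent column is kept,
    # so memory stays at O(n) beyond the int8 dosage matrix.  Updates are
    # in-place to avoid per-column temporaries at large n.
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    b1 = np.empty(n, dtype=np.int8)
    b2 = np.empty(n, dtype=np.int8)

    def fill(j):
        np.less(z1, thresh[j], out=b1.view(bool))
        np.less(z2, thresh[j], out=b2.view(bool))
        np.add(b1, b2, out=counts[:, j])

    fill(0)
    for j in range(1, m):
        for z in (z1, z2):
            eps = rng.standard_normal(n)
            z *= ld_rho
            eps *= innov
            z += eps
        fill(j)

    ids = np.array([f"{chrom}:snp{j}" for j in range(m)], dtype=object)
    positions = 1 + bp_spacing * np.arange(m, dtype=np.int64)
    chrom_arr = np.full(m, chrom, dtype=object)
    return GenotypeMatrix(counts=counts, ids=ids, chrom=chrom_arr,
                          positions=positions, freqs=freqs)


def scale_genotypes(
    G: GenotypeMatrix,
    use_sample_freq: bool = True,
    dtype=np.float64,
) -> ScaledDesign:
    """Center and scale genotypes: w_i = (x_i - 2 p_i)/sqrt(2 p_i (1 - p_i)).

    With ``use_sample_freq`` the allele frequencies are re-estimated from G
    and columns are additionally normalised by their in-sample standard
    deviation (population variance), which makes each column exactly mean 0,
    variance 1 — the convention under which the per-variant weight in the
    summary-statistic reconstruction is simply the sample size.

    Without it, the stored (expected) frequencies are used and columns are
    only approximately standardised.

    ``dtype`` may be lowered to float32 for very large n*m.
    """
    x = G.counts
    if use_sample_freq:
        p = x.mean(axis=0, dtype=np.float64) / 2.0
        mono = (p <= 0.0) | (p >= 1.0)
        if mono.any():
            j = int(np.nonzero(mono)[0][0])
            raise ValueError(
                f"monomorphic variant {G.ids[j]!r} (column {j}, sample freq "
                f"{p[j]:g}) cannot be scaled"
            )
        W = x.astype(dtype, copy=True)
        W -= (2.0 * p).astype(dtype)
        # exact in-sample standardisation (population sd); accumulate the
        # column sums of squares blockwise in float64 to avoid a full upcast
        n = W.shape[0]
        ssq = np.zeros(W.shape[1])
        blk = max(1, int(2**25 // max(W.shape[1], 1)))
        for s in range(0, n, blk):
            chunk = W[s:s + blk].astype(np.float64, copy=False)
            ssq += np.einsum("ij,ij->j", chunk, chunk)
        sd = np.sqrt(ssq / n)
        if np.any(sd == 0.0):
            j = int(np.nonzero(sd == 0.0)[0][0])
            raise ValueError(f"zero-variance variant {G.ids[j]!r} (column {j})")
        W /= sd.astype(dtype)
    else:
        p = np.asarray(G.freqs, dtype=np.float64)
        if np.any((p <= 0.0) | (p >= 1.0)):
            j = int(np.nonzero((p <= 0.0) | (p >= 1.0))[0][0])
            raise ValueError(f"variant {G.ids[j]!r} has frequency {p[j]:g} outside (0,1)")
        W = x.astype(dtype, copy=True)
        W -= (2.0 * p).astype(dtype)
        W /= np.sqrt(2.0 * p * (1.0 - p)).astype(dtype)
    return ScaledDesign(W=W, ids=G.ids, chrom=G.chrom, positions=G.positions,
                        freqs=p, a1=G.a1, a2=G.a2)


# ---------------------------------------------------------------------------
# plain-text container I/O

def write_genotypes_tsv(G: GenotypeMatrix, path, sample_ids=None) -> None:
    """Write dosages as TSV: one row per sample, variant ids as columns."""
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(G.n)]
    df = pd.DataFrame(G.counts, columns=list(G.ids))
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False)


def write_variant_table(G: GenotypeMatrix, path) -> None:
    """PLINK .bim-like variant table: chrom, id, pos, a1, a2, freq."""
    pd.DataFrame({
        "chrom": G.chrom, "id": G.ids, "pos": G.positions,
        "a1": G.a1, "a2": G.a2, "freq": G.freqs,
    }).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path, variant_table=None) -> GenotypeMatrix:
    """Read a genotype TSV written by :func:`write_genotypes_tsv`."""
    df = pd.read_csv(path, sep="\t")
    ids = np.array(df.columns[1:], dtype=object)
    counts = df.iloc[:, 1:].to_numpy(dtype=np.int8)
    m = len(ids)
    if variant_table is not None:
        vt = pd.read_csv(variant_table, sep="\t")
        vt = vt.set_index("id").loc[ids].reset_index()
        chrom = vt["chrom"].astype(str).to_numpy(dtype=object)
        positions = vt["pos"].to_numpy(dtype=np.int64)
        freqs = vt["freq"].to_numpy(dtype=np.float64)
        a1 = vt["a1"].astype(str).to_numpy(dtype=object)
        a2 = vt["a2"].astype(str).to_numpy(dtype=object)
    else:
        chrom = np.full(m, "1", dtype=object)
        positions = 1 + 1000 * np.arange(m, dtype=np.int64)
        freqs = counts.mean(axis=0, dtype=np.float64) / 2.0
        a1 = a2 = None
    return GenotypeMatrix(counts=counts, ids=ids, chrom=chrom,
                          positions=positions, freqs=freqs, a1=a1, a2=a2)
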