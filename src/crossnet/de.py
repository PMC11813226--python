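"""Simplified negative-binomial differential expression.

A deliberately small stand-in for the full DESeq2 machinery: median-of-
ratios size factors, per-gene method-of-moments dispersion (pooled within
groups, floored), a Wald test on the log mean ratio, and BH adjustment.
Dispersion shrinkage, Cook's filtering and independent filtering are not
reproduced, so DEG counts on real data will differ from tool-exact runs;
the null behaviour of this test is verified by simulation instead.

Also provides TPM, a log2 variance-stabilizing surrogate, and sample PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import CountDataset
from .stats import bh_adjust

LN2 = np.log(2.0)


@dataclass
class ContrastSpec:
    """A pairwise contrast ``numerator_group`` vs ``denominator_group``."""

    name: str
    numerator_group: str
    denominator_group: str

    def __post_init__(self):
        if self.numerator_group == self.denominator_group:
            raise ValueError("contrast groups must be distinct")


@dataclass
class ContrastResult:
    """Per-gene table for one contrast.

    ``table`` columns: log2fc, se (natural-log scale), wald_z, p, padj,
    mean_norm_count. ``excluded`` lists all-zero genes that were not tested.
    """

    spec: ContrastSpec
    table: pd.DataFrame
    excluded: list = field(default_factory=list)

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]


@dataclass
class DEGSets:
    """Up/down DEG id-sets at ``padj < alpha`` split by log2FC sign."""

    up: set
    down: set
    alpha: float
    background_n: int

    @property
    def all(self) -> set:
        return self.up | self.down


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios normalization factors.

    The reference is the per-gene geometric mean over genes positive in all
    samples; factor_j is the median ratio counts[g, j] / reference[g].
    If no gene is positive in every sample, raises unless
    ``pseudo_reference=True``, which falls back to a 0.5-pseudo-count
    geometric mean over all genes.
    """
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if allpos.any():
        ref = np.exp(np.log(x[allpos]).mean(axis=1))
        ratios = x[allpos] / ref[:, None]
    elif pseudo_reference:
        xp = x + 0.5
        ref = np.exp(np.log(xp).mean(axis=1))
        ratios = xp / ref[:, None]
    else:
        raise ValueError(
            "no gene has positive counts in every sample; "
            "retry with pseudo_reference=True"
        )
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def _group_stats(y: np.ndarray):
    """Mean and unbiased variance across columns."""
    m = y.mean(axis=1)
    v = y.var(axis=1, ddof=1)
    return m, v


def nb_wald_contrast(ds: CountDataset, spec: ContrastSpec, alpha: float = 0.01,
                     dispersion_floor: float = 1e-8):
    """NB Wald test of ``spec`` on one tissue.

    Per gene: normalized counts, group means m1 (numerator) / m0
    (denominator), shared method-of-moments dispersion pooled within the two
    groups, log2FC = log2(m1/m0) with a 0.5 pseudo offset on zero group
    means, delta-method SE of the log mean ratio, two-sided normal p and BH
    adjustment. All-zero genes are excluded and recorded.

    Returns ``(ContrastResult, DEGSets)``.
    """
    for g in (spec.numerator_group, spec.denominator_group):
        if (ds.meta["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} absent or has fewer than 2 samples")
    s1 = ds.samples_in_group(spec.numerator_group)
    s0 = ds.samples_in_group(spec.denominator_group)
    sub = ds.counts[list(s1) + list(s0)]
    sf = size_factors(sub, pseudo_reference=True)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    n1, n0 = len(s1), len(s0)
    y1, y0 = norm[:, :n1], norm[:, n1:]

    tested = (sub.to_numpy().sum(axis=1) > 0)
    excluded = list(sub.index[~tested])

    m1, v1 = _group_stats(y1)
    m0, v0 = _group_stats(y0)
    pooled_var = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    mbar = (n1 * m1 + n0 * m0) / (n1 + n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.maximum((pooled_var - mbar) / mbar**2, dispersion_floor)
        a1 = np.where(m1 > 0, m1, 0.5)
        a0 = np.where(m0 > 0, m0, 0.5)
        log2fc = np.log2(a1 / a0)
        se = np.sqrt((1.0 / a1 + phi) / n1 + (1.0 / a0 + phi) / n0)
        z = log2fc * LN2 / se
    # t reference with the dispersion-estimation df: the plug-in SE makes the
    # Wald statistic t-like at small n; a normal reference is anticonservative
    p = 2.0 * sps.t.sf(np.abs(z), df=n1 + n0 - 2)
    p = np.where(tested, p, np.nan)
    padj = bh_adjust(np.where(tested, p, np.nan))

    table = pd.DataFrame(
        {
            "log2fc": np.where(tested, log2fc, np.nan),
            "se": np.where(tested, se, np.nan),
            "wald_z": np.where(tested, z, np.nan),
            "p": p,
            "padj": padj,
            "mean_norm_count": norm.mean(axis=1),
        },
        index=sub.index,
    )
    sig = table.index[(table["padj"] < alpha).fillna(False)]
    up = set(sig[table.loc[sig, "log2fc"] > 0])
    down = set(sig[table.loc[sig, "log2fc"] < 0])
    degs = DEGSets(up=up, down=down, alpha=alpha, background_n=int(tested.sum()))
    return ContrastResult(spec=spec, table=table, excluded=excluded), degs


def tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million. Each column sums to 1e6 (unless all-zero)."""
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for every gene")
    rate = counts.div(lengths / 1000.0, axis=0)
    denom = rate.sum(axis=0)
    return rate.div(denom.replace(0, np.nan), axis=1).fillna(0.0) * 1e6


def vst_surrogate(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1); a stand-in for the parametric VST."""
    if (np.asarray(factors) <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts.div(factors, axis=1) + 1.0)


def pca_coords(matrix: pd.DataFrame, n_components: int = 2):
    """Sample coordinates on the top principal components.

    ``matrix`` is features x samples; rows are centered. Returns
    ``(coords: samples x components DataFrame, variance_fractions)``.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncating")
        n_components = rank
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    coords = pd.DataFrame(
        (vt[:n_components].T * s[:n_components]),
        index=matrix.columns,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return coords, frac[:n_components]
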