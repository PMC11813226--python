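"""Tissue-specific co-expression networks and module analysis.

Pipeline: filter lowly-expressed genes on mean TPM; all-pairs Spearman
correlation over the tissue's samples (all groups pooled); BH across all
tested pairs; keep positive, FDR-significant pairs and of those the top
decile by correlation ("edge" interpretation of the top-10% rule); Leiden
modularity communities on the rho-weighted graph; discard communities
below the minimum size; summarize each module by its eigengene, the first
principal component of the gene-standardized module submatrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import logging

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

from .de import DEGSets
from .stats import bh_adjust, hypergeom_overlap


@dataclass
class CoexprNetwork:
    """Undirected positive-correlation network; edges canonical i < j."""

    nodes: list
    edges: pd.DataFrame  # columns gene_i, gene_j, rho, p, q
    tissue: str
    n_candidate_edges: int = 0
    n_constant_pairs_excluded: int = 0


@dataclass
class Module:
    id: str
    genes: set
    eigengene: Optional[pd.Series] = None
    var_explained: Optional[float] = None


@dataclass
class ModuleSet:
    tissue: str
    modules: list = field(default_factory=list)
    unassigned: set = field(default_factory=set)

    def __getitem__(self, module_id: str) -> Module:
        for m in self.modules:
            if m.id == module_id:
                return m
        raise KeyError(module_id)

    @property
    def sizes(self):
        return {m.id: len(m.genes) for m in self.modules}


def filter_low_expression(tpm_matrix: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Genes whose mean TPM across the tissue's samples is >= threshold."""
    keep = tpm_matrix.index[tpm_matrix.mean(axis=1) >= threshold]
    if len(keep) == 0:
        raise ValueError("all genes fall below the expression threshold")
    return keep


def _spearman_matrix(x: np.ndarray):
    """Pairwise Spearman rho over rows of ``x`` plus two-sided p (t reference)."""
    n = x.shape[1]
    ranks = sps.rankdata(x, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), np.nan, np.where(np.abs(rho) >= 1.0, 0.0, p))
    return rho, p


def build_network(expr: pd.DataFrame, tissue: str = "tissue", fdr: float = 0.05,
                  top_frac: float = 0.10, top_frac_basis: str = "all_pairs") -> CoexprNetwork:
    """Build the retained-edge co-expression network of one tissue.

    All gene pairs are tested (Spearman); BH is applied across every tested
    pair; candidate edges are positive correlations with q < ``fdr``; of
    those, the strongest are retained by descending rho, ties broken by
    canonical (gene_i, gene_j) order. ``top_frac_basis`` sets what the
    top-``top_frac`` cut is a fraction *of*: ``"all_pairs"`` (default)
    keeps up to ``top_frac * n_tested_pairs`` edges, so the FDR filter is
    the binding constraint whenever fewer than that fraction of pairs is
    significant; ``"candidates"`` keeps ``top_frac * n_candidates``, a
    strictly harsher cut. Pairs involving a constant gene have undefined
    rho and are excluded (counted).
    """
    if top_frac_basis not in ("all_pairs", "candidates"):
        raise ValueError("top_frac_basis must be 'all_pairs' or 'candidates'")
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples to build a network")
    genes = list(expr.index)
    x = expr.to_numpy(dtype=float)
    constant = x.std(axis=1) == 0
    rho, p = _spearman_matrix(x)
    iu, ju = np.triu_indices(len(genes), k=1)
    rho_u, p_u = rho[iu, ju], p[iu, ju]
    bad = constant[iu] | constant[ju] | np.isnan(rho_u)
    q = bh_adjust(np.where(bad, np.nan, p_u))
    cand = (~bad) & (rho_u > 0) & (q < fdr)
    n_cand = int(cand.sum())
    n_basis = n_cand if top_frac_basis == "candidates" else int((~bad).sum())
    n_keep = min(n_cand, int(np.floor(top_frac * n_basis)))
    logger.info("network %s: %d tested pairs, %d candidates, retaining %d edges "
                "(top_frac=%.3g basis=%s, fdr=%.3g)",
                tissue, int((~bad).sum()), n_cand, n_keep, top_frac, top_frac_basis, fdr)
    idx = np.flatnonzero(cand)
    # sort by descending rho, ties by canonical pair order (i then j ascending)
    order = np.lexsort((ju[idx], iu[idx], -rho_u[idx]))
    keep = idx[order][:n_keep]
    edges = pd.DataFrame(
        {
            "gene_i": [genes[i] for i in iu[keep]],
            "gene_j": [genes[j] for j in ju[keep]],
            "rho": rho_u[keep],
            "p": p_u[keep],
            "q": q[keep],
        }
    )
    return CoexprNetwork(
        nodes=genes,
        edges=edges,
        tissue=tissue,
        n_candidate_edges=n_cand,
        n_constant_pairs_excluded=int(bad.sum()),
    )


def detect_modules(net: CoexprNetwork, expr: Optional[pd.DataFrame] = None,
                   min_size: int = 30, seed: int = 0) -> ModuleSet:
    """Leiden modularity communities on the rho-weighted retained graph.

    Communities smaller than ``min_size`` go to ``unassigned``. Modules are
    labelled ``{tissue}.M{k}`` by descending size (M0 largest). If ``expr``
    is given, eigengenes are computed for each module.
    """
    mods = ModuleSet(tissue=net.tissue)
    if net.edges.empty:
        mods.unassigned = set(net.nodes)
        return mods
    used = sorted(set(net.edges["gene_i"]) | set(net.edges["gene_j"]))
    index = {g: i for i, g in enumerate(used)}
    g = ig.Graph(
        n=len(used),
        edges=[(index[a], index[b]) for a, b in zip(net.edges["gene_i"], net.edges["gene_j"])],
    )
    g.es["weight"] = list(net.edges["rho"])
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition, weights="weight", seed=int(seed)
    )
    communities = sorted((list(c) for c in part), key=len, reverse=True)
    unassigned = set(net.nodes) - set(used)
    k = 0
    for comm in communities:
        members = {used[i] for i in comm}
        if len(members) < min_size:
            unassigned |= members
            continue
        mod = Module(id=f"{net.tissue}.M{k}", genes=members)
        if expr is not None:
            mod.eigengene, mod.var_explained = eigengene(expr.loc[sorted(members)])
        mods.modules.append(mod)
        k += 1
    mods.unassigned = unassigned
    return mods


def eigengene(expr_submatrix: pd.DataFrame):
    """Module eigengene: PC1 scores of the gene-standardized submatrix.

    Rows are the module's genes, columns samples. The returned per-sample
    vector has unit norm and is oriented to correlate positively with the
    mean standardized module expression. Returns ``(eigengene,
    var_explained)``.
    """
    if expr_submatrix.shape[0] < 2 or expr_submatrix.shape[1] < 3:
        raise ValueError("eigengene needs >=2 genes and >=3 samples")
    x = expr_submatrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).all():
        raise ValueError("constant module submatrix has no eigengene")
    z = (x - mu) / np.where(sd == 0, 1.0, sd)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=expr_submatrix.columns, name="eigengene"), var_explained


def module_deg_enrichment(mods: ModuleSet, deg_sets: dict, background_n: int,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric enrichment of each module in each DEG set.

    ``deg_sets`` maps a contrast name to its :class:`DEGSets`; each module
    is tested against the up and down set of every contrast. Returns a
    long-format table with a ``significant`` flag at p < ``alpha`` (flags
    combine into patterns such as sucrose-up & dose1-down).
    """
    rows = []
    for mod in mods.modules:
        for contrast, degs in deg_sets.items():
            for direction, ids in (("up", degs.up), ("down", degs.down)):
                k = len(mod.genes & ids)
                p = hypergeom_overlap(k, len(ids), len(mod.genes), background_n) if ids else 1.0
                rows.append(
                    {
                        "module": mod.id,
                        "contrast": contrast,
                        "direction": direction,
                        "k": k,
                        "module_size": len(mod.genes),
                        "deg_size": len(ids),
                        "p": p,
                    }
                )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["padj"] = bh_adjust(table["p"])
        table["significant"] = table["p"] < alpha
    return table


def module_patterns(enrichment: pd.DataFrame, sucrose_contrast: str,
                    treatment_contrast: str) -> dict:
    """Classify modules by their enrichment pattern.

    Returns module id -> pattern string; the dual pattern
    ``"sucrose-up/treatment-down"`` marks induced-then-suppressed modules,
    ``"sucrose-down/treatment-up"`` the converse.
    """
    out = {}
    if enrichment.empty:
        return out
    sig = enrichment[enrichment["significant"]]
    for module in enrichment["module"].unique():
        hits = {(r.contrast, r.direction) for r in sig[sig["module"] == module].itertuples()}
        if (sucrose_contrast, "up") in hits and (treatment_contrast, "down") in hits:
            out[module] = "sucrose-up/treatment-down"
        elif (sucrose_contrast, "down") in hits and (treatment_contrast, "up") in hits:
            out[module] = "sucrose-down/treatment-up"
        elif any(c == sucrose_contrast for c, _ in hits):
            out[module] = "sucrose"
        elif any(c == treatment_contrast for c, _ in hits):
            out[module] = "treatment"
        else:
            out[module] = "none"
    return out


@dataclass
class CrossModuleCorr:
    pairs: pd.DataFrame  # module_a, module_b, R, p, padj, significant


def cross_tissue_module_correlation(mods_a: ModuleSet, mods_b: ModuleSet,
                                    animals_a: pd.Series, animals_b: pd.Series,
                                    alpha: float = 0.05) -> CrossModuleCorr:
    """Spearman correlation of inter-tissue module eigengenes.

    Eigengenes are aligned on animal id (``animals_*`` map each tissue's
    sample id to its animal); BH is applied across all tested pairs.
    """
    if mods_a.tissue == mods_b.tissue:
        raise ValueError("modules must come from different tissues")
    shared = sorted(set(animals_a) & set(animals_b))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared animals across tissues")
    sample_of_a = {v: k for k, v in animals_a.items()}
    sample_of_b = {v: k for k, v in animals_b.items()}
    rows = []
    for ma in mods_a.modules:
        ea = ma.eigengene[[sample_of_a[x] for x in shared]].to_numpy()
        for mb in mods_b.modules:
            eb = mb.eigengene[[sample_of_b[x] for x in shared]].to_numpy()
            r, p = sps.spearmanr(ea, eb)
            rows.append({"module_a": ma.id, "module_b": mb.id, "R": float(r), "p": float(p)})
    pairs = pd.DataFrame(rows)
    if not pairs.empty:
        pairs["padj"] = bh_adjust(pairs["p"])
        pairs["significant"] = pairs["padj"] < alpha
    return CrossModuleCorr(pairs=pairs)
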