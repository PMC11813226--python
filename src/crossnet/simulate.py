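"""Synthetic multi-tissue RNA-seq study generator.

Emulates a four-arm dietary-intervention design (control, sucrose,
sucrose + inhibitor dose 1, sucrose + inhibitor dose 2) profiled in
several tissues of the same animals:

* negative-binomial counts with a mean-dependent dispersion trend
  phi(mu) = a0/mu + a1 and log-normal library sizes;
* planted sucrose DEGs (log2 fold changes of both signs) of which a
  configurable fraction is *reversed* by each treatment dose (the treated
  group's mean returns to the control baseline; non-reversed DEGs retain
  the sucrose effect);
* a configurable fraction of DEGs shared between tissues with correlated
  log2FC, supporting cross-tissue concordance analyses;
* planted co-expression modules driven by per-sample latent factors, with
  selected module pairs in different tissues coupled through a shared
  per-animal factor at a target correlation;
* a :class:`GroundTruth` record of everything planted, for recovery tests.

Animal ids are shared across tissues and are the cross-tissue join key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import GROUPS, CountDataset

TISSUES = ("Liver", "vWAT", "SkM", "Brain")


@dataclass
class SimulationConfig:
    """Parameters of the planted study; defaults emulate the four-arm,
    four-tissue design at desk scale.

    Proportions are in [0, 1]; ``n_animals_per_group >= 3``; module sizes
    at least 2. A fixed ``seed`` makes every output byte-identical.
    """

    n_tissues: int = 4
    n_genes_per_tissue: int = 2000
    n_animals_per_group: int = 10
    groups: tuple = GROUPS
    # planted differential expression
    frac_sucrose_deg: float = 0.15
    deg_up_frac: float = 0.6          # sucrose-induced fraction of DEGs (rest repressed)
    lfc_location: float = 1.5
    lfc_scale: float = 0.4
    reversal_frac_d1: float = 0.6
    reversal_frac_d2: float = 0.3
    frac_deg_shared: float = 0.3      # DEGs planted identically (in id) across tissues
    shared_lfc_corr: float = 0.8      # correlation of shared-DEG log2FCs between tissues
    # planted co-expression structure
    n_modules_per_tissue: int = 3
    module_size_range: tuple = (30, 60)
    module_loading: float = 0.9
    module_amplitude: float = 0.5     # log-scale amplitude of loading x factor
    module0_deg_frac: float = 0.8     # fraction of module 0 made of up+reversed DEGs
    n_cross_tissue_pairs: int = 2
    cross_module_corr: float = 0.7
    # noise model
    mean_log: float = np.log(150.0)
    mean_sd: float = 1.0
    dispersion_a0: float = 3.0
    dispersion_a1: float = 0.05
    libsize_log_sd: float = 0.15
    gene_length_kb_log_mean: float = np.log(2.0)
    gene_length_kb_log_sd: float = 0.6
    seed: int = 0

    def validate(self):
        for name in ("frac_sucrose_deg", "deg_up_frac", "reversal_frac_d1",
                     "reversal_frac_d2", "frac_deg_shared", "module0_deg_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if not -1.0 < self.cross_module_corr < 1.0:
            raise ValueError("cross_module_corr must be in (-1, 1)")
        if self.n_animals_per_group < 3:
            raise ValueError("need at least 3 animals per group")
        if self.module_size_range[0] < 2:
            raise ValueError("module sizes must be at least 2")
        if self.n_modules_per_tissue * self.module_size_range[1] > self.n_genes_per_tissue:
            raise ValueError(
                "module sizes exceed gene count: "
                f"{self.n_modules_per_tissue} x {self.module_size_range[1]} > "
                f"{self.n_genes_per_tissue}"
            )
        if self.libsize_log_sd < 0:
            raise ValueError("libsize_log_sd must be nonnegative")
        return self


@dataclass
class GroundTruth:
    """Record of planted structure, keyed by tissue label."""

    deg_up: dict = field(default_factory=dict)       # tissue -> {gene: true lfc > 0}
    deg_down: dict = field(default_factory=dict)     # tissue -> {gene: true lfc < 0}
    reversed_d1: dict = field(default_factory=dict)  # tissue -> set of gene ids
    reversed_d2: dict = field(default_factory=dict)
    module_membership: dict = field(default_factory=dict)  # tissue -> {gene: module idx}
    cross_pairs: list = field(default_factory=list)  # (tissueA, modA, tissueB, modB, rho)
    latent_factors: dict = field(default_factory=dict)  # tissue -> DataFrame module x sample
    shared_deg: list = field(default_factory=list)   # gene ids planted in every tissue

    def validate(self):
        for t in self.deg_up:
            degs = set(self.deg_up[t]) | set(self.deg_down[t])
            if not set(self.reversed_d1.get(t, ())) <= degs:
                raise AssertionError("reversed_d1 not a subset of planted DEGs")
            if not set(self.reversed_d2.get(t, ())) <= degs:
                raise AssertionError("reversed_d2 not a subset of planted DEGs")
        return self

    def to_json(self, path):
        payload = {
            "deg_up": {t: dict(v) for t, v in self.deg_up.items()},
            "deg_down": {t: dict(v) for t, v in self.deg_down.items()},
            "reversed_d1": {t: sorted(v) for t, v in self.reversed_d1.items()},
            "reversed_d2": {t: sorted(v) for t, v in self.reversed_d2.items()},
            "module_membership": {
                t: {g: int(m) for g, m in v.items()}
                for t, v in self.module_membership.items()
            },
            "cross_pairs": [list(p) for p in self.cross_pairs],
            "shared_deg": sorted(self.shared_deg),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _nb_sample(rng, mean, phi):
    """NB draw with Var = mu + phi mu^2 via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    lam = np.where(
        phi > 0, rng.gamma(shape=1.0 / np.maximum(phi, 1e-12), scale=mean * phi), mean
    )
    return rng.poisson(lam)


def simulate_study(config: SimulationConfig):
    """Generate one multi-tissue study.

    Returns ``(datasets, truth)`` where ``datasets`` is a list of
    :class:`CountDataset`, one per tissue sharing animal ids, and ``truth``
    a :class:`GroundTruth`.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    tissues = [TISSUES[i] if i < len(TISSUES) else f"Tissue{i}" for i in range(cfg.n_tissues)]
    n_per = cfg.n_animals_per_group
    animals = [f"R{idx:03d}" for idx in range(len(cfg.groups) * n_per)]
    animal_group = {a: cfg.groups[i // n_per] for i, a in enumerate(animals)}
    genes = [f"g{i:05d}" for i in range(cfg.n_genes_per_tissue)]

    truth = GroundTruth()

    # --- planted module gene blocks (disjoint, at the head of the gene list)
    sizes = {}
    for t in tissues:
        sizes[t] = rng.integers(
            cfg.module_size_range[0], cfg.module_size_range[1] + 1,
            size=cfg.n_modules_per_tissue,
        )
        start, membership = 0, {}
        for m, sz in enumerate(sizes[t]):
            for g in genes[start:start + sz]:
                membership[g] = m
            start += sz
        truth.module_membership[t] = membership

    # --- cross-tissue module couplings: pair module m of tissue 2k with
    # module m of tissue 2k+1 style round-robin over available tissue pairs
    pair_slots = [
        (tissues[i], m, tissues[j], m)
        for m in range(cfg.n_modules_per_tissue)
        for i in range(len(tissues))
        for j in range(i + 1, len(tissues))
    ]
    cross = pair_slots[: cfg.n_cross_tissue_pairs]
    truth.cross_pairs = [(a, ma, b, mb, cfg.cross_module_corr) for a, ma, b, mb in cross]

    # --- shared DEG core, planted identically (by id) in every tissue
    n_deg = int(round(cfg.frac_sucrose_deg * cfg.n_genes_per_tissue))
    n_shared = int(round(cfg.frac_deg_shared * n_deg))
    module_genes_all = {g for t in tissues for g in truth.module_membership[t]}
    free_genes = [g for g in genes if g not in module_genes_all]
    shared_core = list(rng.choice(free_genes, size=n_shared, replace=False)) if n_shared else []
    truth.shared_deg = list(shared_core)
    shared_sign = np.where(rng.random(n_shared) < cfg.deg_up_frac, 1.0, -1.0)
    shared_mag = np.abs(rng.normal(cfg.lfc_location, cfg.lfc_scale, size=n_shared))
    corr = cfg.shared_lfc_corr

    # latent per-animal factors for coupled module pairs
    shared_factor = {
        idx: rng.normal(size=len(animals)) for idx in range(len(cross))
    }

    datasets = []
    for t in tissues:
        sample_ids = [f"{t}_{a}" for a in animals]
        meta = pd.DataFrame(
            {
                "animal_id": animals,
                "tissue": t,
                "group": [animal_group[a] for a in animals],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        baseline = rng.lognormal(cfg.mean_log, cfg.mean_sd, size=len(genes))
        phi = cfg.dispersion_a0 / baseline + cfg.dispersion_a1

        # ---- choose DEGs: shared core + per-tissue extras; module 0 genes
        # preferentially planted as sucrose-up & dose-1-reversed
        lfc = {}
        mod0 = [g for g, m in truth.module_membership[t].items() if m == 0]
        n_mod0_deg = int(round(cfg.module0_deg_frac * len(mod0))) if n_deg else 0
        mod0_deg = list(rng.choice(mod0, size=min(n_mod0_deg, n_deg), replace=False))
        for g in mod0_deg:
            lfc[g] = abs(rng.normal(cfg.lfc_location, cfg.lfc_scale))
        for i, g in enumerate(shared_core):
            if len(lfc) >= n_deg:
                break
            # per-tissue magnitude correlated with the shared magnitude
            z = corr * (shared_mag[i] - cfg.lfc_location) / max(cfg.lfc_scale, 1e-12)
            mag = cfg.lfc_location + cfg.lfc_scale * (
                z + np.sqrt(max(0.0, 1 - corr**2)) * rng.normal()
            )
            lfc[g] = shared_sign[i] * abs(mag)
        remaining = [g for g in genes if g not in lfc and g not in shared_core
                     and g not in mod0]
        n_extra = n_deg - len(lfc)
        if n_extra > 0:
            extras = rng.choice(remaining, size=n_extra, replace=False)
            sign = np.where(rng.random(n_extra) < cfg.deg_up_frac, 1.0, -1.0)
            mag = np.abs(rng.normal(cfg.lfc_location, cfg.lfc_scale, size=n_extra))
            for g, s, m_ in zip(extras, sign, mag):
                lfc[g] = s * m_
        truth.deg_up[t] = {g: v for g, v in lfc.items() if v > 0}
        truth.deg_down[t] = {g: v for g, v in lfc.items() if v < 0}

        # ---- reversal: module-0 DEGs are reversed first under dose 1 so the
        # module carries the up-then-suppressed pattern
        deg_ids = list(lfc)
        n_rev1 = int(round(cfg.reversal_frac_d1 * len(deg_ids)))
        n_rev2 = int(round(cfg.reversal_frac_d2 * len(deg_ids)))
        rest = [g for g in deg_ids if g not in mod0_deg]
        prio = mod0_deg + list(rng.permutation(rest))
        rev1 = set(prio[:n_rev1])
        rev2 = set(rng.choice(deg_ids, size=n_rev2, replace=False)) if n_rev2 else set()
        truth.reversed_d1[t] = rev1
        truth.reversed_d2[t] = rev2

        # ---- per-sample group multiplier
        group_of = meta["group"].to_numpy()
        mult = np.ones((len(genes), len(sample_ids)))
        gidx = {g: i for i, g in enumerate(genes)}
        for g, v in lfc.items():
            fold = 2.0 ** v
            row = gidx[g]
            mult[row, group_of == "sucrose"] *= fold
            if g not in rev1:
                mult[row, group_of == "JNK_D1"] *= fold
            if g not in rev2:
                mult[row, group_of == "JNK_D2"] *= fold

        # ---- module latent factors (per sample = per animal within tissue)
        factors = np.empty((cfg.n_modules_per_tissue, len(sample_ids)))
        for m in range(cfg.n_modules_per_tissue):
            factors[m] = rng.normal(size=len(sample_ids))
        for idx, (ta, ma, tb, mb) in enumerate(cross):
            rho = cfg.cross_module_corr
            if t == ta:
                factors[ma] = shared_factor[idx]
            elif t == tb:
                factors[mb] = (
                    rho * shared_factor[idx]
                    + np.sqrt(1 - rho**2) * rng.normal(size=len(sample_ids))
                )
        truth.latent_factors[t] = pd.DataFrame(
            factors, index=[f"{t}.mod{m}" for m in range(cfg.n_modules_per_tissue)],
            columns=sample_ids,
        )
        for g, m in truth.module_membership[t].items():
            mult[gidx[g]] *= np.exp(
                cfg.module_amplitude * cfg.module_loading * factors[m]
            )

        # ---- library sizes and NB sampling
        libsize = rng.lognormal(0.0, cfg.libsize_log_sd, size=len(sample_ids))
        mean = baseline[:, None] * mult * libsize[None, :]
        counts = _nb_sample(rng, mean, phi[:, None])
        lengths = np.round(
            1000 * rng.lognormal(cfg.gene_length_kb_log_mean, cfg.gene_length_kb_log_sd,
                                 size=len(genes))
        ).astype(int).clip(min=100)
        ds = CountDataset(
            counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                                columns=sample_ids),
            gene_lengths=pd.Series(lengths, index=pd.Index(genes, name="gene_id"),
                                   name="length_bp"),
            meta=meta,
            tissue=t,
        )
        datasets.append(ds)

    return datasets, truth.validate()


def simulate_module_matrix(n_modules=3, module_size=50, n_samples=40, loading=0.9,
                           n_noise_genes=0, seed=0):
    """Gaussian latent-factor expression matrix for network benchmarking.

    Each module gene is ``loading * f_m + sqrt(1 - loading^2) * noise`` for a
    per-sample module factor ``f_m``, so the within-module gene-gene
    correlation is ``loading**2``. Returns ``(DataFrame genes x samples,
    labels)`` with label -1 for noise genes.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    factors = rng.normal(size=(n_modules, n_samples))
    for m in range(n_modules):
        noise = rng.normal(size=(module_size, n_samples))
        rows.append(loading * factors[m] + np.sqrt(1 - loading**2) * noise)
        labels += [m] * module_size
    if n_noise_genes:
        rows.append(rng.normal(size=(n_noise_genes, n_samples)))
        labels += [-1] * n_noise_genes
    mat = np.vstack(rows)
    genes = [f"g{i:05d}" for i in range(mat.shape[0])]
    return (
        pd.DataFrame(mat, index=genes, columns=[f"s{j:03d}" for j in range(n_samples)]),
        np.array(labels),
    )
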