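"""End-to-end orchestration: simulate -> differential expression ->
reversal accounting -> co-expression modules -> gene-set enrichment ->
metabolic activity -> report.

Stages write plain-text artifacts into the run directory and are skipped
on rerun when their outputs already exist and nothing upstream changed;
deleting an intermediate recomputes it and everything downstream. A fixed
config + seed reproduces the report byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import CountDataset, read_dataset, write_dataset
from .de import ContrastSpec, ContrastResult, DEGSets, nb_wald_contrast, tpm
from .enrichment import GeneSetCollection, enrich, read_gmt, write_gmt
from .metabolism import (
    compass_scores, differential_activity, reaction_expression,
    reversal_of_activity, toy_model, write_model,
)
from .network import (
    build_network, cross_tissue_module_correlation, detect_modules,
    filter_low_expression, module_deg_enrichment, module_patterns,
)
from .reversal import cross_tissue_concordance, reversal_fraction, reversal_report
from .simulate import SimulationConfig, simulate_study
from .stats import format_percentage

logger = logging.getLogger(__name__)

CONTRASTS = (
    ContrastSpec("sucrose_vs_control", "sucrose", "control"),
    ContrastSpec("D1_vs_sucrose", "JNK_D1", "sucrose"),
    ContrastSpec("D2_vs_sucrose", "JNK_D2", "sucrose"),
)
STAGES = ("simulate", "diffexpr", "reversal", "coexpr", "enrich", "metab", "report")


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the analysis protocol
    (DEG padj<0.01, edge FDR 0.05 + top decile, module minimum 30 genes,
    module/metabolic alpha 0.05)."""

    outdir: str = "crossnet_run"
    seed: int = 0
    alpha_deg: float = 0.01
    fdr_edge: float = 0.05
    top_frac: float = 0.10
    min_module: int = 30
    alpha_module: float = 0.05
    alpha_metab: float = 0.05
    tpm_threshold: float = 1.0
    compass_w: float = 0.95
    gmt_path: str | None = None
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self):
        for name in ("alpha_deg", "fdr_edge", "top_frac", "alpha_module", "alpha_metab"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must be in (0, 1)")

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(**{"seed": self.seed, **self.simulation})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def _deg_sets_from_table(table: pd.DataFrame, alpha: float) -> DEGSets:
    sig = table.index[(table["padj"] < alpha).fillna(False)]
    return DEGSets(
        up=set(sig[table.loc[sig, "log2fc"] > 0]),
        down=set(sig[table.loc[sig, "log2fc"] < 0]),
        alpha=alpha,
        background_n=int(table["p"].notna().sum()),
    )


class PipelineRun:
    """One pipeline execution rooted at ``config.outdir``."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.root = Path(config.outdir)
        self.root.mkdir(parents=True, exist_ok=True)
        self.stages_run: list[str] = []
        self.tissues: list[str] = []
        self.datasets: dict[str, CountDataset] = {}
        self.truth_json: dict = {}
        self.results: dict[str, ContrastResult] = {}   # "tissue/contrast"
        self.degs: dict[str, DEGSets] = {}
        self.tpm: dict[str, pd.DataFrame] = {}
        self.modules: dict = {}
        self.report: dict = {}

    # ---- stage framework -------------------------------------------------
    def _stage(self, name, outputs, compute, load):
        missing = [p for p in outputs if not Path(p).exists()]
        upstream_ran = bool(self.stages_run)
        if missing or upstream_ran:
            logger.info("stage %s: running (missing=%d upstream_ran=%s)",
                        name, len(missing), upstream_ran)
            try:
                compute()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            self.stages_run.append(name)
        else:
            logger.info("stage %s: outputs present, loading", name)
            load()

    # ---- simulate --------------------------------------------------------
    def _simulate_outputs(self):
        sim = self.cfg.sim_config()
        from .simulate import TISSUES
        tissues = [TISSUES[i] if i < len(TISSUES) else f"Tissue{i}"
                   for i in range(sim.n_tissues)]
        files = [self.root / "ground_truth.json"]
        for t in tissues:
            files += [self.root / f"{t}_counts.tsv", self.root / f"{t}_meta.tsv",
                      self.root / f"{t}_gene_lengths.tsv"]
        return tissues, files

    def _run_simulate(self):
        datasets, truth = simulate_study(self.cfg.sim_config())
        for ds in datasets:
            write_dataset(ds, self.root)
            self.datasets[ds.tissue] = ds
        truth.to_json(self.root / "ground_truth.json")
        self.truth_json = json.loads((self.root / "ground_truth.json").read_text())

    def _load_simulate(self):
        for t in self.tissues:
            self.datasets[t] = read_dataset(self.root, t)
        self.truth_json = json.loads((self.root / "ground_truth.json").read_text())

    # ---- differential expression ----------------------------------------
    def _run_diffexpr(self):
        for t, ds in self.datasets.items():
            for spec in CONTRASTS:
                res, degs = nb_wald_contrast(ds, spec, alpha=self.cfg.alpha_deg)
                key = f"{t}/{spec.name}"
                self.results[key] = res
                self.degs[key] = degs
                res.table.to_csv(self.root / f"de_{t}_{spec.name}.tsv", sep="\t",
                                 index_label="gene_id")

    def _load_diffexpr(self):
        for t in self.tissues:
            for spec in CONTRASTS:
                table = pd.read_csv(self.root / f"de_{t}_{spec.name}.tsv", sep="\t",
                                    index_col="gene_id")
                key = f"{t}/{spec.name}"
                self.results[key] = ContrastResult(spec=spec, table=table)
                self.degs[key] = _deg_sets_from_table(table, self.cfg.alpha_deg)

    # ---- reversal + cross-tissue concordance -----------------------------
    def _run_reversal(self):
        out = {"reversal": {}, "concordance": {}}
        for t in self.tissues:
            suc = self.degs[f"{t}/sucrose_vs_control"]
            n_bg = suc.background_n
            for treat in ("D1_vs_sucrose", "D2_vs_sucrose"):
                rep = reversal_report(suc, self.degs[f"{t}/{treat}"], n_bg)
                out["reversal"][f"{t}/{treat}"] = {
                    **dataclasses.asdict(rep),
                    "reversal_fraction": reversal_fraction(rep),
                }
        for i, ta in enumerate(self.tissues):
            for tb in self.tissues[i + 1:]:
                ka, kb = f"{ta}/D1_vs_sucrose", f"{tb}/D1_vs_sucrose"
                rep = cross_tissue_concordance(
                    self.results[ka], self.results[kb], self.degs[ka], self.degs[kb]
                )
                out["concordance"][f"{ta}~{tb}"] = dataclasses.asdict(rep)
        (self.root / "reversal.json").write_text(json.dumps(out, indent=1, sort_keys=True))
        self._reversal = out

    def _load_reversal(self):
        self._reversal = json.loads((self.root / "reversal.json").read_text())

    # ---- co-expression ----------------------------------------------------
    def _run_coexpr(self):
        cross_rows = []
        self.modules = {}
        patterns = {}
        for t in self.tissues:
            ds = self.datasets[t]
            mat = tpm(ds.counts, ds.gene_lengths)
            self.tpm[t] = mat
            keep = filter_low_expression(mat, self.cfg.tpm_threshold)
            expr = np.log2(mat.loc[keep] + 1.0)
            net = build_network(expr, tissue=t, fdr=self.cfg.fdr_edge,
                                top_frac=self.cfg.top_frac)
            net.edges.to_csv(self.root / f"edges_{t}.tsv", sep="\t", index=False)
            mods = detect_modules(net, expr=expr, min_size=self.cfg.min_module,
                                  seed=self.cfg.seed)
            self.modules[t] = mods
            membership = pd.DataFrame(
                [(m.id, g) for m in mods.modules for g in sorted(m.genes)],
                columns=["module", "gene_id"],
            )
            membership.to_csv(self.root / f"modules_{t}.tsv", sep="\t", index=False)
            if mods.modules:
                eig = pd.DataFrame({m.id: m.eigengene for m in mods.modules}).T
                eig.to_csv(self.root / f"eigengenes_{t}.tsv", sep="\t",
                           index_label="module")
            else:
                (self.root / f"eigengenes_{t}.tsv").write_text("module\n")
            deg_sets = {s.name: self.degs[f"{t}/{s.name}"] for s in CONTRASTS}
            enr = module_deg_enrichment(mods, deg_sets, background_n=len(keep),
                                        alpha=self.cfg.alpha_module)
            enr.to_csv(self.root / f"module_deg_enrichment_{t}.tsv", sep="\t", index=False)
            patterns[t] = module_patterns(enr, "sucrose_vs_control", "D1_vs_sucrose")
        for i, ta in enumerate(self.tissues):
            for tb in self.tissues[i + 1:]:
                if not (self.modules[ta].modules and self.modules[tb].modules):
                    continue
                cc = cross_tissue_module_correlation(
                    self.modules[ta], self.modules[tb],
                    self.datasets[ta].meta["animal_id"],
                    self.datasets[tb].meta["animal_id"],
                    alpha=self.cfg.alpha_module,
                )
                cross_rows.append(cc.pairs)
        cross = (pd.concat(cross_rows, ignore_index=True)
                 if cross_rows else pd.DataFrame(
                     columns=["module_a", "module_b", "R", "p", "padj", "significant"]))
        cross.to_csv(self.root / "cross_tissue_modules.tsv", sep="\t", index=False)
        (self.root / "module_patterns.json").write_text(
            json.dumps(patterns, indent=1, sort_keys=True))
        self._cross_modules = cross
        self._patterns = patterns

    def _load_coexpr(self):
        from .network import Module, ModuleSet
        self.modules = {}
        for t in self.tissues:
            membership = pd.read_csv(self.root / f"modules_{t}.tsv", sep="\t")
            eig_path = self.root / f"eigengenes_{t}.tsv"
            eig = pd.read_csv(eig_path, sep="\t", index_col="module")
            mods = ModuleSet(tissue=t)
            for mid, grp in membership.groupby("module"):
                m = Module(id=mid, genes=set(grp["gene_id"]))
                if mid in eig.index:
                    m.eigengene = eig.loc[mid]
                mods.modules.append(m)
            mods.modules.sort(key=lambda m: len(m.genes), reverse=True)
            self.modules[t] = mods
        self._cross_modules = pd.read_csv(self.root / "cross_tissue_modules.tsv", sep="\t")
        self._patterns = json.loads((self.root / "module_patterns.json").read_text())

    # ---- gene-set enrichment ----------------------------------------------
    def _collection(self) -> GeneSetCollection:
        if self.cfg.gmt_path:
            return read_gmt(self.cfg.gmt_path)
        # synthetic collection from the planted module memberships
        sets, desc = {}, {}
        for t, members in self.truth_json.get("module_membership", {}).items():
            by_mod = {}
            for g, m in members.items():
                by_mod.setdefault(m, set()).add(g)
            for m, genes in sorted(by_mod.items()):
                name = f"PLANTED_{t.upper()}_MOD{m}"
                sets[name] = genes
                desc[name] = f"synthetic planted module {m} of {t}"
        coll = GeneSetCollection(sets=sets, descriptions=desc, source="synthetic-planted")
        write_gmt(coll, self.root / "planted_modules.gmt")
        return coll

    def _run_enrich(self):
        coll = self._collection()
        rows = []
        for t in self.tissues:
            universe = set(self.results[f"{t}/sucrose_vs_control"].table.index)
            for mod in self.modules[t].modules:
                table = enrich(mod.genes & universe, coll, universe)
                table.insert(0, "query", mod.id)
                rows.append(table)
        out = (pd.concat(rows, ignore_index=True) if rows
               else pd.DataFrame(columns=["query", "set", "k", "K", "n", "N", "p", "padj"]))
        out.to_csv(self.root / "module_set_enrichment.tsv", sep="\t", index=False)
        self._enrichment = out

    def _load_enrich(self):
        self._enrichment = pd.read_csv(self.root / "module_set_enrichment.tsv", sep="\t")

    # ---- metabolic activity ------------------------------------------------
    def _metab_gene_map(self, tissue: str, model_genes: list[str]) -> dict:
        """Deterministic model-gene -> data-gene map favouring planted
        reversed DEGs so treatment effects propagate into reaction scores."""
        up = self.truth_json.get("deg_up", {}).get(tissue, {})
        rev = set(self.truth_json.get("reversed_d1", {}).get(tissue, []))
        pool = sorted(set(up) & rev) + sorted(set(up) - rev)
        pool += [g for g in sorted(self.datasets[tissue].counts.index) if g not in pool]
        return {mg: pool[i % len(pool)] for i, mg in enumerate(model_genes)}

    def _run_metab(self):
        model = toy_model()
        write_model(model, self.root / "toy_model.json")
        model_genes = sorted({g for r in model.reactions if r.gpr for g in r.gpr.genes()})
        out = {}
        for t in self.tissues:
            ds = self.datasets[t]
            mat = self.tpm.get(t)
            if mat is None:
                mat = tpm(ds.counts, ds.gene_lengths)
            gene_map = self._metab_gene_map(t, model_genes)
            pd.Series(gene_map).rename("data_gene").to_csv(
                self.root / f"metab_gene_map_{t}.tsv", sep="\t",
                index_label="model_gene")
            expr = mat.loc[[gene_map[mg] for mg in model_genes]].copy()
            expr.index = model_genes
            expr = expr / expr.to_numpy().mean()  # scale to O(1) penalties
            rexpr = reaction_expression(model, expr)
            scores = compass_scores(model, rexpr, w=self.cfg.compass_w)
            scores.scores.to_csv(self.root / f"metab_scores_{t}.tsv", sep="\t",
                                 index_label="reaction")
            groups = ds.meta["group"]
            diff_suc = differential_activity(scores, groups, "sucrose", "control",
                                             model, alpha=self.cfg.alpha_metab)
            diff_d1 = differential_activity(scores, groups, "JNK_D1", "sucrose",
                                            model, alpha=self.cfg.alpha_metab)
            diff_suc.table.to_csv(self.root / f"metab_diff_{t}_sucrose.tsv",
                                  sep="\t", index=False)
            diff_d1.table.to_csv(self.root / f"metab_diff_{t}_D1.tsv",
                                 sep="\t", index=False)
            frac, rev_ids = reversal_of_activity(diff_suc, diff_d1)
            out[t] = {
                "n_scored": int(diff_suc.table.shape[0]),
                "n_sig_sucrose": int(diff_suc.table["significant"].sum())
                if not diff_suc.table.empty else 0,
                "n_sig_d1": int(diff_d1.table["significant"].sum())
                if not diff_d1.table.empty else 0,
                "activity_reversal_fraction": frac,
                "reversed_reactions": rev_ids,
                "blocked": scores.blocked,
            }
        (self.root / "metab_summary.json").write_text(
            json.dumps(out, indent=1, sort_keys=True))
        self._metab = out

    def _load_metab(self):
        self._metab = json.loads((self.root / "metab_summary.json").read_text())

    # ---- report -------------------------------------------------------------
    def _run_report(self):
        deg_counts = {}
        for t in self.tissues:
            deg_counts[t] = {}
            for spec in CONTRASTS:
                d = self.degs[f"{t}/{spec.name}"]
                n = len(d.all)
                deg_counts[t][spec.name] = {
                    "n_deg": n,
                    "n_up": len(d.up),
                    "n_down": len(d.down),
                    "background_n": d.background_n,
                    "pct_of_universe": format_percentage(n, d.background_n)
                    if d.background_n else None,
                }
        report = {
            "provenance": {
                "config": self.cfg.to_dict(),
                "config_hash": self.cfg.hash(),
                "seed": self.cfg.seed,
                "version": __version__,
            },
            "deg_counts": deg_counts,
            "reversal": self._reversal["reversal"],
            "concordance": self._reversal["concordance"],
            "modules": {
                t: {"sizes": self.modules[t].sizes,
                    "n_unassigned": len(self.modules[t].unassigned),
                    "patterns": self._patterns.get(t, {})}
                for t in self.tissues
            },
            "cross_tissue_modules": self._cross_modules.to_dict(orient="records"),
            "metabolic": self._metab,
        }
        self.report = report
        (self.root / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (self.root / "report.txt").write_text(render_report(report))

    def _load_report(self):
        self.report = json.loads((self.root / "report.json").read_text())

    # ---- driver --------------------------------------------------------------
    def run(self) -> dict:
        self.tissues, sim_files = self._simulate_outputs()
        de_files = [self.root / f"de_{t}_{s.name}.tsv"
                    for t in self.tissues for s in CONTRASTS]
        coexpr_files = (
            [self.root / f"edges_{t}.tsv" for t in self.tissues]
            + [self.root / f"modules_{t}.tsv" for t in self.tissues]
            + [self.root / f"eigengenes_{t}.tsv" for t in self.tissues]
            + [self.root / "cross_tissue_modules.tsv", self.root / "module_patterns.json"]
        )
        metab_files = [self.root / "metab_summary.json"] + [
            self.root / f"metab_scores_{t}.tsv" for t in self.tissues]
        plan = [
            ("simulate", sim_files, self._run_simulate, self._load_simulate),
            ("diffexpr", de_files, self._run_diffexpr, self._load_diffexpr),
            ("reversal", [self.root / "reversal.json"], self._run_reversal,
             self._load_reversal),
            ("coexpr", coexpr_files, self._run_coexpr, self._load_coexpr),
            ("enrich", [self.root / "module_set_enrichment.tsv"], self._run_enrich,
             self._load_enrich),
            ("metab", metab_files, self._run_metab, self._load_metab),
            ("report", [self.root / "report.json", self.root / "report.txt"],
             self._run_report, self._load_report),
        ]
        for name, outputs, compute, load in plan:
            self._stage(name, outputs, compute, load)
        return self.report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the study report dict."""
    return PipelineRun(config).run()


def _fmt_pct(x):
    return "n/a" if x is None else f"{x:.1f}%"


def render_report(report: dict) -> str:
    """Human-readable text summary of a study report."""
    lines = []
    prov = report["provenance"]
    lines.append("crossnet study report")
    lines.append(f"seed={prov['seed']} config_hash={prov['config_hash']} "
                 f"version={prov['version']}")
    lines.append("")
    lines.append("Differential expression (padj < alpha):")
    for t, contrasts in sorted(report["deg_counts"].items()):
        for name, d in contrasts.items():
            lines.append(
                f"  {t:8s} {name:20s} n={d['n_deg']:5d} "
                f"(up {d['n_up']}, down {d['n_down']}) "
                f"{_fmt_pct(d['pct_of_universe'])} of {d['background_n']} genes"
            )
    lines.append("")
    lines.append("Reversal of sucrose DEGs by treatment:")
    for key, r in sorted(report["reversal"].items()):
        lines.append(
            f"  {key:24s} suppressed {r['n_suppressed']}/{r['n_sucrose_up']} "
            f"({_fmt_pct(r['pct_suppressed'])}), restored "
            f"{r['n_restored']}/{r['n_sucrose_down']} ({_fmt_pct(r['pct_restored'])})"
        )
    lines.append("")
    lines.append("Cross-tissue log2FC concordance of shared dose-1 DEGs:")
    for key, c in sorted(report["concordance"].items()):
        rho = "n/a" if c["spearman_rho"] is None else f"{c['spearman_rho']:.2f}"
        lines.append(
            f"  {key:16s} shared={c['n_shared']:4d} same-sign "
            f"{_fmt_pct(c['pct_same_sign'])} rho={rho}"
        )
    lines.append("")
    lines.append("Co-expression modules:")
    for t, m in sorted(report["modules"].items()):
        if not m["sizes"]:
            lines.append(f"  {t:8s} no modules >= min size")
            continue
        sizes = ", ".join(f"{k}:{v}" for k, v in sorted(m["sizes"].items()))
        lines.append(f"  {t:8s} {sizes} (unassigned {m['n_unassigned']})")
        for mod, pat in sorted(m["patterns"].items()):
            if pat != "none":
                lines.append(f"           {mod}: {pat}")
    lines.append("")
    sig_pairs = [p for p in report["cross_tissue_modules"] if p.get("significant")]
    lines.append(f"Cross-tissue module pairs significant at BH padj: {len(sig_pairs)}")
    for p in sig_pairs:
        lines.append(
            f"  {p['module_a']} ~ {p['module_b']}: R={p['R']:.2f} padj={p['padj']:.3g}"
        )
    lines.append("")
    lines.append("Metabolic reaction activity:")
    for t, m in sorted(report["metabolic"].items()):
        frac = m["activity_reversal_fraction"]
        frac = "n/a" if frac is None else f"{100 * frac:.1f}%"
        lines.append(
            f"  {t:8s} altered by sucrose: {m['n_sig_sucrose']}/{m['n_scored']} "
            f"reactions; reversed by dose 1: {frac}"
        )
    return "\n".join(lines) + "\n"
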