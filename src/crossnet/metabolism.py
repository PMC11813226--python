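"""Expression-constrained metabolic reaction-activity scoring.

A desk-scale reimplementation of flux-penalty ("Compass-style") reaction
scoring on small stoichiometric models. For each reaction and sample:

1. LP-1 maximizes the reaction's flux subject to steady state (S v = 0)
   and bounds, giving v_max; reactions with v_max below tolerance are
   *blocked* and not scored.
2. LP-2 minimizes the expression-derived penalty sum(penalty_i * |v_i|)
   (implemented by splitting every flux into nonnegative forward/backward
   parts) subject to steady state, bounds, and v_r >= w * v_max.
3. The score is -log(optimal penalty + eps); higher = the network can
   sustain near-maximal flux through the reaction with better-expressed
   enzymes.

Gene-to-reaction expression uses the GPR rule with AND -> min (limiting
subunit) and OR -> sum (isozymes add capacity); the penalty of a
gene-associated reaction is 1/(1 + expression); reactions without a GPR
carry zero penalty by default (they contribute no expression evidence).

Downstream differential activity mirrors the transcriptome statistics:
two-sided Wilcoxon rank-sum per reaction (exact for small groups without
ties), BH across reactions, Cohen's d, and subsystem summaries.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import linprog

from .stats import bh_adjust

logger = logging.getLogger(__name__)

BLOCKED_TOL = 1e-9


# --------------------------------------------------------------------------
# GPR boolean expressions

class GPR:
    """AND/OR tree over gene ids; AND evaluates to min, OR to sum."""

    def __init__(self, op, children=None, gene=None):
        self.op = op          # 'gene' | 'and' | 'or'
        self.children = children or []
        self.gene = gene

    def evaluate(self, expr: dict, missing_warned: Optional[set] = None) -> float:
        if self.op == "gene":
            if self.gene not in expr:
                if missing_warned is not None and self.gene not in missing_warned:
                    logger.warning("GPR references missing gene %s; treated as 0", self.gene)
                    missing_warned.add(self.gene)
                return 0.0
            return float(expr[self.gene])
        vals = [c.evaluate(expr, missing_warned) for c in self.children]
        return min(vals) if self.op == "and" else sum(vals)

    def genes(self) -> set:
        if self.op == "gene":
            return {self.gene}
        return set().union(*(c.genes() for c in self.children))

    def unparse(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = " and " if self.op == "and" else " or "
        parts = [
            f"({c.unparse()})" if c.op != "gene" else c.unparse() for c in self.children
        ]
        return sep.join(parts)


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GPR:
    """Parse a GPR string such as ``"(g1 and g2) or g3"`` (case-insensitive
    AND/OR, parentheses). Raises ``ValueError`` with the token position on
    malformed input such as ``"A AND"``.
    """
    tokens = _TOKEN.findall(text)
    if not tokens:
        raise ValueError("empty GPR expression")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def parse_or():
        nonlocal pos
        node = parse_and()
        children = [node]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else GPR("or", children)

    def parse_and():
        nonlocal pos
        node = parse_atom()
        children = [node]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else GPR("and", children)

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ValueError(f"GPR ended unexpectedly at token {pos} in {text!r}")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parenthesis at token {pos} in {text!r}")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"unexpected token {tok!r} at position {pos} in {text!r}")
        pos += 1
        return GPR("gene", gene=tok)

    tree = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens at position {pos} in {text!r}")
    return tree


# --------------------------------------------------------------------------
# Model container and JSON I/O

@dataclass
class Reaction:
    id: str
    stoichiometry: dict            # metabolite id -> coefficient
    lower_bound: float
    upper_bound: float
    gpr: Optional[GPR] = None
    subsystem: str = "unassigned"


@dataclass
class MetabolicModel:
    id: str
    metabolites: list
    reactions: list = field(default_factory=list)

    def __post_init__(self):
        mets = set(self.metabolites)
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - mets
            if unknown:
                raise ValueError(
                    f"reaction {rxn.id} references unknown metabolites {sorted(unknown)}"
                )
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"reaction {rxn.id}: lower bound exceeds upper bound")
            if not rxn.subsystem:
                raise ValueError(f"reaction {rxn.id}: subsystem must be nonempty")

    @property
    def reaction_ids(self):
        return [r.id for r in self.reactions]

    def stoichiometric_matrix(self) -> np.ndarray:
        midx = {m: i for i, m in enumerate(self.metabolites)}
        s = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for m, c in rxn.stoichiometry.items():
                s[midx[m], j] = c
        return s

    def bounds(self):
        return np.array([(r.lower_bound, r.upper_bound) for r in self.reactions])


def read_model(path) -> MetabolicModel:
    """Read a BiGG-style JSON model (metabolites, reactions with
    stoichiometry/bounds/GPR/subsystem)."""
    data = json.loads(Path(path).read_text())
    reactions = [
        Reaction(
            id=r["id"],
            stoichiometry={m: float(c) for m, c in r["stoichiometry"].items()},
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            gpr=parse_gpr(r["gpr"]) if r.get("gpr") else None,
            subsystem=r.get("subsystem", "unassigned"),
        )
        for r in data["reactions"]
    ]
    return MetabolicModel(
        id=data.get("id", Path(path).stem),
        metabolites=[m["id"] if isinstance(m, dict) else m for m in data["metabolites"]],
        reactions=reactions,
    )


def write_model(model: MetabolicModel, path):
    data = {
        "id": model.id,
        "metabolites": [{"id": m} for m in model.metabolites],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.unparse() if r.gpr else None,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# Scoring

def reaction_expression(model: MetabolicModel, expr: pd.DataFrame) -> pd.DataFrame:
    """GPR-resolved expression per reaction and sample.

    ``expr`` is gene x sample, nonnegative. Reactions without a GPR get
    NaN (unassociated). Missing genes evaluate to 0 with one warning each.
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression must be nonnegative")
    warned = set()
    out = np.full((len(model.reactions), expr.shape[1]), np.nan)
    for j, sample in enumerate(expr.columns):
        col = expr[sample].to_dict()
        for i, rxn in enumerate(model.reactions):
            if rxn.gpr is not None:
                out[i, j] = rxn.gpr.evaluate(col, warned)
    return pd.DataFrame(out, index=model.reaction_ids, columns=expr.columns)


@dataclass
class ReactionScores:
    scores: pd.DataFrame     # reaction x sample, NaN for blocked reactions
    penalties: pd.DataFrame  # optimal LP-2 penalty per reaction/sample
    blocked: list            # reaction ids with v_max <= tolerance
    params: dict


def _max_flux(s: np.ndarray, bounds: np.ndarray, r: int) -> float:
    c = np.zeros(s.shape[1])
    c[r] = -1.0
    res = linprog(c, A_eq=s, b_eq=np.zeros(s.shape[0]), bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LP-1 failed for reaction index {r}: {res.message}")
    return -res.fun


def compass_scores(model: MetabolicModel, reaction_expr: pd.DataFrame, w: float = 0.95,
                   eps: float = 1e-10,
                   unassociated_penalty: str = "zero") -> ReactionScores:
    """Potential-activity scores for every unblocked reaction and sample.

    ``reaction_expr`` is the GPR-resolved reaction x sample expression
    (NaN = unassociated). Penalty per reaction i: 1/(1+expr_i) if
    gene-associated else 0 (``unassociated_penalty="zero"``) or the mean
    associated penalty (``"mean"``). See module docstring for the LPs.
    """
    if not 0 < w <= 1:
        raise ValueError("w must be in (0, 1]")
    s = model.stoichiometric_matrix()
    bounds = model.bounds()
    nr = len(model.reactions)
    vmax = np.array([_max_flux(s, bounds, r) for r in range(nr)])
    blocked = [model.reaction_ids[r] for r in range(nr) if vmax[r] <= BLOCKED_TOL]

    # split system: variables [v+; v-], net flux v = v+ - v-
    ub_pos = np.maximum(bounds[:, 1], 0.0)
    ub_neg = np.maximum(-bounds[:, 0], 0.0)
    a_eq = np.hstack([s, -s])
    split_bounds = [(0.0, u) for u in ub_pos] + [(0.0, u) for u in ub_neg]

    scores = np.full((nr, reaction_expr.shape[1]), np.nan)
    penalties = np.full((nr, reaction_expr.shape[1]), np.nan)
    for j, sample in enumerate(reaction_expr.columns):
        e = reaction_expr[sample].to_numpy(dtype=float)
        pen = np.where(np.isnan(e), np.nan, 1.0 / (1.0 + np.nan_to_num(e)))
        if unassociated_penalty == "zero":
            fill = 0.0
        elif unassociated_penalty == "mean":
            fill = np.nanmean(pen) if not np.all(np.isnan(pen)) else 0.0
        else:
            raise ValueError("unassociated_penalty must be 'zero' or 'mean'")
        pen = np.where(np.isnan(pen), fill, pen)
        c = np.concatenate([pen, pen])
        for r in range(nr):
            if vmax[r] <= BLOCKED_TOL:
                continue
            # v_r >= w * vmax  ->  -(v_r+ - v_r-) <= -w*vmax
            a_ub = np.zeros((1, 2 * nr))
            a_ub[0, r] = -1.0
            a_ub[0, nr + r] = 1.0
            res = linprog(
                c, A_ub=a_ub, b_ub=[-w * vmax[r]], A_eq=a_eq,
                b_eq=np.zeros(s.shape[0]), bounds=split_bounds, method="highs",
            )
            if not res.success:
                warnings.warn(f"LP-2 infeasible for reaction {model.reaction_ids[r]}")
                continue
            penalties[r, j] = res.fun
            scores[r, j] = -np.log(res.fun + eps)
    cols = reaction_expr.columns
    return ReactionScores(
        scores=pd.DataFrame(scores, index=model.reaction_ids, columns=cols),
        penalties=pd.DataFrame(penalties, index=model.reaction_ids, columns=cols),
        blocked=blocked,
        params={"w": w, "eps": eps, "unassociated_penalty": unassociated_penalty},
    )


# --------------------------------------------------------------------------
# Differential activity

def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact when the smaller group has <= 10 observations and there are no
    ties; otherwise the normal approximation with tie and continuity
    correction. Identical constant groups give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 10 and not ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def cohens_d(x, y) -> float:
    """(mean(x) - mean(y)) / pooled SD (unbiased variances); 0 if SD = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    pooled = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / np.sqrt(pooled))


@dataclass
class DiffActivity:
    contrast: str
    table: pd.DataFrame  # reaction, subsystem, cohens_d, p, padj, significant, sign

    def subsystem_summary(self) -> pd.DataFrame:
        """Counts of significant reactions per subsystem per d-sign."""
        sig = self.table[self.table["significant"]]
        return (
            sig.groupby(["subsystem", "sign"]).size().rename("n_reactions").reset_index()
        )


def differential_activity(scores: ReactionScores, groups: pd.Series,
                          numerator: str, denominator: str,
                          model: MetabolicModel, alpha: float = 0.05) -> DiffActivity:
    """Wilcoxon + Cohen's d per reaction between two sample groups.

    ``groups`` maps sample id -> group label. BH across scored reactions;
    significance at padj < ``alpha``; sign is the sign of Cohen's d.
    """
    s1 = [c for c in scores.scores.columns if groups[c] == numerator]
    s0 = [c for c in scores.scores.columns if groups[c] == denominator]
    if len(s1) < 2 or len(s0) < 2:
        raise ValueError("need at least 2 samples in each group")
    subsys = {r.id: r.subsystem for r in model.reactions}
    rows = []
    for rid, row in scores.scores.iterrows():
        x, y = row[s1].to_numpy(), row[s0].to_numpy()
        if np.isnan(x).any() or np.isnan(y).any():
            continue
        rows.append(
            {
                "reaction": rid,
                "subsystem": subsys[rid],
                "cohens_d": cohens_d(x, y),
                "p": wilcoxon_rank_sum(x, y),
            }
        )
    table = pd.DataFrame(rows, columns=["reaction", "subsystem", "cohens_d", "p"])
    if not table.empty:
        table["padj"] = bh_adjust(table["p"])
        table["significant"] = table["padj"] < alpha
        table["sign"] = np.where(table["cohens_d"] >= 0, "+", "-")
    return DiffActivity(contrast=f"{numerator}_vs_{denominator}", table=table)


def reversal_of_activity(diff_sucrose: DiffActivity, diff_treat: DiffActivity):
    """Fraction of sucrose-altered reactions reversed under treatment.

    Among reactions significant in the sucrose contrast, the fraction also
    significant in the treatment contrast with an oppositely signed
    Cohen's d. Returns ``(fraction or None, list of reversed reaction ids)``.
    """
    s = diff_sucrose.table.set_index("reaction")
    t = diff_treat.table.set_index("reaction")
    sig = s.index[s["significant"]]
    if len(sig) == 0:
        return None, []
    reversed_ids = [
        r for r in sig
        if r in t.index and t.loc[r, "significant"]
        and s.loc[r, "cohens_d"] * t.loc[r, "cohens_d"] < 0
    ]
    return len(reversed_ids) / len(sig), reversed_ids


def toy_model(n_pathways: int = 3, reactions_per_pathway: int = 3,
              bound: float = 10.0) -> MetabolicModel:
    """Small linear-pathway model for demonstrations and pipeline runs.

    Each pathway p is an uptake -> conversion chain -> secretion:
    ``EX_in_p: -> M_p0``, ``R_p_k: M_p(k-1) -> M_pk`` (gene-associated),
    ``EX_out_p: M_p_last ->``. Conversion k carries the GPR
    ``mg_p_k_a or mg_p_k_b`` for odd k and ``mg_p_k_a and mg_p_k_b`` for
    even k; pathways alternate subsystems.
    """
    mets, rxns = [], []
    subsystems = ["citric acid cycle", "fatty acid oxidation", "fatty acid synthesis",
                  "tryptophan metabolism", "glycolysis"]
    for p in range(n_pathways):
        chain = [f"M_{p}_{k}" for k in range(reactions_per_pathway + 1)]
        mets += chain
        sub = subsystems[p % len(subsystems)]
        rxns.append(Reaction(f"EX_in_{p}", {chain[0]: 1.0}, 0.0, bound, None, sub))
        for k in range(reactions_per_pathway):
            op = "or" if k % 2 else "and"
            gpr = parse_gpr(f"mg_{p}_{k}_a {op} mg_{p}_{k}_b")
            rxns.append(
                Reaction(f"R_{p}_{k}", {chain[k]: -1.0, chain[k + 1]: 1.0},
                         0.0, bound, gpr, sub)
            )
        rxns.append(Reaction(f"EX_out_{p}", {chain[-1]: -1.0}, 0.0, bound, None, sub))
    return MetabolicModel(id="toy", metabolites=mets, reactions=rxns)
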