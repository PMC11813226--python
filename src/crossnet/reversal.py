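"""Direction-aware reversal accounting between contrasts.

"Suppressed" genes are induced by sucrose (sucrose-vs-control up) and
significantly down in the treatment-vs-sucrose contrast; "restored" genes
are the mirror image. Overlap significance uses the upper-tail
hypergeometric test; set similarity uses the Jaccard index. Cross-tissue
concordance compares log2 fold changes of DEGs shared between two tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .de import ContrastResult, DEGSets
from .stats import format_percentage, hypergeom_overlap, jaccard


@dataclass
class ReversalReport:
    n_sucrose_up: int
    n_sucrose_down: int
    n_suppressed: int           # sucrose-up ∩ treatment-down
    n_restored: int             # sucrose-down ∩ treatment-up
    pct_suppressed: Optional[float]  # None when the sucrose set is empty
    pct_restored: Optional[float]
    p_hyper_suppressed: Optional[float]
    p_hyper_restored: Optional[float]
    jaccard_up: float
    jaccard_down: float
    background_n: int
    decimals: int = 1


def reversal_report(sucrose: DEGSets, treatment: DEGSets, background_n: int,
                    decimals: int = 1) -> ReversalReport:
    """Overlap accounting between a sucrose contrast and a treatment contrast.

    Percentages are 100 x overlap / |sucrose set| at ``decimals`` places;
    they are reported as None (not 0) when the sucrose set is empty.
    Hypergeometric parameters: N = background_n, K = |sucrose set|,
    n = |treatment opposite-sign set|, k = overlap.
    """
    suppressed = sucrose.up & treatment.down
    restored = sucrose.down & treatment.up

    def _pct(k, K):
        return format_percentage(k, K, decimals) if K else None

    def _p(k, K, n):
        return hypergeom_overlap(k, K, n, background_n) if K else None

    return ReversalReport(
        n_sucrose_up=len(sucrose.up),
        n_sucrose_down=len(sucrose.down),
        n_suppressed=len(suppressed),
        n_restored=len(restored),
        pct_suppressed=_pct(len(suppressed), len(sucrose.up)),
        pct_restored=_pct(len(restored), len(sucrose.down)),
        p_hyper_suppressed=_p(len(suppressed), len(sucrose.up), len(treatment.down)),
        p_hyper_restored=_p(len(restored), len(sucrose.down), len(treatment.up)),
        jaccard_up=jaccard(sucrose.up, treatment.down),
        jaccard_down=jaccard(sucrose.down, treatment.up),
        background_n=background_n,
        decimals=decimals,
    )


@dataclass
class ConcordanceReport:
    n_shared: int
    pct_same_sign: Optional[float]
    spearman_rho: Optional[float]
    p: Optional[float]


def cross_tissue_concordance(res_a: ContrastResult, res_b: ContrastResult,
                             deg_a: DEGSets, deg_b: DEGSets) -> ConcordanceReport:
    """log2FC concordance of DEGs shared between two tissues.

    Shared genes are DEGs (either direction) in both tissues; sign
    agreement is the fraction with log2FC of the same sign (zero-log2FC
    genes excluded from the percentage); Spearman rho over paired log2FC,
    reported as not-applicable (None) below 3 shared genes.
    """
    shared = sorted(deg_a.all & deg_b.all)
    n = len(shared)
    if n == 0:
        return ConcordanceReport(0, None, None, None)
    a = res_a.table.loc[shared, "log2fc"].to_numpy()
    b = res_b.table.loc[shared, "log2fc"].to_numpy()
    nz = (a != 0) & (b != 0)
    pct = format_percentage(int((a[nz] * b[nz] > 0).sum()), int(nz.sum())) if nz.any() else None
    if n < 3:
        return ConcordanceReport(n, pct, None, None)
    rho, p = sps.spearmanr(a, b)
    return ConcordanceReport(n, pct, float(rho), float(p))


def reversal_fraction(report: ReversalReport) -> Optional[float]:
    """Overall fraction of sucrose DEGs reversed (suppressed + restored)."""
    denom = report.n_sucrose_up + report.n_sucrose_down
    if denom == 0:
        return None
    return (report.n_suppressed + report.n_restored) / denom
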