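"""Peak-to-gene association and the expression-change comparison for the
most strongly opening and closing peaks."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Gene, Peak

logger = logging.getLogger(__name__)

MAX_LINK_DIST = 10_000
MIN_GROUP_SIZE = 3


def link_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    interactions: set[tuple[str, str]] | None = None,
    max_dist: int = MAX_LINK_DIST,
) -> pd.DataFrame:
    """Link each peak to every gene whose TSS lies within ``max_dist``.

    The distance is from the TSS to the nearest peak edge (0 when the TSS
    falls inside the peak) and is reported signed: negative when the peak
    is upstream of the gene, strand-aware. An optional interaction table
    of (peak_id, gene_id) pairs restricts links to listed pairs that also
    satisfy the distance rule — the distance rule always dominates.
    """
    gene_by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.tss.chrom, []).append(g)
    rows = []
    for p in peaks:
        iv = p.interval
        for g in gene_by_chrom.get(iv.chrom, ()):  # genomes are small; linear is fine
            tss = g.tss.start
            if tss < iv.start:
                dist = iv.start - tss
                peak_is_right = True
            elif tss >= iv.end:
                dist = tss - (iv.end - 1)
                peak_is_right = False
            else:
                dist = 0
                peak_is_right = False
            if dist > max_dist:
                continue
            if interactions is not None and (p.id, g.id) not in interactions:
                continue
            # upstream (negative): peak on the 5' side of the TSS
            if dist == 0:
                signed = 0
            elif g.tss.strand == "-":
                signed = -dist if peak_is_right else dist
            else:
                signed = dist if peak_is_right else -dist
            rows.append({"peak_id": p.id, "gene_id": g.id, "signed_distance": signed})
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "signed_distance"])


def group_expression_change(
    ranked: pd.DataFrame,
    links: pd.DataFrame,
    expression: pd.DataFrame,
    n_top: int = 100,
    classic_t: bool = False,
) -> dict:
    """Expression change of genes linked to the top opening vs closing peaks.

    Takes the genes linked to the ``n_top`` lowest-rank (most opening) and
    ``n_top`` highest-rank (most closing) peaks. A gene linked to both
    groups is assigned to the group of its most extreme-ranked peak, the
    opening group on ties. Reports group means, the Welch t statistic
    (``classic_t`` switches to the pooled-variance variant) and the
    two-sided p, plus the per-group log2fc values for box-plot export.
    """
    m = len(ranked)
    ranks = ranked["rank"]
    opening_ids = set(ranked.index[ranks <= n_top])
    closing_ids = set(ranked.index[ranks > m - n_top])
    expr = expression.set_index("gene_id")["log2fc"]

    best: dict[str, tuple[int, str]] = {}  # gene -> (extremity, group)
    for _, row in links.iterrows():
        pid, gid = row["peak_id"], row["gene_id"]
        if pid in opening_ids:
            group = "opening"
            extremity = int(ranked.loc[pid, "rank"]) - 1
        elif pid in closing_ids:
            group = "closing"
            extremity = m - int(ranked.loc[pid, "rank"])
        else:
            continue
        if gid not in best or extremity < best[gid][0] or (
            extremity == best[gid][0] and group == "opening"
        ):
            best[gid] = (extremity, group)

    groups: dict[str, list[float]] = {"opening": [], "closing": []}
    for gid, (_, group) in best.items():
        if gid in expr.index:
            groups[group].append(float(expr.loc[gid]))
    for name, vals in groups.items():
        if len(vals) < MIN_GROUP_SIZE:
            raise ValueError(f"{name} group has {len(vals)} genes; need >= {MIN_GROUP_SIZE}")
    a = np.array(groups["opening"])
    b = np.array(groups["closing"])
    t, p = stats.ttest_ind(a, b, equal_var=classic_t)
    return {
        "mean_opening": float(a.mean()),
        "mean_closing": float(b.mean()),
        "n_opening": len(a),
        "n_closing": len(b),
        "t_statistic": float(t),
        "pvalue": float(p),
        "opening_log2fc": a,
        "closing_log2fc": b,
    }
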