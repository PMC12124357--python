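"""Cross-species expression and accessibility comparisons.

Per-gene human/NHP fold changes (counts-per-million scale), one-sided
gene-set shift tests with BH adjustment at q < 0.1, equal-count pseudotime
binning, gene-module Fisher enrichment, and a GSEA-style ranked enrichment
of accessibility fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import fisher_enrichment
from .strclass import adjust_pvalues, rank_sum_one_sided


def log_fold_change(
    expr_human: pd.DataFrame, expr_other: pd.DataFrame, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2 fold change, human over other species.

    Each condition column is scaled to counts per million, replicate
    conditions are averaged, and LFC = log2((cpm_h + pc) / (cpm_o + pc)).
    """
    if set(expr_human.index) != set(expr_other.index):
        raise ValueError("gene universes differ between the two tables")
    expr_other = expr_other.loc[expr_human.index]

    def cpm_mean(df: pd.DataFrame) -> pd.Series:
        cpm = df / df.sum(axis=0) * 1e6
        return cpm.mean(axis=1)

    h = cpm_mean(expr_human)
    o = cpm_mean(expr_other)
    lfc = np.log2((h + pseudocount) / (o + pseudocount))
    lfc.name = "lfc"
    return lfc


def gene_set_shift_test(
    lfc: pd.Series,
    set_genes,
    background_genes,
    alternative: str = "greater",
) -> float:
    """One-sided rank-sum of set LFCs against disjoint background LFCs."""
    set_genes = [g for g in set_genes if g in lfc.index]
    background_genes = [g for g in background_genes if g in lfc.index]
    if not set_genes or not background_genes:
        raise ValueError("empty gene set or background after intersection")
    if set(set_genes) & set(background_genes):
        raise ValueError("set and background must be disjoint")
    return rank_sum_one_sided(
        lfc.loc[set_genes].to_numpy(), lfc.loc[background_genes].to_numpy(), alternative
    )


def gene_set_shift_table(
    lfc_by_condition: dict[str, pd.Series],
    set_genes,
    background_genes,
    alternative: str = "greater",
    fdr_alpha: float = 0.1,
) -> pd.DataFrame:
    """Shift test across conditions with BH adjustment at q < ``fdr_alpha``."""
    conds = list(lfc_by_condition)
    ps = [
        gene_set_shift_test(lfc_by_condition[c], set_genes, background_genes, alternative)
        for c in conds
    ]
    qs = adjust_pvalues(ps, "bh")
    return pd.DataFrame(
        {"condition": conds, "p": ps, "q": qs, "significant": qs < fdr_alpha}
    ).set_index("condition")


def pseudotime_bin_means(
    cell_expr: pd.DataFrame, pseudotime: pd.Series, n_bins: int = 100
) -> pd.DataFrame:
    """Average expression per gene in equal-count pseudotime bins.

    Cells (columns of ``cell_expr``) are sorted by pseudotime and split into
    ``n_bins`` quantile bins of near-equal size, so no bin is empty; each
    bin's per-gene mean is returned (genes x bins).
    """
    cells = list(cell_expr.columns)
    if pseudotime.isna().any() or not np.isfinite(pseudotime.to_numpy()).all():
        raise ValueError("every cell needs a finite pseudotime")
    missing = set(cells) - set(pseudotime.index)
    if missing:
        raise ValueError(f"cells without pseudotime: {sorted(missing)[:3]} ...")
    if len(cells) < n_bins:
        raise ValueError(
            f"fewer cells ({len(cells)}) than bins ({n_bins}); lower n_bins"
        )
    order = pseudotime.loc[cells].sort_values(kind="stable").index
    chunks = np.array_split(np.arange(len(order)), n_bins)
    out = {}
    for bi, chunk in enumerate(chunks):
        ids = order[chunk]
        out[f"bin_{bi + 1:03d}"] = cell_expr[ids].mean(axis=1)
    return pd.DataFrame(out)


def module_enrichment(
    module_assignment: pd.Series, set_genes, universe
) -> pd.DataFrame:
    """Per-module Fisher enrichment of a gene set, BH-adjusted across modules.

    ``module_assignment`` maps gene -> module label for genes belonging to a
    module (a subset of the universe).
    """
    universe = list(universe)
    uset = set(universe)
    stray = set(module_assignment.index) - uset
    if stray:
        raise ValueError(f"module genes outside universe: {sorted(stray)[:3]} ...")
    set_genes = set(set_genes) & uset
    rows = []
    modules = sorted(module_assignment.unique())
    results = []
    for mod in modules:
        members = set(module_assignment.index[module_assignment == mod])
        in_set = np.array([g in set_genes for g in universe])
        in_mod = np.array([g in members for g in universe])
        res = fisher_enrichment(in_mod[in_set], in_mod[~in_set], label=str(mod))
        results.append(res)
    qs = adjust_pvalues([r.p_two_sided for r in results], "bh")
    for res, q in zip(results, qs):
        res.adjusted_p = float(q)
        rows.append(
            (res.label, res.a, res.b, res.c, res.d, res.odds_ratio, res.p_two_sided, q)
        )
    return pd.DataFrame(
        rows, columns=["module", "a", "b", "c", "d", "odds_ratio", "p", "q"]
    ).set_index("module")


@dataclass
class RankedEnrichment:
    es: float
    p: float
    leading_edge: list[str] = field(default_factory=list)
    n_perm: int = 0
    seed: int = 0


def _running_es(scores: np.ndarray, member: np.ndarray, w: float) -> tuple[float, int]:
    weights = np.abs(scores) ** w
    total = weights[member].sum()
    if total == 0:  # all member scores zero at w>0: fall back to equal steps
        inc = np.where(member, 1.0 / member.sum(), 0.0)
    else:
        inc = np.where(member, weights / total, 0.0)
    n_non = (~member).sum()
    dec = np.where(member, 0.0, 1.0 / n_non)
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def ranked_set_enrichment(
    item_scores: pd.Series,
    member_flags: pd.Series,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> RankedEnrichment:
    """GSEA-style enrichment of members among descending-ranked scores.

    The running sum gains ``|score|^w / sum_members |score|^w`` at members
    and loses ``1/(N - N_members)`` at non-members; ES is the signed maximum
    deviation.  The p-value permutes member labels (seeded), one-sided toward
    the observed ES sign.
    """
    scores = item_scores.to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    member = member_flags.loc[item_scores.index].to_numpy(dtype=bool)
    if member.all() or not member.any():
        raise ValueError("need at least one member and one non-member")
    order = np.argsort(-scores, kind="stable")
    s, m = scores[order], member[order]
    es, peak = _running_es(s, m, weight_exponent)
    ids = item_scores.index.to_numpy()[order]
    if es >= 0:
        leading = [str(g) for g in ids[: peak + 1][m[: peak + 1]]]
    else:
        leading = [str(g) for g in ids[peak:][m[peak:]]]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        es_p, _ = _running_es(s, perm, weight_exponent)
        if es >= 0:
            exceed += es_p >= es
        else:
            exceed += es_p <= es
    p = (1 + exceed) / (1 + n_perm)
    return RankedEnrichment(es, float(p), leading, n_perm, seed)
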