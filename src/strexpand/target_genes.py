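"""Candidate target genes of expanded STR loci, via three mechanisms.

RBC (regulation by colocalization): an expanded STR inside the gene's
promoter (TSS +- 3 kb) or body.  RBL (by looping): at least two distinct
expanded STRs inside the anchors of the gene's promoter-centered chromatin
loops, pooled over tissues.  RBT (by TAD): the gene body intersects an
innermost hierarchical TAD (ihTAD) that itself contains an expanded STR.
Genes supported by two or more mechanisms are RBM (regulation by multiple
mechanisms) genes.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .intervals import overlaps

PROMOTER_HALFWIDTH = 3000


def _gene_promoters(genes: pd.DataFrame, halfwidth: int = PROMOTER_HALFWIDTH):
    return pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": (genes["tss"] - halfwidth).clip(lower=0),
            "end": genes["tss"] + halfwidth,
        },
        index=genes.index,
    )


def _support_map(track: pd.DataFrame, hestrs: pd.DataFrame) -> dict[int, set[str]]:
    """Map track row index -> set of overlapping heSTR locus_ids."""
    _, pairs = overlaps(hestrs, track, return_pairs=True)
    out: dict[int, set[str]] = {}
    ids = hestrs["locus_id"]
    for a_idx, b_idx in pairs:
        out.setdefault(b_idx, set()).add(ids.loc[a_idx])
    return out


def rbc_genes(hestrs: pd.DataFrame, genes: pd.DataFrame) -> dict[str, set[str]]:
    """Genes housing at least one expanded STR in promoter or gene body."""
    prom_support = _support_map(_gene_promoters(genes), hestrs)
    body_support = _support_map(genes[["chrom", "start", "end"]], hestrs)
    out: dict[str, set[str]] = {}
    for idx, row in genes.iterrows():
        support = prom_support.get(idx, set()) | body_support.get(idx, set())
        if support:
            out[row["gene_id"]] = support
    return out


def rbl_genes(
    hestrs: pd.DataFrame, loops: pd.DataFrame, min_hestrs: int = 2
) -> dict[str, set[str]]:
    """Genes whose promoter-loop anchors catch >= ``min_hestrs`` distinct loci.

    ``loops`` columns: gene_id, chrom, a1_start, a1_end, a2_start, a2_end
    (plus optional tissue).  Both anchors count; loops are pooled across
    tissues.  Trans (cross-chromosome) loops are rejected with a warning.
    """
    if len(loops) == 0:
        return {}
    if "chrom2" in loops.columns:
        trans = loops["chrom"] != loops["chrom2"]
        if trans.any():
            warnings.warn(f"dropping {int(trans.sum())} trans loops")
            loops = loops[~trans]
    anchors = pd.concat(
        [
            loops[["gene_id", "chrom", "a1_start", "a1_end"]].rename(
                columns={"a1_start": "start", "a1_end": "end"}
            ),
            loops[["gene_id", "chrom", "a2_start", "a2_end"]].rename(
                columns={"a2_start": "start", "a2_end": "end"}
            ),
        ],
        ignore_index=True,
    )
    support = _support_map(anchors[["chrom", "start", "end"]], hestrs)
    per_gene: dict[str, set[str]] = {}
    for idx, gene in anchors["gene_id"].items():
        if idx in support:
            per_gene.setdefault(gene, set()).update(support[idx])
    return {g: s for g, s in per_gene.items() if len(s) >= min_hestrs}


def rbt_genes(
    hestrs: pd.DataFrame, ihtads: pd.DataFrame, genes: pd.DataFrame
) -> dict[str, set[str]]:
    """Genes whose body overlaps an ihTAD (any tissue) containing a locus."""
    if len(ihtads) == 0:
        return {}
    tad_support = _support_map(ihtads[["chrom", "start", "end"]], hestrs)
    hot_tads = ihtads.loc[list(tad_support)]
    if not len(hot_tads):
        return {}
    bodies = genes[["chrom", "start", "end"]]
    _, pairs = overlaps(bodies, hot_tads, return_pairs=True)
    out: dict[str, set[str]] = {}
    for g_idx, t_idx in pairs:
        gene = genes.loc[g_idx, "gene_id"]
        out.setdefault(gene, set()).update(tad_support[t_idx])
    return out


def categorize(
    rbc: dict[str, set[str]],
    rbl: dict[str, set[str]],
    rbt: dict[str, set[str]],
) -> pd.DataFrame:
    """Per-gene mechanism booleans and the RBC/RBL/RBT-only vs RBM partition."""
    universe = sorted(set(rbc) | set(rbl) | set(rbt))
    rows = []
    for g in universe:
        flags = (g in rbc, g in rbl, g in rbt)
        k = sum(flags)
        if k >= 2:
            cat = "RBM"
        elif flags[0]:
            cat = "RBC-only"
        elif flags[1]:
            cat = "RBL-only"
        else:
            cat = "RBT-only"
        support = sorted(rbc.get(g, set()) | rbl.get(g, set()) | rbt.get(g, set()))
        rows.append((g, *flags, cat, ",".join(support)))
    return pd.DataFrame(
        rows, columns=["gene_id", "rbc", "rbl", "rbt", "category", "support"]
    ).set_index("gene_id")
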