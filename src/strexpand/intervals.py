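"""Genomic-interval engine and enrichment statistics.

Tracks are plain DataFrames with ``chrom``, ``start``, ``end`` (0-based,
half-open) plus optional ``name``, ``strand`` and ``value`` columns.  Strand
is carried but ignored by all comparisons (the features involved are
strandless peaks and domains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _check_track(df: pd.DataFrame, name: str = "track") -> pd.DataFrame:
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{name} lacks column {col!r}")
    if len(df) and (df["end"] <= df["start"]).any():
        raise ValueError(f"{name} has intervals with end <= start")
    return df


def overlaps(
    a: pd.DataFrame,
    b: pd.DataFrame,
    slop: int = 0,
    min_overlap: int = 1,
    return_pairs: bool = False,
):
    """Per-a-interval overlap flags against track b extended by ``slop``.

    Half-open overlap after symmetric extension of b; an overlap counts when
    its length is at least ``min_overlap`` bp.  Optionally also returns the
    (a_index, b_index) pair list.
    """
    if slop < 0:
        raise ValueError("slop must be >= 0")
    _check_track(a, "a")
    _check_track(b, "b")
    flags = np.zeros(len(a), dtype=bool)
    pairs: list[tuple[int, int]] = []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in b.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy() - slop
        ends = grp["end"].to_numpy() + slop
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        idx = grp.index.to_numpy()[order]
        by_chrom[chrom] = (starts, ends, idx)

    a_chroms = a["chrom"].to_numpy()
    a_starts = a["start"].to_numpy()
    a_ends = a["end"].to_numpy()
    for i in range(len(a)):
        got = by_chrom.get(a_chroms[i])
        if got is None:
            continue
        starts, ends, idx = got
        # candidates: b.start < a.end - min_overlap + 1
        hi = np.searchsorted(starts, a_ends[i] - min_overlap, side="right")
        if hi == 0:
            continue
        ov = np.minimum(a_ends[i], ends[:hi]) - np.maximum(a_starts[i], starts[:hi])
        hit = ov >= min_overlap
        if hit.any():
            flags[i] = True
            if return_pairs:
                pairs.extend((a.index[i], j) for j in idx[:hi][hit])
    if return_pairs:
        return flags, pairs
    return flags


def closest_distance(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Distance from each a-interval to the nearest b-interval (0 if they
    overlap; inf when b has no interval on that chromosome)."""
    _check_track(a, "a")
    _check_track(b, "b")
    by_chrom = {}
    for chrom, grp in b.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        max_end = np.maximum.accumulate(ends)
        by_chrom[chrom] = (starts, ends, max_end)
    out = np.full(len(a), math.inf)
    for i, (chrom, s, e) in enumerate(
        zip(a["chrom"].to_numpy(), a["start"].to_numpy(), a["end"].to_numpy())
    ):
        got = by_chrom.get(chrom)
        if got is None:
            continue
        starts, ends, max_end = got
        k = np.searchsorted(starts, e, side="left")  # b intervals starting >= a.end
        best = math.inf
        if k < len(starts):
            best = starts[k] - e
        if k > 0:
            # any overlap among intervals starting before a.end?
            if max_end[k - 1] > s:
                ov = np.minimum(e, ends[:k]) - np.maximum(s, starts[:k])
                if (ov > 0).any():
                    out[i] = 0.0
                    continue
            best = min(best, float(s - max_end[k - 1]))
        out[i] = max(best, 0.0)
    return out


def annotate_region_category(
    strs: pd.DataFrame,
    genes: pd.DataFrame,
    exons: pd.DataFrame | None = None,
    promoter_halfwidth: int = 3000,
) -> pd.Series:
    """Assign each STR to promoter, exon, intron or intergenic.

    The promoter is the transcription start site +- ``promoter_halfwidth``
    (3 kb by default); precedence is promoter > exon > intron, and an STR
    touching neither a promoter nor a gene body is intergenic.
    """
    _check_track(strs, "strs")
    for col in ("gene_id", "chrom", "tss", "start", "end"):
        if col not in genes.columns:
            raise ValueError(f"gene models lack column {col!r}")
    if len(genes) and (genes["end"] <= genes["start"]).any():
        raise ValueError("gene with end <= start")
    prom = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": (genes["tss"] - promoter_halfwidth).clip(lower=0),
            "end": genes["tss"] + promoter_halfwidth,
        }
    )
    body = genes[["chrom", "start", "end"]]
    in_prom = overlaps(strs, prom)
    in_body = overlaps(strs, body)
    if exons is not None and len(exons):
        in_exon = overlaps(strs, _check_track(exons, "exons"))
    else:
        in_exon = np.zeros(len(strs), dtype=bool)
    out = np.where(
        in_prom, "promoter", np.where(in_exon & in_body, "exon",
                                      np.where(in_body, "intron", "intergenic"))
    )
    return pd.Series(out, index=strs.index, name="region")


@dataclass
class EnrichmentResult:
    """2x2 overlap enrichment: {set, background} x {overlapping, not}."""

    a: int  # set, overlapping
    b: int  # set, not
    c: int  # background, overlapping
    d: int  # background, not
    odds_ratio: float
    p_two_sided: float
    adjusted_p: float = float("nan")
    haldane_corrected: bool = False
    label: str = ""


def fisher_enrichment(
    set_flags, background_flags, label: str = ""
) -> EnrichmentResult:
    """Fisher's exact test of feature overlap, set versus background.

    Two-sided exact p by summing hypergeometric probabilities no larger than
    the observed table's; odds ratio is the sample ``ad/bc`` with the
    Haldane-Anscombe +0.5 correction applied (and flagged) only when a cell
    is zero.  Set and background must be disjoint groups of loci.
    """
    set_flags = np.asarray(set_flags, dtype=bool)
    background_flags = np.asarray(background_flags, dtype=bool)
    if set_flags.size == 0 or background_flags.size == 0:
        raise ValueError("empty set or background")
    a = int(set_flags.sum())
    b = int((~set_flags).sum())
    c = int(background_flags.sum())
    d = int((~background_flags).sum())
    if a + c == 0 or b + d == 0:
        raise ValueError("degenerate margin: feature column all-zero or all-one")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        corrected = True
    else:
        orr = (a * d) / (b * c)
        corrected = False
    return EnrichmentResult(a, b, c, d, float(orr), float(p),
                            haldane_corrected=corrected, label=label)


def density_profile(
    strs: pd.DataFrame,
    feature_centers: pd.DataFrame,
    half_window: int = 2000,
    n_bins: int = 40,
) -> pd.DataFrame:
    """STR density around feature centers, within +-``half_window`` bp.

    STR midpoints are assigned to their offset from the NEAREST feature
    center; density is loci per bp per feature.  Returns a frame with bin
    edges and densities.
    """
    if n_bins % 2:
        raise ValueError("n_bins must be even")
    if half_window <= 0:
        raise ValueError("half_window must be > 0")
    _check_track(strs, "strs")
    _check_track(feature_centers, "features")
    if not len(feature_centers):
        raise ValueError("no features")
    centers_by_chrom = {
        chrom: np.sort(((grp["start"] + grp["end"]) // 2).to_numpy())
        for chrom, grp in feature_centers.groupby("chrom", sort=False)
    }
    offsets = []
    for chrom, s, e in zip(
        strs["chrom"].to_numpy(), strs["start"].to_numpy(), strs["end"].to_numpy()
    ):
        centers = centers_by_chrom.get(chrom)
        if centers is None:
            continue
        mid = (s + e) // 2
        k = np.searchsorted(centers, mid)
        cands = centers[max(0, k - 1) : k + 1]
        if len(cands) == 0:
            continue
        off = mid - cands[np.argmin(np.abs(cands - mid))]
        if -half_window <= off < half_window:
            offsets.append(off)
    edges = np.linspace(-half_window, half_window, n_bins + 1)
    counts, _ = np.histogram(offsets, bins=edges)
    width = edges[1] - edges[0]
    dens = counts / (width * len(feature_centers))
    return pd.DataFrame(
        {"bin_start": edges[:-1].astype(int), "bin_end": edges[1:].astype(int),
         "count": counts, "density": dens}
    )


def permutation_resample_test(
    observed_stat: float,
    hestr_ids,
    pool_ids,
    stat_fn,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> float:
    """Empirical p for a set statistic against size-matched resamples.

    Draws ``len(hestr_ids)``-sized subsets from the pool, recomputes
    ``stat_fn`` and returns ``(1 + #{perm >= obs}) / (1 + n_perm)`` (or the
    mirrored tail for ``alternative='less'``).
    """
    hestr_ids = list(hestr_ids)
    pool_ids = list(pool_ids)
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if len(hestr_ids) > len(pool_ids):
        raise ValueError("set larger than resampling pool")
    rng = np.random.default_rng(seed)
    k = len(hestr_ids)
    exceed = 0
    pool = np.asarray(pool_ids, dtype=object)
    for _ in range(n_perm):
        sub = pool[rng.choice(len(pool), size=k, replace=False)]
        s = stat_fn(list(sub))
        if alternative == "greater":
            exceed += s >= observed_stat
        else:
            exceed += s <= observed_stat
    return (1 + exceed) / (1 + n_perm)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided pooled-z chi-square test (no continuity correction)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("zero denominators")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts exceed denominators")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if denom == 0:
        return 1.0
    z2 = (p1 - p2) ** 2 / denom
    return float(stats.chi2.sf(z2, df=1))


def random_effects_pool(log_or_list, se_list) -> dict:
    """DerSimonian-Laird random-effects pooling of log odds ratios.

    Returns the pooled OR with its 95% CI and the between-study variance
    tau^2.  A single study passes through unchanged with tau^2 = 0.
    """
    y = np.asarray(log_or_list, dtype=float)
    se = np.asarray(se_list, dtype=float)
    if y.size == 0:
        raise ValueError("no studies")
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    w = 1.0 / se**2
    ybar = np.sum(w * y) / np.sum(w)
    if y.size == 1:
        tau2 = 0.0
    else:
        q = float(np.sum(w * (y - ybar) ** 2))
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (y.size - 1)) / c)
    wstar = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(wstar * y) / np.sum(wstar))
    pooled_se = float(1.0 / math.sqrt(np.sum(wstar)))
    z = 1.959963984540054
    return {
        "pooled_log_or": pooled,
        "pooled_or": math.exp(pooled),
        "ci95": (math.exp(pooled - z * pooled_se), math.exp(pooled + z * pooled_se)),
        "tau2": float(tau2),
        "pooled_se": pooled_se,
        "n_studies": int(y.size),
    }
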