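"""Locus classification cascade: coverage -> unimodality -> consistency -> expansion.

Each homologous STR locus is pushed through four stages:

1. coverage     -- at least ``min_human_calls`` human calls and calls in at
                   least ``min_nhp_species`` distinct non-human-primate (NHP)
                   species, otherwise ``excluded_low_coverage``;
2. unimodality  -- Hartigan's dip test on the pooled close-NHP copy numbers,
                   Benjamini-Hochberg across loci; multimodal loci
                   (``q < dip_fdr_alpha``) become ``excluded_multimodal``;
3. consistency  -- two-sample Kolmogorov-Smirnov of distant-NHP against
                   close-NHP copy numbers, BH across loci; shifted loci
                   become ``excluded_distant_shift``; survivors are ncSTRs
                   (NHP-conserved STRs);
4. expansion    -- one-tailed Wilcoxon rank-sum of human against pooled NHP
                   copy numbers, Bonferroni over the ncSTRs tested; loci with
                   adjusted p below ``hestr_alpha`` are heSTRs
                   (human-specific expanded STRs).

Downstream comparisons use ncSTRs *excluding* heSTRs as the background group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

CLADES = ("human", "close_nhp", "distant_nhp")

TIER_LOW_COVERAGE = "excluded_low_coverage"
TIER_MULTIMODAL = "excluded_multimodal"
TIER_DISTANT_SHIFT = "excluded_distant_shift"
TIER_NCSTR = "ncSTR"
TIER_HESTR = "heSTR"


# ---------------------------------------------------------------------------
# Hartigan & Hartigan dip statistic


def _ecdf_corners(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct values v with ECDF left limits a and right values b."""
    v, counts = np.unique(x, return_counts=True)
    c = np.cumsum(counts)
    n = c[-1]
    b = c / n
    a = (c - counts) / n
    return v, a, b


def _one_sided_dips(v: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-mode lower bound for the convex (left) piece of a unimodal fit.

    ``out[j]`` is the smallest d for which a nondecreasing convex function g
    exists with ``b_i - d <= g_i <= a_i + d`` for i < j, ignoring the hand-off
    to the concave piece: half the largest amount by which the lower corners b
    poke above the greatest convex minorant of the upper corners a on 0..j.
    """
    K = len(v)
    out = np.zeros(K)
    hull: list[int] = [0]
    for j in range(1, K):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            if (a[j] - a[i2]) * (v[i2] - v[i1]) < (a[i2] - a[i1]) * (v[j] - v[i2]):
                hull.pop()
            else:
                break
        hull.append(j)
        gcm = np.interp(v[:j], v[hull], a[hull])
        out[j] = 0.5 * float(np.max(b[:j] - gcm))
    return out


def _forward_floor(v: np.ndarray, a: np.ndarray, b: np.ndarray, d: float):
    """Forced value floors for the convex piece at bandwidth d.

    Propagates, left to right, the minimal value a nondecreasing convex
    function confined to the corner bands ``[b_i - d, a_i + d]`` can take at
    each point: a lower band met at one point combined with an upper band met
    earlier forces a minimum slope, which extrapolates forward.  Returns
    (ok, emin): ``ok[j]`` -- all strict-prefix bands are satisfiable;
    ``emin[j]`` -- the forced floor at j when j is the mode (endpoint band
    ``a_j - d``).
    """
    K = len(v)
    l = np.maximum(0.0, b - d)
    u = a + d
    E = np.empty(K)
    S = np.empty(K)
    emin = np.empty(K)
    ok = np.empty(K, dtype=bool)
    prefix_ok = True
    for t in range(K):
        prop = float(np.max(E[:t] + (v[t] - v[:t]) * S[:t])) if t else 0.0
        E[t] = max(l[t], prop)
        emin[t] = max(a[t] - d, prop, 0.0)
        ok[t] = prefix_ok
        if E[t] > u[t] + 1e-12:
            prefix_ok = False
        S[t] = float(np.max((E[t] - u[:t]) / (v[t] - v[:t]))) if t else 0.0
        if S[t] < 0.0:
            S[t] = 0.0
    return ok, emin


def _dip_feasible(v, a, b, K, d) -> bool:
    """Is there a unimodal df within sup-distance d of this ECDF?"""
    okL, emin = _forward_floor(v, a, b, d)
    okR, emax_m = _forward_floor(-v[::-1], 1.0 - b[::-1], 1.0 - a[::-1], d)
    okR = okR[::-1]
    emax = 1.0 - emax_m[::-1]
    for j in range(K):
        if (
            okL[j]
            and okR[j]
            and emin[j] <= a[j] + d + 1e-12
            and emax[j] >= b[j] - d - 1e-12
            and emin[j] <= emax[j] + 1e-12
        ):
            return True
    return False


def dip_statistic(x) -> float:
    """Hartigan & Hartigan's dip: sup-distance from the ECDF to the closest
    unimodal distribution function.

    For each candidate mode the convex and concave flanks must thread the
    ECDF corner bands; the decoupled flank requirements give a sharp lower
    bound via greatest-convex-minorant geometry, which is then certified (and
    in the rare cases where the two flanks' hand-off binds, tightened by
    bisection) against an exact band-threading feasibility test.  A single
    point mass has dip 0 (a unimodal df may place an atom at its mode); two
    equal point masses attain the upper bound 0.25.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    v, a, b = _ecdf_corners(x)
    K = len(v)
    if K == 1:
        return 0.0
    d_left = _one_sided_dips(v, a, b)
    d_right = _one_sided_dips(-v[::-1], 1.0 - b[::-1], 1.0 - a[::-1])[::-1]
    d0 = float(np.maximum(d_left, d_right).min())
    if _dip_feasible(v, a, b, K, d0 + 1e-11):
        return d0
    lo, hi = d0, 0.25
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if _dip_feasible(v, a, b, K, mid):
            hi = mid
        else:
            lo = mid
    return hi


_NULL_TABLE_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def dip_null_table(n: int, n_boot: int = 10_000, seed: int = 0) -> np.ndarray:
    """Seeded Monte-Carlo dips of uniform(0,1) samples of size ``n``."""
    if n < 4:
        raise ValueError("dip calibration needs n >= 4")
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    key = (n, n_boot, seed)
    if key not in _NULL_TABLE_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([seed, n, n_boot]))
        u = rng.random((n_boot, n))
        _NULL_TABLE_CACHE[key] = np.array([dip_statistic(row) for row in u])
    return _NULL_TABLE_CACHE[key]


def dip_pvalue(dip: float, n: int, n_boot: int = 10_000, seed: int = 0) -> float:
    """Monte-Carlo p-value of an observed dip against the uniform null.

    ``(1 + #{null dips >= observed}) / (1 + n_boot)`` with the null table
    cached per (n, n_boot, seed).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    null = dip_null_table(n, n_boot, seed)
    return float((1 + np.sum(null >= dip)) / (1 + n_boot))


# ---------------------------------------------------------------------------
# Two-sample tests


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the sup-distance between the two ECDFs; the p-value comes from
    scipy's ks_2samp with its default method selection (exact at the small
    per-clade sample sizes used here).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ties switch scipy to asymptotic
        res = stats.ks_2samp(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def rank_sum_one_sided(x, y, alternative: str = "greater") -> float:
    """Wilcoxon rank-sum p-value with midranks and tie-corrected variance.

    Normal approximation without continuity correction, matching the
    behaviour of the classical ranksums routine while remaining valid under
    ties.  ``alternative='greater'`` tests whether x is stochastically larger
    than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n - 1) * n)
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # all values identical
        return 0.5
    z = (w - mu) / np.sqrt(var)
    if alternative == "less":
        z = -z
    return float(stats.norm.sf(z))


def adjust_pvalues(ps, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``bh`` gives Benjamini-Hochberg step-up q-values; ``bonferroni`` gives
    ``min(1, m * p)``.
    """
    from statsmodels.stats.multitest import multipletests

    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps.copy()
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in key:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(ps, method=key[method])[1]


# ---------------------------------------------------------------------------
# Cascade


@dataclass
class PipelineConfig:
    """Thresholds of the classification cascade.

    ``hestr_alpha`` defaults to 0.05 (Bonferroni-adjusted, one-tailed); 0.01
    is the conservative alternative and both are echoed into output headers.
    """

    min_human_calls: int = 10
    min_nhp_species: int = 6
    dip_fdr_alpha: float = 0.05
    ks_fdr_alpha: float = 0.05
    hestr_alpha: float = 0.05
    hestr_adjust: str = "bonferroni"
    hestr_alternative: str = "greater"
    dip_n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self):
        for name in ("dip_fdr_alpha", "ks_fdr_alpha", "hestr_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_human_calls < 1:
            raise ValueError("min_human_calls must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClassificationRecord:
    locus_id: str
    n_human_calls: int = 0
    n_nhp_species_present: int = 0
    dip_stat: float = np.nan
    dip_p: float = np.nan
    dip_q: float = np.nan
    ks_stat: float = np.nan
    ks_p: float = np.nan
    ks_q: float = np.nan
    rs_p: float = np.nan
    rs_p_adj: float = np.nan
    tier: str = TIER_LOW_COVERAGE


def _check_meta(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    required = {"haplotype_id", "species", "clade"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata lacks columns: {sorted(required - set(meta.columns))}")
    meta = meta.set_index("haplotype_id") if meta.index.name != "haplotype_id" else meta
    missing = set(matrix.columns) - set(meta.index)
    if missing:
        raise ValueError(f"matrix columns without metadata: {sorted(missing)[:5]} ...")
    bad = set(meta["clade"].unique()) - set(CLADES)
    if bad:
        raise ValueError(f"unknown clades {sorted(bad)}; expected {CLADES}")
    return meta.loc[list(matrix.columns)]


def filter_homologous(
    matrix: pd.DataFrame, meta: pd.DataFrame, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Coverage filter: per-locus human call counts and NHP species presence.

    Returns a frame indexed by locus with ``n_human_calls``,
    ``n_nhp_species_present`` and a boolean ``kept`` column.  A species is
    present when at least one of its haplotypes has a call.
    """
    cfg = cfg or PipelineConfig()
    meta = _check_meta(matrix, meta)
    human_cols = meta.index[meta["clade"] == "human"]
    nhp = meta[meta["clade"].isin(["close_nhp", "distant_nhp"])]
    n_species_total = nhp["species"].nunique()
    if cfg.min_nhp_species > n_species_total:
        raise ValueError(
            f"min_nhp_species={cfg.min_nhp_species} exceeds the "
            f"{n_species_total} NHP species in the metadata"
        )
    called = matrix.notna()
    n_human = called[human_cols].sum(axis=1)
    by_species = {
        sp: called[nhp.index[nhp["species"] == sp]].any(axis=1)
        for sp in nhp["species"].unique()
    }
    n_species = pd.DataFrame(by_species).sum(axis=1)
    return pd.DataFrame(
        {
            "n_human_calls": n_human.astype(int),
            "n_nhp_species_present": n_species.astype(int),
            "kept": (n_human >= cfg.min_human_calls)
            & (n_species >= cfg.min_nhp_species),
        }
    )


def classify(
    matrix: pd.DataFrame, meta: pd.DataFrame, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Run the full cascade; one row per locus with all statistics and a tier.

    Stage FDRs are computed over the loci actually entering each stage.  Loci
    whose pooled close-NHP sample has fewer than 4 distinct values are
    treated as unimodal by convention (dip 0, p 1).
    """
    cfg = cfg or PipelineConfig()
    meta = _check_meta(matrix, meta)
    human_cols = list(meta.index[meta["clade"] == "human"])
    close_cols = list(meta.index[meta["clade"] == "close_nhp"])
    distant_cols = list(meta.index[meta["clade"] == "distant_nhp"])

    cov = filter_homologous(matrix, meta.reset_index(), cfg)
    records = {
        lid: ClassificationRecord(
            lid,
            n_human_calls=int(cov.loc[lid, "n_human_calls"]),
            n_nhp_species_present=int(cov.loc[lid, "n_nhp_species_present"]),
        )
        for lid in matrix.index
    }

    # Stage 1: dip on pooled close-NHP values
    stage1 = [lid for lid in matrix.index if cov.loc[lid, "kept"]]
    dip_ps = []
    for lid in stage1:
        vals = matrix.loc[lid, close_cols].dropna().to_numpy(dtype=float)
        if len(np.unique(vals)) < 4:
            d, p = 0.0, 1.0
        else:
            d = dip_statistic(vals)
            p = dip_pvalue(d, len(vals), cfg.dip_n_boot, cfg.seed)
        records[lid].dip_stat, records[lid].dip_p = d, p
        dip_ps.append(p)
    dip_qs = adjust_pvalues(dip_ps, "bh")
    stage2 = []
    for lid, q in zip(stage1, dip_qs):
        records[lid].dip_q = q
        if q < cfg.dip_fdr_alpha:
            records[lid].tier = TIER_MULTIMODAL
        else:
            stage2.append(lid)

    # Stage 2: K-S distant vs close
    ks_ps = []
    for lid in stage2:
        x = matrix.loc[lid, distant_cols].dropna().to_numpy(dtype=float)
        y = matrix.loc[lid, close_cols].dropna().to_numpy(dtype=float)
        if x.size == 0 or y.size == 0:
            d, p = np.nan, 1.0
        else:
            d, p = ks_two_sample(x, y)
        records[lid].ks_stat, records[lid].ks_p = d, p
        ks_ps.append(p)
    ks_qs = adjust_pvalues(ks_ps, "bh")
    stage3 = []
    for lid, q in zip(stage2, ks_qs):
        records[lid].ks_q = q
        if q < cfg.ks_fdr_alpha:
            records[lid].tier = TIER_DISTANT_SHIFT
        else:
            records[lid].tier = TIER_NCSTR
            stage3.append(lid)

    # Stage 3: one-tailed rank-sum human vs pooled NHP over ncSTRs
    nhp_cols = close_cols + distant_cols
    rs_ps = []
    for lid in stage3:
        x = matrix.loc[lid, human_cols].dropna().to_numpy(dtype=float)
        y = matrix.loc[lid, nhp_cols].dropna().to_numpy(dtype=float)
        rs_ps.append(rank_sum_one_sided(x, y, cfg.hestr_alternative))
    rs_adj = adjust_pvalues(rs_ps, cfg.hestr_adjust)
    for lid, p, padj in zip(stage3, rs_ps, rs_adj):
        records[lid].rs_p, records[lid].rs_p_adj = p, padj
        if padj < cfg.hestr_alpha:
            records[lid].tier = TIER_HESTR

    out = pd.DataFrame([asdict(records[lid]) for lid in matrix.index])
    return out.set_index("locus_id")


def tier_counts(classification: pd.DataFrame) -> dict[str, int]:
    counts = classification["tier"].value_counts().to_dict()
    for tier in (
        TIER_LOW_COVERAGE,
        TIER_MULTIMODAL,
        TIER_DISTANT_SHIFT,
        TIER_NCSTR,
        TIER_HESTR,
    ):
        counts.setdefault(tier, 0)
    return counts


def background_ncstrs(classification: pd.DataFrame) -> pd.Index:
    """ncSTRs excluding heSTRs: the background set for downstream comparisons."""
    return classification.index[classification["tier"] == TIER_NCSTR]
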