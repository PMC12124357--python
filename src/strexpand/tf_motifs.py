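"""PWM scanning of STR flanks and per-TF binding-site bias.

Position weight matrices (MEME minimal format) are scored as log2 odds
against a background base composition; the per-motif score threshold is the
smallest score whose null tail probability under the background model is at
most alpha (1e-4 by default, the conventional site threshold), computed by
exact dynamic programming over the discretized score distribution.  Per-TF
bias between expanded-STR and conserved-STR flanks is a Fisher test on flank
occupancy with selection at OR > 1 and FDR-adjusted p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import fisher_enrichment
from .strclass import adjust_pvalues

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """Probability matrix, 4 x L with rows A, C, G, T."""

    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x L with L >= 1")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"{self.tf_name}: PWM columns must sum to 1")
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    score: float


def read_meme(path) -> list[PWM]:
    """Parse a MEME minimal-format motif file."""
    pwms: list[PWM] = []
    name = None
    width = None
    rows: list[list[float]] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            s = line.strip()
            if s.lower().startswith("background letter frequencies"):
                freq_line = next(lines).split()
                background = np.array(
                    [float(freq_line[freq_line.index(b) + 1]) for b in "ACGT"]
                )
            elif s.startswith("MOTIF"):
                parts = s.split()
                name = parts[2] if len(parts) > 2 else parts[1]
                rows, width = [], None
            elif s.startswith("letter-probability matrix"):
                if "w=" in s:
                    width = int(s.split("w=")[1].split()[0])
            elif name is not None and s and s[0] in "0123456789.":
                rows.append([float(x) for x in s.split()])
                if width is not None and len(rows) == width:
                    pwms.append(PWM(name, np.array(rows).T, background.copy()))
                    name = None
    if name is not None and rows:  # width not declared
        pwms.append(PWM(name, np.array(rows).T, background.copy()))
    return pwms


def logodds_matrix(pwm: PWM) -> np.ndarray:
    """4 x L log2((p + pc) / (bg + pc)) scoring matrix."""
    pc = pwm.pseudocount
    bg = pwm.background[:, None]
    if pc == 0 and (bg == 0).any():
        raise ValueError("zero background frequency with zero pseudocount")
    with np.errstate(divide="ignore"):
        lo = np.log2((pwm.matrix + pc) / (bg + pc))
    return lo


def score_threshold(
    logodds: np.ndarray,
    background: np.ndarray | None = None,
    alpha: float = 1e-4,
    granularity: float = 0.01,
) -> float:
    """Smallest score s with null tail P_bg(score >= s) <= alpha.

    The null distribution of the window score under the background model is
    computed exactly by dynamic programming over scores discretized to
    ``granularity`` bits (positionwise convolution of the per-column score
    distributions).
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    lo = np.asarray(logodds, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    scaled = np.round(lo / granularity).astype(np.int64)
    L = lo.shape[1]
    if alpha == 1.0:
        return float(lo.min(axis=0).sum())
    col = scaled[:, 0]
    lo0 = int(col.min())
    cur = np.zeros(int(col.max()) - lo0 + 1)
    for bidx in range(4):
        cur[col[bidx] - lo0] += bg[bidx]
    cur_off = lo0
    for j in range(1, L):
        col = scaled[:, j]
        cj_lo = int(col.min())
        step = np.zeros(int(col.max()) - cj_lo + 1)
        for bidx in range(4):
            step[col[bidx] - cj_lo] += bg[bidx]
        cur = np.convolve(cur, step)
        cur_off += cj_lo
    tail = np.cumsum(cur[::-1])[::-1]
    ok = np.nonzero(tail <= alpha)[0]
    if len(ok) == 0:
        return float((cur_off + len(cur)) * granularity)  # unattainable
    return float((cur_off + ok[0]) * granularity)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_IDX.items():
        out[arr == ord(base)] = idx
    return out


_RC = str.maketrans("ACGTN", "TGCAN")


def scan_sequence(
    seq: str, logodds: np.ndarray, threshold: float, both_strands: bool = True
) -> list[tuple[int, str, float]]:
    """All windows scoring at least ``threshold``; N-containing windows skip."""
    L = logodds.shape[1]
    out = []
    for strand in ("+", "-") if both_strands else ("+",):
        s = seq if strand == "+" else seq.translate(_RC)[::-1]
        enc = _encode(s)
        n = len(enc)
        if n < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        valid = (windows >= 0).all(axis=1)
        scores = np.zeros(len(windows))
        cols = np.arange(L)
        safe = np.where(windows >= 0, windows, 0)
        scores = logodds[safe, cols].sum(axis=1)
        hits = np.nonzero(valid & (scores >= threshold))[0]
        for off in hits:
            pos = int(off) if strand == "+" else len(seq) - L - int(off)
            out.append((pos, strand, float(scores[off])))
    return out


def scan_flanks(
    sequences: dict[str, str],
    pwm: PWM,
    threshold: float | None = None,
    both_strands: bool = True,
    alpha: float = 1e-4,
) -> list[MotifHit]:
    """Scan every flank sequence with one PWM; overlapping hits all report."""
    lo = logodds_matrix(pwm)
    if threshold is None:
        threshold = score_threshold(lo, pwm.background, alpha=alpha)
    hits = []
    for sid, seq in sequences.items():
        for pos, strand, score in scan_sequence(seq, lo, threshold, both_strands):
            hits.append(MotifHit(sid, pos, strand, score))
    return hits


def occupancy_counts(hits: list[MotifHit], sequence_ids) -> tuple[int, dict[str, int]]:
    """Number of flanks with >= 1 hit, plus per-flank hit counts."""
    per = {sid: 0 for sid in sequence_ids}
    for h in hits:
        per[h.sequence_id] += 1
    return sum(1 for v in per.values() if v > 0), per


@dataclass
class TFBiasRecord:
    tf_name: str
    hits_hestr: int
    hits_ncstr: int
    flanks_hestr: int
    flanks_ncstr: int
    odds_ratio: float
    p: float
    q: float = float("nan")
    biased: bool = False


def tf_bias(
    occupied_hestr: dict[str, int],
    occupied_ncstr: dict[str, int],
    n_flanks_hestr: int,
    n_flanks_ncstr: int,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-TF occupancy bias between expanded and conserved STR flanks.

    Inputs map tf_name -> number of flank units with at least one binding
    site, from identical scan settings in both groups.  The 2x2 per TF is
    {occupied, not} x {heSTR flanks, ncSTR flanks}; BH across TFs; a TF is
    biased iff OR > 1 and q < ``fdr_alpha``.
    """
    if n_flanks_hestr <= 0 or n_flanks_ncstr <= 0:
        raise ValueError("zero flanks in a group")
    tfs = sorted(set(occupied_hestr) | set(occupied_ncstr))
    recs = []
    for tf in tfs:
        kh = int(occupied_hestr.get(tf, 0))
        kn = int(occupied_ncstr.get(tf, 0))
        set_flags = np.concatenate(
            [np.ones(kh, bool), np.zeros(n_flanks_hestr - kh, bool)]
        )
        bg_flags = np.concatenate(
            [np.ones(kn, bool), np.zeros(n_flanks_ncstr - kn, bool)]
        )
        try:
            res = fisher_enrichment(set_flags, bg_flags, label=tf)
            orr, p = res.odds_ratio, res.p_two_sided
        except ValueError:  # degenerate margin: all or no flanks occupied
            orr, p = 1.0, 1.0
        recs.append(
            TFBiasRecord(tf, kh, kn, n_flanks_hestr, n_flanks_ncstr, orr, p)
        )
    qs = adjust_pvalues([r.p for r in recs], "bh")
    for r, q in zip(recs, qs):
        r.q = float(q)
        r.biased = bool(r.odds_ratio > 1 and q < fdr_alpha)
    return pd.DataFrame(
        [
            (r.tf_name, r.hits_hestr, r.hits_ncstr, r.flanks_hestr, r.flanks_ncstr,
             r.odds_ratio, r.p, r.q, r.biased)
            for r in recs
        ],
        columns=["tf_name", "hits_hestr", "hits_ncstr", "flanks_hestr",
                 "flanks_ncstr", "odds_ratio", "p", "q", "biased"],
    ).set_index("tf_name")


def cross_species_or_shift(
    or_human: pd.Series, or_by_species: pd.DataFrame
) -> float:
    """One-sided Wilcoxon signed-rank: human OR exceeds the NHP species mean.

    Per TF, d = OR_human - mean over species; zeros are dropped (standard
    convention).  All-zero differences degenerate to p = 1 with a warning.
    """
    common = or_human.index.intersection(or_by_species.index)
    if len(common) < 5:
        raise ValueError("need at least 5 shared TFs")
    d = (or_human.loc[common] - or_by_species.loc[common].mean(axis=1)).to_numpy()
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all OR differences are zero; shift test degenerate")
        return 1.0
    return float(stats.wilcoxon(d, alternative="greater").pvalue)
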