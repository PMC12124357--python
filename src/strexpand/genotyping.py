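"""STR copy-number genotyping in haploid genome assemblies.

A reference STR panel (1--6 bp ``Simple_repeat`` motifs) is mapped into each
target haploid genome by anchoring the 500-bp flanking sequences, the repeat
tract is re-detected inside the mapped region, and the copy number is the
tract length divided by the motif length.  All coordinates are 0-based
half-open (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DNA = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

DEFAULT_FLANK_LEN = 500
DEFAULT_SEED_K = 21
DEFAULT_CANDIDATE_CAP = 64


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonicalize_motif(motif: str) -> str:
    """Canonical form of a repeat motif.

    The lexicographically smallest string among all cyclic rotations of the
    motif and of its reverse complement, so that e.g. ``CA``, ``AC``, ``TG``
    and ``GT`` all canonicalize to ``AC``.  Idempotent by construction.
    """
    motif = motif.upper()
    if not motif or any(c not in DNA for c in motif):
        raise ValueError(f"motif must be a non-empty ACGT string, got {motif!r}")
    rc = reverse_complement(motif)
    doubled, rc_doubled = motif + motif, rc + rc
    m = len(motif)
    candidates = [doubled[i : i + m] for i in range(m)]
    candidates += [rc_doubled[i : i + m] for i in range(m)]
    return min(candidates)


def primitive_motif(unit: str) -> str:
    """Shortest string whose tandem repetition yields ``unit``."""
    m = len(unit)
    for p in range(1, m + 1):
        if m % p == 0 and unit == unit[:p] * (m // p):
            return unit[:p]
    return unit


@dataclass(frozen=True)
class STRLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    motif: str
    canonical_motif: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.locus_id}: end <= start")
        if self.end - self.start < len(self.motif):
            raise ValueError(f"{self.locus_id}: interval shorter than motif")
        if not self.canonical_motif:
            object.__setattr__(self, "canonical_motif", canonicalize_motif(self.motif))


@dataclass
class STRPanel:
    """Ordered reference panel of STR loci."""

    loci: list[STRLocus] = field(default_factory=list)

    def __len__(self):
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, i):
        return self.loci[i]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (l.chrom, l.start, l.end, l.motif, l.canonical_motif, l.locus_id)
                for l in self.loci
            ],
            columns=["chrom", "start", "end", "motif", "canonical_motif", "locus_id"],
        )


@dataclass(frozen=True)
class MappedRegion:
    target_id: str
    start: int
    end: int
    identity_fraction: float = 1.0

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("mapped region end <= start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatTract:
    start: int
    end: int
    motif: str  # primitive, canonical
    copy_number: float
    purity: float = 1.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenotypeCall:
    locus_id: str
    haplotype_id: str
    status: str  # "called" | "missing"
    copy_number: float | None = None
    tract: RepeatTract | None = None

    def __post_init__(self):
        if (self.status == "missing") != (self.copy_number is None):
            raise ValueError("status 'missing' iff copy_number absent")


def build_reference_panel(records: pd.DataFrame) -> STRPanel:
    """Filter a repeat-annotation table down to the STR reference panel.

    Keeps records whose repeat class is ``Simple_repeat`` and whose motif is
    an ACGT string of 1--6 bp.  Malformed records are rejected with a warning
    rather than aborting the panel build.  Locus ids are stable
    ``chrom:start-end:motif`` strings.
    """
    required = {"chrom", "start", "end", "motif"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"panel table lacks columns: {sorted(missing)}")
    loci: list[STRLocus] = []
    has_class = "class" in records.columns
    for rec in records.to_dict("records"):
        if has_class and rec["class"] != "Simple_repeat":
            continue
        motif = str(rec["motif"]).upper()
        if not (1 <= len(motif) <= 6) or any(c not in DNA for c in motif):
            if 1 <= len(motif) <= 6:
                warnings.warn(f"rejecting record with non-ACGT motif {motif!r}")
            continue
        start, end = int(rec["start"]), int(rec["end"])
        chrom = str(rec["chrom"])
        if end <= start:
            warnings.warn(f"rejecting record with end <= start at {chrom}:{start}")
            continue
        locus_id = f"{chrom}:{start}-{end}:{motif}"
        loci.append(STRLocus(locus_id, chrom, start, end, motif))
    return STRPanel(loci)


# ---------------------------------------------------------------------------
# Repeat-tract detection


def detect_repeats(
    segment: str, min_copies: float = 2.0, min_tract_bp: int = 2
) -> list[RepeatTract]:
    """Find maximal perfect tandem tracts of 1--6 bp motifs in ``segment``.

    For each motif length ``m`` maximal runs with ``segment[i] == segment[i+m]``
    are located; a run of r matched positions is a tract of length ``r + m``.
    Tracts whose repeat unit is itself a repetition of a shorter motif are
    collapsed onto the primitive motif (reported once, at the primitive
    length).  Motifs are reported in canonical form.
    """
    if not segment:
        raise ValueError("empty segment")
    seq = segment.upper()
    n = len(seq)
    out: list[RepeatTract] = []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for m in range(1, 7):
        if n < 2 * m:
            continue
        match = arr[m:] == arr[:-m]  # match[i]: seq[i] == seq[i+m]
        # maximal runs of True
        padded = np.concatenate(([False], match, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]  # run is match[starts:ends]
        for s, e in zip(starts, ends):
            tract_len = (e - s) + m
            unit = seq[s : s + m]
            if primitive_motif(unit) != unit:
                continue  # reported at the primitive motif length
            copies = tract_len / m
            if copies < min_copies or tract_len < min_tract_bp:
                continue
            out.append(
                RepeatTract(
                    start=int(s),
                    end=int(s + tract_len),
                    motif=canonicalize_motif(unit),
                    copy_number=copies,
                )
            )
    out.sort(key=lambda t: (t.start, t.end, t.motif))
    return out


# ---------------------------------------------------------------------------
# Locus localization by flank anchoring


def _find_all(target: str, seed: str) -> list[int]:
    hits, i = [], target.find(seed)
    while i != -1:
        hits.append(i)
        i = target.find(seed, i + 1)
    return hits


def _anchor_positions(
    target: str, flank: str, k: int, from_end: bool
) -> list[tuple[int, int]]:
    """Exact-seed hits of a flank in the target.

    Seeds of length ``k`` are tried at successive offsets into the flank
    (stepping inward) until one has at least one exact hit.  Returns
    ``(anchor_start_in_target, offset_of_seed_in_flank)`` pairs.
    """
    L = len(flank)
    if L < k:
        return []
    offsets = range(L - k, -1, -k) if from_end else range(0, L - k + 1, k)
    for off in offsets:
        seed = flank[off : off + k]
        hits = _find_all(target, seed)
        if hits:
            return [(h, off) for h in hits]
    return []


def locate_locus(
    query: str,
    target: str,
    *,
    target_id: str = "target",
    flank_len: int = DEFAULT_FLANK_LEN,
    k: int = DEFAULT_SEED_K,
    candidate_cap: int = DEFAULT_CANDIDATE_CAP,
) -> MappedRegion | None:
    """Locate ``query`` (STR plus flanks) in a target sequence.

    The left and right flanks are anchored by exact seed k-mers with the seed
    slid inward when the outermost k-mer carries a mismatch.  Candidate
    regions pair a left with a right anchor; the LONGEST candidate region is
    returned, mirroring the longest-mapped-region rule used to resolve
    multi-mapping.  ``None`` when no anchor pair is found.
    """
    query = query.upper()
    target = target.upper()
    if len(query) < 2 * k:
        raise ValueError("query shorter than two anchor seeds")
    left = query[:flank_len]
    right = query[-flank_len:]
    lhits = _anchor_positions(target, left, k, from_end=False)
    rhits = _anchor_positions(target, right, k, from_end=True)
    if not lhits or not rhits:
        return None
    if len(lhits) * len(rhits) > candidate_cap:
        raise ValueError(
            f"ambiguous anchoring: {len(lhits)}x{len(rhits)} candidate pairs "
            f"exceed cap {candidate_cap}"
        )
    best: MappedRegion | None = None
    for lpos, loff in lhits:
        rstart = lpos - loff  # inferred region start
        for rpos, roff in rhits:
            rend = rpos + (len(right) - roff)  # inferred region end
            if rend <= rstart or rpos <= lpos:
                continue
            rstart_c = max(0, rstart)
            rend_c = min(len(target), rend)
            region = MappedRegion(
                target_id,
                rstart_c,
                rend_c,
                identity_fraction=_quick_identity(query, target[rstart_c:rend_c]),
            )
            if best is None or region.length > best.length:
                best = region
    return best


def _quick_identity(query: str, segment: str) -> float:
    if len(query) == len(segment):
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        s = np.frombuffer(segment.encode(), dtype=np.uint8)
        return float((q == s).mean()) if len(q) else 0.0
    # length change (e.g. copy-number difference): compare the aligned ends
    m = min(len(query), len(segment)) // 2
    if m == 0:
        return 0.0
    q = np.frombuffer((query[:m] + query[-m:]).encode(), dtype=np.uint8)
    s = np.frombuffer((segment[:m] + segment[-m:]).encode(), dtype=np.uint8)
    return float((q == s).mean())


def longest_region(regions: Iterable[MappedRegion]) -> MappedRegion | None:
    """Apply the longest-mapped-region rule to externally supplied intervals."""
    regions = list(regions)
    if not regions:
        return None
    return max(regions, key=lambda r: r.length)


# ---------------------------------------------------------------------------
# Per-locus call


def call_str(
    tracts: Sequence[RepeatTract],
    expected_canonical_motif: str,
    region: MappedRegion,
    *,
    locus_id: str = "",
    haplotype_id: str = "",
    flank_len: int = DEFAULT_FLANK_LEN,
) -> GenotypeCall:
    """Select the genotyped tract for a locus inside its mapped region.

    Tracts whose canonical motif differs from the expected one are dropped.
    When several remain, the tract whose boundaries sit closest to
    ``flank_len`` bp from the region boundaries wins (L1 sum over both
    boundaries); exact ties resolve to the smaller start coordinate.
    """
    matching = [t for t in tracts if t.motif == expected_canonical_motif]
    if not matching:
        return GenotypeCall(locus_id, haplotype_id, "missing")

    def score(t: RepeatTract) -> tuple[float, int]:
        left_gap = t.start
        right_gap = region.length - t.end
        return (abs(left_gap - flank_len) + abs(right_gap - flank_len), t.start)

    best = min(matching, key=score)
    return GenotypeCall(locus_id, haplotype_id, "called", best.copy_number, best)


def genotype_cohort(
    panel: STRPanel,
    reference: Mapping[str, str],
    genomes: Mapping[str, Mapping[str, str]],
    *,
    flank_len: int = DEFAULT_FLANK_LEN,
    k: int = DEFAULT_SEED_K,
    min_copies: float = 2.0,
) -> pd.DataFrame:
    """Genotype every panel locus in every haploid genome.

    ``reference`` maps contig -> sequence for the assembly the panel
    coordinates refer to; ``genomes`` maps haplotype_id -> contig -> sequence.
    Returns a loci x haplotypes copy-number matrix with NaN for missing calls.
    Deterministic given its inputs.
    """
    hap_ids = list(genomes)
    if len(set(hap_ids)) != len(hap_ids):
        raise ValueError("duplicate haplotype ids")
    mat = pd.DataFrame(
        np.nan, index=pd.Index(panel.locus_ids, name="locus_id"), columns=hap_ids
    )
    queries: list[tuple[STRLocus, str]] = []
    for locus in panel:
        if locus.chrom not in reference:
            raise ValueError(f"panel contig {locus.chrom!r} absent from reference")
        contig = reference[locus.chrom]
        qs = max(0, locus.start - flank_len)
        qe = min(len(contig), locus.end + flank_len)
        queries.append((locus, contig[qs:qe]))
    for hap_id in hap_ids:
        contigs = genomes[hap_id]
        for locus, query in queries:
            call = _genotype_one(locus, query, contigs, flank_len, k, min_copies, hap_id)
            if call.status == "called":
                mat.loc[locus.locus_id, hap_id] = call.copy_number
    return mat


def _genotype_one(
    locus: STRLocus,
    query: str,
    contigs: Mapping[str, str],
    flank_len: int,
    k: int,
    min_copies: float,
    hap_id: str,
) -> GenotypeCall:
    best: MappedRegion | None = None
    for name, seq in contigs.items():
        try:
            region = locate_locus(
                query, seq, target_id=name, flank_len=flank_len, k=k
            )
        except ValueError:
            return GenotypeCall(locus.locus_id, hap_id, "missing")
        if region is not None and (best is None or region.length > best.length):
            best = region
    if best is None:
        return GenotypeCall(locus.locus_id, hap_id, "missing")
    segment = contigs[best.target_id][best.start : best.end]
    tracts = detect_repeats(segment, min_copies=min_copies)
    return call_str(
        tracts,
        locus.canonical_motif,
        best,
        locus_id=locus.locus_id,
        haplotype_id=hap_id,
        flank_len=flank_len,
    )
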