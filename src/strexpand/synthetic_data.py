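"""Synthetic inputs for every pipeline stage, with known truth labels.

The default cohort design mirrors the study population the classifier is
built for: 148 human haplotypes, 18 haplotypes from four closely related
great-ape species and 8 from three more distantly related primates.  Copy
numbers are truncated (>= 1) normals rounded to 0.1 copies; multimodality is
a symmetric two-component mixture; every generator is a pure function of its
parameters and a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotyping import DNA, STRLocus, STRPanel, primitive_motif

SCENARIOS = ("conserved", "human_expanded", "close_multimodal", "distant_shifted")

DEFAULT_CLOSE_SPECIES = [
    ("chimpanzee", 6),
    ("bonobo", 4),
    ("gorilla", 4),
    ("orangutan", 4),
]
DEFAULT_DISTANT_SPECIES = [("gibbon", 3), ("rhesus_macaque", 3), ("crab_eating_macaque", 2)]


@dataclass
class CohortDesign:
    """Haplotype counts per species; defaults reproduce the 148 + 18 + 8 cohort."""

    n_human: int = 148
    close_species: list[tuple[str, int]] = field(
        default_factory=lambda: list(DEFAULT_CLOSE_SPECIES)
    )
    distant_species: list[tuple[str, int]] = field(
        default_factory=lambda: list(DEFAULT_DISTANT_SPECIES)
    )
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for a CohortDesign")
        names = [s for s, _ in self.close_species] + [s for s, _ in self.distant_species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        counts = [self.n_human] + [n for _, n in self.close_species + self.distant_species]
        if any(c < 0 for c in counts):
            raise ValueError("haplotype counts must be >= 0")

    @property
    def n_close(self) -> int:
        return sum(n for _, n in self.close_species)

    @property
    def n_distant(self) -> int:
        return sum(n for _, n in self.distant_species)

    def metadata(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_human):
            hap = f"human_{i + 1:03d}"
            rows.append((hap, hap.rsplit("_", 1)[0] + f"_s{i + 1:03d}", "human", "human"))
        for species, n in self.close_species:
            for i in range(n):
                hap = f"{species}_{i + 1:02d}"
                rows.append((hap, f"{species}_s{i + 1:02d}", species, "close_nhp"))
        for species, n in self.distant_species:
            for i in range(n):
                hap = f"{species}_{i + 1:02d}"
                rows.append((hap, f"{species}_s{i + 1:02d}", species, "distant_nhp"))
        return pd.DataFrame(rows, columns=["haplotype_id", "sample_id", "species", "clade"])


@dataclass
class LocusScenario:
    """Distributional scenario planted at a locus.

    ``effect`` is the expansion shift (human_expanded), mixture separation
    (close_multimodal) or distant-clade shift (distant_shifted), in copies.
    """

    scenario: str
    base_mean: float = 20.0
    base_sd: float = 1.0
    effect: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.base_sd <= 0:
            raise ValueError("base_sd must be > 0")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must be in [0, 1]")


def _draw(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    vals = rng.normal(mean, sd, size)
    return np.round(np.maximum(vals, 1.0), 1)


def gen_cohort_matrix(
    design: CohortDesign, scenarios: Sequence[tuple[LocusScenario, int]]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a loci x haplotypes copy-number matrix with planted truth.

    Returns ``(matrix, meta, truth)``: matrix has NaN for missing entries;
    truth maps each locus to its planted scenario and parameters.  Identical
    (design, scenarios) give identical output.
    """
    if not scenarios or all(n <= 0 for _, n in scenarios):
        raise ValueError("at least one scenario with n_loci > 0 is required")
    rng = np.random.default_rng(design.seed)
    meta = design.metadata()
    clades = meta["clade"].to_numpy()
    hum = clades == "human"
    close = clades == "close_nhp"
    distant = clades == "distant_nhp"
    n_hap = len(meta)

    rows, truth_rows, locus_ids = [], [], []
    idx = 0
    for scen, n_loci in scenarios:
        for _ in range(max(0, n_loci)):
            idx += 1
            lid = f"L{idx:06d}"
            vals = np.empty(n_hap)
            if scen.scenario == "conserved":
                vals[:] = _draw(rng, scen.base_mean, scen.base_sd, n_hap)
            elif scen.scenario == "human_expanded":
                vals[:] = _draw(rng, scen.base_mean, scen.base_sd, n_hap)
                vals[hum] = _draw(rng, scen.base_mean + scen.effect, scen.base_sd, hum.sum())
            elif scen.scenario == "close_multimodal":
                vals[:] = _draw(rng, scen.base_mean, scen.base_sd, n_hap)
                comp = rng.random(close.sum()) < 0.5
                means = np.where(
                    comp, scen.base_mean - scen.effect / 2, scen.base_mean + scen.effect / 2
                )
                vals[close] = np.round(
                    np.maximum(rng.normal(means, scen.base_sd), 1.0), 1
                )
            else:  # distant_shifted
                vals[:] = _draw(rng, scen.base_mean, scen.base_sd, n_hap)
                vals[distant] = _draw(
                    rng, scen.base_mean + scen.effect, scen.base_sd, distant.sum()
                )
            if scen.missing_rate > 0:
                vals[rng.random(n_hap) < scen.missing_rate] = np.nan
            rows.append(vals)
            locus_ids.append(lid)
            truth_rows.append(
                (lid, scen.scenario, scen.base_mean, scen.base_sd, scen.effect,
                 scen.missing_rate)
            )
    matrix = pd.DataFrame(
        np.array(rows), index=pd.Index(locus_ids, name="locus_id"),
        columns=meta["haplotype_id"].tolist(),
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["locus_id", "scenario", "base_mean", "base_sd", "effect", "missing_rate"],
    ).set_index("locus_id")
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# Genotyping fixtures


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, length)])


def _random_primitive_motif(rng: np.random.Generator, mmin: int, mmax: int) -> str:
    while True:
        m = int(rng.integers(mmin, mmax + 1))
        motif = _random_seq(rng, m)
        if primitive_motif(motif) == motif and len(set(motif)) >= min(2, m):
            return motif


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def gen_genotyping_fixture(
    n_loci: int,
    *,
    motif_length_range: tuple[int, int] = (1, 6),
    copies_range: tuple[int, int] = (8, 30),
    flank_len: int = 500,
    snv_rate: float = 0.0,
    n_haplotypes: int = 4,
    spacer_len: int = 100,
    seed: int | None = None,
) -> tuple[dict[str, str], dict[str, dict[str, str]], STRPanel, pd.DataFrame]:
    """Toy genomes with planted STR tracts in unique flanks.

    Returns ``(reference, genomes, panel, truth)``.  ``reference`` maps
    contig -> sequence for the panel's reference assembly; ``genomes`` maps
    haplotype_id -> contigs.  Each locus carries a pure tandem tract of a
    primitive motif; per-haplotype copy numbers vary within ``copies_range``.
    Flank uniqueness is enforced by rejection sampling against 21-mer
    collisions so anchoring is unambiguous at ``snv_rate`` 0; SNVs mutate
    flank (not tract) bases i.i.d.  Truth records exact tract coordinates.
    """
    mmin, mmax = motif_length_range
    if mmin < 1 or mmax > 6 or mmin > mmax:
        raise ValueError("motif lengths must lie within 1-6")
    if copies_range[0] < 2:
        raise ValueError("copies must be >= 2")
    if flank_len < mmax:
        raise ValueError("flank_len must be >= motif length")
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)

    k = 21
    seen: set[str] = set()
    loci = []
    for i in range(n_loci):
        motif = _random_primitive_motif(rng, mmin, mmax)
        while True:  # unique flanks, no accidental tract extension
            left = _random_seq(rng, flank_len)
            right = _random_seq(rng, flank_len)
            if left[-1] == motif[-1] or right[0] == motif[0]:
                continue
            kms = _kmers(left, k) | _kmers(right, k)
            if len(kms) == 2 * (flank_len - k + 1) and not (kms & seen):
                seen |= kms
                break
        ref_copies = int(rng.integers(copies_range[0], copies_range[1] + 1))
        hap_copies = rng.integers(copies_range[0], copies_range[1] + 1, n_haplotypes)
        loci.append((f"S{i + 1:05d}", motif, left, right, ref_copies, hap_copies))

    def assemble(which: int | None) -> tuple[dict[str, str], list[tuple[str, int, int, int]]]:
        parts, coords = [], []
        pos = 0
        for lid, motif, left, right, ref_c, hap_c in loci:
            copies = ref_c if which is None else int(hap_c[which])
            spacer = _random_seq(spacer_rng, spacer_len)
            tract = motif * copies
            parts += [spacer, left, tract, right]
            pos += spacer_len + flank_len
            coords.append((lid, pos, pos + len(tract), copies))
            pos += len(tract) + flank_len
        return {"chr1": "".join(parts)}, coords

    spacer_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    reference, ref_coords = assemble(None)
    genomes: dict[str, dict[str, str]] = {}
    truth_rows = []
    for h in range(n_haplotypes):
        spacer_rng = np.random.default_rng(np.random.SeedSequence([seed, 2 + h]))
        contigs, coords = assemble(h)
        hap_id = f"hap_{h + 1:02d}"
        if snv_rate > 0:
            contigs = {
                name: _mutate_outside_tracts(seq, coords, snv_rate, rng)
                for name, seq in contigs.items()
            }
        genomes[hap_id] = contigs
        for lid, start, end, copies in coords:
            truth_rows.append((lid, hap_id, start, end, float(copies)))
    panel = STRPanel(
        [
            STRLocus(lid, "chr1", start, end, loci[i][1])
            for i, (lid, start, end, _c) in enumerate(ref_coords)
        ]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["locus_id", "haplotype_id", "start", "end", "copy_number"]
    )
    return reference, genomes, panel, truth


def _mutate_outside_tracts(seq, coords, rate, rng):
    arr = np.array(list(seq))
    protect = np.zeros(len(arr), dtype=bool)
    for _lid, start, end, _c in coords:
        protect[start:end] = True
    hit = (rng.random(len(arr)) < rate) & ~protect
    if hit.any():
        subs = np.array(list(DNA))[rng.integers(0, 4, hit.sum())]
        arr[hit] = subs  # may silently resample the same base
    return "".join(arr)


# ---------------------------------------------------------------------------
# Annotation / expression fixtures


def gen_annotation_fixture(
    genome_size: int,
    strs: pd.DataFrame,
    enriched_subset: Sequence[str],
    n_features: int,
    enrichment_factor: float,
    *,
    feature_len: int = 200,
    disjoint: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Feature track whose overlap odds with ``enriched_subset`` are planted.

    Features are placed either uniformly or directly onto a random member of
    the enriched subset, with the mixing weight chosen so that the
    per-feature probability of hitting the subset is ``enrichment_factor``
    times the uniform-background rate.  ``enrichment_factor=inf`` puts every
    feature on the subset.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if n_features == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1 (or inf)")
    sub = strs[strs["locus_id"].isin(set(enriched_subset))] if len(enriched_subset) else strs.iloc[:0]
    if len(sub) == 0 and enrichment_factor > 1:
        raise ValueError("enriched_subset is empty or unknown")
    rng = np.random.default_rng(seed)
    # uniform-background probability that a feature overlaps the subset
    p0 = min(
        1.0,
        float(((sub["end"] - sub["start"]) + feature_len).sum()) / genome_size,
    ) if len(sub) else 0.0
    if np.isinf(enrichment_factor):
        q = 1.0
    else:
        target = min(1.0, enrichment_factor * p0)
        q = 0.0 if p0 >= 1.0 else max(0.0, (target - p0) / (1.0 - p0))
    if disjoint and n_features * feature_len > genome_size:
        raise ValueError(
            f"genome of {genome_size} bp cannot hold {n_features} disjoint "
            f"{feature_len}-bp features"
        )
    rows = []
    taken: list[tuple[int, int]] = []
    for i in range(n_features):
        for _attempt in range(1000):
            if len(sub) and rng.random() < q:
                t = sub.iloc[int(rng.integers(0, len(sub)))]
                center = int(rng.integers(t["start"], t["end"]))
                start = max(0, center - feature_len // 2)
            else:
                start = int(rng.integers(0, max(1, genome_size - feature_len)))
            end = min(genome_size, start + feature_len)
            if not disjoint or all(e <= start or end <= s for s, e in taken):
                break
        else:
            raise ValueError("could not place disjoint features; genome too full")
        if disjoint:
            taken.append((start, end))
        rows.append(("chr1", start, end, f"feat_{i + 1:05d}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def gen_expression_fixture(
    gene_sets: Mapping[str, Sequence[str]],
    lfc_effect: float | Mapping[str, float],
    noise_sd: float,
    n_conditions: int,
    *,
    n_background: int = 1000,
    base_log_mean: float = 5.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Paired human/NHP expression tables with a planted log2 fold change.

    The human table equals the NHP table times ``2**lfc_effect`` for genes in
    the target sets (per-set effects via a mapping) and ``2**eps``,
    ``eps ~ N(0, noise_sd)``, elsewhere (and multiplicatively on top for set
    genes).  Returns ``(human, nhp, set_membership)``.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    set_genes: dict[str, str] = {}
    for name, genes in gene_sets.items():
        for g in genes:
            if g in set_genes and set_genes[g] != name:
                raise ValueError(f"gene {g} appears in multiple sets")
            set_genes[g] = name
    background = [f"bg_{i + 1:05d}" for i in range(n_background)]
    genes = list(set_genes) + background
    membership = pd.Series(
        [set_genes.get(g, "background") for g in genes], index=genes, name="gene_set"
    )
    base = rng.lognormal(mean=base_log_mean, sigma=1.0, size=(len(genes), n_conditions))
    nhp = pd.DataFrame(
        base, index=genes, columns=[f"cond_{j + 1:02d}" for j in range(n_conditions)]
    )
    if isinstance(lfc_effect, Mapping):
        eff = np.array([lfc_effect.get(membership[g], 0.0) for g in genes])
    else:
        eff = np.where(membership.to_numpy() != "background", float(lfc_effect), 0.0)
    eps = (
        rng.normal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else np.zeros(base.shape)
    )
    human = nhp * np.power(2.0, eff[:, None] + eps)
    return human, nhp, membership
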