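"""Readers and writers for the pipeline's plain-text interchange formats.

Matrices and metadata are TSV; interval tracks are BED3/BED6 (0-based,
half-open, no headers, optional 5th ``value`` column for TADs); loops are
BEDPE with a gene_id column; FASTA goes through Biopython.  All floats are
written with a fixed format so outputs are byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.6g"


def read_matrix(path) -> pd.DataFrame:
    """Loci x haplotypes copy-number TSV with 'NA' for missing."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FORMAT,
                  index_label="locus_id")


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"haplotype_id", "species", "clade"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata lacks columns {sorted(required - set(meta.columns))}")
    return meta


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """BED3+ without header: chrom, start, end[, name[, value[, strand]]]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "value", "strand"][: df.shape[1]]
    df.columns = cols + [f"extra_{i}" for i in range(df.shape[1] - len(cols))]
    return df


def write_bed(track: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "value", "strand")
            if c in track.columns]
    track[cols].to_csv(path, sep="\t", header=False, index=False,
                       float_format=FLOAT_FORMAT)


def read_bedpe_loops(path) -> pd.DataFrame:
    """BEDPE with a trailing gene_id (and optional tissue) column."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    base = ["chrom", "a1_start", "a1_end", "chrom2", "a2_start", "a2_end", "gene_id"]
    cols = base[: df.shape[1]]
    df.columns = cols + (["tissue"] if df.shape[1] == len(base) + 1 else [])[
        : max(0, df.shape[1] - len(cols))
    ]
    return df


def read_genes(path) -> pd.DataFrame:
    """Gene models TSV: gene_id, chrom, strand, tss, start, end."""
    genes = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "start", "end"}
    if not required <= set(genes.columns):
        raise ValueError(f"gene table lacks columns {sorted(required - set(genes.columns))}")
    return genes


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_classification(classification: pd.DataFrame, path, config: dict | None = None):
    """Classification TSV with a config-echo header and a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        if config:
            fh.write("# config: " + json.dumps(config, sort_keys=True) + "\n")
        classification.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)
    from .strclass import tier_counts

    summary = {"tiers": tier_counts(classification)}
    if config:
        summary["config"] = config
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"unserializable {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
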