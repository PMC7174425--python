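"""Reading, writing and quality filtering of gene presence/absence data.

Two on-disk dialects are supported for the genome x gene-cluster membership
matrix: the Roary ``gene_presence_absence.csv`` layout (14 metadata columns
followed by one column per genome; a non-empty cell marks presence, and
semicolon-joined paralog cells count as a single presence) and a generic
binary TSV (header row of cluster ids, first column genome id, cells 0/1).

Genome-level filters applied before any feature computation:

* assembly quality — keep genomes with at most ``max_contigs`` contigs;
* redundancy — of any genome pair with identical core genomes (pairwise
  core-genome nucleotide identity at the configured threshold, default 1.0)
  and gene-content Jaccard similarity above ``jaccard_threshold`` (default
  0.99), only one member is retained;
* sample size — a species enters the analysis only with at least
  ``n_min`` genomes (default 10).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateIdError, FormatError, SpeciesExcludedError

logger = logging.getLogger(__name__)

#: Column names of the 14 Roary metadata columns preceding genome columns.
ROARY_META_COLUMNS = (
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
)


@dataclass
class GenomeRecord:
    """Per-genome assembly metadata used by the quality filters."""

    genome_id: str
    species_id: str
    n_contigs: int | None
    n_genes: int = 0

    def __post_init__(self):
        if self.n_contigs is not None and self.n_contigs < 1:
            raise ValueError(f"n_contigs must be >= 1, got {self.n_contigs}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass
class GenePresenceMatrix:
    """Binary genome x gene-cluster membership for one species.

    ``presence[i, j]`` is True when genome ``genome_ids[i]`` carries cluster
    ``cluster_ids[j]``. Every retained cluster is present in at least one
    genome; readers drop all-zero clusters with a warning.
    """

    species_id: str
    genome_ids: list[str]
    cluster_ids: list[str]
    presence: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        n_g, n_c = self.presence.shape
        if n_g != len(self.genome_ids) or n_c != len(self.cluster_ids):
            raise ValueError("presence shape does not match id lists")
        for name, ids in (("genome", self.genome_ids), ("cluster", self.cluster_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({x for x in ids if ids.count(x) > 1})
                raise DuplicateIdError(f"duplicate {name} ids: {dup}")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def gene_counts(self) -> np.ndarray:
        """Per-genome gene totals (row sums)."""
        return self.presence.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence.astype(int), index=self.genome_ids, columns=self.cluster_ids
        )

    def subset_genomes(self, keep: Sequence[str]) -> "GenePresenceMatrix":
        """Restrict to the given genomes, preserving both orderings.

        Clusters that lose all carriers are dropped.
        """
        keep_set = set(keep)
        idx = [i for i, g in enumerate(self.genome_ids) if g in keep_set]
        sub = self.presence[idx]
        col_keep = sub.any(axis=0)
        return GenePresenceMatrix(
            species_id=self.species_id,
            genome_ids=[self.genome_ids[i] for i in idx],
            cluster_ids=[c for c, k in zip(self.cluster_ids, col_keep) if k],
            presence=sub[:, col_keep],
        )


def _drop_empty_clusters(
    species_id: str, genome_ids: list[str], cluster_ids: list[str], presence: np.ndarray
) -> GenePresenceMatrix:
    keep = presence.any(axis=0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d cluster(s) with zero total presence", species_id, n_dropped
        )
    return GenePresenceMatrix(
        species_id=species_id,
        genome_ids=genome_ids,
        cluster_ids=[c for c, k in zip(cluster_ids, keep) if k],
        presence=presence[:, keep],
    )


def read_presence_matrix(
    path, dialect: str = "roary_csv", species_id: str | None = None
) -> GenePresenceMatrix:
    """Read a gene presence/absence matrix.

    Parameters
    ----------
    path
        File path of the matrix.
    dialect
        ``"roary_csv"`` (clusters as rows, 14 metadata columns then genome
        columns) or ``"binary_tsv"`` (genomes as rows, cluster-id header).
    species_id
        Species label to attach; defaults to the file stem.
    """
    species_id = species_id if species_id is not None else _stem(path)
    if dialect == "roary_csv":
        return _read_roary_csv(path, species_id)
    if dialect == "binary_tsv":
        return _read_binary_tsv(path, species_id)
    raise ValueError(f"unknown dialect {dialect!r}")


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def _read_roary_csv(path, species_id: str) -> GenePresenceMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) <= len(ROARY_META_COLUMNS):
        raise FormatError(
            f"{path}: expected at least {len(ROARY_META_COLUMNS) + 1} columns "
            f"(14 metadata + genomes), found {len(header)}"
        )
    for i, expected in enumerate(ROARY_META_COLUMNS[:1]):
        # only the leading "Gene" column name is stable across Roary versions
        if header[i] != expected:
            raise FormatError(
                f"{path}: malformed header, column {i + 1} is {header[i]!r}, "
                f"expected {expected!r}"
            )
    genome_ids = header[len(ROARY_META_COLUMNS):]
    if len(set(genome_ids)) != len(genome_ids):
        dup = sorted({g for g in genome_ids if genome_ids.count(g) > 1})
        raise DuplicateIdError(f"{path}: duplicate genome column(s): {dup}")
    cluster_ids = []
    cols = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}: row {r} has {len(row)} fields, expected {len(header)}")
        cluster_ids.append(row[0])
        cols.append([cell.strip() != "" for cell in row[len(ROARY_META_COLUMNS):]])
    if len(set(cluster_ids)) != len(cluster_ids):
        dup = sorted({c for c in cluster_ids if cluster_ids.count(c) > 1})
        raise DuplicateIdError(f"{path}: duplicate cluster id(s): {dup}")
    presence = np.array(cols, dtype=bool).T if cols else np.zeros((len(genome_ids), 0), bool)
    return _drop_empty_clusters(species_id, list(genome_ids), cluster_ids, presence)


def _read_binary_tsv(path, species_id: str) -> GenePresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise DuplicateIdError(f"{path}: duplicate genome id(s) in first column")
    if df.columns.has_duplicates:
        raise DuplicateIdError(f"{path}: duplicate cluster id(s) in header")
    try:
        values = df.astype(int).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell in binary matrix: {exc}") from exc
    if not np.isin(values, (0, 1)).all():
        raise FormatError(f"{path}: cells must be 0 or 1")
    return _drop_empty_clusters(
        species_id, [str(g) for g in df.index], [str(c) for c in df.columns], values.astype(bool)
    )


def write_presence_matrix(m: GenePresenceMatrix, path, dialect: str = "binary_tsv") -> None:
    """Write a matrix in the given dialect; read/write round-trips exactly."""
    if dialect == "binary_tsv":
        m.to_frame().to_csv(path, sep="\t")
        return
    if dialect == "roary_csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(list(ROARY_META_COLUMNS) + list(m.genome_ids))
            counts = m.presence.sum(axis=0)
            for j, cluster in enumerate(m.cluster_ids):
                meta = [cluster, "", "", str(int(counts[j]))] + [""] * 10
                cells = [
                    f"{g}_{cluster}" if m.presence[i, j] else ""
                    for i, g in enumerate(m.genome_ids)
                ]
                w.writerow(meta + cells)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def read_genome_metadata(path) -> list[GenomeRecord]:
    """Read a genome metadata TSV (genome_id, species_id, n_contigs[, n_genes])."""
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "species_id", "n_contigs"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        n_contigs = getattr(row, "n_contigs")
        n_contigs = None if pd.isna(n_contigs) else int(n_contigs)
        records.append(
            GenomeRecord(
                genome_id=str(row.genome_id),
                species_id=str(row.species_id),
                n_contigs=n_contigs,
                n_genes=int(getattr(row, "n_genes", 0) or 0),
            )
        )
    return records


def filter_quality(
    genomes: Iterable[GenomeRecord],
    max_contigs: int | float = 300,
    on_missing: str = "drop",
) -> list[GenomeRecord]:
    """Keep genomes assembled into at most ``max_contigs`` contigs.

    ``on_missing`` controls genomes without a contig count: ``"drop"``
    removes them with a warning, ``"error"`` raises.
    """
    kept = []
    for rec in genomes:
        if rec.n_contigs is None:
            if on_missing == "error":
                raise ValueError(f"genome {rec.genome_id!r} has no contig count")
            logger.warning("genome %s has no contig count; dropped", rec.genome_id)
            continue
        if rec.n_contigs <= max_contigs:
            kept.append(rec)
    return kept


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dedup_genomes(
    m: GenePresenceMatrix,
    core_identity: pd.DataFrame,
    jaccard_threshold: float = 0.99,
    identity_threshold: float = 1.0,
) -> GenePresenceMatrix:
    """Remove redundant genomes.

    A genome pair is redundant when its core-genome nucleotide identity is at
    least ``identity_threshold`` (default 1.0, i.e. identical core genomes)
    and its gene-content Jaccard similarity exceeds ``jaccard_threshold``.
    Pairs are processed in lexicographic order and the lexicographically
    smaller genome id of each redundant pair is kept, which makes the result
    deterministic and the operation idempotent.
    """
    missing = [g for g in m.genome_ids if g not in core_identity.index or g not in core_identity.columns]
    if missing:
        raise KeyError(f"core identity matrix missing genome(s): {missing}")
    rows = {g: m.presence[i] for i, g in enumerate(m.genome_ids)}
    alive = set(m.genome_ids)
    for gi, gj in _sorted_pairs(m.genome_ids):
        if gi not in alive or gj not in alive:
            continue
        if core_identity.loc[gi, gj] >= identity_threshold and _jaccard(rows[gi], rows[gj]) > jaccard_threshold:
            alive.discard(max(gi, gj))
    if len(alive) == len(m.genome_ids):
        return m
    return m.subset_genomes([g for g in m.genome_ids if g in alive])


def _sorted_pairs(ids: Sequence[str]):
    s = sorted(ids)
    for i in range(len(s)):
        for j in range(i + 1, len(s)):
            yield s[i], s[j]


def require_min_genomes(m: GenePresenceMatrix, n_min: int = 10) -> GenePresenceMatrix:
    """Pass the matrix through unchanged or raise ``SpeciesExcludedError``."""
    if m.n_genomes < n_min:
        raise SpeciesExcludedError(m.species_id, m.n_genomes, n_min)
    return m
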