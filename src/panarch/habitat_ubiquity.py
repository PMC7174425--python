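"""Species-habitat association testing and the ubiquity statistic.

Habitat evidence comes in as sample x species incidence with one habitat
label per sample. For each (species, habitat) pair a 2x2 contingency table
(presence/absence x in-habitat/out-of-habitat samples) is tested with
Fisher's exact test; p-values are Benjamini-Hochberg adjusted across all
pairs, and an association is called positive when the adjusted value is at
or below ``alpha`` (default 0.05) and the odds ratio exceeds 1. A species'
ubiquity is its number of positive associations across habitats.

Gene-catalogue style evidence (per-sample gene-detection counts) is reduced
to binary habitat presence by the at-least-``min_genes``-in-one-sample rule
(default 10), and binary presence tables from multiple annotation sources
can be merged under a source-prefixed habitat namespace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import PanarchError


@dataclass
class IncidenceTable:
    """Sample x species incidence with a per-sample habitat label.

    ``presence`` is a boolean DataFrame indexed by sample_id with species
    columns; ``habitats`` maps each sample_id to exactly one habitat drawn
    from the declared vocabulary.
    """

    presence: pd.DataFrame
    habitats: pd.Series

    def __post_init__(self):
        self.presence = self.presence.astype(bool)
        self.habitats = self.habitats.reindex(self.presence.index)
        if self.habitats.isna().any():
            missing = list(self.presence.index[self.habitats.isna()])
            raise ValueError(f"samples without a habitat label: {missing[:5]}")

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def vocabulary(self) -> list[str]:
        return sorted(self.habitats.unique())

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "IncidenceTable":
        """Build from a long table with columns sample_id, habitat, species_id, present."""
        required = {"sample_id", "habitat", "species_id", "present"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long incidence table missing column(s) {sorted(missing)}")
        wide = (
            df.pivot_table(index="sample_id", columns="species_id", values="present",
                           aggfunc="max", fill_value=0)
            .astype(bool)
        )
        hab = df.drop_duplicates("sample_id").set_index("sample_id")["habitat"]
        if df.groupby("sample_id")["habitat"].nunique().gt(1).any():
            raise ValueError("a sample carries more than one habitat label")
        return cls(presence=wide, habitats=hab)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.presence.astype(int)
            .rename_axis(index="sample_id", columns="species_id")
            .stack()
            .rename("present")
            .reset_index()
        )
        long.insert(1, "habitat", self.habitats.loc[long["sample_id"]].to_numpy())
        return long


def build_contingency(inc: IncidenceTable, species: str, habitat: str) -> tuple[int, int, int, int]:
    """2x2 counts (a, b, c, d) for one species-habitat pair.

    a: in-habitat samples with the species present; b: in-habitat without;
    c: out-of-habitat with; d: out-of-habitat without.
    """
    if habitat not in set(inc.habitats):
        raise ValueError(f"habitat {habitat!r} not in vocabulary")
    in_h = (inc.habitats == habitat).to_numpy()
    if in_h.sum() == 0:  # defensive; vocabulary check above already implies > 0
        raise PanarchError(f"no samples labelled {habitat!r}")
    pres = inc.presence[species].to_numpy()
    a = int((pres & in_h).sum())
    b = int((~pres & in_h).sum())
    c = int((pres & ~in_h).sum())
    d = int((~pres & ~in_h).sum())
    return a, b, c, d


def fisher_exact(table, sided: str = "two") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns the sample (cross-product) odds ratio — ``inf`` when b*c == 0
    and a*d > 0 — and the exact hypergeometric p-value. Degenerate tables
    (a zero margin) return p = 1.
    """
    a, b, c, d = np.asarray(table, dtype=np.int64).ravel()
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be nonnegative")
    alternative = {"two": "two-sided", "greater": "greater"}[sided]
    res = scipy.stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = a * d / (b * c)
    return float(odds), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate(
    inc: IncidenceTable,
    alpha: float = 0.05,
    sided: str = "two",
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher tests for every species x habitat pair, BH-adjusted jointly.

    Returns one row per pair with columns species_id, habitat, a, b, c, d,
    odds_ratio, p, q, positive. Positive means q <= alpha and odds_ratio > 1.
    """
    species = list(inc.species) if species is None else species
    rows = []
    for sp in species:
        for hab in inc.vocabulary:
            a, b, c, d = build_contingency(inc, sp, hab)
            odds, p = fisher_exact((a, b, c, d), sided=sided)
            rows.append((sp, hab, a, b, c, d, odds, p))
    df = pd.DataFrame(
        rows, columns=["species_id", "habitat", "a", "b", "c", "d", "odds_ratio", "p"]
    )
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["positive"] = (df["q"] <= alpha) & (df["odds_ratio"] > 1)
    return df


def ubiquity(associations: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Per-species ubiquity: the number of positive habitat associations."""
    pos = (associations["q"] <= alpha) & (associations["odds_ratio"] > 1)
    counts = associations.loc[pos].groupby("species_id").size()
    all_species = associations["species_id"].unique()
    return counts.reindex(all_species, fill_value=0).rename("ubiquity").astype(int)


def gmgc_presence(
    gene_counts: pd.DataFrame, sample_habitats: pd.Series, min_genes: int = 10
) -> pd.DataFrame:
    """Binary species x habitat presence from per-sample gene-detection counts.

    A species is present in a habitat when at least one sample of that
    habitat detected at least ``min_genes`` of its pangenome's genes.
    """
    if (gene_counts.to_numpy() < 0).any():
        raise ValueError("gene-detection counts must be nonnegative")
    hits = gene_counts >= min_genes  # species x sample
    habs = sample_habitats.reindex(gene_counts.columns)
    if habs.isna().any():
        raise ValueError("every sample column needs a habitat label")
    return hits.T.groupby(habs).any().T


def merge_habitat_sources(sources: list[tuple[str, pd.DataFrame]]) -> pd.DataFrame:
    """Union binary species x habitat tables under a prefixed namespace.

    Each source's habitat descriptors are prefixed ``source:descriptor``;
    a duplicate full descriptor name raises. Species missing from a source
    count as absent there.
    """
    renamed = []
    seen: set[str] = set()
    for name, df in sources:
        cols = [f"{name}:{c}" for c in df.columns]
        clash = seen.intersection(cols)
        if clash:
            raise ValueError(f"duplicate habitat descriptor(s) across sources: {sorted(clash)}")
        seen.update(cols)
        renamed.append(df.astype(bool).set_axis(cols, axis=1))
    merged = pd.concat(renamed, axis=1).fillna(False).astype(bool)
    return merged.sort_index()
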