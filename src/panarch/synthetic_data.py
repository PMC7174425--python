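"""Synthetic worlds with known ground truth.

Every pipeline stage is testable without external genome collections: this
module simulates a birth-death species tree, species traits with
controllable phylogenetic signal (Pagel's lambda) and habitat effects,
within-species gene content (fixed core plus a Beta-frequency accessory
pool plus Poisson influx of never-seen genes — the simplest generator that
yields tunable Heaps-like openness and a U-shaped gene-frequency
spectrum), star-genealogy core alignments with a target nucleotide
diversity, functional annotations, and habitat-labelled sample incidence
with controllable detection probabilities.

Default parameter values mirror the study conditions of the analysis this
package reproduces: ~150 species, >= 10 genomes per species, 50 samples
per habitat, strong in-habitat detection (0.9) against a low false-positive
floor (0.02).
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .habitat_ubiquity import IncidenceTable
from .io_formats import GenePresenceMatrix
from .phylo_comparative import cophenetic_matrix, lambda_transform, pc_decompose, phylo_covariance

BASES = np.frombuffer(b"ACGT", dtype="S1")
COG_CATEGORIES = tuple("JKLDVTMNUOCGEFHIPQRS")


@dataclass
class WorldConfig:
    """Parameters of one synthetic world; defaults are the study conditions."""

    n_species: int = 150
    n_habitats: int = 20
    birth_rate: float = 1.0
    death_rate: float = 0.0
    habitat_prob: float = 0.25          # P(species prefers a given habitat)
    trait_lambda: float = 1.0           # phylogenetic signal of the size trait
    trait_sigma2: float = 1.0
    habitat_effect_sd: float = 1.0      # sd of per-habitat additive effects
    noise_sigma2: float = 0.25
    core_size: int = 1500
    accessory_pool: int = 2000
    accessory_freq_alpha: float = 0.3   # Beta shape -> U-shaped spectrum
    accessory_freq_beta: float = 0.7
    novel_influx: float = 20.0          # Poisson mean of new genes per genome
    n_genomes_min: int = 10             # per-species genome counts drawn uniformly
    n_genomes_max: int = 30
    pi_target: float = 0.02
    alignment_length: int = 5000
    samples_per_habitat: int = 50
    detect_p_in: float = 0.9
    detect_p_out: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        for p in (self.habitat_prob, self.detect_p_in, self.detect_p_out):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.pi_target < 0.75:
            raise ValueError("pi_target must lie in [0, 0.75)")
        if not 10 <= self.n_genomes_min <= self.n_genomes_max:
            raise ValueError("need 10 <= n_genomes_min <= n_genomes_max")


@dataclass
class SyntheticWorld:
    """A complete simulated input set plus its generative ground truth."""

    config: WorldConfig
    tree: dendropy.Tree
    habitat_matrix: pd.DataFrame
    matrices: dict[str, GenePresenceMatrix]
    alignments: dict[str, dict[str, str]]
    annotations: dict[str, dict[str, set[str]]]
    cluster_categories: dict[str, dict[str, str]]
    incidence: IncidenceTable
    traits: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return sorted(self.matrices)


def simulate_tree(
    n: int, birth: float = 1.0, death: float = 0.0, seed: int | None = None,
    max_retries: int = 20,
) -> dendropy.Tree:
    """Birth-death tree with ``n`` extant tips, labelled S0001..Sn."""
    rng = random.Random(seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            tree = birthdeath.birth_death_tree(
                birth_rate=birth, death_rate=death, num_extant_tips=n, rng=rng,
            )
            break
        except Exception as exc:  # all lineages went extinct; retry
            last_err = exc
    else:
        raise RuntimeError(f"birth-death simulation failed after {max_retries} tries") from last_err
    # the simulation stops exactly at the n-th speciation, leaving two
    # zero-length terminal branches (a singular Brownian covariance); let the
    # process run for one further exponential waiting time so every tip edge
    # is positive, and drop the root edge (no shared pre-root variance)
    extra = rng.expovariate(n * birth)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = None
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"S{i:04d}"
    return tree


def simulate_trait(
    tree: dendropy.Tree,
    lam: float = 1.0,
    sigma2: float = 1.0,
    habitat_matrix: pd.DataFrame | None = None,
    effects: np.ndarray | None = None,
    noise_sigma2: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.Series, dict]:
    """Species trait = Brownian motion + habitat effects + iid noise.

    The Brownian component is drawn from N(0, sigma2 * V(lambda)) with
    V(lambda) the tree covariance with off-diagonals scaled by lambda.
    Returns the trait and the realized variance decomposition of the draw
    (not the configured one), so recovery tests compare against what was
    actually generated.
    """
    C = phylo_covariance(tree)
    labels = list(C.index)
    rng = np.random.default_rng(seed)
    if sigma2 > 0:
        V = sigma2 * lambda_transform(C.to_numpy(), lam)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(len(labels)))
        brownian = L @ rng.standard_normal(len(labels))
    else:
        brownian = np.zeros(len(labels))
    hab_comp = np.zeros(len(labels))
    if habitat_matrix is not None and effects is not None:
        H = habitat_matrix.reindex(labels).to_numpy(dtype=float)
        hab_comp = H @ np.asarray(effects, dtype=float)
    noise = math.sqrt(noise_sigma2) * rng.standard_normal(len(labels)) if noise_sigma2 else np.zeros(len(labels))
    trait = brownian + hab_comp + noise
    total = trait.var(ddof=1) if len(labels) > 1 else 0.0
    truth = {
        "var_brownian": float(np.var(brownian, ddof=1)),
        "var_habitat": float(np.var(hab_comp, ddof=1)),
        "var_noise": float(np.var(noise, ddof=1)),
        "var_total": float(total),
        "lambda": lam,
    }
    return pd.Series(trait, index=labels, name="trait"), truth


def simulate_habitat_matrix(
    n_species: int, n_habitats: int, prob: float = 0.25, seed: int | None = None,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Binary species x habitat preferences, iid Bernoulli(prob)."""
    rng = np.random.default_rng(seed)
    species = species or [f"S{i:04d}" for i in range(1, n_species + 1)]
    habitats = [f"H{j:02d}" for j in range(1, n_habitats + 1)]
    M = rng.random((n_species, n_habitats)) < prob
    return pd.DataFrame(M, index=species, columns=habitats)


def simulate_pangenome(
    species_id: str,
    core_size: int = 1500,
    accessory_pool: int = 2000,
    freq_alpha: float = 0.3,
    freq_beta: float = 0.7,
    novel_influx: float = 20.0,
    n_genomes: int = 12,
    seed: int | None = None,
) -> GenePresenceMatrix:
    """Within-species gene content under the core/accessory/influx model.

    All genomes carry every core cluster; each accessory cluster has a
    Beta(alpha, beta) carriage frequency and enters each genome
    independently; each genome additionally gains Poisson(novel_influx)
    private, never-seen-before clusters. Accessory clusters absent from all
    genomes are dropped (they were never observed).
    """
    rng = np.random.default_rng(seed)
    genome_ids = [f"{species_id}.g{i:03d}" for i in range(1, n_genomes + 1)]
    blocks = [np.ones((n_genomes, core_size), dtype=bool)]
    cluster_ids = [f"core{i:05d}" for i in range(1, core_size + 1)]
    if accessory_pool:
        freqs = rng.beta(freq_alpha, freq_beta, size=accessory_pool)
        acc = rng.random((n_genomes, accessory_pool)) < freqs
        seen = acc.any(axis=0)
        blocks.append(acc[:, seen])
        cluster_ids += [f"acc{i:05d}" for i in range(1, accessory_pool + 1) if seen[i - 1]]
    if novel_influx > 0:
        counts = rng.poisson(novel_influx, size=n_genomes)
        total = int(counts.sum())
        nov = np.zeros((n_genomes, total), dtype=bool)
        start = 0
        for g, c in enumerate(counts):
            nov[g, start:start + c] = True
            start += c
        blocks.append(nov)
        cluster_ids += [f"nov{i:05d}" for i in range(1, total + 1)]
    presence = np.hstack(blocks)
    return GenePresenceMatrix(
        species_id=species_id, genome_ids=genome_ids,
        cluster_ids=cluster_ids, presence=presence,
    )


def _mutation_prob(pi_target: float) -> float:
    # expected pairwise difference per site between two independently mutated
    # copies: 2q(1-q) + (2/3)q^2 = pi  =>  (4/3)q^2 - 2q + pi = 0
    if pi_target == 0:
        return 0.0
    disc = 4.0 - (16.0 / 3.0) * pi_target
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def simulate_core_alignment(
    n_genomes: int, length: int = 5000, pi_target: float = 0.02,
    seed: int | None = None, genome_ids: list[str] | None = None,
) -> dict[str, str]:
    """Star-genealogy core alignment with expected pairwise diversity pi.

    A random ancestral sequence is mutated independently per genome with a
    per-site substitution probability solved so that the expected pairwise
    difference per site equals ``pi_target``.
    """
    rng = np.random.default_rng(seed)
    genome_ids = genome_ids or [f"g{i:03d}" for i in range(1, n_genomes + 1)]
    q = _mutation_prob(pi_target)
    anc = rng.integers(0, 4, size=length)
    out = {}
    for gid in genome_ids:
        seq = anc.copy()
        hit = rng.random(length) < q
        # substitute with one of the three other bases, uniformly
        seq[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        out[gid] = BASES[seq].tobytes().decode()
    return out


def simulate_annotations(
    m: GenePresenceMatrix, seed: int | None = None
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Assign each cluster an orthologous group and a COG category.

    Returns per-genome OG sets (for functional distance) and the
    cluster -> category map (for COG-frequency analyses). OG ids reuse the
    cluster ids, so genomes sharing clusters share OGs.
    """
    rng = np.random.default_rng(seed)
    cats = rng.choice(len(COG_CATEGORIES), size=m.n_clusters)
    cluster_cat = {c: COG_CATEGORIES[k] for c, k in zip(m.cluster_ids, cats)}
    genome_sets = {
        g: {m.cluster_ids[j] for j in np.flatnonzero(m.presence[i])}
        for i, g in enumerate(m.genome_ids)
    }
    return genome_sets, cluster_cat


def simulate_incidence(
    habitat_matrix: pd.DataFrame,
    samples_per_habitat: int = 50,
    detect_p_in: float = 0.9,
    detect_p_out: float = 0.02,
    seed: int | None = None,
) -> tuple[IncidenceTable, pd.Series]:
    """Habitat-labelled sample incidence under a two-rate detection model.

    A species is detected in a sample with probability ``detect_p_in`` when
    the sample's habitat is among its true preferences and ``detect_p_out``
    otherwise. Returns the incidence table and the true per-species
    ubiquity (row sums of the preference matrix).
    """
    if not detect_p_in > detect_p_out:
        raise ValueError("detect_p_in must exceed detect_p_out")
    rng = np.random.default_rng(seed)
    species = list(habitat_matrix.index)
    habitats = list(habitat_matrix.columns)
    sample_ids, sample_habs, rows = [], [], []
    for hab in habitats:
        in_hab = habitat_matrix[hab].to_numpy(dtype=bool)
        p = np.where(in_hab, detect_p_in, detect_p_out)
        for s in range(1, samples_per_habitat + 1):
            sample_ids.append(f"{hab}.s{s:03d}")
            sample_habs.append(hab)
            rows.append(rng.random(len(species)) < p)
    inc = IncidenceTable(
        presence=pd.DataFrame(np.array(rows), index=sample_ids, columns=species),
        habitats=pd.Series(sample_habs, index=sample_ids, name="habitat"),
    )
    truth = habitat_matrix.sum(axis=1).rename("true_ubiquity")
    return inc, truth


def simulate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a full synthetic world from one config (and its seed).

    Per-component seeds are derived from ``config.seed`` with fixed offsets,
    so the same config is byte-identical on rerun.
    """
    base = config.seed
    tree = simulate_tree(config.n_species, config.birth_rate, config.death_rate, seed=base)
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    habitat_matrix = simulate_habitat_matrix(
        config.n_species, config.n_habitats, config.habitat_prob,
        seed=base + 1, species=species,
    )
    rng = np.random.default_rng(base + 2)
    effects = rng.normal(0.0, config.habitat_effect_sd, size=config.n_habitats)
    size_trait, trait_truth = simulate_trait(
        tree, lam=config.trait_lambda, sigma2=config.trait_sigma2,
        habitat_matrix=habitat_matrix, effects=effects,
        noise_sigma2=config.noise_sigma2, seed=base + 3,
    )
    # map the latent size trait onto per-species accessory-pool sizes so the
    # habitat/phylogeny structure propagates into measurable pangenome features
    z = (size_trait - size_trait.mean()) / max(size_trait.std(ddof=1), 1e-9)
    pool_sizes = np.clip(
        (config.accessory_pool * (1.0 + 0.4 * z)).round().astype(int), 100, None
    )
    genome_counts = rng.integers(config.n_genomes_min, config.n_genomes_max + 1,
                                 size=len(species))
    matrices, alignments, annotations, cluster_cats = {}, {}, {}, {}
    for k, sp in enumerate(species):
        n_genomes = int(genome_counts[k])
        m = simulate_pangenome(
            sp, core_size=config.core_size, accessory_pool=int(pool_sizes[sp]),
            freq_alpha=config.accessory_freq_alpha, freq_beta=config.accessory_freq_beta,
            novel_influx=config.novel_influx, n_genomes=n_genomes,
            seed=base + 1000 + k,
        )
        matrices[sp] = m
        alignments[sp] = simulate_core_alignment(
            n_genomes, config.alignment_length, config.pi_target,
            seed=base + 2000 + k, genome_ids=m.genome_ids,
        )
        annotations[sp], cluster_cats[sp] = simulate_annotations(m, seed=base + 3000 + k)
    incidence, true_ubiquity = simulate_incidence(
        habitat_matrix, config.samples_per_habitat,
        config.detect_p_in, config.detect_p_out, seed=base + 4,
    )
    ground_truth = {
        "trait_decomposition": trait_truth,
        "habitat_effects": effects.tolist(),
        "true_ubiquity": true_ubiquity.to_dict(),
        "accessory_pool_sizes": {sp: int(pool_sizes[sp]) for sp in species},
    }
    traits = pd.DataFrame({"size_trait": size_trait})
    return SyntheticWorld(
        config=config, tree=tree, habitat_matrix=habitat_matrix,
        matrices=matrices, alignments=alignments, annotations=annotations,
        cluster_categories=cluster_cats, incidence=incidence,
        traits=traits, ground_truth=ground_truth,
    )


def simulate_partition_benchmark(
    n_species: int = 150,
    habitat_share: float = 0.5,
    phylo_share: float = 0.2,
    n_phylo_pcs: int = 5,
    n_habitat_pcs: int = 10,
    n_habitats: int = 20,
    seed: int | None = None,
):
    """A world where a feature's variance decomposition is known exactly.

    Builds a tree and habitat matrix, extracts their leading PCs, and
    composes a feature from a random linear combination of the phylogenetic
    PCs (weight ``sqrt(phylo_share)``), the habitat PCs
    (``sqrt(habitat_share)``) and white noise. Returns
    ``(y, blocks, truth)`` where ``blocks`` are ready for
    :class:`~panarch.variance_partition.VariancePartition` and ``truth``
    holds the realized (not just the configured) variance shares.
    """
    from .variance_partition import PredictorBlock

    if habitat_share + phylo_share >= 1:
        raise ValueError("shares must sum to < 1")
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_species, seed=None if seed is None else seed + 1)
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    coph = cophenetic_matrix(tree)
    hab = simulate_habitat_matrix(
        n_species, n_habitats, seed=None if seed is None else seed + 2, species=species
    )
    phylo_pcs = pc_decompose(coph, selection="fixed", n_components=n_phylo_pcs)
    hab_pcs = pc_decompose(hab.astype(float), selection="fixed", n_components=n_habitat_pcs)
    P = phylo_pcs.retained_scores().reindex(species)
    H = hab_pcs.retained_scores().reindex(species)

    def _unit(M: pd.DataFrame) -> np.ndarray:
        v = M.to_numpy() @ rng.standard_normal(M.shape[1])
        return (v - v.mean()) / v.std(ddof=1)

    u_p, u_h = _unit(P), _unit(H)
    e = rng.standard_normal(len(species))
    e = (e - e.mean()) / e.std(ddof=1)
    y_vals = (
        math.sqrt(phylo_share) * u_p
        + math.sqrt(habitat_share) * u_h
        + math.sqrt(1.0 - phylo_share - habitat_share) * e
    )
    y = pd.Series(y_vals, index=species, name="synthetic_feature")
    var_y = y_vals.var(ddof=1)
    truth = {
        "phylo_share": float(phylo_share * np.var(u_p, ddof=1) / var_y),
        "habitat_share": float(habitat_share * np.var(u_h, ddof=1) / var_y),
    }
    n_genomes = pd.DataFrame(
        {"n_genomes": rng.integers(10, 60, size=len(species))}, index=species
    )
    blocks = [
        PredictorBlock("n_genomes", n_genomes),
        PredictorBlock("phylo_pcs", P),
        PredictorBlock("habitat_pcs", H),
    ]
    return y, blocks, truth


# ---------------------------------------------------------------------------
# on-disk serialization


def write_world(world: SyntheticWorld, outdir) -> None:
    """Write every pipeline input format for a world (deterministic bytes)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    world.tree.write(path=os.path.join(outdir, "species_tree.nwk"), schema="newick")
    world.habitat_matrix.astype(int).to_csv(os.path.join(outdir, "habitat_matrix.tsv"), sep="\t")
    world.incidence.to_long().to_csv(os.path.join(outdir, "incidence.tsv"), sep="\t", index=False)
    world.traits.to_csv(os.path.join(outdir, "traits.tsv"), sep="\t")
    pg_dir = os.path.join(outdir, "pangenomes")
    aln_dir = os.path.join(outdir, "alignments")
    ann_dir = os.path.join(outdir, "annotations")
    for d in (pg_dir, aln_dir, ann_dir):
        os.makedirs(d, exist_ok=True)
    from .io_formats import write_presence_matrix

    for sp in world.species:
        write_presence_matrix(world.matrices[sp], os.path.join(pg_dir, f"{sp}.tsv"))
        with open(os.path.join(aln_dir, f"{sp}.fasta"), "w") as fh:
            for gid, seq in world.alignments[sp].items():
                fh.write(f">{gid}\n{seq}\n")
        rows = []
        for gid in sorted(world.annotations[sp]):
            for og in sorted(world.annotations[sp][gid]):
                rows.append((gid, og, og, world.cluster_categories[sp][og]))
        pd.DataFrame(rows, columns=["genome_id", "cluster_id", "og_id", "cog_category"]).to_csv(
            os.path.join(ann_dir, f"{sp}.tsv"), sep="\t", index=False
        )
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(world.ground_truth, fh, indent=2, sort_keys=True, default=float)
    with open(os.path.join(outdir, "world_config.json"), "w") as fh:
        json.dump(asdict(world.config), fh, indent=2, sort_keys=True)
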