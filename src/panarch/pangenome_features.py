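"""Per-species pangenome feature suite.

Given one species' genome x gene-cluster presence/absence matrix, this module
computes the standard descriptors of pangenome architecture:

* partition sizes — core (present in every genome), extended core (frequency
  > 90%), shell, cloud (frequency < 15%), unique genes and total pangenome;
* rarefaction curves — mean cumulative pangenome / core-genome size over
  random genome input orders (30 permutations by default);
* saturation fits — nonlinear least squares of the power law
  ``G = k * N**gamma + c`` to the pangenome curve, the decay
  ``G = k * N**-alpha`` (Heaps' law) to the new-genes-per-genome curve, and
  the exponential ``G = k * exp(-N*gamma) + c`` to the core curve, with
  openness classification from the fitted exponents;
* genome fluidity, Chao's lower bound on pangenome gene richness,
  sample-size-normalized core/pangenome sizes over random nine-genome draws,
  core-genome nucleotide diversity, and mean pairwise functional
  (orthologous-group Jaccard) distance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import AlignmentError
from .io_formats import GenePresenceMatrix

logger = logging.getLogger(__name__)

CURVE_MODELS = ("pan_power_law", "new_genes_decay", "core_exp_decay")


@dataclass(frozen=True)
class PartitionThresholds:
    """Genome-frequency thresholds of the pangenome partition.

    ``extended_core_min`` is an exclusive lower bound (default 0.90: extended
    core means frequency > 90%); ``cloud_max`` is an exclusive upper bound
    (default 0.15: cloud means frequency < 15%). Core requires presence in
    every genome.
    """

    extended_core_min: float = 0.90
    cloud_max: float = 0.15

    def __post_init__(self):
        if not (0.0 < self.cloud_max < self.extended_core_min < 1.0):
            raise ValueError(
                f"require 0 < cloud_max < extended_core_min < 1, got "
                f"({self.cloud_max}, {self.extended_core_min})"
            )


@dataclass(frozen=True)
class PartitionSizes:
    core: int
    extended_core: int
    shell: int
    cloud: int
    unique: int
    pangenome: int


def partition_sizes(
    m: GenePresenceMatrix, thresholds: PartitionThresholds = PartitionThresholds()
) -> PartitionSizes:
    """Partition clusters by genome frequency into core/shell/cloud.

    With ``f`` the fraction of genomes carrying a cluster: core iff ``f == 1``;
    extended core iff ``f > extended_core_min`` (a superset of the core);
    cloud iff ``f < cloud_max``; shell is the remainder, so
    ``core + shell + cloud == pangenome`` exactly. Unique genes (present in a
    single genome) are a subset of the cloud whenever ``n_genomes > 1/cloud_max``.
    """
    if m.n_genomes == 0 or m.n_clusters == 0:
        raise ValueError("cannot partition an empty matrix")
    counts = m.presence.sum(axis=0)
    f = counts / m.n_genomes
    core = int((counts == m.n_genomes).sum())
    extended = int((f > thresholds.extended_core_min).sum())
    cloud = int((f < thresholds.cloud_max).sum())
    unique = int((counts == 1).sum())
    pangenome = m.n_clusters
    shell = pangenome - core - cloud
    return PartitionSizes(core, extended, shell, cloud, unique, pangenome)


@dataclass
class RarefactionCurves:
    """Mean gene-accumulation curves over genome input-order permutations."""

    N: np.ndarray
    pan_mean: np.ndarray
    core_mean: np.ndarray
    new_genes_mean: np.ndarray
    n_permutations: int
    seed: int | None = None


def rarefaction(
    m: GenePresenceMatrix,
    n_perm: int = 30,
    seed: int | None = None,
    exhaustive: bool = False,
) -> RarefactionCurves:
    """Pan/core rarefaction via random input-order permutations.

    For each permutation of genome order, the pangenome curve is the
    cumulative union size and the core curve the cumulative intersection size
    after each added genome; means over permutations are returned. The
    new-genes curve is the first difference of the pangenome curve, with
    ``new_genes_mean[0] = pan_mean[0]``.

    ``exhaustive=True`` enumerates all ``n!`` orderings (guarded to n <= 8)
    instead of sampling.
    """
    n = m.n_genomes
    if n == 0:
        raise ValueError("empty matrix")
    P = m.presence
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to 8 genomes")
        orders = list(itertools.permutations(range(n)))
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n) for _ in range(n_perm)]
    pan = np.zeros(n)
    core = np.zeros(n)
    for order in orders:
        Q = P[np.asarray(order)]
        pan += np.maximum.accumulate(Q, axis=0).sum(axis=1)
        core += np.minimum.accumulate(Q, axis=0).sum(axis=1)
    pan /= len(orders)
    core /= len(orders)
    new = np.empty(n)
    new[0] = pan[0]
    new[1:] = np.diff(pan)
    return RarefactionCurves(
        N=np.arange(1, n + 1),
        pan_mean=pan,
        core_mean=core,
        new_genes_mean=new,
        n_permutations=len(orders),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# saturation-curve fitting


@dataclass
class CurveFitResults:
    """Fitted gene-accumulation model parameters and openness label."""

    model: str
    k: float
    c: float | None
    exponent: float  # gamma for the power/exponential models, alpha for the decay
    converged: bool
    rss: float
    n_points: int

    @property
    def gamma(self) -> float | None:
        return self.exponent if self.model != "new_genes_decay" else None

    @property
    def alpha(self) -> float | None:
        return self.exponent if self.model == "new_genes_decay" else None

    @property
    def openness(self) -> str:
        return classify_openness(self)

    def predict(self, N: np.ndarray) -> np.ndarray:
        N = np.asarray(N, dtype=float)
        if self.model == "pan_power_law":
            return self.k * N ** self.exponent + self.c
        if self.model == "new_genes_decay":
            return self.k * N ** (-self.exponent)
        return self.k * np.exp(-N * self.exponent) + self.c

    def summary(self) -> str:
        lines = [
            f"Gene accumulation fit: {self.model}",
            f"  n points   {self.n_points}",
            f"  k          {self.k:.6g}",
        ]
        if self.c is not None:
            lines.append(f"  c          {self.c:.6g}")
        name = "alpha" if self.model == "new_genes_decay" else "gamma"
        lines += [
            f"  {name:<10} {self.exponent:.6g}",
            f"  rss        {self.rss:.6g}",
            f"  converged  {self.converged}",
            f"  openness   {self.openness}",
        ]
        return "\n".join(lines)


class GeneAccumulation:
    """Nonlinear least-squares model of a mean gene-accumulation curve.

    Parameters
    ----------
    N, G
        Genome counts and mean gene counts of the curve to fit.
    model
        ``"pan_power_law"``: ``G = k*N**gamma + c`` (pangenome curve);
        ``"new_genes_decay"``: ``G = k*N**-alpha`` (new genes per genome,
        Heaps' law); ``"core_exp_decay"``: ``G = k*exp(-N*gamma) + c``
        (core curve).

    Fitting is multi-start: starting values come from log-log (or
    semi-log) linear regressions over a small grid of offsets ``c``, and
    the best residual sum of squares wins. ``k`` is constrained positive.
    """

    def __init__(self, N: Sequence[float], G: Sequence[float], model: str = "pan_power_law"):
        if model not in CURVE_MODELS:
            raise ValueError(f"model must be one of {CURVE_MODELS}")
        self.N = np.asarray(N, dtype=float)
        self.G = np.asarray(G, dtype=float)
        if self.N.shape != self.G.shape or self.N.ndim != 1:
            raise ValueError("N and G must be 1-d arrays of equal length")
        min_pts = 3 if model == "new_genes_decay" else 4
        if len(self.N) < min_pts:
            raise ValueError(f"{model} needs at least {min_pts} curve points")
        self.model = model

    @classmethod
    def from_curves(cls, curves: RarefactionCurves, model: str) -> "GeneAccumulation":
        if model == "new_genes_decay":
            # drop N=1: the first point is genome size, not gene influx
            return cls(curves.N[1:], curves.new_genes_mean[1:], model)
        G = curves.pan_mean if model == "pan_power_law" else curves.core_mean
        return cls(curves.N, G, model)

    # -- internal helpers ---------------------------------------------------
    def _residuals(self, params: np.ndarray) -> np.ndarray:
        if self.model == "new_genes_decay":
            k, a = params
            return k * self.N ** (-a) - self.G
        k, e, c = params
        if self.model == "pan_power_law":
            return k * self.N ** e + c - self.G
        return k * np.exp(-self.N * e) + c - self.G

    def _starts(self) -> list[np.ndarray]:
        N, G = self.N, self.G
        starts: list[np.ndarray] = []
        gmin, gmax = G.min(), G.max()
        span = max(gmax - gmin, 1e-9)
        if self.model == "new_genes_decay":
            pos = G > 0
            if pos.sum() >= 2:
                b, loga = np.polyfit(np.log(N[pos]), np.log(G[pos]), 1)
                starts.append(np.array([math.exp(loga), -b]))
            starts.append(np.array([max(G[0], 1e-6), 1.0]))
            starts.append(np.array([max(gmax, 1e-6), 0.5]))
            return starts
        if self.model == "pan_power_law":
            for frac in (0.0, 0.5, 0.9, 0.99):
                c0 = gmin - frac * span if G[-1] >= G[0] else gmax + frac * span
                resid = G - c0
                sign = 1.0 if resid.mean() >= 0 else -1.0
                r = np.abs(resid)
                pos = r > 1e-12
                if pos.sum() >= 2:
                    b, loga = np.polyfit(np.log(N[pos]), np.log(r[pos]), 1)
                    starts.append(np.array([sign * math.exp(loga), b, c0]))
            starts.append(np.array([span if span > 0 else 1.0, 0.5, gmin]))
            starts.append(np.array([max(G[0], 1e-6), 0.0, 0.0]))
        else:  # core_exp_decay: asymptote c ~ min(G)
            for frac in (0.999, 0.9, 0.5):
                c0 = gmin - (1 - frac) * span
                r = G - c0
                pos = r > 1e-12
                if pos.sum() >= 2:
                    b, loga = np.polyfit(N[pos], np.log(r[pos]), 1)
                    starts.append(np.array([math.exp(loga), -b, c0]))
            starts.append(np.array([span if span > 0 else 1.0, 0.1, gmin]))
        return starts[:10]

    def fit(self) -> CurveFitResults:
        best = None
        for x0 in self._starts():
            x0 = np.asarray(x0, dtype=float)
            if self.model == "new_genes_decay":
                lb = np.array([1e-12, -np.inf])
                ub = np.array([np.inf, np.inf])
            else:
                lb = np.array([-np.inf, -np.inf, -np.inf])
                ub = np.array([np.inf, np.inf, np.inf])
                if x0[0] > 0:
                    lb[0] = 1e-12
            x0 = np.clip(x0, lb + 1e-12, ub - 1e-12 if np.isfinite(ub).all() else None)
            try:
                sol = least_squares(
                    self._residuals, x0, bounds=(lb, ub),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
                )
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol)
        if best is None:
            nan = float("nan")
            return CurveFitResults(self.model, nan, None, nan, False, nan, len(self.N))
        rss, sol = best
        if self.model == "new_genes_decay":
            k, e = sol.x
            c = None
        else:
            k, e, c = sol.x
        if abs(e) < 1e-10:
            # flat-curve degeneracy: any k fits with exponent 0; report the
            # saturated exponent exactly
            e = 0.0
        return CurveFitResults(
            model=self.model,
            k=float(k),
            c=None if c is None else float(c),
            exponent=float(e),
            converged=bool(sol.success),
            rss=rss,
            n_points=len(self.N),
        )


def fit_curve(curves: RarefactionCurves, model: str) -> CurveFitResults:
    """Fit one of the gene-accumulation models to a rarefaction curve."""
    return GeneAccumulation.from_curves(curves, model).fit()


def classify_openness(fit: CurveFitResults) -> str:
    """Openness label from the fitted saturation exponent.

    Pangenome power law: exponent gamma <= 0 means the pangenome is closed
    (saturated); 0 < gamma <= 1 means open; gamma > 1 is left undefined.
    New-genes decay: alpha < 1 means open, alpha > 1 closed, alpha == 1
    undefined. The core-decay model carries no openness semantics.
    """
    if not fit.converged or not math.isfinite(fit.exponent):
        return "undefined"
    if fit.model == "pan_power_law":
        g = fit.exponent
        if g <= 0:
            return "closed"
        if g <= 1:
            return "open"
        return "undefined"
    if fit.model == "new_genes_decay":
        a = fit.exponent
        if a < 1:
            return "open"
        if a > 1:
            return "closed"
        return "undefined"
    return "undefined"


# ---------------------------------------------------------------------------
# scalar features


def genome_fluidity(m: GenePresenceMatrix) -> float:
    """Genomic fluidity: mean over genome pairs of unique-gene fraction.

    For a pair (i, j) with gene totals M_i, M_j and U_i, U_j genes found in
    only one member, the pair contributes (U_i + U_j) / (M_i + M_j).
    """
    n = m.n_genomes
    if n < 2:
        raise ValueError("fluidity needs at least two genomes")
    P = m.presence
    totals = P.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("fluidity undefined: a genome has zero genes")
    shared = (P.astype(np.int64) @ P.T.astype(np.int64))
    acc = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            s = shared[i, j]
            acc += ((totals[i] - s) + (totals[j] - s)) / (totals[i] + totals[j])
    return acc / (n * (n - 1) / 2)


def chao_lower_bound(m: GenePresenceMatrix) -> float:
    """Chao's lower bound on total pangenome gene richness.

    ``S = S_obs + Q1^2 / (2*Q2)`` with Q1/Q2 the clusters present in exactly
    one/two genomes; when Q2 == 0 the bias-corrected form
    ``S_obs + Q1*(Q1-1)/2`` is used.
    """
    counts = m.presence.sum(axis=0)
    s_obs = m.n_clusters
    q1 = int((counts == 1).sum())
    q2 = int((counts == 2).sum())
    if q2 > 0:
        return s_obs + q1 * q1 / (2 * q2)
    return s_obs + q1 * (q1 - 1) / 2


def normalized_sizes(
    m: GenePresenceMatrix, k: int = 9, n_draws: int = 30, seed: int | None = None
) -> tuple[float, float]:
    """Sample-size-normalized (core, pangenome) sizes.

    Means of the intersection and union sizes over ``n_draws`` distinct
    random ``k``-genome subsets (all subsets when fewer exist), removing the
    dependence of raw sizes on the number of sequenced genomes.
    """
    n = m.n_genomes
    if n < k:
        raise ValueError(
            f"normalized sizes need at least {k} genomes (species has {n}); "
            f"species below the 10-genome floor are excluded upstream"
        )
    total = math.comb(n, k)
    if total <= n_draws:
        subsets = list(itertools.combinations(range(n), k))
    else:
        rng = np.random.default_rng(seed)
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < n_draws:
            chosen.add(tuple(sorted(rng.choice(n, size=k, replace=False).tolist())))
        subsets = sorted(chosen)
    core_sizes = []
    pan_sizes = []
    for idx in subsets:
        sub = m.presence[list(idx)]
        core_sizes.append(sub.all(axis=0).sum())
        pan_sizes.append(sub.any(axis=0).sum())
    return float(np.mean(core_sizes)), float(np.mean(pan_sizes))


_GAP_CHARS = frozenset(b"-.nN?")


def core_nucleotide_diversity(
    alignment: Mapping[str, str] | Sequence[tuple[str, str]],
    method: str = "pairwise",
) -> float:
    """Nucleotide diversity of a core-genome alignment.

    ``method="pairwise"`` (default): mean over sequence pairs of the
    proportion of differing sites, excluding gap/ambiguity columns pairwise
    (per pair, not listwise) to maximize usable sites.
    ``method="sitewise"``: mean per-site heterozygosity
    ``sum_s 2*sum_{a<b} p_a p_b / S`` over ungapped site observations — an
    alternative estimator exposed for sensitivity checks.
    """
    items = list(alignment.items()) if isinstance(alignment, Mapping) else list(alignment)
    if len(items) < 2:
        raise AlignmentError("need at least two sequences")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
    arr = np.frombuffer("".join(s for _, s in items).encode(), dtype="S1").reshape(len(items), -1)
    arr = np.char.upper(arr)
    valid = ~np.isin(arr, [b"-", b".", b"N", b"?"])
    if method == "pairwise":
        n = len(items)
        props = []
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i] & valid[j]
                sites = int(both.sum())
                if sites == 0:
                    continue
                diff = int((arr[i][both] != arr[j][both]).sum())
                props.append(diff / sites)
        if not props:
            raise AlignmentError("no comparable ungapped sites in any pair")
        return float(np.mean(props))
    if method == "sitewise":
        hets = []
        for s in range(arr.shape[1]):
            col = arr[valid[:, s], s]
            if len(col) < 2:
                continue
            _, counts = np.unique(col, return_counts=True)
            p = counts / counts.sum()
            hets.append(1.0 - float((p ** 2).sum()))
        if not hets:
            raise AlignmentError("no comparable sites")
        return float(np.mean(hets))
    raise ValueError(f"unknown method {method!r}")


def functional_distance(annotations: Mapping[str, Iterable[str]]) -> float:
    """Mean pairwise Jaccard distance between genomes' functional-group sets.

    Genomes with an empty annotation set are excluded with a warning rather
    than treated as maximally distant.
    """
    sets = {g: set(v) for g, v in annotations.items()}
    empty = sorted(g for g, v in sets.items() if not v)
    if empty:
        logger.warning("excluding %d genome(s) without annotations: %s", len(empty), empty)
        for g in empty:
            del sets[g]
    ids = sorted(sets)
    if len(ids) < 2:
        raise ValueError("functional distance needs >= 2 annotated genomes")
    dists = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = sets[ids[i]], sets[ids[j]]
            dists.append(1.0 - len(a & b) / len(a | b))
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class PangenomeFeatureSet:
    """The per-species feature vector consumed by the downstream analyses."""

    species_id: str
    n_genomes: int
    core_size: int
    extended_core_size: int
    shell_size: int
    cloud_size: int
    unique_gene_count: int
    pangenome_size: int
    mean_genome_size: float
    norm_core_size: float | None
    norm_pan_size: float | None
    fluidity: float
    chao_lower_bound: float
    heaps_alpha: float | None
    gamma_pan: float | None
    gamma_core: float | None
    openness: str
    core_nt_diversity: float | None = None
    functional_distance: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    FEATURE_COLUMNS = (
        "n_genomes", "core_size", "extended_core_size", "shell_size", "cloud_size",
        "unique_gene_count", "pangenome_size", "mean_genome_size", "norm_core_size",
        "norm_pan_size", "fluidity", "chao_lower_bound", "heaps_alpha", "gamma_pan",
        "gamma_core", "core_nt_diversity", "functional_distance",
    )


def compute_feature_set(
    m: GenePresenceMatrix,
    alignment: Mapping[str, str] | None = None,
    annotations: Mapping[str, Iterable[str]] | None = None,
    thresholds: PartitionThresholds = PartitionThresholds(),
    n_perm: int = 30,
    norm_k: int = 9,
    norm_draws: int = 30,
    seed: int | None = None,
) -> PangenomeFeatureSet:
    """Compute the full feature suite for one species.

    Seeded sub-computations (rarefaction and normalized sizes) derive their
    streams from ``seed`` with fixed offsets so one species-level seed
    reproduces everything.
    """
    sizes = partition_sizes(m, thresholds)
    curves = rarefaction(m, n_perm=n_perm, seed=None if seed is None else seed + 1)
    pan_fit = fit_curve(curves, "pan_power_law")
    new_fit = fit_curve(curves, "new_genes_decay") if m.n_genomes >= 4 else None
    core_fit = fit_curve(curves, "core_exp_decay")
    try:
        norm_core, norm_pan = normalized_sizes(
            m, k=norm_k, n_draws=norm_draws, seed=None if seed is None else seed + 2
        )
    except ValueError:
        norm_core = norm_pan = None
    pi = core_nucleotide_diversity(alignment) if alignment is not None else None
    fdist = functional_distance(annotations) if annotations is not None else None
    return PangenomeFeatureSet(
        species_id=m.species_id,
        n_genomes=m.n_genomes,
        core_size=sizes.core,
        extended_core_size=sizes.extended_core,
        shell_size=sizes.shell,
        cloud_size=sizes.cloud,
        unique_gene_count=sizes.unique,
        pangenome_size=sizes.pangenome,
        mean_genome_size=float(m.gene_counts().mean()),
        norm_core_size=norm_core,
        norm_pan_size=norm_pan,
        fluidity=genome_fluidity(m),
        chao_lower_bound=chao_lower_bound(m),
        heaps_alpha=None if new_fit is None else new_fit.exponent,
        gamma_pan=pan_fit.exponent if pan_fit.converged else None,
        gamma_core=core_fit.exponent if core_fit.converged else None,
        openness=pan_fit.openness,
        core_nt_diversity=pi,
        functional_distance=fdist,
    )
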