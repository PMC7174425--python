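"""CAR-score variance partitioning of pangenome features.

A feature observed across species is regressed on grouped predictors —
the number of genomes per species, optionally a covariate (genome size or
core-genome nucleotide diversity), the leading phylogenetic PCs of the
cophenetic distance matrix, and the leading habitat PCs of the binary
species x habitat matrix. CAR (correlation-adjusted marginal correlation)
scores are the correlations between the response and the Mahalanobis-
decorrelated predictors,

    omega = R_XX^(-1/2) r_Xy,

whose squares sum to the model R^2 and decompose it additively over
predictors regardless of entry order. Block shares are sums of omega^2
over each block's columns. Statistical calibration comes from a
permutation null in which the rows of the phylogenetic and habitat blocks
are shuffled (whole rows within each block, preserving intra-block
correlation) and shares recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODELS = {
    "base": {"n_genomes", "phylo_pcs", "habitat_pcs"},
    "genome_size": {"n_genomes", "covariate", "phylo_pcs", "habitat_pcs"},
    "core_diversity": {"n_genomes", "covariate", "phylo_pcs", "habitat_pcs"},
}

BLOCK_NAMES = ("n_genomes", "covariate", "phylo_pcs", "habitat_pcs")


@dataclass
class PredictorBlock:
    """A named group of predictor columns aligned on species."""

    name: str
    data: pd.DataFrame

    def __post_init__(self):
        if self.name not in BLOCK_NAMES:
            raise ValueError(f"block name must be one of {BLOCK_NAMES}, got {self.name!r}")
        self.data = pd.DataFrame(self.data).astype(float)


def _standardize(A: np.ndarray) -> np.ndarray:
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    return (A - mu) / sd


def car_scores(X, y, on_singular: str = "ridge", ridge: float = 1e-8) -> np.ndarray:
    """CAR scores of predictors X for response y.

    X columns and y are standardized internally; the inverse square root of
    the predictor correlation matrix is taken through its symmetric
    eigendecomposition. Near-singular correlation matrices are handled per
    ``on_singular``: ``"ridge"`` adds ``ridge`` to the eigenvalues,
    ``"error"`` raises. The squared scores sum to the least-squares R^2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations than predictors (n={n}, p={p})")
    Xs = _standardize(X)
    ys = y - y.mean()
    sd = ys.std(ddof=1)
    if sd == 0:
        raise ValueError("response is constant")
    ys = ys / sd
    R = (Xs.T @ Xs) / (n - 1)
    r_xy = (Xs.T @ ys) / (n - 1)
    w, Q = np.linalg.eigh(R)
    if w.min() < 1e-10:
        if on_singular == "error":
            raise np.linalg.LinAlgError(
                f"predictor correlation matrix is singular (min eigenvalue {w.min():.3g})"
            )
        w = w + ridge
    R_inv_sqrt = Q @ np.diag(1.0 / np.sqrt(w)) @ Q.T
    return R_inv_sqrt @ r_xy


@dataclass
class VariancePartitionResults:
    """Per-block explained-variance shares with optional permutation null."""

    feature: str
    model: str
    share_per_block: dict[str, float]
    total_r2: float
    permutation_p: dict[str, float] = field(default_factory=dict)
    null_shares: pd.DataFrame | None = None
    n_permutations: int = 0
    seed: int | None = None
    n_species: int = 0
    n_dropped: int = 0
    car_omega: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block, share in self.share_per_block.items():
            rows.append(
                dict(
                    feature=self.feature, model=self.model, block=block,
                    share=share, perm_p=self.permutation_p.get(block, np.nan),
                )
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"CAR variance partition: {self.feature} ({self.model} model)",
            f"  n species = {self.n_species} (dropped {self.n_dropped}), "
            f"total R^2 = {self.total_r2:.4f}",
            f"  {'block':<14}{'share':>10}{'perm p':>10}",
        ]
        for block, share in self.share_per_block.items():
            p = self.permutation_p.get(block)
            p_s = f"{p:>10.4f}" if p is not None else f"{'':>10}"
            lines.append(f"  {block:<14}{share:>10.4f}{p_s}")
        if self.n_permutations:
            lines.append(f"  permutations = {self.n_permutations}, seed = {self.seed}")
        return "\n".join(lines)


class VariancePartition:
    """CAR-score partition of one feature's variance across predictor blocks.

    Parameters
    ----------
    y
        Feature values indexed by species.
    blocks
        ``PredictorBlock`` list; the ``model`` decides which names must be
        present (``base``: n_genomes + phylo_pcs + habitat_pcs; the
        ``genome_size`` / ``core_diversity`` variants additionally require a
        ``covariate`` block).
    model
        One of ``base``, ``genome_size``, ``core_diversity``.

    Species with any missing value are dropped listwise; the count is
    reported on the results object.
    """

    def __init__(
        self, y: pd.Series, blocks: list[PredictorBlock], model: str = "base",
        feature_name: str | None = None,
    ):
        if model not in MODELS:
            raise ValueError(f"model must be one of {sorted(MODELS)}")
        names = [b.name for b in blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate block names")
        missing = MODELS[model] - set(names)
        if missing:
            raise ValueError(f"model {model!r} requires block(s) {sorted(missing)}")
        blocks = [b for b in blocks if b.name in MODELS[model]]
        y = pd.Series(y).astype(float)
        self.feature = feature_name or (y.name or "feature")
        idx = y.index
        for b in blocks:
            idx = idx.intersection(b.data.index)
        wide = pd.concat([b.data.reindex(idx).add_prefix(f"{b.name}::") for b in blocks], axis=1)
        frame = pd.concat([y.reindex(idx).rename("__y__"), wide], axis=1)
        complete = frame.dropna()
        self.n_dropped = len(frame) - len(complete)
        self.model = model
        self.y = complete["__y__"].to_numpy()
        self.X = complete.drop(columns="__y__")
        self.block_slices: dict[str, list[int]] = {}
        for b in blocks:
            cols = [i for i, c in enumerate(self.X.columns) if c.startswith(f"{b.name}::")]
            self.block_slices[b.name] = cols
        self._check_duplicate_columns()

    def _check_duplicate_columns(self):
        A = self.X.to_numpy()
        sd = A.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = list(self.X.columns[sd == 0])
            raise ValueError(f"constant predictor column(s): {bad}")
        Z = (A - A.mean(axis=0)) / sd
        corr = np.abs(Z.T @ Z) / (len(Z) - 1)
        p = corr.shape[0]
        for i in range(p):
            for j in range(i + 1, p):
                if corr[i, j] > 1 - 1e-12:
                    ci, cj = self.X.columns[i], self.X.columns[j]
                    if ci.split("::")[0] != cj.split("::")[0]:
                        raise ValueError(
                            f"column duplicated across blocks: {ci!r} vs {cj!r}"
                        )

    def _shares(self, X: np.ndarray) -> tuple[dict[str, float], float, np.ndarray]:
        omega = car_scores(X, self.y)
        w2 = omega ** 2
        shares = {name: float(w2[cols].sum()) for name, cols in self.block_slices.items()}
        return shares, float(w2.sum()), omega

    def fit(
        self,
        n_perm: int = 0,
        seed: int | None = None,
        permute_blocks: tuple[str, ...] = ("phylo_pcs", "habitat_pcs"),
        joint: bool = True,
    ) -> VariancePartitionResults:
        """Compute shares, optionally with a row-permutation null.

        Each permutation independently shuffles the rows of the blocks in
        ``permute_blocks`` (simultaneously when ``joint``, matching the
        default procedure; separately per block otherwise) and recomputes
        the shares; the empirical p of a block is the fraction of permuted
        shares at least as large as the observed one (add-one corrected).
        """
        X = self.X.to_numpy()
        shares, total, omega = self._shares(X)
        perm_p: dict[str, float] = {}
        null_df = None
        if n_perm:
            if n_perm < 100:
                raise ValueError("need at least 100 permutations for a usable null")
            rng = np.random.default_rng(seed)
            targets = [b for b in permute_blocks if b in self.block_slices]
            null = {b: np.empty(n_perm) for b in targets}
            n = X.shape[0]
            if joint:
                # one run permuting every target block (independent row orders)
                for it in range(n_perm):
                    Xp = X.copy()
                    for b in targets:
                        cols = self.block_slices[b]
                        Xp[:, cols] = X[rng.permutation(n)][:, cols]
                    s, _, _ = self._shares(Xp)
                    for b in targets:
                        null[b][it] = s[b]
            else:
                # separate runs, each permuting a single block
                for b in targets:
                    cols = self.block_slices[b]
                    for it in range(n_perm):
                        Xp = X.copy()
                        Xp[:, cols] = X[rng.permutation(n)][:, cols]
                        null[b][it] = self._shares(Xp)[0][b]
            for b in targets:
                perm_p[b] = float((1 + (null[b] >= shares[b]).sum()) / (1 + n_perm))
            null_df = pd.DataFrame(null)
        return VariancePartitionResults(
            feature=self.feature,
            model=self.model,
            share_per_block={name: shares[name] for name in self.block_slices},
            total_r2=total,
            permutation_p=perm_p,
            null_shares=null_df,
            n_permutations=n_perm,
            seed=seed,
            n_species=len(self.y),
            n_dropped=self.n_dropped,
            car_omega=pd.Series(omega, index=self.X.columns),
        )


def partition_feature(
    y: pd.Series, blocks: list[PredictorBlock], model: str = "base", **fit_kwargs
) -> VariancePartitionResults:
    """Convenience wrapper: ``VariancePartition(y, blocks, model).fit()``."""
    return VariancePartition(y, blocks, model).fit(**fit_kwargs)
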