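"""Trial data containers and the AMMI design/incidence structure.

The linear-bilinear (AMMI) model for a multi-environment trial reads

    y = X1 beta + Z g + sum_k lambda_k diag(Z alpha_k) X2 gamma_k + eps

where ``y`` stacks plot-level records, ``X1`` is the incidence of blocks
nested within environments, ``X2`` the incidence of environments, ``Z``
the incidence of genotypes, and the bilinear terms decompose the
genotype-by-environment interaction (GEI) through singular values
``lambda_k`` and centered, orthonormal singular vectors ``alpha_k``
(genotypic, length g) and ``gamma_k`` (environmental, length e).

Everything downstream (Gibbs sampler, reversible jump, cross-validation)
works from the integer index arrays stored here rather than from dense
incidence matrices; the dense ``X1``/``X2``/``Z`` are available as
properties for checking and for small-instance oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_COLUMNS = {
    "genotype": "genotype",
    "environment": "environment",
    "block": "block",
    "response": "response",
}


class TrialFormatError(ValueError):
    """Raised when an input table does not have the expected layout."""


@dataclass
class TrialData:
    """Long-format phenotype records with genotype/environment/block labels.

    Labels are kept verbatim; internally every record carries 0-based
    indices into the lexicographically sorted genotype, environment and
    block-within-environment (cell) label lists.  Unbalance is allowed:
    a (genotype, environment) cell may hold any number of records.
    """

    table: pd.DataFrame
    genotypes: np.ndarray
    environments: np.ndarray
    block_cells: list[tuple]
    geno_idx: np.ndarray
    env_idx: np.ndarray
    cell_idx: np.ndarray
    y: np.ndarray
    n_dropped: int = 0

    @property
    def g(self) -> int:
        return len(self.genotypes)

    @property
    def e(self) -> int:
        return len(self.environments)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_cells(self) -> int:
        """Number of block-within-environment cells (columns of X1)."""
        return len(self.block_cells)

    @property
    def t_max(self) -> int:
        return min(self.g, self.e) - 1

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, columns: dict | None = None) -> "TrialData":
        cols = dict(DEFAULT_COLUMNS)
        if columns:
            cols.update(columns)
        for key in ("genotype", "environment", "block", "response"):
            if cols[key] not in frame.columns:
                raise TrialFormatError(
                    f"missing required column {cols[key]!r} (mapped from {key!r})"
                )
        df = frame[[cols["genotype"], cols["environment"], cols["block"], cols["response"]]].copy()
        df.columns = ["genotype", "environment", "block", "response"]
        df["response"] = pd.to_numeric(df["response"], errors="coerce")
        n_raw = len(df)
        df = df.dropna(subset=["response"]).reset_index(drop=True)
        if df.empty:
            raise TrialFormatError("no usable records: table is empty after dropping missing responses")
        genotypes = np.array(sorted(df["genotype"].unique(), key=str))
        environments = np.array(sorted(df["environment"].unique(), key=str))
        # blocks are nested within environments: a cell is an (env, block) pair
        cells = sorted({(ev, bl) for ev, bl in zip(df["environment"], df["block"])}, key=lambda p: (str(p[0]), str(p[1])))
        gmap = {lab: i for i, lab in enumerate(genotypes)}
        emap = {lab: i for i, lab in enumerate(environments)}
        cmap = {cell: i for i, cell in enumerate(cells)}
        geno_idx = df["genotype"].map(gmap).to_numpy(dtype=np.intp)
        env_idx = df["environment"].map(emap).to_numpy(dtype=np.intp)
        cell_idx = np.array([cmap[(ev, bl)] for ev, bl in zip(df["environment"], df["block"])], dtype=np.intp)
        return cls(
            table=df,
            genotypes=genotypes,
            environments=environments,
            block_cells=cells,
            geno_idx=geno_idx,
            env_idx=env_idx,
            cell_idx=cell_idx,
            y=df["response"].to_numpy(dtype=float),
            n_dropped=n_raw - len(df),
        )

    def subset(self, keep: np.ndarray) -> "TrialData":
        """Rebuild a TrialData from a boolean/record mask (used by cross-validation)."""
        return TrialData.from_frame(self.table.loc[np.asarray(keep)].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def read_trial_table(path, columns: dict | None = None) -> TrialData:
    """Read a long-format trial CSV into a :class:`TrialData`.

    ``columns`` maps the canonical names (genotype, environment, block,
    response) to the file's actual column names.  Records whose response
    does not parse as a number are dropped; the count is available as
    ``TrialData.n_dropped``.
    """
    frame = pd.read_csv(path)
    return TrialData.from_frame(frame, columns)


@dataclass
class DesignMatrices:
    """Incidence structure of the AMMI model.

    ``X1`` (n x er') indexes blocks within environments, ``X2`` (n x e)
    indexes environments and ``Z`` (n x g) genotypes.  The samplers only
    need the index arrays plus the per-column record counts; the dense
    0/1 matrices are built lazily.
    """

    geno_idx: np.ndarray
    env_idx: np.ndarray
    cell_idx: np.ndarray
    g: int
    e: int
    n_cells: int

    count_cell: np.ndarray = field(init=False)
    count_geno: np.ndarray = field(init=False)
    count_env: np.ndarray = field(init=False)

    cross_cell_geno: np.ndarray = field(init=False)

    def __post_init__(self):
        n = len(self.geno_idx)
        self.count_cell = np.bincount(self.cell_idx, minlength=self.n_cells).astype(float)
        self.count_geno = np.bincount(self.geno_idx, minlength=self.g).astype(float)
        self.count_env = np.bincount(self.env_idx, minlength=self.e).astype(float)
        if np.any(self.count_cell == 0):
            raise ValueError("every block-within-environment cell must hold at least one record")
        self.n = n
        # X1'Z: records shared by each (block cell, genotype) pair
        cross = np.zeros((self.n_cells, self.g))
        np.add.at(cross, (self.cell_idx, self.geno_idx), 1.0)
        self.cross_cell_geno = cross

    @property
    def X1(self) -> np.ndarray:
        M = np.zeros((self.n, self.n_cells))
        M[np.arange(self.n), self.cell_idx] = 1.0
        return M

    @property
    def X2(self) -> np.ndarray:
        M = np.zeros((self.n, self.e))
        M[np.arange(self.n), self.env_idx] = 1.0
        return M

    @property
    def Z(self) -> np.ndarray:
        M = np.zeros((self.n, self.g))
        M[np.arange(self.n), self.geno_idx] = 1.0
        return M


def build_designs(data: TrialData) -> DesignMatrices:
    """Build the X1/X2/Z incidence structure from a :class:`TrialData`."""
    return DesignMatrices(
        geno_idx=data.geno_idx,
        env_idx=data.env_idx,
        cell_idx=data.cell_idx,
        g=data.g,
        e=data.e,
        n_cells=data.n_cells,
    )


@dataclass
class ModelState:
    """One full parameter configuration of the AMMI model at dimension t.

    Invariants: singular values ordered ``lambda_1 >= ... >= lambda_t >= 0``;
    each singular vector has unit norm, is centered (orthogonal to the ones
    vector) and orthogonal to the other vectors on its side; all variance
    components strictly positive.
    """

    beta: np.ndarray          # block-within-environment effects (n_cells,)
    gvec: np.ndarray          # genotype effects (g,)
    lambdas: np.ndarray       # (t,)
    alphas: np.ndarray        # (g, t)
    gammas: np.ndarray        # (e, t)
    sigma2_lambda: np.ndarray  # (t,)
    sigma2_g: float
    sigma2_e: float
    mu: float

    @property
    def t(self) -> int:
        return len(self.lambdas)

    def copy(self) -> "ModelState":
        return ModelState(
            beta=self.beta.copy(),
            gvec=self.gvec.copy(),
            lambdas=self.lambdas.copy(),
            alphas=self.alphas.copy(),
            gammas=self.gammas.copy(),
            sigma2_lambda=self.sigma2_lambda.copy(),
            sigma2_g=self.sigma2_g,
            sigma2_e=self.sigma2_e,
            mu=self.mu,
        )

    def check(self, atol: float = 1e-8) -> None:
        """Raise AssertionError if any structural invariant is violated."""
        t = self.t
        if t:
            assert np.all(np.diff(self.lambdas) <= atol), "singular values out of order"
            assert np.all(self.lambdas >= -atol), "negative singular value"
            for side in (self.alphas, self.gammas):
                G = side.T @ side
                assert np.allclose(G, np.eye(t), atol=1e-6), "singular vectors not orthonormal"
                assert np.all(np.abs(side.sum(axis=0)) < 1e-6), "singular vectors not centered"
        assert self.sigma2_g > 0 and self.sigma2_e > 0, "variance components must be positive"


def theta_vector(state: ModelState, designs: DesignMatrices) -> np.ndarray:
    """Record-level model mean: X1 beta + Z g + sum_k lambda_k diag(Z alpha_k) X2 gamma_k."""
    theta = state.beta[designs.cell_idx] + state.gvec[designs.geno_idx]
    if state.t:
        prod = state.alphas[designs.geno_idx, :] * state.gammas[designs.env_idx, :]
        theta = theta + prod @ state.lambdas
    return theta


@dataclass
class CenteredGEMatrix:
    """g x e matrix of cell-mean interaction effects, double-centered."""

    values: np.ndarray
    imputed_cells: list = field(default_factory=list)

    def check(self, atol: float = 1e-8) -> None:
        assert np.all(np.abs(self.values.sum(axis=0)) < atol)
        assert np.all(np.abs(self.values.sum(axis=1)) < atol)


def double_center(M: np.ndarray) -> np.ndarray:
    """Subtract row means, column means and add back the grand mean."""
    return M - M.mean(axis=1, keepdims=True) - M.mean(axis=0, keepdims=True) + M.mean()


def cell_mean_interaction(data: TrialData) -> CenteredGEMatrix:
    """Double-centered matrix of cell means (diagnostic / truth oracle only).

    Empty cells are imputed by the additive fit (genotype mean + environment
    mean - grand mean) before centering and flagged; the MCMC samplers never
    touch this matrix.
    """
    sums = np.zeros((data.g, data.e))
    counts = np.zeros((data.g, data.e))
    np.add.at(sums, (data.geno_idx, data.env_idx), data.y)
    np.add.at(counts, (data.geno_idx, data.env_idx), 1.0)
    imputed = list(zip(*np.nonzero(counts == 0)))
    with np.errstate(invalid="ignore"):
        means = sums / counts
    if imputed:
        grand = data.y.mean()
        gm = np.array([data.y[data.geno_idx == i].mean() for i in range(data.g)])
        em = np.array([data.y[data.env_idx == j].mean() for j in range(data.e)])
        for i, j in imputed:
            means[i, j] = gm[i] + em[j] - grand
    return CenteredGEMatrix(values=double_center(means), imputed_cells=imputed)
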