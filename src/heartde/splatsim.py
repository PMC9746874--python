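"""Artificial count simulators: a splat-style gamma-Poisson benchmark
generator with known DE multipliers, and a plain UMI-like source generator
for feeding the semi-simulation.

The splat-style model follows the standard hierarchical recipe for droplet
scRNA-seq counts: gene base means are gamma distributed, each cell has a
log-normal library-size factor, the expected count of gene j in cell i is
``libsize_i * mean_j / sum(mean)``, and observed counts are gamma-Poisson
(negative binomial) with dispersion derived from a biological coefficient
of variation (variance = mu + (bcv*mu)^2).  DE genes receive a log-normal
multiplicative factor on their group-2 mean, upward or downward with equal
probability.  An optional logistic-in-log-mean dropout step can zero
entries on top.  This is a generative re-implementation in the spirit of
the splat model, not a numerical port of any existing package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import optimize

from .errors import ValidationError
from .io_counts import CountMatrix, GroupLabels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplatConfig:
    """Parameters of the splat-style two-group simulation.

    n_genes_nonde, n_genes_de
        Numbers of null and DE genes (total genes = sum).
    n_cells
        Total cells; split into two equal groups.
    de_factor, de_factor_scale
        Location and sd of the log-normal DE multiplier: a DE gene's
        group-2 mean is multiplied by ``f`` or ``1/f`` (equal probability)
        with ``f = exp(Normal(de_factor, de_factor_scale))``.
    mean_shape, mean_rate
        Gamma hyperparameters of the gene base means.
    libsize_loc, libsize_scale
        Log-normal hyperparameters of per-cell library sizes.
    bcv
        Biological coefficient of variation; NB dispersion is ``bcv**2``
        (gamma shape ``1/bcv**2``).
    dropout_mid, dropout_shape
        Optional logistic dropout on the log expected count; disabled when
        ``dropout_mid`` is None.
    """

    n_cells: int
    n_genes_nonde: int = 10000
    n_genes_de: int = 1000
    de_factor: float = 0.5
    de_factor_scale: float = 0.4
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    libsize_loc: float = math.log(2000.0)
    libsize_scale: float = 0.3
    bcv: float = 0.2
    dropout_mid: float | None = None
    dropout_shape: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValidationError("n_cells must be >= 2")
        if self.n_genes_nonde < 1 or self.n_genes_de < 0:
            raise ValidationError("gene counts must be positive")
        if self.de_factor < 0 or self.de_factor_scale < 0:
            raise ValidationError("de_factor parameters must be >= 0")
        if min(self.mean_shape, self.mean_rate, self.bcv) <= 0:
            raise ValidationError("mean_shape, mean_rate and bcv must be > 0")


@dataclass
class SimDataset:
    """Simulated counts with the known truth."""

    counts: CountMatrix
    groups: GroupLabels
    truth_de: set[str]
    multipliers: np.ndarray


def _sample_nb_sparse(rng, mean_rows, libsize, size, chunk=256, dropout=None):
    """Sample gamma-Poisson counts gene-chunk by gene-chunk into CSR.

    ``mean_rows`` is (G, n_cells is implied by libsize) broadcastable per
    gene; ``size`` is the gamma shape (1 / bcv^2).  Returns a CSR matrix.
    Chunking keeps peak memory at ``chunk * n_cells`` doubles.
    """
    G = mean_rows.shape[0]
    n_cells = libsize.size
    blocks = []
    for start in range(0, G, chunk):
        stop = min(start + chunk, G)
        mu = mean_rows[start:stop, None] * libsize[None, :]
        lam = rng.gamma(shape=size, scale=mu / size)
        block = rng.poisson(lam)
        if dropout is not None:
            mid, shape = dropout
            with np.errstate(divide="ignore"):
                logmu = np.log(np.where(mu > 0, mu, np.finfo(float).tiny))
            p_drop = 1.0 / (1.0 + np.exp(-shape * (logmu - mid)))
            block = np.where(rng.random(block.shape) < p_drop, 0, block)
        blocks.append(sp.csr_matrix(block))
    return sp.vstack(blocks, format="csr")


def simulate_splat_like(config: SplatConfig) -> SimDataset:
    """Generate a two-group dataset with known multiplicative DE.

    Deterministic given ``config.seed``.  The returned ``multipliers`` array
    holds each gene's group-2 / group-1 expected-mean ratio; the truth set
    is exactly the genes whose multiplier differs from 1.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes_nonde + config.n_genes_de
    base_means = rng.gamma(shape=config.mean_shape, scale=1.0 / config.mean_rate, size=G)

    multipliers = np.ones(G)
    de_idx = rng.choice(G, size=config.n_genes_de, replace=False)
    factors = np.exp(rng.normal(config.de_factor, config.de_factor_scale, config.n_genes_de))
    down = rng.random(config.n_genes_de) < 0.5
    multipliers[de_idx] = np.where(down, 1.0 / factors, factors)

    means1 = base_means
    means2 = base_means * multipliers
    n1 = config.n_cells // 2
    n2 = config.n_cells - n1
    libsize = np.exp(
        rng.normal(config.libsize_loc, config.libsize_scale, config.n_cells)
    )
    size = 1.0 / config.bcv**2
    dropout = (
        None
        if config.dropout_mid is None
        else (config.dropout_mid, config.dropout_shape)
    )
    X1 = _sample_nb_sparse(
        rng, means1 / means1.sum(), libsize[:n1], size, dropout=dropout
    )
    X2 = sp.csr_matrix((G, 0), dtype=np.int64)
    if n2:
        X2 = _sample_nb_sparse(
            rng, means2 / means2.sum(), libsize[n1:], size, dropout=dropout
        )
    values = sp.hstack([X1, X2], format="csr")

    gene_ids = [f"gene{j + 1}" for j in range(G)]
    cell_ids = [f"cell{i + 1}" for i in range(config.n_cells)]
    counts = CountMatrix(values, gene_ids, cell_ids)
    assignment = np.concatenate(
        [np.ones(n1, dtype=np.int8), np.full(n2, 2, dtype=np.int8)]
    )
    groups = GroupLabels(assignment, cell_ids=cell_ids)
    truth = {gene_ids[j] for j in np.flatnonzero(multipliers != 1.0)}
    logger.info(
        "splat-like simulation: %d genes (%d DE), %d cells, density %.3f",
        G,
        len(truth),
        config.n_cells,
        counts.density(),
    )
    return SimDataset(counts=counts, groups=groups, truth_de=truth, multipliers=multipliers)


def simulate_pbmc_like_source(
    n_genes: int,
    n_cells: int,
    sparsity_target: float = 0.9,
    seed: int = 0,
    mean_shape: float = 0.4,
    nb_size: float = 2.0,
) -> CountMatrix:
    """Generate an exchangeable UMI-like source matrix for the semi-simulation.

    Gene means are drawn from a heavy-tailed gamma (shape ``mean_shape``)
    and rescaled by a common factor solved so that the expected overall zero
    fraction equals ``sparsity_target``; counts are negative binomial with
    gamma shape ``nb_size`` (dispersion ``1/nb_size``), i.i.d. across cells
    so the cells carry no group structure.
    """
    if not 0.5 < sparsity_target < 0.99:
        raise ValidationError("sparsity_target must be in (0.5, 0.99)")
    if n_genes < 1 or n_cells < 1:
        raise ValidationError("n_genes and n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    mu = rng.gamma(shape=mean_shape, scale=1.0, size=n_genes)
    mu = np.maximum(mu, 1e-12)
    r = nb_size

    def zero_fraction(log_c: float) -> float:
        return float(np.mean((r / (r + np.exp(log_c) * mu)) ** r)) - sparsity_target

    lo, hi = -20.0, 20.0
    if zero_fraction(lo) < 0 or zero_fraction(hi) > 0:
        raise ValidationError(
            f"sparsity target {sparsity_target} unreachable for these gene means"
        )
    log_c = optimize.brentq(zero_fraction, lo, hi, xtol=1e-10)
    mu *= np.exp(log_c)

    values = _sample_nb_sparse(rng, mu, np.ones(n_cells), size=r)
    gene_ids = [f"gene{j + 1}" for j in range(n_genes)]
    cell_ids = [f"cell{i + 1}" for i in range(n_cells)]
    counts = CountMatrix(values, gene_ids, cell_ids)
    logger.info(
        "pbmc-like source: %d genes x %d cells, zero fraction %.3f (target %.2f)",
        n_genes,
        n_cells,
        1.0 - counts.density(),
        sparsity_target,
    )
    return counts
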