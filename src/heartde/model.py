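"""End-to-end differential-expression model and results objects.

:class:`HeartDE` is constructed from a :class:`~heartde.io_counts.CountMatrix`
and a two-level :class:`~heartde.io_counts.GroupLabels`; ``fit()`` runs the
three component tests for every gene, combines them with Fisher's method,
calibrates the chi-square degrees of freedom of the combined statistic on
the genome-wide distribution, adjusts for multiple testing by
Benjamini-Hochberg and returns a :class:`HeartDEResults`.

The functional entry point :func:`run_heart` does the same without the
object ceremony and is what the CLI and the benchmark code call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps

from .errors import ValidationError
from .io_counts import CountMatrix, GroupLabels, write_results
from .stats import P_FLOOR, _clamp, _welch_from_stats, bh_adjust, estimate_df, proportion_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeartConfig:
    """Tuning knobs for the combination test.

    alpha
        FDR level for the final DE call.
    min_cells_on
        Minimum positive cells per group for the location and dispersion
        components; below it those components report no evidence.  3 is the
        smallest count at which a variance and a median-deviation spread are
        meaningful.
    min_total_cells
        Total-cell threshold below which a small-sample warning is logged;
        the test is known to lose power on tiny datasets.
    df_fit
        ``"mle"`` calibrates the combined-statistic degrees of freedom from
        the data; ``"fixed6"`` uses the independence value 6.
    normalize
        ``None`` tests raw counts (the default); ``"cpm"`` rescales each
        cell to counts per million before the positive-part tests (the
        expressing-cell proportions are scale-invariant and unaffected).
    """

    alpha: float = 0.05
    min_cells_on: int = 3
    min_total_cells: int = 60
    df_fit: str = "mle"
    normalize: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.min_cells_on < 2:
            raise ValidationError("min_cells_on must be >= 2")
        if self.df_fit not in ("mle", "fixed6"):
            raise ValidationError("df_fit must be 'mle' or 'fixed6'")
        if self.normalize not in (None, "cpm"):
            raise ValidationError("normalize must be None or 'cpm'")


@dataclass
class HeartResultTable:
    """Per-gene combined-test results.

    ``frame`` has one row per gene with the component statistics and
    p-values (z/L1, t/L2, W/L3), the positive-cell counts m1/m2, the number
    of valid components, the combined statistic Q, its p-value under the
    calibrated chi-square, the BH-adjusted q and the DE call at ``alpha``.
    """

    frame: pd.DataFrame
    fitted_df: float
    alpha: float

    @property
    def de_genes(self) -> list[str]:
        return list(self.frame.loc[self.frame["is_de"], "gene_id"])

    @property
    def n_significant(self) -> int:
        return int(self.frame["is_de"].sum())

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# vectorised per-group summaries
# ---------------------------------------------------------------------------


def _group_positive_stats(X: sp.csr_matrix):
    """Positive-part count, mean and sample variance per gene (row)."""
    m = np.diff(X.indptr)
    total = np.asarray(X.sum(axis=1)).ravel()
    totalsq = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        xbar = np.where(m > 0, total / np.maximum(m, 1), 0.0)
        var = np.where(
            m > 1, (totalsq - np.maximum(m, 1) * xbar**2) / np.maximum(m - 1, 1), 0.0
        )
    return m, xbar, np.maximum(var, 0.0)


def _brown_forsythe_rows(X1: sp.csr_matrix, X2: sp.csr_matrix, rows: np.ndarray):
    """Brown-Forsythe W and one-sided F p-value for the given genes.

    Iterates over genes because per-row medians do not vectorise over a
    ragged sparse structure; each iteration touches only that gene's stored
    positive values.
    """
    W = np.zeros(rows.size)
    L3 = np.ones(rows.size)
    ind1, dat1 = X1.indptr, X1.data
    ind2, dat2 = X2.indptr, X2.data
    for k, g in enumerate(rows):
        x1 = dat1[ind1[g] : ind1[g + 1]]
        x2 = dat2[ind2[g] : ind2[g + 1]]
        m1, m2 = x1.size, x2.size
        z1 = np.abs(x1 - np.median(x1))
        z2 = np.abs(x2 - np.median(x2))
        zbar1 = z1.mean()
        zbar2 = z2.mean()
        zbar = (m1 * zbar1 + m2 * zbar2) / (m1 + m2)
        ssb = m1 * (zbar1 - zbar) ** 2 + m2 * (zbar2 - zbar) ** 2
        ssw = np.sum((z1 - zbar1) ** 2) + np.sum((z2 - zbar2) ** 2)
        if ssw == 0.0:
            if ssb > 0.0:
                W[k] = np.inf
                L3[k] = P_FLOOR
            continue
        dof = m1 + m2 - 2
        W[k] = dof * ssb / ssw
    todo = np.isfinite(W) & (W > 0)
    if todo.any():
        dof = np.array(
            [
                (ind1[g + 1] - ind1[g]) + (ind2[g + 1] - ind2[g]) - 2
                for g in rows[todo]
            ]
        )
        L3[todo] = _clamp(sps.f.sf(W[todo], 1, dof))
    return W, L3


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_heart(
    counts: CountMatrix, groups: GroupLabels, config: HeartConfig | None = None
) -> HeartResultTable:
    """Run the full combination test on every gene.

    The location and dispersion components are computed only for genes with
    at least ``config.min_cells_on`` positive cells in each group; otherwise
    they contribute no evidence (p = 1, recorded as invalid).  The combined
    statistic's degrees of freedom are fitted once, on genes where all three
    components were valid, and genes with fewer valid components use that df
    scaled by ``n_valid / 3``.
    """
    config = config or HeartConfig()
    if groups.n_cells != counts.n_cells:
        raise ValidationError(
            f"{groups.n_cells} group labels for {counts.n_cells} cells"
        )
    if groups.cell_ids is not None and groups.cell_ids != counts.cell_ids:
        raise ValidationError("group labels and counts disagree on cell ids")
    n1, n2 = groups.n1, groups.n2
    if n1 + n2 < config.min_total_cells:
        logger.warning(
            "only %d cells in total (< %d); the test loses power on small datasets",
            n1 + n2,
            config.min_total_cells,
        )

    csc = counts.values.tocsc()
    X1 = csc[:, groups.indices(1)].tocsr()
    X2 = csc[:, groups.indices(2)].tocsr()
    if config.normalize == "cpm":
        X1, X2 = (_cpm(X) for X in (X1, X2))
    G = counts.n_genes

    # component 1: expressing-cell proportions
    m1 = np.diff(X1.indptr)
    m2 = np.diff(X2.indptr)
    z, L1 = proportion_test(m1, n1, m2, n2)
    z = np.atleast_1d(z)
    L1 = np.atleast_1d(L1)
    pooled = (m1 + m2) / (n1 + n2)
    valid1 = (pooled > 0) & (pooled < 1)

    # components 2 and 3: positive parts only
    _, xbar1, v1 = _group_positive_stats(X1)
    _, xbar2, v2 = _group_positive_stats(X2)
    eligible = (m1 >= config.min_cells_on) & (m2 >= config.min_cells_on)
    t = np.zeros(G)
    df_t = np.zeros(G)
    L2 = np.ones(G)
    if eligible.any():
        e = eligible
        t[e], df_t[e], L2[e] = _welch_from_stats(
            xbar1[e], v1[e], m1[e], xbar2[e], v2[e], m2[e]
        )
    W = np.zeros(G)
    L3 = np.ones(G)
    rows = np.flatnonzero(eligible)
    if rows.size:
        W[rows], L3[rows] = _brown_forsythe_rows(X1, X2, rows)

    L1 = _clamp(L1)
    L2 = _clamp(L2)
    L3 = _clamp(L3)
    valid = np.column_stack([valid1, eligible, eligible])
    logs = np.column_stack([np.log(L1), np.log(L2), np.log(L3)])
    Q = -2.0 * np.sum(np.where(valid, logs, 0.0), axis=1)
    n_valid = valid.sum(axis=1)

    if config.df_fit == "fixed6":
        fitted_df = 6.0
    else:
        fitted_df = estimate_df(Q[n_valid == 3])
    logger.info("fitted combined-statistic df = %.3f", fitted_df)

    p = np.ones(G)
    testable = n_valid > 0
    p[testable] = _clamp(
        sps.chi2.sf(Q[testable], fitted_df * n_valid[testable] / 3.0)
    )
    q = bh_adjust(p)
    is_de = q < config.alpha
    logger.info("%d of %d genes called DE at FDR %.3g", int(is_de.sum()), G, config.alpha)

    frame = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "m1": m1,
            "m2": m2,
            "p_hat1": m1 / n1,
            "p_hat2": m2 / n2,
            "z": z,
            "L1": L1,
            "xbar1": xbar1,
            "xbar2": xbar2,
            "s1_sq": v1,
            "s2_sq": v2,
            "t": t,
            "df_t": df_t,
            "L2": L2,
            "W": W,
            "L3": L3,
            "n_valid": n_valid,
            "Q": Q,
            "p": p,
            "q": q,
            "is_de": is_de,
        }
    )
    return HeartResultTable(frame=frame, fitted_df=fitted_df, alpha=config.alpha)


def _cpm(X: sp.csr_matrix) -> sp.csr_matrix:
    """Counts-per-million rescaling per cell (column)."""
    depth = np.asarray(X.sum(axis=0)).ravel()
    scale = np.divide(1e6, depth, out=np.zeros_like(depth, dtype=float), where=depth > 0)
    return X.multiply(sp.csr_matrix(scale)).tocsr()


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class HeartDE:
    """Differential-expression model for two groups of cells.

    Parameters
    ----------
    counts
        Gene x cell integer count matrix.
    groups
        Two-level cell grouping aligned with the matrix columns.
    config
        Optional :class:`HeartConfig`; keyword overrides are also accepted
        by :meth:`fit`.

    Examples
    --------
    >>> model = HeartDE(counts, groups)
    >>> res = model.fit()
    >>> res.de_genes[:5]
    """

    def __init__(
        self,
        counts: CountMatrix,
        groups: GroupLabels,
        config: HeartConfig | None = None,
    ) -> None:
        self.counts = counts
        self.groups = groups
        self.config = config or HeartConfig()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, labels, **config_kwargs) -> "HeartDE":
        """Build a model from a genes x cells DataFrame and per-cell labels.

        ``labels`` is a sequence (or mapping indexed like the columns) with
        exactly two distinct values; they are coded 1 and 2 in sorted order.
        """
        counts = CountMatrix(
            sp.csr_matrix(frame.to_numpy()),
            list(frame.index.astype(str)),
            list(frame.columns.astype(str)),
        )
        if isinstance(labels, pd.Series):
            labels = labels.reindex(frame.columns)
            if labels.isna().any():
                raise ValidationError("labels missing for some cells")
            labels = labels.to_numpy()
        labels = np.asarray(labels)
        levels = sorted(pd.unique(labels).tolist())
        if len(levels) != 2:
            raise ValidationError(f"expected exactly 2 group levels, got {levels}")
        assignment = np.where(labels == levels[0], 1, 2)
        groups = GroupLabels(
            assignment,
            cell_ids=counts.cell_ids,
            level_names={1: str(levels[0]), 2: str(levels[1])},
        )
        config = HeartConfig(**config_kwargs) if config_kwargs else None
        return cls(counts, groups, config)

    def fit(self, **overrides) -> "HeartDEResults":
        """Run the test; keyword overrides update the model config."""
        config = replace(self.config, **overrides) if overrides else self.config
        table = run_heart(self.counts, self.groups, config)
        return HeartDEResults(self, table)


class HeartDEResults:
    """Fitted results: per-gene table, calibrated df, and DE calls."""

    def __init__(self, model: HeartDE, table: HeartResultTable) -> None:
        self.model = model
        self.table = table

    @property
    def frame(self) -> pd.DataFrame:
        return self.table.frame

    @property
    def fitted_df(self) -> float:
        return self.table.fitted_df

    @property
    def alpha(self) -> float:
        return self.table.alpha

    @property
    def de_genes(self) -> list[str]:
        return self.table.de_genes

    @property
    def n_significant(self) -> int:
        return self.table.n_significant

    def save(self, path) -> None:
        write_results(self.table, path)

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        f = self.frame
        top = f.nsmallest(min(10, len(f)), "q")
        lines = [
            "HEART combination test",
            "=" * 58,
            f"genes tested:        {len(f)}",
            f"cells (group 1/2):   {self.model.groups.n1} / {self.model.groups.n2}",
            f"fitted df of Q:      {self.fitted_df:.3f}",
            f"DE genes (q < {self.alpha:g}): {self.n_significant}",
            "-" * 58,
            "top genes by q:",
            top[["gene_id", "m1", "m2", "Q", "p", "q"]].to_string(index=False),
        ]
        return "\n".join(lines)

    def plot_qq(self, ax=None):
        """QQ-plot of combined p-values against the uniform distribution."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = np.sort(self.frame["p"].to_numpy())
        expected = (np.arange(1, p.size + 1) - 0.5) / p.size
        ax.plot(-np.log10(expected), -np.log10(p), ".", markersize=3)
        lim = max(1.0, -np.log10(max(p.min(), 1e-30)))
        ax.plot([0, lim], [0, lim], "k--", linewidth=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        return ax
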