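"""Semi-simulation benchmarks: plant known DE genes into a real count matrix.

The construction keeps every marginal feature of the source data intact.
Cells are split uniformly at random into two pseudo-groups, which by
exchangeability creates an exact global null.  Ground-truth DE genes are
then created by swapping the group-2 expression vectors of mean-matched
gene pairs: genes are ranked by their group-2 mean count, the first ``k``
genes with mean just above an anchor ``s1`` are paired rank-by-rank with
the first ``k`` genes with mean just above ``s2 = FC * s1``, and each
pair's group-2 rows are exchanged.  The fold-change-like parameter ``FC``
controls the DE strength; the paired genes (2k of them) are the truth set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError
from .io_counts import CountMatrix, GroupLabels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SemiSimConfig:
    """Settings for one semi-simulated dataset.

    fc
        DE strength: the high anchor is ``s2 = fc * s1``. Must exceed 1.
    k
        Genes per selection set; the truth set has ``2k`` genes.
    s1
        Lower mean-count anchor, or ``"auto"`` to use the median of the
        positive group-2 gene means.
    seed
        Seed for the cell split (the only randomness).
    null_mode
        Skip the swap entirely: a pure null split with an empty truth set.
    """

    fc: float = 2.5
    k: int = 200
    s1: float | str = "auto"
    seed: int = 0
    null_mode: bool = False

    def __post_init__(self) -> None:
        if self.fc <= 1:
            raise ValidationError("fc must be > 1")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.s1 != "auto" and not (isinstance(self.s1, (int, float)) and self.s1 > 0):
            raise ValidationError("s1 must be positive or 'auto'")


@dataclass
class SemiSimDataset:
    """A swapped dataset with its ground truth and provenance."""

    counts: CountMatrix
    groups: GroupLabels
    truth_de: set[str]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    s1_used: float = float("nan")
    s2_used: float = float("nan")
    config: SemiSimConfig | None = None


def split_cells(counts: CountMatrix, seed: int) -> GroupLabels:
    """Uniformly random balanced split of the cells into two groups.

    Group sizes differ by at most one; the assignment is a deterministic
    function of the seed.
    """
    n = counts.n_cells
    if n < 2:
        raise ValidationError("need at least 2 cells to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.full(n, 2, dtype=np.int8)
    assignment[perm[: n // 2]] = 1
    return GroupLabels(assignment, cell_ids=list(counts.cell_ids))


def select_swap_genes(group2_means: np.ndarray, s1: float, fc: float, k: int):
    """Choose the two mean-matched gene sets to swap, paired by rank.

    Genes are sorted by their group-2 mean count (ascending, ties broken by
    index).  The low set is the first ``k`` genes with mean strictly above
    ``s1``; the high set is the first ``k`` genes with mean strictly above
    ``s2 = fc * s1`` that are not already in the low set.  Returns a list of
    ``k`` (low_index, high_index) pairs, matched in rank order.
    """
    means = np.asarray(group2_means, dtype=float)
    order = np.argsort(means, kind="mergesort")
    sorted_means = means[order]
    s2 = fc * s1

    low_start = np.searchsorted(sorted_means, s1, side="right")
    if low_start + k > means.size:
        raise ValidationError(
            f"only {means.size - low_start} genes with mean > s1={s1:g}; "
            f"need {k}. Lower s1 or k."
        )
    low = order[low_start : low_start + k]

    high_start = np.searchsorted(sorted_means, s2, side="right")
    low_set = set(low.tolist())
    high: list[int] = []
    pos = high_start
    while len(high) < k and pos < means.size:
        g = order[pos]
        if g not in low_set:
            high.append(g)
        pos += 1
    if len(high) < k:
        raise ValidationError(
            f"only {len(high)} non-overlapping genes with mean > s2={s2:g}; "
            f"need {k}. Lower s1 or k."
        )
    return list(zip(low.tolist(), high))


def _resolve_s1(group2_means: np.ndarray) -> float:
    positive = group2_means[group2_means > 0]
    if positive.size == 0:
        raise ValidationError("all genes are zero in group 2; cannot resolve s1")
    return float(np.quantile(positive, 0.5))


def make_semisim(counts: CountMatrix, config: SemiSimConfig) -> SemiSimDataset:
    """Build a semi-simulated benchmark dataset from a source matrix.

    In ``null_mode`` only the random split happens and the truth set is
    empty.  Otherwise the selected gene pairs have their group-2 rows
    exchanged exactly (cell-aligned), so group 1 stays bit-identical to the
    source and the combined count mass of each pair within group 2 is
    conserved.
    """
    groups = split_cells(counts, config.seed)
    if config.null_mode:
        return SemiSimDataset(
            counts=counts, groups=groups, truth_de=set(), config=config
        )

    idx2 = groups.indices(2)
    csc = counts.values.tocsc()
    G2 = csc[:, idx2].tocsr()
    means2 = np.asarray(G2.sum(axis=1)).ravel() / idx2.size
    s1 = _resolve_s1(means2) if config.s1 == "auto" else float(config.s1)
    pairs_idx = select_swap_genes(means2, s1, config.fc, config.k)
    logger.info(
        "semisim: s1=%.4g s2=%.4g, swapping %d gene pairs", s1, config.fc * s1, config.k
    )

    perm = np.arange(counts.n_genes)
    for low, high in pairs_idx:
        perm[low], perm[high] = high, low
    G2_swapped = G2[perm, :]

    idx1 = groups.indices(1)
    G1 = csc[:, idx1].tocsr()
    stacked = sp.hstack([G1, G2_swapped], format="csc")
    col_order = np.concatenate([idx1, idx2])
    inverse = np.empty_like(col_order)
    inverse[col_order] = np.arange(col_order.size)
    values = stacked[:, inverse].tocsr()

    gene_ids = counts.gene_ids
    pairs = [(gene_ids[lo], gene_ids[hi]) for lo, hi in pairs_idx]
    truth = {g for pair in pairs for g in pair}
    return SemiSimDataset(
        counts=CountMatrix(values, list(gene_ids), list(counts.cell_ids)),
        groups=groups,
        truth_de=truth,
        pairs=pairs,
        s1_used=s1,
        s2_used=config.fc * s1,
        config=config,
    )
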