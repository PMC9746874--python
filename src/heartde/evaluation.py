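"""Benchmark metrics: per-gene confusion counts and replicated grids.

Every simulated dataset carries an exact truth set, so method quality is a
plain 2x2 confusion over the gene universe: TPR (recall), precision, F1,
specificity and the realized FDR.  Grids average the metrics over seeded
replicates -- metric first, mean second, matching how simulation studies
usually report "average over replications" -- rather than pooling counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import HeartConfig, run_heart
from .semisim import SemiSimConfig, make_semisim
from .splatsim import SplatConfig, simulate_pbmc_like_source, simulate_splat_like


@dataclass(frozen=True)
class ConfusionMetrics:
    """Gene-level confusion counts and the derived rates.

    Ratios with an empty denominator (e.g. precision with no calls) are
    reported as 0.0 and flagged in ``undefined`` by name.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    tpr: float
    precision: float
    f1: float
    specificity: float
    fdr: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "tpr": self.tpr,
            "precision": self.precision,
            "f1": self.f1,
            "specificity": self.specificity,
            "fdr": self.fdr,
        }


def _ratio(num: int, den: int, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def confusion_metrics(called, truth, universe) -> ConfusionMetrics:
    """Confusion metrics of a call set against a truth set over a universe."""
    called = set(called)
    truth = set(truth)
    universe = set(universe)
    if not called <= universe:
        raise ValidationError("called genes outside the universe")
    if not truth <= universe:
        raise ValidationError("truth genes outside the universe")
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    tn = len(universe) - tp - fp - fn
    undefined: set[str] = set()
    tpr = _ratio(tp, tp + fn, "tpr", undefined)
    precision = _ratio(tp, tp + fp, "precision", undefined)
    specificity = _ratio(tn, tn + fp, "specificity", undefined)
    fdr = _ratio(fp, tp + fp, "fdr", undefined)
    if precision + tpr > 0:
        f1 = 2.0 * precision * tpr / (precision + tpr)
    else:
        undefined.add("f1")
        f1 = 0.0
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        tpr=tpr,
        precision=precision,
        f1=f1,
        specificity=specificity,
        fdr=fdr,
        undefined=frozenset(undefined),
    )


_METRICS = ["tpr", "precision", "f1", "specificity", "fdr"]


def _replicate_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def evaluate_heart_on(dataset, heart_config: HeartConfig | None = None) -> ConfusionMetrics:
    """Run the test on a simulated dataset and score it against its truth."""
    table = run_heart(dataset.counts, dataset.groups, heart_config)
    return confusion_metrics(
        set(table.de_genes), dataset.truth_de, set(dataset.counts.gene_ids)
    )


def _one_replicate(generator: str, cfg: dict, rep_seed: int, heart_config):
    if generator == "splat":
        sim_cfg = SplatConfig(**{**cfg, "seed": rep_seed})
        dataset = simulate_splat_like(sim_cfg)
    elif generator == "semisim":
        cfg = dict(cfg)
        source_kwargs = cfg.pop("source", {})
        source = simulate_pbmc_like_source(
            n_genes=source_kwargs.get("n_genes", 10000),
            n_cells=source_kwargs.get("n_cells", 4000),
            sparsity_target=source_kwargs.get("sparsity_target", 0.9),
            seed=rep_seed,
        )
        sim_cfg = SemiSimConfig(**{**cfg, "seed": rep_seed})
        dataset = make_semisim(source, sim_cfg)
    else:
        raise ValidationError(f"unknown generator {generator!r}")
    return evaluate_heart_on(dataset, heart_config)


def benchmark_grid(
    generator: str,
    grid: list[dict],
    replicates: int = 20,
    seed: int = 0,
    heart_config: HeartConfig | None = None,
    pooled: bool = False,
) -> pd.DataFrame:
    """Run the test over a grid of simulator configs with seeded replicates.

    Each grid entry is a dict of :class:`SplatConfig` or
    :class:`SemiSimConfig` keyword arguments (for ``semisim`` an optional
    ``source`` sub-dict sizes the synthetic source matrix).  Replicate seeds
    are spawned deterministically from ``seed``.  Per metric the table holds
    the mean and sd over replicates; ``pooled=True`` instead sums the
    confusion counts over replicates and derives the rates once.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rows = []
    for cfg_i, cfg in enumerate(grid):
        seeds = _replicate_seeds(seed + cfg_i, replicates)
        results = [
            _one_replicate(generator, cfg, rep_seed, heart_config) for rep_seed in seeds
        ]
        row: dict = {"config": cfg_i, **{k: v for k, v in cfg.items() if k != "source"}}
        if pooled:
            tp, fp, fn, tn = (
                sum(getattr(r, c) for r in results) for c in ("tp", "fp", "fn", "tn")
            )
            undefined: set[str] = set()
            tpr = _ratio(tp, tp + fn, "tpr", undefined)
            precision = _ratio(tp, tp + fp, "precision", undefined)
            pooled_vals = {
                "tpr": tpr,
                "precision": precision,
                "f1": 2 * precision * tpr / (precision + tpr) if precision + tpr else 0.0,
                "specificity": _ratio(tn, tn + fp, "specificity", undefined),
                "fdr": _ratio(fp, tp + fp, "fdr", undefined),
            }
            for m in _METRICS:
                row[f"{m}_mean"] = pooled_vals[m]
                row[f"{m}_sd"] = float("nan")
        else:
            for m in _METRICS:
                vals = np.array([getattr(r, m) for r in results])
                row[f"{m}_mean"] = float(vals.mean())
                row[f"{m}_sd"] = float(vals.std(ddof=1)) if replicates > 1 else float("nan")
        row["undefined_any"] = any(r.undefined for r in results)
        rows.append(row)
    return pd.DataFrame(rows)
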