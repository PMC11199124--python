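"""Variable-importance machinery.

Boosted-tree importance is the classical relative influence: each covariate's
share of the total squared-error reduction across every split in every tree,
normalized to sum to 100.  Lasso "importance" is variable selection — the set
of covariates with nonzero coefficients — ranked by absolute standardized
coefficient (a documented convention; selection itself is the primary signal).
For hybrid models importance derives solely from the trend component, since
residual kriging attributes nothing to covariates.

Across several datasets (e.g. separate ecoregions), :func:`topk_frequency`
counts how often each covariate lands in a model's top-k, producing the
frequency ranking used to compare which drivers recur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SpatialDataset
from .errors import DataValidationError
from .evaluation import cross_validate
from .hybrid import HybridModel

__all__ = [
    "ImportanceTable",
    "brt_importance",
    "lasso_selection",
    "importance_table",
    "topk_frequency",
    "ablation_rerun",
    "plot_topk_frequency",
]


@dataclass(frozen=True)
class ImportanceTable:
    """Per-variable importance scores with a deterministic rank order.

    ``selected`` marks variables that carry any importance (for the lasso,
    exactly the nonzero-coefficient set).  ``all_zero`` flags the degenerate
    constant-response case where no variable reduced error.
    """

    names: tuple[str, ...]
    scores: np.ndarray
    kind: str
    selected: np.ndarray
    all_zero: bool = False

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape[0] != len(self.names):
            raise DataValidationError("scores length must match names")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "selected", np.asarray(self.selected, dtype=int))

    def ranking(self) -> list[str]:
        """Names sorted by decreasing score; ties broken alphabetically."""
        order = sorted(range(len(self.names)), key=lambda j: (-self.scores[j], self.names[j]))
        return [self.names[j] for j in order]

    def top(self, k: int) -> list[str]:
        """Top-k variables by score; zero-score variables never qualify."""
        positive = [n for n in self.ranking() if self.scores[self.names.index(n)] > 0]
        return positive[:k]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"variable": self.names, "score": self.scores})
        df["selected"] = np.isin(np.arange(len(self.names)), self.selected)
        return df.sort_values(
            ["score", "variable"], ascending=[False, True], ignore_index=True
        )


def brt_importance(model) -> ImportanceTable:
    """Relative influence of a fitted boosted-tree trend, summing to 100."""
    if getattr(model, "kind", None) != "brt":
        raise DataValidationError("brt_importance requires a fitted BRT trend")
    scores = np.asarray(model.importance_scores, dtype=float)
    total = scores.sum()
    if total == 0:
        return ImportanceTable(
            names=model.feature_names,
            scores=np.zeros_like(scores),
            kind="brt",
            selected=np.empty(0, dtype=int),
            all_zero=True,
        )
    scores = scores * (100.0 / total)
    return ImportanceTable(
        names=model.feature_names,
        scores=scores,
        kind="brt",
        selected=np.flatnonzero(scores > 0),
    )


def lasso_selection(model) -> ImportanceTable:
    """Selected-variable table of a fitted lasso: |coefficient| scores, zeros dropped."""
    if getattr(model, "kind", None) != "lasso":
        raise DataValidationError("lasso_selection requires a fitted lasso trend")
    scores = np.abs(np.asarray(model.coef, dtype=float))
    return ImportanceTable(
        names=model.feature_names,
        scores=scores,
        kind="lasso",
        selected=np.flatnonzero(scores > 0),
        all_zero=bool(np.all(scores == 0)),
    )


def importance_table(model) -> ImportanceTable:
    """Importance of any trend or hybrid model.

    For a hybrid this is exactly its trend component's importance: the kriged
    residual part carries no covariate attribution.
    """
    if isinstance(model, HybridModel):
        model = model.trend
    kind = getattr(model, "kind", None)
    if kind == "brt":
        return brt_importance(model)
    if kind == "lasso":
        return lasso_selection(model)
    raise DataValidationError(f"cannot compute importance for {type(model).__name__}")


def topk_frequency(tables, k: int = 15) -> pd.DataFrame:
    """Count, per variable, the datasets where it ranks in the top-k.

    All tables must share one variable universe.  The result is sorted by
    decreasing frequency (ties by name) with columns ``variable`` and
    ``frequency``; variables never in any top-k appear with frequency 0.
    """
    tables = list(tables)
    if not tables:
        raise DataValidationError("need at least one importance table")
    universe = set(tables[0].names)
    for t in tables[1:]:
        if set(t.names) != universe:
            diff = sorted(universe.symmetric_difference(t.names))
            raise DataValidationError(
                f"inconsistent variable universes; symmetric difference: {diff}"
            )
    counts = {name: 0 for name in sorted(universe)}
    for t in tables:
        for name in t.top(k):
            counts[name] += 1
    df = pd.DataFrame(
        {"variable": list(counts.keys()), "frequency": list(counts.values())}
    )
    return df.sort_values(
        ["frequency", "variable"], ascending=[False, True], ignore_index=True
    )


def ablation_rerun(
    data: SpatialDataset,
    drop,
    algo_params: dict[str, dict],
    k: int = 10,
    seed: int = 0,
    allow_small_n: bool = False,
) -> pd.DataFrame:
    """Cross-validate before and after removing named covariates.

    Both runs share the identical fold partition, so the per-algorithm RMSE
    delta is a paired comparison of the full and reduced covariate sets.
    Returns one row per algorithm: baseline RMSE, ablated RMSE, delta.
    """
    reduced = data.drop_covariates(drop)  # raises on unknown names
    rows = []
    for algo, params in algo_params.items():
        base = cross_validate(
            data, algo, params, k=k, seed=seed, allow_small_n=allow_small_n
        )
        abl = cross_validate(
            reduced, algo, params, k=k, seed=seed, allow_small_n=allow_small_n
        )
        rows.append(
            {
                "algorithm": algo,
                "dropped": ",".join(drop),
                "baseline_rmse": base.pooled_rmse,
                "ablated_rmse": abl.pooled_rmse,
                "delta_rmse": abl.pooled_rmse - base.pooled_rmse,
            }
        )
    return pd.DataFrame(rows)


def plot_topk_frequency(freq: pd.DataFrame, ax=None, title=None):
    """Horizontal bar chart of a top-k frequency ranking, decreasing order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(freq) + 1))
    shown = freq[freq["frequency"] > 0]
    ax.barh(shown["variable"][::-1], shown["frequency"][::-1])
    ax.set_xlabel("datasets with variable in top-k")
    if title:
        ax.set_title(title)
    return ax
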