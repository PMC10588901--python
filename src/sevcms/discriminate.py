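"""Burden labels and ROC/AUC screening of per-parameter discriminatory power.

For each disease model, animals are labeled 1 ("with burden": treated,
epileptic or mutant) or 0 ("without burden": sham-implanted or wild-type
controls) from the study config's group map; groups mapped to ``exclude``
(typically naive, non-implanted animals) are left out. Each parameter is then
scored by the area under its ROC curve. The AUC is computed by the
Mann-Whitney pair-counting identity — the fraction of (burden, control)
pairs the parameter orders correctly, ties counting one half — and the curve
itself comes from all distinct score thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .datasets import DatasetError, ParameterTable, StudyConfig


@dataclass
class BurdenLabels:
    """Binary burden labels per animal, with exclusions and provenance."""

    labels: dict[str, int]  # animal_id -> 0/1
    excluded: list[str]
    mapping: dict[str, object]  # group -> 0 | 1 | "exclude"


@dataclass
class RocResult:
    """ROC curve and AUC for one parameter."""

    parameter: str
    auc: float  # orientation: larger score => burden
    auc_oriented: float  # max(auc, 1 - auc)
    flipped: bool  # True when the oriented AUC reversed the direction
    curve: np.ndarray  # (n_points, 2): (1 - specificity, sensitivity)
    n_pos: int
    n_neg: int


def make_burden_labels(table: ParameterTable, config: StudyConfig) -> BurdenLabels:
    """Map group labels to the binary burden classifier.

    Every group present in the table must be mapped in
    ``config.group_burden_map`` to 0, 1 or ``"exclude"``; an unmapped group
    is a hard error so that a typo cannot silently drop animals.
    """
    mapping = config.group_burden_map
    groups = set(table.meta["group"])
    unmapped = sorted(g for g in groups if g not in mapping)
    if unmapped:
        raise DatasetError(
            f"groups without burden mapping: {unmapped}; map each to 0, 1 or 'exclude'"
        )
    labels: dict[str, int] = {}
    excluded: list[str] = []
    for rec in table.meta.itertuples():
        val = mapping[rec.group]
        if val == "exclude":
            excluded.append(rec.animal_id)
        elif val in (0, 1):
            labels[rec.animal_id] = int(val)
        else:
            raise DatasetError(f"invalid burden mapping {val!r} for group {rec.group!r}")
    return BurdenLabels(labels=labels, excluded=excluded, mapping=dict(mapping))


def pair_counting_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as (concordant + 0.5 * tied) / (n_pos * n_neg).

    Equivalent to the Mann-Whitney U statistic normalized by the number of
    (positive, negative) pairs; computed via rank sums in O(n log n).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    n_pos, n_neg = len(pos), len(neg)
    if n_pos == 0 or n_neg == 0:
        raise DatasetError("AUC requires at least one animal in each class")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[:n_pos].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_auc(scores: pd.Series, labels: BurdenLabels,
                parameter: str = "") -> RocResult:
    """ROC curve and AUC for one parameter's scores against the burden labels.

    Animals with a missing score are dropped pairwise. The emitted curve runs
    from (0, 0) to (1, 1) over all distinct thresholds; its trapezoidal area
    equals the pair-counting AUC.
    """
    ids = [a for a in scores.index if a in labels.labels]
    y = np.array([labels.labels[a] for a in ids])
    s = scores.loc[ids].to_numpy(dtype=float)
    ok = ~np.isnan(s)
    y, s = y[ok], s[ok]
    if len(s) == 0:
        raise DatasetError(f"all scores missing for parameter {parameter!r}")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DatasetError(
            f"parameter {parameter!r}: one burden class is empty "
            f"(n_pos={n_pos}, n_neg={n_neg})"
        )
    auc = pair_counting_auc(s[y == 1], s[y == 0])
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    curve = np.column_stack([fpr, tpr])
    oriented = max(auc, 1.0 - auc)
    return RocResult(
        parameter=parameter, auc=auc, auc_oriented=oriented,
        flipped=oriented != auc, curve=curve, n_pos=n_pos, n_neg=n_neg,
    )


def roc_table(table: ParameterTable, config: StudyConfig,
              parameters: list[str] | None = None) -> tuple[pd.DataFrame, list[RocResult]]:
    """Per-parameter AUC screen for one model's table.

    Returns a tidy summary frame (parameter, auc, auc_oriented, flipped,
    n_pos, n_neg) plus the full :class:`RocResult` objects with curves.
    """
    labels = make_burden_labels(table, config)
    results = []
    for p in parameters or table.parameters:
        scores = pd.Series(table.values[p].to_numpy(), index=table.animal_ids)
        results.append(compute_auc(scores, labels, parameter=p))
    frame = pd.DataFrame(
        [{"parameter": r.parameter, "auc": r.auc, "auc_oriented": r.auc_oriented,
          "flipped": r.flipped, "n_pos": r.n_pos, "n_neg": r.n_neg}
         for r in results]
    )
    return frame, results
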