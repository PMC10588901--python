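"""Spearman correlation screening and redundancy pruning.

Highly correlated parameter pairs carry overlapping information (e.g. open
field distance and velocity, which is distance over test duration), and
letting them all enter the composite analyses would let one behavioral
construct dominate. This module computes the pairwise Spearman matrix on
pairwise-complete observations, flags significant (|r| > 0.5, p < 0.05) and
redundant (|r| > 0.7, p < 0.05) pairs, and prunes redundant parameters under
configurable keep-rules.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DatasetError, ParameterTable, StudyConfig

#: Minimum complete pairwise observations for a defined correlation.
MIN_PAIR_N = 3

#: Largest pair count for which the exact permutation p-value is enumerated.
EXACT_P_MAX_N = 8


@dataclass
class CorrelationResult:
    """Symmetric Spearman r and p matrices with per-pair sample sizes."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame
    undefined: pd.DataFrame  # True where r could not be computed

    @property
    def parameters(self) -> list[str]:
        return list(self.r.columns)


@dataclass
class RedundancyReport:
    """Significant / redundant pair flags and the pruning ledger."""

    significant_pairs: list[dict] = field(default_factory=list)
    redundant_pairs: list[dict] = field(default_factory=list)
    dropped: list[dict] = field(default_factory=list)

    def redundant_set(self) -> set[tuple[str, str]]:
        return {(d["a"], d["b"]) for d in self.redundant_pairs}


def _spearman_r(rx: np.ndarray, ry: np.ndarray) -> float:
    """Product-moment correlation of two mid-rank vectors."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def exact_spearman_pvalue(x, y, alternative: str = "two-sided") -> float:
    """Exact permutation p-value for the Spearman coefficient.

    Enumerates all n! orderings of one variable; suited to n <= 8
    (40320 permutations). Ties are handled with mid-ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > EXACT_P_MAX_N:
        raise ValueError(f"exact enumeration limited to n <= {EXACT_P_MAX_N}, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r_obs = _spearman_r(rx, ry)
    eps = 1e-12
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r_perm = _spearman_r(rx, np.asarray(perm))
        total += 1
        if alternative == "two-sided":
            count += abs(r_perm) >= abs(r_obs) - eps
        elif alternative == "greater":
            count += r_perm >= r_obs - eps
        elif alternative == "less":
            count += r_perm <= r_obs + eps
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return count / total


def spearman_matrix(table: ParameterTable, exact_small_n: bool = True) -> CorrelationResult:
    """Pairwise-complete Spearman correlation matrix with two-sided p-values.

    Coefficients use mid-ranks (tie-corrected). p-values come from the
    large-sample t approximation, replaced by exact permutation enumeration
    when a pair has at most 8 complete observations. Pairs with fewer than 3
    complete observations, or involving a constant column, are marked
    undefined rather than propagating NaN silently.
    """
    params = table.parameters
    k = len(params)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n_mat = np.zeros((k, k), dtype=int)
    undef = np.zeros((k, k), dtype=bool)
    X = table.values.to_numpy()

    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        n_mat[i, i] = int(np.sum(~np.isnan(X[:, i])))
        if np.nanstd(X[:, i]) == 0:
            undef[i, :] = undef[:, i] = True
            r[i, i] = np.nan

    for i, j in itertools.combinations(range(k), 2):
        ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
        n = int(ok.sum())
        n_mat[i, j] = n_mat[j, i] = n
        if n < MIN_PAIR_N:
            undef[i, j] = undef[j, i] = True
            continue
        xi, xj = X[ok, i], X[ok, j]
        if np.std(xi) == 0 or np.std(xj) == 0:
            undef[i, j] = undef[j, i] = True
            continue
        rho = _spearman_r(stats.rankdata(xi), stats.rankdata(xj))
        if exact_small_n and n <= EXACT_P_MAX_N:
            pv = exact_spearman_pvalue(xi, xj, alternative="two-sided")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pv = float(stats.spearmanr(xi, xj).pvalue)
        r[i, j] = r[j, i] = rho
        p[i, j] = p[j, i] = pv

    as_df = lambda a: pd.DataFrame(a, index=params, columns=params)
    return CorrelationResult(r=as_df(r), p=as_df(p),
                             n_pairs=as_df(n_mat), undefined=as_df(undef))


def flag_pairs(corr: CorrelationResult, config: StudyConfig) -> RedundancyReport:
    """Flag significant and redundant pairs under strict cutoffs.

    A pair is significant when |r| > ``r_significant`` and p < ``p_cut``;
    redundant when additionally |r| > ``r_redundant``. Both comparisons are
    strict, so r exactly at a cutoff does not trigger it.
    """
    report = RedundancyReport()
    params = corr.parameters
    for i, j in itertools.combinations(range(len(params)), 2):
        a, b = params[i], params[j]
        if bool(corr.undefined.iloc[i, j]):
            continue
        rv = float(corr.r.iloc[i, j])
        pv = float(corr.p.iloc[i, j])
        if pv < config.p_cut and abs(rv) > config.r_significant:
            entry = {"a": a, "b": b, "r": rv, "p": pv}
            report.significant_pairs.append(entry)
            if abs(rv) > config.r_redundant:
                report.redundant_pairs.append(dict(entry))
    return report


def prune_parameters(
    table: ParameterTable,
    report: RedundancyReport,
    keep_rules: list[str] | None = None,
    manual_exclusions: dict[str, str] | None = None,
) -> tuple[ParameterTable, RedundancyReport]:
    """Drop parameters until no redundant pair remains among the survivors.

    ``keep_rules`` is an ordered keep-preference list: a parameter appearing
    earlier is protected more strongly, and parameters not listed are dropped
    first. Ties are broken by dropping the member with the larger total |r|
    over its redundant pairs, then lexicographically (the later name goes).
    ``manual_exclusions`` applies configured post-correlation removals (e.g.
    a redundant-in-spirit assay judged less sensitive) with their reasons.

    Returns the pruned table and the report with the ``dropped`` ledger
    filled in.
    """
    keep_rules = list(keep_rules or [])
    unknown = [kr for kr in keep_rules if kr not in table.parameters]
    if unknown:
        warnings.warn(f"keep_rules name unknown parameters: {unknown}", stacklevel=2)

    def keep_priority(p: str) -> int:
        return keep_rules.index(p) if p in keep_rules else len(keep_rules)

    alive = list(table.parameters)
    edges = [d for d in report.redundant_pairs]

    def alive_edges():
        return [d for d in edges if d["a"] in alive and d["b"] in alive]

    while True:
        current = alive_edges()
        if not current:
            break
        # candidates: every parameter in >= 1 redundant pair
        total_r: dict[str, float] = {}
        for d in current:
            for name in (d["a"], d["b"]):
                total_r[name] = total_r.get(name, 0.0) + abs(d["r"])
        # drop the least-protected; tie-break by larger total |r|, then by
        # lexicographically later name
        victim = max(
            total_r,
            key=lambda name: (keep_priority(name), total_r[name], name),
        )
        pair = next(d for d in current if victim in (d["a"], d["b"]))
        if keep_priority(victim) == len(keep_rules) and any(
            keep_priority(o) < len(keep_rules)
            for o in total_r if o != victim
        ):
            rule = "keep_rule"
        else:
            rule = "total_abs_r"
        report.dropped.append({
            "parameter": victim, "reason": "redundant", "rule": rule,
            "pair": (pair["a"], pair["b"]), "r": pair["r"], "p": pair["p"],
        })
        alive.remove(victim)

    for name, reason in (manual_exclusions or {}).items():
        if name in alive:
            report.dropped.append({
                "parameter": name, "reason": "manual_post_correlation",
                "rule": "config", "pair": None, "r": None, "p": None,
                "detail": reason,
            })
            alive.remove(name)

    return table.select_parameters(alive), report
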