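"""Synthetic severity-assessment datasets with known ground truth.

Emulates the structure of a multi-model welfare study: several animal
groups (e.g. naive / sham / treated), a battery of numeric parameters of
which a subset is informative (its group means are shifted by a planted
standardized effect), blocks of mutually correlated parameters (the same
behavioral construct measured several ways), optional lognormal marginals
(to exercise the Box-Cox stage away from lambda = 1), and completely-at-
random missingness. Because the marginals are unit-variance normal before
any monotone marginal transform, the expected AUC of an informative
parameter between two groups shifted by d is the binormal closed form
Phi(d / sqrt(2)), which the ground-truth object carries for every
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datasets import DatasetError, ParameterTable, table_from_dataframe


@dataclass
class GroupSpec:
    """One animal group: label, burden class (0/1/"exclude") and size."""

    label: str
    burden: object  # 0 | 1 | "exclude"
    size: int
    model: str = "synthetic"

    def __post_init__(self):
        if self.size < 2:
            raise DatasetError(f"group {self.label!r} needs size >= 2, got {self.size}")


@dataclass
class SyntheticSpec:
    """Full description of a synthetic dataset.

    ``effects`` maps parameter index -> {group label -> standardized mean
    shift}; parameters not listed are pure noise. ``correlation_blocks`` is
    a list of (parameter indices, rho) with equicorrelation rho inside each
    block, realized through a shared latent factor. ``distributions`` may
    mark individual parameters "lognormal" (the unit-variance normal draw is
    exponentiated, a strictly monotone marginal transform that leaves every
    rank-based quantity unchanged).
    """

    groups: list[GroupSpec]
    n_parameters: int = 10
    effects: dict[int, dict[str, float]] = field(default_factory=dict)
    correlation_blocks: list[tuple[list[int], float]] = field(default_factory=list)
    distributions: dict[int, str] = field(default_factory=dict)
    missing_rate: float = 0.0
    age_brackets: list[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.missing_rate <= 0.5):
            raise DatasetError(f"missing_rate must lie in [0, 0.5], got {self.missing_rate}")
        seen: set[int] = set()
        for idxs, rho in self.correlation_blocks:
            if not (-1 < rho < 1):
                raise DatasetError(f"block correlation must lie in (-1, 1), got {rho}")
            if rho < 0 and len(idxs) > 2:
                raise DatasetError(
                    "negative equicorrelation is only positive-definite for pairs"
                )
            if seen & set(idxs):
                raise DatasetError("correlation blocks must be disjoint")
            seen |= set(idxs)
        for i in self.effects:
            if not (0 <= i < self.n_parameters):
                raise DatasetError(f"effect index {i} out of range")

    @property
    def parameter_names(self) -> list[str]:
        return [f"param_{i + 1:02d}" for i in range(self.n_parameters)]


@dataclass
class GroundTruth:
    """What the generator planted, for oracle-style checks."""

    informative: list[str]
    severity_order: list[str]  # group labels, least to most severe
    expected_auc: dict[str, float]  # parameter -> Phi(d / sqrt(2)) vs burden-0 groups
    missing_mask: pd.DataFrame = None


def generate_dataset(spec: SyntheticSpec) -> tuple[ParameterTable, GroundTruth]:
    """Draw one dataset and its ground truth from a :class:`SyntheticSpec`.

    Same seed, same spec -> bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.parameter_names
    n_total = sum(g.size for g in spec.groups)
    p = spec.n_parameters

    # unit-variance noise with block equicorrelation via a shared factor:
    # x = sqrt(rho) * f_block + sqrt(1 - rho) * eps
    X = rng.standard_normal((n_total, p))
    for idxs, rho in spec.correlation_blocks:
        if rho >= 0:
            f = rng.standard_normal(n_total)
            for i in idxs:
                X[:, i] = np.sqrt(rho) * f + np.sqrt(1 - rho) * X[:, i]
        else:  # a negatively correlated pair
            a, b = idxs
            f = rng.standard_normal(n_total)
            X[:, a] = np.sqrt(-rho) * f + np.sqrt(1 + rho) * X[:, a]
            X[:, b] = -np.sqrt(-rho) * f + np.sqrt(1 + rho) * X[:, b]

    meta_rows = []
    row = 0
    group_rows: dict[str, slice] = {}
    for g in spec.groups:
        group_rows[g.label] = slice(row, row + g.size)
        for i in range(g.size):
            bracket = ""
            if spec.age_brackets:
                bracket = spec.age_brackets[i % len(spec.age_brackets)]
            meta_rows.append({
                "animal_id": f"{g.model}_{g.label}_{i + 1:03d}",
                "model": g.model, "group": g.label,
                "age_bracket": bracket,
                "sex": "female" if rng.random() < 0.5 else "male",
            })
        row += g.size

    for i, shifts in spec.effects.items():
        for label, d in shifts.items():
            if label not in group_rows:
                raise DatasetError(f"effect names unknown group {label!r}")
            X[group_rows[label], i] += d

    # planted severity = total shift applied to each group over informative params
    severity = {g.label: sum(spec.effects.get(i, {}).get(g.label, 0.0)
                             for i in spec.effects) for g in spec.groups}
    severity_order = sorted(severity, key=lambda lab: severity[lab])

    # expected AUC of each parameter for burden-1 vs burden-0 groups
    burden_map = {g.label: g.burden for g in spec.groups}
    pos = [g.label for g in spec.groups if g.burden == 1]
    neg = [g.label for g in spec.groups if g.burden == 0]
    expected_auc = {}
    for i, name in enumerate(names):
        if pos and neg:
            d_pos = np.mean([spec.effects.get(i, {}).get(lab, 0.0) for lab in pos])
            d_neg = np.mean([spec.effects.get(i, {}).get(lab, 0.0) for lab in neg])
            expected_auc[name] = float(norm.cdf((d_pos - d_neg) / np.sqrt(2)))

    for i, dist in spec.distributions.items():
        if dist == "lognormal":
            X[:, i] = np.exp(X[:, i])
        elif dist != "normal":
            raise DatasetError(f"unknown distribution {dist!r}")

    mask = rng.random((n_total, p)) < spec.missing_rate
    X = X.astype(float)
    X[mask] = np.nan

    df = pd.DataFrame(meta_rows)
    for j, name in enumerate(names):
        df[name] = X[:, j]
    table = table_from_dataframe(df, source="<synthetic>")
    truth = GroundTruth(
        informative=[names[i] for i in sorted(spec.effects)],
        severity_order=severity_order,
        expected_auc=expected_auc,
        missing_mask=pd.DataFrame(mask, columns=names),
    )
    return table, truth


def default_three_group_spec(
    n_per_group: int = 30,
    n_parameters: int = 15,
    n_informative: int = 3,
    effect: float = 1.5,
    rho_block: float = 0.4,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> SyntheticSpec:
    """Canonical naive / sham / treated study with planted treated severity.

    Mirrors a single induced-disease subproject: the treated group is
    shifted by ``effect`` standard deviations on each informative parameter,
    the sham group by a third of that (surgery without disease), and the
    naive group not at all. One block of parameters is correlated at
    ``rho_block`` to emulate readouts of a shared behavioral construct.
    """
    groups = [
        GroupSpec("naive", "exclude", n_per_group),
        GroupSpec("sham", 0, n_per_group),
        GroupSpec("treated", 1, n_per_group),
    ]
    informative = list(range(n_informative))
    effects = {i: {"treated": effect, "sham": effect / 3.0} for i in informative}
    block = list(range(n_informative, min(n_informative + 3, n_parameters)))
    blocks = [(block, rho_block)] if len(block) >= 2 else []
    return SyntheticSpec(
        groups=groups, n_parameters=n_parameters, effects=effects,
        correlation_blocks=blocks, missing_rate=missing_rate, seed=seed,
    )
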