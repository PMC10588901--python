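"""Parameter preselection: data-integrity (missingness) filter plus manual exclusions.

Only parameter columns are ever dropped; animals are never removed at this
stage. A parameter is removed when strictly more than ``missingness_cut``
(default 20%) of its cells are missing — a column with exactly 20% missing is
retained — or when the study config lists it with a manual exclusion reason
(e.g. body-weight parameters confounded by model-specific weight gain).
Every removal is logged with its reason and observed missingness fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .datasets import DatasetError, ParameterTable, StudyConfig


@dataclass
class PreselectionResult:
    """Ledger of the preselection step."""

    retained: list[str]
    removed: list[dict]  # {"parameter", "reason", "missingness", "detail"}
    missingness: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"parameter": p, "status": "retained",
                 "missingness": self.missingness[p]} for p in self.retained]
        rows += [{"parameter": r["parameter"], "status": f"removed ({r['reason']})",
                  "missingness": r["missingness"]} for r in self.removed]
        return pd.DataFrame(rows)


def compute_missingness(table: ParameterTable) -> dict[str, float]:
    """Fraction of missing cells per parameter (missing / total rows)."""
    if table.n_animals == 0:
        raise DatasetError("cannot compute missingness on a zero-row table")
    frac = table.values.isna().mean(axis=0)
    return {p: float(frac[p]) for p in table.parameters}


def apply_preselection(
    table: ParameterTable, config: StudyConfig
) -> tuple[ParameterTable, PreselectionResult]:
    """Drop parameters failing the missingness rule or listed for manual exclusion.

    Returns the filtered table and a :class:`PreselectionResult` recording,
    for every removed parameter, whether the missingness rule or a manual
    config entry removed it.
    """
    missingness = compute_missingness(table)
    removed: list[dict] = []
    retained: list[str] = []

    absent = [p for p in config.exclusion_list if p not in table.parameters]
    if absent:
        warnings.warn(f"exclusion_list names absent parameters: {absent}", stacklevel=2)

    for p in table.parameters:
        if p in config.exclusion_list:
            removed.append({
                "parameter": p, "reason": "manual",
                "missingness": missingness[p],
                "detail": str(config.exclusion_list[p]),
            })
        elif missingness[p] > config.missingness_cut:
            removed.append({
                "parameter": p, "reason": "missingness",
                "missingness": missingness[p],
                "detail": f"> {config.missingness_cut:.0%} missing",
            })
        else:
            retained.append(p)

    if not retained:
        raise DatasetError("preselection removed every parameter; check config")
    result = PreselectionResult(retained=retained, removed=removed, missingness=missingness)
    return table.select_parameters(retained), result
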