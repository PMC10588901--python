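"""Shipped study configurations and synthetic study-structured tables.

The configs encode two reference multi-model mouse welfare study designs'
parameter inventories and exclusion judgments: the adult combined set of
three induced epilepsy models (22 parameters after preselection, 17 after
redundancy pruning) and the young genetic-model sets (13 parameters in
early adolescence, 14 in late adolescence, burrowing being assessed only
later in development). Manual exclusions carry their stated reasons
(injury risk, pilot-quality data, model-specific body-weight confounds).

``make_adult_tables`` builds SYNTHETIC tables with the exact column
inventory, group structure (28 + 41 + 44 animals with the 15 naive animals
shared between the two kindling subprojects) and missingness pattern
(grimace scale > 20% missing) of the adult combined dataset. Values are
simulated stand-ins, not the deposited measurements; they exist so the
structural behavior of the pipeline (counts, combination, exclusion logic)
can be exercised without any download.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import ParameterTable, StudyConfig, table_from_dataframe

# -- adult combined set: three induced epilepsy models -----------------------

#: The 22 parameters present after preselection of the adult combined set.
ADULT_PARAMETERS = [
    "nest_building",
    "burrowing_2h_light",
    "burrowing_overnight",
    "irwin_score",
    "of_distance",
    "of_rearing",
    "of_immobility",
    "of_center_time",
    "of_wall_time",
    "of_velocity",
    "si_active",
    "si_passive",
    "saccharin_preference",
    "bwb_time_white",
    "bwb_stretching",
    "bwb_latency",
    "epm_closed_arms",
    "epm_open_arms",
    "epm_open_13",
    "epm_stretching",
    "epm_head_dips",
    "fcm",
]

#: Removed at preselection by the missingness rule in the adult set.
ADULT_MISSINGNESS_REMOVED = ["mgs"]

#: Manual preselection exclusions with their study reasons.
ADULT_MANUAL_EXCLUSIONS = {
    "body_weight_g": "model-specific weight gain unrelated to distress",
    "body_weight_change_pct": "model-specific weight gain unrelated to distress",
    "soiling_level": "assessed in a single subproject only",
    "corticosterone_serum": "invasive sampling; fecal metabolites retained",
    "telemetry_recording": "invasive instrumentation without added value",
    "spontaneous_seizures": "model-defining outcome, not a welfare parameter",
    "induced_seizures": "model-defining outcome, not a welfare parameter",
}

#: Redundancy-driven and sensitivity-driven removals after correlation.
ADULT_POST_CORRELATION = {
    "of_wall_time": "redundant with open-field center time (strong negative r)",
    "of_immobility": "redundant with open-field distance (strong negative r)",
    "of_velocity": "redundant with open-field distance (velocity = distance/time)",
    "epm_closed_arms": "redundant with open-arm duration and head dips",
    "burrowing_overnight": "light-phase burrowing is the more sensitive readout",
}

ADULT_KEEP_RULES = ["burrowing_2h_light", "of_distance", "of_center_time",
                    "epm_open_arms", "epm_head_dips"]


def adult_epilepsy_config(seed: int = 0) -> StudyConfig:
    """Config reproducing the adult combined-set analysis settings (k = 6)."""
    return StudyConfig(
        group_burden_map={"naive": "exclude", "sham": 0, "treated": 1},
        exclusion_list=dict(ADULT_MANUAL_EXCLUSIONS),
        post_correlation_exclusions=dict(ADULT_POST_CORRELATION),
        keep_rules=list(ADULT_KEEP_RULES),
        k=6,
        seed=seed,
    )


# -- young genetic models -----------------------------------------------------

#: Parameters after preselection in early adolescence (13) ...
YOUNG_EARLY_PARAMETERS = [
    "nest_building",
    "irwin_score",
    "temperature",
    "of_distance",
    "of_rearing",
    "of_immobility",
    "of_center_time",
    "of_wall_time",
    "of_jumps",
    "saccharin_preference",
    "fcm",
    "homecage_feeding",
    "homecage_drinking",
]

#: ... and in late adolescence (14; burrowing only shows later in development).
YOUNG_LATE_PARAMETERS = YOUNG_EARLY_PARAMETERS + ["burrowing_overnight_mean"]

YOUNG_MISSINGNESS_REMOVED = ["voluntary_wheel_running"]

YOUNG_MANUAL_EXCLUSIONS = {
    "homecage_distance": "60-minute pilot acquisition, no circadian coverage",
    "homecage_velocity": "60-minute pilot acquisition, no circadian coverage",
    "homecage_center": "covered cage top; center not comparable to open field",
    "body_weight_g": "background-strain differences between the genetic models",
    "body_weight_change_pct": "background-strain differences between the genetic models",
}

YOUNG_POST_CORRELATION = {
    "of_center_time": "redundant with wall-zone duration; transient thigmotaxis "
                      "makes the wall zone the informative readout",
    "of_immobility": "redundant with open-field distance (strong negative r)",
}


def young_genetic_config(seed: int = 0) -> StudyConfig:
    """Config reproducing the young genetic-model analysis settings (k = 4)."""
    return StudyConfig(
        group_burden_map={"wildtype": 0, "mutant": 1},
        exclusion_list=dict(YOUNG_MANUAL_EXCLUSIONS),
        post_correlation_exclusions=dict(YOUNG_POST_CORRELATION),
        keep_rules=["of_wall_time", "of_distance"],
        k=4,
        seed=seed,
    )


# -- synthetic study-structured tables ---------------------------------------

#: Group sizes of the three adult subprojects; the naive group is shared
#: between the two kindling models.
ADULT_GROUPS = {
    "kainate": {"naive": 8, "sham": 8, "treated": 12},
    "hippocampal_kindling": {"naive": 15, "sham": 15, "treated": 11},
    "amygdala_kindling": {"naive": 15, "sham": 15, "treated": 14},
}

#: Parameters on which the synthetic treated groups are shifted (severity).
_ADULT_INFORMATIVE = {
    "irwin_score": 1.2, "burrowing_2h_light": -1.0, "nest_building": -0.8,
    "si_active": -0.8, "bwb_stretching": 0.9, "saccharin_preference": -0.7,
}

#: Built-in strong dependencies among the adult parameters (same construct
#: measured twice), so the redundancy pruning stage has real work to do.
_ADULT_DERIVED = [
    # (derived, source, slope, noise_sd): derived = slope*source + noise
    ("of_velocity", "of_distance", 1.0, 0.25),
    ("of_immobility", "of_distance", -1.0, 0.25),
    ("of_wall_time", "of_center_time", -1.0, 0.30),
    ("epm_closed_arms", "epm_open_arms", -1.0, 0.30),
    ("burrowing_overnight", "burrowing_2h_light", 1.0, 0.35),
]


def make_adult_tables(seed: int = 0) -> list[ParameterTable]:
    """Three SYNTHETIC subproject tables with the adult study's structure.

    Column inventory, group sizes, shared naive animals (the two kindling
    subprojects use the same 15 naive mice, carried with model label
    ``"kindling"`` and byte-identical rows in both tables), and the >20%
    missingness of the grimace-scale column all follow the reference study
    design; the values themselves are simulated (treated groups shifted on
    distress-sensitive parameters, sham groups mildly).
    """
    rng = np.random.default_rng(seed)
    raw_params = (ADULT_PARAMETERS + ADULT_MISSINGNESS_REMOVED
                  + list(ADULT_MANUAL_EXCLUSIONS))
    derived_names = {p for p, *_ in _ADULT_DERIVED}

    def fill_values(df: pd.DataFrame) -> pd.DataFrame:
        n = len(df)
        vals = {}
        for p in raw_params:
            if p in derived_names:
                continue
            x = rng.standard_normal(n)
            shift = _ADULT_INFORMATIVE.get(p, 0.0)
            x += np.where(df["group"] == "treated", shift, 0.0)
            x += np.where(df["group"] == "sham", shift / 3.0, 0.0)
            vals[p] = x
        for derived, source, slope, noise in _ADULT_DERIVED:
            vals[derived] = slope * vals[source] + noise * rng.standard_normal(n)
        for p in raw_params:  # preserve the inventory's column order
            df[p] = vals[p]
        # grimace scale scored in a subset of animals only -> >20% missing
        df.loc[rng.random(n) < 0.35, "mgs"] = np.nan
        for p in ("saccharin_preference", "fcm"):
            df.loc[rng.random(n) < 0.05, p] = np.nan
        return df

    def meta_rows(model, group, size, id_prefix=None):
        prefix = id_prefix or f"{model}_{group}"
        return [{"animal_id": f"{prefix}_{i + 1:02d}", "model": model,
                 "group": group, "age_bracket": "adult", "sex": "female"}
                for i in range(size)]

    # shared naive block of the two kindling subprojects, generated once
    shared_naive = fill_values(pd.DataFrame(
        meta_rows("kindling", "naive", ADULT_GROUPS["hippocampal_kindling"]["naive"])))

    tables = []
    for model, groups in ADULT_GROUPS.items():
        rows = []
        for group, size in groups.items():
            if "kindling" in model and group == "naive":
                continue
            rows += meta_rows(model, group, size)
        df = fill_values(pd.DataFrame(rows))
        if "kindling" in model:
            df = pd.concat([shared_naive.copy(), df], ignore_index=True)
        tables.append(table_from_dataframe(df, source=f"<synthetic {model}>"))
    return tables


def make_young_table(age_bracket: str = "early_adolescence", seed: int = 0,
                     n_per_group: int = 20) -> ParameterTable:
    """SYNTHETIC young genetic-model table (Scn1a / Gria1 structure).

    Two models x (wildtype, mutant) with the early- or late-adolescent
    parameter inventory, voluntary wheel running > 20% missing (not assessed
    in one model), and the Scn1a mutants shifted on distress-sensitive
    parameters.
    """
    if age_bracket not in ("early_adolescence", "late_adolescence"):
        raise ValueError(f"unknown age bracket {age_bracket!r}")
    params = (YOUNG_EARLY_PARAMETERS if age_bracket == "early_adolescence"
              else YOUNG_LATE_PARAMETERS)
    raw_params = params + YOUNG_MISSINGNESS_REMOVED + list(YOUNG_MANUAL_EXCLUSIONS)
    rng = np.random.default_rng(seed)
    rows = []
    for model, mutant_shift in (("Scn1a", 1.2), ("Gria1", 0.3)):
        for group in ("wildtype", "mutant"):
            for i in range(n_per_group):
                rows.append({"animal_id": f"{model}_{group}_{age_bracket}_{i + 1:02d}",
                             "model": model, "group": group,
                             "age_bracket": age_bracket, "sex": "female"})
    df = pd.DataFrame(rows)
    n = len(df)
    informative = {"irwin_score": 1.0, "fcm": 1.0, "temperature": -0.8,
                   "nest_building": -0.6}
    derived = [("of_wall_time", "of_center_time", -1.0, 0.3),
               ("of_immobility", "of_distance", -1.0, 0.25)]
    base = {d[1] for d in derived}
    vals = {}
    for p in raw_params:
        if p in {d[0] for d in derived}:
            continue
        x = rng.standard_normal(n)
        shift = informative.get(p, 0.0)
        is_scn1a_mut = (df["model"] == "Scn1a") & (df["group"] == "mutant")
        is_gria1_mut = (df["model"] == "Gria1") & (df["group"] == "mutant")
        x += np.where(is_scn1a_mut, 1.2 * shift, 0.0)
        x += np.where(is_gria1_mut, 0.3 * shift, 0.0)
        vals[p] = x
    for d, s, slope, noise in derived:
        vals[d] = slope * vals[s] + noise * rng.standard_normal(n)
    for p, x in vals.items():
        df[p] = x
    # wheel running not assessed in the Scn1a model (injury risk) -> 50% missing
    df.loc[df["model"] == "Scn1a", "voluntary_wheel_running"] = np.nan
    return table_from_dataframe(df, source=f"<synthetic young {age_bracket}>")
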