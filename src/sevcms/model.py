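"""Model/Results surface for the full composite severity workflow.

``CompositeSeverityModel`` holds a validated dataset plus a study config;
``fit()`` executes the whole pipeline — parameter preselection, Spearman
redundancy pruning, optional per-model ROC screening, resampled Box-Cox/PCA
parameter ranking, composite scoring, and k-means severity clustering — and
returns a ``SeverityResults`` object carrying every stage's output, a
``summary()`` table, and writers for the full report bundle.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, correlate, discriminate, preselect, ranking
from .datasets import DatasetError, ParameterTable, StudyConfig, load_table

__all__ = ["CompositeSeverityModel", "SeverityResults", "run_workflow"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from the global seed."""
    return (int(base_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


class CompositeSeverityModel:
    """Composite-measure-scheme severity assessment for one combined dataset.

    Parameters
    ----------
    table:
        Validated animals x parameters table.
    config:
        Study configuration (cutoffs, resample counts, burden map, k, seed).
    """

    def __init__(self, table: ParameterTable, config: StudyConfig | None = None):
        self.table = table
        self.config = config or StudyConfig()

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: StudyConfig | None = None
                       ) -> "CompositeSeverityModel":
        from .datasets import table_from_dataframe
        return cls(table_from_dataframe(df, config), config)

    @classmethod
    def from_csv(cls, path, config: StudyConfig | None = None
                 ) -> "CompositeSeverityModel":
        return cls(load_table(path, config), config)

    # -- fitting -----------------------------------------------------------
    def validate(self) -> dict:
        """Schema/dry-run check: returns a summary without computing anything."""
        cfg = self.config
        groups = sorted(set(self.table.meta["group"]))
        unmapped = [g for g in groups if cfg.group_burden_map and g not in cfg.group_burden_map]
        return {
            "n_animals": self.table.n_animals,
            "n_parameters": len(self.table.parameters),
            "groups": groups,
            "models": sorted(set(self.table.meta["model"])),
            "unmapped_groups": unmapped,
        }

    def fit(self, seed: int | None = None, compute_roc: bool | None = None
            ) -> "SeverityResults":
        """Run the full workflow and return a :class:`SeverityResults`.

        ``seed`` overrides the config seed; every random stage derives its
        own seed from it, so identical seed + input give identical results.
        ROC screening runs when the burden map contains both classes (or
        explicitly via ``compute_roc``).
        """
        cfg = self.config
        base_seed = cfg.seed if seed is None else seed
        timings: dict[str, float] = {}

        def timed(name):
            timings[name] = time.perf_counter()
            return name

        def done(name):
            timings[name] = time.perf_counter() - timings[name]

        # 1. preselection
        timed("preselect")
        table1, presel = preselect.apply_preselection(self.table, cfg)
        done("preselect")

        # 2. correlation + pruning
        timed("correlate")
        corr = correlate.spearman_matrix(table1)
        report = correlate.flag_pairs(corr, cfg)
        table2, report = correlate.prune_parameters(
            table1, report, keep_rules=cfg.keep_rules,
            manual_exclusions=cfg.post_correlation_exclusions,
        )
        done("correlate")

        # 3. per-model ROC screening
        timed("roc")
        burden_vals = set(cfg.group_burden_map.values())
        roc_possible = {0, 1} <= burden_vals
        roc_tables: dict[str, pd.DataFrame] = {}
        roc_curves: dict[str, list] = {}
        if compute_roc if compute_roc is not None else roc_possible:
            for model_name in sorted(set(table2.meta["model"])):
                sub = table2.filter(model=model_name)
                present = {cfg.group_burden_map.get(g) for g in set(sub.meta["group"])}
                if not ({0, 1} <= present):
                    continue
                frame, curves = discriminate.roc_table(sub, cfg)
                roc_tables[model_name] = frame
                roc_curves[model_name] = curves
        done("roc")

        # 4. reference PCA on the full pruned table
        timed("pca")
        reference = ranking.fit_reference_pca(table2, cfg)
        done("pca")

        # 5. resampled parameter ranking
        timed("ranking")
        rank_result = ranking.resampled_parameter_ranking(
            table2, cfg, seed=stage_seed(base_seed, "ranking"))
        done("ranking")

        # 6. composite scores
        timed("composite")
        composite = ranking.compute_composite_scores(table2, reference, cfg)
        done("composite")

        # 7. clusters
        timed("cluster")
        explained = reference.explained_fraction
        k_suggested = clustering.suggest_k(explained) if len(explained) >= 3 else None
        k = cfg.k if cfg.k is not None else k_suggested
        if k is None:
            raise DatasetError("set config.k or provide >= 3 components for the elbow")
        cluster_model = clustering.fit_cluster_thresholds(
            composite.scores.to_numpy(), k,
            n_resamples=cfg.cluster_resamples, ci_level=cfg.ci_level,
            seed=stage_seed(base_seed, "cluster"),
        )
        assignments, unassigned = clustering.assign_severity(composite.scores, cluster_model)
        allocation = clustering.allocation_table(assignments, table2.meta, k)
        allocation.unassigned = unassigned
        allocation_pooled = clustering.allocation_table_pooled(
            composite.scores, cluster_model, table2.meta)
        done("cluster")

        return SeverityResults(
            model=self, seed=base_seed, table_preselected=table1,
            table_pruned=table2, preselection=presel, correlation=corr,
            redundancy=report, roc_tables=roc_tables, roc_curves=roc_curves,
            reference_pca=reference, ranking=rank_result, composite=composite,
            k_suggested=k_suggested, cluster_model=cluster_model,
            assignments=assignments, allocation=allocation,
            allocation_pooled=allocation_pooled, timings=timings,
        )


@dataclass
class SeverityResults:
    """Everything the fitted severity workflow produced."""

    model: CompositeSeverityModel
    seed: int
    table_preselected: ParameterTable
    table_pruned: ParameterTable
    preselection: preselect.PreselectionResult
    correlation: correlate.CorrelationResult
    redundancy: correlate.RedundancyReport
    roc_tables: dict
    roc_curves: dict
    reference_pca: ranking.PcaRun
    ranking: ranking.RankingResult
    composite: ranking.CompositeScores
    k_suggested: int | None
    cluster_model: clustering.ClusterModel
    assignments: pd.Series
    allocation: clustering.AllocationResult
    allocation_pooled: clustering.AllocationResult
    timings: dict = field(default_factory=dict)

    # -- headline quantities ----------------------------------------------
    @property
    def n_selected_components(self) -> int:
        return len(self.reference_pca.selected)

    def explained_percent(self, pc: int = 1) -> float:
        """Explained-variance percentage of the given component (1-based)."""
        return 100.0 * float(self.reference_pca.explained_fraction[pc - 1])

    def summary(self) -> str:
        """Human-readable multi-section summary of the fitted workflow."""
        ref = self.reference_pca
        lines = []
        add = lines.append
        add("Composite severity workflow")
        add("=" * 64)
        add(f"animals: {self.table_pruned.n_animals}    seed: {self.seed}")
        add(f"parameters: {len(self.model.table.parameters)} input -> "
            f"{len(self.table_preselected.parameters)} after preselection -> "
            f"{len(self.table_pruned.parameters)} after redundancy pruning")
        add("")
        add("Retained principal components (SD > "
            f"{self.model.config.sd_threshold:g}):")
        for j in ref.selected:
            add(f"  {ref.pc_names[j]}: SD {ref.component_sds[j]:.3f}, "
                f"{100 * ref.explained_fraction[j]:.1f}% of variance")
        add("")
        add("Top-ranked parameters (mean rank over resampled PCAs):")
        top = self.ranking.summary(top=5)
        for row in top.itertuples():
            add(f"  {row.position}. {row.parameter}  (mean rank {row.mean_rank:.2f})")
        add("")
        k = self.cluster_model.k
        add(f"Severity clusters: k = {k}"
            + (f" (elbow suggestion: {self.k_suggested})" if self.k_suggested else ""))
        for i, t in enumerate(self.cluster_model.thresholds):
            lo, hi = self.cluster_model.threshold_ci[i]
            add(f"  threshold {i + 1}|{i + 2}: {t:.3f}  "
                f"[{lo:.3f}, {hi:.3f}] {100 * self.cluster_model.ci_level:.0f}% CI")
        add("")
        add("Cluster allocation (% of group, cluster "
            f"{k} = highest severity):")
        gt = self.allocation.group_table
        for row in gt.itertuples(index=False):
            pcts = "  ".join(f"{getattr(row, f'cluster_{c}'):5.1f}" for c in range(1, k + 1))
            add(f"  {row.model}/{row.group} (n={row.n}): {pcts}")
        if self.roc_tables:
            add("")
            add("ROC screening (AUC, oriented):")
            for mname, frame in self.roc_tables.items():
                best = frame.sort_values("auc_oriented", ascending=False).head(3)
                tops = ", ".join(f"{r.parameter}={r.auc_oriented:.3f}"
                                 for r in best.itertuples())
                add(f"  {mname}: {tops}")
        return "\n".join(lines)

    # -- report bundle ------------------------------------------------------
    def to_summary_dict(self) -> dict:
        ref = self.reference_pca
        return {
            "seed": self.seed,
            "n_animals": self.table_pruned.n_animals,
            "n_parameters_input": len(self.model.table.parameters),
            "n_parameters_preselected": len(self.table_preselected.parameters),
            "n_parameters_pruned": len(self.table_pruned.parameters),
            "removed_preselection": self.preselection.removed,
            "dropped_redundant": self.redundancy.dropped,
            "component_sds": [round(float(s), 10) for s in ref.component_sds],
            "explained_fraction": [round(float(e), 10) for e in ref.explained_fraction],
            "selected_components": [ref.pc_names[j] for j in ref.selected],
            "k": self.cluster_model.k,
            "k_suggested": self.k_suggested,
            "thresholds": [round(float(t), 10) for t in self.cluster_model.thresholds],
            "threshold_ci": [[round(float(v), 10) for v in row]
                             for row in self.cluster_model.threshold_ci],
            "ci_level": self.cluster_model.ci_level,
            "composite_variant": self.composite.variant,
            "pc_signs": self.composite.pc_signs,
            "severity_disclaimer": self.cluster_model.disclaimer,
            "config": self.model.config.to_dict(),
        }

    def write_report(self, out_dir, plots: bool = True) -> list[str]:
        """Write the CSV/JSON report bundle (and plots) to ``out_dir``.

        Timings go to a separate file so the numeric report is reproducible
        byte-for-byte under a fixed seed.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []

        def save_csv(df: pd.DataFrame, name: str, index=False):
            path = out / name
            df.to_csv(path, index=index, float_format="%.10g")
            written.append(str(path))

        save_csv(self.correlation.r, "correlation_r.csv", index=True)
        save_csv(self.correlation.p, "correlation_p.csv", index=True)
        save_csv(self.preselection.to_frame(), "preselection.csv")
        save_csv(self.ranking.summary(top=30), "ranking_top30.csv")
        sds = pd.DataFrame({
            "component": self.reference_pca.pc_names,
            "sd": self.reference_pca.component_sds,
            "explained_fraction": self.reference_pca.explained_fraction,
        })
        save_csv(sds, "component_sds.csv")
        comp = pd.DataFrame({
            "animal_id": self.composite.scores.index,
            "composite_score": self.composite.scores.to_numpy(),
            "cluster": self.assignments.to_numpy(),
        })
        save_csv(comp, "composite_scores.csv")
        thr = pd.DataFrame({
            "boundary": [f"{i + 1}|{i + 2}" for i in range(len(self.cluster_model.thresholds))],
            "threshold": self.cluster_model.thresholds,
            "ci_lower": self.cluster_model.threshold_ci[:, 0]
            if len(self.cluster_model.thresholds) else [],
            "ci_upper": self.cluster_model.threshold_ci[:, 1]
            if len(self.cluster_model.thresholds) else [],
        })
        save_csv(thr, "cluster_thresholds.csv")
        save_csv(self.allocation.group_table, "allocation.csv")
        save_csv(self.allocation_pooled.group_table, "allocation_pooled.csv")
        for mname, frame in self.roc_tables.items():
            save_csv(frame, f"auc_{mname}.csv")

        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(self.to_summary_dict(), indent=2,
                                           sort_keys=True) + "\n")
        written.append(str(summary_path))
        (out / "timings.json").write_text(json.dumps(self.timings, indent=2) + "\n")

        if plots:
            from . import plotting
            written += plotting.write_all(self, out)
        return written


def run_workflow(tables, config: StudyConfig, seed: int | None = None
                 ) -> SeverityResults:
    """Combine one or more tables and fit the full workflow."""
    from .datasets import combine_tables
    tables = list(tables) if not isinstance(tables, ParameterTable) else [tables]
    if not tables:
        raise DatasetError("run_workflow needs at least one table")
    table = tables[0] if len(tables) == 1 else combine_tables(tables)
    return CompositeSeverityModel(table, config).fit(seed=seed)
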