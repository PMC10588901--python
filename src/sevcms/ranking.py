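"""Resampled PCA parameter ranking and the per-animal composite severity score.

The core procedure: each parameter is shifted to strictly positive support,
Box-Cox transformed (lambda chosen by profile likelihood on a grid), and
standardized to mean 0 / SD 1; a PCA is run on the normalized matrix and the
components with SD > 1 are retained. This is repeated over many random
training subsets (by default 100 draws of 80% of the animals, stratified by
group), and within every retained component of every run the parameters are
ranked by the magnitude of their loadings. Aggregating those ranks
identifies the parameters that consistently carry the most variance.
A composite severity score per animal is then built from the ranked sums of
the retained components of a reference PCA.

The conventional literature description of the transform order (standardize,
then Box-Cox) is not
well-defined because Box-Cox requires positive input; the order implemented
here (shift -> Box-Cox -> standardize) preserves the intent of symmetrizing
each parameter before putting all parameters on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DatasetError, ParameterTable, StudyConfig

#: Box-Cox lambda grid: [-2, 2] in steps of 0.01.
BOXCOX_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)

#: Floor applied after the positivity shift when new data fall below the
#: training minimum (Box-Cox needs strictly positive input).
_POSITIVE_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# Normalization: shift -> Box-Cox -> standardize
# ---------------------------------------------------------------------------

def boxcox_loglik_grid(x: np.ndarray, grid: np.ndarray = BOXCOX_GRID) -> np.ndarray:
    """Profile log-likelihood of the Box-Cox parameter over a lambda grid.

    llf(lambda) = -(n/2) log(sigma^2_mle(y_lambda)) + (lambda - 1) sum(log x),
    vectorized over the whole grid.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive input")
    n = len(x)
    logx = np.log(x)
    lam = grid[:, None]  # (g, 1)
    with np.errstate(over="ignore"):
        y = np.where(lam == 0, logx[None, :], (np.exp(lam * logx[None, :]) - 1.0) / np.where(lam == 0, 1.0, lam))
    var = y.var(axis=1)  # MLE variance (ddof=0)
    var = np.maximum(var, 1e-300)
    return -(n / 2.0) * np.log(var) + (grid - 1.0) * logx.sum()


def boxcox_transform(x: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


@dataclass
class NormalizationModel:
    """Per-parameter shift, Box-Cox lambda, and standardization constants."""

    shift: pd.Series
    lam: pd.Series
    mean: pd.Series
    sd: pd.Series
    n_fit_rows: int

    @property
    def parameters(self) -> list[str]:
        return list(self.shift.index)

    def apply(self, values: pd.DataFrame) -> pd.DataFrame:
        """Transform a values frame; missing cells stay missing."""
        out = {}
        for p in self.parameters:
            x = values[p].to_numpy(dtype=float)
            y = np.full_like(x, np.nan)
            ok = ~np.isnan(x)
            shifted = np.maximum(x[ok] + self.shift[p], _POSITIVE_FLOOR)
            t = boxcox_transform(shifted, float(self.lam[p]))
            y[ok] = (t - self.mean[p]) / self.sd[p]
            out[p] = y
        return pd.DataFrame(out, index=values.index)


def fit_normalizer(table: ParameterTable | pd.DataFrame) -> NormalizationModel:
    """Fit shift, Box-Cox lambda and standardization constants per parameter.

    Missing cells are ignored during fitting. Every parameter must be
    non-constant on the fit rows. The shift is 1 - min, mapping the observed
    minimum to exactly 1; lambda maximizes the profile log-likelihood over
    the grid [-2, 2] step 0.01.
    """
    values = table.values if isinstance(table, ParameterTable) else table
    shift, lam, mean, sd = {}, {}, {}, {}
    for p in values.columns:
        x = values[p].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        if len(x) < 2 or np.all(x == x[0]):
            raise DatasetError(f"parameter {p!r} is constant (or empty) on the fit rows")
        s = 1.0 - x.min()
        xs = x + s
        llf = boxcox_loglik_grid(xs)
        best = float(BOXCOX_GRID[int(np.argmax(llf))])
        t = boxcox_transform(xs, best)
        mu = float(t.mean())
        sigma = float(t.std(ddof=1))
        if sigma == 0:
            raise DatasetError(f"parameter {p!r} has zero variance after transform")
        shift[p], lam[p], mean[p], sd[p] = s, best, mu, sigma
    idx = list(values.columns)
    return NormalizationModel(
        shift=pd.Series(shift, index=idx), lam=pd.Series(lam, index=idx),
        mean=pd.Series(mean, index=idx), sd=pd.Series(sd, index=idx),
        n_fit_rows=len(values),
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaRun:
    """One PCA decomposition: SDs, loadings, scores, retained components."""

    component_sds: np.ndarray  # non-increasing
    loadings: pd.DataFrame  # parameters x PCs, orthonormal columns
    scores: pd.DataFrame  # animals x PCs
    explained_fraction: np.ndarray
    selected: list[int]  # 0-based indices of retained components
    center: pd.Series  # column means removed before projection
    normalizer: NormalizationModel | None = None
    impute_medians: pd.Series | None = None

    @property
    def pc_names(self) -> list[str]:
        return list(self.loadings.columns)

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        """Project new raw values through normalizer, imputation and loadings."""
        if self.normalizer is None:
            raise DatasetError("PcaRun has no attached normalizer")
        norm = self.normalizer.apply(values)
        if self.impute_medians is not None:
            norm = norm.fillna(self.impute_medians)
        X = norm[self.loadings.index].to_numpy() - self.center.to_numpy()
        return pd.DataFrame(X @ self.loadings.to_numpy(),
                            index=values.index, columns=self.pc_names)


def run_pca(normalized: pd.DataFrame) -> PcaRun:
    """Eigen-decomposition of the covariance of a complete normalized matrix.

    Components are ordered by SD descending with a deterministic sign
    convention: the largest-magnitude entry of each loading vector is made
    positive.
    """
    if normalized.isna().any().any():
        raise DatasetError("run_pca requires a complete matrix; impute missing cells first")
    n, p = normalized.shape
    if n < 3:
        raise DatasetError(f"PCA requires at least 3 rows, got {n}")
    X = normalized.to_numpy(dtype=float)
    center = X.mean(axis=0)
    Xc = X - center
    cov = Xc.T @ Xc / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    # sign convention for backend-independent determinism
    for j in range(p):
        i_max = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i_max, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    sds = np.sqrt(eigval)
    pc_names = [f"PC{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(eigvec, index=normalized.columns, columns=pc_names)
    scores = pd.DataFrame(Xc @ eigvec, index=normalized.index, columns=pc_names)
    total = eigval.sum()
    explained = eigval / total if total > 0 else np.zeros_like(eigval)
    return PcaRun(component_sds=sds, loadings=loadings, scores=scores,
                  explained_fraction=explained, selected=[],
                  center=pd.Series(center, index=normalized.columns))


def select_components(run: PcaRun, sd_threshold: float = 1.0) -> list[int]:
    """Indices (0-based) of components with SD strictly above the threshold."""
    if sd_threshold <= 0:
        raise DatasetError("sd_threshold must be positive")
    selected = [j for j, s in enumerate(run.component_sds) if s > sd_threshold]
    if not selected:
        raise DatasetError(
            f"no component has SD > {sd_threshold}; review the threshold or the data"
        )
    return selected


def fit_reference_pca(table: ParameterTable, config: StudyConfig,
                      rows: np.ndarray | None = None) -> PcaRun:
    """Fit normalizer + PCA on the given rows (default: all) and select components.

    Residual missing cells are imputed with the fit-rows' per-parameter
    median of the normalized values before the decomposition.
    """
    values = table.values if rows is None else table.values.iloc[rows]
    normalizer = fit_normalizer(values)
    norm = normalizer.apply(values)
    medians = norm.median(axis=0)
    norm = norm.fillna(medians)
    run = run_pca(norm)
    run.selected = select_components(run, config.sd_threshold)
    run.normalizer = normalizer
    run.impute_medians = medians
    return run


# ---------------------------------------------------------------------------
# Resampled ranking
# ---------------------------------------------------------------------------

@dataclass
class RankingResult:
    """Aggregated parameter ranks over resampled training PCAs.

    ``records`` keeps the full rank permutation of every (resample,
    retained-PC) unit for inspection. The headline parameter ranking
    (``mean_rank``, ``summary``, ``top_n_counts``) aggregates, by default,
    the per-run *burden-aligned* ranks (``combined``): within each run the
    burden indicator is regressed on the retained component scores, the
    coefficient vector is mapped back to parameter space through the
    loadings, and parameters are ranked by the magnitude of that combined
    direction. This keeps a distress signal visible even when sampling
    noise splits it across components or demotes it below a noise axis.
    When no burden labels are configured the headline falls back to
    ``scope="leading"`` (ranks on the leading retained component);
    ``scope="all_selected"`` gives the flat average over every retained
    component.
    """

    records: pd.DataFrame  # columns: run, pc, parameter, rank
    n_resamples: int
    train_fraction: float
    stratified: bool
    seed: int
    n_selected_per_run: list[int]
    combined: pd.DataFrame | None = None  # columns: run, parameter, rank

    def _scoped(self, scope: str | None) -> pd.DataFrame:
        if scope is None:
            scope = "combined" if self.combined is not None else "leading"
        if scope == "combined":
            if self.combined is None:
                raise DatasetError(
                    "combined ranks unavailable: no burden labels were "
                    "configured; use scope='leading' or 'all_selected'"
                )
            return self.combined
        if scope == "leading":
            return self.records[self.records["pc"] == "PC1"]
        if scope == "all_selected":
            return self.records
        raise DatasetError(f"unknown ranking scope {scope!r}")

    def mean_rank(self, scope: str | None = None) -> pd.Series:
        return (self._scoped(scope).groupby("parameter")["rank"].mean()
                .sort_values(kind="stable"))

    def rank_histogram(self, parameter: str, scope: str | None = None) -> pd.Series:
        sub = self._scoped(scope)
        return (sub[sub["parameter"] == parameter]["rank"]
                .value_counts().sort_index())

    def top_n_counts(self, n: int = 1, scope: str | None = None) -> pd.Series:
        """Per parameter: number of runs whose best scoped rank is <= n."""
        sub = self._scoped(scope)
        best = sub.groupby(["run", "parameter"])["rank"].min().reset_index()
        hit = best[best["rank"] <= n]
        counts = hit.groupby("parameter")["run"].nunique()
        params = sorted(self.records["parameter"].unique())
        return counts.reindex(params, fill_value=0)

    def summary(self, top: int | None = 30, scope: str | None = None) -> pd.DataFrame:
        """Ranking table sorted by mean rank (default: top 30 rows)."""
        mr = self.mean_rank(scope)
        out = pd.DataFrame({
            "parameter": mr.index,
            "mean_rank": mr.to_numpy(),
            "top1_runs": self.top_n_counts(1, scope).reindex(mr.index).to_numpy(),
            "top5_runs": self.top_n_counts(5, scope).reindex(mr.index).to_numpy(),
        }).reset_index(drop=True)
        out.insert(0, "position", np.arange(1, len(out) + 1))
        return out.head(top) if top else out


def _stratified_subsample(meta: pd.DataFrame, fraction: float, rng: np.random.Generator,
                          stratify: bool) -> np.ndarray:
    n = len(meta)
    if not stratify:
        size = int(round(fraction * n))
        if size < 3:
            raise DatasetError("training subset smaller than 3 rows")
        return np.sort(rng.choice(n, size=size, replace=False))
    rows = []
    for _, idx in meta.groupby("group", sort=True).indices.items():
        size = int(round(fraction * len(idx)))
        if size < 2:
            raise DatasetError(
                f"group stratum with {len(idx)} rows yields a training stratum of "
                f"{size} < 2; disable stratification or enlarge the group"
            )
        rows.append(rng.choice(idx, size=size, replace=False))
    return np.sort(np.concatenate(rows))


def resampled_parameter_ranking(
    table: ParameterTable, config: StudyConfig,
    seed: int | None = None,
) -> RankingResult:
    """Rank parameters by loading magnitude over resampled training PCAs.

    For each of ``config.n_resamples`` runs a random ``train_fraction`` of
    the rows is drawn without replacement (stratified by group unless
    disabled), the normalizer and PCA are fitted on that subset, components
    with SD above the threshold are retained (per run, unless
    ``freeze_components`` pins the count from a full-data fit), and within
    each retained component parameters are ranked by |loading| descending
    (rank 1 = largest).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    params = table.parameters
    frozen_m = None
    if config.freeze_components:
        full = fit_reference_pca(table, config)
        frozen_m = len(full.selected)

    # burden indicator (1 = burdened) for the combined, burden-aligned ranks;
    # NaN where a group is excluded or unmapped
    burden_all = np.array([
        float(config.group_burden_map[g])
        if config.group_burden_map.get(g) in (0, 1) else np.nan
        for g in table.meta["group"]
    ])
    have_burden = (np.nansum(burden_all == 1) > 0) and (np.nansum(burden_all == 0) > 0)

    def ordinal_ranks(magnitudes: np.ndarray) -> np.ndarray:
        order = np.argsort(-magnitudes, kind="stable")
        ranks = np.empty(len(magnitudes), dtype=int)
        ranks[order] = np.arange(1, len(magnitudes) + 1)
        return ranks

    rows_out = []
    combined_out = []
    n_selected_per_run = []
    for run_idx in range(config.n_resamples):
        rows = _stratified_subsample(table.meta, config.train_fraction, rng,
                                     config.stratify)
        run = fit_reference_pca(table.subset_rows(np.isin(np.arange(table.n_animals), rows)),
                                config)
        selected = list(range(frozen_m)) if frozen_m is not None else run.selected
        n_selected_per_run.append(len(selected))
        for j in selected:
            pc = run.pc_names[j]
            ranks = ordinal_ranks(run.loadings[pc].abs().to_numpy())
            for p_idx, p in enumerate(params):
                rows_out.append((run_idx, pc, p, int(ranks[p_idx])))
        if have_burden:
            b = burden_all[rows]
            ok = ~np.isnan(b)
            bc = b[ok] - b[ok].mean()
            direction = np.zeros(len(params))
            for j in selected:
                pc = run.pc_names[j]
                s = run.scores[pc].to_numpy()[ok]
                direction += (s @ bc) / (s @ s) * run.loadings[pc].to_numpy()
            ranks = ordinal_ranks(np.abs(direction))
            for p_idx, p in enumerate(params):
                combined_out.append((run_idx, p, int(ranks[p_idx])))
    records = pd.DataFrame(rows_out, columns=["run", "pc", "parameter", "rank"])
    combined = (pd.DataFrame(combined_out, columns=["run", "parameter", "rank"])
                if have_burden else None)
    return RankingResult(records=records, n_resamples=config.n_resamples,
                         train_fraction=config.train_fraction,
                         stratified=config.stratify, seed=seed,
                         n_selected_per_run=n_selected_per_run,
                         combined=combined)


# ---------------------------------------------------------------------------
# Composite score
# ---------------------------------------------------------------------------

@dataclass
class CompositeScores:
    """Per-animal composite severity score from the retained components."""

    scores: pd.Series  # indexed by animal_id
    variant: str  # "rank_sum" | "score_sum"
    pc_signs: dict[str, int]  # orientation applied per retained PC
    n_selected: int


def _midrank_ecdf(train: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Midrank plotting position of each query value within the training scores.

    (count less + 0.5 * count equal) / n, clipped into (0, 1].
    """
    train = np.sort(train)
    n = len(train)
    less = np.searchsorted(train, query, side="left")
    leq = np.searchsorted(train, query, side="right")
    frac = (less + 0.5 * (leq - less)) / n
    return np.clip(frac, 0.5 / n, 1.0)


def compute_composite_scores(
    table: ParameterTable,
    reference_run: PcaRun,
    config: StudyConfig,
    train_index: pd.Index | None = None,
    pc_signs: dict[str, int] | None = None,
) -> CompositeScores:
    """Combine retained PC scores into one severity score per animal.

    Each retained component is first oriented so that its training scores
    correlate non-negatively with the burden indicator (group mapped to 1 =
    burdened), or flipped per the explicit ``pc_signs``. Under the default
    ``rank_sum`` variant every animal's oriented PC score is mapped through
    the empirical (midrank) CDF of the training scores and the fractions are
    summed over the retained components, giving a score in (0, m] for m
    retained components. The ``score_sum`` variant instead sums the oriented
    scores weighted by explained-variance fraction.
    """
    pcs = [reference_run.pc_names[j] for j in reference_run.selected]
    all_scores = reference_run.transform(table.values.set_axis(table.animal_ids))
    all_scores.index = table.animal_ids
    train_scores = all_scores if train_index is None else all_scores.loc[train_index]

    if pc_signs is None:
        burden = pd.Series(
            [config.group_burden_map.get(g) for g in table.meta["group"]],
            index=table.animal_ids,
        )
        burden = burden[burden.isin([0, 1])].astype(float)
        if burden.nunique() < 2:
            raise DatasetError(
                "cannot orient components: configure group_burden_map with both "
                "classes or pass explicit pc_signs"
            )
        common = [a for a in train_scores.index if a in burden.index]
        pc_signs = {}
        for pc in pcs:
            s = train_scores.loc[common, pc].to_numpy()
            b = burden.loc[common].to_numpy()
            cov = np.cov(s, b)[0, 1]
            pc_signs[pc] = -1 if cov < 0 else 1

    variant = config.composite_variant
    total = pd.Series(0.0, index=all_scores.index)
    for j, pc in zip(reference_run.selected, pcs):
        sign = pc_signs[pc]
        oriented_all = sign * all_scores[pc].to_numpy()
        oriented_train = sign * train_scores[pc].to_numpy()
        if variant == "rank_sum":
            total += _midrank_ecdf(oriented_train, oriented_all)
        else:  # score_sum
            total += reference_run.explained_fraction[j] * oriented_all
    return CompositeScores(scores=total, variant=variant,
                           pc_signs=pc_signs, n_selected=len(pcs))
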