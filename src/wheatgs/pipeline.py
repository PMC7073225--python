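"""Replicated cross-validation and the QC-scenario x model x trait grid.

Prediction accuracy is the Pearson correlation between observed adjusted
phenotypes (BLUEs) and predicted GEBVs in the validation fold.  The default
protocol is five-fold cross-validation replicated 50 times: every replicate
re-partitions the lines with its own derived seed, each fold in turn is the
validation population and the rest the training population, all
hyperparameter selection (inner CV, REML) happens inside the training fold,
and the replicate accuracy is the mean of within-fold correlations.

Seed policy: the master seed spawns one child seed per (replicate) via
``numpy.random.SeedSequence``, and model-level stochastic seeds (forest
bootstraps) derive from the replicate seed, so a full grid rerun with the
same master seed is byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import QCScheme, apply_qc, compute_marker_stats, impute_empirical
from .matrix import GenotypeMatrix
from .models import build_design, make_model, vanraden_grm


@dataclass
class CVSpec:
    n_folds: int = 5
    n_replicates: int = 50
    seed: int = 0
    accuracy_pooling: str = "per-fold"  # "per-fold" | "pooled"

    def validate(self, n_lines: int) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.accuracy_pooling not in ("per-fold", "pooled"):
            raise ValueError("accuracy_pooling must be per-fold or pooled")
        if n_lines < self.n_folds:
            raise ValueError("fewer lines than folds")
        if n_lines // self.n_folds < 3:
            raise ValueError(
                "folds would hold < 3 lines; reduce n_folds or add lines"
            )


@dataclass
class CVResult:
    scenario: str
    model_id: str
    trait: str
    replicate_accuracies: np.ndarray
    n_flagged_undefined: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.replicate_accuracies))

    @property
    def se_accuracy(self) -> float:
        a = self.replicate_accuracies
        if len(a) < 2:
            return float("nan")
        return float(np.std(a, ddof=1) / np.sqrt(len(a)))


@dataclass
class ComparisonTest:
    trait: str
    model_id: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float


def _fold_partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into k folds with sizes differing by <= 1."""
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0, True  # undefined correlation flagged, counted as 0
    return float(np.corrcoef(a, b)[0, 1]), False


def _fit_predict(model_id, X_train, y_train, X_test, grm_parts, seed,
                 model_params):
    params = dict(model_params or {})
    if model_id == "RForest":
        params.setdefault("random_state", seed)
        model = make_model(model_id, **params)
        model.fit(X_train, y_train)
        return model.predict(X_test)
    if model_id == "GBLUP":
        K_tt, K_vt = grm_parts
        model = make_model(model_id, **params)
        model.fit(K_tt, y_train)
        return model.predict(K_vt)
    model = make_model(model_id, **params)
    model.fit(X_train, y_train)
    return model.predict(X_test)


def cross_validate(
    genotypes: GenotypeMatrix,
    blues: pd.Series,
    model_id: str,
    spec: CVSpec,
    scenario: str = "default",
    model_params: dict | None = None,
) -> CVResult:
    """Replicated k-fold cross-validated prediction accuracy for one model.

    ``blues`` is indexed by line ID.  The design (and for GBLUP the GRM) is
    built once from the genotypes; per replicate a seeded partition assigns
    each line to exactly one validation fold.  Undefined within-fold
    correlations (constant predictions) are recorded as 0 and flagged so
    replicate vectors stay equal length.
    """
    y = blues.reindex(genotypes.line_ids)
    if y.isna().any():
        raise ValueError("phenotype missing for some genotyped lines")
    y = y.to_numpy(dtype=float)
    n = len(y)
    spec.validate(n)
    if genotypes.n_markers < 1:
        raise ValueError("empty marker set; QC removed everything?")
    design = build_design(genotypes, coding="centered")
    G = vanraden_grm(design).G if model_id == "GBLUP" else None

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    accuracies = np.empty(spec.n_replicates)
    n_flagged = 0
    trait = blues.name if blues.name else "trait"
    for rep, seq in enumerate(seeds):
        rng = np.random.default_rng(seq)
        model_seed = int(rng.integers(0, 2**31 - 1))
        folds = _fold_partition(n, spec.n_folds, rng)
        fold_corrs = []
        pooled_pred = np.empty(n)
        for fold in folds:
            test = np.zeros(n, dtype=bool)
            test[fold] = True
            grm_parts = None
            if model_id == "GBLUP":
                grm_parts = (G[np.ix_(~test, ~test)], G[np.ix_(test, ~test)])
            pred = _fit_predict(
                model_id, design.X[~test], y[~test], design.X[test],
                grm_parts, model_seed, model_params,
            )
            if spec.accuracy_pooling == "per-fold":
                c, flagged = _safe_corr(y[test], pred)
                fold_corrs.append(c)
                n_flagged += int(flagged)
            else:
                pooled_pred[test] = pred
        if spec.accuracy_pooling == "per-fold":
            accuracies[rep] = float(np.mean(fold_corrs))
        else:
            c, flagged = _safe_corr(y, pooled_pred)
            accuracies[rep] = c
            n_flagged += int(flagged)
    return CVResult(
        scenario=scenario,
        model_id=model_id,
        trait=str(trait),
        replicate_accuracies=accuracies,
        n_flagged_undefined=n_flagged,
    )


def cross_validate_with_selection(
    genotypes: GenotypeMatrix,
    blues: pd.Series,
    model_id: str,
    spec: CVSpec,
    threshold: float = 1.0,
    n_pcs: int = 5,
    model_params: dict | None = None,
) -> CVResult:
    """Leakage-free GWAS-derived CV: scan and select markers inside each
    training fold, then predict the held-out fold on the selected set."""
    from .gwas import gwas_scan, select_markers

    y = blues.reindex(genotypes.line_ids)
    if y.isna().any():
        raise ValueError("phenotype missing for some genotyped lines")
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    spec.validate(n)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    accuracies = np.empty(spec.n_replicates)
    n_flagged = 0
    for rep, seq in enumerate(seeds):
        rng = np.random.default_rng(seq)
        model_seed = int(rng.integers(0, 2**31 - 1))
        folds = _fold_partition(n, spec.n_folds, rng)
        fold_corrs = []
        for fold in folds:
            test = np.zeros(n, dtype=bool)
            test[fold] = True
            train_panel = genotypes.subset_lines(~test)
            scan = gwas_scan(train_panel, y[~test].rename(blues.name),
                             n_pcs=n_pcs)
            sel = select_markers(scan, threshold=threshold)
            if len(sel.marker_ids) < 2:
                fold_corrs.append(0.0)
                n_flagged += 1
                continue
            reduced = genotypes.subset_markers(np.array(sel.marker_ids))
            design = build_design(reduced, coding="centered")
            grm_parts = None
            if model_id == "GBLUP":
                G = vanraden_grm(design).G
                grm_parts = (G[np.ix_(~test, ~test)], G[np.ix_(test, ~test)])
            pred = _fit_predict(
                model_id, design.X[~test], yv[~test], design.X[test],
                grm_parts, model_seed, model_params,
            )
            c, flagged = _safe_corr(yv[test], pred)
            fold_corrs.append(c)
            n_flagged += int(flagged)
        accuracies[rep] = float(np.mean(fold_corrs))
    return CVResult(
        scenario="gwas-per-fold",
        model_id=model_id,
        trait=str(blues.name or "trait"),
        replicate_accuracies=accuracies,
        n_flagged_undefined=n_flagged,
    )


@dataclass
class GridResult:
    results: list[CVResult]
    marker_counts: pd.DataFrame  # rows: missing level, cols: MAF level


def run_scenario_grid(
    genotypes: GenotypeMatrix,
    blues: pd.DataFrame,
    schemes,
    model_ids,
    spec: CVSpec,
    impute: bool = False,
    include_non_qc: bool = False,
    impute_seed: int = 0,
) -> GridResult:
    """Cross-validate every QC scheme x model x trait combination.

    Produces the marker-count table over the scheme grid and a CVResult per
    combination.  ``impute`` runs empirical imputation after QC (the
    imputed-vs-raw contrast); ``include_non_qc`` adds the all-polymorphic-
    markers reference scenario.  Schemes that empty the panel are skipped
    with a warning.
    """
    stats = compute_marker_stats(genotypes)
    counts = {}
    results: list[CVResult] = []
    work_items: list[tuple[str, GenotypeMatrix]] = []
    for scheme in schemes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sub = apply_qc(genotypes, stats, scheme)
        counts[(scheme.missing_level, scheme.maf_level)] = sub.n_markers
        if sub.n_markers == 0:
            warnings.warn(
                f"scheme {scheme.label()} retains no markers; skipped",
                UserWarning,
            )
            continue
        work_items.append((scheme.label(), sub))
    if include_non_qc:
        poly = stats["maf"].to_numpy() > 0
        work_items.append(("non-QC", genotypes.subset_markers(poly)))
    for label, sub in work_items:
        if impute:
            sub = impute_empirical(sub, seed=impute_seed)
            label = f"{label}+imputed"
        for trait in blues.columns:
            for model_id in model_ids:
                results.append(
                    cross_validate(
                        sub, blues[trait], model_id, spec, scenario=label
                    )
                )
    miss_levels = sorted({k[0] for k in counts})
    maf_levels = sorted({k[1] for k in counts})
    count_table = pd.DataFrame(
        [
            [counts.get((mr, mf), np.nan) for mf in maf_levels]
            for mr in miss_levels
        ],
        index=pd.Index(miss_levels, name="missing_level"),
        columns=pd.Index(maf_levels, name="maf_level"),
    )
    return GridResult(results=results, marker_counts=count_table)


def compare_qc(result_a: CVResult, result_b: CVResult) -> ComparisonTest:
    """Welch two-sample t-test on replicate accuracy vectors (A vs B)."""
    if result_a.trait != result_b.trait or result_a.model_id != result_b.model_id:
        raise ValueError("comparison requires matching trait and model")
    a, b = result_a.replicate_accuracies, result_b.replicate_accuracies
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per arm")
    if np.var(a) == 0 and np.var(b) == 0:
        t, p = (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonTest(
        trait=result_a.trait,
        model_id=result_a.model_id,
        mean_a=result_a.mean_accuracy,
        mean_b=result_b.mean_accuracy,
        t_statistic=float(t),
        p_value=float(p),
    )


def summarize(results: list[CVResult], directory=None) -> dict[str, pd.DataFrame]:
    """Accuracy summary tables per scenario.

    For each scenario: a trait x model table of mean accuracy with SE, row
    and column means, top-3 model flags per trait (ties on the rounded 3rd
    decimal all flagged), and a tally of how often each model reaches the
    top 3 across traits.  Deterministic given its inputs; optionally written
    as delimited text under ``directory``.
    """
    if not results:
        raise ValueError("no results to summarize")
    frames: dict[str, pd.DataFrame] = {}
    rows = [
        {
            "scenario": r.scenario,
            "trait": r.trait,
            "model": r.model_id,
            "mean_accuracy": r.mean_accuracy,
            "se": r.se_accuracy,
            "n_replicates": len(r.replicate_accuracies),
        }
        for r in results
    ]
    long = pd.DataFrame(rows)
    frames["long"] = long
    for scenario, grp in long.groupby("scenario"):
        acc = grp.pivot_table(index="trait", columns="model",
                              values="mean_accuracy")
        acc.loc["model_mean"] = acc.mean(axis=0)
        acc["trait_mean"] = acc.mean(axis=1)
        frames[f"accuracy_{scenario}"] = acc
        flags = []
        tally: dict[str, int] = {}
        for trait, sub in grp.groupby("trait"):
            vals = sub.set_index("model")["mean_accuracy"].round(3)
            if len(vals) == 0:
                continue
            cutoff = vals.sort_values(ascending=False).iloc[
                min(2, len(vals) - 1)
            ]
            top = vals[vals >= cutoff].index.tolist()
            for m in top:
                tally[m] = tally.get(m, 0) + 1
            flags.append({"trait": trait, "top3_models": ",".join(sorted(top))})
        frames[f"top3_{scenario}"] = pd.DataFrame(flags)
        frames[f"tally_{scenario}"] = pd.DataFrame(
            sorted(tally.items()), columns=["model", "times_in_top3"]
        )
    if directory is not None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            df.to_csv(directory / f"{name}.tsv", sep="\t")
    return frames
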