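"""Mixed-model association scan and GWAS-derived marker selection.

The scan fits the PCA + K mixed model once under the null —
``y = PC covariates + polygenic u + eps`` with ``u ~ N(0, K sigma_u^2)`` —
by spectral REML, then tests each marker by generalized least squares with
the null variance structure held fixed (the population-parameters-
previously-determined / EMMAX approximation).  Markers crossing a permissive
``-log10 P >= 1`` threshold feed a genomic-selection run on the reduced
marker set.

Note on the selection design: by default the scan uses the *whole* panel
(training and validation lines together) before cross-validation, matching
how GWAS-derived genomic selection is done on a single population.  That
leaks phenotype information into marker selection and inflates apparent
accuracy; every result carries the ``selection="full-panel"`` tag, and a
leakage-free alternative (re-scanning within each training fold) is
available via ``per_fold=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import GenotypeMatrix
from .models import GRM, build_design, reml_single_component, vanraden_grm


@dataclass
class GWASResult:
    table: pd.DataFrame  # marker, chrom, pos_mb, effect, se, p, neg_log10_p
    n_pcs: int
    kinship_method: str
    delta: float  # null-model variance ratio sigma_e^2 / sigma_u^2
    n_skipped_constant: int


@dataclass
class MarkerSelection:
    marker_ids: list[str]
    threshold: float
    scenario: str  # "imputed" | "non-imputed" | custom tag


def genotype_pcs(genotypes: GenotypeMatrix, n_pcs: int = 5) -> np.ndarray:
    """Leading principal components of the centered, mean-filled genotype
    matrix (line-space left singular vectors scaled by singular values)."""
    design = build_design(genotypes, coding="centered")
    U, s, _ = np.linalg.svd(design.X, full_matrices=False)
    k = min(n_pcs, (s > 1e-10).sum())
    return U[:, :k] * s[:k]


def gwas_scan(
    genotypes: GenotypeMatrix,
    blues: pd.Series,
    n_pcs: int = 5,
    kinship: GRM | None = None,
) -> GWASResult:
    """Single-marker mixed-model scan with PC covariates and kinship.

    ``blues`` must be indexed by line ID and cover every line in the panel.
    Missing marker calls are marker-mean filled for testing.  Constant
    markers are skipped (logged in the result).  P-values are two-sided from
    the Wald t statistic with n - p - 1 degrees of freedom.
    """
    y = blues.reindex(genotypes.line_ids)
    if y.isna().any():
        missing = y[y.isna()].index.tolist()[:5]
        raise ValueError(f"phenotype missing for lines {missing}")
    y = y.to_numpy(dtype=float)
    design = build_design(genotypes, coding="centered", drop_constant=False)
    if kinship is None:
        kinship = vanraden_grm(
            build_design(genotypes, coding="centered", drop_constant=True)
        )
    if list(kinship.line_ids) != list(genotypes.line_ids):
        try:
            K = kinship.block(genotypes.line_ids, genotypes.line_ids)
        except KeyError as exc:
            raise ValueError("kinship does not cover all lines") from exc
    else:
        K = kinship.G
    n = len(y)
    X0 = np.ones((n, 1))
    if n_pcs > 0:
        X0 = np.hstack([X0, genotype_pcs(genotypes, n_pcs)])
    p0 = X0.shape[1]

    null = reml_single_component(y, K, X=X0)
    delta = null["delta"]

    # rotate into the eigenbasis of K so the covariance is diagonal
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    d = np.maximum(d, 0.0)
    w = 1.0 / (d + delta)  # inverse variance weights (up to sigma_u^2)
    yt = U.T @ y
    X0t = U.T @ X0
    Mt = U.T @ design.X  # n x m rotated markers

    sw = np.sqrt(w)
    yw = yt * sw
    X0w = X0t * sw[:, None]
    Mw = Mt * sw[:, None]

    # residualize phenotype and markers on the null covariates
    Q, _ = np.linalg.qr(X0w)
    yr = yw - Q @ (Q.T @ yw)
    Mr = Mw - Q @ (Q.T @ Mw)

    mm = np.einsum("ij,ij->j", Mr, Mr)
    constant = mm <= 1e-12
    my = Mr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = my / mm
    dof = n - p0 - 1
    rss = np.maximum(yr @ yr - beta * my, 0.0)
    sigma2 = rss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / mm)
        tstat = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "marker": design.marker_ids,
            "chrom": genotypes.map["chrom"].to_numpy(),
            "pos_mb": genotypes.map["pos_mb"].to_numpy(),
            "effect": beta,
            "se": se,
            "p": pvals,
            "neg_log10_p": -np.log10(pvals),
        }
    )
    n_const = int(constant.sum())
    if n_const:
        table = table[~constant].reset_index(drop=True)
    return GWASResult(
        table=table,
        n_pcs=n_pcs,
        kinship_method=kinship.method,
        delta=float(delta),
        n_skipped_constant=n_const,
    )


def select_markers(
    result: GWASResult, threshold: float = 1.0, scenario: str = "non-imputed"
) -> MarkerSelection:
    """Markers at ``-log10 P >= threshold`` (permissive by design, so
    small-effect loci are not missed)."""
    sel = result.table[result.table["neg_log10_p"] >= threshold]
    ids = sel["marker"].tolist()
    if not ids:
        warnings.warn("GWAS selection is empty at this threshold", UserWarning)
    return MarkerSelection(marker_ids=ids, threshold=threshold,
                           scenario=scenario)


def gwas_derived_gs(
    genotypes: GenotypeMatrix,
    blues: pd.Series,
    model_ids,
    cv_spec=None,
    impute_first: bool = False,
    threshold: float = 1.0,
    n_pcs: int = 5,
    per_fold: bool = False,
    seed: int = 0,
    model_params: dict | None = None,
):
    """GWAS-derived genomic selection for one trait.

    Excludes position-unknown markers, optionally imputes (seeded), scans,
    selects at the threshold, then cross-validates each requested model on
    the selected marker set.  Default is the full-panel selection design
    (see module docstring for the leakage caveat); ``per_fold=True``
    re-scans and re-selects inside every training fold instead.

    Returns ``(results, selection)`` where ``results`` is a list of
    :class:`wheatgs.pipeline.CVResult` tagged with the scenario, and
    ``selection`` the full-panel :class:`MarkerSelection` (None when
    ``per_fold``).
    """
    from .genotypes import impute_empirical
    from .pipeline import CVSpec, cross_validate, cross_validate_with_selection

    if cv_spec is None:
        cv_spec = CVSpec(seed=seed)
    scenario = "imputed" if impute_first else "non-imputed"
    known = genotypes.map["position_known"].to_numpy()
    panel = genotypes.subset_markers(known) if not known.all() else genotypes
    if impute_first:
        panel = impute_empirical(panel, seed=seed)
    tag_mode = "per-fold" if per_fold else "full-panel"
    results = []
    if per_fold:
        for model_id in model_ids:
            res = cross_validate_with_selection(
                panel, blues, model_id, cv_spec, threshold=threshold,
                n_pcs=n_pcs, model_params=(model_params or {}).get(model_id),
            )
            res.scenario = f"gwas-{scenario}-{tag_mode}"
            results.append(res)
        return results, None
    scan = gwas_scan(panel, blues, n_pcs=n_pcs)
    selection = select_markers(scan, threshold=threshold, scenario=scenario)
    if len(selection.marker_ids) < 2:
        raise ValueError(
            "fewer than 2 markers selected; genomic selection refused"
        )
    reduced = panel.subset_markers(np.array(selection.marker_ids))
    for model_id in model_ids:
        res = cross_validate(
            reduced, blues, model_id, cv_spec,
            model_params=(model_params or {}).get(model_id),
        )
        res.scenario = f"gwas-{scenario}-{tag_mode}"
        results.append(res)
    return results, selection


def manhattan_plot(result: GWASResult, path, threshold: float = 1.0) -> None:
    """Write a Manhattan plot of the scan to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table.copy()
    chroms = list(dict.fromkeys(tab["chrom"]))
    offset, ticks = 0.0, []
    xs = np.empty(len(tab))
    for c in chroms:
        mask = (tab["chrom"] == c).to_numpy()
        pos = tab.loc[mask, "pos_mb"].to_numpy()
        span = np.nanmax(pos) if mask.any() else 0.0
        xs[mask] = pos + offset
        ticks.append(offset + span / 2)
        offset += span + 10.0
    fig, ax = plt.subplots(figsize=(10, 3))
    for i, c in enumerate(chroms):
        mask = (tab["chrom"] == c).to_numpy()
        ax.scatter(xs[mask], tab.loc[mask, "neg_log10_p"], s=4,
                   color="C0" if i % 2 == 0 else "C1")
    ax.axhline(threshold, color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks, chroms, rotation=90, fontsize=6)
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(result: GWASResult, path) -> None:
    """Write a quantile-quantile plot of observed vs expected p-values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = np.sort(result.table["neg_log10_p"].to_numpy())[::-1]
    k = len(obs)
    exp = -np.log10((np.arange(1, k + 1) - 0.5) / k)
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.scatter(exp, obs, s=5)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} P$")
    ax.set_ylabel("observed $-\\log_{10} P$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
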