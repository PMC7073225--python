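"""Multi-environment phenotype analysis.

The trial model is a randomized complete block design repeated over
environments:

    y_ijk = mu + R_k(j) + G_i + E_j + GE_ij + eps_ijk,   eps ~ N(0, sigma_eps^2)

with genotype i, environment j, replication k nested in environment.
``anova_components`` produces the mean squares and moment estimates of the
variance components; ``heritability`` derives plot-level and genotype-mean
heritability; ``compute_blue`` produces fixed-effect adjusted line means
(BLUEs) used as the phenotype for genomic prediction; ``trait_correlations``
reports pairwise Pearson correlations between trait BLUEs.

Two sigma_G^2 moment estimators are offered.  ``estimator="ratio"`` (the
default) uses sigma_G^2 = (MS_G - MS_eps) / (e*r), the form conventionally
printed alongside this design; under a model with genuine GxE variance it
absorbs sigma_GE^2/e into sigma_G^2.  ``estimator="textbook"`` uses the
expected-mean-square solution sigma_G^2 = (MS_G - MS_GE) / (e*r), which is
unbiased when E[MS_G] = sigma_eps^2 + r*sigma_GE^2 + e*r*sigma_G^2; use it
for parameter-recovery work.  Both are reported in the result so the choice
is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

REQUIRED_COLUMNS = ("line", "environment", "replication", "trait", "value")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    dup = table.duplicated(
        subset=["line", "environment", "replication", "trait"]
    )
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (line, environment, replication, "
            "trait) records"
        )
    if not np.isfinite(table["value"]).all():
        raise ValueError("non-finite phenotype values")
    return table


@dataclass
class VarianceComponents:
    trait: str
    e: int  # number of environments
    r: int  # replications per environment
    n_geno: int
    ms: dict[str, float]  # MS_G, MS_E, MS_R, MS_GE, MS_eps
    df: dict[str, float]
    sigma2_G: float
    sigma2_GE: float
    sigma2_eps: float
    sigma2_G_ratio: float  # (MS_G - MS_eps)/(e r), as conventionally printed
    sigma2_G_textbook: float  # (MS_G - MS_GE)/(e r)
    estimator: str
    truncated: list[str] = field(default_factory=list)
    balanced: bool = True

    @property
    def H2_plot(self) -> float:
        return heritability(self)[0]

    @property
    def H2_mean(self) -> float:
        return heritability(self)[1]


def _balanced_mean_squares(df: pd.DataFrame):
    """Exact sums of squares for the balanced G x E x R(E) layout."""
    g = df["line"].nunique()
    e = df["environment"].nunique()
    r = df["replication"].nunique()
    y = df["value"].to_numpy()
    grand = y.mean()
    m_g = df.groupby("line")["value"].mean()
    m_e = df.groupby("environment")["value"].mean()
    m_ge = df.groupby(["line", "environment"])["value"].mean().unstack()
    m_er = df.groupby(["environment", "replication"])["value"].mean()

    ss_g = e * r * ((m_g - grand) ** 2).sum()
    ss_e = g * r * ((m_e - grand) ** 2).sum()
    ss_r = g * ((m_er - m_er.groupby("environment").transform("mean")) ** 2).sum()
    inter = m_ge.sub(m_g, axis=0).sub(m_e, axis=1) + grand
    ss_ge = r * (inter**2).to_numpy().sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_eps = ss_tot - ss_g - ss_e - ss_r - ss_ge

    dfs = {
        "G": g - 1,
        "E": e - 1,
        "R": e * (r - 1),
        "GE": (g - 1) * (e - 1),
        "eps": e * (g - 1) * (r - 1),
    }
    sss = {"G": ss_g, "E": ss_e, "R": ss_r, "GE": ss_ge, "eps": ss_eps}
    ms = {k: sss[k] / dfs[k] for k in sss}
    return ms, dfs, g, e, r


def _unbalanced_mean_squares(df: pd.DataFrame):
    """Sequential least-squares decomposition for unbalanced layouts."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    work = df.rename(columns={"value": "y"}).copy()
    for c in ("line", "environment", "replication"):
        work[c] = work[c].astype(str)
    model = smf.ols(
        "y ~ C(environment) + C(environment):C(replication) + C(line)"
        " + C(line):C(environment)",
        data=work,
    ).fit()
    table = sm.stats.anova_lm(model, typ=1)
    key = {
        "C(environment)": "E",
        "C(environment):C(replication)": "R",
        "C(line)": "G",
        "C(line):C(environment)": "GE",
        "Residual": "eps",
    }
    dfs, ms = {}, {}
    for row, label in key.items():
        if row not in table.index:
            raise ValueError(
                "layout too sparse for the least-squares decomposition; "
                f"term {row} is absent"
            )
        dfs[label] = float(table.loc[row, "df"])
        if dfs[label] <= 0:
            raise ValueError(f"zero degrees of freedom for term {label}")
        ms[label] = float(table.loc[row, "sum_sq"]) / dfs[label]
    g = work["line"].nunique()
    e = work["environment"].nunique()
    counts = work.groupby("environment")["replication"].nunique()
    r = int(round(counts.mean()))
    return ms, dfs, g, e, r


def anova_components(
    table: pd.DataFrame, trait: str, estimator: str = "ratio"
) -> VarianceComponents:
    """Mean squares and moment variance components for one trait.

    Balanced layouts use exact closed-form sums of squares; unbalanced
    layouts fall back to a sequential least-squares decomposition and are
    flagged (``balanced=False``).  Negative moment estimates are truncated
    to zero and listed in ``truncated``.
    """
    if estimator not in ("ratio", "textbook"):
        raise ValueError("estimator must be 'ratio' or 'textbook'")
    validate_table(table)
    df = table[table["trait"] == trait]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    g = df["line"].nunique()
    e = df["environment"].nunique()
    r = df["replication"].nunique()
    if g < 2 or e < 2 or r < 2:
        raise ValueError(
            ">=2 genotypes, environments and replications required "
            f"(got {g}, {e}, {r})"
        )
    expected = g * e * r
    balanced = (
        len(df) == expected
        and df.groupby(["line", "environment"]).size().eq(r).all()
    )
    if balanced:
        ms, dfs, g, e, r = _balanced_mean_squares(df)
    else:
        ms, dfs, g, e, r = _unbalanced_mean_squares(df)

    s2_eps = ms["eps"]
    s2_ge = (ms["GE"] - ms["eps"]) / r
    s2_g_ratio = (ms["G"] - ms["eps"]) / (e * r)
    s2_g_textbook = (ms["G"] - ms["GE"]) / (e * r)
    s2_g = s2_g_ratio if estimator == "ratio" else s2_g_textbook

    truncated = []
    if s2_ge < 0:
        truncated.append("sigma2_GE")
        s2_ge = 0.0
    if s2_g < 0:
        truncated.append("sigma2_G")
        s2_g = 0.0
    return VarianceComponents(
        trait=trait,
        e=e,
        r=r,
        n_geno=g,
        ms={f"MS_{k}": v for k, v in ms.items()},
        df=dfs,
        sigma2_G=float(s2_g),
        sigma2_GE=float(s2_ge),
        sigma2_eps=float(s2_eps),
        sigma2_G_ratio=float(s2_g_ratio),
        sigma2_G_textbook=float(s2_g_textbook),
        estimator=estimator,
        truncated=truncated,
        balanced=bool(balanced),
    )


def heritability(vc: VarianceComponents) -> tuple[float, float]:
    """Plot-level and genotype-mean heritability.

    H2_plot = sG2 / (sG2 + sGE2 + se2);
    H2_mean = sG2 / (sG2 + sGE2/e + se2/(e*r)).
    All-zero components are undefined and raise.
    """
    s2g, s2ge, s2e = vc.sigma2_G, vc.sigma2_GE, vc.sigma2_eps
    denom_plot = s2g + s2ge + s2e
    denom_mean = s2g + s2ge / vc.e + s2e / (vc.e * vc.r)
    if denom_plot <= 0:
        raise ValueError(
            f"heritability undefined for {vc.trait}: all components zero"
        )
    return float(s2g / denom_plot), float(s2g / denom_mean)


def compute_blue(table: pd.DataFrame, trait: str) -> pd.Series:
    """Adjusted line means from the two-way fixed model.

    Fits y = mu + G_i + E_j by least squares (replications pooled into the
    residual) with a sum-to-zero constraint on environment effects, and
    returns mu + G_i per line.  On balanced data this equals the raw line
    mean.  A disconnected line-environment incidence graph makes line
    contrasts inestimable and raises, naming the components.
    """
    validate_table(table)
    df = table[table["trait"] == trait]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    lines = sorted(df["line"].unique())
    envs = sorted(df["environment"].unique())
    _check_connected(df, lines, envs)
    li = {s: i for i, s in enumerate(lines)}
    ei = {s: i for i, s in enumerate(envs)}
    n = len(df)
    g, e = len(lines), len(envs)
    # columns: g line indicators + (e-1) sum-to-zero environment contrasts
    X = np.zeros((n, g + e - 1))
    rows_l = df["line"].map(li).to_numpy()
    rows_e = df["environment"].map(ei).to_numpy()
    X[np.arange(n), rows_l] = 1.0
    for j in range(e - 1):
        X[rows_e == j, g + j] = 1.0
        X[rows_e == e - 1, g + j] = -1.0
    beta, *_ = np.linalg.lstsq(X, df["value"].to_numpy(), rcond=None)
    return pd.Series(beta[:g], index=pd.Index(lines, name="line"), name=trait)


def _check_connected(df: pd.DataFrame, lines, envs) -> None:
    parent: dict[str, str] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for line, env in df[["line", "environment"]].drop_duplicates().itertuples(
        index=False
    ):
        a, b = find(f"L:{line}"), find(f"E:{env}")
        if a != b:
            parent[a] = b
    roots = {find(f"L:{s}") for s in lines} | {find(f"E:{s}") for s in envs}
    if len(roots) > 1:
        comps: dict[str, list[str]] = {}
        for s in lines:
            comps.setdefault(find(f"L:{s}"), []).append(str(s))
        raise ValueError(
            "line-environment incidence is disconnected; line components: "
            + "; ".join(",".join(v) for v in comps.values())
        )


def blue_table(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """BLUEs for every requested trait, lines as rows."""
    if traits is None:
        traits = sorted(table["trait"].unique())
    return pd.concat([compute_blue(table, t) for t in traits], axis=1)


def trait_correlations(blues: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between trait BLUEs with significance.

    Returns long-format rows (trait_a, trait_b, r, p_value, stars); stars
    mark p < 0.05 (*) and p < 0.001 (***).  Constant traits are flagged with
    NaN correlation.
    """
    if len(blues) < 3:
        raise ValueError("need >= 3 lines for correlation")
    traits = list(blues.columns)
    rows = []
    for i, a in enumerate(traits):
        for b in traits[i + 1 :]:
            x, y = blues[a].to_numpy(), blues[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((a, b, np.nan, np.nan, "undefined"))
                continue
            r, p = sps.pearsonr(x, y)
            stars = "***" if p < 0.001 else ("*" if p < 0.05 else "")
            rows.append((a, b, float(r), float(p), stars))
    return pd.DataFrame(
        rows, columns=["trait_a", "trait_b", "r", "p_value", "stars"]
    )
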