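"""Synthetic wheat-panel generator.

Emulates a diversity panel of inbred winter-wheat cultivars genotyped on a
SNP array and phenotyped in replicated multi-environment yield trials:

* genotypes coded 0/2 (homozygotes; a configurable heterozygosity rate covers
  residual heterozygosity), markers laid out on 21 chromosomes with
  block-structured linkage disequilibrium decaying with marker distance;
* a minor-allele-frequency spectrum skewed toward rare alleles, a
  configurable monomorphic fraction, and per-marker missing-call rates drawn
  from a Beta spectrum (array panels routinely reach 80% missing at the worst
  markers with a panel mean near 28%);
* phenotypes built generatively from the randomized-complete-block
  multi-environment model
  ``y_ijk = mu + R_k(j) + G_i + E_j + GE_ij + eps_ijk``
  with additive QTL genetic values rescaled to a target genetic variance and
  independent normal environment, genotype-by-environment,
  replication-within-environment and residual effects.

Every draw flows from a single seed; fixed seed means bit-identical output.
A :class:`TruthRecord` retains the QTL, their effects and each line's true
breeding value for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import (
    GenotypeMatrix,
    read_genotypes,
    write_genotypes,
    write_marker_map,
)

#: Default per-trait variance targets (sigma_G^2, sigma_E^2, sigma_GE^2,
#: sigma_eps^2).  The six traits span the heritability/architecture range of
#: a wheat yield trial: GY is GxE-dominated, HD environment-dominated, PH/TKW
#: strongly genetic.
DEFAULT_VARIANCE_TARGETS: dict[str, tuple[float, float, float, float]] = {
    "GY": (12.1, 43.0, 39.4, 5.5),
    "SN": (34.3, 24.1, 36.2, 5.4),
    "TKW": (41.4, 27.7, 23.8, 7.2),
    "SL": (42.9, 8.2, 34.7, 14.1),
    "HD": (12.6, 79.3, 7.3, 0.8),
    "PH": (60.2, 12.0, 23.1, 4.8),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel.

    Defaults mirror the scale of a 166-line Chinese winter-wheat diversity
    panel: 6,000 markers on 21 chromosomes, three environments with three
    replications, missing rates up to 0.8 averaging ~0.28.
    """

    n_lines: int = 166
    n_markers: int = 6000
    n_chromosomes: int = 21
    chrom_length_mb: float = 700.0
    maf_spectrum: tuple[float, float] = (0.5, 2.0)  # Beta over allele freq
    ld_block_mean_markers: float = 10.0
    ld_within_block_corr: float = 0.6
    missing_rate_spectrum: tuple[float, float] = (0.56, 1.44)  # mean 0.28
    missing_rate_max: float = 0.8
    monomorphic_fraction: float = 0.02
    heterozygosity_rate: float = 0.0
    position_unknown_fraction: float = 0.0
    n_qtl: int = 50
    qtl_effect_sd: float = 1.0
    n_environments: int = 3
    n_replications: int = 3
    mu: float = 0.0
    rep_variance: float = 0.0
    variance_targets: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_TARGETS)
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_lines", "n_markers", "n_chromosomes", "n_qtl",
                     "n_environments", "n_replications"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.ld_within_block_corr < 1.0:
            raise ValueError("ld_within_block_corr must be in [0, 1)")
        for name in ("monomorphic_fraction", "heterozygosity_rate",
                     "position_unknown_fraction", "missing_rate_max"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for trait, vt in self.variance_targets.items():
            if len(vt) != 4 or any(v < 0 for v in vt):
                raise ValueError(
                    f"variance target for {trait} must be four values >= 0"
                )


@dataclass
class TruthRecord:
    """Ground truth of one simulated trait set."""

    qtl_marker_ids: list[str]
    qtl_effects: dict[str, np.ndarray]  # trait -> rescaled additive effects
    true_breeding_values: dict[str, np.ndarray]  # trait -> per line
    realized_variance_components: dict[str, dict[str, float]]
    line_ids: list[str]


def _rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed))


def simulate_genotypes(
    config: SimulationConfig, return_complete: bool = False
):
    """Draw a genotype panel with block LD and per-marker missingness.

    LD construction: markers are partitioned into blocks (geometric sizes
    with the configured mean).  Within a block all markers share one allele
    frequency; the allele vector of each marker after the first copies the
    previous marker's alleles per line with probability rho
    (``ld_within_block_corr``) and redraws fresh Bernoulli draws otherwise.
    Adjacent within-block genotype correlation is therefore rho in
    expectation (so r^2 ~ rho^2), decaying as rho^k with marker lag k.

    With ``return_complete`` the pre-masking matrix (no missing calls) is
    returned alongside, for generating phenotypes from fully observed QTL.
    """
    config.validate()
    rng = _rng(config)
    n, m = config.n_lines, config.n_markers

    # chromosome assignment: equal split, positions uniform then sorted
    chrom_sizes = np.full(config.n_chromosomes, m // config.n_chromosomes)
    chrom_sizes[: m % config.n_chromosomes] += 1
    chrom_labels: list[str] = []
    pos_mb = np.empty(m)
    start = 0
    for c, size in enumerate(chrom_sizes):
        chrom_labels.extend([f"chr{c + 1}"] * size)
        pos_mb[start : start + size] = np.sort(
            rng.uniform(0.0, config.chrom_length_mb, size)
        )
        start += size

    # block partition (blocks never span chromosomes)
    block_id = np.empty(m, dtype=int)
    next_block = 0
    start = 0
    p_geo = min(1.0, 1.0 / config.ld_block_mean_markers)
    for size in chrom_sizes:
        filled = 0
        while filled < size:
            blen = int(rng.geometric(p_geo))
            blen = min(blen, size - filled)
            block_id[start + filled : start + filled + blen] = next_block
            next_block += 1
            filled += blen
        start += size

    n_blocks = next_block
    block_freq = rng.beta(*config.maf_spectrum, size=n_blocks)
    block_freq = np.clip(block_freq, 0.005, 0.995)
    mono_mask = rng.random(m) < config.monomorphic_fraction

    rho = config.ld_within_block_corr
    alleles = np.empty((n, m), dtype=np.int8)
    prev_block = -1
    for j in range(m):
        b = block_id[j]
        p = block_freq[b]
        fresh = rng.random(n) < p
        if b == prev_block:
            copy = rng.random(n) < rho
            alleles[:, j] = np.where(copy, alleles[:, j - 1], fresh)
        else:
            alleles[:, j] = fresh
        prev_block = b

    calls = alleles.astype(float) * 2.0
    if config.heterozygosity_rate > 0:
        het = rng.random((n, m)) < config.heterozygosity_rate
        calls[het] = 1.0
    calls[:, mono_mask] = 0.0

    # missingness completely at random per marker
    rates = rng.beta(*config.missing_rate_spectrum, size=m)
    rates = np.minimum(rates, config.missing_rate_max)
    complete = calls.copy()
    miss = rng.random((n, m)) < rates[None, :]
    calls[miss] = np.nan

    line_ids = [f"L{i + 1:04d}" for i in range(n)]
    marker_ids = [f"M{j + 1:06d}" for j in range(m)]
    if config.position_unknown_fraction > 0:
        unknown = rng.random(m) < config.position_unknown_fraction
        pos_col = pos_mb.copy()
        pos_col[unknown] = np.nan
    else:
        pos_col = pos_mb
    marker_map = pd.DataFrame(
        {
            "marker": marker_ids,
            "chrom": chrom_labels,
            "pos_mb": pos_col,
            "position_known": ~np.isnan(pos_col),
            "ld_block": block_id,  # generator metadata, not part of the dialect
        }
    )
    matrix = GenotypeMatrix(line_ids, marker_ids, calls, marker_map)
    if return_complete:
        complete_matrix = GenotypeMatrix(
            line_ids, marker_ids, complete, marker_map.copy()
        )
        return matrix, complete_matrix
    return matrix


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate replicated multi-environment phenotypes from additive QTL.

    Per trait: ``n_qtl`` polymorphic markers are drawn, additive effects
    ~ N(0, qtl_effect_sd^2); the centered additive score is rescaled so its
    panel variance equals the trait's sigma_G^2 target; environment, GxE,
    replication-within-environment and residual effects are independent
    normals at their target variances.  Missing QTL calls (if the matrix has
    any) are filled with the marker mean for scoring, so prefer passing the
    complete matrix from ``simulate_genotypes(..., return_complete=True)``.

    Returns the long-format phenotype table (line, environment, replication,
    trait, value) and the :class:`TruthRecord`.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    calls = genotypes.calls
    n = genotypes.n_lines
    e, r = config.n_environments, config.n_replications

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        obs_mean = np.nanmean(calls, axis=0)
        filled = np.where(np.isnan(calls), obs_mean[None, :], calls)
        poly = np.nanvar(filled, axis=0) > 0
    n_poly = int(poly.sum())
    if config.n_qtl > n_poly:
        raise ValueError(
            f"n_qtl={config.n_qtl} exceeds the {n_poly} polymorphic markers"
        )
    qtl_idx = np.sort(rng.choice(np.flatnonzero(poly), config.n_qtl,
                                 replace=False))
    qtl_ids = [genotypes.marker_ids[j] for j in qtl_idx]
    X_qtl = filled[:, qtl_idx]
    Xc = X_qtl - X_qtl.mean(axis=0)

    env_labels = [f"E{j + 1}" for j in range(e)]
    rep_labels = [f"R{k + 1}" for k in range(r)]

    records: list[pd.DataFrame] = []
    qtl_effects: dict[str, np.ndarray] = {}
    tbv: dict[str, np.ndarray] = {}
    realized: dict[str, dict[str, float]] = {}
    for trait, (s2g, s2e, s2ge, s2eps) in config.variance_targets.items():
        raw_effects = rng.normal(0.0, config.qtl_effect_sd, config.n_qtl)
        score = Xc @ raw_effects
        v = score.var(ddof=0)
        scale = np.sqrt(s2g / v) if (v > 0 and s2g > 0) else 0.0
        effects = raw_effects * scale
        g = Xc @ effects
        env_eff = rng.normal(0.0, np.sqrt(s2e), e)
        ge_eff = rng.normal(0.0, np.sqrt(s2ge), (n, e))
        rep_eff = rng.normal(0.0, np.sqrt(config.rep_variance), (e, r))
        eps = rng.normal(0.0, np.sqrt(s2eps), (n, e, r))
        y = (
            config.mu
            + g[:, None, None]
            + env_eff[None, :, None]
            + ge_eff[:, :, None]
            + rep_eff[None, :, :]
            + eps
        )
        idx = pd.MultiIndex.from_product(
            [genotypes.line_ids, env_labels, rep_labels],
            names=["line", "environment", "replication"],
        )
        df = pd.DataFrame({"value": y.ravel()}, index=idx).reset_index()
        df.insert(3, "trait", trait)
        records.append(df)
        qtl_effects[trait] = effects
        tbv[trait] = g
        realized[trait] = {
            "sigma2_G": float(g.var(ddof=0)),
            "sigma2_E": float(env_eff.var(ddof=0)),
            "sigma2_GE": float(ge_eff.var(ddof=0)),
            "sigma2_eps": float(eps.var(ddof=0)),
        }

    table = pd.concat(records, ignore_index=True)
    truth = TruthRecord(
        qtl_marker_ids=qtl_ids,
        qtl_effects=qtl_effects,
        true_breeding_values=tbv,
        realized_variance_components=realized,
        line_ids=list(genotypes.line_ids),
    )
    return table, truth


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """Genotypes (with missingness) plus phenotypes scored on the complete
    pre-masking genotypes, so true breeding values are exact."""
    masked, complete = simulate_genotypes(config, return_complete=True)
    phenotypes, truth = simulate_phenotypes(complete, config)
    return masked, phenotypes, truth


def write_fixtures(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    truth: TruthRecord,
    directory,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write the panel as plain-text files that round-trip losslessly.

    Emits ``genotypes.tsv``, ``marker_map.tsv``, ``phenotypes.tsv``,
    ``truth.json`` and a ``manifest.json`` naming the seed and config.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": directory / "genotypes.tsv",
        "marker_map": directory / "marker_map.tsv",
        "phenotypes": directory / "phenotypes.tsv",
        "truth": directory / "truth.json",
        "manifest": directory / "manifest.json",
    }
    write_genotypes(genotypes, paths["genotypes"])
    write_marker_map(genotypes, paths["marker_map"])
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    truth_obj = {
        "qtl_marker_ids": truth.qtl_marker_ids,
        "line_ids": truth.line_ids,
        "qtl_effects": {t: v.tolist() for t, v in truth.qtl_effects.items()},
        "true_breeding_values": {
            t: v.tolist() for t, v in truth.true_breeding_values.items()
        },
        "realized_variance_components": truth.realized_variance_components,
    }
    paths["truth"].write_text(json.dumps(truth_obj, indent=1, sort_keys=True))
    manifest = {"format": "wheatgs-panel-v1"}
    if config is not None:
        manifest["seed"] = config.seed
        manifest["config"] = dataclasses.asdict(config)
    paths["manifest"].write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return paths


def read_fixtures(directory) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    directory = Path(directory)
    genotypes = read_genotypes(
        directory / "genotypes.tsv", map_path=directory / "marker_map.tsv"
    )
    phenotypes = pd.read_csv(directory / "phenotypes.tsv", sep="\t")
    obj = json.loads((directory / "truth.json").read_text())
    truth = TruthRecord(
        qtl_marker_ids=obj["qtl_marker_ids"],
        qtl_effects={t: np.array(v) for t, v in obj["qtl_effects"].items()},
        true_breeding_values={
            t: np.array(v) for t, v in obj["true_breeding_values"].items()
        },
        realized_variance_components=obj["realized_variance_components"],
        line_ids=obj["line_ids"],
    )
    return genotypes, phenotypes, truth
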