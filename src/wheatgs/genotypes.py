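"""Marker statistics, quality control, redundancy binning, imputation, LD.

Quality control follows the missing-rate x minor-allele-frequency grid used
in array-genotyped wheat panels: five missing-rate levels (0%, 20%, 40%,
60%, 80%) crossed with three MAF levels (0%, 5%, 10%).  Threshold semantics
are strict: a marker is retained when its missing rate is *below* the level
and its MAF is *above* the level, with two documented boundary cases — the
0% missing level keeps only markers with no missing call at all, and the 80%
level is inclusive (<= 0.8) because panels are conventionally pre-cleaned of
markers missing in more than 80% of lines, making 80% the full-panel row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

MISSING_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8)
MAF_LEVELS = (0.0, 0.05, 0.10)


@dataclass(frozen=True)
class QCScheme:
    """One cell of the QC grid.

    ``missing_level``: retain markers with missing rate < level (== 0 at the
    0% level, <= 0.8 at the 80% level).  ``maf_level``: retain markers with
    MAF > level (0% keeps all polymorphic markers).
    Arbitrary thresholds outside the canonical grids are accepted.
    """

    missing_level: float
    maf_level: float

    def label(self) -> str:
        return (
            f"miss{int(round(self.missing_level * 100))}"
            f"_maf{int(round(self.maf_level * 100))}"
        )


def compute_marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker missing rate, MAF, gene diversity (GD) and PIC.

    Allele frequencies use observed calls only.  For a biallelic locus with
    allele frequencies p and q = 1 - p:

    * ``gd`` (expected heterozygosity) = 1 - p^2 - q^2 = 2pq
    * ``pic`` = 1 - p^2 - q^2 - 2 p^2 q^2

    Monomorphic markers have maf = gd = pic = 0.  Markers with every call
    missing are flagged ``undefined`` and carry NaN statistics; summaries
    should exclude them.
    """
    if matrix.n_lines < 1:
        raise ValueError("at least one line required")
    calls = matrix.calls
    n = matrix.n_lines
    n_obs = np.sum(~np.isnan(calls), axis=0)
    missing_rate = 1.0 - n_obs / n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(calls, axis=0) / 2.0  # alt-allele frequency
    q = 1.0 - p
    maf = np.minimum(p, q)
    gd = 2.0 * p * q
    pic = gd - 2.0 * p**2 * q**2
    undefined = n_obs == 0
    for arr in (maf, gd, pic):
        arr[undefined] = np.nan
    return pd.DataFrame(
        {
            "marker": matrix.marker_ids,
            "missing_rate": missing_rate,
            "maf": maf,
            "gd": gd,
            "pic": pic,
            "undefined": undefined,
        }
    )


def apply_qc(
    matrix: GenotypeMatrix, stats: pd.DataFrame, scheme: QCScheme
) -> GenotypeMatrix:
    """Filter markers by the scheme; marker order is preserved.

    Emits a warning (and returns the empty matrix) when no marker survives;
    model fitting refuses empty designs downstream.
    """
    if len(stats) != matrix.n_markers:
        raise ValueError("stats were not computed on this matrix")
    mr = stats["missing_rate"].to_numpy()
    maf = stats["maf"].to_numpy()
    if scheme.missing_level <= 0.0:
        keep_mr = mr == 0.0
    elif scheme.missing_level >= 0.8:
        keep_mr = mr <= scheme.missing_level
    else:
        keep_mr = mr < scheme.missing_level
    with np.errstate(invalid="ignore"):
        keep_maf = maf > scheme.maf_level
    keep = keep_mr & keep_maf & ~stats["undefined"].to_numpy()
    if not keep.any():
        warnings.warn(
            f"QC scheme {scheme.label()} removed every marker", UserWarning
        )
    return matrix.subset_markers(keep)


def bin_redundant_markers(
    matrix: GenotypeMatrix,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Collapse groups of markers with identical calls AND missing patterns.

    Markers are grouped when their call vectors agree on the shared
    non-missing lines and their missing masks are identical (together:
    byte-identical columns).  One representative per group is retained —
    the lowest missing rate, ties broken by map order; within a group the
    missing patterns are identical so the tie rule reduces to map order.
    Returns the reduced matrix and a report mapping removed -> representative.
    """
    calls = matrix.calls
    keys: dict[bytes, int] = {}
    representative = np.arange(matrix.n_markers)
    removed: list[tuple[str, str]] = []
    enc = np.where(np.isnan(calls), -1.0, calls)
    for j in range(matrix.n_markers):
        key = enc[:, j].tobytes()
        if key in keys:
            rep = keys[key]
            representative[j] = rep
            removed.append((matrix.marker_ids[j], matrix.marker_ids[rep]))
        else:
            keys[key] = j
    keep = representative == np.arange(matrix.n_markers)
    report = pd.DataFrame(removed, columns=["removed", "representative"])
    return matrix.subset_markers(keep), report


def impute_empirical(matrix: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing calls by sampling each marker's observed genotype
    frequencies (empirical-distribution imputation).

    Observed calls are untouched; identical seeds give identical draws.
    A marker with no observed call cannot be imputed and raises, pointing at
    prior QC.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    calls = matrix.calls.copy()
    for j in range(matrix.n_markers):
        col = calls[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        observed = col[~miss]
        if observed.size == 0:
            raise ValueError(
                f"marker {matrix.marker_ids[j]!r} has no observed call; "
                "apply QC before imputation"
            )
        calls[miss, j] = rng.choice(observed, size=int(miss.sum()))
    return GenotypeMatrix(
        list(matrix.line_ids), list(matrix.marker_ids), calls,
        matrix.map.copy(),
    )


@dataclass
class LDSummary:
    """Pairwise same-chromosome r^2 records and their distance-binned means."""

    pairs: pd.DataFrame  # columns: marker_a, marker_b, chrom, distance_mb, r2
    mean_r2_overall: float
    binned_means: pd.DataFrame  # columns: bin_left, bin_right, mean_r2, n_pairs
    n_pairs_skipped: int  # pairs with < 3 co-observed lines


def ld_scan(
    matrix: GenotypeMatrix,
    max_missing: float = 0.4,
    window_mb: float | None = None,
    bin_edges_mb=None,
    min_shared: int = 3,
) -> LDSummary:
    """Linkage disequilibrium as squared genotype-code correlation.

    Considers same-chromosome marker pairs with known positions, restricted
    to markers with missing rate below ``max_missing`` and (optionally) to
    pairs closer than ``window_mb``.  r^2 for a pair is the squared Pearson
    correlation of genotype codes over lines where both calls are observed
    (appropriate for inbred panels); pairs with fewer than ``min_shared``
    co-observed lines are skipped and counted.
    """
    n = matrix.n_lines
    mr = np.isnan(matrix.calls).mean(axis=0)
    known = matrix.map["position_known"].to_numpy()
    include = (mr < max_missing) & known
    records: list[tuple[str, str, str, float, float]] = []
    skipped = 0
    for chrom, grp in matrix.map[include].groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos_mb"].to_numpy()
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        sub = matrix.calls[:, idx]
        k = len(idx)
        for a in range(k):
            for b in range(a + 1, k):
                d = pos[b] - pos[a]
                if window_mb is not None and d > window_mb:
                    break
                x, y = sub[:, a], sub[:, b]
                both = ~np.isnan(x) & ~np.isnan(y)
                if both.sum() < min_shared:
                    skipped += 1
                    continue
                xs, ys = x[both], y[both]
                sx, sy = xs.std(), ys.std()
                if sx == 0 or sy == 0:
                    skipped += 1
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                records.append(
                    (
                        matrix.marker_ids[idx[a]],
                        matrix.marker_ids[idx[b]],
                        str(chrom),
                        float(d),
                        float(r * r),
                    )
                )
    pairs = pd.DataFrame(
        records, columns=["marker_a", "marker_b", "chrom", "distance_mb", "r2"]
    )
    mean_r2 = float(pairs["r2"].mean()) if len(pairs) else float("nan")
    if bin_edges_mb is None:
        bin_edges_mb = [0.0, 1.0, 10.0, 100.0, 1000.0]
    edges = np.asarray(bin_edges_mb, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = pairs[(pairs["distance_mb"] >= lo) & (pairs["distance_mb"] < hi)]
        rows.append(
            (lo, hi, float(sel["r2"].mean()) if len(sel) else np.nan, len(sel))
        )
    binned = pd.DataFrame(
        rows, columns=["bin_left", "bin_right", "mean_r2", "n_pairs"]
    )
    return LDSummary(pairs, mean_r2, binned, skipped)
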