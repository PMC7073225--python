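"""Genotype matrix container and file I/O.

The panel is a set of (mostly inbred) wheat lines genotyped at biallelic SNP
markers.  Calls are coded as the count of the alternate allele: 0 and 2 for
the two homozygotes, 1 for a heterozygote, ``NaN`` for a missing call.  Each
marker carries a map record (chromosome label, physical position in Mb); a
marker whose physical position is unknown keeps its chromosome label but has
``position_known`` False.

The native on-disk dialect is plain delimited text (see :func:`read_genotypes`
/ :func:`write_genotypes`); biallelic VCF can be imported with
:func:`read_vcf`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"
_LEGAL_CODES = {"0", "1", "2"}


class GenotypeParseError(ValueError):
    """Raised when a genotype file contains an illegal cell or duplicate ID."""


@dataclass
class GenotypeMatrix:
    """Lines x markers genotype calls plus the marker map.

    Parameters
    ----------
    line_ids
        Unique line identifiers, length ``n_lines``.
    marker_ids
        Unique marker identifiers, length ``n_markers``.
    calls
        ``(n_lines, n_markers)`` float array with entries in {0, 1, 2, NaN}.
    map
        DataFrame indexed like ``marker_ids`` with columns ``chrom``,
        ``pos_mb`` (float, NaN when unknown) and ``position_known`` (bool).
    """

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    map: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.line_ids = [str(s) for s in self.line_ids]
        self.marker_ids = [str(s) for s in self.marker_ids]
        if len(set(self.line_ids)) != len(self.line_ids):
            raise GenotypeParseError("duplicate line IDs")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeParseError("duplicate marker IDs")
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        observed = self.calls[~np.isnan(self.calls)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
            raise GenotypeParseError(f"illegal genotype code {bad!r}")
        if self.map is None:
            self.map = default_map(self.marker_ids)
        else:
            self.map = self.map.reset_index(drop=True)
            if len(self.map) != len(self.marker_ids):
                raise ValueError("marker map length does not match marker count")
            if "position_known" not in self.map.columns:
                self.map = self.map.assign(
                    position_known=~self.map["pos_mb"].isna()
                )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to markers selected by ``keep``.

        ``keep`` may be a boolean mask, integer indices, or marker IDs.
        Marker order follows ``keep`` (map order when a mask).
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            lookup = {m: i for i, m in enumerate(self.marker_ids)}
            idx = np.array([lookup[str(m)] for m in keep], dtype=int)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            marker_ids=[self.marker_ids[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            map=self.map.iloc[idx].reset_index(drop=True),
        )

    def subset_lines(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            lookup = {s: i for i, s in enumerate(self.line_ids)}
            idx = np.array([lookup[str(s)] for s in keep], dtype=int)
        return GenotypeMatrix(
            line_ids=[self.line_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            calls=self.calls[idx, :].copy(),
            map=self.map.copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls, equal_nan=True)
        )


def default_map(marker_ids: list[str]) -> pd.DataFrame:
    """Placeholder map: unknown chromosome and position for every marker."""
    return pd.DataFrame(
        {
            "marker": list(marker_ids),
            "chrom": ["un"] * len(marker_ids),
            "pos_mb": [np.nan] * len(marker_ids),
            "position_known": [False] * len(marker_ids),
        }
    )


def read_genotypes(path, map_path=None, sep: str = "\t") -> GenotypeMatrix:
    """Read the native delimited genotype dialect.

    First column holds the line ID, remaining columns one marker each, cells
    in {0, 1, 2, NA}.  An unknown code raises :class:`GenotypeParseError`
    naming the offending row and column.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header[1:])) != len(header[1:]):
        dup = sorted({m for m in header[1:] if header[1:].count(m) > 1})
        raise GenotypeParseError(f"duplicate marker IDs in header: {dup}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    marker_ids = list(df.columns[1:])
    line_ids = df.iloc[:, 0].tolist()
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    calls = np.empty(raw.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(raw):
        cell = str(cell).strip()
        if cell == MISSING_TOKEN or cell == "":
            calls[i, j] = np.nan
        elif cell in _LEGAL_CODES:
            calls[i, j] = float(cell)
        else:
            raise GenotypeParseError(
                f"unknown genotype code {cell!r} at line {line_ids[i]!r}, "
                f"marker {marker_ids[j]!r}"
            )
    marker_map = read_marker_map(map_path, sep=sep) if map_path else None
    if marker_map is not None:
        marker_map = (
            marker_map.set_index("marker").loc[marker_ids].reset_index()
        )
    return GenotypeMatrix(line_ids, marker_ids, calls, marker_map)


def write_genotypes(matrix: GenotypeMatrix, path, sep: str = "\t") -> None:
    codes = np.full(matrix.calls.shape, MISSING_TOKEN, dtype=object)
    obs = ~np.isnan(matrix.calls)
    codes[obs] = matrix.calls[obs].astype(int).astype(str)
    df = pd.DataFrame(codes, columns=matrix.marker_ids)
    df.insert(0, "line", matrix.line_ids)
    df.to_csv(path, sep=sep, index=False)


def read_marker_map(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    df = df.rename(columns={df.columns[0]: "marker"})
    df["marker"] = df["marker"].astype(str)
    df["pos_mb"] = pd.to_numeric(df["pos_mb"], errors="coerce")
    df["position_known"] = ~df["pos_mb"].isna()
    return df[["marker", "chrom", "pos_mb", "position_known"]]


def write_marker_map(matrix: GenotypeMatrix, path, sep: str = "\t") -> None:
    out = matrix.map[["marker", "chrom", "pos_mb"]].copy()
    out.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_vcf(path) -> GenotypeMatrix:
    """Import biallelic SNP records from a VCF.

    GT fields map to alternate-allele dosage (0/0 -> 0, 0/1 -> 1, 1/1 -> 2,
    missing -> NaN).  VCF POS is 1-based bp and is stored as Mb (pos / 1e6).
    Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    chroms: list[str] = []
    pos_mb: list[float] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeParseError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "only biallelic SNPs are supported"
            )
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        marker_ids.append(mid)
        chroms.append(rec.CHROM)
        pos_mb.append(rec.POS / 1e6)
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=unknown
        g = np.asarray(rec.gt_types, dtype=float)
        g[g == 3] = np.nan
        cols.append(g)
    vcf.close()
    calls = np.column_stack(cols) if cols else np.empty((len(line_ids), 0))
    marker_map = pd.DataFrame(
        {
            "marker": marker_ids,
            "chrom": chroms,
            "pos_mb": pos_mb,
            "position_known": [True] * len(marker_ids),
        }
    )
    return GenotypeMatrix(line_ids, marker_ids, calls, marker_map)
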