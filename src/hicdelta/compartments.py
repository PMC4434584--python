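"""Compartment eigenvector (E1) tracks and track-to-track comparison.

E1 is computed per chromosome from the cis observed/expected
Pearson-correlation matrix: divide each diagonal of the balanced cis
block by its mean, correlate the resulting columns, and take the leading
eigenvector.  Tracks are scaled to unit variance over non-missing bins.

Two tracks are compared by fitting a least-squares line to the
(E1_a, E1_b) scatter and reporting each dot's perpendicular distance to
that line, plus Pearson/Spearman summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import (
    BinningMismatchError,
    ContactMap,
    CorrectedMap,
    GenomeBinning,
    as_map,
)

__all__ = [
    "EigenTrack",
    "E1Comparison",
    "DegenerateChromosomeWarning",
    "compute_e1",
    "compare_e1",
    "write_bedgraph",
    "read_bedgraph",
]


class DegenerateChromosomeWarning(UserWarning):
    pass


@dataclass
class EigenTrack:
    """Per-bin E1 values; NaN where the source map is masked/degenerate."""

    binning: GenomeBinning
    values: np.ndarray
    reference: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.binning.n_bins,):
            raise ValueError("track length does not match binning")

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class E1Comparison:
    distance: np.ndarray          # per-bin perpendicular distance, NaN if missing
    slope: float
    intercept: float
    pearson: float
    spearman: float
    n: int


def _oe_correlation(cis: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the observed/expected cis block.

    ``positions`` are original bin offsets of the (unmasked) rows, so the
    expected value at each genomic separation is computed on true
    distances even when masked bins were dropped.
    """
    d = np.abs(np.subtract.outer(positions, positions))
    sums = np.bincount(d.ravel(), weights=cis.ravel())
    counts = np.bincount(d.ravel())
    means = np.divide(
        sums, counts, out=np.zeros_like(sums), where=counts > 0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = cis / means[d]
    oe[~np.isfinite(oe)] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(oe)
    return corr


def compute_e1(
    corrected: CorrectedMap | ContactMap,
    reference_track: np.ndarray | None = None,
    min_bins: int = 4,
) -> EigenTrack:
    """Leading-eigenvector compartment track of a balanced map.

    Per chromosome: observed/expected, Pearson-correlation matrix, leading
    eigenvector.  The per-chromosome vectors are scaled to unit variance,
    oriented (positively correlated with ``reference_track`` if given,
    otherwise so their sum is non-negative) and finally the whole track is
    rescaled to unit variance over non-missing bins.

    Chromosomes with fewer than ``min_bins`` unmasked bins or a degenerate
    correlation matrix yield missing values and a warning.
    """
    cmap = as_map(corrected)
    binning = cmap.binning
    values = np.full(binning.n_bins, np.nan)

    for ci, (name, _) in enumerate(binning.chromosomes):
        sl = binning.chrom_slice(ci)
        mask = cmap.mask[sl].copy()
        block = cmap.counts[sl, sl]
        mask &= block.sum(axis=1) > 0
        if mask.sum() < min_bins:
            warnings.warn(
                f"chromosome {name}: fewer than {min_bins} usable bins; "
                "E1 set to missing",
                DegenerateChromosomeWarning,
            )
            continue
        pos = np.nonzero(mask)[0]
        cis = block[np.ix_(pos, pos)]
        corr = _oe_correlation(cis, pos)
        if not np.all(np.isfinite(corr)) or np.allclose(corr, corr.flat[0]):
            warnings.warn(
                f"chromosome {name}: degenerate correlation matrix; "
                "E1 set to missing",
                DegenerateChromosomeWarning,
            )
            continue
        eigvals, eigvecs = np.linalg.eigh(corr)
        e1 = eigvecs[:, -1]
        sd = e1.std()
        if sd == 0:
            warnings.warn(
                f"chromosome {name}: constant eigenvector; E1 set to missing",
                DegenerateChromosomeWarning,
            )
            continue
        e1 = e1 / sd
        # orientation
        if reference_track is not None:
            ref = np.asarray(reference_track, dtype=float)[sl][pos]
            good = np.isfinite(ref)
            if good.any() and np.ptp(ref[good]) > 0:
                r = np.corrcoef(e1[good], ref[good])[0, 1]
                if np.isfinite(r) and r < 0:
                    e1 = -e1
            elif e1.sum() < 0:
                e1 = -e1
        elif e1.sum() < 0:
            e1 = -e1
        values[sl.start + pos] = e1

    finite = np.isfinite(values)
    if finite.any():
        sd = values[finite].std()
        if sd > 0:
            values[finite] /= sd
    return EigenTrack(
        binning,
        values,
        reference="user" if reference_track is not None else "sum-positive",
    )


def compare_e1(
    track_a: EigenTrack, track_b: EigenTrack, line: str = "ols"
) -> E1Comparison:
    """Per-bin distance from each (E1_a, E1_b) dot to the fitted line.

    ``line="ols"`` fits ordinary least squares of b on a (the default);
    ``line="tls"`` fits the total-least-squares (orthogonal) line, which
    makes the distances symmetric under exchanging the tracks.  In both
    cases the reported distance is the perpendicular (geometric) distance.
    """
    if track_a.binning != track_b.binning:
        raise BinningMismatchError("tracks do not share a binning")
    x = track_a.values
    y = track_b.values
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 bins present in both tracks")
    xs, ys = x[ok], y[ok]

    if line == "ols":
        if np.ptp(xs) == 0:
            raise ValueError("degenerate scatter: constant x values")
        slope, intercept = np.polyfit(xs, ys, 1)
    elif line == "tls":
        xc, yc = xs - xs.mean(), ys - ys.mean()
        cov = np.cov(np.vstack([xc, yc]))
        _, vecs = np.linalg.eigh(cov)
        v = vecs[:, -1]  # principal direction
        if v[0] == 0:
            raise ValueError("TLS line is vertical; distances undefined")
        slope = v[1] / v[0]
        intercept = ys.mean() - slope * xs.mean()
    else:
        raise ValueError(f"unknown line mode {line!r}")

    dist = np.full_like(x, np.nan)
    dist[ok] = np.abs(slope * xs - ys + intercept) / np.hypot(slope, 1.0)

    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        pearson = spearman = np.nan
    else:
        pearson = float(stats.pearsonr(xs, ys)[0])
        spearman = float(stats.spearmanr(xs, ys)[0])
    return E1Comparison(
        distance=dist,
        slope=float(slope),
        intercept=float(intercept),
        pearson=pearson,
        spearman=spearman,
        n=int(ok.sum()),
    )


def write_bedgraph(track: EigenTrack, path) -> None:
    with open(path, "w") as fh:
        for idx, (chrom, start, end) in enumerate(track.binning.bins()):
            v = track.values[idx]
            if np.isfinite(v):
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.17g}\n")


def read_bedgraph(binning: GenomeBinning, path) -> EigenTrack:
    values = np.full(binning.n_bins, np.nan)
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 4 or parts[0].startswith(("#", "track")):
                continue
            idx = binning.bin_index(parts[0], int(parts[1]))
            values[idx] = float(parts[3])
    return EigenTrack(binning, values)
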