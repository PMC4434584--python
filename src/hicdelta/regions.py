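"""Per-bin three-metric comparison of two contact maps.

For every bin: the Euclidean distance between its intra-chromosomal
contact profiles in the two maps, the Pearson and Spearman correlation of
those profiles, and the eigenvector (E1) line-distance.  Low-quality bins
are flagged from a split-half reference profile (median minus one SD rule,
with +-1 bin flanks) and excluded; the remaining bins are ranked per
metric, the top-n candidate sets are cleansed against a reference map's
own rankings, and their intersection is reported together with the
expected random overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import BinningMismatchError, ContactMap, GenomeBinning, as_map

__all__ = [
    "BinDifferenceTable",
    "CandidateSet",
    "bin_euclidean_profile",
    "bin_correlation_profile",
    "poor_bin_filter",
    "difference_table",
    "select_candidates",
    "expected_overlap",
]


def _check(a, b) -> tuple[ContactMap, ContactMap]:
    a, b = as_map(a), as_map(b)
    if a.binning != b.binning:
        raise BinningMismatchError("maps do not share a binning")
    return a, b


def bin_euclidean_profile(map_a, map_b) -> np.ndarray:
    """Per-bin Euclidean distance over intra-chromosomal partners j != i."""
    a, b = _check(map_a, map_b)
    n = a.n_bins
    out = np.zeros(n)
    d2 = (a.counts - b.counts) ** 2
    for ci in range(a.binning.n_chromosomes):
        sl = a.binning.chrom_slice(ci)
        block = d2[sl, sl]
        out[sl] = np.sqrt(block.sum(axis=1) - np.diag(block))
    return out


def bin_correlation_profile(map_a, map_b) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin Pearson and Spearman of the two intra-chromosomal rows.

    A bin whose row is constant in either map (zero variance) gets NaN in
    both coefficients; callers flag such bins.
    """
    a, b = _check(map_a, map_b)
    n = a.n_bins
    pear = np.full(n, np.nan)
    spear = np.full(n, np.nan)
    for ci in range(a.binning.n_chromosomes):
        sl = a.binning.chrom_slice(ci)
        A = a.counts[sl, sl]
        B = b.counts[sl, sl]
        nb = sl.stop - sl.start
        if nb < 4:  # fewer than 3 partners after dropping self
            continue
        for k in range(nb):
            keep = np.arange(nb) != k
            x, y = A[k, keep], B[k, keep]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            pear[sl.start + k] = _pearson(x, y)
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            if np.ptp(rx) == 0 or np.ptp(ry) == 0:
                continue
            spear[sl.start + k] = _pearson(rx, ry)
    return pear, spear


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    return float((xc * yc).sum() / denom)


def poor_bin_filter(
    reference_profile: np.ndarray, binning: GenomeBinning
) -> tuple[np.ndarray, np.ndarray]:
    """Flag poor bins (C_i < median - SD of the reference split-half
    correlations) and one flanking bin on each side within the chromosome.

    Non-finite reference values are themselves flagged poor.  Returns
    boolean (poor, flank) arrays.
    """
    c = np.asarray(reference_profile, dtype=float)
    if c.shape != (binning.n_bins,):
        raise BinningMismatchError("profile length does not match binning")
    finite = np.isfinite(c)
    if finite.sum() < 3:
        raise ValueError("fewer than 3 finite reference correlations")
    med = np.median(c[finite])
    sd = float(np.std(c[finite], ddof=1))
    poor = ~finite | (np.where(finite, c, np.inf) < med - sd)

    flank = np.zeros_like(poor)
    chrom = binning.bin_chrom
    idx = np.nonzero(poor)[0]
    for i in idx:
        for j in (i - 1, i + 1):
            if 0 <= j < binning.n_bins and chrom[j] == chrom[i] and not poor[j]:
                flank[j] = True
    return poor, flank


@dataclass
class BinDifferenceTable:
    """Per-bin metrics, flags and per-metric ranks (rank 1 = most different)."""

    binning: GenomeBinning
    frame: pd.DataFrame

    @property
    def n_ranked(self) -> int:
        return int((~self.frame["excluded"]).sum())

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _rank_most_different(
    values: np.ndarray, excluded: np.ndarray, largest: bool
) -> np.ndarray:
    """Dense 1..N ranks over non-excluded bins; ties broken by bin index."""
    n = len(values)
    ranks = np.full(n, np.nan)
    idx = np.nonzero(~excluded)[0]
    v = values[idx]
    # NaN metric values rank last
    key = np.where(np.isfinite(v), v, -np.inf if largest else np.inf)
    order = np.lexsort((idx, -key if largest else key))
    ranks[idx[order]] = np.arange(1, len(idx) + 1)
    return ranks


def difference_table(
    map_a,
    map_b,
    eigen_distance: np.ndarray,
    poor: np.ndarray | None = None,
    flank: np.ndarray | None = None,
) -> BinDifferenceTable:
    """Assemble the three metrics into a ranked per-bin table.

    ``eigen_distance`` is the per-bin E1 line distance (NaN where missing).
    Bins flagged poor/flank are excluded and carry no ranks.
    """
    a, b = _check(map_a, map_b)
    binning = a.binning
    n = binning.n_bins
    eucl = bin_euclidean_profile(a, b)
    pear, spear = bin_correlation_profile(a, b)
    eig = np.asarray(eigen_distance, dtype=float)
    if eig.shape != (n,):
        raise BinningMismatchError("eigen distance length does not match binning")
    poor = np.zeros(n, bool) if poor is None else np.asarray(poor, bool)
    flank = np.zeros(n, bool) if flank is None else np.asarray(flank, bool)
    excluded = poor | flank

    frame = pd.DataFrame(
        {
            "bin": np.arange(n),
            "chrom": [binning.chrom_names[c] for c in binning.bin_chrom],
            "start": binning.bin_start,
            "end": binning.bin_end,
            "euclidean": eucl,
            "pearson": pear,
            "spearman": spear,
            "eigen_distance": eig,
            "poor": poor,
            "flank": flank,
            "excluded": excluded,
            "rank_euclidean": _rank_most_different(eucl, excluded, largest=True),
            "rank_pearson": _rank_most_different(pear, excluded, largest=False),
            "rank_eigen": _rank_most_different(eig, excluded, largest=True),
        }
    )
    return BinDifferenceTable(binning, frame)


@dataclass
class CandidateSet:
    """Top-n most-different bins per metric, reference-cleansed."""

    sets: dict            # metric -> set of bin indices after exclusion
    intersection: set
    n_euclidean: int
    n_pearson: int
    n_eigen: int
    n_total: int
    expected: float

    def summary(self) -> dict:
        return {
            "n_euclidean": self.n_euclidean,
            "n_pearson": self.n_pearson,
            "n_eigen": self.n_eigen,
            "n_total": self.n_total,
            "expected_overlap": self.expected,
            "intersection": sorted(self.intersection),
            "intersection_size": len(self.intersection),
        }


_METRICS = ("rank_euclidean", "rank_pearson", "rank_eigen")


def _top_n(table: BinDifferenceTable, metric: str, n: int) -> set:
    f = table.frame
    return set(f.loc[f[metric] <= n, "bin"].astype(int))


def select_candidates(
    table: BinDifferenceTable,
    reference_table: BinDifferenceTable | None = None,
    n: int = 100,
) -> CandidateSet:
    """Intersect the three per-metric top-n candidate sets.

    Bins that also rank in the reference table's top n for the same metric
    (region-specific biases visible even between split halves of one map)
    are removed from that metric's candidates before intersecting.
    """
    if n > table.n_ranked:
        raise ValueError(
            f"n={n} exceeds the {table.n_ranked} ranked bins available"
        )
    if reference_table is not None and reference_table.binning != table.binning:
        raise BinningMismatchError("reference table has a different binning")

    sets = {}
    for metric in _METRICS:
        cand = _top_n(table, metric, n)
        if reference_table is not None:
            cand -= _top_n(reference_table, metric, n)
        sets[metric] = cand

    inter = sets["rank_euclidean"] & sets["rank_pearson"] & sets["rank_eigen"]
    n_total = table.n_ranked
    n_e, n_p, n_v = (
        len(sets["rank_euclidean"]),
        len(sets["rank_pearson"]),
        len(sets["rank_eigen"]),
    )
    return CandidateSet(
        sets=sets,
        intersection=inter,
        n_euclidean=n_e,
        n_pearson=n_p,
        n_eigen=n_v,
        n_total=n_total,
        expected=expected_overlap(n_e, n_p, n_v, n_total),
    )


def expected_overlap(n_eucl: int, n_p: int, n_e1: int, n_total: int) -> float:
    """Expected size of a random three-way overlap: N_Eucl*N_P*N_E1 / N_T**2."""
    if n_total <= 0:
        raise ValueError("total bin count must be positive")
    return (n_eucl * n_p * n_e1) / (n_total ** 2)
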