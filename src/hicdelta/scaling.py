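"""Distance-scaling curves P(s), power-law fits, and chromosome-level
interaction statistics (cis/trans ratios, interchromosomal enrichment and
its correlation with chromosome-length differences)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import ContactMap, GenomeBinning, as_map

__all__ = [
    "ScalingCurve",
    "PowerLawFit",
    "InterchromMatrix",
    "ps_curve",
    "fit_power_law",
    "ps_ratio",
    "cis_trans_ratio",
    "interchrom_enrichment",
    "length_diff_correlation",
]


@dataclass
class ScalingCurve:
    """Mean contact frequency per locus pair versus genomic separation.

    ``distances`` are bp (geometric centers for log bins, exact separations
    for per-diagonal binning), ``values`` the per-pair means, ``n_pairs``
    the number of locus pairs contributing to each point.
    """

    distances: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("frequencies must be non-negative")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("distance_bp\tmean_frequency\tn_pairs\n")
            for d, v, n in zip(self.distances, self.values, self.n_pairs):
                fh.write(f"{d:.10g}\t{v:.10g}\t{int(n)}\n")


@dataclass
class PowerLawFit:
    exponent: float          # log-log slope, sign included
    stderr: float
    fit_range: tuple[float, float]
    n_points: int

    def to_dict(self) -> dict:
        return {
            "exponent": self.exponent,
            "stderr": self.stderr,
            "fit_range_bp": list(self.fit_range),
            "n_points": self.n_points,
        }


def _diagonal_totals(cmap: ContactMap) -> tuple[np.ndarray, np.ndarray]:
    """(sum, pair count) per separation in bins, aggregated over chromosomes.

    Masked bins are excluded from both the sums and the pair counts; each
    unordered pair contributes once.
    """
    m = as_map(cmap)
    binning = m.binning
    max_sep = max(binning.chrom_nbins(c) for c in range(binning.n_chromosomes))
    sums = np.zeros(max_sep)
    pairs = np.zeros(max_sep, dtype=np.int64)
    for ci in range(binning.n_chromosomes):
        sl = binning.chrom_slice(ci)
        keep = np.nonzero(m.mask[sl])[0]
        if len(keep) < 2:
            continue
        block = m.counts[sl, sl][np.ix_(keep, keep)]
        sep = np.abs(np.subtract.outer(keep, keep))
        iu = np.triu_indices(len(keep), k=1)
        s = sep[iu]
        sums += np.bincount(s, weights=block[iu], minlength=max_sep)[:max_sep]
        pairs += np.bincount(s, minlength=max_sep)[:max_sep]
    return sums, pairs


def ps_curve(
    cmap, binning_scheme: str = "per_diagonal", log_ratio: float = 1.3
) -> ScalingCurve:
    """Contact frequency versus genomic distance, averaged over chromosomes.

    ``per_diagonal`` yields one point per bin separation; ``log`` pools
    separations into geometric bins with the given ratio (display use).
    """
    m = as_map(cmap)
    sums, pairs = _diagonal_totals(m)
    if sums[1:].sum() == 0:
        raise ValueError("map has no intrachromosomal contacts")
    bs = m.binning.bin_size
    seps = np.arange(1, len(sums))  # skip separation 0 (self-contacts)
    sums, pairs = sums[1:], pairs[1:]

    if binning_scheme == "per_diagonal":
        keep = pairs > 0
        values = sums[keep] / pairs[keep]
        return ScalingCurve(seps[keep] * bs, values, pairs[keep])
    if binning_scheme == "log":
        edges = [1.0]
        while edges[-1] < len(sums) + 1:
            edges.append(max(edges[-1] * log_ratio, edges[-1] + 1))
        edges = np.asarray(edges)
        idx = np.digitize(seps, edges) - 1
        nb = len(edges) - 1
        bsum = np.bincount(idx, weights=sums, minlength=nb)
        bpair = np.bincount(idx, weights=pairs, minlength=nb).astype(np.int64)
        centers = np.sqrt(edges[:-1] * edges[1:]) * bs
        keep = bpair > 0
        return ScalingCurve(centers[keep], bsum[keep] / bpair[keep], bpair[keep])
    raise ValueError(f"unknown binning scheme {binning_scheme!r}")


def fit_power_law(
    curve: ScalingCurve,
    fit_range: tuple[float, float] | None = None,
    min_pairs: int = 100,
    drop_first: bool = True,
) -> PowerLawFit:
    """OLS fit of log10 P on log10 s.

    Without an explicit ``fit_range`` the fit uses all points except the
    first distance bin and any point supported by fewer than ``min_pairs``
    locus pairs.  Non-positive frequencies are excluded with a warning.
    """
    d, v, n = curve.distances, curve.values, curve.n_pairs
    keep = np.ones(len(d), dtype=bool)
    if fit_range is not None:
        keep &= (d >= fit_range[0]) & (d <= fit_range[1])
    else:
        if drop_first and len(d):
            keep[0] = False
        keep &= n >= min_pairs
    if np.any(keep & (v <= 0)):
        warnings.warn("non-positive frequencies excluded from power-law fit")
        keep &= v > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 positive curve points in fit range")

    x = np.log10(d[keep])
    y = np.log10(v[keep])
    res = stats.linregress(x, y)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return PowerLawFit(
        exponent=float(res.slope),
        stderr=stderr,
        fit_range=(float(d[keep].min()), float(d[keep].max())),
        n_points=int(keep.sum()),
    )


def ps_ratio(curve_a: ScalingCurve, curve_b: ScalingCurve) -> np.ndarray:
    """Elementwise a/b over shared distance bins; NaN where either side
    is non-positive."""
    if len(curve_a.distances) != len(curve_b.distances) or not np.allclose(
        curve_a.distances, curve_b.distances
    ):
        raise ValueError("curves do not share distance bins")
    a, b = curve_a.values, curve_b.values
    out = np.full(len(a), np.nan)
    ok = (a > 0) & (b > 0)
    out[ok] = a[ok] / b[ok]
    return out


def cis_trans_ratio(cmap) -> tuple[dict, float]:
    """Intra/inter contact ratio per chromosome and genome-wide.

    Both sides use the symmetric-matrix counting convention (off-diagonal
    entries contribute twice): a chromosome's trans total is the full sum
    of matrix entries linking it to any other chromosome.  A chromosome
    with zero trans contacts reports an infinite ratio with a warning.
    """
    m = as_map(cmap)
    binning = m.binning
    per_chrom: dict[str, float] = {}
    total_intra = 0.0
    total_trans = 0.0
    for ci, (name, _) in enumerate(binning.chromosomes):
        sl = binning.chrom_slice(ci)
        intra = float(m.counts[sl, sl].sum())
        trans = 2.0 * (float(m.counts[sl, :].sum()) - intra)
        total_intra += intra
        total_trans += trans / 2.0  # each trans entry shared by two chroms
        if trans == 0:
            warnings.warn(f"chromosome {name} has no trans contacts")
            per_chrom[name] = np.inf
        else:
            per_chrom[name] = intra / trans
    if total_trans == 0:
        warnings.warn("map has no trans contacts")
        return per_chrom, np.inf
    return per_chrom, total_intra / total_trans


@dataclass
class InterchromMatrix:
    """Observed, expected and enrichment values per chromosome pair.

    ``observed[i, j]`` is the trans contact sum between chromosomes i and
    j (zero diagonal); ``totals[i]`` its row sums S_i; ``grand_total`` T
    counts every chromosome pair once.
    """

    chrom_names: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    enrichment: np.ndarray
    totals: np.ndarray
    grand_total: float

    def pairs(self):
        n = len(self.chrom_names)
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom_i\tchrom_j\tobserved\texpected\tenrichment\n")
            for i, j in self.pairs():
                fh.write(
                    f"{self.chrom_names[i]}\t{self.chrom_names[j]}\t"
                    f"{self.observed[i, j]:.10g}\t{self.expected[i, j]:.10g}\t"
                    f"{self.enrichment[i, j]:.10g}\n"
                )


def interchrom_enrichment(
    cmap, as_printed: bool = False, double_count_total: bool = True
) -> InterchromMatrix:
    """Observed/expected trans contact enrichment per chromosome pair.

    Expected_ij = 0.5 * (S_i*S_j/(T - S_i) + S_i*S_j/(T - S_j)).  With
    ``double_count_total`` (default) T = sum of the S_i, i.e. every trans
    contact is counted at both ends — the convention under which a uniform
    trans background yields enrichment 1 for equal-size chromosomes.
    ``double_count_total=False`` counts each chromosome pair once instead.
    The ``as_printed`` audit mode repeats (T - S_i) in both terms as in
    the source formula.
    """
    m = as_map(cmap)
    binning = m.binning
    nc = binning.n_chromosomes
    if nc < 3:
        raise ValueError("need at least 3 chromosomes")

    obs = np.zeros((nc, nc))
    for i in range(nc):
        sli = binning.chrom_slice(i)
        for j in range(i + 1, nc):
            slj = binning.chrom_slice(j)
            obs[i, j] = obs[j, i] = float(m.counts[sli, slj].sum())
    totals = obs.sum(axis=1)
    if np.any(totals == 0):
        bad = [binning.chrom_names[i] for i in np.nonzero(totals == 0)[0]]
        raise ValueError(f"chromosomes with zero trans contacts: {bad}")
    if double_count_total:
        grand = totals.sum()
    else:
        grand = obs[np.triu_indices(nc, k=1)].sum()

    expected = np.zeros((nc, nc))
    enrich = np.zeros((nc, nc))
    for i in range(nc):
        for j in range(nc):
            if i == j:
                continue
            si, sj = totals[i], totals[j]
            if as_printed:
                exp = 0.5 * (si * sj / (grand - si) + sj * si / (grand - si))
            else:
                exp = 0.5 * (si * sj / (grand - si) + si * sj / (grand - sj))
            expected[i, j] = exp
            enrich[i, j] = obs[i, j] / exp if exp > 0 else np.nan
    return InterchromMatrix(
        chrom_names=binning.chrom_names,
        observed=obs,
        expected=expected,
        enrichment=enrich,
        totals=totals,
        grand_total=float(grand),
    )


def length_diff_correlation(
    interchrom: InterchromMatrix, binning: GenomeBinning
) -> float:
    """Pearson r between pairwise enrichment and |length_i - length_j|."""
    lengths = dict(binning.chromosomes)
    xs, ys = [], []
    for i, j in interchrom.pairs():
        li = lengths[interchrom.chrom_names[i]]
        lj = lengths[interchrom.chrom_names[j]]
        xs.append(abs(li - lj))
        ys.append(interchrom.enrichment[i, j])
    if len(xs) < 3:
        raise ValueError("need at least 3 chromosome pairs")
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if np.ptp(ys) == 0 or np.ptp(xs) == 0:
        raise ValueError("correlation undefined for constant values")
    return float(stats.pearsonr(xs, ys)[0])
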