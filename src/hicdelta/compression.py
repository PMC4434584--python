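"""Per-distance "compression" normalization.

Rescales one balanced map's intra-chromosomal diagonal sums to match
another's distance scaling, preserving within-distance contact ratios and
the source map's total mass.  Coefficient K_j is the ratio of the two
maps' diagonal-j sums; its relative error combines the sqrt(K)/K read
errors of the two sums in quadrature, and coefficients with error above a
gate (default 5%) are left at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import BinningMismatchError, ContactMap, CorrectedMap, as_map

__all__ = [
    "CompressionCoefficients",
    "diagonal_sums",
    "compression_coefficients",
    "apply_compression",
]


def diagonal_sums(cmap) -> np.ndarray:
    """Sum of intra-chromosomal entries at each bin separation.

    Entry ``j`` of the result is the genome-wide sum, over all
    chromosomes, of matrix entries whose bins are ``j`` apart (each
    unordered pair counted once; ``j = 0`` is the main diagonal).
    """
    m = as_map(cmap)
    binning = m.binning
    max_sep = max(binning.chrom_nbins(c) for c in range(binning.n_chromosomes))
    sums = np.zeros(max_sep)
    for ci in range(binning.n_chromosomes):
        sl = binning.chrom_slice(ci)
        block = m.counts[sl, sl]
        nb = sl.stop - sl.start
        for j in range(nb):
            sums[j] += np.trace(block, offset=j)
    return sums


@dataclass
class CompressionCoefficients:
    """Per-distance ratios K_j with error estimates and applied flags.

    ``applied[j]`` is True where the coefficient is defined and its
    relative error is at most the gate; unapplied distances act as K = 1.
    """

    k: np.ndarray
    error: np.ndarray
    applied: np.ndarray
    target_sums: np.ndarray
    source_sums: np.ndarray
    error_gate: float = 0.05

    @property
    def effective(self) -> np.ndarray:
        return np.where(self.applied, self.k, 1.0)

    def to_tsv(self, path, bin_size: int = 1) -> None:
        with open(path, "w") as fh:
            fh.write("distance_bp\tK\terror\tapplied\n")
            for j in range(len(self.k)):
                fh.write(
                    f"{j * bin_size}\t{self.k[j]:.10g}\t{self.error[j]:.10g}\t"
                    f"{int(self.applied[j])}\n"
                )


def _raw_counts(m, raw):
    if isinstance(m, CorrectedMap):
        return m.raw
    if raw is not None:
        return as_map(raw)
    if as_map(m).value_kind == "raw":
        return as_map(m)
    raise ValueError("corrected map passed without raw counts for errors")


def compression_coefficients(
    target,
    source,
    raw_target=None,
    raw_source=None,
    error_gate: float = 0.05,
) -> CompressionCoefficients:
    """K_j = target diagonal-j sum / source diagonal-j sum.

    The relative error of each K_j is sqrt(1/R_t + 1/R_s), where R are the
    raw read supports of the two diagonal sums; coefficients with error
    above ``error_gate`` (or an undefined source sum) are not applied.
    """
    t, s = as_map(target), as_map(source)
    if t.binning != s.binning:
        raise BinningMismatchError("maps do not share a binning")
    t_sums = diagonal_sums(t)
    s_sums = diagonal_sums(s)
    rt = diagonal_sums(_raw_counts(target, raw_target))
    rs = diagonal_sums(_raw_counts(source, raw_source))

    n = len(t_sums)
    k = np.ones(n)
    err = np.full(n, np.inf)
    applied = np.zeros(n, dtype=bool)
    for j in range(n):
        if s_sums[j] == 0:
            if t_sums[j] > 0:
                warnings.warn(
                    f"distance {j}: source diagonal sum is zero; skipped"
                )
            continue
        k[j] = t_sums[j] / s_sums[j]
        if rt[j] > 0 and rs[j] > 0:
            err[j] = float(np.sqrt(1.0 / rt[j] + 1.0 / rs[j]))
        applied[j] = err[j] <= error_gate
    return CompressionCoefficients(
        k=k, error=err, applied=applied,
        target_sums=t_sums, source_sums=s_sums, error_gate=error_gate,
    )


def apply_compression(source, coeffs: CompressionCoefficients) -> ContactMap:
    """Multiply each applied intra-chromosomal diagonal by its K_j, leave
    trans contacts untouched, then rescale the whole matrix back to the
    source's original total."""
    m = as_map(source)
    binning = m.binning
    if len(coeffs.k) != max(
        binning.chrom_nbins(c) for c in range(binning.n_chromosomes)
    ):
        raise BinningMismatchError("coefficients were computed for a "
                                   "different binning")
    out = m.counts.copy()
    eff = coeffs.effective
    for ci in range(binning.n_chromosomes):
        sl = binning.chrom_slice(ci)
        nb = sl.stop - sl.start
        sep = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
        out[sl, sl] = out[sl, sl] * eff[sep]
    total = out.sum()
    if total > 0:
        out *= m.total / total
    return ContactMap(binning, out, value_kind=m.value_kind, mask=m.mask.copy())
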