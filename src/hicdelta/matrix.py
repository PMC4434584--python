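"""Binned contact-map data model, text I/O and matrix balancing.

The central objects are :class:`GenomeBinning` (the coordinate authority:
a fixed-size partition of a multi-chromosome genome into 0-based half-open
bins with a genome-wide bin index) and :class:`ContactMap` (a symmetric,
non-negative matrix of contact support between bins).  Maps are stored
densely; on disk the canonical format is an upper-triangle sparse triplet
TSV together with a two-column chromosome-sizes file.

Balancing (:func:`iterative_correction`) removes multiplicative per-bin
biases so that every unmasked bin has the same total visibility, and
rescales the result back to the input total.  The read-support error model
(:func:`interaction_error`) and the mappability rule
(:func:`mappable_contacts`) always operate on raw read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ContactMapError",
    "FormatError",
    "BinningMismatchError",
    "BalanceError",
    "GenomeBinning",
    "ContactMap",
    "CorrectedMap",
    "read_chrom_sizes",
    "read_contact_map",
    "write_contact_map",
    "write_dense",
    "write_biases",
    "read_biases",
    "iterative_correction",
    "interaction_error",
    "mappable_contacts",
]


class ContactMapError(ValueError):
    """Invalid contact-map content or construction."""


class FormatError(ContactMapError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


class BinningMismatchError(ContactMapError):
    """Two maps/tracks do not share a binning."""


class BalanceError(RuntimeError):
    """Iterative correction failed (non-convergence or no usable bins)."""


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeBinning:
    """Partition of a multi-chromosome genome into fixed-size bins.

    Bins are 0-based half-open intervals that tile each chromosome in file
    order without gaps or overlaps; every bin except possibly the last one
    per chromosome has length ``bin_size``.  The genome-wide bin index runs
    over concatenated chromosomes.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Bin width in base pairs.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int

    # derived, filled in __post_init__
    _offsets: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        if not chroms:
            raise ContactMapError("binning requires at least one chromosome")
        if self.bin_size <= 0:
            raise ContactMapError("bin_size must be positive")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ContactMapError("duplicate chromosome names")
        for n, l in chroms:
            if l <= 0:
                raise ContactMapError(f"chromosome {n!r} has non-positive length")
        nbins = [-(-l // self.bin_size) for _, l in chroms]  # ceil division
        offsets = np.concatenate([[0], np.cumsum(nbins)])
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "_offsets", offsets)

    # -- basic queries ------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return int(self._offsets[-1])

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def chrom_lengths(self) -> tuple[int, ...]:
        return tuple(l for _, l in self.chromosomes)

    def chrom_nbins(self, c) -> int:
        i = self._chrom_index(c)
        return int(self._offsets[i + 1] - self._offsets[i])

    def _chrom_index(self, c) -> int:
        if isinstance(c, (int, np.integer)):
            return int(c)
        for i, (n, _) in enumerate(self.chromosomes):
            if n == c:
                return i
        raise KeyError(f"unknown chromosome {c!r}")

    def chrom_slice(self, c) -> slice:
        """Genome-wide bin-index slice covering chromosome ``c``."""
        i = self._chrom_index(c)
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    @property
    def bin_chrom(self) -> np.ndarray:
        """Per-bin chromosome index (int array of length n_bins)."""
        out = np.empty(self.n_bins, dtype=np.int64)
        for i in range(self.n_chromosomes):
            out[self._offsets[i]:self._offsets[i + 1]] = i
        return out

    @property
    def bin_start(self) -> np.ndarray:
        starts = np.empty(self.n_bins, dtype=np.int64)
        for i in range(self.n_chromosomes):
            n = self._offsets[i + 1] - self._offsets[i]
            starts[self._offsets[i]:self._offsets[i + 1]] = (
                np.arange(n) * self.bin_size
            )
        return starts

    @property
    def bin_end(self) -> np.ndarray:
        ends = self.bin_start + self.bin_size
        lengths = np.asarray(self.chrom_lengths)[self.bin_chrom]
        return np.minimum(ends, lengths)

    def bin_index(self, chrom, pos: int) -> int:
        """Genome-wide index of the bin containing ``pos`` on ``chrom``."""
        i = self._chrom_index(chrom)
        if not 0 <= pos < self.chromosomes[i][1]:
            raise IndexError(f"position {pos} outside chromosome {chrom!r}")
        return int(self._offsets[i]) + pos // self.bin_size

    def bin_location(self, idx: int) -> tuple[str, int, int]:
        """(chromosome, start, end) of genome-wide bin ``idx``."""
        if not 0 <= idx < self.n_bins:
            raise IndexError(f"bin index {idx} out of range")
        c = int(np.searchsorted(self._offsets, idx, side="right")) - 1
        name, length = self.chromosomes[c]
        start = (idx - int(self._offsets[c])) * self.bin_size
        return name, start, min(start + self.bin_size, length)

    def bins(self) -> Iterator[tuple[str, int, int]]:
        for idx in range(self.n_bins):
            yield self.bin_location(idx)

    def intra_mask(self) -> np.ndarray:
        """Boolean matrix: True where both bins are on the same chromosome."""
        c = self.bin_chrom
        return c[:, None] == c[None, :]

    # -- constructors / serialization --------------------------------------

    @classmethod
    def from_chrom_sizes(cls, path, bin_size: int) -> "GenomeBinning":
        return cls(tuple(read_chrom_sizes(path)), bin_size)

    @classmethod
    def from_bin_counts(
        cls, chrom_bins: Sequence[int], bin_size: int = 1_000_000,
        names: Sequence[str] | None = None,
    ) -> "GenomeBinning":
        """Binning with ``chrom_bins[i]`` full bins on chromosome i."""
        if names is None:
            names = [f"chr{i + 1}" for i in range(len(chrom_bins))]
        chroms = tuple(
            (n, int(b) * bin_size) for n, b in zip(names, chrom_bins)
        )
        return cls(chroms, bin_size)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.bins():
                fh.write(f"{chrom}\t{start}\t{end}\n")

    def write_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")

    def __eq__(self, other):
        return (
            isinstance(other, GenomeBinning)
            and self.chromosomes == other.chromosomes
            and self.bin_size == other.bin_size
        )

    def __hash__(self):
        return hash((self.chromosomes, self.bin_size))


def _check_same_binning(a: "ContactMap", b: "ContactMap") -> None:
    if a.binning != b.binning:
        raise BinningMismatchError("maps do not share a binning")


# ---------------------------------------------------------------------------
# contact map
# ---------------------------------------------------------------------------


@dataclass
class ContactMap:
    """Symmetric binned contact matrix.

    ``counts`` holds raw read counts or corrected (real-valued) support.
    ``mask`` flags usable bins (True = usable); in corrected maps masked
    bins carry all-zero rows.  The ``total`` is the plain matrix sum, i.e.
    the diagonal counts once and every off-diagonal entry twice.
    """

    binning: GenomeBinning
    counts: np.ndarray
    value_kind: str = "raw"
    mask: np.ndarray | None = None

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        n = self.binning.n_bins
        if c.shape != (n, n):
            raise ContactMapError(
                f"counts shape {c.shape} does not match {n} bins"
            )
        if not np.allclose(c, c.T, rtol=1e-9, atol=0):
            raise ContactMapError("counts matrix is not symmetric")
        if np.any(c < 0):
            raise ContactMapError("negative contact counts")
        if self.value_kind not in ("raw", "corrected"):
            raise ContactMapError(f"bad value_kind {self.value_kind!r}")
        self.counts = c
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ContactMapError("mask length does not match bins")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins

    def copy(self) -> "ContactMap":
        return ContactMap(
            self.binning, self.counts.copy(), self.value_kind, self.mask.copy()
        )

    def cis_block(self, chrom) -> np.ndarray:
        sl = self.binning.chrom_slice(chrom)
        return self.counts[sl, sl]


@dataclass
class CorrectedMap:
    """Result of iterative correction.

    ``map`` is the balanced :class:`ContactMap` (value_kind="corrected"),
    ``biases`` the per-bin positive multipliers (NaN for masked bins) with
    ``corrected[i, j] == raw[i, j] / (biases[i] * biases[j])``, ``raw`` the
    input map, and ``convergence`` the (iterations, final residual) pair.
    """

    map: ContactMap
    biases: np.ndarray
    raw: ContactMap
    convergence: tuple[int, float]

    @property
    def counts(self) -> np.ndarray:
        return self.map.counts

    @property
    def binning(self) -> GenomeBinning:
        return self.map.binning

    @property
    def mask(self) -> np.ndarray:
        return self.map.mask


def as_map(m) -> ContactMap:
    """Accept a ContactMap or CorrectedMap, return the ContactMap."""
    if isinstance(m, CorrectedMap):
        return m.map
    return m


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> list[tuple[str, int]]:
    """Two-column (name, length) TSV."""
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError("expected two columns", path, ln)
            try:
                out.append((parts[0], int(parts[1])))
            except ValueError:
                raise FormatError(
                    f"bad chromosome length {parts[1]!r}", path, ln
                ) from None
    if not out:
        raise FormatError("empty chromosome-sizes file", path)
    return out


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_contact_map(
    matrix_path, chrom_sizes_path, bin_size: int,
    fmt: str = "auto", value_kind: str = "raw",
) -> ContactMap:
    """Read a contact map from a sparse-triplet or dense TSV.

    Triplet files hold ``bin_i  bin_j  count`` records (header allowed);
    records for one triangle are mirrored, duplicate (i, j) pairs —
    including mirrored duplicates — are an error.  Dense files hold the
    full symmetric matrix, one row per line, no header.
    """
    binning = GenomeBinning.from_chrom_sizes(chrom_sizes_path, bin_size)
    n = binning.n_bins
    path = Path(matrix_path)

    with open(path) as fh:
        lines = fh.readlines()

    # sniff format: triplet is canonical; a dense file is recognized by its
    # first numeric row having one column per bin (for a 3-bin genome the
    # two are ambiguous — pass fmt="dense" explicitly there)
    if fmt == "auto":
        fmt = "triplet"
        for line in lines:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if all(_is_number(p) for p in parts):
                if len(parts) == n and n != 3:
                    fmt = "dense"
                break

    counts = np.zeros((n, n), dtype=float)

    if fmt == "triplet":
        seen: set[tuple[int, int]] = set()
        for ln, line in enumerate(lines, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if not all(_is_number(p) for p in parts):
                continue  # header line
            if len(parts) != 3:
                raise FormatError(
                    f"expected 3 columns, got {len(parts)}", path, ln
                )
            try:
                i, j = int(parts[0]), int(parts[1])
                v = float(parts[2])
            except ValueError:
                raise FormatError(f"malformed record {s!r}", path, ln) from None
            if not (0 <= i < n and 0 <= j < n):
                raise FormatError(
                    f"bin index ({i}, {j}) out of range for {n} bins", path, ln
                )
            if v < 0:
                raise FormatError(f"negative count {v}", path, ln)
            key = (min(i, j), max(i, j))
            if key in seen:
                raise FormatError(f"duplicate record for bins {key}", path, ln)
            seen.add(key)
            counts[i, j] = v
            counts[j, i] = v
    elif fmt == "dense":
        rows = []
        for ln, line in enumerate(lines, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != n:
                raise FormatError(
                    f"expected {n} columns, got {len(parts)}", path, ln
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise FormatError("malformed numeric row", path, ln) from None
        if len(rows) != n:
            raise FormatError(f"expected {n} rows, got {len(rows)}", path)
        counts = np.asarray(rows)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    return ContactMap(binning, counts, value_kind=value_kind)


def write_contact_map(cmap: ContactMap, path) -> None:
    """Upper-triangle sparse triplet TSV (canonical on-disk form)."""
    m = as_map(cmap)
    i, j = np.nonzero(np.triu(m.counts))
    with open(path, "w") as fh:
        fh.write("bin1\tbin2\tcount\n")
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\t{m.counts[a, b]:.17g}\n")


def write_dense(cmap: ContactMap, path) -> None:
    m = as_map(cmap)
    np.savetxt(path, m.counts, fmt="%.17g", delimiter="\t")


def write_biases(corrected: CorrectedMap, path) -> None:
    """Sidecar TSV of per-bin biases (chrom, start, end, bias)."""
    binning = corrected.binning
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tbias\n")
        for idx, (chrom, start, end) in enumerate(binning.bins()):
            fh.write(f"{chrom}\t{start}\t{end}\t{corrected.biases[idx]:.17g}\n")


def read_biases(path) -> np.ndarray:
    vals = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 4 and _is_number(parts[3]):
                vals.append(float(parts[3]))
    return np.asarray(vals)


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------


def iterative_correction(
    cmap: ContactMap,
    tolerance: float = 1e-6,
    max_iter: int = 200,
    mask_percentile: float = 0.0,
) -> CorrectedMap:
    """Balance a contact map so all unmasked bins have equal row sums.

    Alternating (Sinkhorn-style) normalization: at each step row sums over
    unmasked bins are driven to their mean; the accumulated per-bin factors
    are the biases.  Bins with zero marginal — and optionally the bottom
    ``mask_percentile`` percent of coverage — are masked before balancing.
    The output is rescaled so its total equals the input total.

    Raises
    ------
    BalanceError
        If no bin survives masking, or the residual (max relative deviation
        of row sums from their mean) is still above ``tolerance`` after
        ``max_iter`` iterations.
    """
    raw = cmap.counts
    n = cmap.n_bins
    marginal = raw.sum(axis=1)
    mask = (marginal > 0) & cmap.mask
    if mask_percentile > 0 and mask.any():
        thr = np.percentile(marginal[mask], mask_percentile)
        mask &= marginal > thr
    if not mask.any():
        raise BalanceError("all bins masked; nothing to balance")

    sub = raw[np.ix_(mask, mask)].astype(float)
    m = sub.shape[0]
    biases_sub = np.ones(m)
    residual = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        s = sub.sum(axis=1)
        mean = s.mean()
        if mean == 0:
            raise BalanceError("zero total among unmasked bins")
        target = s / mean
        residual = float(np.abs(target - 1).max())
        if residual < tolerance:
            break
        # guard bins that momentarily hit zero row sum
        target[target == 0] = 1.0
        sub /= np.outer(target, target)
        biases_sub *= target
    else:
        raise BalanceError(
            f"no convergence after {max_iter} iterations "
            f"(residual {residual:.3g} > tolerance {tolerance:.3g})"
        )

    # reconstruct exactly from biases so corrected == raw/(b_i b_j) holds,
    # then fold the global rescale (output total == input total) into them
    biases = np.full(n, np.nan)
    biases[mask] = biases_sub
    corrected = np.zeros_like(raw, dtype=float)
    idx = np.ix_(mask, mask)
    corrected[idx] = raw[idx] / np.outer(biases_sub, biases_sub)
    current = corrected.sum()
    if current > 0:
        scale = cmap.total / current
        biases[mask] /= np.sqrt(scale)
        corrected[idx] = raw[idx] / np.outer(biases[mask], biases[mask])

    out = ContactMap(cmap.binning, corrected, value_kind="corrected", mask=mask)
    return CorrectedMap(
        map=out, biases=biases, raw=cmap, convergence=(iterations, residual)
    )


# ---------------------------------------------------------------------------
# read-support error model & mappability
# ---------------------------------------------------------------------------


def interaction_error(K):
    """Relative error of a contact supported by ``K`` raw reads: sqrt(K)/K.

    Accepts a scalar or array; every entry must be positive (the error is
    undefined for unsupported contacts).
    """
    arr = np.asarray(K, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("interaction error undefined for K <= 0")
    out = np.sqrt(arr) / arr
    return float(out) if np.ndim(K) == 0 else out


def mappable_contacts(cmap: ContactMap) -> set[tuple[int, int]]:
    """Bin pairs supported by more than one raw read, reported once (i <= j)."""
    m = as_map(cmap)
    i, j = np.nonzero(np.triu(m.counts >= 2))
    return set(zip(i.tolist(), j.tolist()))


def mappable_mask(counts: np.ndarray) -> np.ndarray:
    """Boolean matrix of the >1-read mappability rule."""
    return np.asarray(counts) >= 2
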