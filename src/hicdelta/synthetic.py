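"""Synthetic binned contact maps with known ground truth.

Expectation model, per cell type:

* intra-chromosomal pairs decay as ``s**(-alpha)`` with genomic separation
  ``s`` (in bins, the main diagonal treated as s = 1), modulated by a
  multiplicative plaid compartment term ``(1 + e_i * e_j)`` and an optional
  within-TAD enrichment factor;
* trans pairs carry a uniform background holding a configurable fraction
  of the total expected contact mass;
* planted cell-type-specific differences multiply the expectation of the
  selected (bins x partners) rectangle.

The unplanted expectation matrix is normalized so its full (symmetric)
sum equals the requested sequencing depth; planted factors are applied
afterwards so that the cross-cell-type expectation ratio at planted pairs
equals the planted fold exactly.  Sampling is independent Poisson per
unordered pair, mirrored to a symmetric integer map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import yaml

from .matrix import ContactMap, GenomeBinning

__all__ = [
    "PlantedDifference",
    "SyntheticSpec",
    "SyntheticPair",
    "alternating_profile",
    "expected_matrix",
    "expected_count",
    "generate_map",
    "generate_pair",
    "thin_split",
]


@dataclass(frozen=True)
class PlantedDifference:
    """A multiplicative contact gain/loss planted in one cell type.

    ``bins`` is a set of genome-wide bin indices; ``partners`` is a second
    bin set or the string ``"all"``; the expectation of every (bin,
    partner) pair is multiplied by ``factor`` in cell type ``cell_type``.
    """

    cell_type: str
    bins: tuple[int, ...]
    partners: tuple[int, ...] | str
    factor: float

    def __post_init__(self):
        object.__setattr__(self, "bins", tuple(int(b) for b in self.bins))
        if self.partners != "all":
            object.__setattr__(
                self, "partners", tuple(int(b) for b in self.partners)
            )
        if self.factor <= 0:
            raise ValueError("planted factor must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic two-cell-type contact-map pair."""

    chrom_bins: tuple[int, ...]
    bin_size: int = 1_000_000
    alpha: Mapping[str, float] = field(
        default_factory=lambda: {"a": 1.0, "b": 1.0}
    )
    depth: float = 1e6
    trans_weight: float = 0.05
    compartment_profile: tuple[float, ...] | None = None
    tad_boundaries: tuple[tuple[int, ...], ...] | None = None
    tad_factor: float = 1.0
    planted: tuple[PlantedDifference, ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "chrom_bins", tuple(int(b) for b in self.chrom_bins)
        )
        object.__setattr__(self, "alpha", dict(self.alpha))
        object.__setattr__(self, "planted", tuple(self.planted))
        if any(b <= 0 for b in self.chrom_bins):
            raise ValueError("chromosome sizes must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for ct, a in self.alpha.items():
            if a <= 0:
                raise ValueError(f"decay exponent for {ct!r} must be positive")
        if not 0 <= self.trans_weight < 1:
            raise ValueError("trans_weight must be in [0, 1)")
        if self.trans_weight > 0 and len(self.chrom_bins) < 2:
            raise ValueError("trans_weight > 0 needs at least 2 chromosomes")
        n = sum(self.chrom_bins)
        if self.compartment_profile is not None:
            prof = tuple(float(x) for x in self.compartment_profile)
            if len(prof) != n:
                raise ValueError("compartment profile length != bin count")
            if not all(np.isfinite(prof)):
                raise ValueError("compartment amplitudes must be finite")
            if any(abs(x) >= 1 for x in prof):
                raise ValueError(
                    "compartment amplitudes must lie in (-1, 1) to keep "
                    "the plaid factor positive"
                )
            object.__setattr__(self, "compartment_profile", prof)
        if self.tad_factor <= 0:
            raise ValueError("tad_factor must be positive")
        for diff in self.planted:
            if diff.cell_type not in self.alpha:
                raise ValueError(f"unknown cell type {diff.cell_type!r}")
            sets = [diff.bins]
            if diff.partners != "all":
                sets.append(diff.partners)
            for s in sets:
                if any(not 0 <= b < n for b in s):
                    raise ValueError("planted bin outside genome")

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(sorted(self.alpha))

    @property
    def n_bins(self) -> int:
        return sum(self.chrom_bins)

    def binning(self) -> GenomeBinning:
        return GenomeBinning.from_bin_counts(self.chrom_bins, self.bin_size)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "chrom_bins": list(self.chrom_bins),
            "bin_size": self.bin_size,
            "alpha": dict(self.alpha),
            "depth": self.depth,
            "trans_weight": self.trans_weight,
            "tad_factor": self.tad_factor,
            "seed": self.seed,
        }
        if self.compartment_profile is not None:
            d["compartment_profile"] = list(self.compartment_profile)
        if self.tad_boundaries is not None:
            d["tad_boundaries"] = [list(t) for t in self.tad_boundaries]
        d["planted"] = [
            {
                "cell_type": p.cell_type,
                "bins": list(p.bins),
                "partners": ("all" if p.partners == "all" else list(p.partners)),
                "factor": p.factor,
            }
            for p in self.planted
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpec":
        d = dict(d)
        comp = d.get("compartment_profile")
        if comp is None and "compartments" in d:
            c = d.pop("compartments")
            comp = alternating_profile(
                d["chrom_bins"], c["block_bins"], c["amplitude"]
            ).tolist()
        planted = tuple(
            PlantedDifference(
                cell_type=p["cell_type"],
                bins=tuple(p["bins"]),
                partners=("all" if p["partners"] == "all" else tuple(p["partners"])),
                factor=float(p["factor"]),
            )
            for p in d.get("planted", ())
        )
        tads = d.get("tad_boundaries")
        return cls(
            chrom_bins=tuple(d["chrom_bins"]),
            bin_size=int(d.get("bin_size", 1_000_000)),
            alpha=dict(d.get("alpha", {"a": 1.0, "b": 1.0})),
            depth=float(d.get("depth", 1e6)),
            trans_weight=float(d.get("trans_weight", 0.05)),
            compartment_profile=tuple(comp) if comp is not None else None,
            tad_boundaries=tuple(tuple(t) for t in tads) if tads else None,
            tad_factor=float(d.get("tad_factor", 1.0)),
            planted=planted,
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def ground_truth(self) -> dict:
        """Planted bins, exponents and compartment labels for downstream checks."""
        planted_bins = sorted(
            {b for p in self.planted for b in p.bins}
        )
        return {
            "alpha": dict(self.alpha),
            "compartment_profile": (
                list(self.compartment_profile)
                if self.compartment_profile is not None
                else None
            ),
            "planted": self.to_dict()["planted"],
            "planted_bins": planted_bins,
        }


def alternating_profile(
    chrom_bins: Sequence[int], block_bins: int, amplitude: float
) -> np.ndarray:
    """Per-bin signed amplitude alternating in blocks along each chromosome."""
    parts = []
    for nb in chrom_bins:
        idx = np.arange(nb) // block_bins
        parts.append(np.where(idx % 2 == 0, amplitude, -amplitude))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# expectation
# ---------------------------------------------------------------------------


def _planted_multiplier(spec: SyntheticSpec, cell_type: str, n: int) -> np.ndarray | None:
    diffs = [p for p in spec.planted if p.cell_type == cell_type]
    if not diffs:
        return None
    mult = np.ones((n, n))
    for p in diffs:
        rows = np.asarray(p.bins, dtype=int)
        if p.partners == "all":
            cols = np.arange(n)
        else:
            cols = np.asarray(p.partners, dtype=int)
        sel = np.zeros((n, n), dtype=bool)
        sel[np.ix_(rows, cols)] = True
        sel[np.ix_(cols, rows)] = True
        mult[sel] *= p.factor
    return mult


def expected_matrix(spec: SyntheticSpec, cell_type: str) -> np.ndarray:
    """Dense symmetric expectation matrix for one cell type.

    Without planted differences the full-matrix sum equals ``spec.depth``
    exactly (up to float rounding); planted multiplicative differences are
    applied after normalization so fold ratios between cell types are exact.
    """
    if cell_type not in spec.alpha:
        raise KeyError(f"unknown cell type {cell_type!r}")
    alpha = spec.alpha[cell_type]
    n = spec.n_bins
    binning = spec.binning()

    intra = np.zeros((n, n))
    for ci in range(binning.n_chromosomes):
        sl = binning.chrom_slice(ci)
        nb = sl.stop - sl.start
        s = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
        w = np.maximum(s, 1).astype(float) ** (-alpha)
        if spec.compartment_profile is not None:
            e = np.asarray(spec.compartment_profile[sl.start:sl.stop])
            w = w * (1.0 + np.outer(e, e))
        if spec.tad_boundaries is not None and spec.tad_factor != 1.0:
            bounds = spec.tad_boundaries[ci]
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                w[lo:hi, lo:hi] *= spec.tad_factor
        intra[sl, sl] = w

    expectation = np.zeros((n, n))
    intra_mass = (1.0 - spec.trans_weight) * spec.depth
    expectation += intra * (intra_mass / intra.sum())

    if spec.trans_weight > 0:
        trans = (~binning.intra_mask()).astype(float)
        expectation += trans * (spec.trans_weight * spec.depth / trans.sum())

    mult = _planted_multiplier(spec, cell_type, n)
    if mult is not None:
        expectation = expectation * mult
    return expectation


def expected_count(spec: SyntheticSpec, cell_type: str, i: int, j: int) -> float:
    """Expectation of a single matrix entry (full-matrix convention)."""
    n = spec.n_bins
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"bin pair ({i}, {j}) outside genome of {n} bins")
    return float(expected_matrix(spec, cell_type)[i, j])


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


class SyntheticPair(NamedTuple):
    map_a: ContactMap
    map_b: ContactMap
    truth: dict


def _sample_symmetric(
    expectation: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Poisson draw per unordered pair, mirrored into a symmetric matrix."""
    n = expectation.shape[0]
    iu = np.triu_indices(n)
    draws = rng.poisson(expectation[iu]).astype(float)
    out = np.zeros((n, n))
    out[iu] = draws
    out = out + out.T
    out[np.diag_indices(n)] /= 2
    return out


def generate_map(
    spec: SyntheticSpec, cell_type: str, rng: np.random.Generator
) -> ContactMap:
    exp = expected_matrix(spec, cell_type)
    counts = _sample_symmetric(exp, rng)
    return ContactMap(spec.binning(), counts, value_kind="raw")


def _type_signature(spec: SyntheticSpec, cell_type: str) -> int:
    """Stable integer fingerprint of one cell type's generator parameters.

    Child RNG seeds derive from (master seed, signature), so two cell
    types with identical parameters draw identical maps, while any
    parameter difference decorrelates their noise.
    """
    import hashlib

    planted = sorted(
        (p.bins, p.partners, p.factor)
        for p in spec.planted
        if p.cell_type == cell_type
    )
    blob = repr((spec.alpha[cell_type], planted)).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:8], "little")


def generate_pair(spec: SyntheticSpec) -> SyntheticPair:
    """Sample one map per cell type (two cell types required).

    Child seeds are spawned deterministically from the master seed and
    each cell type's parameter fingerprint, so identical per-type
    parameters with the same master seed yield identical maps — and
    repeated runs are bit-identical.
    """
    types = spec.cell_types
    if len(types) != 2:
        raise ValueError(f"generate_pair needs exactly 2 cell types, got {types}")
    maps = {}
    for ct in types:
        seed = np.random.SeedSequence([spec.seed, _type_signature(spec, ct)])
        maps[ct] = generate_map(spec, ct, np.random.default_rng(seed))
    return SyntheticPair(maps[types[0]], maps[types[1]], spec.ground_truth())


def thin_split(
    cmap: ContactMap, seed: int
) -> tuple[ContactMap, ContactMap]:
    """Binomial-thin a raw map into two halves that sum to it exactly.

    Every read is assigned to one half with probability 1/2, independently
    per unordered bin pair.
    """
    if cmap.value_kind != "raw":
        raise ValueError("thin_split requires raw counts")
    counts = cmap.counts
    ints = np.rint(counts).astype(np.int64)
    if not np.allclose(counts, ints):
        raise ValueError("thin_split requires integer read counts")
    rng = np.random.default_rng(seed)
    n = cmap.n_bins
    iu = np.triu_indices(n)
    half = rng.binomial(ints[iu], 0.5).astype(float)
    h1 = np.zeros((n, n))
    h1[iu] = half
    h1 = h1 + h1.T
    h1[np.diag_indices(n)] /= 2
    h2 = counts - h1
    return (
        ContactMap(cmap.binning, h1, value_kind="raw", mask=cmap.mask.copy()),
        ContactMap(cmap.binning, h2, value_kind="raw", mask=cmap.mask.copy()),
    )
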