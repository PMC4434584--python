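"""Per-contact differential testing under the uniform probability model.

Each contact's probability is its support divided by the map's total
support over mappable contacts (pairs backed by more than one raw read).
Contacts passing the normal-approximation gate M*P*(1-P) > 9 in both
datasets are tested with an unpooled two-proportion z statistic; p-values
are Bonferroni-adjusted by the number of gated tests and classified by a
q threshold and a fold-change threshold.

Supports may be corrected (real-valued) map entries; mappability is
always decided on raw read counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import (
    BinningMismatchError,
    ContactMap,
    CorrectedMap,
    as_map,
    mappable_mask,
)

__all__ = [
    "ContactTestTable",
    "contact_probability",
    "normal_approx_ok",
    "two_proportion_pvalue",
    "bonferroni",
    "classify_contacts",
    "contact_test_table",
]

CLASS_UNTESTABLE = "untestable"
CLASS_NOT_SIG = "not_significant"
CLASS_SIG = "significant"
CLASS_SIG_2FOLD = "significant_2fold"


def _support_and_raw(m, raw) -> tuple[ContactMap, np.ndarray]:
    """Resolve (support map, raw counts) from ContactMap/CorrectedMap input."""
    if isinstance(m, CorrectedMap):
        return m.map, m.raw.counts
    if raw is not None:
        return m, as_map(raw).counts
    if m.value_kind != "raw":
        raise ValueError(
            "corrected map passed without raw counts for the mappability rule"
        )
    return m, m.counts


def _total_support(values: np.ndarray, mappable: np.ndarray) -> float:
    """Total support over mappable contacts, each unordered pair counted once."""
    sel = np.triu(mappable)
    return float(values[sel].sum())


def contact_probability(
    cmap, i: int, j: int, raw=None
) -> tuple[float, float, float]:
    """(m, M, P) for one contact under the uniform probability model.

    m is the support of (i, j) — zero if the pair is unmappable; M is the
    total support over mappable contacts; P = m/M.
    """
    support, rawc = _support_and_raw(cmap, raw)
    mapp = mappable_mask(rawc)
    M = _total_support(support.counts, mapp)
    if M == 0:
        raise ValueError("map has no mappable contacts (M == 0)")
    m = float(support.counts[i, j]) if mapp[i, j] else 0.0
    return m, M, m / M


def normal_approx_ok(M: float, P: float) -> bool:
    """Normal-approximation gate for the binomial: M*P*(1-P) > 9."""
    if M < 0 or not 0 <= P <= 1:
        raise ValueError("require M >= 0 and P in [0, 1]")
    return bool(M * P * (1.0 - P) > 9.0)


def two_proportion_pvalue(
    p_a: float, m_a: float, p_b: float, m_b: float, as_printed: bool = False
) -> tuple[float, float]:
    """Unpooled two-proportion z test.

    Returns (z, p) with z = (P_a - P_b) / sqrt(P_a(1-P_a)/M_a +
    P_b(1-P_b)/M_b) and the conventional two-sided p = 2*(1 - Phi(|z|)).
    ``as_printed=True`` instead returns 2*Phi(z) - 1 (a confidence level,
    kept for audit of the source formula).
    """
    se = np.sqrt(p_a * (1 - p_a) / m_a + p_b * (1 - p_b) / m_b)
    if se == 0:
        raise ZeroDivisionError("standard error is zero")
    z = (p_a - p_b) / se
    if as_printed:
        p = 2.0 * stats.norm.cdf(z) - 1.0
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bonferroni(p_values, n_tests: int | None = None) -> np.ndarray:
    """q = min(1, p * n_tests); n_tests defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p) if n_tests is None else n_tests
    return np.minimum(1.0, p * n)


@dataclass
class ContactTestTable:
    """Per-contact test results (pairs i <= j) plus test-wide totals."""

    frame: pd.DataFrame
    m_total_a: float
    m_total_b: float
    n_tests: int

    def counts(self) -> dict:
        c = self.frame["cls"].value_counts().to_dict()
        return {
            k: int(c.get(k, 0))
            for k in (CLASS_UNTESTABLE, CLASS_NOT_SIG, CLASS_SIG, CLASS_SIG_2FOLD)
        }

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _ratio(p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.maximum(p_a / p_b, p_b / p_a)
    return r


def classify_contacts(
    table: ContactTestTable, q_threshold: float = 0.05, fold: float = 2.0
) -> tuple[pd.Series, dict]:
    """(Re)classify a test table at the given thresholds.

    significant iff q < q_threshold; significant_2fold additionally needs
    a probability ratio above ``fold``.  Returns (labels, class counts).
    """
    f = table.frame
    cls = np.full(len(f), CLASS_UNTESTABLE, dtype=object)
    tested = np.isfinite(f["q"].to_numpy())
    q = f["q"].to_numpy()
    ratio = f["ratio"].to_numpy()
    sig = tested & (q < q_threshold)
    cls[tested & ~sig] = CLASS_NOT_SIG
    cls[sig & ~(ratio > fold)] = CLASS_SIG
    cls[sig & (ratio > fold)] = CLASS_SIG_2FOLD
    labels = pd.Series(cls, index=f.index, name="cls")
    table.frame["cls"] = labels
    counts = table.counts()
    return labels, counts


def contact_test_table(
    map_a,
    map_b,
    raw_a=None,
    raw_b=None,
    q_threshold: float = 0.05,
    fold: float = 2.0,
    mappable: str = "both",
    as_printed: bool = False,
) -> ContactTestTable:
    """Run the full differential-contact test between two maps.

    The table covers contacts mappable in both datasets (``mappable=
    "both"``, the default) or in either (``"union"``, in which case the
    unmappable side contributes support zero).  Gated contacts get z, p
    and Bonferroni q values; the rest are untestable.
    """
    sup_a, rawc_a = _support_and_raw(map_a, raw_a)
    sup_b, rawc_b = _support_and_raw(map_b, raw_b)
    if sup_a.binning != sup_b.binning:
        raise BinningMismatchError("maps do not share a binning")

    mapp_a = mappable_mask(rawc_a)
    mapp_b = mappable_mask(rawc_b)
    M_a = _total_support(sup_a.counts, mapp_a)
    M_b = _total_support(sup_b.counts, mapp_b)
    if M_a == 0 or M_b == 0:
        raise ValueError("a map has no mappable contacts")

    if mappable == "both":
        covered = mapp_a & mapp_b
    elif mappable == "union":
        covered = mapp_a | mapp_b
    else:
        raise ValueError(f"unknown mappable mode {mappable!r}")

    bi, bj = np.nonzero(np.triu(covered))
    m_a = np.where(mapp_a[bi, bj], sup_a.counts[bi, bj], 0.0)
    m_b = np.where(mapp_b[bi, bj], sup_b.counts[bi, bj], 0.0)
    p_a = m_a / M_a
    p_b = m_b / M_b

    gate = (M_a * p_a * (1 - p_a) > 9.0) & (M_b * p_b * (1 - p_b) > 9.0)

    var = p_a * (1 - p_a) / M_a + p_b * (1 - p_b) / M_b
    z = np.full(len(bi), np.nan)
    p = np.full(len(bi), np.nan)
    ok = gate & (var > 0)
    se = np.sqrt(var[ok])
    z[ok] = (p_a[ok] - p_b[ok]) / se
    if as_printed:
        p[ok] = 2.0 * stats.norm.cdf(z[ok]) - 1.0
    else:
        p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))

    n_tests = int(ok.sum())
    q = np.full(len(bi), np.nan)
    if n_tests:
        q[ok] = bonferroni(p[ok], n_tests)

    frame = pd.DataFrame(
        {
            "bin1": bi,
            "bin2": bj,
            "p_a": p_a,
            "p_b": p_b,
            "z": z,
            "p": p,
            "q": q,
            "ratio": _ratio(p_a, p_b),
        }
    )
    table = ContactTestTable(
        frame=frame, m_total_a=M_a, m_total_b=M_b, n_tests=n_tests
    )
    classify_contacts(table, q_threshold=q_threshold, fold=fold)
    return table
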