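"""Local/global ancestry arithmetic.

Local ancestry at a marker is the unordered pair of ancestral origins of the
two chromosome copies, drawn from {E (European), N (Native American),
A (African)} and collapsed to one of six diplotype categories
(EE, EN, EA, NN, NA, AA).  This module provides the category algebra and its
dummy coding for regression (EE is the reference category), global ancestry
as the chromosome-average of local-ancestry allele counts, observed and
expected ancestry-switch counts, and f-value (FST-type) ancestry-informative
marker (AIM) selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ancestral population codes, in canonical order.
ANCESTRIES: tuple[str, ...] = ("E", "N", "A")

#: The six unordered diplotype categories, in canonical order.
CATEGORIES: tuple[str, ...] = ("EE", "EN", "EA", "NN", "NA", "AA")

#: Population pair labels used for pairwise f values.
PAIRS: tuple[str, ...] = ("E-N", "E-A", "N-A")

_RANK = {a: i for i, a in enumerate(ANCESTRIES)}

# allele counts (E, N, A) contributed by each category
_CATEGORY_COUNTS: dict[str, tuple[int, int, int]] = {
    "EE": (2, 0, 0),
    "EN": (1, 1, 0),
    "EA": (1, 0, 1),
    "NN": (0, 2, 0),
    "NA": (0, 1, 1),
    "AA": (0, 0, 2),
}


def diplotype_category(ancestry_1: str, ancestry_2: str) -> str:
    """Canonical unordered diplotype label for a pair of ancestry codes.

    Symmetric in its arguments: ``diplotype_category("N", "E") == "EN"``.
    """
    for a in (ancestry_1, ancestry_2):
        if a not in _RANK:
            raise ValueError(f"unknown ancestry code {a!r}; expected one of {ANCESTRIES}")
    first, second = sorted((ancestry_1, ancestry_2), key=_RANK.__getitem__)
    return first + second


def _validate_categories(values: np.ndarray) -> None:
    bad = ~np.isin(values, CATEGORIES)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid diplotype category {values[tuple(idx)]!r} at position {tuple(idx)}"
        )


def dummy_code(
    categories: Sequence[str] | np.ndarray | pd.Series,
    reference: str = "EE",
) -> pd.DataFrame:
    """Indicator columns for the non-reference diplotype categories present.

    One 0/1 column per non-reference category with at least one carrier, named
    ``D_<cat>``; the reference category (EE by default) is the omitted
    baseline.  Categories with no carriers are dropped and logged.
    """
    if reference not in CATEGORIES:
        raise ValueError(f"unknown reference category {reference!r}")
    cats = np.asarray(categories, dtype=object)
    _validate_categories(cats)
    index = categories.index if isinstance(categories, pd.Series) else None
    cols = {}
    absent = []
    for cat in CATEGORIES:
        if cat == reference:
            continue
        ind = (cats == cat).astype(float)
        if ind.any():
            cols[f"D_{cat}"] = ind
        else:
            absent.append(cat)
    if absent:
        logger.debug("dummy_code: categories with no carriers dropped: %s", absent)
    return pd.DataFrame(cols, index=index)


def allele_counts(diplotypes: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-individual, per-marker ancestry allele counts.

    Returns an ``(n_individuals, n_markers, 3)`` integer array of E/N/A allele
    counts; each (individual, marker) slice sums to 2.
    """
    values = np.asarray(diplotypes, dtype=object)
    if values.ndim == 1:
        values = values[None, :]
    _validate_categories(values)
    lut = np.array([_CATEGORY_COUNTS[c] for c in CATEGORIES])
    codes = np.searchsorted(
        np.sort(CATEGORIES), values.astype("U2")
    )  # positions in sorted order
    order = np.argsort(CATEGORIES)
    return lut[order][codes]


def global_from_local(diplotypes: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Global ancestry proportions by averaging local ancestry over markers.

    For each individual, the proportion for population P equals the total
    P-allele count over all markers divided by twice the number of markers;
    rows sum to 1.
    """
    values = np.asarray(diplotypes, dtype=object)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] == 0:
        raise ValueError("global ancestry requires at least one marker")
    counts = allele_counts(values).sum(axis=1)  # (n, 3)
    props = counts / (2.0 * values.shape[1])
    index = diplotypes.index if isinstance(diplotypes, pd.DataFrame) else None
    return pd.DataFrame(props, columns=["ga_E", "ga_N", "ga_A"], index=index)


def expected_switches(model: "SwitchModel | object", z: float) -> tuple[float, float]:
    """Expected diploid ancestry-switch count B and block count B + 1.

    For a 2-way admixed diploid genome, B = (2 x 2 x 0.01) T L z (1 - z) where
    T is generations since admixture, L the chromosome genetic length in cM
    and z the global proportion of one ancestral component.  Symmetric in
    z <-> 1 - z and maximal at z = 0.5.
    """
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"ancestry proportion z must lie in [0, 1]; got {z}")
    b = 0.04 * model.T * model.L * z * (1.0 - z)
    return b, b + 1.0


def count_switches(diplotypes: pd.DataFrame | np.ndarray) -> pd.Series:
    """Observed ancestry switches per individual along the marker order.

    A switch is counted at each adjacent marker pair where the unordered
    diplotype category differs (the minimum-switch reading of hard-called
    diplotype sequences).  Markers must already be in map order.
    """
    values = np.asarray(diplotypes, dtype=object)
    if values.ndim == 1:
        values = values[None, :]
    _validate_categories(values)
    if values.shape[1] < 2:
        warnings.warn("fewer than two markers: switch counts are all zero", stacklevel=2)
        counts = np.zeros(values.shape[0], dtype=int)
    else:
        counts = (values[:, 1:] != values[:, :-1]).sum(axis=1)
    index = diplotypes.index if isinstance(diplotypes, pd.DataFrame) else None
    return pd.Series(counts, index=index, name="switches")


def count_haplotype_switches(haplotypes: np.ndarray) -> np.ndarray:
    """Per-individual switch counts summed over the two haplotypes.

    ``haplotypes`` is an ``(n, 2, n_markers)`` integer array of ancestry codes
    (available from simulation truth; hard-called diplotype input loses phase
    and uses :func:`count_switches` instead).
    """
    hap = np.asarray(haplotypes)
    if hap.ndim != 3 or hap.shape[1] != 2:
        raise ValueError("expected haplotype array of shape (n, 2, n_markers)")
    if hap.shape[2] < 2:
        return np.zeros(hap.shape[0], dtype=int)
    return (hap[:, :, 1:] != hap[:, :, :-1]).sum(axis=(1, 2))


def switch_summary(counts: Iterable[int]) -> tuple[float, float]:
    """Cohort mean and (sample) standard deviation of switch counts."""
    arr = np.asarray(list(counts), dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def aim_f(freq_pop1, freq_pop2):
    """Per-marker f value (two-population FST-type differentiation).

    f = 1 - [p1 (1 - p1) + p2 (1 - p2)] / [2 pbar (1 - pbar)] with
    pbar = (p1 + p2) / 2 -- the standard two-population fixation-index
    estimator.  Zero when the frequencies agree; approaches 1 for fixed
    differences.  Fixed alleles (frequency 0 or 1 in either population) make
    f undefined; those markers yield NaN with a warning and are never
    selected.
    """
    p1 = np.asarray(freq_pop1, dtype=float)
    p2 = np.asarray(freq_pop2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    fixed = (p1 <= 0) | (p1 >= 1) | (p2 <= 0) | (p2 >= 1)
    if np.any(fixed):
        warnings.warn(
            f"{int(np.count_nonzero(fixed))} marker(s) with fixed alleles: f undefined, skipped",
            stacklevel=2,
        )
    pbar = (p1 + p2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        het_within = p1 * (1 - p1) + p2 * (1 - p2)
        f = 1.0 - het_within / (2.0 * pbar * (1.0 - pbar))
    f = np.where(fixed, np.nan, f)
    if np.ndim(freq_pop1) == 0 and np.ndim(freq_pop2) == 0:
        return float(f)
    return f


@dataclass(frozen=True)
class AimScore:
    """Pairwise f values per marker for the three population pairs.

    ``table`` has one row per marker and columns "E-N", "E-A", "N-A";
    NaN marks an undefined (fixed-allele) comparison.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [p for p in PAIRS if p not in self.table.columns]
        if missing:
            raise ValueError(f"AimScore table missing pair columns {missing}")
        vals = self.table[list(PAIRS)].to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= -1e-12) & (vals <= 1 + 1e-12))
        if not ok.all():
            raise ValueError("f values must lie in [0, 1] (or be NaN)")

    @classmethod
    def from_frequencies(cls, freqs: pd.DataFrame) -> "AimScore":
        """Compute all three pairwise f values from a (markers x {E,N,A}) frequency table."""
        table = pd.DataFrame(index=freqs.index)
        for pair in PAIRS:
            a, b = pair.split("-")
            table[pair] = aim_f(freqs[a].to_numpy(), freqs[b].to_numpy())
        return cls(table)


def select_aims(
    scores: AimScore,
    threshold: float = 0.25,
    rule: str = "any_pair",
    pairs: Sequence[str] = ("E-N", "N-A"),
) -> pd.Index:
    """Select ancestry-informative markers by thresholding pairwise f values.

    ``any_pair`` keeps markers whose f exceeds ``threshold`` for at least one
    of the three population pairs; ``both_named_pairs`` requires f above the
    threshold for both pairs in ``pairs`` (default E-N and N-A, the two
    contrasts against the Native American panel).  The ``both_named_pairs``
    selection is always a subset of the ``any_pair`` selection at the same
    threshold, and raising the threshold never enlarges either set.  NaN f
    values never satisfy the threshold.
    """
    table = scores.table
    if rule == "any_pair":
        mask = (table[list(PAIRS)] > threshold).any(axis=1)
    elif rule == "both_named_pairs":
        if len(pairs) != 2 or any(p not in PAIRS for p in pairs):
            raise ValueError(f"pairs must be two of {PAIRS}; got {pairs}")
        mask = (table[list(pairs)] > threshold).all(axis=1)
    else:
        raise ValueError(f"unknown rule {rule!r}; expected 'any_pair' or 'both_named_pairs'")
    return table.index[mask]


def read_local_ancestry(path, markers: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a local-ancestry TSV (individuals x markers).

    Cells are either two-letter categories ("EN") or LAMP-LD-style paired
    integer codes ("01"), mapped as 0=E, 1=N, 2=A per haplotype.
    """
    # "NA" is a real category (Native American / African), not a missing value
    frame = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    digit_map = {"0": "E", "1": "N", "2": "A"}

    def normalise(cell: str) -> str:
        cell = cell.strip()
        if len(cell) != 2:
            raise ValueError(f"malformed local-ancestry cell {cell!r}")
        try:
            if cell[0] in digit_map and cell[1] in digit_map:
                return diplotype_category(digit_map[cell[0]], digit_map[cell[1]])
            return diplotype_category(cell[0], cell[1])
        except ValueError as err:
            raise ValueError(f"malformed local-ancestry cell {cell!r}") from err

    out = frame.map(normalise)
    if markers is not None:
        out = out.loc[:, list(markers)]
    return out


__all__ = [
    "ANCESTRIES",
    "CATEGORIES",
    "PAIRS",
    "AimScore",
    "aim_f",
    "allele_counts",
    "count_haplotype_switches",
    "count_switches",
    "diplotype_category",
    "dummy_code",
    "expected_switches",
    "global_from_local",
    "read_local_ancestry",
    "select_aims",
    "switch_summary",
]
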