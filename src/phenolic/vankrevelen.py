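"""Refined Van Krevelen classification of FT-ICR-MS molecular formulae.

A Van Krevelen diagram places each molecular formula at (O:C, H:C). The
classical "lignin-like" and "tannin-like" regions hide real chemical
distinctions, so the regions used here are refined boundaries derived from
characterized natural substrates, separating lignin from condensed tannins
(CT, flavanol polymers) and hydrolysable tannins (HT, gallo-/ellagitannins):

* lignin: 0.3 < O:C < 0.48 and 1.08 < H:C < 1.28
* hydrolysable tannin: 0.6 < O:C < 0.7 and 0.58 < H:C < 0.89
* condensed tannin: 0.4 < O:C < 0.5 and 0.74 < H:C < 0.88

All inequalities are strict (open intervals), so a formula sitting exactly on
a boundary belongs to no region. The three default regions are pairwise
disjoint, making classification single-valued. Percent polyphenol of a
sample is the intensity-weighted percentage of features falling in any of
the three regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LIGNIN = "lignin"
HT = "HT"
CT = "CT"
NONE_CLASS = "none"
POLYPHENOL_CLASSES = (LIGNIN, HT, CT)


@dataclass(frozen=True)
class Region:
    """Open rectangle in (O:C, H:C) space."""

    oc: tuple[float, float]
    hc: tuple[float, float]

    def contains(self, oc: float, hc: float) -> bool:
        return self.oc[0] < oc < self.oc[1] and self.hc[0] < hc < self.hc[1]

    def overlaps(self, other: "Region") -> bool:
        return (
            self.oc[0] < other.oc[1]
            and other.oc[0] < self.oc[1]
            and self.hc[0] < other.hc[1]
            and other.hc[0] < self.hc[1]
        )


@dataclass(frozen=True)
class ClassBoundaries:
    lignin: Region = Region(oc=(0.3, 0.48), hc=(1.08, 1.28))
    ht: Region = Region(oc=(0.6, 0.7), hc=(0.58, 0.89))
    ct: Region = Region(oc=(0.4, 0.5), hc=(0.74, 0.88))

    def regions(self) -> dict[str, Region]:
        return {LIGNIN: self.lignin, HT: self.ht, CT: self.ct}


DEFAULT_BOUNDARIES = ClassBoundaries()


@dataclass(frozen=True)
class FormulaRecord:
    """One FT-ICR-MS feature: elemental composition plus intensity."""

    sample_id: str
    C: int
    H: int
    O: int
    intensity: float
    N: int = 0
    S: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        if min(self.C, self.H, self.O, self.N, self.S, self.P) < 0:
            raise ValueError("element counts must be non-negative")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


class UnclassifiableFormula(ValueError):
    pass


def classify(
    record: FormulaRecord | tuple[int, int, int],
    boundaries: ClassBoundaries = DEFAULT_BOUNDARIES,
) -> str:
    """Classify one formula by its O:C and H:C ratios.

    Accepts a :class:`FormulaRecord` or a bare (C, H, O) tuple. Heteroatoms
    play no role in classification. Raises for carbon-free formulae, for
    which the ratios are undefined.
    """
    if isinstance(record, FormulaRecord):
        c, h, o = record.C, record.H, record.O
    else:
        c, h, o = record
    if c < 1:
        raise UnclassifiableFormula("formula without carbon cannot be classified")
    oc, hc = o / c, h / c
    for name, region in boundaries.regions().items():
        if region.contains(oc, hc):
            return name
    return NONE_CLASS


def classify_table(
    records: pd.DataFrame, boundaries: ClassBoundaries = DEFAULT_BOUNDARIES
) -> pd.DataFrame:
    """Vectorized classification of a peak-list table.

    Requires columns ``C``, ``H``, ``O``; other columns pass through. Adds
    ``OC``, ``HC`` and ``vk_class``. Rows with C = 0 get class ``none`` and a
    warning (ratios undefined).
    """
    out = records.copy()
    c = out["C"].to_numpy(dtype=float)
    if (c < 1).any():
        warnings.warn(f"{int((c < 1).sum())} carbon-free rows are unclassifiable")
    with np.errstate(divide="ignore", invalid="ignore"):
        oc = np.where(c >= 1, out["O"].to_numpy(dtype=float) / c, np.nan)
        hc = np.where(c >= 1, out["H"].to_numpy(dtype=float) / c, np.nan)
    cls = np.full(len(out), NONE_CLASS, dtype=object)
    for name, region in boundaries.regions().items():
        inside = (
            (oc > region.oc[0]) & (oc < region.oc[1])
            & (hc > region.hc[0]) & (hc < region.hc[1])
        )
        cls[inside] = name
    out["OC"], out["HC"], out["vk_class"] = oc, hc, cls
    return out


def percent_polyphenol(
    records: pd.DataFrame, boundaries: ClassBoundaries = DEFAULT_BOUNDARIES
) -> pd.DataFrame:
    """Per-sample intensity percentages of each polyphenol class.

    ``records`` needs columns ``sample_id``, ``C``, ``H``, ``O``,
    ``intensity``. For each sample: percent of a class = 100 x (summed
    intensity of its features / total summed intensity of all features), and
    ``percent_polyphenol`` = %CT + %HT + %lignin. Samples with zero total
    intensity are undefined and reported as NaN with a warning.
    """
    classified = classify_table(records, boundaries)
    rows = []
    for sample, sub in classified.groupby("sample_id", sort=True):
        total = sub["intensity"].sum()
        if total == 0:
            warnings.warn(f"sample {sample!r} has zero total intensity")
            rows.append(
                {"sample_id": sample, **{f"percent_{c}": np.nan for c in POLYPHENOL_CLASSES},
                 "percent_polyphenol": np.nan}
            )
            continue
        row = {"sample_id": sample}
        for c in POLYPHENOL_CLASSES:
            row[f"percent_{c}"] = 100.0 * sub.loc[sub["vk_class"] == c, "intensity"].sum() / total
        row["percent_polyphenol"] = sum(row[f"percent_{c}"] for c in POLYPHENOL_CLASSES)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def percent_polyphenol_by_group(
    records: pd.DataFrame,
    sample_metadata: pd.DataFrame,
    boundaries: ClassBoundaries = DEFAULT_BOUNDARIES,
    group_cols: tuple[str, ...] = ("habitat", "depth"),
) -> pd.DataFrame:
    """Replicate-averaged class percentages per (habitat, depth) group.

    Percentages are computed per sample first, then averaged across the
    replicates of each group (class-then-average order).
    """
    per_sample = percent_polyphenol(records, boundaries)
    joined = per_sample.join(sample_metadata.loc[per_sample.index, list(group_cols)])
    return joined.groupby(list(group_cols), sort=True).mean()
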