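"""Genus-level talent/dominance metrics and the enzyme-latch statistics.

Two genus-level importance metrics summarize genome-resolved
metatranscriptomes:

* **talent** — the number of unique transformation pathways a genus
  expresses in a habitat (union over depths and replicates); a genus is
  talented when that count reaches the threshold (default 15, derived as the
  empirical upper-tail 0.05 quantile of the observed distribution) in at
  least one habitat.
* **dominance** — the genus's share of summed normalized expression of a
  trophic level's pathway genes, computed per (habitat, depth) stratum and
  averaged over depths within the habitat; a genus is dominant when any
  (trophic level, habitat) average share reaches the threshold (default 10%).

The statistical battery used to evaluate enzyme-latch-style relationships is
also here: two-sided Wilcoxon/Mann-Whitney rank-sum comparisons between
saturated and unsaturated samples, and Pearson correlations with
Benjamini-Hochberg adjustment applied within declared comparison groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_TALENT_THRESHOLD = 15
DEFAULT_DOMINANCE_THRESHOLD = 0.10
DEFAULT_ALPHA = 0.05
_EXACT_MAX_N = 10  # exact rank-sum enumeration up to this group size, no ties


@dataclass
class GenusExpressionProfile:
    """Aggregated expression view of one genus.

    ``expressed_pathways``: habitat -> set of pathway ids expressed by any
    member genome in any sample of that habitat.
    ``trophic_expression``: (trophic_level, habitat, depth) -> summed
    normalized expression of the genus's pathway-member genes.
    """

    genus: str
    expressed_pathways: dict[str, set[int]] = field(default_factory=dict)
    trophic_expression: dict[tuple[str, str, str], float] = field(default_factory=dict)


@dataclass
class MetricResult:
    genus: str
    talented_by_habitat: dict[str, bool]
    talented: bool
    talent_count: int  # max pathways expressed in any single habitat
    dominance_shares: dict[tuple[str, str], float]  # (trophic, habitat) -> mean share
    dominant_by: dict[tuple[str, str], bool]
    dominant: bool
    dominance_share: float  # max average share over (trophic, habitat)


@dataclass
class LatchTestResult:
    label: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    direction: str | None = None
    group: str | None = None
    n: int | None = None
    significant: bool | None = None


# ---------------------------------------------------------------------------
# talent

def talent(
    profiles: list[GenusExpressionProfile],
    threshold: int = DEFAULT_TALENT_THRESHOLD,
) -> dict[str, MetricResult]:
    """Flag genera expressing >= ``threshold`` unique pathways in a habitat."""
    if threshold < 1:
        raise ValueError("talent threshold must be >= 1")
    results = {}
    for prof in profiles:
        by_habitat = {
            h: len(pids) >= threshold for h, pids in sorted(prof.expressed_pathways.items())
        }
        counts = [len(p) for p in prof.expressed_pathways.values()]
        results[prof.genus] = MetricResult(
            genus=prof.genus,
            talented_by_habitat=by_habitat,
            talented=any(by_habitat.values()),
            talent_count=max(counts, default=0),
            dominance_shares={},
            dominant_by={},
            dominant=False,
            dominance_share=0.0,
        )
    return results


# ---------------------------------------------------------------------------
# dominance

def dominance(
    profiles: list[GenusExpressionProfile],
    threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
) -> dict[str, MetricResult]:
    """Flag genera holding >= ``threshold`` average share of a trophic level.

    Share is computed per (trophic level, habitat, depth) stratum as the
    genus's summed expression over the total across genera, then averaged
    over the depths of each habitat. Strata with zero community-wide
    expression are undefined and excluded from the average (with a warning).
    """
    if not (0 < threshold <= 1):
        raise ValueError("dominance threshold must be in (0, 1]")
    totals: dict[tuple[str, str, str], float] = {}
    for prof in profiles:
        for key, val in prof.trophic_expression.items():
            totals[key] = totals.get(key, 0.0) + val

    dead = sorted(k for k, v in totals.items() if v == 0)
    if dead:
        warnings.warn(
            f"strata with zero total expression excluded from dominance: {dead[:5]}"
        )

    results = {}
    for prof in profiles:
        # collect per-stratum shares keyed by (trophic, habitat)
        shares: dict[tuple[str, str], list[float]] = {}
        for (troph, habitat, depth), total in sorted(totals.items()):
            if total == 0:
                continue
            val = prof.trophic_expression.get((troph, habitat, depth), 0.0)
            shares.setdefault((troph, habitat), []).append(val / total)
        mean_shares = {k: float(np.mean(v)) for k, v in shares.items()}
        # inclusive threshold with an absolute guard so a share that is
        # exactly 10% up to float rounding still qualifies
        dominant_by = {k: s >= threshold - 1e-12 for k, s in mean_shares.items()}
        results[prof.genus] = MetricResult(
            genus=prof.genus,
            talented_by_habitat={},
            talented=False,
            talent_count=0,
            dominance_shares=mean_shares,
            dominant_by=dominant_by,
            dominant=any(dominant_by.values()),
            dominance_share=max(mean_shares.values(), default=0.0),
        )
    return results


def genus_metrics(
    profiles: list[GenusExpressionProfile],
    talent_threshold: int = DEFAULT_TALENT_THRESHOLD,
    dominance_threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
) -> pd.DataFrame:
    """Combined talent + dominance table, one row per genus."""
    tal = talent(profiles, talent_threshold)
    dom = dominance(profiles, dominance_threshold)
    rows = []
    for prof in profiles:
        t, d = tal[prof.genus], dom[prof.genus]
        rows.append(
            {
                "genus": prof.genus,
                "talent_count": t.talent_count,
                "talented": t.talented,
                "dominance_share": d.dominance_share,
                "dominant": d.dominant,
                "talented_or_dominant": t.talented or d.dominant,
            }
        )
    return pd.DataFrame(rows).set_index("genus").sort_index()


def build_genus_profiles(
    genomes,
    db,
    statuses,
    normalized: pd.DataFrame,
    metadata: pd.DataFrame,
) -> list[GenusExpressionProfile]:
    """Aggregate genome-level pathway statuses and expression to genus level.

    ``statuses`` is the genome x pathway sweep from the distillation step
    (carrying per-sample expressed flags); ``normalized`` the geTMM matrix.
    Expressed-pathway sets take the union over a genus's member genomes and
    over all samples of each habitat. Trophic-level expression sums geTMM
    over every gene annotated to a pathway-member family, attributed to each
    trophic level the gene's pathways belong to.
    """
    genus_of = {g.genome_id: g.genus for g in genomes}
    habitat_of = metadata["habitat"].to_dict()
    depth_of = metadata["depth"].to_dict()

    expressed: dict[str, dict[str, set[int]]] = {}
    for s in statuses:
        genus = genus_of[s.genome_id]
        for sample in s.expressed_in:
            expressed.setdefault(genus, {}).setdefault(
                habitat_of[sample], set()
            ).add(s.pathway_id)

    # gene -> trophic levels of the pathways its families belong to
    family_trophics: dict[str, set[str]] = {}
    for pid, pw in db.pathways.items():
        for step in pw.steps:
            for fid in step:
                family_trophics.setdefault(fid, set()).add(pw.trophic_level)

    trophic_expr: dict[str, dict[tuple[str, str, str], float]] = {}
    norm_index = set(normalized.index)
    for genome in genomes:
        genus = genome.genus
        for ann in genome.annotations:
            if ann.gene_id not in norm_index:
                continue
            for troph in family_trophics.get(ann.family_id, ()):
                row = normalized.loc[ann.gene_id]
                for sample, value in row.items():
                    key = (troph, habitat_of[sample], depth_of[sample])
                    d = trophic_expr.setdefault(genus, {})
                    d[key] = d.get(key, 0.0) + float(value)

    genera = sorted({g.genus for g in genomes})
    return [
        GenusExpressionProfile(
            genus=g,
            expressed_pathways=expressed.get(g, {}),
            trophic_expression=trophic_expr.get(g, {}),
        )
        for g in genera
    ]


# ---------------------------------------------------------------------------
# empirical threshold derivation

@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    tail_fraction: float
    attainable: bool


def empirical_threshold(values, alpha: float = DEFAULT_ALPHA) -> ThresholdResult:
    """Smallest observed value whose upper-tail fraction is <= ``alpha``.

    This is how a metric cutoff is anchored to the community-wide
    distribution: a genus at or above the threshold sits in the extreme
    ``alpha`` tail. When no observed value has a small enough tail (e.g. all
    values identical), the result is flagged unattainable and the threshold
    is placed just above the maximum.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty value distribution")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    n = vals.size
    for t in np.unique(vals):  # ascending support
        tail = float((vals >= t).sum()) / n
        if tail <= alpha:
            return ThresholdResult(float(t), tail, True)
    top = float(vals.max())
    eps = np.spacing(abs(top)) if top != 0 else np.finfo(float).eps
    return ThresholdResult(top + eps, 0.0, False)


# ---------------------------------------------------------------------------
# rank-sum comparison

def compare_by_saturation(
    values, saturation_labels, group_names: tuple[str, str] = ("saturated", "unsaturated")
) -> LatchTestResult:
    """Two-sided rank-sum test between the two saturation groups.

    Uses exact enumeration when both groups have <= 10 observations and the
    pooled data carry no ties, and the tie-corrected normal approximation
    (with continuity correction) otherwise.
    """
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(saturation_labels))
    a = values[labels == group_names[0]]
    b = values[labels == group_names[1]]
    for name, grp in zip(group_names, (a, b)):
        if grp.size == 0:
            raise ValueError(f"group {name!r} is empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= _EXACT_MAX_N and b.size <= _EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = "greater" if np.median(a) > np.median(b) else (
        "less" if np.median(a) < np.median(b) else "equal"
    )
    return LatchTestResult(
        label=f"{group_names[0]} vs {group_names[1]}",
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        direction=direction,
        n=int(pooled.size),
    )


# ---------------------------------------------------------------------------
# BH-adjusted correlations

def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjustment (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def correlate_with_bh(
    pair_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Pearson correlations with BH adjustment within comparison groups.

    ``pair_table`` needs columns ``group``, ``label``, ``x``, ``y`` where each
    distinct ``label`` names one correlation (rows are its paired
    observations). Adjustment pools p-values *within* each ``group`` only —
    the grouping is an explicit analysis choice, never inferred. Correlations
    with a zero-variance variable are reported with undefined (NaN) r and p
    and excluded from adjustment.
    """
    required = {"group", "label", "x", "y"}
    if not required <= set(pair_table.columns):
        raise ValueError(f"pair table must have columns {sorted(required)}")
    rows = []
    for (group, label), sub in pair_table.groupby(["group", "label"], sort=True):
        xy = sub[["x", "y"]].dropna()
        if len(xy) < 3:
            raise ValueError(f"correlation {label!r}: need >= 3 complete pairs")
        x, y = xy["x"].to_numpy(), xy["y"].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((group, label, np.nan, np.nan, len(xy)))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((group, label, float(r), float(p), len(xy)))
    out = pd.DataFrame(rows, columns=["group", "label", "r", "p_value", "n"])
    out["p_adjusted"] = np.nan
    for _, idx in out.groupby("group").groups.items():
        keep = [i for i in idx if pd.notna(out.loc[i, "p_value"])]
        if keep:
            out.loc[keep, "p_adjusted"] = benjamini_hochberg(out.loc[keep, "p_value"])
    out["significant"] = out["p_adjusted"] < alpha
    out["direction"] = np.sign(out["r"]).map({1.0: "positive", -1.0: "negative", 0.0: "none"})
    return out
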