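"""Count filtering and geTMM normalization (gene-length-corrected TMM).

geTMM makes metatranscriptome expression comparable both across samples and
across genes: raw counts are first converted to reads-per-kilobase (RPK),
removing gene-length bias, and the RPK matrix is then scaled per sample by a
trimmed-mean-of-M-values (TMM) factor and per-million scaled. TMM assumes
most genes are not differentially expressed between a sample and a reference
sample, estimates each sample's scaling factor from the doubly trimmed,
precision-weighted mean of gene-wise log2 expression ratios (M-values), and
is robust to a minority of highly expressed genes that would distort naive
library-size scaling.

The TMM computation here follows the canonical definition: reference sample
chosen by the 75th-percentile rule, M/A computed over genes positive in both
samples (no pseudo-counts), a 30% two-sided trim on M and a 5% trim on A,
inverse-asymptotic-variance weights, and factors rescaled to geometric mean
one. All tuning parameters are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_MIN_COUNT = 5
DEFAULT_TRIM_M = 0.30
DEFAULT_TRIM_A = 0.05


@dataclass
class CountMatrix:
    """Gene x sample raw counts with per-gene lengths and sample metadata."""

    counts: pd.DataFrame  # genes x samples, non-negative
    gene_lengths: pd.Series  # bp per gene
    sample_metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = set(self.counts.index) - set(self.gene_lengths.index)
        if missing:
            raise ValueError(
                f"genes missing lengths: {sorted(missing)[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        bad = self.gene_lengths.loc[list(self.counts.index)]
        bad = bad[bad <= 0]
        if len(bad):
            raise ValueError(f"non-positive gene lengths: {sorted(bad.index)[:10]}")
        if len(self.sample_metadata):
            uncovered = set(self.counts.columns) - set(self.sample_metadata.index)
            if uncovered:
                raise ValueError(f"samples missing metadata: {sorted(uncovered)}")


@dataclass
class NormalizedMatrix:
    getmm: pd.DataFrame  # genes x samples, per-million scale
    tmm_factors: pd.Series  # per sample, geometric mean 1
    reference_sample: str


def filter_counts(
    counts: pd.DataFrame, min_count: int = DEFAULT_MIN_COUNT, per: str = "cell"
) -> pd.DataFrame:
    """Zero out low counts; dimensions are unchanged.

    ``per="cell"`` (default) zeroes individual cells below ``min_count``;
    ``per="gene"`` zeroes whole gene rows whose maximum count across samples
    is below ``min_count``.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    out = counts.copy()
    if per == "cell":
        out[out < min_count] = 0
    elif per == "gene":
        out.loc[out.max(axis=1) < min_count] = 0
    else:
        raise ValueError(f"unknown filter mode {per!r}")
    return out


def rpk(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase: count / (length / 1000)."""
    missing = set(counts.index) - set(gene_lengths.index)
    if missing:
        raise ValueError(f"genes missing lengths: {sorted(missing)}")
    kb = gene_lengths.loc[list(counts.index)].astype(float) / 1000.0
    return counts.div(kb, axis=0)


def _choose_reference(mat: np.ndarray) -> int:
    # sample whose 75th-percentile count proportion is closest to the mean
    lib = mat.sum(axis=0)
    q75 = np.array(
        [
            np.quantile(mat[:, j], 0.75) / lib[j] if lib[j] > 0 else 0.0
            for j in range(mat.shape[1])
        ]
    )
    return int(np.argmin(np.abs(q75 - q75.mean())))


def _pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_M: float,
    trim_A: float,
    weighted: bool = True,
) -> tuple[float, dict]:
    """TMM factor of one sample against the reference (log2 scale math)."""
    N, R = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    diag: dict = {"n_pairs": int(both.sum())}
    if N == 0 or R == 0 or both.sum() == 0:
        warnings.warn("empty overlap between sample and reference; factor = 1")
        return 1.0, diag
    x, r = obs[both], ref[both]
    M = np.log2((x / N) / (r / R))
    A = 0.5 * np.log2((x / N) * (r / R))
    w = (N - x) / (N * x) + (R - r) / (R * r)  # asymptotic variance of M
    diag.update(M=M, A=A, weights=w)
    if both.sum() == 1:
        warnings.warn("single shared positive gene; factor = 1")
        return 1.0, diag
    if np.max(np.abs(M)) < 1e-6:
        return 1.0, diag
    n = len(M)
    lo_m = int(np.floor(n * trim_M)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_A)) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(M)
    rank_a = rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    diag["kept"] = keep
    if not keep.any():
        warnings.warn("double trim removed every gene; factor = 1")
        return 1.0, diag
    if weighted:
        f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    else:
        f = np.mean(M[keep])
    if not np.isfinite(f):
        return 1.0, diag
    return float(2.0 ** f), diag


def tmm_factors(
    rpk_matrix: pd.DataFrame,
    trim_M: float = DEFAULT_TRIM_M,
    trim_A: float = DEFAULT_TRIM_A,
    weighted: bool = True,
) -> tuple[pd.Series, str]:
    """Per-sample TMM factors on an RPK matrix, geometric mean rescaled to 1.

    Returns ``(factors, reference_sample)``. Degenerate samples (no overlap
    with the reference, or a single shared gene) get factor 1 with a warning.

    ``weighted=True`` (default) uses the canonical inverse-asymptotic-variance
    weights on the trimmed M-values; because those weights depend on library
    depth, scaling a single library is then only approximately neutral
    (relative drift around 1e-3). ``weighted=False`` takes the plain trimmed
    mean, which is exactly invariant to per-sample scaling.
    """
    if rpk_matrix.shape[1] < 1:
        raise ValueError("need at least one sample")
    mat = rpk_matrix.to_numpy(dtype=float)
    ref_idx = _choose_reference(mat)
    ref = mat[:, ref_idx]
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            factors[j] = 1.0
            continue
        factors[j], _ = _pair_factor(mat[:, j], ref, trim_M, trim_A, weighted)
    # rescale so factors multiply to one: keeps geTMM on a symmetric scale
    factors = factors / np.exp(np.mean(np.log(factors)))
    return (
        pd.Series(factors, index=rpk_matrix.columns, name="tmm_factor"),
        str(rpk_matrix.columns[ref_idx]),
    )


def getmm(
    matrix: CountMatrix,
    min_count: int | None = None,
    trim_M: float = DEFAULT_TRIM_M,
    trim_A: float = DEFAULT_TRIM_A,
    weighted: bool = True,
) -> NormalizedMatrix:
    """Full geTMM transform of a (filtered) count matrix.

    geTMM_ij = RPK_ij / (libsize_j * factor_j) * 1e6, with libsize_j the
    column sum of the RPK matrix. Pass ``min_count`` to apply the global
    count filter first; leave it None when the matrix is already filtered.
    An all-zero sample normalizes to zeros with a warning.
    """
    counts = matrix.counts
    if min_count is not None:
        counts = filter_counts(counts, min_count)
    rpk_mat = rpk(counts, matrix.gene_lengths)
    factors, ref_sample = tmm_factors(rpk_mat, trim_M, trim_A, weighted)
    lib = rpk_mat.sum(axis=0)
    zero = lib[lib == 0].index
    if len(zero):
        warnings.warn(f"all-zero samples normalize to zeros: {sorted(zero)}")
    denom = (lib * factors).replace(0, np.nan)
    out = rpk_mat.div(denom, axis=1).fillna(0.0) * 1e6
    return NormalizedMatrix(getmm=out, tmm_factors=factors, reference_sample=ref_sample)
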