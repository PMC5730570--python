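"""Expression-matrix preprocessing and SAM-style differential expression.

The processing order is: detection filter → quantile normalization →
log2 transform → moderated difference statistic (d) with exhaustive
label-permutation FDR → DEG calling at FDR and |log2FC| thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Condition = Literal["A", "B"]


class ExpressionInputError(ValueError):
    """Raised when an expression matrix violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Genes × samples intensity matrix with per-cell detection flags.

    Parameters
    ----------
    values
        DataFrame of positive intensities, index = gene ids,
        columns = sample ids.
    detected
        Boolean DataFrame of the same shape (present/absent calls).
    condition
        Mapping sample id → ``"A"`` or ``"B"``. Condition A is the
        reference (stem-like) group; log2 fold changes are B − A.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    condition: dict[str, Condition]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ExpressionInputError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ExpressionInputError("duplicate sample ids")
        if self.detected.shape != self.values.shape:
            raise ExpressionInputError("detection flags shape mismatch")
        missing = set(self.values.columns) - set(self.condition)
        if missing:
            raise ExpressionInputError(
                f"samples without condition label: {sorted(missing)}"
            )
        labels = {self.condition[s] for s in self.values.columns}
        if self.values.shape[1] and labels != {"A", "B"}:
            raise ExpressionInputError(
                f"both conditions must be present, got {sorted(labels)}"
            )
        self.detected = self.detected.loc[self.values.index, self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, cond: Condition) -> list[str]:
        return [s for s in self.values.columns if self.condition[s] == cond]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            detected=self.detected.loc[values.index, values.columns],
            condition=dict(self.condition),
        )


@dataclass
class DEResult:
    """Per-gene differential-expression statistics and calls.

    ``table`` columns: ``d`` (moderated difference statistic), ``log2fc``
    (mean log2 B − mean log2 A), ``fdr``, ``call`` ∈ {``up_in_B``,
    ``up_in_A``, ``not_de``}.
    """

    table: pd.DataFrame
    s0: float
    fdr_threshold: float = 0.001
    lfc_threshold: float = 1.0
    n_permutations: int = 0
    exhaustive: bool = True

    def up_in(self, cond: Condition) -> set[str]:
        call = "up_in_B" if cond == "B" else "up_in_A"
        return set(self.table.index[self.table["call"] == call])


def detection_filter(
    matrix: ExpressionMatrix,
    min_frac_a: float = 2 / 3,
    min_frac_b: float = 1.0,
) -> ExpressionMatrix:
    """Retain genes detected in enough samples of either condition.

    A gene is kept iff it is detected in at least
    ``ceil(min_frac_a * |A|)`` samples of condition A **or** at least
    ``ceil(min_frac_b * |B|)`` samples of condition B.  The defaults
    reproduce the 2-of-3 / 2-of-2 rule for a 3-vs-2 design.
    """
    a = matrix.samples_of("A")
    b = matrix.samples_of("B")
    need_a = math.ceil(min_frac_a * len(a))
    need_b = math.ceil(min_frac_b * len(b))
    det = matrix.detected
    keep = (det[a].sum(axis=1) >= need_a) | (det[b].sum(axis=1) >= need_b)
    if not keep.any():
        logger.warning("detection filter removed every gene")
    return matrix.with_values(matrix.values.loc[keep])


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the same empirical distribution.

    The reference distribution is the across-column mean of order
    statistics.  Ties within a column receive the mean of the reference
    values at the tied ranks, so tied input cells stay tied.
    """
    if values.shape[0] < 1 or values.shape[1] < 2:
        raise ExpressionInputError("need >=1 gene and >=2 samples")
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = col[order]
        # assign reference values; average reference over runs of ties
        assigned = reference.copy()
        start = 0
        for end in range(1, len(ranked) + 1):
            if end == len(ranked) or ranked[end] != ranked[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[order, j] = assigned
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log2_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Element-wise log2; rejects non-positive cells by name."""
    arr = values.to_numpy(dtype=float)
    bad = np.argwhere(arr <= 0)
    if bad.size:
        i, j = bad[0]
        raise ExpressionInputError(
            f"non-positive intensity at gene={values.index[i]!r}, "
            f"sample={values.columns[j]!r}: {arr[i, j]}"
        )
    return pd.DataFrame(np.log2(arr), index=values.index, columns=values.columns)


def _d_and_lfc(
    log2_values: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    s0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated difference statistic for one labelling of the columns."""
    a = log2_values[:, idx_a]
    b = log2_values[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    lfc = b.mean(axis=1) - a.mean(axis=1)
    pooled_var = (
        ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / (na + nb - 2)
    s = np.sqrt((1.0 / na + 1.0 / nb) * pooled_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(s + s0 > 0, lfc / (s + s0), 0.0)
    return d, s


def resolve_s0(s: np.ndarray, policy: float | str = "median") -> float:
    """Resolve the variance-stabilizing fudge factor s0.

    ``"median"`` → median of the per-gene standard errors (a common
    simplification of the original percentile search); a float is used
    as-is (``0`` gives the classical two-sample t numerator/denominator).
    """
    if isinstance(policy, str):
        if policy != "median":
            raise ValueError(f"unknown s0 policy {policy!r}")
        return float(np.median(s))
    s0 = float(policy)
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    return s0


def sam_statistic(
    log2_matrix: ExpressionMatrix,
    s0_policy: float | str = "median",
) -> pd.DataFrame:
    """Per-gene (d, log2fc, s) on log2 values, plus the resolved s0.

    d = (mean_B − mean_A) / (s + s0) with s the pooled standard error of
    the mean difference.  Both conditions need ≥2 samples.
    """
    a = log2_matrix.samples_of("A")
    b = log2_matrix.samples_of("B")
    if len(a) < 2 or len(b) < 2:
        raise ExpressionInputError(
            f"need >=2 samples per condition for variance estimation "
            f"(got |A|={len(a)}, |B|={len(b)})"
        )
    vals = log2_matrix.values.to_numpy(dtype=float)
    cols = list(log2_matrix.values.columns)
    idx_a = np.array([cols.index(s_) for s_ in a])
    idx_b = np.array([cols.index(s_) for s_ in b])
    d_raw, s = _d_and_lfc(vals, idx_a, idx_b, s0=0.0)
    lfc = vals[:, idx_b].mean(axis=1) - vals[:, idx_a].mean(axis=1)
    s0 = resolve_s0(s, s0_policy)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(s + s0 > 0, lfc / (s + s0), 0.0)
    out = pd.DataFrame(
        {"d": d, "log2fc": lfc, "s": s}, index=log2_matrix.values.index
    )
    out.attrs["s0"] = s0
    return out


def _distinct_relabelings(n_a: int, n_b: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """All distinct assignments of n_a+n_b columns into groups of those sizes."""
    n = n_a + n_b
    out = []
    for combo in combinations(range(n), n_a):
        idx_a = np.array(combo)
        idx_b = np.array([i for i in range(n) if i not in set(combo)])
        out.append((idx_a, idx_b))
    return out


def sam_fdr(
    log2_matrix: ExpressionMatrix,
    n_perms: int = 1000,
    s0_policy: float | str = "median",
    rng: np.random.Generator | None = None,
) -> DEResult:
    """Permutation FDR for the moderated difference statistic.

    All distinct relabelings of the samples into groups of the original
    sizes are enumerated (C(5,3)=10 for a 3-vs-2 design); if there are
    more than ``n_perms`` they are subsampled with ``rng``.  For a
    threshold t, FDR(t) = median over permutations of #{|d*| ≥ t} divided
    by the observed #{|d| ≥ t} (π0 = 1, capped at 1); each gene gets
    FDR at its own |d|, made monotone non-increasing in |d|.
    """
    stats = sam_statistic(log2_matrix, s0_policy)
    s0 = stats.attrs["s0"]
    a = log2_matrix.samples_of("A")
    b = log2_matrix.samples_of("B")
    cols = list(log2_matrix.values.columns)
    ordered = a + b
    vals = log2_matrix.values[ordered].to_numpy(dtype=float)

    relabelings = _distinct_relabelings(len(a), len(b))
    exhaustive = len(relabelings) <= n_perms
    if not exhaustive:
        rng = rng if rng is not None else np.random.default_rng()
        pick = rng.choice(len(relabelings), size=n_perms, replace=False)
        relabelings = [relabelings[i] for i in sorted(pick)]
    else:
        logger.info(
            "using exhaustive set of %d relabelings (requested %d)",
            len(relabelings),
            n_perms,
        )

    abs_d = np.abs(stats["d"].to_numpy())
    # permuted |d*| counts at each observed threshold, via sorted search
    perm_counts = np.empty((len(relabelings), len(abs_d)))
    for p, (idx_a, idx_b) in enumerate(relabelings):
        d_star, _ = _d_and_lfc(vals, idx_a, idx_b, s0=s0)
        sorted_abs = np.sort(np.abs(d_star))
        # count of |d*| >= t  (ties at t count as called)
        perm_counts[p] = len(sorted_abs) - np.searchsorted(
            sorted_abs, abs_d, side="left"
        )
    median_false = np.median(perm_counts, axis=0)
    sorted_obs = np.sort(abs_d)
    observed = len(abs_d) - np.searchsorted(sorted_obs, abs_d, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed > 0, median_false / observed, 1.0)
    fdr = np.minimum(fdr, 1.0)

    # enforce monotone non-increasing FDR in |d|
    order = np.argsort(-abs_d, kind="mergesort")
    running = np.minimum.accumulate(fdr[order][::-1])[::-1]
    fdr_mono = np.empty_like(fdr)
    fdr_mono[order] = running

    table = pd.DataFrame(
        {
            "d": stats["d"],
            "log2fc": stats["log2fc"],
            "fdr": fdr_mono,
            "call": "not_de",
        },
        index=stats.index,
    )
    return DEResult(
        table=table,
        s0=s0,
        n_permutations=len(relabelings),
        exhaustive=exhaustive,
    )


def call_degs(
    de: DEResult,
    fdr_threshold: float = 0.001,
    lfc_threshold: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Threshold the DE table into (up_in_B, up_in_A) gene sets.

    up_in_B = {fdr < fdr_threshold and log2fc ≥ lfc_threshold};
    up_in_A symmetric with log2fc ≤ −lfc_threshold.  Updates the
    ``call`` column in place.
    """
    t = de.table
    sig = t["fdr"] < fdr_threshold
    up_b = sig & (t["log2fc"] >= lfc_threshold)
    up_a = sig & (t["log2fc"] <= -lfc_threshold)
    t["call"] = np.select([up_b, up_a], ["up_in_B", "up_in_A"], default="not_de")
    de.fdr_threshold = fdr_threshold
    de.lfc_threshold = lfc_threshold
    return set(t.index[up_b]), set(t.index[up_a])
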