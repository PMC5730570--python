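"""Regulator–DEG association tests.

Two complementary routes per regulator: a one-sided Fisher exact test on
target-set / DEG-set overlap (Bonferroni-corrected across regulators),
and a weighted z-score comparing the sum of regulator–gene association
scores over the overlap against a resampled null of equal-size subsets
drawn from the regulator's full target set.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


class EnrichmentInputError(ValueError):
    pass


@dataclass
class RegulatoryNetwork:
    """Scored regulator → gene edges.

    ``edges``: DataFrame with columns ``regulator``, ``gene``, ``score``;
    scores in (0,1], no duplicate (regulator, gene) pairs.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"regulator", "gene", "score"}
        if not required.issubset(self.edges.columns):
            raise EnrichmentInputError(f"edge table needs columns {sorted(required)}")
        s = self.edges["score"].to_numpy(dtype=float)
        if len(s) and (np.any(s <= 0) or np.any(s > 1)):
            raise EnrichmentInputError("scores must lie in (0, 1]")
        if self.edges.duplicated(["regulator", "gene"]).any():
            raise EnrichmentInputError("duplicate (regulator, gene) edges")

    @property
    def regulators(self) -> list[str]:
        return sorted(self.edges["regulator"].unique())

    @property
    def genes(self) -> set[str]:
        return set(self.edges["gene"])

    def target_scores(self, regulator: str) -> dict[str, float]:
        sub = self.edges[self.edges["regulator"] == regulator]
        return dict(zip(sub["gene"], sub["score"].astype(float)))

    def target_set(self, regulator: str) -> set[str]:
        return set(self.edges.loc[self.edges["regulator"] == regulator, "gene"])


@dataclass
class EnrichmentResult:
    """Per-regulator enrichment table (one row per regulator).

    Columns: n_universe, n_deg, n_targets, n_overlap, p_fisher, p_adj,
    significant, aggregate, null_mean, null_sd, z, degenerate.
    z is NaN when the overlap is empty (not computable); degenerate is
    True when the resampled null has zero spread (z forced to 0).
    """

    table: pd.DataFrame
    alpha: float = 0.05
    n_resamples: int = 1000


def fisher_overrepresentation(
    targets: set[str], degs: set[str], universe: set[str]
) -> float:
    """One-sided over-representation p-value, P(X ≥ observed overlap).

    X is hypergeometric with population |universe|, successes |targets|,
    draws |degs|.
    """
    if not universe:
        raise EnrichmentInputError("empty universe")
    stray = degs - universe
    if stray:
        raise EnrichmentInputError(
            f"DEGs outside universe: {sorted(stray)[:10]}"
        )
    stray = targets - universe
    if stray:
        raise EnrichmentInputError(
            f"targets outside universe: {sorted(stray)[:10]}"
        )
    k = len(targets & degs)
    return float(hypergeom.sf(k - 1, len(universe), len(targets), len(degs)))


def bonferroni_adjust(
    pvalues: list[float] | np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """p_adj = min(1, m·p); significant iff p_adj < alpha."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) and (np.any(p < 0) or np.any(p > 1)):
        raise EnrichmentInputError("p-values must lie in [0, 1]")
    adj = np.minimum(1.0, len(p) * p)
    return adj, adj < alpha


def regulator_rng(master_seed: int, regulator: str) -> np.random.Generator:
    """Independent, order-free stream per regulator.

    The substream key is a stable hash of the regulator id, so adding or
    removing other regulators never perturbs this one's null.
    """
    digest = hashlib.blake2b(regulator.encode(), digest_size=8).digest()
    key = int.from_bytes(digest, "big")
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


def weighted_zscore(
    target_scores: dict[str, float],
    degs: set[str],
    n_resamples: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float, float, bool]:
    """Standardize the aggregate score of targets∩DEGs against a resampled null.

    aggregate A = Σ score(g) over g in target∩DEG; the null is the
    aggregate of ``n_resamples`` uniformly drawn subsets of the full
    target set, each of size |target∩DEG| (without replacement within a
    subset).  Returns (aggregate, null_mean, null_sd, z, degenerate);
    sd uses the population convention.  If the null has zero spread,
    z = 0 and degenerate is True.

    Raises on empty overlap: the caller reports the statistic as missing.
    """
    if n_resamples < 1:
        raise EnrichmentInputError("n_resamples must be >= 1")
    overlap = [g for g in target_scores if g in degs]
    k = len(overlap)
    if k == 0:
        raise EnrichmentInputError("empty target/DEG overlap: z not computable")
    aggregate = float(sum(target_scores[g] for g in overlap))
    scores = np.array(sorted(target_scores.values()), dtype=float)
    rng = rng if rng is not None else np.random.default_rng()
    # uniform k-subsets without replacement: order-statistics trick on
    # iid uniform keys (vectorized over all resamples)
    keys = rng.random((n_resamples, len(scores)))
    subset_idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null = scores[subset_idx].sum(axis=1)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    if null_sd == 0.0:
        return aggregate, null_mean, null_sd, 0.0, True
    z = (aggregate - null_mean) / null_sd
    return aggregate, null_mean, null_sd, float(z), False


def enrich_all(
    network: RegulatoryNetwork,
    degs: set[str],
    universe: set[str],
    n_resamples: int = 1000,
    alpha: float = 0.05,
    master_seed: int = 0,
) -> EnrichmentResult:
    """Fisher + weighted-z enrichment for every regulator in the network.

    Target sets and DEGs are intersected with ``universe`` before
    testing.  Each regulator draws its resampling null from its own
    seeded substream derived from ``master_seed``, so results are
    deterministic and order-independent.
    """
    degs_u = degs & universe
    rows = []
    for reg in network.regulators:
        scores = {
            g: s for g, s in network.target_scores(reg).items() if g in universe
        }
        targets = set(scores)
        row: dict[str, object] = {
            "regulator": reg,
            "n_universe": len(universe),
            "n_deg": len(degs_u),
            "n_targets": len(targets),
            "n_overlap": len(targets & degs_u),
        }
        if not targets:
            logger.warning("regulator %s has an empty target set", reg)
            row.update(
                p_fisher=np.nan,
                aggregate=np.nan,
                null_mean=np.nan,
                null_sd=np.nan,
                z=np.nan,
                degenerate=False,
            )
            rows.append(row)
            continue
        row["p_fisher"] = fisher_overrepresentation(targets, degs_u, universe)
        if row["n_overlap"] == 0:
            row.update(
                aggregate=0.0,
                null_mean=np.nan,
                null_sd=np.nan,
                z=np.nan,
                degenerate=False,
            )
        else:
            agg, mu, sd, z, degen = weighted_zscore(
                scores,
                degs_u,
                n_resamples=n_resamples,
                rng=regulator_rng(master_seed, reg),
            )
            row.update(
                aggregate=agg, null_mean=mu, null_sd=sd, z=z, degenerate=degen
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("regulator")
    p = table["p_fisher"].to_numpy(dtype=float)
    # Bonferroni m = number of regulators actually tested (non-NaN p)
    tested = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    adj[tested] = np.minimum(1.0, tested.sum() * p[tested])
    table["p_adj"] = adj
    table["significant"] = np.where(np.isnan(adj), False, adj < alpha)
    cols = [
        "n_universe",
        "n_deg",
        "n_targets",
        "n_overlap",
        "p_fisher",
        "p_adj",
        "significant",
        "aggregate",
        "null_mean",
        "null_sd",
        "z",
        "degenerate",
    ]
    return EnrichmentResult(
        table=table[cols], alpha=alpha, n_resamples=n_resamples
    )
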