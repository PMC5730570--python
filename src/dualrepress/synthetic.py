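"""Synthetic benchmark generators with planted, recorded ground truth.

Every generator is driven by a :class:`SynthConfig` whose ``seed`` fixes
all downstream draws (same config → byte-identical artifacts).  Each
stage derives its own substream from the master seed, so e.g. the
network draw does not shift when sequence parameters change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dualrepress.expression import ExpressionMatrix
from dualrepress.enrichment import RegulatoryNetwork
from dualrepress.seeds import MirnaRecord, scan_region, seed_motifs


class SynthConfigError(ValueError):
    pass


# substream keys, one per generator stage
_EXPR_KEY = 1
_NET_KEY = 2
_SEQ_KEY = 3
_ANNOT_KEY = 4


@dataclass
class SynthConfig:
    """Parameters of the synthetic benchmark.

    Defaults emulate the benchmark's reference design: 3-vs-2
    replicates, ~10% planted differential genes at |log2FC| ≈ 2,
    association scores ~ Beta(2, 2) on (0, 1].
    """

    n_genes: int = 1000
    n_samples_a: int = 3
    n_samples_b: int = 2
    frac_de: float = 0.1
    lfc_mean: float = 2.0
    lfc_sd: float = 0.0
    noise_sd: float = 0.25
    detect_prob: float = 0.95
    n_regulators: int = 10
    target_set_size: int = 100
    planted_regulator_odds: float = 8.0
    score_shape_a: float = 2.0
    score_shape_b: float = 2.0
    n_transcripts: int = 50
    region_len: int = 200
    seed: int = 0
    # intensity model (log2 scale); not part of the minimal surface but
    # needed to place the matrix on a plausible microarray scale
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    annotation_size: int = 50
    annotation_name: str = "SET1"
    frac_dual: float = 0.42
    # score concordance for the planted regulator: its edges to planted
    # up-genes draw scores from Beta(shift·a, b), stochastically larger
    # than background, so the weighted z-score has signal to detect
    planted_score_shift: float = 3.0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_a": self.n_samples_a,
            "n_samples_b": self.n_samples_b,
            "n_regulators": self.n_regulators,
            "target_set_size": self.target_set_size,
            "n_transcripts": self.n_transcripts,
            "region_len": self.region_len,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise SynthConfigError(f"{name} must be a positive integer, got {v}")
        for name, v in {
            "frac_de": self.frac_de,
            "detect_prob": self.detect_prob,
            "frac_dual": self.frac_dual,
        }.items():
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{name} must lie in [0, 1], got {v}")
        for name, v in {
            "noise_sd": self.noise_sd,
            "lfc_sd": self.lfc_sd,
            "baseline_sd": self.baseline_sd,
        }.items():
            if v < 0:
                raise SynthConfigError(f"{name} must be >= 0, got {v}")
        if self.planted_regulator_odds <= 0:
            raise SynthConfigError("planted_regulator_odds must be > 0")
        if self.planted_score_shift <= 0:
            raise SynthConfigError("planted_score_shift must be > 0")
        if self.score_shape_a <= 0 or self.score_shape_b <= 0:
            raise SynthConfigError("score shape parameters must be > 0")
        if self.target_set_size > self.n_genes:
            raise SynthConfigError("target_set_size exceeds n_genes")
        if self.annotation_size > self.n_genes:
            raise SynthConfigError("annotation_size exceeds n_genes")

    def rng(self, stage_key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage_key]))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SynthConfig":
        known = {f for f in cls.__dataclass_fields__}
        stray = set(data) - known
        if stray:
            raise SynthConfigError(f"unknown config keys: {sorted(stray)}")
        return cls(**data)

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def regulator_ids(self) -> list[str]:
        width = len(str(self.n_regulators))
        return [f"R{i:0{width}d}" for i in range(1, self.n_regulators + 1)]

    def sample_ids(self) -> tuple[list[str], list[str]]:
        a = [f"A{i}" for i in range(1, self.n_samples_a + 1)]
        b = [f"B{i}" for i in range(1, self.n_samples_b + 1)]
        return a, b


@dataclass
class TruthRecord:
    """Planted ground truth accumulated across the generator stages.

    ``de_genes`` maps gene id → signed planted log2FC (positive = higher
    in condition B); ``planted_sites`` maps ``<gene>|<region>`` record
    ids to planted (kind, 0-based start) site lists.
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    enriched_regulators: set[str] = field(default_factory=set)
    planted_sites: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    annotation_members: set[str] = field(default_factory=set)

    def up_genes(self) -> set[str]:
        return {g for g, lfc in self.de_genes.items() if lfc > 0}

    def down_genes(self) -> set[str]:
        return {g for g, lfc in self.de_genes.items() if lfc < 0}

    def seed_positive_genes(self) -> set[str]:
        return {
            rec.split("|")[0] for rec, sites in self.planted_sites.items() if sites
        }


def generate_expression(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, TruthRecord]:
    """Linear-scale intensity matrix with planted condition effects.

    log2 intensity = per-gene baseline + condition effect (the planted
    signed log2FC added to condition-B samples of DE genes) + N(0,
    noise_sd) per cell; emitted on the linear scale so the pipeline's
    own log2 transform is exercised.  Detection flags are Bernoulli
    (detect_prob) per cell.
    """
    rng = config.rng(_EXPR_KEY)
    genes = config.gene_ids()
    a_ids, b_ids = config.sample_ids()
    samples = a_ids + b_ids

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    n_de = int(round(config.frac_de * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    magnitudes = config.lfc_mean + config.lfc_sd * rng.standard_normal(n_de)
    planted = np.zeros(config.n_genes)
    planted[de_idx] = signs * magnitudes

    log2 = np.tile(baseline[:, None], (1, len(samples)))
    log2[:, len(a_ids):] += planted[:, None]
    log2 += rng.normal(0.0, config.noise_sd, size=log2.shape)

    detected = rng.random(log2.shape) < config.detect_prob
    values = pd.DataFrame(np.power(2.0, log2), index=genes, columns=samples)
    det = pd.DataFrame(detected, index=genes, columns=samples)
    condition = {s: ("A" if s in a_ids else "B") for s in samples}

    truth = TruthRecord(
        de_genes={genes[i]: float(planted[i]) for i in sorted(de_idx)}
    )
    return ExpressionMatrix(values=values, detected=det, condition=condition), truth


def generate_network(
    config: SynthConfig, truth: TruthRecord
) -> tuple[RegulatoryNetwork, TruthRecord]:
    """Scored regulator → gene edges with one planted enriched regulator.

    The first regulator samples its targets with planted up-regulated
    DEGs weighted ``planted_regulator_odds`` : 1 against the rest; all
    other regulators sample uniformly.  Edge scores ~ Beta(score_shape_a,
    score_shape_b), truncated to (0, 1]; for the planted regulator's
    edges to planted up-genes, the first Beta shape is multiplied by
    ``planted_score_shift`` so binding scores concord with expression
    change (this is what the weighted z-score detects).  With odds = 1
    no regulator is planted and all scores are background draws.
    """
    if config.target_set_size > config.n_genes:
        raise SynthConfigError("target_set_size exceeds n_genes")
    rng = config.rng(_NET_KEY)
    genes = np.array(config.gene_ids())
    regulators = config.regulator_ids()
    planted_reg = regulators[0]
    planted_up = truth.up_genes()

    weights = np.ones(config.n_genes)
    weights[np.isin(genes, sorted(planted_up))] = config.planted_regulator_odds

    def _draw_scores(shape_a: float, n: int) -> np.ndarray:
        scores = rng.beta(shape_a, config.score_shape_b, n)
        while np.any(scores <= 0.0):  # Beta support is open; guard exact zeros
            scores[scores <= 0.0] = rng.beta(
                shape_a, config.score_shape_b, int((scores <= 0).sum())
            )
        return scores

    rows = []
    is_null = config.planted_regulator_odds == 1.0
    for reg in regulators:
        if reg == planted_reg and not is_null:
            p = weights / weights.sum()
            targets = rng.choice(genes, size=config.target_set_size, replace=False, p=p)
        else:
            targets = rng.choice(genes, size=config.target_set_size, replace=False)
        scores = _draw_scores(config.score_shape_a, config.target_set_size)
        if reg == planted_reg and not is_null:
            boosted = np.isin(targets, sorted(planted_up))
            scores[boosted] = _draw_scores(
                config.planted_score_shift * config.score_shape_a,
                int(boosted.sum()),
            )
        for g, s in sorted(zip(targets, scores)):
            rows.append({"regulator": reg, "gene": g, "score": float(s)})

    truth.enriched_regulators = (
        {planted_reg} if config.planted_regulator_odds != 1.0 else set()
    )
    edges = pd.DataFrame(rows, columns=["regulator", "gene", "score"])
    return RegulatoryNetwork(edges=edges), truth


_SITE_LEN = {"6mer": 6, "7mer": 7}
_MAX_REGION_TRIES = 2000


def _plant_region(
    rng: np.random.Generator,
    length: int,
    kinds: Sequence[str],
    match6: str,
    match7: str,
) -> tuple[str, list[tuple[str, int]]]:
    """One region whose scan result equals the planted site list exactly.

    Background and site placement are rejection-sampled until a scan of
    the assembled sequence reports precisely the planted (kind, start)
    set — no accidental motifs, no subsumed or clobbered plants.
    """
    need = sum(_SITE_LEN[k] + 1 for k in kinds)
    if need > length:
        raise SynthConfigError(
            f"region of length {length} cannot host sites {list(kinds)}"
        )
    bases = np.array(list("ACGT"))
    for _ in range(_MAX_REGION_TRIES):
        seq = rng.choice(bases, size=length)
        placed: list[tuple[str, int]] = []
        taken: list[tuple[int, int]] = []
        ok = True
        for kind in kinds:
            site_len = _SITE_LEN[kind]
            for _try in range(200):
                start = int(rng.integers(0, length - site_len + 1))
                # 1-nt buffer keeps plants from abutting/overwriting each other
                span = (start - 1, start + site_len + 1)
                if all(span[1] <= lo or span[0] >= hi for lo, hi in taken):
                    break
            else:
                ok = False
                break
            motif = match7 if kind == "7mer" else match6
            seq[start : start + site_len] = list(motif)
            taken.append(span)
            placed.append((kind, start))
        if not ok:
            continue
        sequence = "".join(seq)
        _, _, found = scan_region(sequence, match6, match7)
        if sorted(found) == sorted(placed):
            return sequence, sorted(placed, key=lambda kp: kp[1])
    raise SynthConfigError(
        f"could not realize sites {list(kinds)} in a region of length {length}"
    )


def generate_transcript_regions(
    config: SynthConfig,
    mirna: MirnaRecord,
    truth: TruthRecord | None = None,
    genes: Sequence[str] | None = None,
    site_plan: Mapping[str, Sequence[str]] | None = None,
) -> tuple[dict[str, str], TruthRecord]:
    """3'UTR and ORF sequences per gene with planted seed-match sites.

    ``site_plan`` maps ``<gene>|<region>`` ids to lists of site kinds
    (``"6mer"``/``"7mer"``); regions without an entry are guaranteed
    site-free.  With no plan, roughly half of the transcripts get one
    7-mer in their 3'UTR.  Backgrounds are rejection-sampled so the
    scanner's counts equal the planted counts exactly.
    """
    if config.region_len < 8:
        raise SynthConfigError("region_len must be >= 8")
    truth = truth if truth is not None else TruthRecord()
    rng = config.rng(_SEQ_KEY)
    if genes is None:
        genes = config.gene_ids()[: config.n_transcripts]
    genes = list(genes)[: config.n_transcripts] if site_plan is None else list(genes)
    match6, match7 = seed_motifs(mirna)

    if site_plan is None:
        site_plan = {}
        chosen = rng.random(len(genes)) < 0.5
        for g, has in zip(genes, chosen):
            if has:
                site_plan[f"{g}|3UTR"] = ["7mer"]

    records: dict[str, str] = {}
    for g in genes:
        for region in ("3UTR", "ORF"):
            rec_id = f"{g}|{region}"
            kinds = list(site_plan.get(rec_id, []))
            seq, placed = _plant_region(
                rng, config.region_len, kinds, match6, match7
            )
            records[rec_id] = seq
            truth.planted_sites[rec_id] = placed
    return records, truth


def generate_annotation(
    config: SynthConfig,
    truth: TruthRecord,
    members: Sequence[str] | None = None,
    size: int | None = None,
) -> tuple[dict[str, set[str]], TruthRecord]:
    """One named gene set (GMT-shaped), membership recorded in the truth.

    With explicit ``members`` they are used as-is; otherwise ``size``
    genes (default ``annotation_size``) are drawn uniformly from the
    gene universe.
    """
    if members is None:
        rng = config.rng(_ANNOT_KEY)
        size = config.annotation_size if size is None else size
        genes = config.gene_ids()
        members = list(rng.choice(genes, size=size, replace=False)) if size else []
    member_set = set(str(m) for m in members)
    truth.annotation_members = member_set
    return {config.annotation_name: member_set}, truth
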