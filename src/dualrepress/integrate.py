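"""Intersection of binding, derepression, annotation and seed evidence.

Produces the per-gene bound+derepressed table (annotation-filtered,
score-sorted) and the dual-regulation candidate table, plus a run
manifest for exact re-runs.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from dualrepress import io
from dualrepress.enrichment import RegulatoryNetwork
from dualrepress.expression import DEResult

logger = logging.getLogger(__name__)


class IntegrationError(ValueError):
    pass


def bound_upregulated(
    network: RegulatoryNetwork,
    regulator: str,
    de: DEResult,
    annotation: set[str],
) -> pd.DataFrame:
    """Genes bound by ``regulator``, called up_in_B, and annotated.

    Rows carry the regulator–gene association score and log2FC, sorted
    by descending score (ties broken by gene id).
    """
    if regulator not in network.regulators:
        raise IntegrationError(f"unknown regulator {regulator!r}")
    scores = network.target_scores(regulator)
    up_b = de.up_in("B")
    genes = sorted(set(scores) & up_b & annotation)
    table = pd.DataFrame(
        {
            "gene": genes,
            "assoc_score": [scores[g] for g in genes],
            "log2fc": [float(de.table.loc[g, "log2fc"]) for g in genes],
        }
    )
    table = table.sort_values(
        ["assoc_score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def dual_regulated(
    bound_up: pd.DataFrame, seed_report: pd.DataFrame
) -> pd.DataFrame:
    """Join seed-match evidence onto the bound+derepressed table.

    Every row of ``bound_up`` is bound, derepressed and annotated by
    construction; ``dual`` is therefore true exactly for the rows whose
    gene has at least one seed site in any region.  Genes absent from
    the seed report get mirna_target = False.
    """
    if bound_up["gene"].duplicated().any():
        dupes = bound_up.loc[bound_up["gene"].duplicated(), "gene"].tolist()
        raise IntegrationError(f"duplicate gene rows: {dupes}")
    if seed_report.empty:
        totals = pd.DataFrame(columns=["n_7mer", "n_6mer"])
    else:
        totals = seed_report.groupby("gene")[["n_7mer", "n_6mer"]].sum()
    out = bound_up.copy()
    out["bound"] = True
    out["derepressed"] = True
    out["annotated"] = True
    out["n_7mer"] = (
        out["gene"].map(totals["n_7mer"]).fillna(0).astype(int)
        if len(totals)
        else 0
    )
    out["n_6mer"] = (
        out["gene"].map(totals["n_6mer"]).fillna(0).astype(int)
        if len(totals)
        else 0
    )
    out["mirna_target"] = (out["n_7mer"] + out["n_6mer"]) > 0
    out["dual"] = out["bound"] & out["derepressed"] & out["mirna_target"]
    return out


def write_report(
    outdir: str | Path,
    tables: Mapping[str, pd.DataFrame],
    config_snapshot: Mapping,
    master_seed: int,
    input_checksums: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write all output tables plus a manifest enabling exact re-runs.

    ``tables`` maps basename (without extension) → DataFrame; each is
    written as ``<outdir>/<name>.tsv`` with canonical float formatting.
    The manifest records the config, master seed, library versions and
    the checksums of every written (and input) file.
    """
    outdir = Path(outdir)
    if not outdir.exists():
        logger.info("creating output directory %s", outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format=io.FLOAT_FMT)
        paths[name] = path
    manifest = {
        "config": {k: _plain(v) for k, v in dict(config_snapshot).items()},
        "master_seed": int(master_seed),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {name: io.file_sha256(p) for name, p in paths.items()},
        "inputs": dict(input_checksums or {}),
    }
    manifest_path = outdir / "manifest.yaml"
    io.write_yaml(manifest, manifest_path)
    paths["manifest"] = manifest_path
    return paths


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
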