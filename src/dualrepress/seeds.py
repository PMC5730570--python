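"""miRNA seed-match scanning of transcript regions.

Motifs are the reverse complements of miRNA positions 2–7 (6-mer) and
2–8 (7-mer, m8-anchored).  A 7-mer site is not double-counted as its
internal 6-mer; overlapping sites of the same kind are all counted.
Scanning is on the given sense strand only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
VALID_REGION = ("3UTR", "ORF")


class SeedScanError(ValueError):
    pass


@dataclass(frozen=True)
class MirnaRecord:
    """A mature miRNA sequence, 5'→3', over {A,C,G,U,T}, length ≥ 8."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - set("ACGT")
        if bad:
            raise SeedScanError(f"invalid miRNA characters: {sorted(bad)}")
        if len(seq) < 8:
            raise SeedScanError(
                f"miRNA {self.id!r} too short ({len(seq)} nt; need >= 8)"
            )
        object.__setattr__(self, "sequence", seq)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seed_motifs(mirna: MirnaRecord) -> tuple[str, str]:
    """(6-mer, 7-mer) DNA match motifs for a miRNA.

    match6 = revcomp of miRNA positions 2–7 (1-based); match7 = revcomp
    of positions 2–8.  match6 is always the 6-nt suffix of match7.
    """
    seq = mirna.sequence
    return revcomp(seq[1:7]), revcomp(seq[1:8])


def scan_region(
    sequence: str, match6: str, match7: str
) -> tuple[int, int, list[tuple[str, int]]]:
    """Count seed-match sites in one region.

    Every (possibly overlapping) start of ``match7`` is a 7-mer site.
    Every start of ``match6`` is a 6-mer site unless it sits at p+1 for
    a counted 7-mer start p (the 7-mer's own internal 6-mer).  Returns
    (n_7mer, n_6mer, positions) with 0-based starts, positions sorted.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise SeedScanError(
            f"invalid character {seq[pos]!r} at position {pos}"
        )
    starts7 = _all_starts(seq, match7)
    suppressed = {p + 1 for p in starts7}
    starts6 = [p for p in _all_starts(seq, match6) if p not in suppressed]
    positions = sorted(
        [("7mer", p) for p in starts7] + [("6mer", p) for p in starts6],
        key=lambda kp: (kp[1], kp[0]),
    )
    return len(starts7), len(starts6), positions


def _all_starts(seq: str, motif: str) -> list[int]:
    """All overlapping occurrence starts of motif in seq (N never matches)."""
    out = []
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def parse_region_id(record_id: str) -> tuple[str, str]:
    """Split a ``<gene>|<region>`` FASTA id; region must be 3UTR or ORF."""
    parts = record_id.split("|")
    if len(parts) != 2 or parts[1] not in VALID_REGION:
        raise SeedScanError(
            f"malformed record id {record_id!r}: expected '<gene>|<region>' "
            f"with region in {VALID_REGION}"
        )
    return parts[0], parts[1]


def scan_all(regions: dict[str, str], mirna: MirnaRecord) -> pd.DataFrame:
    """Scan every region record against one miRNA.

    ``regions`` maps FASTA record id (``<gene>|<region>``) to sequence.
    Returns a DataFrame with one row per record: gene, region, n_7mer,
    n_6mer, positions (list of (kind, start)), has_any.
    """
    match6, match7 = seed_motifs(mirna)
    rows = []
    for rec_id, seq in regions.items():
        gene, region = parse_region_id(rec_id)
        n7, n6, positions = scan_region(seq, match6, match7)
        rows.append(
            {
                "gene": gene,
                "region": region,
                "n_7mer": n7,
                "n_6mer": n6,
                "positions": positions,
                "has_any": n7 + n6 > 0,
            }
        )
    columns = ["gene", "region", "n_7mer", "n_6mer", "positions", "has_any"]
    return pd.DataFrame(rows, columns=columns)


def mirna_target_genes(report: pd.DataFrame) -> set[str]:
    """Genes with at least one seed site in any region."""
    if report.empty:
        return set()
    return set(report.loc[report["has_any"], "gene"])
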