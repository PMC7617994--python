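"""In silico species demultiplexing of mixed-species reads.

Reads from a pooled multi-species sequencing run are aligned to each
candidate genome separately; the per-genome alignments are compared
via an additive CIGAR-based score and each read is assigned to the
genome it supports strictly best. Ties (including the no-alignment
case) are reported as ambiguous and dropped downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

UNALIGNED_SCORE = float("-inf")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    species: str
    cigar: str | None  # None for unmapped reads
    nm: int | None = None


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"invalid CIGAR string: {cigar!r}")
    return [(int(n), op) for n, op in ops]


def alignment_score(aln: ReadAlignment) -> float:
    """Additive alignment support score.

    score = (sum of M/= op lengths) - NM - (sum of I/D/S op lengths).
    Hard clips consume no bases and are ignored; unmapped reads score
    -inf so they never win an assignment. The score is monotone
    non-increasing in the edit distance and in indel/clip lengths.
    """
    if aln.cigar is None or aln.cigar == "*":
        return UNALIGNED_SCORE
    matched = penalized = 0
    for n, op in parse_cigar(aln.cigar):
        if op in ("M", "="):
            matched += n
        elif op in ("I", "D", "S"):
            penalized += n
    nm = aln.nm or 0
    return float(matched - nm - penalized)


def assign_species(alignments: list[ReadAlignment]) -> str | None:
    """Assign a read to the species with strictly maximal score.

    Returns the species id, or None when the read is ambiguous (tie at
    the maximum, or no scoring alignment at all).
    """
    if not alignments:
        return None
    scores = {a.species: alignment_score(a) for a in alignments}
    if len(scores) != len(alignments):
        raise ValueError("at most one alignment per species per read")
    best = max(scores.values())
    if best == UNALIGNED_SCORE:
        return None
    winners = [sp for sp, s in scores.items() if s == best]
    return winners[0] if len(winners) == 1 else None


def demux_table(alignments: pd.DataFrame) -> pd.DataFrame:
    """Assign every read in a long-format alignment table.

    Expects columns read_id, species, cigar, nm. Returns one row per
    read with the assigned species (NA = ambiguous).
    """
    rows = []
    for read_id, group in alignments.groupby("read_id", sort=True):
        alns = [
            ReadAlignment(
                read_id=read_id,
                species=r["species"],
                cigar=None if pd.isna(r["cigar"]) else r["cigar"],
                nm=None if pd.isna(r["nm"]) else int(r["nm"]),
            )
            for _, r in group.iterrows()
        ]
        rows.append({"read_id": read_id, "assigned": assign_species(alns)})
    return pd.DataFrame(rows)


def demux_sam_files(sam_paths: dict[str, str | Path]) -> pd.DataFrame:
    """Demultiplex reads given one SAM file per candidate species.

    Only primary alignments are considered. Returns the per-read
    assignment table (NA = ambiguous).
    """
    import pysam

    records: dict[str, dict[str, ReadAlignment]] = {}
    for sp, path in sam_paths.items():
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                nm = rec.get_tag("NM") if rec.has_tag("NM") else None
                records.setdefault(rec.query_name, {})[sp] = ReadAlignment(
                    read_id=rec.query_name,
                    species=sp,
                    cigar=rec.cigarstring if not rec.is_unmapped else None,
                    nm=nm,
                )
    rows = [
        {"read_id": rid, "assigned": assign_species(list(by_sp.values()))}
        for rid, by_sp in sorted(records.items())
    ]
    return pd.DataFrame(rows)


def demux_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Assigned / ambiguous counts per outcome."""
    counts = (
        assignments["assigned"].fillna("ambiguous").value_counts().rename_axis("outcome")
    )
    return counts.reset_index(name="n_reads")
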