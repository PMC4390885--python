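"""Curation of homology-search hits into accepted family members.

Raw BLAST hits of miRNA precursors against genomes are noisy; three rules
turn them into trustworthy presence/absence (and copy-number) calls:

1. significance — the hit's E-value must not exceed a cap (default 1e-10);
2. coverage — the aligned query span must cover at least a fraction of the
   precursor length (default 90%), measured as ``(qend - qstart + 1) /
   query_length`` on 1-based inclusive query coordinates;
3. mature containment — the hit must span the position of every annotated
   mature sequence within the precursor (a hit missing the functional
   product is not evidence of a working gene copy).

At family level, two admission rules decide what enters the analysis: a
family recovered in no genome at all is dropped, and a family with more
than a copy cap (default 100, strictly greater) in any single species is
dropped — such enormous families are typically repeat-derived, where the
single-origin assumption of Dollo parsimony breaks down.

Each hit is judged on its own merits (no cross-hit coupling), so tightening
any threshold can only shrink the accepted set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "HomologyHit",
    "FilterConfig",
    "MatureNotFoundError",
    "locate_mature",
    "mature_intervals",
    "filter_hits",
    "family_admission",
    "admission_table",
    "read_blast_tab",
    "read_fasta_sequences",
]

#: Standard 12-column tabular hit format (BLAST outfmt 6).
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class MatureNotFoundError(ValueError):
    """Mature sequence is not an exact substring of its precursor."""


@dataclass(frozen=True)
class HomologyHit:
    """One homology-search hit of a precursor query in a target genome."""

    query_id: str
    subject_id: str
    target_species: str
    e_value: float
    query_start: int  # 1-based inclusive
    query_end: int
    subject_start: int = 0
    subject_end: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError(
                f"hit {self.query_id!r}: query_start > query_end "
                f"({self.query_start} > {self.query_end})"
            )
        if self.e_value < 0:
            raise ValueError(f"hit {self.query_id!r}: negative E-value")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass(frozen=True)
class FilterConfig:
    """Hit- and family-level curation thresholds."""

    max_evalue: float = 1e-10
    min_query_coverage: float = 0.90
    max_copies_per_species: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.min_query_coverage <= 1:
            raise ValueError("min_query_coverage must be in (0, 1]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be nonnegative")


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


def locate_mature(precursor: str, mature: str) -> tuple[int, int]:
    """Leftmost 1-based inclusive interval of a mature within its precursor.

    Comparison is case-insensitive and DNA/RNA agnostic (T == U).  A mature
    that is not a contiguous exact substring raises
    :class:`MatureNotFoundError` and must be mapped manually.
    """
    hay, needle = _normalize(precursor), _normalize(mature)
    if not needle:
        raise MatureNotFoundError("empty mature sequence")
    pos = hay.find(needle)
    if pos < 0:
        raise MatureNotFoundError(
            "mature sequence not found as a substring of the precursor"
        )
    return pos + 1, pos + len(needle)


def mature_intervals(
    precursors: Mapping[str, str],
    matures: Mapping[str, str],
    assign: Callable[[str], Iterable[str]] | None = None,
) -> tuple[dict[str, list[tuple[int, int]]], list[str]]:
    """Locate every mature on its precursor(s).

    Without an explicit ``assign`` rule (mature id -> precursor ids), each
    mature is assigned to every precursor that contains it as a substring —
    conservative for paralogous precursors sharing one mature product.
    Returns ``(intervals by precursor id, mature ids matched nowhere)``.
    """
    intervals: dict[str, list[tuple[int, int]]] = {pid: [] for pid in precursors}
    unmatched: list[str] = []
    for mid, mseq in matures.items():
        candidates = (
            list(assign(mid)) if assign is not None else list(precursors)
        )
        hit_any = False
        for pid in candidates:
            if pid not in precursors:
                continue
            try:
                intervals[pid].append(locate_mature(precursors[pid], mseq))
                hit_any = True
            except MatureNotFoundError:
                if assign is not None:
                    raise MatureNotFoundError(
                        f"mature {mid!r} assigned to precursor {pid!r} "
                        "but not found in its sequence"
                    ) from None
        if not hit_any:
            unmatched.append(mid)
    return intervals, unmatched


def filter_hits(
    hits: Iterable[HomologyHit],
    query_lengths: Mapping[str, int],
    mature_map: Mapping[str, Sequence[tuple[int, int]]],
    config: FilterConfig | None = None,
) -> list[HomologyHit]:
    """Accept the hits passing all three curation rules.

    A hit is accepted iff its E-value is at most ``max_evalue``, its aligned
    query span covers at least ``min_query_coverage`` of the query length,
    and every mature interval of the query lies within the hit's query span.
    """
    config = config or FilterConfig()
    accepted = []
    for hit in hits:
        if hit.query_id not in query_lengths:
            raise KeyError(f"hit references unknown query {hit.query_id!r}")
        if hit.e_value > config.max_evalue:
            continue
        qlen = query_lengths[hit.query_id]
        if hit.query_span < config.min_query_coverage * qlen:
            continue
        spans = mature_map.get(hit.query_id, ())
        if not all(
            hit.query_start <= lo and hi <= hit.query_end for lo, hi in spans
        ):
            continue
        accepted.append(hit)
    return accepted


def family_admission(
    species_counts: Mapping[str, int],
    config: FilterConfig | None = None,
) -> tuple[bool, str | None]:
    """Keep/drop decision for one family from its per-species copy counts.

    Dropped when recovered nowhere, or when any single species carries more
    than ``max_copies_per_species`` copies (strictly more: a species at
    exactly the cap is kept).
    """
    config = config or FilterConfig()
    if not any(c >= 1 for c in species_counts.values()):
        return False, "not recovered"
    worst = max(species_counts.values())
    if worst > config.max_copies_per_species:
        return False, f"copy cap ({worst} copies in one species)"
    return True, None


def admission_table(
    family_counts: Mapping[str, Mapping[str, int]],
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Admission decisions for many families; one row each."""
    rows = []
    for fam, counts in family_counts.items():
        keep, reason = family_admission(counts, config)
        rows.append((fam, keep, reason if reason else ""))
    return pd.DataFrame(rows, columns=["family_id", "keep", "reason"])


def read_blast_tab(
    source,
    species_rule: Callable[[str], str] | None = None,
) -> list[HomologyHit]:
    """Read 12-column tabular hits (outfmt 6).

    ``species_rule`` maps a subject identifier to a taxon label; by default
    the token before the first ``|`` or whitespace of the subject id is
    used.  Strand is inferred from the subject coordinate orientation.
    """
    table = pd.read_csv(source, sep="\t", names=BLAST6_COLUMNS, comment="#")

    def default_rule(sseqid: str) -> str:
        return sseqid.split("|")[0].split()[0]

    rule = species_rule or default_rule
    hits = []
    for row in table.itertuples(index=False):
        sstart, send = int(row.sstart), int(row.send)
        hits.append(
            HomologyHit(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                target_species=rule(str(row.sseqid)),
                e_value=float(row.evalue),
                query_start=int(row.qstart),
                query_end=int(row.qend),
                subject_start=min(sstart, send),
                subject_end=max(sstart, send),
                strand="+" if send >= sstart else "-",
            )
        )
    return hits


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """id -> sequence map from a FASTA file (for precursors or matures)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
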