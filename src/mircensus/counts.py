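"""Per-family paralog-count profiles.

A family's leaf data is simply how many copies of it each species carries.
Profiles are built either from a families x species TSV matrix or from
taxon-labelled sequence records (one FASTA per family, miRBase-style
identifiers such as ``hsa-mir-17`` whose prefix before the first ``-`` names
the species).  Sequences themselves are never inspected: alignments are
consumed as plain record collections and gap columns are irrelevant to
counting.

A species present on the tree but absent from the data is counted 0, i.e.
the family is treated as absent there — that is exactly how the downstream
Dollo loss inference reads non-observation.  Species with no usable genome
should instead be excluded from both the tree and the profiles (see
:func:`read_species_exclusions`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .treeio import PhyloTree

__all__ = [
    "CountProfile",
    "CountsError",
    "counts_from_sequences",
    "counts_from_fasta",
    "read_count_matrix",
    "profiles_to_matrix",
    "read_species_exclusions",
    "MIRBASE_PREFIX_RULE",
]

#: Default taxon rule: the token before the first '-' of a miRBase-style
#: identifier (``hsa-mir-1-2`` -> ``hsa``).
MIRBASE_PREFIX_RULE = r"^([^-\s]+)-"


class CountsError(ValueError):
    """Invalid count data (all-zero family, unknown species, bad cell)."""


@dataclass(frozen=True)
class CountProfile:
    """Nonnegative paralog counts of one family, keyed by leaf label."""

    family_id: str
    counts: Mapping[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        bad = {t: c for t, c in self.counts.items() if c < 0 or int(c) != c}
        if bad:
            raise CountsError(
                f"family {self.family_id!r}: non-integer or negative counts {bad}"
            )
        object.__setattr__(
            self, "counts", {t: int(c) for t, c in self.counts.items()}
        )
        if not any(c >= 1 for c in self.counts.values()):
            raise CountsError(
                f"family {self.family_id!r} observed in no species (all-zero profile)"
            )

    @property
    def present(self) -> frozenset[str]:
        """Leaf labels where the family is observed (count >= 1)."""
        return frozenset(t for t, c in self.counts.items() if c >= 1)

    def count(self, taxon: str) -> int:
        return self.counts.get(taxon, 0)

    def validate_against(self, tree: PhyloTree) -> None:
        unknown = sorted(set(self.counts) - set(tree.leaf_labels()))
        if unknown:
            raise CountsError(
                f"family {self.family_id!r}: species not on the tree: {unknown}"
            )


def _compile_rule(
    taxon_rule: str | Callable[[str], str | None],
) -> Callable[[str], str | None]:
    if callable(taxon_rule):
        return taxon_rule
    pattern = re.compile(taxon_rule)

    def extract(identifier: str) -> str | None:
        m = pattern.search(identifier)
        if m is None:
            return None
        return m.group(1) if m.groups() else m.group(0)

    return extract


def counts_from_sequences(
    records: Iterable[tuple[str, str]],
    family_id: str,
    taxon_rule: str | Callable[[str], str | None] = MIRBASE_PREFIX_RULE,
    tree: PhyloTree | None = None,
) -> CountProfile:
    """Count records per taxon token extracted from sequence identifiers.

    ``records`` is a sequence of ``(identifier, sequence)`` pairs; sequences
    are not inspected.  ``taxon_rule`` is a regex (first group = taxon token)
    or a callable returning the token (``None`` for no match).  If ``tree``
    is given, every token must be one of its leaf labels.
    """
    extract = _compile_rule(taxon_rule)
    tally: dict[str, int] = {}
    for identifier, _seq in records:
        token = extract(identifier)
        if not token:
            raise CountsError(
                f"family {family_id!r}: cannot extract a taxon token from "
                f"identifier {identifier!r}"
            )
        tally[token] = tally.get(token, 0) + 1
    if not tally:
        raise CountsError(f"family {family_id!r} has no records (observed nowhere)")
    profile = CountProfile(family_id, tally)
    if tree is not None:
        profile.validate_against(tree)
    return profile


def counts_from_fasta(
    path: str | Path,
    family_id: str | None = None,
    taxon_rule: str | Callable[[str], str | None] = MIRBASE_PREFIX_RULE,
    tree: PhyloTree | None = None,
) -> CountProfile:
    """Build a profile from one FASTA file (aligned or not) of family members."""
    path = Path(path)
    fam = family_id if family_id is not None else path.stem
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return counts_from_sequences(records, fam, taxon_rule=taxon_rule, tree=tree)


def read_count_matrix(
    source,
    tree: PhyloTree,
    exclude_species: Iterable[str] = (),
) -> list[CountProfile]:
    """Read a families x species TSV matrix into one profile per row.

    The header row carries species labels; the first column carries family
    identifiers.  Species on the tree but absent from the table get count 0
    in every profile.  All-zero rows are rejected.  ``exclude_species``
    drops those columns before profiling (pair it with a tree from which the
    same species were pruned, otherwise they will read as absences).
    """
    table = pd.read_csv(source, sep="\t", index_col=0)
    excluded = set(exclude_species)
    table = table.drop(columns=[c for c in table.columns if c in excluded])

    leaf_labels = set(tree.leaf_labels())
    unknown = sorted(set(table.columns) - leaf_labels)
    if unknown:
        raise CountsError(f"species in matrix but not on the tree: {unknown}")

    profiles: list[CountProfile] = []
    for family_id, row in table.iterrows():
        cells: dict[str, int] = {}
        for species, value in row.items():
            fval = float(value)
            if pd.isna(fval) or fval < 0 or not fval.is_integer():
                raise CountsError(
                    f"family {family_id!r}, species {species!r}: "
                    f"cell {value!r} is not a nonnegative integer"
                )
            cells[str(species)] = int(fval)
        for species in leaf_labels - set(cells):
            cells[species] = 0
        try:
            profiles.append(CountProfile(str(family_id), cells))
        except CountsError as exc:
            raise CountsError(str(exc)) from None
    return profiles


def profiles_to_matrix(
    profiles: Sequence[CountProfile], tree: PhyloTree
) -> pd.DataFrame:
    """Families x species integer matrix (species in tree leaf order)."""
    species = list(tree.leaf_labels())
    data = {p.family_id: [p.count(s) for s in species] for p in profiles}
    return pd.DataFrame.from_dict(data, orient="index", columns=species).astype(int)


def read_species_exclusions(path: str | Path) -> list[str]:
    """One species label per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        token = line.strip()
        if token and not token.startswith("#"):
            out.append(token)
    return out
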