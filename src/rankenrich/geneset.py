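"""Gene set libraries: GMT parsing and size filtering.

GMT ("gene matrix transposed") is the de-facto standard interchange format
for gene set libraries: one set per line, tab separated, with the set name in
field 1, a free-text description in field 2 and member identifiers in fields
3 onward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .exceptions import ValidationError

__all__ = ["GeneSet", "GeneSetLibrary", "read_gmt", "write_gmt", "filter_sets"]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers with an optional description."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


class GeneSetLibrary:
    """An ordered collection of uniquely named :class:`GeneSet` objects."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self._sets:
            raise ValidationError(f"duplicate gene set name {gs.name!r}")
        self._sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def sizes(self) -> pd.Series:
        """Member counts per set, in library order."""
        return pd.Series({g.name: len(g) for g in self}, dtype=int)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetLibrary":
        return cls(GeneSet(name, frozenset(m)) for name, m in mapping.items())

    def __repr__(self) -> str:
        return f"GeneSetLibrary({len(self)} sets)"


def read_gmt(path) -> GeneSetLibrary:
    """Parse a GMT file into a :class:`GeneSetLibrary`.

    Empty member tokens are dropped and duplicate members collapsed.  A line
    with fewer than three tab-separated fields, an empty file or duplicated
    set names are all hard errors: a malformed library silently shrinking is
    worse than a parse failure.
    """
    sets: list[GeneSet] = []
    seen: dict[str, int] = {}
    duplicates: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            members = frozenset(tok for tok in fields[2:] if tok)
            if not members:
                raise ValidationError(f"{path}: line {lineno}: set {name!r} has no members")
            if name in seen:
                duplicates.append(name)
            else:
                seen[name] = lineno
                sets.append(GeneSet(name, members, description))
    if duplicates:
        raise ValidationError(
            f"{path}: duplicate gene set names: {sorted(set(duplicates))}"
        )
    if not sets:
        raise ValidationError(f"{path}: no gene sets found (empty GMT file)")
    return GeneSetLibrary(sets)


def write_gmt(library: GeneSetLibrary, path) -> None:
    """Write a library in GMT format (members in sorted order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in library:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def filter_sets(
    library: GeneSetLibrary,
    ranked: pd.DataFrame,
    min_size: int = 10,
) -> tuple[GeneSetLibrary, int]:
    """Restrict sets to genes present in the ranked profile and drop small ones.

    Effective membership is the intersection with the profile's gene
    identifiers; sets whose effective size falls below *min_size* are
    excluded.  Sets must additionally have at least ``n_contrasts + 2``
    effective members for the MANOVA error degrees of freedom to be positive;
    when *min_size* is below that, such sets are excluded with a warning.

    Returns the retained library (with effective members recorded) and the
    number of sets excluded.
    """
    if min_size < 2:
        raise ValidationError(f"min_size must be >= 2, got {min_size}")
    genes = frozenset(map(str, ranked.index))
    k = ranked.shape[1]
    retained: list[GeneSet] = []
    excluded = 0
    too_few_df = 0
    for gs in library:
        effective = gs.members & genes
        if len(effective) < min_size:
            excluded += 1
            continue
        if len(effective) < k + 2:
            excluded += 1
            too_few_df += 1
            continue
        retained.append(GeneSet(gs.name, effective, gs.description))
    if too_few_df:
        warnings.warn(
            f"excluded {too_few_df} sets with fewer than {k + 2} effective "
            "members (needed for positive MANOVA error degrees of freedom)",
            stacklevel=2,
        )
    return GeneSetLibrary(retained), excluded
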