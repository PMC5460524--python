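"""Gene-set (pathway) collections: GMT reading/writing and size filtering.

Pathway collections are carried in the GMT dialect where each line is
``set_id <TAB> description <TAB> gene1 <TAB> gene2 ...``; the second field
is always a description and never a gene.  Downstream statistics only ever
see genes that are measurable in the expression matrix, so the effective
size of a set is the size of its intersection with the gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping


class GmtParseError(ValueError):
    """Raised for malformed GMT content (too few fields, duplicate ids)."""


@dataclass(frozen=True)
class GeneSet:
    """A named pathway: an identifier, a free-text description, and members.

    Members are stored as a frozenset — membership is unordered and
    duplicate-free by construction.
    """

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValueError("set_id must be non-empty")
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")

    @property
    def size(self) -> int:
        return len(self.members)

    def effective_members(self, universe: Iterable[str]) -> frozenset[str]:
        """Members restricted to a universe of measurable genes."""
        return self.members & frozenset(universe)


@dataclass
class GeneSetCollection:
    """An ordered list of gene sets with unique ids, plus an optional universe.

    The universe, when set, records the measurable genes the collection was
    filtered against; statistics downstream treat it as the sampling frame.
    """

    sets: list[GeneSet] = field(default_factory=list)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GmtParseError(f"duplicate set ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.sets]

    def as_dict(self) -> Mapping[str, frozenset[str]]:
        return {s.set_id: s.members for s in self.sets}


def parse_gmt(path) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Each non-blank line must carry at least three tab-separated fields
    (id, description, one or more genes).  Duplicate genes within a line
    are collapsed with a warning; a duplicate set id is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, name, *genes = fields
            genes = [g for g in genes if g]  # trailing tabs are tolerated
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: set {set_id!r} has no genes")
            if set_id in seen:
                raise GmtParseError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            seen.add(set_id)
            uniq = frozenset(genes)
            if len(uniq) < len(genes):
                warnings.warn(
                    f"{path}: line {lineno}: set {set_id!r} lists duplicate genes; "
                    f"deduplicated {len(genes)} -> {len(uniq)}",
                    stacklevel=2,
                )
            sets.append(GeneSet(set_id=set_id, name=name, members=uniq))
    return GeneSetCollection(sets=sets)


def write_gmt(coll: GeneSetCollection, path) -> None:
    """Write a collection back to GMT.  Members are emitted sorted so the
    file is deterministic; GMT has no member order semantics."""
    with open(path, "wt", encoding="utf-8") as fh:
        for s in coll.sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def filter_gene_sets(
    coll: GeneSetCollection,
    universe: Iterable[str],
    min_size: int = 15,
    max_size: int = 500,
) -> GeneSetCollection:
    """Restrict sets to a gene universe and keep those with
    ``min_size <= |members ∩ universe| <= max_size``.

    Sizes are counted after intersecting with the universe, because the
    statistics downstream only ever see measurable genes.  The input
    collection is not modified.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    uni = frozenset(universe)
    if not uni:
        raise ValueError("universe is empty")
    kept: list[GeneSet] = []
    for s in coll.sets:
        eff = s.members & uni
        if min_size <= len(eff) <= max_size:
            kept.append(GeneSet(set_id=s.set_id, name=s.name, members=eff))
    return GeneSetCollection(sets=kept, universe=uni)
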