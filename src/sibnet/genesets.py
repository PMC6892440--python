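"""Gene-set collections and GMT (gene matrix transposed) file handling.

GMT is a tab-separated format with one set per line: name, description, then
one column per member gene.  Lines with fewer than three fields are malformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Set, Tuple


class GmtFormatError(ValueError):
    """A malformed GMT line; carries the 1-based line number."""

    def __init__(self, path, line_no: int, message: str) -> None:
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions; members unique within a set."""

    sets: Dict[str, Set[str]] = field(default_factory=dict)
    descriptions: Dict[str, str] = field(default_factory=dict)

    def add(self, name: str, members, description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        self.sets[name] = set(members)
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> Set[str]:
        return self.sets[name]

    def __iter__(self) -> Iterator[Tuple[str, Set[str]]]:
        return iter(self.sets.items())

    def names(self) -> List[str]:
        return list(self.sets)

    def all_genes(self) -> Set[str]:
        out: Set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file; raises :class:`GmtFormatError` with the line number on malformed lines."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(path, line_no, f"expected >= 3 tab-separated fields, got {len(fields)}")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise GmtFormatError(path, line_no, f"gene set {name!r} has no members")
            coll.add(name, members, desc)
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
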