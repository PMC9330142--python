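"""Haplogroup phylogeny: data model, flat-file dialect, and path queries.

The tree is rooted at the reference state (every edge variant is expressed
as a difference from the rCRS coordinate frame), so the expected variant
set of a haplogroup is simply the union of edge events on its root path,
with back-mutations ("!"-suffixed events) removing the earlier event at
the same position.

File dialect (TSV): columns ``node``, ``parent`` (empty for the root) and
``variants`` — ";"-separated canonical labels, e.g. ``m.11778G>A``,
``m.249delA``, ``m.573insC``; a trailing ``!`` marks a back-mutation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ParseError, ValidationError

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

RCRS_LENGTH = 16_569

_SUB_RE = re.compile(r"^m\.(\d+)([ACGTN])>([ACGTN])$")
_DEL_RE = re.compile(r"^m\.(\d+)del([ACGTN]+)$")
_INS_RE = re.compile(r"^m\.(\d+)ins([ACGTN]+)$")


@dataclass(frozen=True, order=True)
class TreeEdgeVariant:
    """One mutation event on a tree edge, in rCRS-style coordinates."""

    position: int
    ref_allele: str
    alt_allele: str
    kind: str = SUBSTITUTION
    is_back_mutation: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.kind == SUBSTITUTION:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValidationError(
                    f"substitution alleles must be single bases: "
                    f"{self.ref_allele!r}>{self.alt_allele!r} at {self.position}"
                )
            if self.ref_allele == self.alt_allele:
                raise ValidationError(
                    f"ref and alt alleles are identical at {self.position}"
                )

    @property
    def label(self) -> str:
        """Canonical ``m.`` label, with ``!`` appended for back-mutations."""
        return self.key + ("!" if self.is_back_mutation else "")

    @property
    def key(self) -> str:
        """Identity label, ignoring the back-mutation flag."""
        if self.kind == DELETION:
            return f"m.{self.position}del{self.ref_allele}"
        if self.kind == INSERTION:
            return f"m.{self.position}ins{self.alt_allele}"
        return f"m.{self.position}{self.ref_allele}>{self.alt_allele}"


def parse_variant_label(label: str) -> TreeEdgeVariant:
    """Parse a canonical variant label such as ``m.11778G>A`` or ``m.249delA``."""
    text = label.strip()
    back = text.endswith("!")
    if back:
        text = text[:-1]
    m = _SUB_RE.match(text)
    if m:
        return TreeEdgeVariant(int(m.group(1)), m.group(2), m.group(3),
                               SUBSTITUTION, back)
    m = _DEL_RE.match(text)
    if m:
        return TreeEdgeVariant(int(m.group(1)), m.group(2), "", DELETION, back)
    m = _INS_RE.match(text)
    if m:
        return TreeEdgeVariant(int(m.group(1)), "", m.group(2), INSERTION, back)
    raise ParseError(f"unrecognised variant label {label!r}")


@dataclass
class _Node:
    parent: str | None
    variants: tuple[TreeEdgeVariant, ...]


@dataclass
class HaplogroupTree:
    """Rooted maternal phylogeny with variant-bearing edges.

    ``nodes`` maps each haplogroup label to its parent label (``None`` for
    the root) and the edge events between parent and node. Construction
    validates the single-root / acyclic / connected invariants.
    """

    root_name: str
    nodes: dict[str, _Node]
    genome_length: int = RCRS_LENGTH
    multiallelic_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str | None, Iterable[TreeEdgeVariant]]],
        genome_length: int = RCRS_LENGTH,
        multiallelic_positions: Iterable[int] = (),
    ) -> "HaplogroupTree":
        nodes: dict[str, _Node] = {}
        root = None
        for name, parent, variants in edges:
            if name in nodes:
                raise ValidationError(f"duplicate node {name!r}")
            if parent is None:
                if root is not None:
                    raise ValidationError(
                        f"multiple roots: {root!r} and {name!r}"
                    )
                root = name
            nodes[name] = _Node(parent, tuple(variants))
        if root is None:
            raise ValidationError("tree has no root (a node with empty parent)")
        return cls(root, nodes, genome_length, frozenset(multiallelic_positions))

    def _validate(self) -> None:
        if self.root_name not in self.nodes:
            raise ValidationError(f"root {self.root_name!r} is not a node")
        if self.nodes[self.root_name].variants:
            raise ValidationError("root must carry no edge variants")
        for name, node in self.nodes.items():
            if name == self.root_name:
                continue
            if node.parent not in self.nodes:
                raise ValidationError(
                    f"node {name!r} has unknown parent {node.parent!r}"
                )
        # walk every root path: detects cycles/disconnection and, unless a
        # position is declared multi-allelic, repeated forward events at one
        # position on a single path
        for name in self.nodes:
            self._walk_expected(name)

    # -- queries ------------------------------------------------------

    def path_to_root(self, haplogroup: str) -> list[str]:
        """Node labels from the root down to ``haplogroup`` (inclusive)."""
        if haplogroup not in self.nodes:
            raise KeyError(f"unknown haplogroup {haplogroup!r}")
        path: list[str] = []
        seen: set[str] = set()
        cur: str | None = haplogroup
        while cur is not None:
            if cur in seen:
                raise ValidationError(f"cycle in tree at {cur!r}")
            seen.add(cur)
            path.append(cur)
            cur = self.nodes[cur].parent
        if path[-1] != self.root_name:
            raise ValidationError(
                f"node {haplogroup!r} is disconnected from the root"
            )
        return path[::-1]

    def depth(self, haplogroup: str) -> int:
        return len(self.path_to_root(haplogroup)) - 1

    def _walk_expected(self, haplogroup: str) -> dict[int, TreeEdgeVariant]:
        surviving: dict[int, TreeEdgeVariant] = {}
        for name in self.path_to_root(haplogroup):
            for v in self.nodes[name].variants:
                if v.is_back_mutation:
                    surviving.pop(v.position, None)
                elif (v.position in surviving
                      and v.position not in self.multiallelic_positions):
                    raise ValidationError(
                        f"position {v.position} mutated twice on the path to "
                        f"{haplogroup!r} without a back-mutation; declare it "
                        "multi-allelic if intended"
                    )
                else:
                    surviving[v.position] = replace(v, is_back_mutation=False)
        return surviving

    def expected_variants(self, haplogroup: str) -> set[TreeEdgeVariant]:
        """Variants an individual of ``haplogroup`` is expected to carry.

        The union of forward edge events on the root path, with each
        back-mutation removing the earlier event at its position.
        """
        return set(self._walk_expected(haplogroup).values())

    def defining_nodes(self, variant: TreeEdgeVariant) -> list[str]:
        """Every haplogroup whose edge carries ``variant`` as a forward event.

        An empty list means the variant is not haplogroup-defining anywhere
        in this tree. Back-mutation entries are ignored. Order follows node
        insertion (file) order.
        """
        key = variant.key
        return [
            name
            for name, node in self.nodes.items()
            if any(not v.is_back_mutation and v.key == key for v in node.variants)
        ]

    def all_forward_variants(self) -> set[TreeEdgeVariant]:
        """Every distinct forward edge event in the tree."""
        return {
            replace(v, is_back_mutation=False)
            for node in self.nodes.values()
            for v in node.variants
            if not v.is_back_mutation
        }

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, haplogroup: str) -> bool:
        return haplogroup in self.nodes

    # -- serialisation ------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#genome_length={self.genome_length}\n")
            if self.multiallelic_positions:
                joined = ",".join(map(str, sorted(self.multiallelic_positions)))
                fh.write(f"#multiallelic={joined}\n")
            fh.write("node\tparent\tvariants\n")
            for name, node in self.nodes.items():
                labels = ";".join(v.label for v in node.variants)
                fh.write(f"{name}\t{node.parent or ''}\t{labels}\n")


def load_tree(path: str | Path) -> HaplogroupTree:
    """Load a haplogroup tree from the flat TSV dialect.

    Raises :class:`ParseError` naming the offending line on malformed
    input and :class:`ValidationError` on duplicate nodes, dangling
    parents, or undeclared multi-allelic paths.
    """
    path = Path(path)
    edges: list[tuple[str, str | None, list[TreeEdgeVariant]]] = []
    genome_length = RCRS_LENGTH
    multiallelic: set[int] = set()
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#genome_length="):
                genome_length = int(line.split("=", 1)[1])
                continue
            if line.startswith("#multiallelic="):
                multiallelic.update(
                    int(x) for x in line.split("=", 1)[1].split(",") if x
                )
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields[:3]] != ["node", "parent", "variants"]:
                    raise ParseError(
                        "expected header 'node<TAB>parent<TAB>variants'",
                        str(path), lineno,
                    )
                header_seen = True
                continue
            name = fields[0].strip()
            if not name:
                raise ParseError("empty node label", str(path), lineno)
            parent = fields[1].strip() or None if len(fields) > 1 else None
            var_field = fields[2].strip() if len(fields) > 2 else ""
            try:
                variants = [
                    parse_variant_label(lbl)
                    for lbl in var_field.split(";")
                    if lbl.strip()
                ]
            except ParseError as exc:
                raise ParseError(str(exc), str(path), lineno) from None
            for v in variants:
                if v.position > genome_length:
                    raise ParseError(
                        f"position {v.position} beyond genome length "
                        f"{genome_length}", str(path), lineno,
                    )
            edges.append((name, parent, variants))
    if not header_seen:
        raise ParseError("empty tree file", str(path))
    return HaplogroupTree.from_edges(edges, genome_length, multiallelic)
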