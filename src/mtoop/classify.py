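"""Haplogroup assignment, macro-lineage labels, and variant placement.

Assignment ranks every tree node with a Kulczynski-style score balancing
the fraction of the node's expected variants found in the sample against
the fraction of the sample's (non-hotspot) variants the node explains.
Placement then partitions a sample's homoplasmic variants into three
disjoint classes: ``expected`` (on the assigned haplogroup's root path),
``out_of_place`` (haplogroup-defining somewhere else in the phylogeny —
"local private" variants) and ``global_private`` (absent from the tree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DataError, ValidationError
from .phylotree import HaplogroupTree
from .profiles import DEFAULT_HOTSPOTS, ObservedCall, in_intervals

EXPECTED = "expected"
OUT_OF_PLACE = "out_of_place"
GLOBAL_PRIVATE = "global_private"

AFRICAN_LINEAGES = frozenset({"L0", "L1", "L2", "L3", "L4", "L5", "L6"})
EUROPEAN_LINEAGES = frozenset({"H", "V", "U", "K", "T", "J", "I", "W", "X"})
OTHER = "other"

# longest-prefix-wins lineage table; prefixes mapping to OTHER pre-empt a
# shorter listed letter (e.g. HV is its own clade, not part of H or V)
_LINEAGE_PREFIXES: dict[str, str] = {
    **{lin: lin for lin in AFRICAN_LINEAGES},
    **{lin: lin for lin in EUROPEAN_LINEAGES},
    "HV": OTHER,
}


def lineage_of(haplogroup: str) -> str:
    """Macro-lineage of a haplogroup label (``"other"`` if unlisted).

    African lineages are L0–L6 (two-character prefixes); European ones are
    H, V, U, K, T, J, I, W, X. Labels whose prefix belongs to a different
    named clade (e.g. ``HV0a``) and anything unlisted map to ``"other"``.
    """
    if not haplogroup:
        raise ValidationError("empty haplogroup label")
    best = None
    for prefix, lineage in _LINEAGE_PREFIXES.items():
        if haplogroup.startswith(prefix):
            if best is None or len(prefix) > len(best[0]):
                best = (prefix, lineage)
    return best[1] if best is not None else OTHER


@dataclass
class PlacementPartition:
    """Disjoint partition of a sample's homoplasmic variant labels."""

    expected: set[str] = field(default_factory=set)
    out_of_place: set[str] = field(default_factory=set)
    global_private: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.expected & self.out_of_place
                or self.expected & self.global_private
                or self.out_of_place & self.global_private):
            raise ValidationError("placement classes must be disjoint")

    def placement_of(self, label: str) -> str:
        if label in self.expected:
            return EXPECTED
        if label in self.out_of_place:
            return OUT_OF_PLACE
        if label in self.global_private:
            return GLOBAL_PRIVATE
        raise KeyError(f"variant {label!r} not in partition")

    def __len__(self) -> int:
        return len(self.expected) + len(self.out_of_place) + len(self.global_private)


def haplogroup_score(
    tree: HaplogroupTree,
    haplogroup: str,
    calls: Sequence[ObservedCall],
    hotspot_regions: Iterable[tuple[int, int]] = DEFAULT_HOTSPOTS,
) -> float:
    """Kulczynski-style match quality of one node for one sample.

    ``0.5 * (|E ∩ O| / |E| + |E ∩ O| / |O'|)`` where E is the node's
    expected variant set, O the observed set and O' the observed set
    outside hotspot intervals. Empty E (the root state) scores 1 on the
    first term; empty O' scores 1 on the second.
    """
    expected_keys = {v.key for v in tree.expected_variants(haplogroup)}
    observed = {c.key for c in calls}
    intervals = tuple(hotspot_regions)
    observed_clean = {
        c.key for c in calls if not in_intervals(c.position, intervals)
    }
    hits = len(expected_keys & observed)
    term1 = hits / len(expected_keys) if expected_keys else 1.0
    term2 = hits / len(observed_clean) if observed_clean else 1.0
    return 0.5 * (term1 + term2)


def assign_haplogroup(
    tree: HaplogroupTree,
    calls: Sequence[ObservedCall],
    hotspot_regions: Iterable[tuple[int, int]] = DEFAULT_HOTSPOTS,
) -> tuple[str, float]:
    """Best-scoring haplogroup for a homoplasmic-filtered call set.

    Scans every node; ties are broken by greater path depth, then by
    lexicographically smaller label, so assignment is deterministic.
    """
    if len(tree) == 0:
        raise DataError("cannot assign a haplogroup on an empty tree")
    best: tuple[float, int, str] | None = None
    for name in tree:
        score = haplogroup_score(tree, name, calls, hotspot_regions)
        # sort key: maximise score, then depth; minimise label
        candidate = (score, tree.depth(name), name)
        if best is None or (candidate[0], candidate[1]) > (best[0], best[1]) \
           or ((candidate[0], candidate[1]) == (best[0], best[1])
               and candidate[2] < best[2]):
            best = candidate
    return best[2], best[0]


def partition_variants(
    tree: HaplogroupTree,
    haplogroup: str,
    calls: Sequence[ObservedCall],
) -> PlacementPartition:
    """Partition homoplasmic variants by placement on the phylogeny.

    ``expected`` — in the assigned haplogroup's expected set;
    ``out_of_place`` — haplogroup-defining on some other branch (local
    private); ``global_private`` — on no edge of the tree at all.
    """
    if haplogroup not in tree:
        raise KeyError(f"unknown haplogroup {haplogroup!r}")
    expected_keys = {v.key for v in tree.expected_variants(haplogroup)}
    partition = PlacementPartition()
    for call in calls:
        if call.key in expected_keys:
            partition.expected.add(call.key)
        elif tree.defining_nodes(call.as_tree_variant()):
            partition.out_of_place.add(call.key)
        else:
            partition.global_private.add(call.key)
    return partition
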