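"""Seeded generators: toy phylogenies and case-control cohorts with truth.

The simulator emulates the structure of a targeted mtDNA case-control
study: each sample descends from a haplogroup drawn by macro-lineage
weight and carries that haplogroup's full expected variant set at
near-fixation heteroplasmy; out-of-place variants are injected from
branches diverging off the sample's maternal line — neither its root
path nor its descendants, whose variants would merely extend the
lineage — guaranteeing true local-private status, at a cohort-dependent
rate; global-private variants occupy
positions absent from every tree edge; and low-heteroplasmy, hotspot and
doubt-flagged decoys straddle the 50%/90% filter thresholds without ever
entering the homoplasmic analysis set.

Generating haplogroups are restricted to nodes carrying at least two
expected variants, mirroring real data (any non-reference haplogroup
carries many defining variants) and making haplogroup recovery exact in
the presence of a single injected out-of-place variant.

One global seed drives an independent substream per sample (spawn key =
sample index), so cohorts are reproducible and stable under changes of
cohort size.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotate import (NON_SYNONYMOUS, PROTEIN, GeneRecord, annotate_variant)
from .classify import EXPECTED, GLOBAL_PRIVATE, OUT_OF_PLACE, lineage_of
from .errors import ConfigError
from .phylotree import (RCRS_LENGTH, SUBSTITUTION, HaplogroupTree,
                        TreeEdgeVariant)
from .profiles import (CASE, CONTROL, DEFAULT_HOTSPOTS, ObservedCall,
                       SampleProfile, in_intervals)
from .stats import CATEGORY_LABELS

_BASES = "ACGT"

DEFAULT_LINEAGE_ROOTS = ("L0", "L1", "L2", "L3", "H", "U", "K", "T",
                         "J", "I", "W", "X", "V")


def simulate_reference(length: int = RCRS_LENGTH, seed: int = 0) -> str:
    """Random nucleotide sequence standing in for a reference genome."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_BASES), size=length))


def _child_name(parent: str, index: int) -> str:
    suffix = string.ascii_lowercase[index % 26] * (1 + index // 26) \
        if parent[-1].isdigit() else str(index + 1)
    return parent + suffix


def build_toy_tree(
    n_nodes: int = 40,
    variants_per_edge: tuple[int, int] = (1, 3),
    seed: int = 0,
    reference_sequence: str | None = None,
    genome_length: int = RCRS_LENGTH,
    avoid_intervals: Sequence[tuple[int, int]] = DEFAULT_HOTSPOTS,
    lineage_roots: Sequence[str] = DEFAULT_LINEAGE_ROOTS,
    root_variants_per_edge: tuple[int, int] = (10, 14),
) -> HaplogroupTree:
    """Random rooted haplogroup tree with unique edge-variant positions.

    Depth-1 nodes are named after macro-lineage roots (truncated to
    ``n_nodes``); deeper nodes get haplogroup-style derived names. Every
    edge carries variants at globally distinct positions outside
    ``avoid_intervals``, so expected sets are unique and filter-safe.
    Lineage-root edges carry long defining-variant chains
    (``root_variants_per_edge``), as macrohaplogroup stems do on the real
    maternal phylogeny; this keeps every lineage eligible as a cohort
    generator and keeps correctly assigned samples above a 90% quality
    gate even when they carry a couple of private variants.
    Deterministic for a fixed seed.
    """
    if n_nodes < 1:
        raise ConfigError("n_nodes must be >= 1")
    lo, hi = variants_per_edge
    if not (1 <= lo <= hi):
        raise ConfigError(f"bad variants_per_edge range {variants_per_edge}")
    if reference_sequence is not None:
        genome_length = len(reference_sequence)
    rng = np.random.default_rng(seed)
    pool = np.array([
        p for p in range(1, genome_length + 1)
        if not in_intervals(p, avoid_intervals)
    ])
    rng.shuffle(pool)
    pool_iter = iter(pool.tolist())

    def make_variants(count: int) -> list[TreeEdgeVariant]:
        out = []
        for _ in range(count):
            try:
                pos = next(pool_iter)
            except StopIteration:  # pragma: no cover - huge trees only
                raise ConfigError("genome exhausted: too many edge variants")
            if reference_sequence is not None:
                ref = reference_sequence[pos - 1]
            else:
                ref = _BASES[rng.integers(4)]
            alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
            out.append(TreeEdgeVariant(pos, ref, alt, SUBSTITUTION))
        return out

    edges: list[tuple[str, str | None, list[TreeEdgeVariant]]] = [
        ("ROOT", None, [])
    ]
    names = ["ROOT"]
    child_count: dict[str, int] = {}
    r_lo, r_hi = root_variants_per_edge
    if not (1 <= r_lo <= r_hi):
        raise ConfigError(
            f"bad root_variants_per_edge range {root_variants_per_edge}")
    for root in lineage_roots[: max(0, n_nodes - 1)]:
        edges.append((root, "ROOT",
                      make_variants(int(rng.integers(r_lo, r_hi + 1)))))
        names.append(root)
    while len(names) < n_nodes:
        parent = names[1 + int(rng.integers(len(names) - 1))]  # never ROOT
        idx = child_count.get(parent, 0)
        child_count[parent] = idx + 1
        name = _child_name(parent, idx)
        edges.append((name, parent,
                      make_variants(int(rng.integers(lo, hi + 1)))))
        names.append(name)
    return HaplogroupTree.from_edges(edges, genome_length)


# ---------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Parameters of the case-control cohort generator.

    Defaults emulate the significant discovery-vs-second-control
    comparison at desk scale: 70 cases vs 53 controls, out-of-place
    carrier probabilities 0.6 vs 0.2, an African-style lineage mix, and
    heteroplasmy draws straddling the 50%/90% thresholds.
    """

    n_cases: int = 70
    n_controls: int = 53
    lineage_weights: dict[str, float] = field(default_factory=lambda: {
        "L0": 0.50, "L1": 0.15, "L2": 0.15, "L3": 0.20,
    })
    p_out_of_place_case: float = 0.6
    p_out_of_place_control: float = 0.2
    p_global_private: float = 0.1
    oxphos_fraction: float = 1.0
    heteroplasmy_homoplasmic: tuple[float, float] = (0.95, 1.0)
    heteroplasmy_decoy: tuple[float, float] = (0.10, 0.90)
    decoy_mean: float = 1.0
    p_hotspot_decoy: float = 0.3
    p_doubt_decoy: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigError("cohort sizes must be >= 0")
        for name in ("p_out_of_place_case", "p_out_of_place_control",
                     "p_global_private", "oxphos_fraction",
                     "p_hotspot_decoy", "p_doubt_decoy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        total = sum(self.lineage_weights.values())
        if self.lineage_weights and abs(total - 1.0) > 1e-9:
            raise ConfigError(f"lineage_weights must sum to 1, got {total}")
        if any(w < 0 for w in self.lineage_weights.values()):
            raise ConfigError("lineage_weights must be non-negative")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated cohort."""

    haplogroups: dict[str, str] = field(default_factory=dict)
    placements: dict[str, dict[str, str]] = field(default_factory=dict)
    carriers: dict[str, dict[str, bool]] = field(default_factory=dict)

    def carrier_count(self, category: str, sample_ids: Sequence[str]) -> int:
        return sum(1 for sid in sample_ids if self.carriers[sid][category])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "haplogroups": self.haplogroups,
                "placements": self.placements,
                "carriers": self.carriers,
            }, fh, indent=1, sort_keys=True)


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(index,)))


def _is_oxphos_position(gene_map: Sequence[GeneRecord], position: int) -> bool:
    return any(g.covers(position) and g.category == PROTEIN and g.complex_
               for g in gene_map)


def simulate_cohort(
    tree: HaplogroupTree,
    gene_map: Sequence[GeneRecord],
    config: CohortSimConfig,
    reference_sequence: str | None = None,
    score_table: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[list[SampleProfile], SimTruth]:
    """Draw a seeded case-control cohort and its ground truth.

    ``reference_sequence`` (the frame the tree was built against) enables
    coding-effect truth for the synonymous/non-synonymous/scored carrier
    categories; without it those categories are recorded as non-carriers.
    ``score_table`` marks which non-synonymous variants count as scored.
    """
    score_table = score_table or {}
    lineages = sorted(config.lineage_weights)
    weights = np.array([config.lineage_weights[lin] for lin in lineages])

    eligible: dict[str, list[str]] = {lin: [] for lin in lineages}
    expected_cache: dict[str, set[TreeEdgeVariant]] = {}
    for name in tree:
        expected_cache[name] = tree.expected_variants(name)
        lin = lineage_of(name) if name != tree.root_name else None
        if lin in eligible and len(expected_cache[name]) >= 2:
            eligible[lin].append(name)
    for lin in lineages:
        if config.lineage_weights[lin] > 0 and not eligible[lin]:
            raise ConfigError(
                f"lineage {lin!r} has positive weight but no tree node with "
                ">= 2 expected variants"
            )
        eligible[lin].sort()

    all_forward = sorted(tree.all_forward_variants(), key=lambda v: v.key)
    children: dict[str, list[str]] = {}
    for name, node in tree.nodes.items():
        if node.parent is not None:
            children.setdefault(node.parent, []).append(name)

    def clade_of(name: str) -> set[str]:
        out, stack = set(), [name]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(children.get(cur, ()))
        return out

    tree_positions = {v.position for node in tree.nodes.values()
                     for v in node.variants}
    genome_length = tree.genome_length
    free_positions = np.array([
        p for p in range(1, genome_length + 1)
        if p not in tree_positions and not in_intervals(p, DEFAULT_HOTSPOTS)
    ])
    hotspot_positions = np.array([
        p for lo, hi in DEFAULT_HOTSPOTS for p in range(lo, hi + 1)
        if p not in tree_positions
    ])

    def annotate_truth(call: ObservedCall) -> dict[str, bool]:
        oxphos = _is_oxphos_position(gene_map, call.position)
        effect = None
        if reference_sequence is not None:
            effect = annotate_variant(gene_map, reference_sequence, call).effect
        return {
            "oxphos_any": oxphos,
            "oxphos_synonymous": oxphos and effect == "synonymous",
            "oxphos_non_synonymous": oxphos and effect == NON_SYNONYMOUS,
            "oxphos_scored_non_synonymous": (
                oxphos and effect == NON_SYNONYMOUS and call.key in score_table
            ),
        }

    profiles: list[SampleProfile] = []
    truth = SimTruth()
    n_total = config.n_cases + config.n_controls
    for i in range(n_total):
        cohort = CASE if i < config.n_cases else CONTROL
        sample_id = f"{'case' if cohort == CASE else 'ctrl'}{i:04d}"
        rng = _sample_rng(config.seed, i)
        lineage = lineages[int(rng.choice(len(lineages), p=weights))]
        node = eligible[lineage][int(rng.integers(len(eligible[lineage])))]
        expected = sorted(expected_cache[node], key=lambda v: v.key)
        # exclude the maternal line AND its descendants: a variant on a
        # descendant edge would extend the lineage, not occur out of place
        path = tree.path_to_root(node)
        own_line = set(path) | clade_of(node)
        line_positions = {
            v.position
            for name in own_line
            for v in tree.nodes[name].variants
        }
        used = set(line_positions)
        calls: list[ObservedCall] = []
        placements: dict[str, str] = {}
        carriers = {cat: False for cat in CATEGORY_LABELS}

        def hom_het(r: np.random.Generator) -> float:
            lo, hi = config.heteroplasmy_homoplasmic
            return float(r.uniform(lo, hi))

        for v in expected:
            calls.append(ObservedCall(v.position, v.ref_allele, v.alt_allele,
                                      v.kind, hom_het(rng)))
            placements[v.key] = EXPECTED

        p_oop = (config.p_out_of_place_case if cohort == CASE
                 else config.p_out_of_place_control)
        if rng.random() < p_oop:
            candidates = [v for v in all_forward if v.position not in used]
            ox = [v for v in candidates
                  if _is_oxphos_position(gene_map, v.position)]
            non_ox = [v for v in candidates
                      if not _is_oxphos_position(gene_map, v.position)]
            pool = ox if (rng.random() < config.oxphos_fraction and ox) \
                else (non_ox or ox)
            if not pool:
                raise ConfigError("no out-of-place candidate variants exist "
                                  "outside this sample's root path")
            v = pool[int(rng.integers(len(pool)))]
            used.add(v.position)
            call = ObservedCall(v.position, v.ref_allele, v.alt_allele,
                                v.kind, hom_het(rng))
            calls.append(call)
            placements[v.key] = OUT_OF_PLACE
            carriers = annotate_truth(call)

        if rng.random() < config.p_global_private:
            free = free_positions[~np.isin(free_positions, list(used))]
            pos = int(free[int(rng.integers(len(free)))])
            used.add(pos)
            ref = (reference_sequence[pos - 1] if reference_sequence
                   else _BASES[rng.integers(4)])
            alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
            call = ObservedCall(pos, ref, alt, SUBSTITUTION, hom_het(rng))
            calls.append(call)
            placements[call.key] = GLOBAL_PRIVATE

        # decoys: exercised by the filters, invisible to the analysis set
        for _ in range(int(rng.poisson(config.decoy_mean))):
            free = free_positions[~np.isin(free_positions, list(used))]
            pos = int(free[int(rng.integers(len(free)))])
            used.add(pos)
            ref = (reference_sequence[pos - 1] if reference_sequence
                   else _BASES[rng.integers(4)])
            alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
            lo, hi = config.heteroplasmy_decoy
            calls.append(ObservedCall(pos, ref, alt, SUBSTITUTION,
                                      float(rng.uniform(lo, hi))))
        if len(hotspot_positions) and rng.random() < config.p_hotspot_decoy:
            pos = int(hotspot_positions[int(rng.integers(
                len(hotspot_positions)))])
            if pos not in used:
                used.add(pos)
                ref = (reference_sequence[pos - 1] if reference_sequence
                       else _BASES[rng.integers(4)])
                alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
                calls.append(ObservedCall(pos, ref, alt, SUBSTITUTION,
                                          hom_het(rng)))
        if rng.random() < config.p_doubt_decoy:
            free = free_positions[~np.isin(free_positions, list(used))]
            pos = int(free[int(rng.integers(len(free)))])
            ref = (reference_sequence[pos - 1] if reference_sequence
                   else _BASES[rng.integers(4)])
            alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
            calls.append(ObservedCall(pos, ref, alt, SUBSTITUTION,
                                      hom_het(rng), doubt_flag=True))

        profiles.append(SampleProfile(sample_id, cohort,
                                      "simulated", calls))
        truth.haplogroups[sample_id] = node
        truth.placements[sample_id] = placements
        truth.carriers[sample_id] = carriers
    return profiles, truth


def simulate_score_table(
    tree: HaplogroupTree,
    gene_map: Sequence[GeneRecord],
    reference_sequence: str,
    coverage: float = 0.75,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Synthetic MitImpact-style score table for the tree's variants.

    Each non-synonymous substitution on a tree edge is included with
    probability ``coverage`` and given uniform pseudo-scores; synonymous
    and non-coding variants are never scored.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(0x5C0BE5,)))
    table: dict[str, dict[str, float]] = {}
    for v in sorted(tree.all_forward_variants(), key=lambda v: v.key):
        if v.kind != SUBSTITUTION:
            continue
        call = ObservedCall(v.position, v.ref_allele, v.alt_allele, v.kind)
        ann = annotate_variant(gene_map, reference_sequence, call)
        if ann.effect == NON_SYNONYMOUS and rng.random() < coverage:
            table[v.key] = {
                "APOGEE": round(float(rng.uniform()), 3),
                "MToolBox": round(float(rng.uniform()), 3),
            }
    return table


def simulate_carrier_counts(
    n_cases: int,
    n_controls: int,
    p_case: float,
    p_control: float,
    n_replicates: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial-level carrier counts for calibration and power studies.

    Returns per-replicate case and control carrier counts drawn with the
    given carrier probabilities — the sampling model underlying a single
    carrier-category comparison.
    """
    rng = np.random.default_rng(seed)
    a = rng.binomial(n_cases, p_case, size=n_replicates)
    c = rng.binomial(n_controls, p_control, size=n_replicates)
    return a, c


@dataclass
class SimulatedStudy:
    """Bundle produced by :func:`simulate_study`."""

    tree: HaplogroupTree
    reference_sequence: str
    gene_map: list[GeneRecord]
    score_table: dict[str, dict[str, float]]
    profiles: list[SampleProfile]
    truth: SimTruth


def simulate_study(
    config: CohortSimConfig,
    gene_map: Sequence[GeneRecord] | None = None,
    n_tree_nodes: int = 40,
    variants_per_edge: tuple[int, int] = (1, 3),
    score_coverage: float = 0.75,
) -> SimulatedStudy:
    """Generate a complete self-contained study from one seed.

    Builds a random reference genome and toy tree, a synthetic score
    table, and a seeded cohort, all deterministic functions of
    ``config.seed``. The packaged rCRS gene map is used by default.
    """
    from .annotate import load_gene_map

    gene_map = list(gene_map) if gene_map is not None else load_gene_map()
    genome_length = max(g.end for g in gene_map)
    ref = simulate_reference(genome_length, seed=config.seed)
    tree = build_toy_tree(n_tree_nodes, variants_per_edge, seed=config.seed,
                          reference_sequence=ref)
    score_table = simulate_score_table(tree, gene_map, ref,
                                       coverage=score_coverage,
                                       seed=config.seed)
    profiles, truth = simulate_cohort(tree, gene_map, config, ref,
                                      score_table)
    return SimulatedStudy(tree, ref, gene_map, score_table, profiles, truth)
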