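"""Case-control study object and fitted results.

:class:`OutOfPlaceStudy` bundles the inputs of an out-of-place mtDNA
variant analysis (sample profiles, haplogroup tree, gene map, optional
reference sequence and lookup tables) with its thresholds, and
``fit()`` executes the pipeline:

    filter calls -> assign haplogroups -> gate samples ->
    partition placements -> annotate -> carrier comparisons

returning an :class:`OutOfPlaceResults` carrying the four category
comparisons, the per-lineage frequency tests, the per-variant partition
report, the exclusion log and stage-count bookkeeping. Re-fitting the
same study is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import annotate as _annotate
from . import classify, profiles as _profiles, stats
from .errors import ConfigError, DataError
from .phylotree import HaplogroupTree, load_tree
from .profiles import CASE, DEFAULT_HOTSPOTS, SampleProfile
from .synthetic import CohortSimConfig, SimulatedStudy, simulate_study

log = logging.getLogger("mtoop")

#: run mode -> macro-lineage allow-list
RUN_MODES: dict[str, frozenset[str]] = {
    "african_discovery_vs_controls": classify.AFRICAN_LINEAGES,
    "discovery_vs_second_controls": classify.AFRICAN_LINEAGES,
    "european_replication": classify.EUROPEAN_LINEAGES,
}


@dataclass
class StageCounts:
    """Sample bookkeeping across pipeline stages."""

    samples_in: int = 0
    excluded_quality: int = 0
    excluded_lineage: int = 0
    analysed: int = 0
    n_cases: int = 0
    n_controls: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


class OutOfPlaceStudy:
    """Out-of-place mtDNA variant case-control analysis.

    Parameters
    ----------
    profiles
        Per-sample variant profiles (cases and controls together).
    tree
        Haplogroup phylogeny in the same coordinate frame as the calls.
    gene_map
        Mitochondrial gene map; defaults to the packaged rCRS map.
    reference_sequence
        Reference genome string enabling coding-effect annotation;
        without it, synonymy-dependent categories degenerate (effects
        fall back to ``"other"``).
    score_table, disease_table
        Optional pathogenicity-score and known-disease lookups.
    run_mode
        Selects the macro-lineage allow-list (African for the discovery
        comparisons, European for replication).
    """

    def __init__(
        self,
        profiles: Sequence[SampleProfile],
        tree: HaplogroupTree,
        gene_map: Sequence[_annotate.GeneRecord] | None = None,
        reference_sequence: str | None = None,
        score_table: Mapping[str, Mapping[str, float]] | None = None,
        disease_table: Mapping[str, str] | None = None,
        run_mode: str = "african_discovery_vs_controls",
        heteroplasmy_annotation: float = 0.50,
        heteroplasmy_homoplasmic: float = 0.90,
        min_quality: float = 0.90,
        alpha_family: float = 0.05,
        hotspot_regions: Sequence[tuple[int, int]] = DEFAULT_HOTSPOTS,
    ):
        if run_mode not in RUN_MODES:
            raise ConfigError(
                f"unknown run_mode {run_mode!r}; choose from "
                f"{sorted(RUN_MODES)}"
            )
        for name, value in (("heteroplasmy_annotation", heteroplasmy_annotation),
                            ("heteroplasmy_homoplasmic", heteroplasmy_homoplasmic),
                            ("min_quality", min_quality),
                            ("alpha_family", alpha_family)):
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        self.profiles = list(profiles)
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate sample_id in study profiles")
        self.tree = tree
        self.gene_map = (list(gene_map) if gene_map is not None
                         else _annotate.load_gene_map())
        self.reference_sequence = reference_sequence
        self.score_table = dict(score_table or {})
        self.disease_table = dict(disease_table or {})
        self.run_mode = run_mode
        self.allowed_lineages = RUN_MODES[run_mode]
        self.heteroplasmy_annotation = heteroplasmy_annotation
        self.heteroplasmy_homoplasmic = heteroplasmy_homoplasmic
        self.min_quality = min_quality
        self.alpha_family = alpha_family
        self.hotspot_regions = tuple(hotspot_regions)
        log.info(
            "study configured: run_mode=%s thresholds(annotation=%.2f, "
            "homoplasmic=%.2f, quality=%.2f) alpha_family=%.4g samples=%d",
            run_mode, heteroplasmy_annotation, heteroplasmy_homoplasmic,
            min_quality, alpha_family, len(self.profiles),
        )

    # -- constructors -------------------------------------------------

    @classmethod
    def from_files(
        cls,
        profiles_path: str | Path,
        tree_path: str | Path,
        gene_map_path: str | Path | None = None,
        reference_path: str | Path | None = None,
        score_table_path: str | Path | None = None,
        disease_table_path: str | Path | None = None,
        cohort_labels: Mapping[str, tuple[str, str]] | None = None,
        **kwargs,
    ) -> "OutOfPlaceStudy":
        """Build a study from the on-disk formats (profile TSV or VCF,
        tree TSV, gene map TSV, FASTA reference, lookup TSVs)."""
        reference = None
        if reference_path is not None:
            from Bio import SeqIO

            record = next(SeqIO.parse(str(reference_path), "fasta"))
            reference = str(record.seq).upper()
        score_table = (_annotate.load_score_table(score_table_path)
                       if score_table_path else None)
        disease_table = (_annotate.load_disease_table(disease_table_path)
                         if disease_table_path else None)
        return cls(
            _profiles.read_profiles(profiles_path, cohort_labels),
            load_tree(tree_path),
            _annotate.load_gene_map(gene_map_path) if gene_map_path else None,
            reference, score_table, disease_table, **kwargs,
        )

    @classmethod
    def from_simulation(
        cls, config: CohortSimConfig, **kwargs
    ) -> tuple["OutOfPlaceStudy", SimulatedStudy]:
        """Simulate a cohort and wrap it in a ready-to-fit study."""
        sim = simulate_study(config)
        study = cls(sim.profiles, sim.tree, sim.gene_map,
                    sim.reference_sequence, sim.score_table, **kwargs)
        return study, sim

    # -- fitting ------------------------------------------------------

    def fit(self) -> "OutOfPlaceResults":
        counts = StageCounts(samples_in=len(self.profiles))
        assigned: list[SampleProfile] = []
        analysis_calls: dict[str, list[_profiles.ObservedCall]] = {}
        for prof in self.profiles:
            calls = _profiles.filter_for_annotation(
                prof.calls, self.hotspot_regions, self.heteroplasmy_annotation)
            calls = _profiles.filter_homoplasmic(
                calls, self.heteroplasmy_homoplasmic)
            analysis_calls[prof.sample_id] = calls
            if prof.assigned_haplogroup is None or prof.haplogroup_quality is None:
                hap, quality = classify.assign_haplogroup(
                    self.tree, calls, self.hotspot_regions)
                prof = SampleProfile(prof.sample_id, prof.cohort, prof.group,
                                     prof.calls, hap, quality)
            assigned.append(prof)
        kept, exclusion_log = _profiles.filter_samples(
            assigned, self.min_quality, self.allowed_lineages)
        for sample_id, reason in exclusion_log:
            log.info("excluded sample %s: %s", sample_id, reason)
        counts.excluded_quality = sum(
            1 for _, r in exclusion_log if r == _profiles.EXCLUDE_QUALITY)
        counts.excluded_lineage = sum(
            1 for _, r in exclusion_log if r == _profiles.EXCLUDE_LINEAGE)
        counts.analysed = len(kept)

        analyzed: list[stats.AnalyzedSample] = []
        partition_rows = []
        for prof in kept:
            calls = analysis_calls[prof.sample_id]
            partition = classify.partition_variants(
                self.tree, prof.assigned_haplogroup, calls)
            variants = []
            for call in calls:
                ann = _annotate.annotate_variant(
                    self.gene_map, self.reference_sequence, call)
                ann = _annotate.attach_scores(ann, self.score_table)
                ann = _annotate.flag_known_pathogenic(ann, self.disease_table)
                ann.placement = partition.placement_of(call.key)
                variants.append(ann)
                partition_rows.append({
                    "sample_id": prof.sample_id,
                    "haplogroup": prof.assigned_haplogroup,
                    "quality": prof.haplogroup_quality,
                    "variant": call.key,
                    "placement": ann.placement,
                })
            analyzed.append(stats.AnalyzedSample(
                prof.sample_id, prof.cohort, variants,
                prof.assigned_haplogroup, prof.haplogroup_quality,
                classify.lineage_of(prof.assigned_haplogroup)))

        cases = [s for s in analyzed if s.cohort == CASE]
        controls = [s for s in analyzed if s.cohort != CASE]
        counts.n_cases, counts.n_controls = len(cases), len(controls)
        comparisons = stats.run_category_comparisons(
            cases, controls, self.alpha_family)
        lineage_results = stats.lineage_frequency_tests(
            cases, controls, self.alpha_family / len(stats.CATEGORY_LABELS))
        for r in comparisons + lineage_results:
            log.info("%s: table=%s p=%.4g alpha=%.4g significant=%s",
                     r.category, r.table.cells(), r.p_value, r.alpha,
                     r.significant)
        report = pd.DataFrame(
            partition_rows,
            columns=["sample_id", "haplogroup", "quality", "variant",
                     "placement"])
        return OutOfPlaceResults(self, comparisons, lineage_results,
                                 report, exclusion_log, counts, analyzed)


@dataclass
class OutOfPlaceResults:
    """Fitted study: comparison results, reports and diagnostics."""

    model: OutOfPlaceStudy
    comparisons: list[stats.ComparisonResult]
    lineage_comparisons: list[stats.ComparisonResult]
    partition_report: pd.DataFrame
    exclusion_log: list[tuple[str, str]]
    counts: StageCounts
    samples: list[stats.AnalyzedSample] = field(default_factory=list)

    def comparisons_frame(self) -> pd.DataFrame:
        return stats.results_frame(self.comparisons)

    def lineage_frame(self) -> pd.DataFrame:
        return stats.results_frame(self.lineage_comparisons)

    def summary(self) -> str:
        """Human-readable account of the fitted study."""
        c = self.counts
        lines = [
            "Out-of-place mtDNA variant analysis",
            "=" * 51,
            f"run mode:   {self.model.run_mode}",
            f"samples:    {c.samples_in} in; {c.excluded_quality} excluded "
            f"(quality <= {self.model.min_quality:.0%}), "
            f"{c.excluded_lineage} excluded (lineage)",
            f"analysed:   {c.analysed} ({c.n_cases} cases, "
            f"{c.n_controls} controls)",
            "",
            "Carrier comparisons (Fisher exact, two-sided; "
            f"alpha = {self.model.alpha_family:.2f}/4 = "
            f"{self.model.alpha_family / 4:.4f})",
            "-" * 51,
        ]
        frame = self.comparisons_frame()
        lines.append(frame.to_string(index=False,
                                     float_format=lambda x: f"{x:.4g}"))
        lines += ["", "Lineage frequency comparisons", "-" * 51,
                  self.lineage_frame().to_string(
                      index=False, float_format=lambda x: f"{x:.4g}")]
        return "\n".join(lines)

    def to_files(self, out_dir: str | Path) -> None:
        """Write the results TSV/JSON bundle to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.comparisons_frame().to_csv(out / "comparisons.tsv", sep="\t",
                                        index=False)
        self.lineage_frame().to_csv(out / "lineage_comparisons.tsv",
                                    sep="\t", index=False)
        self.partition_report.to_csv(out / "partition_report.tsv", sep="\t",
                                     index=False)
        pd.DataFrame(self.exclusion_log,
                     columns=["sample_id", "reason"]).to_csv(
            out / "exclusion_log.tsv", sep="\t", index=False)
        import json

        payload = {
            "counts": self.counts.as_dict(),
            "comparisons": self.comparisons_frame().to_dict("records"),
            "lineage_comparisons": self.lineage_frame().to_dict("records"),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(payload, fh, indent=1)


def run_pipeline(
    config: Mapping,
) -> OutOfPlaceResults:
    """Declarative-config entry point (used by the CLI ``run`` command).

    ``config`` mirrors :meth:`OutOfPlaceStudy.from_files` keys:
    ``profiles``, ``tree``, ``gene_map``, ``reference``, ``score_table``,
    ``disease_table``, ``run_mode`` and optional threshold overrides.
    """
    known_paths = {"profiles": "profiles_path", "tree": "tree_path",
                   "gene_map": "gene_map_path", "reference": "reference_path",
                   "score_table": "score_table_path",
                   "disease_table": "disease_table_path"}
    kwargs = {}
    for key, target in known_paths.items():
        if config.get(key):
            kwargs[target] = config[key]
    for key in ("run_mode", "heteroplasmy_annotation",
                "heteroplasmy_homoplasmic", "min_quality", "alpha_family"):
        if key in config:
            kwargs[key] = config[key]
    if "profiles_path" not in kwargs or "tree_path" not in kwargs:
        raise ConfigError("config must provide 'profiles' and 'tree' paths")
    study = OutOfPlaceStudy.from_files(**kwargs)
    return study.fit()
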