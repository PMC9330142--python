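"""Gene-level annotation of mtDNA variants.

Joins variants to a mitochondrial gene map, flags OXPHOS-complex
membership (the 13 mtDNA-encoded protein subunits of complexes I, III,
IV and V), classifies coding effect under the vertebrate mitochondrial
genetic code (TGA=Trp, AGA/AGG=stop, ATA=Met), and attaches precomputed
pathogenicity scores and known disease associations from lookup tables.

Light-strand genes (e.g. MT-ND6) are handled by reverse-complementing
the affected codon and both alleles before translation. Variants in
overlapping protein genes (ATP8/ATP6, ND4L/ND4) are evaluated in every
covering frame; the overall effect is non-synonymous if any frame is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import DataError, ParseError, ValidationError
from .profiles import ObservedCall
from .phylotree import SUBSTITUTION

HEAVY = "heavy"
LIGHT = "light"
PROTEIN = "protein"

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non_synonymous"
NONCODING = "noncoding"
OTHER_EFFECT = "other"

VERTEBRATE_MITO_TABLE = 2  # NCBI translation table id

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GeneRecord:
    """One feature of the mitochondrial gene map (1-based inclusive)."""

    name: str
    start: int
    end: int
    strand: str = HEAVY
    category: str = PROTEIN
    complex_: str | None = None  # OXPHOS complex: I, III, IV, V

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.name}: start > end")
        if self.strand not in (HEAVY, LIGHT):
            raise ValidationError(f"{self.name}: bad strand {self.strand!r}")
        if (self.complex_ is not None) != (self.category == PROTEIN):
            raise ValidationError(
                f"{self.name}: OXPHOS complex is set iff category is protein"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class AnnotatedVariant:
    """A variant joined to gene context, effect, scores and placement."""

    label: str
    position: int
    kind: str
    gene: str | None = None
    is_oxphos: bool = False
    effect: str = NONCODING
    per_gene_effects: dict[str, str] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)
    known_disease: str | None = None
    placement: str | None = None


def load_gene_map(path: str | Path | None = None) -> list[GeneRecord]:
    """Load a gene map TSV (columns name/start/end/strand/category/complex).

    With no path, the packaged map transcribed from the rCRS
    (NC_012920.1) annotation is returned.
    """
    if path is None:
        path = resources.files("mtoop.data") / "rcrs_gene_map.tsv"
    frame = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "start", "end", "strand", "category", "complex"}
    if not required.issubset(frame.columns):
        raise ParseError(f"gene map lacks column(s) "
                         f"{sorted(required - set(frame.columns))}", str(path))
    records = []
    for _, row in frame.iterrows():
        records.append(GeneRecord(
            row["name"], int(row["start"]), int(row["end"]),
            row["strand"], row["category"],
            row["complex"].strip() or None if row["category"] == PROTEIN else None,
        ))
    return records


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=VERTEBRATE_MITO_TABLE))


def _codon_effect(gene: GeneRecord, reference: str, call: ObservedCall) -> str:
    """Effect of a substitution within one protein gene's reading frame."""
    n_codons = gene.length // 3
    if gene.strand == HEAVY:
        offset = call.position - gene.start
    else:
        offset = gene.end - call.position
    if offset >= 3 * n_codons:
        # trailing 1-2 bases of an incomplete (polyadenylation-completed)
        # stop codon: no defined codon context
        return OTHER_EFFECT
    codon_index, within = divmod(offset, 3)
    if gene.strand == HEAVY:
        lo = gene.start + 3 * codon_index
        codon = reference[lo - 1: lo + 2]
        ref_base, alt_base = call.ref_allele, call.alt_allele
    else:
        hi = gene.end - 3 * codon_index
        codon = _revcomp(reference[hi - 3: hi])
        ref_base = call.ref_allele.translate(_COMPLEMENT)
        alt_base = call.alt_allele.translate(_COMPLEMENT)
    if codon[within] != ref_base:
        raise ValidationError(
            f"reference mismatch in {gene.name} at m.{call.position}: codon "
            f"has {codon[within]!r}, call declares ref {ref_base!r} "
            "(gene orientation)"
        )
    mutated = codon[:within] + alt_base + codon[within + 1:]
    return SYNONYMOUS if _translate(codon) == _translate(mutated) \
        else NON_SYNONYMOUS


def annotate_variant(
    gene_map: Sequence[GeneRecord],
    reference_sequence: str | None,
    call: ObservedCall,
) -> AnnotatedVariant:
    """Annotate one call with gene, OXPHOS membership and coding effect.

    ``reference_sequence`` may be ``None`` when only the gene join is
    needed (placement-level analyses); coding effects of protein-gene
    substitutions then fall back to ``"other"``.
    """
    if reference_sequence is not None:
        if not (1 <= call.position <= len(reference_sequence)):
            raise DataError(
                f"position {call.position} outside reference of length "
                f"{len(reference_sequence)}"
            )
        if call.kind == SUBSTITUTION:
            base = reference_sequence[call.position - 1]
            if base != call.ref_allele:
                raise ValidationError(
                    f"reference mismatch at m.{call.position}: sequence has "
                    f"{base!r}, call declares {call.ref_allele!r}"
                )
    covering = [g for g in gene_map if g.covers(call.position)]
    protein = [g for g in covering if g.category == PROTEIN]
    gene = protein[0].name if protein else (covering[0].name if covering else None)
    is_oxphos = any(g.complex_ for g in protein)
    per_gene: dict[str, str] = {}
    if not protein:
        effect = NONCODING
    elif call.kind != SUBSTITUTION or reference_sequence is None:
        effect = OTHER_EFFECT
    else:
        for g in protein:
            per_gene[g.name] = _codon_effect(g, reference_sequence, call)
        if NON_SYNONYMOUS in per_gene.values():
            effect = NON_SYNONYMOUS
        elif SYNONYMOUS in per_gene.values():
            effect = SYNONYMOUS
        else:
            effect = OTHER_EFFECT
    return AnnotatedVariant(call.key, call.position, call.kind, gene,
                            is_oxphos, effect, per_gene)


def attach_scores(
    annotated: AnnotatedVariant,
    score_table: Mapping[str, Mapping[str, float]],
) -> AnnotatedVariant:
    """Populate pathogenicity scores for non-synonymous variants.

    Scoring tools predict amino-acid-change impact, so only
    non-synonymous substitutions present in the table become "scored"
    (non-empty ``scores``); everything else is returned unchanged.
    """
    if annotated.effect == NON_SYNONYMOUS and annotated.label in score_table:
        return replace(annotated, scores=dict(score_table[annotated.label]))
    return annotated


def flag_known_pathogenic(
    annotated: AnnotatedVariant,
    disease_table: Mapping[str, str],
) -> AnnotatedVariant:
    """Attach a known disease association (e.g. LHON) when listed."""
    disease = disease_table.get(annotated.label)
    if disease is not None:
        return replace(annotated, known_disease=disease)
    return annotated


def load_score_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a long-format score TSV (variant / score_name / value)."""
    frame = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    required = {"variant", "score_name", "value"}
    if not required.issubset(frame.columns):
        raise ParseError(f"score table lacks column(s) "
                         f"{sorted(required - set(frame.columns))}", str(path))
    table: dict[str, dict[str, float]] = {}
    for _, row in frame.iterrows():
        table.setdefault(row["variant"], {})[row["score_name"]] = \
            float(row["value"])
    return table


def load_disease_table(path: str | Path | None = None) -> dict[str, str]:
    """Read a disease-association TSV (variant / disease).

    With no path, the packaged table of confirmed pathogenic mtDNA
    variants (Mitomap-style) is returned.
    """
    if path is None:
        path = resources.files("mtoop.data") / "disease_table.tsv"
    frame = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    if not {"variant", "disease"}.issubset(frame.columns):
        raise ParseError("disease table needs columns variant, disease",
                         str(path))
    return dict(zip(frame["variant"], frame["disease"]))
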