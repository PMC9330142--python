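"""Per-sample variant profiles: readers, heteroplasmy filters, sample gates.

Two input formats are supported: VCF 4.x (single mitochondrial contig,
per-sample allele-fraction FORMAT field) and a flat profile TSV with one
row per (sample, variant). Coordinates are 1-based inclusive throughout,
matching ``m.`` nomenclature.

The two variant filters mirror the analysis protocol: an annotation-stage
filter dropping homopolymer-region calls, doubt heteroplasmies and calls
at heteroplasmy <= 50%, and a homoplasmy gate keeping only operationally
homoplasmic calls (heteroplasmy > 90%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, ParseError, ValidationError
from .phylotree import (DELETION, INSERTION, SUBSTITUTION, TreeEdgeVariant,
                        parse_variant_label)

#: Common mtDNA homopolymer (poly-C) tracts, 1-based inclusive. The
#: analysed protocols exclude "homopolymer regions" without enumerating
#: them; these tracts are the documented, overridable default.
DEFAULT_HOTSPOTS: tuple[tuple[int, int], ...] = (
    (302, 316),
    (513, 526),
    (16180, 16195),
)

CASE = "case"
CONTROL = "control"


def in_intervals(position: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(lo <= position <= hi for lo, hi in intervals)


@dataclass(frozen=True)
class ObservedCall:
    """One variant call in one sample, with its heteroplasmy fraction."""

    position: int
    ref_allele: str
    alt_allele: str
    kind: str = SUBSTITUTION
    heteroplasmy: float = 1.0
    doubt_flag: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.heteroplasmy <= 1.0):
            raise ValidationError(
                f"heteroplasmy must be in (0, 1], got {self.heteroplasmy}"
            )
        if self.kind == SUBSTITUTION and (
            len(self.ref_allele) != 1 or len(self.alt_allele) != 1
        ):
            raise ValidationError(
                "substitutions must have single-base ref and alt, got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )

    @property
    def key(self) -> str:
        """Canonical label shared with tree edge variants."""
        if self.kind == DELETION:
            return f"m.{self.position}del{self.ref_allele}"
        if self.kind == INSERTION:
            return f"m.{self.position}ins{self.alt_allele}"
        return f"m.{self.position}{self.ref_allele}>{self.alt_allele}"

    label = key

    def as_tree_variant(self) -> TreeEdgeVariant:
        return TreeEdgeVariant(self.position, self.ref_allele,
                               self.alt_allele, self.kind)


def call_from_label(label: str, heteroplasmy: float = 1.0,
                    doubt_flag: bool = False) -> ObservedCall:
    v = parse_variant_label(label)
    return ObservedCall(v.position, v.ref_allele, v.alt_allele, v.kind,
                        heteroplasmy, doubt_flag)


@dataclass
class SampleProfile:
    """One individual's mtDNA variant calls plus cohort metadata."""

    sample_id: str
    cohort: str
    group: str = ""
    calls: list[ObservedCall] = field(default_factory=list)
    assigned_haplogroup: str | None = None
    haplogroup_quality: float | None = None

    def __post_init__(self) -> None:
        if self.cohort not in (CASE, CONTROL):
            raise ValidationError(
                f"cohort must be 'case' or 'control', got {self.cohort!r} "
                f"for sample {self.sample_id!r}"
            )
        if self.haplogroup_quality is not None and not (
            0.0 <= self.haplogroup_quality <= 1.0
        ):
            raise ValidationError(
                f"haplogroup_quality must be in [0, 1], got "
                f"{self.haplogroup_quality}"
            )
        self.calls = sorted(self.calls, key=lambda c: (c.position, c.key))


# ---------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------

PROFILE_TSV_COLUMNS = ("sample_id", "cohort", "group", "variant",
                       "heteroplasmy", "doubt_flag")


def read_profiles(
    path: str | Path,
    cohort_labels: Mapping[str, tuple[str, str]] | None = None,
    fmt: str | None = None,
    af_field: str = "AF",
) -> list[SampleProfile]:
    """Read sample profiles from a VCF or a profile TSV.

    ``cohort_labels`` maps sample id to ``(cohort, group)``; it is required
    for VCF input (which carries no cohort metadata) and overrides the
    ``cohort``/``group`` columns of TSV input when given. ``af_field`` names
    the per-sample allele-fraction FORMAT field of VCF input.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "tsv"
    if fmt == "vcf":
        return _read_vcf(path, cohort_labels, af_field)
    return _read_profile_tsv(path, cohort_labels)


def _read_profile_tsv(
    path: Path, cohort_labels: Mapping[str, tuple[str, str]] | None
) -> list[SampleProfile]:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                            comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read profile TSV: {exc}", str(path)) from exc
    missing = [c for c in ("sample_id", "cohort", "variant", "heteroplasmy")
               if c not in frame.columns]
    if missing:
        raise ParseError(f"profile TSV lacks column(s) {missing}", str(path))
    profiles: dict[str, SampleProfile] = {}
    for idx, row in frame.iterrows():
        sid = row["sample_id"].strip()
        if not sid:
            raise ParseError("empty sample_id", str(path), int(idx) + 2)
        cohort, group = row["cohort"].strip(), row.get("group", "").strip()
        if cohort_labels is not None and sid in cohort_labels:
            cohort, group = cohort_labels[sid]
        hap = row.get("haplogroup", "").strip() or None
        qual_txt = row.get("haplogroup_quality", "").strip()
        qual = float(qual_txt) if qual_txt else None
        if sid not in profiles:
            profiles[sid] = SampleProfile(sid, cohort, group, [],
                                          hap, qual)
        else:
            prof = profiles[sid]
            if (prof.cohort, prof.group) != (cohort, group) or (
                hap is not None and prof.assigned_haplogroup not in (None, hap)
            ):
                raise ValidationError(
                    f"inconsistent metadata for duplicated sample {sid!r}"
                )
        label = row["variant"].strip()
        if not label:
            continue  # explicit empty-calls row
        het_txt = row["heteroplasmy"].strip()
        if not het_txt:
            raise ParseError(f"missing heteroplasmy for {sid}/{label}",
                             str(path), int(idx) + 2)
        doubt = row.get("doubt_flag", "").strip().lower() in {"1", "true", "yes"}
        profiles[sid].calls.append(
            call_from_label(label, float(het_txt), doubt)
        )
    out = list(profiles.values())
    for prof in out:
        prof.calls = sorted(prof.calls, key=lambda c: (c.position, c.key))
    return out


def _read_vcf(
    path: Path, cohort_labels: Mapping[str, tuple[str, str]] | None,
    af_field: str,
) -> list[SampleProfile]:
    from cyvcf2 import VCF  # deferred: htslib import is comparatively slow

    if cohort_labels is None:
        raise DataError("VCF input requires cohort_labels (sample -> "
                        "(cohort, group))")
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"cannot open VCF: {exc}", str(path)) from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError(f"duplicate sample_id in VCF header: {path}")
    calls: dict[str, list[ObservedCall]] = {s: [] for s in samples}
    for record in vcf:
        af = record.format(af_field)
        if af is None:
            raise ParseError(
                f"record at position {record.POS} lacks FORMAT/{af_field}",
                str(path),
            )
        for alt_idx, alt in enumerate(record.ALT):  # split multi-allelics
            ref, a, pos, kind = _normalise_vcf_allele(record.REF, alt,
                                                      record.POS)
            for s_idx, sample in enumerate(samples):
                frac = float(af[s_idx][min(alt_idx, af.shape[1] - 1)])
                if math.isnan(frac) or frac <= 0.0:
                    continue
                calls[sample].append(ObservedCall(pos, ref, a, kind, frac))
    out = []
    for sample in samples:
        if sample not in cohort_labels:
            raise DataError(f"sample {sample!r} missing from cohort_labels")
        cohort, group = cohort_labels[sample]
        out.append(SampleProfile(sample, cohort, group, calls[sample]))
    return out


def _normalise_vcf_allele(ref: str, alt: str, pos: int):
    """Reduce a VCF REF/ALT pair to (ref, alt, position, kind)."""
    if len(ref) == 1 and len(alt) == 1:
        return ref, alt, pos, SUBSTITUTION
    if len(ref) > len(alt) and ref.startswith(alt):
        # deletion with left anchor: position of first deleted base
        return ref[len(alt):], "", pos + len(alt), DELETION
    if len(alt) > len(ref) and alt.startswith(ref):
        return "", alt[len(ref):], pos + len(ref) - 1, INSERTION
    raise ParseError(f"unsupported complex allele {ref}>{alt} at {pos}")


# ---------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------

def filter_for_annotation(
    calls: Sequence[ObservedCall],
    hotspot_regions: Iterable[tuple[int, int]] = DEFAULT_HOTSPOTS,
    min_heteroplasmy: float = 0.50,
) -> list[ObservedCall]:
    """Annotation-stage filter.

    Drops doubt heteroplasmies, calls inside any hotspot/homopolymer
    interval, and calls at heteroplasmy <= ``min_heteroplasmy`` (the
    threshold itself is excluded). Order preserved; idempotent.
    """
    intervals = tuple(hotspot_regions)
    return [
        c for c in calls
        if not c.doubt_flag
        and not in_intervals(c.position, intervals)
        and c.heteroplasmy > min_heteroplasmy
    ]


def filter_homoplasmic(
    calls: Sequence[ObservedCall], min_heteroplasmy: float = 0.90
) -> list[ObservedCall]:
    """Keep only operationally homoplasmic calls (heteroplasmy > 90%)."""
    return [c for c in calls if c.heteroplasmy > min_heteroplasmy]


EXCLUDE_QUALITY = "quality"
EXCLUDE_LINEAGE = "lineage"


def filter_samples(
    profiles: Sequence[SampleProfile],
    min_quality: float = 0.90,
    allowed_lineages: Iterable[str] | None = None,
) -> tuple[list[SampleProfile], list[tuple[str, str]]]:
    """Sample exclusion gate: haplogroup quality, then macro-lineage.

    Excludes samples whose haplogroup quality score is <= ``min_quality``
    and, when ``allowed_lineages`` is given, samples whose macro-lineage
    is outside it. Returns the kept profiles and a machine-readable
    exclusion log of ``(sample_id, reason)`` pairs with reasons
    ``"quality"`` / ``"lineage"``.
    """
    from .classify import lineage_of  # local import avoids a module cycle

    allowed = set(allowed_lineages) if allowed_lineages is not None else None
    kept: list[SampleProfile] = []
    log: list[tuple[str, str]] = []
    for prof in profiles:
        if prof.assigned_haplogroup is None or prof.haplogroup_quality is None:
            raise ValidationError(
                f"sample {prof.sample_id!r} lacks an assigned haplogroup or "
                "quality score; assign before filtering"
            )
        if prof.haplogroup_quality <= min_quality:
            log.append((prof.sample_id, EXCLUDE_QUALITY))
        elif allowed is not None and lineage_of(prof.assigned_haplogroup) not in allowed:
            log.append((prof.sample_id, EXCLUDE_LINEAGE))
        else:
            kept.append(prof)
    return kept, log


def write_profile_tsv(profiles: Sequence[SampleProfile],
                      path: str | Path) -> None:
    """Serialise profiles to the flat TSV dialect (one row per call;
    samples without calls get a single empty-variant row)."""
    rows = []
    for prof in profiles:
        base = {
            "sample_id": prof.sample_id,
            "cohort": prof.cohort,
            "group": prof.group,
            "haplogroup": prof.assigned_haplogroup or "",
            "haplogroup_quality": (
                "" if prof.haplogroup_quality is None
                else f"{prof.haplogroup_quality:.6g}"
            ),
        }
        if not prof.calls:
            rows.append({**base, "variant": "", "heteroplasmy": "",
                         "doubt_flag": ""})
        for call in prof.calls:
            rows.append({
                **base,
                "variant": call.key,
                "heteroplasmy": f"{call.heteroplasmy:.6g}",
                "doubt_flag": "1" if call.doubt_flag else "0",
            })
    columns = ["sample_id", "cohort", "group", "variant", "heteroplasmy",
               "doubt_flag", "haplogroup", "haplogroup_quality"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
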