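"""Six-stage SNP filtering cascade and three-caller consensus.

Each caller's raw call set passes, in order, through:

1. bi-allelic SNP extraction,
2. removal of SNPs within a fixed distance of an indel called by the
   same caller (distance measured to the nearest base of the indel's
   reference span, boundary inclusive),
3. a strict phred quality cut (QUAL > 30 by default),
4. removal of sites inside low-complexity / repeat-masked intervals,
5. removal of sites whose total read depth across all samples exceeds a
   cap (3,000 by default) — the signature of collapsed repeats or locus
   duplications attracting excess reads,
6. genotype re-calling from allelic depths (>= 2 alternate reads and
   >= 1 reference read define a heterozygote; see
   :func:`recall_genotype`) followed by a missingness cut over the
   North American discovery panel,
7. removal of any site heterozygous in a doubled-haploid (DH) control —
   a DH fish is homozygous everywhere, so a heterozygous call there
   marks a paralogous sequence variant or similar mapping artifact.

Every stage is a pure, idempotent site filter, so the cascade's final
set is the conjunction of the per-stage predicates; the stage order is
kept only for the per-stage accounting in :class:`FilterReport`.

The consensus step intersects the three filtered call sets on exact
(chrom, pos, ref, alt) identity and reports the full seven-region Venn
decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CallSet,
    GENOTYPE_LABELS,
    IntervalSet,
    SampleMeta,
    VariantRecord,
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering cascade (defaults = study settings)."""

    indel_distance: int = 5  # bases; SNPs this close to an indel span are dropped
    min_qual: float = 30.0  # keep iff QUAL strictly greater
    max_site_depth: int = 3000  # keep iff total site depth <= cap
    max_missing_samples: int = 1  # per site, over the missingness roster
    min_alt_reads: int = 2  # reads required to accept the alternate allele
    min_ref_reads: int = 1  # reads required to accept the reference allele

    def __post_init__(self) -> None:
        for f in ("indel_distance", "min_qual", "max_site_depth",
                  "max_missing_samples", "min_alt_reads", "min_ref_reads"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass
class StageReport:
    stage: str
    records_in: int
    records_removed: int

    @property
    def records_out(self) -> int:
        return self.records_in - self.records_removed


@dataclass
class FilterReport:
    """Per-stage accounting for one caller's cascade run."""

    caller: str
    stages: list[StageReport] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        self.stages.append(StageReport(stage, n_in, n_in - n_out))

    def to_dict(self) -> dict:
        return {
            "caller": self.caller,
            "stages": [
                {"stage": s.stage, "in": s.records_in, "removed": s.records_removed,
                 "out": s.records_out}
                for s in self.stages
            ],
        }


def filter_biallelic_snp(callset: CallSet) -> tuple[CallSet, StageReport]:
    """Keep only single-base substitutions with exactly one alternate allele."""
    kept = [r for r in callset.records if r.is_biallelic_snp]
    return callset.subset(kept), StageReport("biallelic_snp", len(callset), len(callset) - len(kept))


def _indel_exclusion_tree(indels: Sequence[VariantRecord], distance: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in indels:
        start, end = rec.ref_span
        # 1-based positions within `distance` of [start, end]: [start-d, end+d]
        trees.setdefault(rec.chrom, IntervalTree()).addi(start - distance, end + distance + 1)
    return trees


def filter_indel_proximity(
    callset: CallSet, indels: Sequence[VariantRecord], distance: int = 5
) -> tuple[CallSet, StageReport]:
    """Drop SNPs whose gap to the nearest indel reference span is <= distance."""
    if distance < 0:
        raise ValueError("indel distance must be non-negative")
    trees = _indel_exclusion_tree(indels, distance)
    kept = []
    for r in callset.records:
        tree = trees.get(r.chrom)
        if tree is None or not tree.overlaps_point(r.pos):
            kept.append(r)
    return callset.subset(kept), StageReport(
        "indel_proximity", len(callset), len(callset) - len(kept)
    )


def filter_qual(callset: CallSet, min_qual: float = 30.0) -> tuple[CallSet, StageReport]:
    """Keep records with QUAL strictly greater than ``min_qual``."""
    kept = [r for r in callset.records if r.qual > min_qual]
    return callset.subset(kept), StageReport("qual", len(callset), len(callset) - len(kept))


def mask_repeats(callset: CallSet, mask: IntervalSet) -> tuple[CallSet, StageReport]:
    """Drop sites inside repeat-masked (low-complexity) intervals."""
    kept = [r for r in callset.records if not mask.contains(r.chrom, r.pos)]
    return callset.subset(kept), StageReport("repeat_mask", len(callset), len(callset) - len(kept))


def filter_depth(callset: CallSet, max_site_depth: int = 3000) -> tuple[CallSet, StageReport]:
    """Drop sites whose summed read depth exceeds the repeat-screen cap."""
    kept = [r for r in callset.records if r.site_depth <= max_site_depth]
    return callset.subset(kept), StageReport("site_depth", len(callset), len(callset) - len(kept))


def recall_genotype(ref_depth: int, alt_depth: int, config: FilterConfig = FilterConfig()) -> str:
    """Re-call one genotype from allelic read depths.

    An allele counts as present when enough reads support it (>= 2 for
    the alternate, >= 1 for the reference, by default).  Both present ->
    het; only alternate -> hom_alt; only reference -> hom_ref; neither
    -> missing.
    """
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be non-negative")
    alt_present = alt_depth >= config.min_alt_reads
    ref_present = ref_depth >= config.min_ref_reads
    if alt_present and ref_present:
        return "het"
    if alt_present:
        return "hom_alt"
    if ref_present:
        return "hom_ref"
    return "missing"


def recall_record(record: VariantRecord, config: FilterConfig = FilterConfig()) -> VariantRecord:
    """Vectorized :func:`recall_genotype` over every sample of a record."""
    alt_present = record.alt_depths >= config.min_alt_reads
    ref_present = record.ref_depths >= config.min_ref_reads
    calls = np.full(len(record.calls), MISSING, dtype=np.int8)
    calls[ref_present & ~alt_present] = HOM_REF
    calls[alt_present & ~ref_present] = HOM_ALT
    calls[alt_present & ref_present] = HET
    out = record.copy()
    out.calls = calls
    return out


def filter_missingness(
    callset: CallSet,
    max_missing_samples: int = 1,
    roster_subset: Sequence[SampleMeta] | None = None,
    config: FilterConfig = FilterConfig(),
    recall: bool = True,
) -> tuple[CallSet, StageReport]:
    """Re-call genotypes from depths, then cut on missing calls.

    ``roster_subset`` defaults to the North American samples — the
    discovery panel whose completeness the cut enforces.
    """
    if roster_subset is None:
        roster_subset = [s for s in callset.samples if s.continent == "NA"]
    if not roster_subset:
        raise ValueError("missingness roster subset is empty")
    ids = {s.sample_id for s in roster_subset}
    idx = np.asarray([i for i, s in enumerate(callset.samples) if s.sample_id in ids])
    kept = []
    n_in = len(callset)
    for rec in callset.records:
        if recall:
            rec = recall_record(rec, config)
        if int(np.sum(rec.calls[idx] == MISSING)) <= max_missing_samples:
            kept.append(rec)
    return callset.subset(kept), StageReport("missingness", n_in, n_in - len(kept))


def filter_dh_het(
    callset: CallSet, dh_samples: Sequence[SampleMeta] | None = None
) -> tuple[CallSet, StageReport]:
    """Drop sites heterozygous in any doubled-haploid control line.

    Missing DH genotypes never trigger removal.  With no DH samples in
    the roster the stage passes everything through with a warning.
    """
    if dh_samples is None:
        dh_samples = [s for s in callset.samples if s.is_doubled_haploid]
    if not dh_samples:
        warnings.warn("no doubled-haploid samples in roster; DH het filter is a pass-through")
        return callset.subset(list(callset.records)), StageReport("dh_het", len(callset), 0)
    ids = {s.sample_id for s in dh_samples}
    idx = np.asarray([i for i, s in enumerate(callset.samples) if s.sample_id in ids])
    kept = [r for r in callset.records if not np.any(r.calls[idx] == HET)]
    return callset.subset(kept), StageReport("dh_het", len(callset), len(callset) - len(kept))


def run_cascade(
    callset: CallSet,
    mask: IntervalSet,
    config: FilterConfig = FilterConfig(),
    indels: Sequence[VariantRecord] | None = None,
    missingness_roster: Sequence[SampleMeta] | None = None,
) -> tuple[CallSet, FilterReport]:
    """Apply the full cascade to one caller's call set.

    ``indels`` defaults to the indel records of ``callset`` itself, as
    the proximity screen uses the same caller's indel calls.
    """
    if indels is None:
        indels = [r for r in callset.records if r.variant_class == "indel"]
    report = FilterReport(caller=callset.caller)

    cs, st = filter_biallelic_snp(callset)
    report.stages.append(st)
    cs, st = filter_indel_proximity(cs, indels, config.indel_distance)
    report.stages.append(st)
    cs, st = filter_qual(cs, config.min_qual)
    report.stages.append(st)
    cs, st = mask_repeats(cs, mask)
    report.stages.append(st)
    cs, st = filter_depth(cs, config.max_site_depth)
    report.stages.append(st)
    cs, st = filter_missingness(cs, config.max_missing_samples, missingness_roster, config)
    report.stages.append(st)
    cs, st = filter_dh_het(cs)
    report.stages.append(st)
    cs.sort()
    return cs, report


@dataclass
class ConsensusResult:
    """Triple-intersection call set plus Venn accounting."""

    callset: CallSet  # genotypes taken from the reference caller
    venn: dict[str, int]  # 7 regions keyed e.g. 'freebayes_only', 'freebayes_gatk', 'all_three'
    reference_caller: str
    discordant_genotypes: int  # genotype cells where another caller disagrees with the reference

    def to_dict(self) -> dict:
        return {
            "venn": dict(self.venn),
            "reference_caller": self.reference_caller,
            "n_consensus": len(self.callset),
            "discordant_genotypes": self.discordant_genotypes,
        }


def consensus_intersect(callsets: Sequence[CallSet]) -> ConsensusResult:
    """Intersect exactly three filtered call sets on exact site identity.

    Genotypes of the shared set come from the reference caller (first by
    label order); genotype disagreement with the other callers is
    counted but not reconciled.
    """
    if len(callsets) != 3:
        raise ValueError(f"consensus requires exactly 3 call sets, got {len(callsets)}")
    rosters = [cs.sample_ids for cs in callsets]
    if rosters[0] != rosters[1] or rosters[0] != rosters[2]:
        raise ValueError("call sets must share an identical sample roster")
    by_label = sorted(callsets, key=lambda c: c.caller)
    labels = [c.caller for c in by_label]
    if len(set(labels)) != 3:
        raise ValueError("caller labels must be distinct")
    keysets = {c.caller: set(c.site_keys) for c in by_label}
    a, b, c = (keysets[l] for l in labels)

    venn = {
        f"{labels[0]}_only": len(a - b - c),
        f"{labels[1]}_only": len(b - a - c),
        f"{labels[2]}_only": len(c - a - b),
        f"{labels[0]}_{labels[1]}": len((a & b) - c),
        f"{labels[0]}_{labels[2]}": len((a & c) - b),
        f"{labels[1]}_{labels[2]}": len((b & c) - a),
        "all_three": len(a & b & c),
    }

    shared = a & b & c
    ref_caller = by_label[0]
    shared_records = [r for r in ref_caller.records if r.key in shared]
    consensus = CallSet(caller="consensus", samples=ref_caller.samples,
                        records=[r.copy() for r in shared_records])

    discordant = 0
    ref_calls = {r.key: r.calls for r in shared_records}
    for other in by_label[1:]:
        for r in other.records:
            ref = ref_calls.get(r.key)
            if ref is not None:
                discordant += int(np.sum(r.calls != ref))
    return ConsensusResult(consensus, venn, ref_caller.caller, discordant)
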