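"""Core data model shared by every stage of the pipeline.

The atoms are :class:`VariantRecord` (one called variant with per-sample
read support) and :class:`SiteKey` (the identity of a bi-allelic site
across callers).  Per-sample fields are stored as numpy arrays aligned to
the sample roster rather than as one object per genotype, which keeps a
~20,000-site x 115-sample call set cheap to hold and filter.

Genotype codes follow the usual 0/1/2 dosage convention:

* ``HOM_REF = 0`` — homozygous reference
* ``HET = 1`` — heterozygous
* ``HOM_ALT = 2`` — homozygous alternate
* ``MISSING = -1`` — no call

so that the alternate-allele count of a non-missing genotype equals its
code, and subgroup allele counts are plain sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from intervaltree import IntervalTree

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

GENOTYPE_LABELS = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}
LABEL_CODES = {v: k for k, v in GENOTYPE_LABELS.items()}

VALID_STRAINS = ("GNB", "PR", "SJR", "EUR_WILD", "EUR_DH")
CALLERS = ("freebayes", "gatk", "mpileup")  # label order; first is the reference caller


class SiteKey(NamedTuple):
    """Identity of a bi-allelic site: records match across callers iff equal."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced fish: id, breeding strain, year-class, continent, DH status."""

    sample_id: str
    strain: str
    continent: str
    year_class: str | None = None
    is_doubled_haploid: bool = False

    def __post_init__(self) -> None:
        if self.strain not in VALID_STRAINS:
            raise ValueError(f"unknown strain label {self.strain!r} for sample {self.sample_id}")
        if self.continent not in ("NA", "EU"):
            raise ValueError(f"continent must be NA or EU, got {self.continent!r}")
        if self.is_doubled_haploid and self.continent != "EU":
            raise ValueError(
                f"doubled-haploid sample {self.sample_id} must be European (continent EU)"
            )
        if self.strain.startswith("EUR") and self.continent != "EU":
            raise ValueError(f"strain {self.strain} requires continent EU ({self.sample_id})")


def validate_roster(samples: Sequence[SampleMeta]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids in roster: {dup}")


@dataclass(frozen=True)
class GenotypeCall:
    """A single sample's call at a site, with its supporting read depths."""

    ref_depth: int
    alt_depth: int
    call: str  # hom_ref | het | hom_alt | missing

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("read depths must be non-negative")
        if self.call not in LABEL_CODES:
            raise ValueError(f"unknown genotype label {self.call!r}")


def classify_alleles(ref: str, alts: Sequence[str]) -> str:
    """snp iff ref and every alt are single bases; symbolic alleles -> other."""
    alleles = [ref, *alts]
    if any(a is None or a == "" for a in alleles):
        return "other"
    if any(set(a) - set("ACGTNacgtn") for a in alleles):
        return "other"
    if all(len(a) == 1 for a in alleles):
        return "snp"
    return "indel"


@dataclass
class VariantRecord:
    """One called variant; per-sample fields are arrays aligned to the roster."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    site_depth: int  # caller-reported total reads over all samples (DP)
    calls: np.ndarray  # int8 codes, MISSING = -1
    ref_depths: np.ndarray  # int32
    alt_depths: np.ndarray  # int32

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based (got {self.pos})")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.ref_depths = np.asarray(self.ref_depths, dtype=np.int32)
        self.alt_depths = np.asarray(self.alt_depths, dtype=np.int32)
        if not (len(self.calls) == len(self.ref_depths) == len(self.alt_depths)):
            raise ValueError("per-sample arrays must have equal length")

    @property
    def variant_class(self) -> str:
        return classify_alleles(self.ref, self.alts)

    @property
    def is_biallelic_snp(self) -> bool:
        return len(self.alts) == 1 and self.variant_class == "snp"

    @property
    def key(self) -> SiteKey:
        return SiteKey(self.chrom, self.pos, self.ref, self.alts[0] if self.alts else "")

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive reference span affected by this record."""
        return self.pos, self.pos + len(self.ref) - 1

    def genotype(self, i: int) -> GenotypeCall:
        return GenotypeCall(
            int(self.ref_depths[i]), int(self.alt_depths[i]), GENOTYPE_LABELS[int(self.calls[i])]
        )

    def copy(self) -> "VariantRecord":
        return replace(
            self,
            alts=tuple(self.alts),
            calls=self.calls.copy(),
            ref_depths=self.ref_depths.copy(),
            alt_depths=self.alt_depths.copy(),
        )


@dataclass
class CallSet:
    """All variants reported by one caller over a fixed sample roster."""

    caller: str
    samples: list[SampleMeta]
    records: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_roster(self.samples)
        self.sort()

    def sort(self) -> None:
        self.records.sort(key=lambda r: r.key)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def site_keys(self) -> list[SiteKey]:
        return [r.key for r in self.records]

    def subset(self, records: Iterable[VariantRecord]) -> "CallSet":
        return CallSet(self.caller, self.samples, list(records))

    def __len__(self) -> int:
        return len(self.records)


class IntervalSet:
    """Per-chromosome merged intervals, 0-based half-open (BED convention).

    Membership for a 1-based position ``p`` is ``p - 1 in [start, end)``.
    Merging collapses overlapping and book-ended intervals so iteration
    yields disjoint, sorted spans.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for tree in trees.values():
            tree.merge_overlaps(strict=False)  # strict=False also merges book-ended
        self._trees = trees

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff the 1-based position ``pos`` lies inside an interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end) for iv in tree)

    def chroms(self) -> list[str]:
        return sorted(self._trees)

    def total_length(self) -> int:
        return sum(e - b for c in self._trees.values() for b, e in ((iv.begin, iv.end) for iv in c))

    def __bool__(self) -> bool:
        return any(len(t) for t in self._trees.values())


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype dosage matrix (codes 0/1/2, -1 missing)."""

    site_keys: list[SiteKey]
    sample_ids: list[str]
    codes: np.ndarray  # (n_sites, n_samples) int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.site_keys), len(self.sample_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.site_keys)} sites x {len(self.sample_ids)} samples"
            )
        bad = set(np.unique(self.codes)) - {-1, 0, 1, 2}
        if bad:
            raise ValueError(f"invalid genotype codes present: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return len(self.site_keys)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.asarray([index[s] for s in sample_ids], dtype=np.intp)

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(sample_ids)
        return GenotypeMatrix(list(self.site_keys), list(sample_ids), self.codes[:, idx])

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            [self.site_keys[i] for i in idx], list(self.sample_ids), self.codes[idx]
        )


def matrix_from_callset(callset: CallSet) -> GenotypeMatrix:
    """Stack a call set's genotype codes into a sites x samples matrix."""
    if callset.records:
        codes = np.vstack([r.calls for r in callset.records])
    else:
        codes = np.empty((0, len(callset.samples)), dtype=np.int8)
    return GenotypeMatrix(callset.site_keys, callset.sample_ids, codes)
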