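"""Ground-truth simulator for the whole pipeline.

Generates a toy salmon-like genome (repeat-masked tiles, homeologous
duplicate blocks, collapsed-repeat blocks), a structured cohort (three
North American aquaculture strains with year-classes, wild European
fish, and doubled-haploid European controls), true genotypes per site
class, and three emulated caller call sets with caller-specific
sensitivity, false positives, quality scores and noise.

Site classes and what each one exercises downstream:

* ``clean_snp``        — ordinary segregating SNPs; should survive the cascade.
* ``continental_fixed``— alternate allele fixed in NA, reference fixed in
                         EU; the diagnostic-panel truth.
* ``psv``              — paralogous-sequence-variant artifacts inside
                         homeologous blocks: heterozygous in *every*
                         sample including the doubled haploids; removed
                         by the DH-het filter.
* ``deep_repeat``      — sites in collapsed repeats whose summed depth is
                         forced above the depth cap; removed by the
                         depth filter.
* ``masked_snp``       — segregating SNPs inside the low-complexity BED
                         mask; removed by the repeat-mask filter.
* ``indel``            — insertion/deletion records; removed at the
                         bi-allelic SNP stage.
* ``near_indel_snp``   — SNPs placed within the exclusion distance of an
                         indel; removed by the proximity filter.
* ``multiallelic``     — SNPs with two alternate alleles; removed at the
                         bi-allelic stage.

Population model: each site draws an ancestral allele frequency from a
Beta distribution; continent, strain and year-class frequencies are
nested Balding–Nichols (Beta) perturbations with configurable drift
intensities; genotypes are Hardy–Weinberg draws within each terminal
group.  Doubled haploids draw one allele and double it, so they are
homozygous everywhere except at planted PSV artifacts.

Everything is deterministic given the seed: one master SeedSequence is
spawned into independent streams for layout, populations and each
caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    HET,
    MISSING,
    CallSet,
    GenotypeMatrix,
    IntervalSet,
    SampleMeta,
    SiteKey,
    VariantRecord,
)
from . import variant_io

SITE_CLASSES = (
    "clean_snp", "continental_fixed", "psv", "deep_repeat",
    "masked_snp", "indel", "near_indel_snp", "multiallelic",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CallerProfile:
    """Behaviour of one emulated variant caller."""

    sensitivity: float = 1.0  # probability of reporting each true site
    fp_rate: float = 0.0  # false positives as a fraction of true-site count
    genotype_error: float = 0.0  # per-genotype probability of a wrong call
    missing_rate: float = 0.0  # per-genotype probability of a masked call
    qual_below_min_frac: float = 0.0  # fraction of sites drawn with QUAL <= 30


#: Default caller behaviour, loosely ranked like the three real pipelines
#: (mpileup most permissive, freebayes least).
DEFAULT_CALLERS: dict[str, CallerProfile] = {
    "freebayes": CallerProfile(0.86, 0.02, 0.002, 0.003, 0.05),
    "gatk": CallerProfile(0.90, 0.04, 0.002, 0.003, 0.05),
    "mpileup": CallerProfile(0.96, 0.08, 0.002, 0.003, 0.05),
}


def default_roster() -> list[SampleMeta]:
    """The study cohort: 80 NA fish in three strains with year-classes,
    31 wild European fish and 4 European doubled haploids (115 total)."""
    plan = [
        ("GNB", "NA", [("12-13", 12), ("15-16", 4)]),
        ("PR", "NA", [("12-13", 6), ("13-14", 5)]),
        ("SJR", "NA", [("13-14", 14), ("14-15", 14), ("15-16", 12), ("16-17", 13)]),
    ]
    roster: list[SampleMeta] = []
    for strain, cont, ycs in plan:
        for yc, n in ycs:
            for i in range(n):
                roster.append(SampleMeta(f"{strain}_{yc.replace('-', '_')}_{i + 1:02d}",
                                         strain, cont, year_class=yc))
    roster += [SampleMeta(f"EUW_{i + 1:02d}", "EUR_WILD", "EU") for i in range(31)]
    roster += [SampleMeta(f"EUDH_{i + 1:02d}", "EUR_DH", "EU", is_doubled_haploid=True)
               for i in range(4)]
    return roster


@dataclass(frozen=True)
class SimConfig:
    """All simulator knobs in one place; ``seed`` is mandatory."""

    seed: int
    # genome layout
    n_chromosomes: int = 3
    chromosome_length: int = 1_000_000
    tile_size: int = 2_000
    mask_fraction: float = 0.30  # low-complexity fraction written to the BED mask
    homeolog_block_fraction: float = 0.25  # duplicated blocks hosting PSV artifacts
    collapsed_repeat_fraction: float = 0.02  # blocks hosting excess-depth sites
    # site counts per class
    n_clean_snp: int = 16_000
    n_continental_fixed: int = 200
    n_psv: int = 800
    n_deep_repeat: int = 400
    n_masked_snp: int = 400
    n_indel: int = 600
    n_near_indel_snp: int = 400
    n_multiallelic: int = 200
    # population model
    ancestral_beta: tuple[float, float] = (0.4, 0.4)
    continent_fst: float = 0.20
    strain_fst: Mapping[str, float] = field(
        default_factory=lambda: {"GNB": 0.15, "PR": 0.12, "SJR": 0.04}
    )
    year_class_fst: float = 0.02  # drift between year-classes within a strain
    freq_clip: tuple[float, float] = (0.02, 0.98)
    ld_block_copy_prob: float = 0.0  # optional LD mode: P(copy previous site's genotype)
    # sequencing depth
    depth_mean: float = 18.5  # mean per-sample coverage, as in the study
    depth_dispersion: float = 8.0  # negative-binomial size parameter
    depth_floor: int = 0  # clamp per-sample depths upward (0 = off)
    deep_total_depth: int = 3_100  # forced minimum summed depth at deep_repeat sites
    # caller emulation
    callers: Mapping[str, CallerProfile] = field(default_factory=lambda: dict(DEFAULT_CALLERS))
    min_qual: float = 30.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for f in ("mask_fraction", "homeolog_block_fraction", "collapsed_repeat_fraction",
                  "ld_block_copy_prob"):
            if not (0.0 <= getattr(self, f) <= 1.0):
                raise ValueError(f"{f} must be in [0, 1]")
        if self.mask_fraction + self.homeolog_block_fraction + self.collapsed_repeat_fraction > 1:
            raise ValueError("tile fractions exceed the genome")
        if any(n < 0 for n in self.class_counts().values()):
            raise ValueError("site counts must be non-negative")

    def class_counts(self) -> dict[str, int]:
        return {
            "clean_snp": self.n_clean_snp,
            "continental_fixed": self.n_continental_fixed,
            "psv": self.n_psv,
            "deep_repeat": self.n_deep_repeat,
            "masked_snp": self.n_masked_snp,
            "indel": self.n_indel,
            "near_indel_snp": self.n_near_indel_snp,
            "multiallelic": self.n_multiallelic,
        }

    def noiseless(self) -> "SimConfig":
        """Error-free caller settings: every true site reported, no false
        positives, no genotype noise, depths floored so no call is missing."""
        clean = {
            name: CallerProfile(1.0, 0.0, 0.0, 0.0, 0.0) for name in self.callers
        }
        return replace(self, callers=clean, depth_floor=6)


@dataclass
class GenomeLayout:
    """Tile-level genome annotation plus collision-free site placements."""

    chromosome_lengths: dict[str, int]
    mask: IntervalSet  # low-complexity intervals (the BED input)
    homeolog_blocks: IntervalSet
    collapsed_blocks: IntervalSet
    placements: dict[str, list[tuple[str, int]]]  # class -> [(chrom, 1-based pos)]
    indel_partners: list[tuple[tuple[str, int], tuple[str, int]]]  # (indel, nearby SNP)


@dataclass
class SimTruth:
    """Everything the generator knows: classes, genotypes, frequencies."""

    config: SimConfig
    layout: GenomeLayout
    roster: list[SampleMeta]
    site_class: dict[SiteKey, str]
    alleles: dict[SiteKey, tuple[str, tuple[str, ...]]]  # ref, alts per truth site
    matrix: GenotypeMatrix  # true genotypes, all truth sites x all samples
    group_freqs: dict[str, np.ndarray]  # terminal group label -> per-site allele freq
    group_members: dict[str, list[str]]  # terminal group label -> sample ids

    def keys_of_class(self, cls: str) -> list[SiteKey]:
        return [k for k in self.matrix.site_keys if self.site_class[k] == cls]

    def true_diagnostic_sites(self) -> set[SiteKey]:
        """Sites fixed for opposite homozygotes between the true NA genotypes
        and the true wild-European genotypes (planted ones plus any that
        drifted to fixation by chance)."""
        na = [s.sample_id for s in self.roster if s.continent == "NA"]
        eu = [s.sample_id for s in self.roster if s.strain == "EUR_WILD"]
        ina = self.matrix.sample_indices(na)
        ieu = self.matrix.sample_indices(eu)
        out = set()
        for i, key in enumerate(self.matrix.site_keys):
            if self.site_class[key] not in ("clean_snp", "continental_fixed"):
                continue
            row = self.matrix.codes[i]
            a, b = np.unique(row[ina]), np.unique(row[ieu])
            if len(a) == 1 and len(b) == 1 and {int(a[0]), int(b[0])} == {0, 2}:
                out.add(key)
        return out


@dataclass
class SimOutput:
    truth: SimTruth
    callsets: dict[str, CallSet]
    emitted_true: dict[str, set[SiteKey]]  # caller -> true sites it reported
    false_positives: dict[str, set[SiteKey]]


# ---------------------------------------------------------------------------
# genome layout


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> GenomeLayout:
    """Tile the genome into mask / homeolog / collapsed / free blocks and
    place every site class collision-free in its designated territory."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    chrom_len = {f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)}

    tiles: dict[str, list[tuple[str, int, int]]] = {c: [] for c in
                                                    ("mask", "homeolog", "collapsed", "free")}
    for chrom, length in chrom_len.items():
        n_tiles = length // config.tile_size
        n_mask = round(config.mask_fraction * n_tiles)
        n_hom = round(config.homeolog_block_fraction * n_tiles)
        n_col = round(config.collapsed_repeat_fraction * n_tiles)
        labels = np.array(
            ["mask"] * n_mask + ["homeolog"] * n_hom + ["collapsed"] * n_col
            + ["free"] * (n_tiles - n_mask - n_hom - n_col)
        )
        rng.shuffle(labels)
        for t, lab in enumerate(labels):
            start = t * config.tile_size
            tiles[lab].append((chrom, start, start + config.tile_size))

    # slot grid: candidate positions every 15 bp, 8 bp in from tile edges,
    # so distinct placements never fall within indel-exclusion range of
    # each other and never straddle a tile boundary
    stride, pad = 15, 8

    def slots(tile_list):
        out = []
        for chrom, start, end in tile_list:
            out.extend((chrom, p) for p in range(start + pad + 1, end - pad, stride))
        return out

    pools = {lab: slots(tl) for lab, tl in tiles.items()}
    for pool in pools.values():
        rng.shuffle(pool)

    counts = config.class_counts()
    need_free = (counts["clean_snp"] + counts["continental_fixed"] + counts["indel"]
                 + counts["near_indel_snp"] + counts["multiallelic"])
    demands = [("free", need_free), ("mask", counts["masked_snp"]),
               ("homeolog", counts["psv"]), ("collapsed", counts["deep_repeat"])]
    for lab, need in demands:
        if need > len(pools[lab]):
            raise ValueError(
                f"site counts exceed available positions in {lab} territory "
                f"({need} requested, {len(pools[lab])} slots)"
            )

    placements: dict[str, list[tuple[str, int]]] = {}
    it = iter(pools["free"])
    for cls in ("clean_snp", "continental_fixed", "indel", "near_indel_snp", "multiallelic"):
        placements[cls] = sorted(next(it) for _ in range(counts[cls]))
    placements["masked_snp"] = sorted(pools["mask"][: counts["masked_snp"]])
    placements["psv"] = sorted(pools["homeolog"][: counts["psv"]])
    placements["deep_repeat"] = sorted(pools["collapsed"][: counts["deep_repeat"]])

    # pair each near-indel SNP with an indel a few bases away; the SNP slot
    # hosts the indel and the SNP sits 1-5 bp from the end of its span
    partners = []
    paired = []
    for chrom, pos in placements["near_indel_snp"]:
        gap = int(rng.integers(1, 6))
        snp_pos = pos + gap  # insertion at `pos` has span [pos, pos]
        partners.append(((chrom, pos), (chrom, snp_pos)))
        paired.append((chrom, snp_pos))
        placements["indel"].append((chrom, pos))  # the partner is a real indel record
    placements["near_indel_snp"] = paired
    placements["indel"].sort()
    layout = GenomeLayout(
        chromosome_lengths=chrom_len,
        mask=IntervalSet(tiles["mask"]),
        homeolog_blocks=IntervalSet(tiles["homeolog"]),
        collapsed_blocks=IntervalSet(tiles["collapsed"]),
        placements=placements,
        indel_partners=partners,
    )
    return layout


# ---------------------------------------------------------------------------
# populations and true genotypes


def _balding_nichols(p: np.ndarray, fst: float, rng: np.random.Generator,
                     clip: tuple[float, float]) -> np.ndarray:
    if fst <= 0:
        return p
    scale = (1.0 - fst) / fst
    out = rng.beta(np.clip(p, *clip) * scale, np.clip(1.0 - p, *clip) * scale)
    return np.clip(out, *clip)


def simulate_populations(
    config: SimConfig, layout: GenomeLayout, rng: np.random.Generator | None = None
) -> SimTruth:
    """Draw nested allele frequencies and true genotypes for every site."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    roster = default_roster()
    counts = config.class_counts()

    # assemble truth sites with alleles
    site_class: dict[SiteKey, str] = {}
    alleles: dict[SiteKey, tuple[str, tuple[str, ...]]] = {}
    keys: list[SiteKey] = []
    for cls in SITE_CLASSES:
        for chrom, pos in layout.placements[cls]:
            ref = str(rng.choice(_BASES))
            others = [b for b in "ACGT" if b != ref]
            if cls == "indel":
                if rng.random() < 0.5:  # insertion
                    ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 5))))
                    alts: tuple[str, ...] = (ref + ins,)
                else:  # deletion: ref spans 2-6 bases
                    ext = "".join(rng.choice(_BASES, size=int(rng.integers(1, 6))))
                    ref = ref + ext
                    alts = (ref[0],)
            elif cls == "multiallelic":
                two = rng.choice(others, size=2, replace=False)
                alts = (str(two[0]), str(two[1]))
            else:
                alts = (str(rng.choice(others)),)
            key = SiteKey(chrom, pos, ref, alts[0])
            site_class[key] = cls
            alleles[key] = (ref, alts)
            keys.append(key)
    keys.sort()
    n_sites = len(keys)
    classes = np.asarray([site_class[k] for k in keys])

    # nested allele frequencies
    lo, hi = config.freq_clip
    p_anc = np.clip(rng.beta(*config.ancestral_beta, size=n_sites), lo, hi)
    p_na = _balding_nichols(p_anc, config.continent_fst, rng, config.freq_clip)
    p_eu = _balding_nichols(p_anc, config.continent_fst, rng, config.freq_clip)

    group_freqs: dict[str, np.ndarray] = {}
    group_members: dict[str, list[str]] = {}
    na_strains = sorted({s.strain for s in roster if s.continent == "NA"})
    for strain in na_strains:
        p_strain = _balding_nichols(p_na, config.strain_fst.get(strain, 0.1), rng,
                                    config.freq_clip)
        group_freqs[strain] = p_strain
        ycs = sorted({s.year_class for s in roster if s.strain == strain})
        for yc in ycs:
            label = f"{strain}|{yc}"
            group_freqs[label] = _balding_nichols(p_strain, config.year_class_fst, rng,
                                                  config.freq_clip)
            group_members[label] = [s.sample_id for s in roster
                                    if s.strain == strain and s.year_class == yc]
    for label, members in (
        ("EUR_WILD", [s.sample_id for s in roster if s.strain == "EUR_WILD"]),
        ("EUR_DH", [s.sample_id for s in roster if s.strain == "EUR_DH"]),
    ):
        group_freqs[label] = p_eu
        group_members[label] = members

    fixed = classes == "continental_fixed"
    for label in list(group_freqs):
        strain = label.split("|")[0]
        freq = group_freqs[label].copy()
        freq[fixed] = 0.0 if strain.startswith("EUR") else 1.0
        group_freqs[label] = freq

    # genotype draws, Hardy-Weinberg within terminal group
    sample_ids = [s.sample_id for s in roster]
    col = {sid: j for j, sid in enumerate(sample_ids)}
    codes = np.zeros((n_sites, len(roster)), dtype=np.int8)
    dh_ids = {s.sample_id for s in roster if s.is_doubled_haploid}
    for label, members in group_members.items():
        freq = group_freqs[label]
        idx = [col[m] for m in members]
        if set(members) <= dh_ids:
            hap = rng.random((n_sites, len(idx))) < freq[:, None]
            codes[:, idx] = (2 * hap).astype(np.int8)
        else:
            g = rng.binomial(2, freq[:, None], size=(n_sites, len(idx)))
            if config.ld_block_copy_prob > 0:
                g = _apply_ld_copying(g, keys, classes == "clean_snp",
                                      config.ld_block_copy_prob, rng)
            codes[:, idx] = g.astype(np.int8)

    codes[classes == "psv", :] = HET  # duplication collapse: universal heterozygosity
    matrix = GenotypeMatrix(keys, sample_ids, codes)
    return SimTruth(config, layout, roster, site_class, alleles, matrix,
                    group_freqs, group_members)


def _apply_ld_copying(g: np.ndarray, keys: list[SiteKey], allowed: np.ndarray,
                      copy_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Optional LD mode: an eligible site copies the previous eligible
    same-chromosome site's genotype per sample with probability
    ``copy_prob``.  Only ordinary segregating SNPs take part, so planted
    fixed differences and artifact classes keep their signatures."""
    out = g.copy()
    prev: int | None = None
    for i in range(len(keys)):
        if not allowed[i]:
            continue
        if prev is not None and keys[i].chrom == keys[prev].chrom:
            copy = rng.random(g.shape[1]) < copy_prob
            out[i, copy] = out[prev, copy]
        prev = i
    return out


# ---------------------------------------------------------------------------
# caller emulation


def _depths_for(truth: SimTruth, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    cfg = truth.config
    size = cfg.depth_dispersion
    p = size / (size + cfg.depth_mean)
    d = rng.negative_binomial(size, p, size=(n_sites, truth.matrix.n_samples))
    if cfg.depth_floor > 0:
        d = np.maximum(d, cfg.depth_floor)
    return d.astype(np.int64)


def _ad_from_genotypes(gt: np.ndarray, depth: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Allelic depths consistent with the read-support re-calling rule.

    Returns (ref_depth, alt_depth, final_gt) where final_gt is the
    re-call of the produced depths: the intended genotype whenever the
    sampled depth can support it, otherwise missing.
    """
    d = depth
    alt = np.zeros_like(d)
    het = gt == 1
    split = rng.binomial(d, 0.5)
    alt[het] = np.clip(split[het], 2, np.maximum(d[het] - 1, 0))
    hom_alt = gt == 2
    alt[hom_alt] = d[hom_alt]
    hom_ref = gt == 0
    err = (rng.random(d.shape) < 0.03) & (d >= 2)
    alt[hom_ref] = np.where(err[hom_ref], 1, 0)
    ref = d - alt
    masked = gt == MISSING
    ref[masked] = 0
    alt[masked] = 0
    alt_ok = alt >= 2
    ref_ok = ref >= 1
    final = np.full(gt.shape, MISSING, dtype=np.int8)
    final[ref_ok & ~alt_ok] = 0
    final[alt_ok & ~ref_ok] = 2
    final[alt_ok & ref_ok] = 1
    return ref, alt, final


def _quals(n: int, profile: CallerProfile, min_qual: float,
           rng: np.random.Generator) -> np.ndarray:
    q = np.round(min_qual + 1.0 + rng.gamma(4.0, 60.0, size=n), 1)
    low = rng.random(n) < profile.qual_below_min_frac
    q[low] = np.round(rng.uniform(3.0, min_qual - 0.5, size=low.sum()), 1)
    return q


def emulate_callers(truth: SimTruth, rng: np.random.Generator | None = None) -> SimOutput:
    """Emit one noisy call set per configured caller from the truth."""
    cfg = truth.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    streams = {name: np.random.default_rng(s) for name, s in
               zip(sorted(cfg.callers), rng.spawn(len(cfg.callers)))}

    keys = truth.matrix.site_keys
    classes = np.asarray([truth.site_class[k] for k in keys])
    deep = classes == "deep_repeat"
    n_sites = len(keys)
    n_samples = truth.matrix.n_samples

    callsets: dict[str, CallSet] = {}
    emitted_true: dict[str, set[SiteKey]] = {}
    false_pos: dict[str, set[SiteKey]] = {}
    used_positions = {(k.chrom, k.pos) for k in keys}

    for name in sorted(cfg.callers):
        profile = cfg.callers[name]
        crng = streams[name]
        take = crng.random(n_sites) < profile.sensitivity

        gt = truth.matrix.codes.astype(np.int8).copy()
        if profile.genotype_error > 0:
            err = crng.random(gt.shape) < profile.genotype_error
            shift = crng.integers(1, 3, size=gt.shape)
            gt = np.where(err & (gt != MISSING), (gt + shift) % 3, gt).astype(np.int8)
        if profile.missing_rate > 0:
            gt[crng.random(gt.shape) < profile.missing_rate] = MISSING

        depth = _depths_for(truth, n_sites, crng)
        if deep.any():
            total = depth[deep].sum(axis=1)
            factor = np.ceil(cfg.deep_total_depth / np.maximum(total, 1)).astype(np.int64)
            depth[deep] = depth[deep] * np.maximum(factor, 2)[:, None]
        ref_d, alt_d, final_gt = _ad_from_genotypes(gt, depth, crng)
        site_depth = depth.sum(axis=1)
        quals = _quals(n_sites, profile, cfg.min_qual, crng)

        records: list[VariantRecord] = []
        emitted: set[SiteKey] = set()
        for i in np.flatnonzero(take):
            key = keys[i]
            ref, alts = truth.alleles[key]
            records.append(VariantRecord(
                chrom=key.chrom, pos=key.pos, ref=ref, alts=alts,
                qual=float(quals[i]), site_depth=int(site_depth[i]),
                calls=final_gt[i], ref_depths=ref_d[i], alt_depths=alt_d[i],
            ))
            emitted.add(key)

        fps: set[SiteKey] = set()
        n_fp = int(round(profile.fp_rate * n_sites))
        if n_fp:
            chroms = list(truth.layout.chromosome_lengths)
            fp_gt = np.zeros((n_fp, n_samples), dtype=np.int8)
            p_fp = crng.uniform(0.01, 0.08, size=n_fp)
            fp_gt[:] = crng.binomial(2, p_fp[:, None], size=(n_fp, n_samples))
            fp_depth = _depths_for(truth, n_fp, crng)
            fr, fa, fg = _ad_from_genotypes(fp_gt, fp_depth, crng)
            fq = _quals(n_fp, profile, cfg.min_qual, crng)
            made = 0
            while made < n_fp:
                chrom = chroms[int(crng.integers(len(chroms)))]
                pos = int(crng.integers(1, truth.layout.chromosome_lengths[chrom]))
                if (chrom, pos) in used_positions or (chrom, pos) in {(k.chrom, k.pos) for k in fps}:
                    continue
                ref = str(crng.choice(_BASES))
                alt = str(crng.choice([b for b in "ACGT" if b != ref]))
                key = SiteKey(chrom, pos, ref, alt)
                records.append(VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alts=(alt,),
                    qual=float(fq[made]), site_depth=int(fp_depth[made].sum()),
                    calls=fg[made], ref_depths=fr[made], alt_depths=fa[made],
                ))
                fps.add(key)
                made += 1

        callsets[name] = CallSet(caller=name, samples=list(truth.roster), records=records)
        emitted_true[name] = emitted
        false_pos[name] = fps

    return SimOutput(truth, callsets, emitted_true, false_pos)


def generate(config: SimConfig) -> SimOutput:
    """Layout -> populations -> caller emulation, from one seed."""
    ss = np.random.SeedSequence(config.seed).spawn(3)
    layout = simulate_genome(config, np.random.default_rng(ss[0]))
    truth = simulate_populations(config, layout, np.random.default_rng(ss[1]))
    return emulate_callers(truth, np.random.default_rng(ss[2]))


def write_outputs(sim: SimOutput, out_dir: str | Path) -> dict[str, Path]:
    """Write caller VCFs, the repeat BED, sample metadata and truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, cs in sim.callsets.items():
        p = out_dir / f"{name}.vcf"
        variant_io.write_vcf(cs, p)
        paths[f"vcf_{name}"] = p
    paths["mask"] = out_dir / "repeats.bed"
    variant_io.write_intervals(sim.truth.layout.mask, paths["mask"])
    paths["metadata"] = out_dir / "samples.tsv"
    variant_io.write_metadata(sim.truth.roster, paths["metadata"])

    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt,
         "site_class": sim.truth.site_class[k]}
        for k in sim.truth.matrix.site_keys
    ]
    pd.DataFrame(rows).to_csv(truth_dir / "site_classes.tsv", sep="\t", index=False)
    gm = pd.DataFrame(
        sim.truth.matrix.codes,
        index=[f"{k.chrom}:{k.pos}:{k.ref}:{k.alt}" for k in sim.truth.matrix.site_keys],
        columns=sim.truth.matrix.sample_ids,
    )
    gm.to_csv(truth_dir / "genotypes.tsv", sep="\t")
    paths["truth"] = truth_dir
    return paths
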