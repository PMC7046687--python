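"""Reading and writing the pipeline's on-disk formats.

VCF 4.x is read through cyvcf2 and written through pysam; the caller-
specific header dialects (freebayes / bcftools mpileup / GATK) are
normalized here into :class:`~salmonsnp.model.VariantRecord` so that no
caller-specific logic survives past this module.  BED intervals are
0-based half-open and converted at this boundary only; every internal
position is 1-based.

Per-sample allelic depths (an ``AD``-style FORMAT field) are mandatory:
the downstream genotype re-calling rule is defined on read counts, so
records without depths are rejected rather than imputed.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .model import (
    MISSING,
    CallSet,
    IntervalSet,
    SampleMeta,
    VariantRecord,
    validate_roster,
)

# cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_CYVCF2_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_vcf(path: str | Path, caller: str, roster: Sequence[SampleMeta]) -> CallSet:
    """Read one caller's VCF into a :class:`CallSet` aligned to ``roster``.

    Sample columns are reconciled to the roster by name, so the three
    callers' files may list samples in different orders.  Requires GT and
    AD for every roster sample.
    """
    roster = list(roster)
    validate_roster(roster)
    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    missing = [s.sample_id for s in roster if s.sample_id not in vcf_samples]
    if missing:
        raise ValueError(f"VCF {path} lacks sample column(s): {missing}")
    order = np.asarray([vcf_samples.index(s.sample_id) for s in roster], dtype=np.intp)

    records: list[VariantRecord] = []
    for i, v in enumerate(vcf):
        try:
            ad = v.format("AD")
            if ad is None:
                raise ValueError("record has no AD (allelic depth) FORMAT field")
            ad = np.asarray(ad)[order]
            ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes '.' as negative sentinels
            calls = _CYVCF2_CODE[np.asarray(v.gt_types)][order]
            dp = v.INFO.get("DP")
            if dp is None:
                dp = int(ad.sum())
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alts=tuple(v.ALT),
                    # htslib hands QUAL through a float32; 6 significant
                    # digits recovers the decimal printed in the file
                    qual=float(f"{v.QUAL:.6g}") if v.QUAL is not None else 0.0,
                    site_depth=int(dp),
                    calls=calls,
                    ref_depths=ad[:, 0].astype(np.int32),
                    alt_depths=ad[:, 1].astype(np.int32) if ad.shape[1] > 1 else
                        np.zeros(len(roster), dtype=np.int32),
                )
            )
        except Exception as exc:  # re-raise with record coordinates for context
            raise ValueError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    return CallSet(caller=caller, samples=roster, records=records)


def write_vcf(callset: CallSet, path: str | Path) -> None:
    """Write a call set as VCF 4.2 with GT and AD per sample.

    Round-trip contract: reading the file back reproduces every site key,
    QUAL, genotype call and allelic depth of ``callset``.
    """
    header = pysam.VariantHeader()
    seen: list[str] = []
    for rec in callset.records:
        if rec.chrom not in seen:
            seen.append(rec.chrom)
    for chrom in seen:
        header.contigs.add(chrom)
    header.add_meta("INFO", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                   ("Description", "Total read depth over all samples")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
                                     ("Description", "Allelic read depths")])
    for s in callset.sample_ids:
        header.add_sample(s)

    _GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in callset.records:
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
                qual=rec.qual,
            )
            row.info["DP"] = rec.site_depth
            pad = (0,) * (len(rec.alts) - 1)
            for i, sid in enumerate(callset.sample_ids):
                row.samples[sid]["GT"] = _GT[int(rec.calls[i])]
                row.samples[sid]["AD"] = (int(rec.ref_depths[i]), int(rec.alt_depths[i]), *pad)
            out.write(row)


def read_intervals(path: str | Path) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into a merged IntervalSet."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
    return IntervalSet(intervals)


def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in intervals.chroms():
            for start, end in intervals.intervals(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\n")


_META_COLUMNS = ["sample_id", "strain", "year_class", "continent", "is_doubled_haploid"]
_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata table (tab- or comma-separated, with header)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path} lacks column(s): {missing}")
    roster: list[SampleMeta] = []
    for _, row in df.iterrows():
        flag = row["is_doubled_haploid"].strip().lower()
        if flag in _TRUE:
            dh = True
        elif flag in _FALSE:
            dh = False
        else:
            raise ValueError(f"unparseable is_doubled_haploid value {row['is_doubled_haploid']!r}")
        yc = row["year_class"].strip() or None
        roster.append(
            SampleMeta(
                sample_id=row["sample_id"].strip(),
                strain=row["strain"].strip(),
                year_class=yc,
                continent=row["continent"].strip(),
                is_doubled_haploid=dh,
            )
        )
    validate_roster(roster)
    return roster


def write_metadata(roster: Sequence[SampleMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_META_COLUMNS)
        for s in roster:
            w.writerow([s.sample_id, s.strain, s.year_class or "", s.continent,
                        "true" if s.is_doubled_haploid else "false"])


def write_panel(sites: Sequence, path: str | Path) -> None:
    """Write the continent-of-origin diagnostic panel as a TSV.

    One row per site: site key, the fixed homozygous genotype class of
    each continental group, per-caller Weir-Cockerham Fst (empty where
    the caller did not report the site) and the confidence tier.
    """
    rows = []
    callers = sorted({c for s in sites for c in s.fst_per_caller})
    for s in sites:
        row = {
            "chrom": s.key.chrom,
            "pos": s.key.pos,
            "ref": s.key.ref,
            "alt": s.key.alt,
            "na_genotype": s.na_genotype_class,
            "eu_genotype": s.eu_genotype_class,
        }
        for c in callers:
            v = s.fst_per_caller.get(c)
            row[f"fst_{c}"] = "" if v is None else f"{v:.6g}"
        row["tier"] = s.tier
        rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", "na_genotype", "eu_genotype"] + [
        f"fst_{c}" for c in callers
    ] + ["tier"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
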