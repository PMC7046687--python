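"""Population-genetic summaries of the consensus genotype matrix.

Covers the minor-allele-frequency spectrum, per-strain / per-year-class
polymorphism and heterozygosity tables, the per-site two-population
Weir & Cockerham (1984) Fst estimator, and the screen for
continent-of-origin diagnostic markers (sites fixed for opposite
homozygous genotypes in the North American and European groups, i.e.
Fst = 1).

Conventions: missing genotypes are excluded from every allele count (no
imputation); a site is polymorphic in a subgroup iff both alleles are
observed among its non-missing genotypes; average MAF and average
observed heterozygosity in the summary tables are taken over the
subgroup's polymorphic sites only.

The Fst components are evaluated in exact rational arithmetic on the
integer allele and heterozygote counts, so that a fixed difference
yields Fst == 1.0 identically, with no floating-point residue.  The
diagnostic screen nevertheless decides "Fst = 1" membership by the
combinatorial fixed-difference condition itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import HET, MISSING, GenotypeMatrix, SampleMeta, SiteKey


# ---------------------------------------------------------------------------
# per-site statistics


def minor_allele_freq(codes: np.ndarray) -> float:
    """MAF of one site over a subgroup of genotype codes; NaN if all missing."""
    codes = np.asarray(codes)
    obs = codes[codes != MISSING]
    if obs.size == 0:
        return float("nan")
    p = obs.sum() / (2 * obs.size)
    return float(min(p, 1.0 - p))


def is_polymorphic(codes: np.ndarray) -> bool:
    """True iff both alleles are observed among non-missing genotypes."""
    codes = np.asarray(codes)
    obs = codes[codes != MISSING]
    if obs.size == 0:
        return False
    alt = int(obs.sum())
    return 0 < alt < 2 * obs.size


def observed_het(codes: np.ndarray) -> float:
    """Proportion of heterozygous calls among non-missing genotypes."""
    codes = np.asarray(codes)
    obs = codes[codes != MISSING]
    if obs.size == 0:
        return float("nan")
    return float(np.mean(obs == HET))


def _group_site_stats(sub: np.ndarray):
    """Vectorized per-site (n_obs, alt_count, maf, het, polymorphic) over a group."""
    nonmiss = sub != MISSING
    n_obs = nonmiss.sum(axis=1)
    alt = np.where(nonmiss, sub, 0).astype(np.int64).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2.0 * n_obs)
        het = (sub == HET).sum(axis=1) / n_obs
    maf = np.minimum(p, 1.0 - p)
    poly = (alt > 0) & (alt < 2 * n_obs)
    return n_obs, alt, maf, het, poly


def maf_vector(matrix: GenotypeMatrix, sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Per-site MAF over a subgroup (NaN where the subgroup is all-missing)."""
    idx = matrix.sample_indices(sample_ids) if sample_ids is not None else slice(None)
    _, _, maf, _, _ = _group_site_stats(matrix.codes[:, idx])
    return maf


@dataclass
class MafSpectrum:
    """Binned MAF histogram plus the high-MAF (>= 0.25) tally."""

    table: pd.DataFrame  # columns bin_left, bin_right, count
    n_sites: int
    n_high_maf: int  # sites with MAF >= 0.25
    frac_high_maf: float


def maf_spectrum(
    matrix: GenotypeMatrix,
    sample_ids: Sequence[str] | None = None,
    bin_width: float = 0.025,
    high_maf: float = 0.25,
) -> MafSpectrum:
    """Histogram of per-site MAF in right-closed bins covering [0, 0.5].

    Sites with no evaluable genotype in the subgroup are excluded.
    """
    maf = maf_vector(matrix, sample_ids)
    maf = maf[~np.isnan(maf)]
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    # right-closed bins (left, right]; MAF 0 falls in the first bin
    idx = np.clip(np.searchsorted(edges, maf, side="left") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    table = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    n_high = int(np.sum(maf >= high_maf))
    frac = n_high / maf.size if maf.size else float("nan")
    return MafSpectrum(table, int(maf.size), n_high, float(frac))


# ---------------------------------------------------------------------------
# Table-1-style summaries


def strain_summary(
    matrix: GenotypeMatrix,
    roster: Sequence[SampleMeta],
    strains: Sequence[str] | None = None,
    by_year_class: bool = True,
) -> pd.DataFrame:
    """Polymorphism and heterozygosity per strain and per year-class.

    One row per strain and (optionally) per year-class within strain,
    with columns population, n_fish, n_snp, n_polymorphic,
    pct_polymorphic, avg_maf, avg_het.  ``n_snp`` counts sites with at
    least one non-missing genotype in the group; the averages are over
    the group's polymorphic sites.
    """
    in_matrix = set(matrix.sample_ids)
    roster = [s for s in roster if s.sample_id in in_matrix]
    present = sorted({s.strain for s in roster})
    if strains is None:
        strains = present
    else:
        unknown = sorted(set(strains) - set(present))
        if unknown:
            raise ValueError(f"unknown group label(s): {unknown}")

    groups: list[tuple[str, list[str]]] = []
    for strain in strains:
        members = [s for s in roster if s.strain == strain]
        groups.append((strain, [s.sample_id for s in members]))
        if by_year_class:
            ycs = sorted({s.year_class for s in members if s.year_class})
            for yc in ycs:
                ids = [s.sample_id for s in members if s.year_class == yc]
                groups.append((f"{strain}_YC{yc}", ids))

    rows = []
    for label, ids in groups:
        if not ids:
            continue
        idx = matrix.sample_indices(ids)
        n_obs, _, maf, het, poly = _group_site_stats(matrix.codes[:, idx])
        evaluable = n_obs > 0
        n_snp = int(evaluable.sum())
        n_poly = int(poly.sum())
        rows.append(
            {
                "population": label,
                "n_fish": len(ids),
                "n_snp": n_snp,
                "n_polymorphic": n_poly,
                "pct_polymorphic": n_poly / n_snp if n_snp else float("nan"),
                "avg_maf": float(np.mean(maf[poly])) if n_poly else float("nan"),
                "avg_het": float(np.mean(het[poly])) if n_poly else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir & Cockerham per-site Fst


@dataclass
class FstComponents:
    """W&C (1984) variance components: a (among populations), b (among
    individuals within populations), c (within individuals)."""

    a: float
    b: float
    c: float
    fst: float | None  # a / (a + b + c); None when the denominator is zero


def _group_counts(codes: np.ndarray) -> tuple[int, int, int] | None:
    codes = np.asarray(codes)
    obs = codes[codes != MISSING]
    if obs.size == 0:
        return None
    return int(obs.size), int(obs.sum()), int(np.sum(obs == HET))


def wc_fst(codes: np.ndarray, group1: np.ndarray, group2: np.ndarray) -> FstComponents:
    """Two-population per-site Weir & Cockerham Fst from genotype codes.

    ``group1`` / ``group2`` index samples (columns of ``codes``).  The
    components are computed exactly on the integer counts; a group with
    no non-missing genotype, or a site monomorphic in the pooled sample,
    yields ``fst=None``.  With a single individual per population the
    estimator's finite-sample corrections are undefined unless their
    numerators vanish (as they do at a fixed difference).
    """
    codes = np.asarray(codes)
    g1 = _group_counts(codes[np.asarray(group1)])
    g2 = _group_counts(codes[np.asarray(group2)])
    if g1 is None or g2 is None:
        return FstComponents(float("nan"), float("nan"), float("nan"), None)

    (n1, alt1, het1), (n2, alt2, het2) = g1, g2
    r = 2
    p1, p2 = Fraction(alt1, 2 * n1), Fraction(alt2, 2 * n2)
    h1, h2 = Fraction(het1, n1), Fraction(het2, n2)
    nbar = Fraction(n1 + n2, r)
    nc = Fraction(2 * n1 * n2, n1 + n2)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    inner_a = pbar * (1 - pbar) - Fraction(r - 1, r) * s2 - hbar / 4
    inner_b = pbar * (1 - pbar) - Fraction(r - 1, r) * s2 - Fraction(2 * nbar - 1, 4 * nbar) * hbar
    if nbar > 1:
        a = (nbar / nc) * (s2 - inner_a / (nbar - 1))
        b = (nbar / (nbar - 1)) * inner_b
    elif inner_a == 0 and inner_b == 0:
        # one individual per population: corrections are 0/0 but vanish exactly
        a = (nbar / nc) * s2
        b = Fraction(0)
    else:
        return FstComponents(float("nan"), float("nan"), float("nan"), None)
    c = hbar / 2

    denom = a + b + c
    fst = None if denom == 0 else float(a / denom)
    return FstComponents(float(a), float(b), float(c), fst)


# ---------------------------------------------------------------------------
# continent-of-origin diagnostic screen


@dataclass
class DiagnosticSite:
    """A candidate continent-diagnostic marker (fixed difference)."""

    key: SiteKey
    na_genotype_class: str  # 'hom_ref' or 'hom_alt'
    eu_genotype_class: str
    fst_per_caller: dict[str, float | None]
    tier: str  # 'high_confidence' (fixed in all three callers) or 'candidate'


def fixed_difference(
    codes: np.ndarray, group1: np.ndarray, group2: np.ndarray
) -> tuple[str, str] | None:
    """Exact Fst=1 test: opposite homozygote classes fixed in the two groups.

    Returns the (group1, group2) homozygote class labels, or None if the
    site is not a fixed difference (heterozygote present, shared allele,
    or a group with no data).
    """
    codes = np.asarray(codes)
    obs1 = codes[np.asarray(group1)]
    obs2 = codes[np.asarray(group2)]
    obs1 = obs1[obs1 != MISSING]
    obs2 = obs2[obs2 != MISSING]
    if obs1.size == 0 or obs2.size == 0:
        return None
    u1, u2 = np.unique(obs1), np.unique(obs2)
    if len(u1) != 1 or len(u2) != 1:
        return None
    g1, g2 = int(u1[0]), int(u2[0])
    if {g1, g2} != {0, 2}:
        return None
    label = {0: "hom_ref", 2: "hom_alt"}
    return label[g1], label[g2]


def select_diagnostic(
    matrices: Mapping[str, GenotypeMatrix],
    na_sample_ids: Sequence[str],
    eu_sample_ids: Sequence[str],
) -> list[DiagnosticSite]:
    """Screen per-caller genotype matrices for continental fixed differences.

    candidate tier: fixed difference (Fst = 1) in at least one caller.
    high_confidence tier: site present in *all* callers' filtered sets
    and a fixed difference in all of them.  Per-caller Fst values are
    attached for every caller that reports the site.
    """
    if set(na_sample_ids) & set(eu_sample_ids):
        raise ValueError("NA and EU groups overlap")
    callers = sorted(matrices)
    row_index = {c: {k: i for i, k in enumerate(matrices[c].site_keys)} for c in callers}
    idx_na = {c: matrices[c].sample_indices(na_sample_ids) for c in callers}
    idx_eu = {c: matrices[c].sample_indices(eu_sample_ids) for c in callers}

    fixed: dict[SiteKey, dict[str, tuple[str, str]]] = {}
    for c in callers:
        m = matrices[c]
        for i, key in enumerate(m.site_keys):
            fd = fixed_difference(m.codes[i], idx_na[c], idx_eu[c])
            if fd is not None:
                fixed.setdefault(key, {})[c] = fd

    sites: list[DiagnosticSite] = []
    for key in sorted(fixed):
        per_caller = fixed[key]
        fst: dict[str, float | None] = {}
        for c in callers:
            i = row_index[c].get(key)
            if i is None:
                fst[c] = None
            else:
                fst[c] = wc_fst(matrices[c].codes[i], idx_na[c], idx_eu[c]).fst
        tier = (
            "high_confidence"
            if all(key in row_index[c] for c in callers) and len(per_caller) == len(callers)
            else "candidate"
        )
        na_class, eu_class = per_caller[min(per_caller)]
        sites.append(DiagnosticSite(key, na_class, eu_class, fst, tier))
    return sites
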