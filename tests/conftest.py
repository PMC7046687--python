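"""Shared fixtures: small rosters, record builders and a compact simulated run."""

from __future__ import annotations

import numpy as np
import pytest

from salmonsnp.consensus_filter import consensus_intersect, run_cascade
from salmonsnp.model import CallSet, SampleMeta, VariantRecord
from salmonsnp.synthetic_data import SimConfig, generate


def mk_record(
    chrom="chr1",
    pos=100,
    ref="A",
    alts=("T",),
    qual=50.0,
    site_depth=200,
    calls=(0, 1, 2, 0),
    ref_depths=None,
    alt_depths=None,
) -> VariantRecord:
    """Build a record; depths default to values consistent with the calls."""
    calls = np.asarray(calls, dtype=np.int8)
    if ref_depths is None:
        ref_depths = np.select([calls == 0, calls == 1], [10, 5], default=0)
    if alt_depths is None:
        alt_depths = np.select([calls == 2, calls == 1], [10, 5], default=0)
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), qual=qual,
        site_depth=site_depth, calls=calls,
        ref_depths=np.asarray(ref_depths), alt_depths=np.asarray(alt_depths),
    )


def mk_roster(n_na=4, n_eu=0, n_dh=0, strain="SJR"):
    roster = [
        SampleMeta(f"NA{i:02d}", strain, "NA", year_class="13-14") for i in range(n_na)
    ]
    roster += [SampleMeta(f"EU{i:02d}", "EUR_WILD", "EU") for i in range(n_eu)]
    roster += [
        SampleMeta(f"DH{i:02d}", "EUR_DH", "EU", is_doubled_haploid=True)
        for i in range(n_dh)
    ]
    return roster


def small_sim_config(seed=11, **overrides) -> SimConfig:
    """A compact genome (2 x 100 kb) with every site class represented."""
    base = dict(
        seed=seed,
        n_chromosomes=2,
        chromosome_length=100_000,
        n_clean_snp=1500,
        n_continental_fixed=40,
        n_psv=80,
        n_deep_repeat=40,
        n_masked_snp=40,
        n_indel=60,
        n_near_indel_snp=40,
        n_multiallelic=20,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def noiseless_pipeline():
    """Compact noiseless simulation pushed through cascade + consensus."""
    sim = generate(small_sim_config().noiseless())
    filtered = {}
    reports = {}
    for name, cs in sorted(sim.callsets.items()):
        fcs, rep = run_cascade(cs, sim.truth.layout.mask)
        filtered[name] = fcs
        reports[name] = rep
    consensus = consensus_intersect(list(filtered.values()))
    return {"sim": sim, "filtered": filtered, "reports": reports, "consensus": consensus}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_callset(rng, n_records=60, n_samples=8, caller="freebayes", roster=None) -> CallSet:
    """A messy random call set: SNPs, indels, multi-allelics, odd quals/depths."""
    if roster is None:
        roster = mk_roster(n_na=n_samples - 2, n_dh=2)
    n = len(roster)
    records = []
    positions = rng.choice(np.arange(10, 10_000), size=n_records, replace=False)
    for pos in np.sort(positions):
        kind = rng.random()
        if kind < 0.6:
            ref, alts = "A", ("G",)
        elif kind < 0.75:
            ref, alts = "A", ("G", "T")
        elif kind < 0.9:
            ref, alts = "AT", ("A",)
        else:
            ref, alts = "C", ("CTA",)
        calls = rng.integers(-1, 3, size=n).astype(np.int8)
        records.append(
            VariantRecord(
                chrom=str(rng.choice(["chr1", "chr2"])), pos=int(pos), ref=ref,
                alts=alts, qual=float(np.round(rng.uniform(0, 60), 1)),
                site_depth=int(rng.integers(0, 4000)),
                calls=calls,
                ref_depths=rng.integers(0, 12, size=n),
                alt_depths=rng.integers(0, 12, size=n),
            )
        )
    return CallSet(caller=caller, samples=roster, records=records)
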