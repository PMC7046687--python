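"""Strain phylogeny from the consensus genotype matrix.

Preprocessing follows the published tree protocol: restrict to named
chromosome sequences, keep sites with MAF strictly above 0.1, and thin
by linkage disequilibrium so that no retained pair within a sliding
window exceeds r-squared 0.1.  The tree itself is built by
neighbor-joining on allele-sharing distances with a site-resampling
bootstrap; the original study used SNPhylo with DNAML maximum
likelihood, and the substitution of a distance method is deliberate and
recorded in the output (``method`` field) — the quantity of interest
here is strain-level clustering, which a distance tree resolves.

Tie-breaking is everywhere by input order: the earlier site wins an LD
conflict, and neighbor-joining follows the sample order of the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .model import MISSING, GenotypeMatrix
from .popgen import maf_vector


@dataclass(frozen=True)
class LDPruneConfig:
    """MAF and LD-thinning thresholds (defaults = study settings)."""

    maf_min: float = 0.1  # keep iff MAF strictly greater
    r2_max: float = 0.1  # retained pairs within a window must have r2 <= this
    window_size: int = 50  # SNPs per window
    window_step: int = 5  # SNPs advanced between windows

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0 <= self.r2_max <= 1):
            raise ValueError("r2_max must be in [0, 1]")
        if self.window_step > self.window_size or self.window_step < 1:
            raise ValueError("require 1 <= window_step <= window_size")


def maf_prefilter(
    matrix: GenotypeMatrix,
    maf_min: float = 0.1,
    chromosomes: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Keep sites with MAF > maf_min, optionally restricted to named chromosomes.

    ``chromosomes=None`` keeps every contig; pass the chromosome list to
    drop unplaced scaffolds.
    """
    maf = maf_vector(matrix)
    keep = maf > maf_min
    if chromosomes is not None:
        allowed = set(chromosomes)
        on_chrom = np.asarray([k.chrom in allowed for k in matrix.site_keys])
        keep &= on_chrom
    return matrix.take_sites(keep)


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two sites' genotype codes.

    Computed over pairwise-complete samples; NaN with fewer than two
    complete pairs or zero variance at either site.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _window_r2(sub: np.ndarray) -> np.ndarray:
    """r2 matrix for a window of sites (rows = sites); NaN where undefined.

    Pairwise-complete sums are assembled with matrix products over the
    observation-indicator matrix, so missing data costs no Python loop.
    """
    x = np.where(sub == MISSING, 0, sub).astype(np.float64)
    m = (sub != MISSING).astype(np.float64)
    n = m @ m.T  # co-observed sample counts per pair
    sx = x @ m.T  # sum of site i's codes over samples co-observed with j
    sxy = x @ x.T
    sxx = (x * x) @ m.T
    var_i = n * sxx - sx**2
    var_j = var_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        num = n * sxy - sx * sx.T
        r2 = num**2 / (var_i * var_j)
    r2[(n < 2) | (var_i <= 0) | (var_j <= 0)] = np.nan
    return r2


def ld_prune(matrix: GenotypeMatrix, config: LDPruneConfig = LDPruneConfig()) -> GenotypeMatrix:
    """Greedy windowed LD thinning, per chromosome, earlier site wins.

    Guarantees that within any window position of the scan, every pair
    of retained sites has r-squared <= ``config.r2_max`` (pairs whose r2
    is undefined are never pruned).
    """
    n = matrix.n_sites
    keep = np.ones(n, dtype=bool)
    chroms = np.asarray([k.chrom for k in matrix.site_keys])
    for chrom in dict.fromkeys(chroms):  # preserves site order
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), config.window_step):
            widx = idx[start : start + config.window_size]
            if len(widx) < 2:
                continue
            r2 = _window_r2(matrix.codes[widx])
            for b in range(1, len(widx)):
                if not keep[widx[b]]:
                    continue
                for a in range(b):
                    if keep[widx[a]] and r2[a, b] > config.r2_max:
                        keep[widx[b]] = False
                        break
            if start + config.window_size >= len(idx):
                break
    return matrix.take_sites(keep)


def pairwise_distance(matrix: GenotypeMatrix) -> np.ndarray:
    """Allele-sharing distance: mean |dosage difference| / 2 over co-observed sites.

    Symmetric with zero diagonal; raises if any sample pair shares no
    co-observed site.
    """
    codes = matrix.codes
    ind = [(codes == g).astype(np.float64) for g in (0, 1, 2)]
    obs = ind[0] + ind[1] + ind[2]
    counts = obs.T @ obs
    num = np.zeros_like(counts)
    for u in range(3):
        for v in range(3):
            if u != v:
                num += abs(u - v) * (ind[u].T @ ind[v])
    off = ~np.eye(len(counts), dtype=bool)
    if np.any(counts[off] == 0):
        i, j = np.argwhere((counts == 0) & off)[0]
        raise ValueError(
            f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
            "share no co-observed site"
        )
    with np.errstate(invalid="ignore"):
        d = num / (2.0 * counts)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def build_tree(distances: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Neighbor-joining tree; deterministic given the input order.

    An all-zero matrix degenerates to a star tree with zero branch
    lengths (with a warning).
    """
    distances = np.asarray(distances, dtype=float)
    if len(ids) < 3:
        raise ValueError("need at least 3 samples for a tree")
    if np.allclose(distances, 0):
        warnings.warn("all pairwise distances are zero; returning a star tree")
        root = TreeNode()
        for s in ids:
            root.append(TreeNode(name=s, length=0.0))
        return root
    return nj(DistanceMatrix(distances, ids=list(ids)))


def tree_bipartitions(tree: TreeNode, all_tips: Sequence[str]) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, in canonical form.

    Each internal edge splits the tips in two; the side not containing
    the alphabetically first tip represents the split.
    """
    universe = frozenset(all_tips)
    anchor = min(universe)
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = universe - side
        if 2 <= len(side) <= len(universe) - 2:
            out.add(side)
    return out


@dataclass
class PhyloResult:
    """Pruned sites, distances, NJ tree and bootstrap supports."""

    retained_keys: list
    sample_ids: list[str]
    distances: np.ndarray
    tree: TreeNode
    supports: dict[frozenset, float]  # bipartition -> % of replicates
    replicate_bipartitions: list[set[frozenset]] = field(default_factory=list)
    n_reps: int = 0
    method: str = "neighbor-joining, allele-sharing distance, site bootstrap"

    def support_for(self, sample_ids: Sequence[str]) -> float:
        """Bootstrap % of the split isolating exactly this sample group."""
        universe = frozenset(self.sample_ids)
        side = frozenset(sample_ids)
        if min(universe) in side:
            side = universe - side
        hits = sum(1 for reps in self.replicate_bipartitions if side in reps)
        return 100.0 * hits / self.n_reps if self.n_reps else float("nan")

    def is_monophyletic(self, sample_ids: Sequence[str]) -> bool:
        """Whether the group forms a clade of the unrooted reference tree."""
        universe = frozenset(self.sample_ids)
        side = frozenset(sample_ids)
        if len(side) <= 1 or len(side) >= len(universe) - 1:
            return True
        if min(universe) in side:
            side = universe - side
        return side in tree_bipartitions(self.tree, self.sample_ids)

    def newick(self) -> str:
        """Newick with bootstrap supports as internal node labels."""
        tree = self.tree.copy()
        universe = frozenset(self.sample_ids)
        anchor = min(universe)
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = universe - side
            if side in self.supports:
                node.name = f"{self.supports[side]:.1f}"
        return str(tree)


def bootstrap_support(
    matrix: GenotypeMatrix,
    tree: TreeNode,
    n_reps: int = 1000,
    seed: int | None = None,
) -> tuple[dict[frozenset, float], list[set[frozenset]]]:
    """Site-resampling bootstrap supports for a reference tree's splits."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ids = matrix.sample_ids
    ref = tree_bipartitions(tree, ids)
    hits = {bp: 0 for bp in ref}
    rep_sets: list[set[frozenset]] = []
    for _ in range(n_reps):
        take = rng.integers(0, matrix.n_sites, size=matrix.n_sites)
        sub = matrix.take_sites(take)
        d = pairwise_distance(sub)
        bps = tree_bipartitions(build_tree(d, ids), ids)
        rep_sets.append(bps)
        for bp in ref:
            if bp in bps:
                hits[bp] += 1
    supports = {bp: 100.0 * h / n_reps for bp, h in hits.items()}
    return supports, rep_sets


def run_phylo(
    matrix: GenotypeMatrix,
    config: LDPruneConfig = LDPruneConfig(),
    chromosomes: Sequence[str] | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
) -> PhyloResult:
    """MAF filter -> LD prune -> distances -> NJ -> bootstrap, end to end."""
    pruned = maf_prefilter(matrix, config.maf_min, chromosomes)
    if pruned.n_sites == 0:
        raise ValueError("no sites left after the MAF prefilter; cannot build a tree")
    pruned = ld_prune(pruned, config)
    d = pairwise_distance(pruned)
    tree = build_tree(d, pruned.sample_ids)
    supports, rep_sets = bootstrap_support(pruned, tree, n_reps=n_reps, seed=seed)
    return PhyloResult(
        retained_keys=list(pruned.site_keys),
        sample_ids=list(pruned.sample_ids),
        distances=d,
        tree=tree,
        supports=supports,
        replicate_bipartitions=rep_sets,
        n_reps=n_reps,
    )
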