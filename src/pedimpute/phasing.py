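"""Long-range phasing and haplotype-library construction for high-density
genotyped animals.

Chromosomes are divided into *cores* (contiguous SNP windows, e.g. 100
SNP).  Within a core, each animal's heterozygous loci are phased by the
unanimous vote of its *surrogate relatives*: genotyped animals connected
to it exclusively through its sire (paternal side) or dam (maternal
side) and showing no opposing homozygotes with it across the core.  A
surrogate that is homozygous at a locus reveals the allele on the shared
strand.  Fully resolved gametes are catalogued in a per-core haplotype
library; partially resolved gametes are completed against the library
when exactly one entry matches, and remaining unresolved animals (base
animals in particular) are assigned the unique pair of library
haplotypes compatible with their genotype, left unordered until the
pedigree or overlap stitching determines parental origin.

Several phasing rounds with shifted core boundaries give every SNP
membership in differently bounded cores; rounds are merged
conservatively, with inter-round disagreements treated as phasing
errors and reset to unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix, MISSING_ALLELE, MISSING_GENO
from .pedigree import Pedigree


@dataclass
class PhaseConfig:
    core_length: int = 100
    n_rounds: int = 4
    max_mismatch: int = 0  # opposing homozygotes allowed in a surrogate
    min_agree: int = 1  # informative surrogates required for a vote
    hd_threshold: float = 0.9
    # surrogacy is declared on the core extended by this many SNP on each
    # side: a long-range window makes chance opposing-homozygote-free
    # candidates (false surrogates) rare
    surrogate_flank: int = 200


@dataclass
class CoreLayout:
    """One round's tiling of the chromosome into half-open SNP intervals."""

    core_length: int
    offset: int
    cores: list[tuple[int, int]]


@dataclass
class HaplotypeLibrary:
    """Distinct fully resolved haplotypes observed in one core."""

    start: int
    stop: int
    haplotypes: np.ndarray  # (n_hap, core_len) int8 in {0,1}
    counts: np.ndarray  # (n_hap,) int64

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class SurrogateSet:
    """Boolean surrogate matrices over the HD subset: row = target animal,
    column = surrogate (both HD-subset indices)."""

    hd_idx: np.ndarray  # global indices of the HD animals (row/col order)
    paternal: np.ndarray  # (H, H) bool
    maternal: np.ndarray  # (H, H) bool

    def paternal_surrogates(self, row: int) -> np.ndarray:
        return self.hd_idx[np.nonzero(self.paternal[row])[0]]

    def maternal_surrogates(self, row: int) -> np.ndarray:
        return self.hd_idx[np.nonzero(self.maternal[row])[0]]


@dataclass
class CorePhase:
    """Per-(round, core) phasing product kept for the imputation stage."""

    round_idx: int
    start: int
    stop: int
    library: HaplotypeLibrary
    # unique compatible haplotype pair per HD animal (-1 where unknown);
    # ordered=True means slot 0 is the paternal strand
    pairs: np.ndarray  # (H, 2, core_len) int8
    ordered: np.ndarray  # (H,) bool


def build_core_layout(
    n_snp: int, core_length: int = 100, n_rounds: int = 4
) -> list[CoreLayout]:
    """Core tilings for every phasing round; round r is shifted by
    ``floor(r * core_length / n_rounds)`` so that core boundaries differ
    between rounds."""
    if core_length < 10:
        raise ValueError("core_length must be >= 10")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    layouts = []
    for r in range(n_rounds):
        offset = (r * core_length) // n_rounds
        if n_snp <= core_length:
            cores = [(0, n_snp)]
        else:
            bounds = [0]
            pos = offset if offset > 0 else core_length
            while pos < n_snp:
                bounds.append(pos)
                pos += core_length
            bounds.append(n_snp)
            cores = list(zip(bounds[:-1], bounds[1:]))
        layouts.append(CoreLayout(core_length=core_length, offset=offset, cores=cores))
    return layouts


def relatedness_matrix(ped: Pedigree) -> np.ndarray:
    """Boolean matrix: R[a, b] = a and b share a pedigree ancestor
    (individuals count as their own ancestors)."""
    A = ped.ancestor_matrix().astype(np.float32)
    return (A @ A.T) > 0.5


def find_surrogates(
    geno: GenotypeMatrix,
    ped: Pedigree,
    region: tuple[int, int],
    max_mismatch: int = 0,
    hd_idx: np.ndarray | None = None,
    relatedness: np.ndarray | None = None,
) -> SurrogateSet:
    """Surrogate relatives of every HD animal for one SNP region.

    A candidate surrogate j of i must share no more than ``max_mismatch``
    opposing homozygotes with i across the region; it is assigned to the
    paternal side when the pedigree relates j to i's sire but not to i's
    dam (and symmetrically), and held unassigned otherwise.  Genotyped
    parents are always surrogates of their side.
    """
    if hd_idx is None:
        hd_idx = np.nonzero(geno.genotyped)[0]
    if relatedness is None:
        relatedness = relatedness_matrix(ped)
    start, stop = region
    gh = geno.values[hd_idx][:, start:stop]
    hom0 = (gh == 0).astype(np.float32)
    hom2 = (gh == 2).astype(np.float32)
    opposing = hom0 @ hom2.T + hom2 @ hom0.T  # (H, H)
    ok = opposing <= max_mismatch + 0.5

    sire = ped.sire[hd_idx]
    dam = ped.dam[hd_idx]
    H = hd_idx.size
    pat_conn = np.zeros((H, H), dtype=bool)
    mat_conn = np.zeros((H, H), dtype=bool)
    has_s = sire >= 0
    has_d = dam >= 0
    if has_s.any():
        pat_conn[has_s] = relatedness[np.ix_(sire[has_s], hd_idx)]
    if has_d.any():
        mat_conn[has_d] = relatedness[np.ix_(dam[has_d], hd_idx)]
    paternal = pat_conn & ~mat_conn & ok
    maternal = mat_conn & ~pat_conn & ok
    np.fill_diagonal(paternal, False)
    np.fill_diagonal(maternal, False)

    # genotyped parents are unconditional surrogates of their side
    pos_of = {int(g): k for k, g in enumerate(hd_idx)}
    for row in range(H):
        s, d = int(sire[row]), int(dam[row])
        if s in pos_of:
            paternal[row, pos_of[s]] = True
            maternal[row, pos_of[s]] = False
        if d in pos_of:
            maternal[row, pos_of[d]] = True
            paternal[row, pos_of[d]] = False
    return SurrogateSet(hd_idx=hd_idx, paternal=paternal, maternal=maternal)


def phase_core(
    geno: GenotypeMatrix,
    surrogates: SurrogateSet,
    core: tuple[int, int],
    min_agree: int = 1,
) -> np.ndarray:
    """Phase the HD animals within one core by surrogate votes.

    Returns an (H, core_len, 2) int8 block, -1 where unphased.
    Homozygous loci phase themselves; at heterozygous loci the paternal
    allele is set when all informative paternal surrogates (homozygous
    there) agree and at least ``min_agree`` are informative, the maternal
    allele being the complement (and symmetrically for the dam side).
    Conflicting evidence leaves the locus unphased.
    """
    start, stop = core
    gh = geno.values[surrogates.hd_idx][:, start:stop]
    hom0 = (gh == 0).astype(np.float32)
    hom2 = (gh == 2).astype(np.float32)

    def votes(S: np.ndarray) -> np.ndarray:
        Sf = S.astype(np.float32)
        n0 = Sf @ hom0
        n2 = Sf @ hom2
        v = np.full(gh.shape, -1, dtype=np.int8)
        v[(n0 >= min_agree) & (n2 == 0)] = 0
        v[(n2 >= min_agree) & (n0 == 0)] = 1
        return v

    pat_v = votes(surrogates.paternal)
    mat_v = votes(surrogates.maternal)

    phase = np.full(gh.shape + (2,), MISSING_ALLELE, dtype=np.int8)
    phase[gh == 0] = 0
    phase[gh == 2] = 1
    het = gh == 1
    both = het & (pat_v >= 0) & (mat_v >= 0)
    consistent = both & (pat_v + mat_v == 1)
    pat_only = het & (pat_v >= 0) & (mat_v < 0)
    mat_only = het & (mat_v >= 0) & (pat_v < 0)
    for mask, pv in ((consistent, pat_v), (pat_only, pat_v)):
        phase[..., 0][mask] = pv[mask]
        phase[..., 1][mask] = 1 - pv[mask]
    phase[..., 1][mat_only] = mat_v[mat_only]
    phase[..., 0][mat_only] = 1 - mat_v[mat_only]
    return phase


def unique_rows(a: np.ndarray, counts: bool = False):
    """Row-unique for small-int matrices via a packed byte view (much
    faster than ``np.unique(axis=0)`` row sorting)."""
    a = np.ascontiguousarray(a)
    if a.shape[0] == 0:
        return (a, np.zeros(0, dtype=np.int64)) if counts else a
    packed = a.view(np.dtype((np.void, a.shape[1] * a.itemsize)))[:, 0]
    if counts:
        _, idx, cnt = np.unique(packed, return_index=True, return_counts=True)
        return a[idx], cnt
    _, idx = np.unique(packed, return_index=True)
    return a[np.sort(idx)]


def build_library(
    phase_block: np.ndarray,
    start: int = 0,
    stop: int | None = None,
    geno_block: np.ndarray | None = None,
) -> HaplotypeLibrary:
    """Catalogue the distinct fully resolved gamete haplotypes of a core
    and complete partially resolved gametes against them (in place) when
    exactly one library haplotype matches every resolved position.

    ``geno_block`` (animals x core SNP) guards the completion: an
    animal's completions are reverted when they would contradict an
    observed genotype (e.g. both strands of a mostly-unresolved animal
    completed with the same haplotype across heterozygous loci).
    """
    if stop is None:
        stop = start + phase_block.shape[1]
    n_animals, L, _ = phase_block.shape
    gametes = np.ascontiguousarray(phase_block.transpose(0, 2, 1)).reshape(-1, L)
    resolved = gametes >= 0
    full = resolved.all(axis=1)
    if full.any():
        haps, counts = unique_rows(gametes[full], counts=True)
    else:
        haps = np.zeros((0, L), dtype=np.int8)
        counts = np.zeros(0, dtype=np.int64)

    partial = ~full & resolved.any(axis=1)
    if haps.shape[0] and partial.any():
        g = gametes[partial]
        r1 = (g == 1).astype(np.float32)
        r0 = (g == 0).astype(np.float32)
        mism = r1 @ (haps == 0).T.astype(np.float32) + r0 @ (haps == 1).T.astype(np.float32)
        match = mism == 0
        unique = match.sum(axis=1) == 1
        if unique.any():
            which = np.argmax(match[unique], axis=1)
            rows = np.nonzero(partial)[0][unique]
            trial = gametes.copy()
            trial[rows] = haps[which]
            applied = np.zeros(gametes.shape[0], dtype=bool)
            applied[rows] = True
            if geno_block is not None:
                pairs = trial.reshape(n_animals, 2, L)
                both = (pairs >= 0).all(axis=1)
                bad = (
                    (geno_block != MISSING_GENO)
                    & both
                    & (pairs.sum(axis=1) != geno_block)
                ).any(axis=1)
                # revert every completion of a contradicted animal
                applied &= ~np.repeat(bad, 2)
            gametes[applied] = trial[applied]
            kept = applied[rows]
            if kept.any():
                counts = counts + np.bincount(
                    which[kept], minlength=haps.shape[0]
                )
            phase_block[:] = gametes.reshape(n_animals, 2, L).transpose(0, 2, 1)
    return HaplotypeLibrary(start=start, stop=stop, haplotypes=haps.astype(np.int8), counts=counts)


def resolve_pairs(
    geno_block: np.ndarray,
    phase_block: np.ndarray,
    library: HaplotypeLibrary,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each animal the unique unordered library-haplotype pair
    compatible with its genotype over the core.

    Animals whose two gametes are already fully resolved keep them as an
    ordered pair.  For the rest, if exactly one unordered pair (h, h')
    from the library sums to the genotype at every observed locus and
    does not contradict resolved alleles, it is stored; the ordering is
    fixed (and written into ``phase_block``) when the resolved alleles
    admit only one orientation.  Returns (pairs, ordered).
    """
    H, L = geno_block.shape
    pairs = np.full((H, 2, L), MISSING_ALLELE, dtype=np.int8)
    ordered = np.zeros(H, dtype=bool)
    fully = (phase_block >= 0).all(axis=(1, 2))
    pairs[fully, 0] = phase_block[fully, :, 0]
    pairs[fully, 1] = phase_block[fully, :, 1]
    ordered[fully] = True
    if library.n == 0:
        return pairs, ordered

    haps = library.haplotypes
    # genotype-compatibility of each hap as *one member* of the pair
    c0 = (geno_block == 0).astype(np.float32) @ (haps == 1).T.astype(np.float32)
    c2 = (geno_block == 2).astype(np.float32) @ (haps == 0).T.astype(np.float32)
    compat = (c0 + c2) == 0  # (H, n_hap)

    obs = geno_block != MISSING_GENO
    for i in np.nonzero(~fully)[0]:
        cand = np.nonzero(compat[i])[0]
        if cand.size == 0 or cand.size > 64:
            continue  # no or too many candidates: leave unresolved
        g = geno_block[i]
        found: set[tuple[int, int]] = set()
        for a in cand:
            ha = haps[a]
            # complement required at observed loci
            comp = g - ha
            need = obs[i]
            ok = compat[i].copy()
            diff = (haps[:, need] != comp[need]).any(axis=1)
            ok &= ~diff
            for b in np.nonzero(ok)[0]:
                found.add((min(int(a), int(b)), max(int(a), int(b))))
            if len(found) > 1:
                break
        if len(found) != 1:
            continue
        a, b = found.pop()
        ha, hb = haps[a], haps[b]
        # orientation from already resolved alleles
        pat, mat = phase_block[i, :, 0], phase_block[i, :, 1]
        rp, rm = pat >= 0, mat >= 0
        fits_a_pat = not ((ha[rp] != pat[rp]).any() or (hb[rm] != mat[rm]).any())
        fits_b_pat = not ((hb[rp] != pat[rp]).any() or (ha[rm] != mat[rm]).any())
        if fits_a_pat and not fits_b_pat:
            pairs[i, 0], pairs[i, 1] = ha, hb
            ordered[i] = True
            phase_block[i, :, 0], phase_block[i, :, 1] = ha, hb
        elif fits_b_pat and not fits_a_pat:
            pairs[i, 0], pairs[i, 1] = hb, ha
            ordered[i] = True
            phase_block[i, :, 0], phase_block[i, :, 1] = hb, ha
        elif fits_a_pat and fits_b_pat:
            pairs[i, 0], pairs[i, 1] = ha, hb  # unordered (e.g. base animal)
    return pairs, ordered


@dataclass
class PhasingResult:
    """Merged HD phase plus the per-(round, core) libraries and pairs."""

    phase: np.ndarray  # (n_ind, n_snp, 2) int8, -1 unresolved
    cores: list[CorePhase]
    layouts: list[CoreLayout]
    hd_idx: np.ndarray
    n_conflicts: int = 0


def phase_hd(
    geno: GenotypeMatrix,
    ped: Pedigree,
    hd_idx: np.ndarray,
    cfg: PhaseConfig | None = None,
    known_phase: np.ndarray | None = None,
) -> PhasingResult:
    """Run all phasing rounds over the HD animals and merge the results.

    ``known_phase`` (n_ind, n_snp, 2) supplies externally phased alleles
    with known parental origin; they are taken as ground truth and the
    surrogate vote is skipped for loci they resolve.

    Alleles assigned different values by different rounds are treated as
    phasing errors and reset to unresolved.
    """
    cfg = cfg or PhaseConfig()
    n, n_snp = geno.values.shape
    layouts = build_core_layout(n_snp, cfg.core_length, cfg.n_rounds)
    rel = relatedness_matrix(ped)
    merged = np.full((n, n_snp, 2), MISSING_ALLELE, dtype=np.int8)
    if known_phase is not None:
        merged[:] = known_phase
    conflict_locked = np.zeros((n, n_snp, 2), dtype=bool)
    cores: list[CorePhase] = []
    n_conflicts = 0

    for r, layout in enumerate(layouts):
        for (start, stop) in layout.cores:
            declare = (
                max(0, start - cfg.surrogate_flank),
                min(n_snp, stop + cfg.surrogate_flank),
            )
            surro = find_surrogates(
                geno, ped, declare, cfg.max_mismatch, hd_idx, rel
            )
            block = phase_core(geno, surro, (start, stop), cfg.min_agree)
            if known_phase is not None:
                kb = known_phase[hd_idx, start:stop]
                block = np.where(kb >= 0, kb, block)
            lib = build_library(
                block, start, stop, geno.values[hd_idx][:, start:stop]
            )
            pairs, ordered = resolve_pairs(
                geno.values[hd_idx][:, start:stop], block, lib
            )
            cores.append(
                CorePhase(
                    round_idx=r, start=start, stop=stop,
                    library=lib, pairs=pairs, ordered=ordered,
                )
            )
            # conservative merge across rounds
            tgt = merged[hd_idx, start:stop]
            new = block >= 0
            old = tgt >= 0
            clash = new & old & (block != tgt)
            n_conflicts += int(clash.sum())
            take = new & ~old
            tgt[take] = block[take]
            tgt[clash] = MISSING_ALLELE
            lock = conflict_locked[hd_idx, start:stop]
            lock |= clash
            tgt[lock] = MISSING_ALLELE
            merged[hd_idx, start:stop] = tgt
            conflict_locked[hd_idx, start:stop] = lock
    return PhasingResult(
        phase=merged, cores=cores, layouts=layouts, hd_idx=hd_idx,
        n_conflicts=n_conflicts,
    )
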