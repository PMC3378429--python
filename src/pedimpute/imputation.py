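"""The imputation engine: deterministic fill-in rules that propagate
phase and genotypes through the whole pedigree.

After the segregation analysis (probabilities, hard calls) and the
long-range phasing of high-density animals (haplotype libraries), a
fixed hierarchy of sub-steps is applied.  Four *minor* rules do local
bookkeeping (parent-homozygous fill-in, phase complement, parent from
progeny, genotype from alleles) and are re-applied after every *major*
step.  The nine major steps convert probabilities to phase, label base
animals' gametes, vote unresolved alleles against haplotype libraries,
against parental haplotypes, against the animal's own haplotype pair,
against internally rebuilt libraries, track recombination between
parent and offspring, and finally recalculate probabilities so that
every allele has either a hard call or a probability.

All writes are monotone: a resolved allele or genotype is never changed,
and a write that would contradict the observed genotype or the opposite
allele is dropped and counted as a conflict (first writer wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import genotypes as gio
from . import peeling, phasing
from .genotypes import GenotypeMatrix, MISSING_ALLELE, MISSING_GENO
from .pedigree import Pedigree
from .peeling import PeelConfig
from .phasing import PhaseConfig, PhasingResult


@dataclass
class ImputeConfig:
    """Tunable thresholds of the imputation hierarchy.

    The vote thresholds follow an accept-high/reject-low rule: an allele
    is written when its vote count reaches ``accept`` while the opposite
    allele's count stays at or below ``vote_reject``.  The accept
    schedule tightens after the first outer iteration; the
    recombination-scan schedules relax across its internal iterations.
    """

    peel: PeelConfig = field(default_factory=PeelConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    library_mismatch_threshold: int = 0
    # accept count per outer iteration; the first iteration defers the
    # consensus votes entirely (accept above any attainable count) so
    # that Mendelian-certain evidence is laid down before consensus
    # voting starts
    vote_accept_schedule: tuple[int, ...] = (10**6, 6, 4)
    vote_reject: int = 0
    n_outer_iterations: int = 3
    internal_core_lengths: tuple[int, ...] = (50, 100, 200)
    max_recombinations: tuple[int, ...] = (10, 20, 40)
    min_double_crossover_gap: tuple[int, ...] = (100, 50, 25)
    # recombination scan: impute only within this many SNP of an
    # origin-informative locus (relaxed across its iterations)
    anchor_distance_cap: tuple[int, ...] = (50, 100, 200)
    # final recalculation: replace uninformative 50/50 origin
    # probabilities by recombination-distance-weighted ones
    origin_aware_probs: bool = True
    # restrict origin anchors to observation-forced (solid) alleles; a
    # conservative option for error-prone data (fewer anchors, fewer
    # error cascades)
    anchor_require_solid: bool = False

    def accept_at(self, outer_it: int) -> int:
        sched = self.vote_accept_schedule
        return sched[min(outer_it, len(sched) - 1)]


@dataclass
class WorkingState:
    """Mutable phase/genotype state threaded through the sub-steps.

    ``solid`` tracks evidence grade: an allele is solid when its value
    is forced by observed data (an observed genotype, a homozygous
    observed parent, a complement of a solid allele, the long-range
    phase of an HD animal).  Alleles filled by consensus votes or by
    origin interpolation are resolved but not solid.  Only solid
    alleles may serve as origin anchors in the recombination scan, so
    an interpolation error can never manufacture anchors that poison
    the opposite gamete.
    """

    phase: np.ndarray  # (n, s, 2) int8, -1 unresolved
    geno: np.ndarray  # (n, s) int8, 3 missing
    solid: np.ndarray | None = None  # (n, s, 2) bool
    observed: np.ndarray | None = None  # (n, s) bool: genotype from data
    n_conflicts: int = 0
    fill_log: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.solid is None:
            self.solid = self.phase >= 0
        if self.observed is None:
            self.observed = self.geno != MISSING_GENO

    def sync_trust(self) -> None:
        """Mark everything currently resolved as solid (used when a
        state is assembled by hand from trusted arrays)."""
        self.solid = self.phase >= 0
        self.observed = self.geno != MISSING_GENO

    @property
    def n_resolved(self) -> int:
        return int((self.phase >= 0).sum())


def _set_alleles(
    state: WorkingState,
    prop: np.ndarray,
    step: str,
    solid: np.ndarray | bool = False,
) -> int:
    """Monotone, genotype-coherent merge of proposed alleles.

    Proposals for already-resolved slots are ignored; proposals that
    contradict a homozygous genotype, or the resolved opposite allele at
    a heterozygous locus, are dropped and counted as conflicts.
    ``solid`` marks which written alleles are observation-forced.
    """
    ph, g = state.phase, state.geno
    can = (prop >= 0) & (ph < 0)
    if not can.any():
        state.fill_log.append((step, 0))
        return 0
    gg = g[:, :, None]
    bad = can & (((gg == 0) & (prop == 1)) | ((gg == 2) & (prop == 0)))
    other = ph[:, :, ::-1]
    bad |= can & (gg == 1) & (other >= 0) & (prop == other)
    write = can & ~bad
    # both slots proposed at a known-het locus must complement each other
    both = write[:, :, 0] & write[:, :, 1] & (g == 1)
    mism = both & (prop[:, :, 0] + prop[:, :, 1] != 1)
    if mism.any():
        write[mism] = False
        state.n_conflicts += int(mism.sum())
    state.n_conflicts += int(bad.sum())
    ph[write] = prop[write]
    if isinstance(solid, np.ndarray):
        state.solid[write] = solid[write]
    elif solid:
        state.solid[write] = True
    n = int(write.sum())
    state.fill_log.append((step, n))
    return n


# ---------------------------------------------------------------------------
# minor sub-steps

def minor1_parent_homozygous_fill(state: WorkingState, ped: Pedigree) -> int:
    """A homozygous-phased parent determines the offspring's allele on
    the corresponding gamete."""
    ph = state.phase
    prop = np.full_like(ph, MISSING_ALLELE)
    solid = np.zeros_like(state.solid)
    for slot, parents in ((0, ped.sire), (1, ped.dam)):
        kids = np.nonzero(parents >= 0)[0]
        par = parents[kids]
        pp = ph[par]
        homo = (pp[:, :, 0] >= 0) & (pp[:, :, 0] == pp[:, :, 1])
        prop[kids, :, slot] = np.where(homo, pp[:, :, 0], MISSING_ALLELE)
        # forced by data when the parent's genotype is observed
        # homozygous, or its phase is solid on both strands
        forced = (state.observed[par] & (state.geno[par] != 1)) | (
            state.solid[par, :, 0] & state.solid[par, :, 1]
        )
        solid[kids, :, slot] = homo & forced
    return _set_alleles(state, prop, "minor1", solid)


def minor2_phase_complement(state: WorkingState) -> int:
    """Known genotype plus one known allele determines the other."""
    ph, g = state.phase, state.geno
    prop = np.full_like(ph, MISSING_ALLELE)
    solid = np.zeros_like(state.solid)
    known = g != MISSING_GENO
    for slot in (0, 1):
        other = ph[:, :, 1 - slot]
        val = g - other
        ok = known & (other >= 0) & (ph[:, :, slot] < 0)
        good = ok & (val >= 0) & (val <= 1)
        state.n_conflicts += int((ok & ~good).sum())
        prop[:, :, slot][good] = val[good].astype(np.int8)
        solid[:, :, slot] = good & state.observed & state.solid[:, :, 1 - slot]
    return _set_alleles(state, prop, "minor2", solid)


def minor3_parents_from_progeny(state: WorkingState, ped: Pedigree) -> int:
    """A parent with one known allele gains the other when some offspring
    received an allele from it that does not match the known one."""
    ph = state.phase
    n, s, _ = ph.shape
    demand = np.zeros((n, s, 2), dtype=bool)  # [..., a]: some child received a
    for slot, parents in ((0, ped.sire), (1, ped.dam)):
        kids = np.nonzero(parents >= 0)[0]
        if kids.size == 0:
            continue
        order = np.argsort(parents[kids], kind="stable")
        kids_sorted = kids[order]
        groups, starts = np.unique(parents[kids_sorted], return_index=True)
        for a in (0, 1):
            got = ph[kids_sorted, :, slot] == a
            pooled = np.bitwise_or.reduceat(got, starts, axis=0)
            demand[groups, :, a] |= pooled
    prop = np.full_like(ph, MISSING_ALLELE)
    k0 = ph[:, :, 0] >= 0
    k1 = ph[:, :, 1] >= 0
    one = k0 ^ k1
    known_val = np.where(k0, ph[:, :, 0], ph[:, :, 1])
    opp = np.clip(1 - known_val, 0, 1).astype(np.int8)
    demanded = np.take_along_axis(
        demand, opp[:, :, None].astype(np.int64), axis=2
    )[:, :, 0]
    fill = one & demanded
    for slot in (0, 1):
        m = fill & (ph[:, :, slot] < 0)
        prop[:, :, slot][m] = opp[m]
    return _set_alleles(state, prop, "minor3")


def minor4_make_genotype(state: WorkingState) -> int:
    """Both alleles known -> genotype is their sum."""
    ph, g = state.phase, state.geno
    m = (g == MISSING_GENO) & (ph[:, :, 0] >= 0) & (ph[:, :, 1] >= 0)
    g[m] = (ph[:, :, 0] + ph[:, :, 1])[m].astype(np.int8)
    n = int(m.sum())
    state.fill_log.append(("minor4", n))
    return n


def run_minor_steps(state: WorkingState, ped: Pedigree, max_passes: int = 12) -> int:
    """Apply the four minor rules to a fixed point (information can flow
    one pedigree link per pass)."""
    total = 0
    for _ in range(max_passes):
        filled = (
            minor1_parent_homozygous_fill(state, ped)
            + minor2_phase_complement(state)
            + minor3_parents_from_progeny(state, ped)
            + minor4_make_genotype(state)
        )
        total += filled
        if filled == 0:
            break
    return total


# ---------------------------------------------------------------------------
# major sub-steps

def major1_probs_to_phase(
    state: WorkingState, beliefs: np.ndarray, cfg: ImputeConfig
) -> int:
    """Hard-call alleles whose peeled probability clears the threshold.

    Calls whose probability is 1 (or 0) to within numerical tolerance
    are observation-forced (e.g. transmission from a homozygous
    observed parent) and count as solid evidence; merely confident
    calls do not."""
    prop, p1 = peeling.call_alleles(beliefs, cfg.peel)
    certain = (p1 >= 1 - 1e-6) | (p1 <= 1e-6)
    return _set_alleles(state, prop, "major1", solid=certain)


def _stitch_segments(
    segments: list[tuple[int, int, np.ndarray, np.ndarray]],
    anchor: int,
    n_snp: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stitch per-core haplotype pairs into two chromosome-long strands.

    ``segments`` are (start, stop, hap_a, hap_b) sorted by start; the
    anchor segment's hap_a is labeled paternal, and labels are extended
    outward through overlapping segments: a segment joins when exactly
    one of its haplotypes matches the labeled strand at every resolved
    discriminating (heterozygous) overlap position.  Ambiguity stops the
    extension in that direction.
    """
    pat = np.full(n_snp, MISSING_ALLELE, dtype=np.int8)
    mat = np.full(n_snp, MISSING_ALLELE, dtype=np.int8)
    s0, e0, ha, hb = segments[anchor]
    pat[s0:e0], mat[s0:e0] = ha, hb

    def try_join(seg) -> bool:
        s, e, a, b = seg
        ov = (pat[s:e] >= 0) & (a != b)
        if not ov.any():
            return False
        a_fits = (a[ov] == pat[s:e][ov]).all() and (b[ov] == mat[s:e][ov]).all()
        b_fits = (b[ov] == pat[s:e][ov]).all() and (a[ov] == mat[s:e][ov]).all()
        if a_fits == b_fits:
            return False
        p, m = (a, b) if a_fits else (b, a)
        new = pat[s:e] < 0
        pat[s:e][new] = p[new]
        mat[s:e][new] = m[new]
        return True

    for seg in segments[anchor + 1 :]:
        if not try_join(seg):
            break
    for k in range(anchor - 1, -1, -1):
        if not try_join(segments[k]):
            break
    return pat, mat


def major2_fill_base_animals(
    state: WorkingState, ped: Pedigree, phasing_result: PhasingResult
) -> int:
    """Label the gametes of high-density base animals.

    A base animal has no parents, so paternal/maternal labels are
    arbitrary: the pair of haplotypes at the central core of the first
    round is labeled (first haplotype -> paternal, by convention) and the
    labels are propagated outward through the overlapping cores of the
    other rounds.  Cores whose pair orientation was already fixed by
    resolved alleles anchor the labeling instead.
    """
    base = ped.is_base()
    hd_idx = phasing_result.hd_idx
    row_of = {int(g): k for k, g in enumerate(hd_idx)}
    n_snp = state.phase.shape[1]
    by_start = sorted(phasing_result.cores, key=lambda cp: (cp.start, cp.round_idx))
    central_r0 = None
    r0 = [cp for cp in phasing_result.cores if cp.round_idx == 0]
    if r0:
        central_r0 = r0[len(r0) // 2]
    prop = np.full_like(state.phase, MISSING_ALLELE)
    filled_rows = 0
    for i in np.nonzero(base)[0]:
        row = row_of.get(int(i))
        if row is None:
            continue
        segments, anchor, ordered_anchor = [], None, None
        for cp in by_start:
            pr = cp.pairs[row]
            if (pr >= 0).all():
                segments.append((cp.start, cp.stop, pr[0], pr[1]))
                if cp.ordered[row] and ordered_anchor is None:
                    ordered_anchor = len(segments) - 1
                if cp is central_r0:
                    anchor = len(segments) - 1
        if not segments:
            continue
        if ordered_anchor is not None:
            anchor = ordered_anchor
        elif anchor is None:
            anchor = len(segments) // 2
        pat, mat = _stitch_segments(segments, anchor, n_snp)
        prop[i, :, 0], prop[i, :, 1] = pat, mat
        filled_rows += 1
    return _set_alleles(state, prop, "major2", solid=True)


def _library_votes(
    gam: np.ndarray, haps: np.ndarray, threshold: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unanimous-survivor votes of a haplotype library.

    gam: (N, L) resolved alleles (-1 missing); haps: (M, L).
    A library haplotype survives with <= ``threshold`` disagreements at
    the gamete's resolved loci; returns boolean (N, L) vote masks for
    allele 0 and allele 1 (unanimity among survivors).
    """
    r0 = (gam == 0).astype(np.float32)
    r1 = (gam == 1).astype(np.float32)
    hf = haps.astype(np.float32)
    mism = r1 @ (1 - hf).T + r0 @ hf.T  # (N, M)
    surv = mism <= threshold + 0.5
    nsurv = surv.sum(axis=1, keepdims=True)
    cnt1 = surv.astype(np.float32) @ hf  # (N, L)
    vote1 = (cnt1 == nsurv) & (nsurv > 0)
    vote0 = (cnt1 == 0) & (nsurv > 0)
    return vote0, vote1


def _apply_vote_counts(
    state: WorkingState,
    count0: np.ndarray,
    count1: np.ndarray,
    accept: int,
    reject: int,
    step: str,
) -> int:
    prop = np.full_like(state.phase, MISSING_ALLELE)
    prop[(count1 >= accept) & (count0 <= reject)] = 1
    prop[(count0 >= accept) & (count1 <= reject)] = 0
    return _set_alleles(state, prop, step)


def major3_library_imputation(
    state: WorkingState,
    phasing_result: PhasingResult,
    cfg: ImputeConfig,
    accept: int,
) -> int:
    """Vote every gamete's unresolved alleles against the haplotype
    libraries of every core of every phasing round; accept when the vote
    counts accumulated across cores and rounds clear the thresholds."""
    n, s, _ = state.phase.shape
    count0 = np.zeros((n, s, 2), dtype=np.int16)
    count1 = np.zeros((n, s, 2), dtype=np.int16)
    for cp in phasing_result.cores:
        if cp.library.n == 0:
            continue
        sl = slice(cp.start, cp.stop)
        for slot in (0, 1):
            gam = state.phase[:, sl, slot]
            v0, v1 = _library_votes(gam, cp.library.haplotypes, cfg.library_mismatch_threshold)
            unres = gam < 0
            count0[:, sl, slot] += (v0 & unres)
            count1[:, sl, slot] += (v1 & unres)
    return _apply_vote_counts(state, count0, count1, accept, cfg.vote_reject, "major3")


def _pair_candidate_votes(
    gam: np.ndarray, cands: np.ndarray, threshold: int
) -> tuple[np.ndarray, np.ndarray]:
    """Votes from per-animal two-candidate sets.

    gam: (N, L); cands: (N, 2, L), -1 where the candidate itself is
    unresolved (candidate positions without information neither match
    nor vote).
    """
    g = gam[:, None, :]
    known = (g >= 0) & (cands >= 0)
    mism = (known & (g != cands)).sum(axis=2)  # (N, 2)
    has_info = (cands >= 0).any(axis=2)
    surv = (mism <= threshold) & has_info
    c0, c1 = cands[:, 0, :], cands[:, 1, :]
    both = surv[:, 0] & surv[:, 1]
    only0 = surv[:, 0] & ~surv[:, 1]
    only1 = surv[:, 1] & ~surv[:, 0]
    agree = (c0 == c1) & (c0 >= 0)
    vote_val = np.full(gam.shape, MISSING_ALLELE, dtype=np.int8)
    vote_val[both] = np.where(agree[both], c0[both], MISSING_ALLELE)
    vote_val[only0] = c0[only0]
    vote_val[only1] = c1[only1]
    return vote_val == 0, vote_val == 1


def _parent_phase_votes(
    state: WorkingState,
    ped: Pedigree,
    intervals: list[tuple[int, int]],
    source_phase: np.ndarray,
    cfg: ImputeConfig,
    accept: int,
    step: str,
    restrict_parents: np.ndarray | None = None,
) -> int:
    """Vote each gamete against its parent's two haplotypes over a set
    of core intervals.  ``restrict_parents`` (boolean over individuals)
    limits the step to offspring of those parents (the HD requirement of
    the first parental-phase pass)."""
    n, s, _ = state.phase.shape
    count0 = np.zeros((n, s, 2), dtype=np.int16)
    count1 = np.zeros((n, s, 2), dtype=np.int16)
    for slot, parents in ((0, ped.sire), (1, ped.dam)):
        ok = parents >= 0
        if restrict_parents is not None:
            ok = ok & np.isin(parents, np.nonzero(restrict_parents)[0])
        kids = np.nonzero(ok)[0]
        if kids.size == 0:
            continue
        par = parents[kids]
        for (start, stop) in intervals:
            sl = slice(start, stop)
            gam = state.phase[kids, sl, slot]
            cands = source_phase[par, sl, :].transpose(0, 2, 1)  # (K, 2, L)
            v0, v1 = _pair_candidate_votes(gam, cands, cfg.library_mismatch_threshold)
            unres = gam < 0
            count0[kids, sl, slot] += (v0 & unres)
            count1[kids, sl, slot] += (v1 & unres)
    return _apply_vote_counts(state, count0, count1, accept, cfg.vote_reject, step)


def major4_parent_phase_imputation(
    state: WorkingState,
    ped: Pedigree,
    phasing_result: PhasingResult,
    cfg: ImputeConfig,
    accept: int,
) -> int:
    """Candidates restricted to the two long-range-phased haplotypes of
    each HD parent."""
    n = state.phase.shape[0]
    hd_mask = np.zeros(n, dtype=bool)
    hd_mask[phasing_result.hd_idx] = True
    intervals = [(cp.start, cp.stop) for cp in phasing_result.cores]
    return _parent_phase_votes(
        state, ped, intervals, phasing_result.phase, cfg, accept,
        "major4", restrict_parents=hd_mask,
    )


def major5_individual_phase_imputation(
    state: WorkingState,
    phasing_result: PhasingResult,
    cfg: ImputeConfig,
    accept: int,
) -> int:
    """Determine the parental origin of an HD animal's own two
    long-range-phased haplotypes: each gamete is voted against the
    animal's haplotype pair, so a pair haplotype that uniquely matches
    one gamete fills that gamete."""
    n, s, _ = state.phase.shape
    count0 = np.zeros((n, s, 2), dtype=np.int16)
    count1 = np.zeros((n, s, 2), dtype=np.int16)
    hd_idx = phasing_result.hd_idx
    for cp in phasing_result.cores:
        sl = slice(cp.start, cp.stop)
        have = (cp.pairs >= 0).all(axis=(1, 2))
        rows = np.nonzero(have)[0]
        if rows.size == 0:
            continue
        glob = hd_idx[rows]
        cands = cp.pairs[rows]
        for slot in (0, 1):
            gam = state.phase[glob, sl, slot]
            v0, v1 = _pair_candidate_votes(gam, cands, cfg.library_mismatch_threshold)
            unres = gam < 0
            count0[glob, sl, slot] += (v0 & unres)
            count1[glob, sl, slot] += (v1 & unres)
    return _apply_vote_counts(state, count0, count1, accept, cfg.vote_reject, "major5")


def _tile(n_snp: int, length: int) -> list[tuple[int, int]]:
    return [(k, min(k + length, n_snp)) for k in range(0, n_snp, length)]


def major6_internal_library(
    state: WorkingState, cfg: ImputeConfig, accept: int
) -> int:
    """Rebuild haplotype libraries from the current (partially imputed)
    phase of *all* animals at several core lengths and rerun the library
    vote."""
    if not cfg.internal_core_lengths:
        return 0
    n, s, _ = state.phase.shape
    count0 = np.zeros((n, s, 2), dtype=np.int16)
    count1 = np.zeros((n, s, 2), dtype=np.int16)
    for length in cfg.internal_core_lengths:
        for (start, stop) in _tile(s, length):
            sl = slice(start, stop)
            gam_all = state.phase[:, sl, :].transpose(0, 2, 1).reshape(-1, stop - start)
            full = (gam_all >= 0).all(axis=1)
            if not full.any():
                continue
            haps = phasing.unique_rows(np.ascontiguousarray(gam_all[full]))
            for slot in (0, 1):
                gam = state.phase[:, sl, slot]
                v0, v1 = _library_votes(gam, haps, cfg.library_mismatch_threshold)
                unres = gam < 0
                count0[:, sl, slot] += (v0 & unres)
                count1[:, sl, slot] += (v1 & unres)
    return _apply_vote_counts(state, count0, count1, accept, cfg.vote_reject, "major6")


def major7_internal_parent_phase(
    state: WorkingState, ped: Pedigree, cfg: ImputeConfig, accept: int
) -> int:
    """Parental-phase vote for *all* animals using the working (possibly
    imputed) phase of their parents, at the internal core lengths."""
    s = state.phase.shape[1]
    intervals: list[tuple[int, int]] = []
    for length in cfg.internal_core_lengths:
        intervals.extend(_tile(s, length))
    return _parent_phase_votes(
        state, ped, intervals, state.phase, cfg, accept, "major7"
    )


def _ffill(origin: np.ndarray) -> np.ndarray:
    """Forward-fill an origin track (-1 undetermined)."""
    idx = np.where(origin >= 0, np.arange(origin.size), 0)
    np.maximum.accumulate(idx, out=idx)
    out = origin[idx]
    first = np.argmax(origin >= 0) if (origin >= 0).any() else origin.size
    out[:first] = -1
    return out


def _origin_track(
    parent_phase: np.ndarray,
    child_strand: np.ndarray,
    child_solid: np.ndarray | None = None,
    parent_solid: np.ndarray | None = None,
) -> np.ndarray | None:
    """Which parental strand the child's gamete came from, per locus.

    An origin-informative (anchor) locus is one where the parent is
    heterozygous and phased and the child's transmitted allele is
    resolved: the allele then identifies the strand.  When evidence
    grades are supplied, anchors are restricted to observation-forced
    (solid) alleles so that interpolated fills can never act as
    anchors.  Returns int8 with 0 (paternal strand of the parent),
    1 (maternal), -1 undetermined, or None when no locus is
    informative.
    """
    par_het = (
        (parent_phase[:, 0] >= 0)
        & (parent_phase[:, 1] >= 0)
        & (parent_phase[:, 0] != parent_phase[:, 1])
    )
    informative = par_het & (child_strand >= 0)
    if child_solid is not None:
        informative &= child_solid
    if parent_solid is not None:
        informative &= parent_solid[:, 0] & parent_solid[:, 1]
    if not informative.any():
        return None
    origin = np.full(child_strand.size, -1, dtype=np.int8)
    origin[informative] = (
        child_strand[informative] == parent_phase[informative, 1]
    ).astype(np.int8)
    return origin


def _filter_isolated_anchors(origin: np.ndarray, min_gap: int) -> np.ndarray:
    """Drop single anchors that disagree with both neighbours when the
    neighbours lie within ``min_gap`` SNP of each other: such a flip
    would require a double crossover inside an implausibly short
    interval and far more often reflects a wrong hard call."""
    inf_idx = np.nonzero(origin >= 0)[0]
    if inf_idx.size < 3:
        return origin
    o = origin[inf_idx]
    isolated = (
        (o[1:-1] != o[:-2]) & (o[1:-1] != o[2:]) & (o[:-2] == o[2:])
        & ((inf_idx[2:] - inf_idx[:-2]) < min_gap)
    )
    if isolated.any():
        origin = origin.copy()
        origin[inf_idx[1:-1][isolated]] = -1
    return origin


def _anchor_distances(origin: np.ndarray) -> np.ndarray:
    """Distance (in SNP) from every locus to its nearest anchor."""
    n = origin.size
    far = 10**9
    left = _ffill(np.where(origin >= 0, np.arange(n), -1))
    dl = np.where(left >= 0, np.arange(n) - left, far)
    right = _ffill(np.where(origin >= 0, np.arange(n), -1)[::-1])[::-1]
    dr = np.where(right >= 0, right - np.arange(n), far)
    return np.minimum(dl, dr)


def major8_recombination_scan(
    state: WorkingState, ped: Pedigree, cfg: ImputeConfig, iteration: int
) -> int:
    """Impute gametes by locating where recombination occurred.

    Wherever the parent is heterozygous and phased and the child's
    transmitted allele is resolved, the allele identifies the parental
    strand of origin.  Scanning forward and backward, undetermined
    stretches flanked by identical determinations inherit that origin
    (no double crossover assumed in between) and a stretch reached by
    only one scan direction inherits that direction's origin.  Alleles
    are imputed from the identified parental strand subject to the
    iteration's restrictions: implied recombination count, spacing of
    double crossovers, and distance to the nearest origin-informative
    locus.  The minor rules are re-applied after each gamete pass so
    that complements flow before the opposite gamete is scanned.
    """
    k = min(iteration, len(cfg.max_recombinations) - 1)
    max_rec = cfg.max_recombinations[k]
    min_gap = cfg.min_double_crossover_gap[
        min(iteration, len(cfg.min_double_crossover_gap) - 1)
    ]
    cap = cfg.anchor_distance_cap[min(iteration, len(cfg.anchor_distance_cap) - 1)]
    ph = state.phase
    total = 0
    for slot, parents in ((0, ped.sire), (1, ped.dam)):
        prop = np.full_like(ph, MISSING_ALLELE)
        for c in np.nonzero(parents >= 0)[0]:
            p = parents[c]
            pp = ph[p]
            if cfg.anchor_require_solid:
                origin = _origin_track(
                    pp, ph[c, :, slot], state.solid[c, :, slot], state.solid[p]
                )
            else:
                origin = _origin_track(pp, ph[c, :, slot])
            if origin is None:
                continue
            origin = _filter_isolated_anchors(origin, min_gap)
            inf_idx = np.nonzero(origin >= 0)[0]
            if inf_idx.size == 0:
                continue
            o = origin[inf_idx]
            switches = np.nonzero(o[1:] != o[:-1])[0]
            if switches.size > max_rec:
                continue
            if switches.size >= 2:
                # switch positions: midway between the flanking anchors
                pos = (inf_idx[switches] + inf_idx[switches + 1]) / 2
                if np.diff(pos).min() < min_gap:
                    continue
            fwd = _ffill(origin)
            bwd = _ffill(origin[::-1])[::-1]
            agree = np.where(
                fwd < 0, bwd, np.where(bwd < 0, fwd, np.where(fwd == bwd, fwd, -1))
            )
            agree = np.where(_anchor_distances(origin) <= cap, agree, -1)
            src = pp[np.arange(agree.size), np.clip(agree, 0, 1)]
            fill = (agree >= 0) & (ph[c, :, slot] < 0) & (src >= 0)
            prop[c, fill, slot] = src[fill]
        total += _set_alleles(state, prop, "major8")
        run_minor_steps(state, ped, max_passes=2)
    return total


def _estimate_recomb_rate(
    state: WorkingState, ped: Pedigree, require_solid: bool = False
) -> float:
    """Per-SNP recombination rate (Morgans/SNP) estimated from the
    origin switches observed across all parent-offspring gametes."""
    switches = 0
    span = 0
    ph = state.phase
    for slot, parents in ((0, ped.sire), (1, ped.dam)):
        for c in np.nonzero(parents >= 0)[0]:
            p = parents[c]
            if require_solid:
                origin = _origin_track(
                    ph[p], ph[c, :, slot], state.solid[c, :, slot], state.solid[p]
                )
            else:
                origin = _origin_track(ph[p], ph[c, :, slot])
            if origin is None:
                continue
            origin = _filter_isolated_anchors(origin, 50)
            inf_idx = np.nonzero(origin >= 0)[0]
            if inf_idx.size < 2:
                continue
            o = origin[inf_idx]
            switches += int((o[1:] != o[:-1]).sum())
            span += int(inf_idx[-1] - inf_idx[0])
    if span == 0:
        return 0.0
    return switches / span


def _refine_origin_probs(
    state: WorkingState,
    ped: Pedigree,
    probs: np.ndarray,
    rate: float,
    require_solid: bool = False,
) -> None:
    """Sharpen the probabilities of still-unresolved alleles using the
    parental strand of origin inferred from flanking anchors.

    Between anchors the origin is uncertain only through recombination;
    with per-SNP rate r, the probability that the origin at distance d
    matches an anchor is the Haldane no-net-crossover probability
    (1 + exp(-2 r d)) / 2.  The refined allele probability mixes the
    parent's two strand probabilities with these weights.  Applied in
    place; loci without any anchor keep the peeled value.
    """
    if rate <= 0:
        return
    ph = state.phase
    n, s, _ = ph.shape
    idx = np.arange(s)
    for slot, parents in ((0, ped.sire), (1, ped.dam)):
        for c in np.nonzero(parents >= 0)[0]:
            unres = ph[c, :, slot] < 0
            if not unres.any():
                continue
            p = parents[c]
            if require_solid:
                origin = _origin_track(
                    ph[p], ph[c, :, slot], state.solid[c, :, slot], state.solid[p]
                )
            else:
                origin = _origin_track(ph[p], ph[c, :, slot])
            if origin is None:
                continue
            origin = _filter_isolated_anchors(origin, 50)
            anchored = origin >= 0
            left = _ffill(np.where(anchored, idx, -1))
            right = _ffill(np.where(anchored, idx, -1)[::-1])[::-1]
            have_l, have_r = left >= 0, right >= 0
            el = np.where(have_l, np.exp(-2 * rate * (idx - np.where(have_l, left, 0))), 0.0)
            er = np.where(have_r, np.exp(-2 * rate * (np.where(have_r, right, 0) - idx)), 0.0)
            ol = np.where(have_l, origin[np.clip(left, 0, None)], -1)
            orr = np.where(have_r, origin[np.clip(right, 0, None)], -1)
            pe_l, po_l = (1 + el) / 2, (1 - el) / 2
            pe_r, po_r = (1 + er) / 2, (1 - er) / 2
            # probability that the locus has the LEFT anchor's origin
            with np.errstate(invalid="ignore", divide="ignore"):
                same = np.where(
                    ol == orr,
                    pe_l * pe_r / np.maximum(pe_l * pe_r + po_l * po_r, 1e-12),
                    pe_l * po_r / np.maximum(pe_l * po_r + po_l * pe_r, 1e-12),
                )
            q = np.where(have_l & have_r, same, np.where(have_l, pe_l, pe_r))
            oref = np.where(have_l, ol, orr)
            use = unres & (oref >= 0)
            if not use.any():
                continue
            oref = np.clip(oref, 0, 1)
            par_probs = probs[p]  # (s, 2)
            a_ref = par_probs[idx, oref]
            a_alt = par_probs[idx, 1 - oref]
            refined = q * a_ref + (1 - q) * a_alt
            probs[c, use, slot] = refined[use]


def major9_recalculate(
    state: WorkingState,
    ped: Pedigree,
    peel_cfg: PeelConfig,
    allele_freq: np.ndarray,
    cfg: ImputeConfig | None = None,
) -> np.ndarray:
    """Recalculate allele probabilities by peeling the updated genotypes
    (with resolved alleles folded into the penetrance); alleles still
    missing take their recalculated probability, sharpened by the
    recombination-distance origin weighting when enabled."""
    beliefs = peeling.peel(ped, state.geno, allele_freq, peel_cfg, phase=state.phase)
    p1 = peeling.allele_probabilities(beliefs)
    probs = np.where(state.phase >= 0, state.phase.astype(float), p1)
    if cfg is not None and cfg.origin_aware_probs:
        solid = cfg.anchor_require_solid
        rate = _estimate_recomb_rate(state, ped, solid)
        _refine_origin_probs(state, ped, probs, rate, solid)
        np.clip(probs, 0.0, 1.0, out=probs)
    return probs


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class ImputationResult:
    """Final pipeline products for every individual in the pedigree."""

    phase: np.ndarray  # (n, s, 2) hard-called alleles, -1 unresolved
    probs: np.ndarray  # (n, s, 2) P(allele = 1); equals phase where called
    genotypes: np.ndarray  # (n, s) int codes, 3 where not fully resolved
    hard_called: np.ndarray  # (n, s, 2) bool: called without ambiguity
    allele_freq: np.ndarray
    n_conflicts: int
    fill_log: list[tuple[str, int]]
    mendelian_conflicts: list[tuple[str, str, int]]
    phasing: PhasingResult | None = None

    @property
    def dosage(self) -> np.ndarray:
        return self.probs.sum(axis=2)


def run_pipeline(
    ped: Pedigree,
    geno: GenotypeMatrix,
    cfg: ImputeConfig | None = None,
    unmapped_only: bool = False,
    allele_freq: np.ndarray | None = None,
    known_phase: np.ndarray | None = None,
    phasing_result: PhasingResult | None = None,
) -> ImputationResult:
    """Run the full phasing-and-imputation hierarchy.

    Order of operations: Mendelian cleaning; segregation analysis; hard
    calls plus minor rules; then (unless ``unmapped_only``) long-range
    phasing of the HD animals followed by ``n_outer_iterations`` cycles
    of the major sub-steps (each followed by the minor rules); finally
    the probability recalculation.  ``phasing_result`` allows re-using
    the phasing of a previous run on identical HD data; ``known_phase``
    passes externally phased alleles (parental origin known) through to
    the phasing step as ground truth.

    The pipeline is deterministic: identical inputs and configuration
    give identical results.
    """
    cfg = cfg or ImputeConfig()
    mendel_conflicts, clean = gio.check_mendelian(ped, geno)
    hd_ids, _ = gio.split_density(clean, ped, cfg.phase.hd_threshold)
    hd_idx = np.array(sorted(ped.index[a] for a in hd_ids), dtype=np.int64)
    if allele_freq is None:
        allele_freq = gio.allele_frequencies(
            clean, hd_idx if hd_idx.size else None
        )

    state = WorkingState(
        phase=np.full(clean.values.shape + (2,), MISSING_ALLELE, dtype=np.int8),
        geno=clean.values.copy(),
    )
    beliefs = peeling.peel(ped, state.geno, allele_freq, cfg.peel)

    if not unmapped_only and not clean.mapped.all():
        raise NotImplementedError(
            "mixed mapped/unmapped SNP: impute unmapped SNP separately "
            "with unmapped_only=True"
        )

    major1_probs_to_phase(state, beliefs, cfg)
    run_minor_steps(state, ped)

    if not unmapped_only:
        if phasing_result is None:
            phasing_result = phasing.phase_hd(
                clean, ped, hd_idx, cfg.phase, known_phase=known_phase
            )
        _set_alleles(state, phasing_result.phase, "lrp_merge", solid=True)
        run_minor_steps(state, ped)
        for outer in range(cfg.n_outer_iterations):
            accept = cfg.accept_at(outer)
            major2_fill_base_animals(state, ped, phasing_result)
            run_minor_steps(state, ped)
            major3_library_imputation(state, phasing_result, cfg, accept)
            run_minor_steps(state, ped)
            major4_parent_phase_imputation(state, ped, phasing_result, cfg, accept)
            run_minor_steps(state, ped)
            major5_individual_phase_imputation(state, phasing_result, cfg, accept)
            run_minor_steps(state, ped)
            major6_internal_library(state, cfg, accept)
            run_minor_steps(state, ped)
            major7_internal_parent_phase(state, ped, cfg, accept)
            run_minor_steps(state, ped)
            for it in range(len(cfg.max_recombinations)):
                major8_recombination_scan(state, ped, cfg, it)
                run_minor_steps(state, ped)

    hard_called = state.phase >= 0
    probs = major9_recalculate(state, ped, cfg.peel, allele_freq, cfg)
    genotypes = state.geno.copy()
    return ImputationResult(
        phase=state.phase,
        probs=probs,
        genotypes=genotypes,
        hard_called=hard_called,
        allele_freq=allele_freq,
        n_conflicts=state.n_conflicts,
        fill_log=state.fill_log,
        mendelian_conflicts=mendel_conflicts,
        phasing=phasing_result,
    )
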