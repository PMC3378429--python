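"""Single-locus segregation analysis (iterative peeling).

Genotype probabilities for every individual at every locus are computed by
sum-product message passing over the pedigree, with one trio factor per
offspring (sire, dam, child) encoding Mendelian transmission and a
Hardy-Weinberg prior on base animals.  States are *ordered* genotypes
(paternal allele, maternal allele): (0,0), (0,1), (1,0), (1,1).

Messages are iterated to a fixed point: an upward sweep sends each
child's evidence to its parents, a downward sweep sends each parent
pair's evidence to their offspring.  On loop-free pedigrees this
converges to the exact posterior; on looped (inbred) pedigrees it is the
usual iterative-peeling approximation.  All messages are vectorized
across loci, so a whole chromosome is peeled in one call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix, MISSING_ALLELE, MISSING_GENO
from .pedigree import Pedigree

#: P(transmit allele 1 | ordered genotype state)
_T1 = np.array([0.0, 0.5, 0.5, 1.0])
_EPS = 1e-12

# unnormalized penetrance rows for observed codes 0..3
_PENETRANCE = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],  # hom 0
        [0.0, 0.5, 0.5, 0.0],  # het
        [0.0, 0.0, 0.0, 1.0],  # hom 2
        [0.25, 0.25, 0.25, 0.25],  # missing
    ]
)


@dataclass
class PeelConfig:
    """Settings for the segregation analysis.

    call_threshold: allele probability above which a hard 0/1 call is made.
    convergence_tol / max_iterations: fixed-point stopping rule; the
    tolerance is on genotype probabilities, so loop-free pedigrees reach
    the exact posterior well before ``max_iterations``.
    damping is applied to parent-bound messages from ``damping_start``
    iterations onward, which stabilizes looped pedigrees.
    """

    call_threshold: float = 0.99
    max_iterations: int = 30
    convergence_tol: float = 1e-7
    damping: float = 0.5
    damping_start: int = 12
    allele_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.call_threshold < 1:
            raise ValueError("call_threshold must be in (0.5, 1)")


def penetrance(observed: int) -> np.ndarray:
    """Unnormalized ordered-genotype likelihood of one observed code."""
    if observed not in (0, 1, 2, 3):
        raise ValueError(f"invalid genotype code: {observed}")
    return _PENETRANCE[observed].copy()


def _hw_prior(p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg ordered-genotype prior, shape (n_loci, 4)."""
    q = 1 - p
    return np.stack([q * q, q * p, p * q, p * p], axis=-1)


def _normalize(m: np.ndarray) -> np.ndarray:
    s = m.sum(axis=-1, keepdims=True)
    dead = s <= 1e-300
    if dead.any():
        m = np.where(dead, 0.25, m)
        s = np.where(dead, 1.0, s)
    return m / s


def _trio_to_child(t1s: np.ndarray, t1d: np.ndarray) -> np.ndarray:
    """Anterior message to a child given parental allele-1 transmission
    probabilities (each shape (..., n_loci))."""
    return np.stack(
        [
            (1 - t1s) * (1 - t1d),
            (1 - t1s) * t1d,
            t1s * (1 - t1d),
            t1s * t1d,
        ],
        axis=-1,
    )


def _message_to_parent(mc: np.ndarray, t1_other: np.ndarray) -> np.ndarray:
    """Trio-factor message to one parent.

    mc: child's belief excluding its anterior, shape (..., 4).
    t1_other: other parent's allele-1 transmission probability (...,).
    The child state index is (allele from sire, allele from dam); ``mc``
    is marginalized over the other parent's transmitted allele.
    """
    a0 = mc[..., 0] * (1 - t1_other) + mc[..., 1] * t1_other
    a1 = mc[..., 2] * (1 - t1_other) + mc[..., 3] * t1_other
    half = 0.5 * (a0 + a1)
    return np.stack([a0, half, half, a1], axis=-1)


def _message_to_dam(mc: np.ndarray, t1_sire: np.ndarray) -> np.ndarray:
    b0 = mc[..., 0] * (1 - t1_sire) + mc[..., 2] * t1_sire
    b1 = mc[..., 1] * (1 - t1_sire) + mc[..., 3] * t1_sire
    half = 0.5 * (b0 + b1)
    return np.stack([b0, half, half, b1], axis=-1)


class _Grouper:
    """Product-pooling of per-child messages into per-parent arrays using
    sorted segments and log-space reduceat (fast, no ufunc.at)."""

    def __init__(self, parent_idx: np.ndarray, n_parents: int):
        self.order = np.argsort(parent_idx, kind="stable")
        sorted_parents = parent_idx[self.order]
        self.unique, self.starts = np.unique(sorted_parents, return_index=True)
        self.n_parents = n_parents

    def logsum(self, msgs: np.ndarray, out: np.ndarray) -> None:
        """Add per-parent sums of log-messages into ``out`` (n_parents, ...)."""
        if self.order.size == 0:
            return
        logs = np.log(np.maximum(msgs[self.order], _EPS))
        segs = np.add.reduceat(logs, self.starts, axis=0)
        out[self.unique] += segs


def peel(
    ped: Pedigree,
    observed: np.ndarray,
    allele_freq: np.ndarray,
    cfg: PeelConfig | None = None,
    phase: np.ndarray | None = None,
) -> np.ndarray:
    """Peel every locus of every individual.

    Parameters
    ----------
    observed
        (n_ind, n_loci) genotype codes {0,1,2,3}.
    allele_freq
        (n_loci,) base-population allele-1 frequencies (founder prior).
    phase
        Optional (n_ind, n_loci, 2) resolved alleles (-1 missing); any
        resolved allele zeroes out the incompatible ordered states, so
        previously imputed phase sharpens the recalculated probabilities.

    Returns
    -------
    (n_ind, n_loci, 4) posterior ordered-genotype probabilities.
    """
    cfg = cfg or PeelConfig()
    n, s = observed.shape
    p = np.broadcast_to(np.asarray(allele_freq, dtype=float), (s,))

    phi = _PENETRANCE[observed.astype(np.int64)]  # (n, s, 4)
    if phase is not None:
        phi = phi.copy()
        pat, mat = phase[..., 0], phase[..., 1]
        # state index = 2*pat_allele + mat_allele
        phi[pat == 0] *= np.array([1, 1, 0, 0.0])
        phi[pat == 1] *= np.array([0, 0, 1, 1.0])
        phi[mat == 0] *= np.array([1, 0, 1, 0.0])
        phi[mat == 1] *= np.array([0, 1, 0, 1.0])
        dead = phi.sum(axis=-1) <= 0
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} locus observations conflict with phase; reset"
            )
            phi[dead] = 0.25
    phi = _normalize(phi)

    hw = _hw_prior(p)  # (s, 4)
    has_sire = ped.sire >= 0
    has_dam = ped.dam >= 0
    children = np.nonzero(has_sire | has_dam)[0]
    sire_of = ped.sire[children]
    dam_of = ped.dam[children]
    g_sire = _Grouper(sire_of[sire_of >= 0], n)
    g_dam = _Grouper(dam_of[dam_of >= 0], n)
    with_sire = sire_of >= 0
    with_dam = dam_of >= 0

    # Loci are independent, so columns that have converged are compacted
    # away and only the still-active loci are iterated further.
    out = np.empty((n, s, 4))
    cols = np.arange(s)  # active locus -> original index
    pa = p.copy()
    phi_a = phi
    ant = np.broadcast_to(hw, (n, s, 4)).copy()
    postprod = np.full((n, s, 4), 0.25)
    post_s = np.full((len(children), s, 4), 0.25)  # child factor -> sire
    post_d = np.full((len(children), s, 4), 0.25)  # child factor -> dam
    beliefs = _normalize(phi_a * ant)

    def _coparent_t1(full):
        a = cols.size
        t1d = np.broadcast_to(pa, (len(children), a)).copy()
        if with_dam.any():
            md = _normalize(
                np.maximum(full[dam_of[with_dam]] / np.maximum(post_d[with_dam], _EPS), _EPS)
            )
            t1d[with_dam] = md @ _T1
        t1s = np.broadcast_to(pa, (len(children), a)).copy()
        if with_sire.any():
            ms = _normalize(
                np.maximum(full[sire_of[with_sire]] / np.maximum(post_s[with_sire], _EPS), _EPS)
            )
            t1s[with_sire] = ms @ _T1
        return t1s, t1d

    for it in range(cfg.max_iterations):
        full = _normalize(phi_a * ant * postprod)
        mc = _normalize(phi_a[children] * postprod[children])
        t1s, t1d = _coparent_t1(full)

        new_post_s = _normalize(_message_to_parent(mc, t1d))
        new_post_d = _normalize(_message_to_dam(mc, t1s))
        if it >= cfg.damping_start:
            new_post_s = _normalize(
                cfg.damping * new_post_s + (1 - cfg.damping) * post_s
            )
            new_post_d = _normalize(
                cfg.damping * new_post_d + (1 - cfg.damping) * post_d
            )
        post_s, post_d = new_post_s, new_post_d

        # pool child messages into parent posterior products
        logpost = np.zeros((n, cols.size, 4))
        g_sire.logsum(post_s[with_sire], logpost)
        g_dam.logsum(post_d[with_dam], logpost)
        logpost -= logpost.max(axis=-1, keepdims=True)
        postprod = _normalize(np.exp(logpost))

        # downward: anterior of every child from parents (excluding the
        # child's own upward message)
        full = _normalize(phi_a * ant * postprod)
        t1s, t1d = _coparent_t1(full)
        ant[children] = _trio_to_child(t1s, t1d)

        new_beliefs = _normalize(phi_a * ant * postprod)
        delta = np.abs(new_beliefs - beliefs).max(axis=(0, 2))  # per locus
        beliefs = new_beliefs
        done = delta < cfg.convergence_tol
        # one extra sweep after apparent convergence guards against a
        # transiently small delta on deep pedigrees
        if done.all() or it == cfg.max_iterations - 1:
            out[:, cols] = beliefs
            if done.all():
                break
        if done.any() and it < cfg.max_iterations - 1:
            out[:, cols[done]] = beliefs[:, done]
            keep = ~done
            cols = cols[keep]
            pa = pa[keep]
            phi_a = phi_a[:, keep]
            ant = ant[:, keep]
            postprod = postprod[:, keep]
            post_s = post_s[:, keep]
            post_d = post_d[:, keep]
            beliefs = beliefs[:, keep]
    return out


def peel_locus(
    ped: Pedigree,
    observed_column: np.ndarray,
    cfg: PeelConfig | None = None,
    allele_freq: float | None = None,
) -> np.ndarray:
    """Peel a single locus; returns (n_ind, 4) posterior probabilities.

    The allele frequency defaults to the observed allele-1 frequency of
    the column (0.5 when nothing is observed).
    """
    obs = np.asarray(observed_column, dtype=np.int8).reshape(-1, 1)
    if allele_freq is None:
        seen = obs[obs != MISSING_GENO]
        allele_freq = float(seen.mean() / 2) if seen.size else 0.5
        allele_freq = min(max(allele_freq, 1e-4), 1 - 1e-4)
    out = peel(ped, obs, np.array([allele_freq]), cfg)
    return out[:, 0, :]


def allele_probabilities(beliefs: np.ndarray) -> np.ndarray:
    """(..., 4) ordered-genotype probabilities -> (..., 2) per-gamete
    P(allele = 1); [..., 0] paternal, [..., 1] maternal."""
    p_pat = beliefs[..., 2] + beliefs[..., 3]
    p_mat = beliefs[..., 1] + beliefs[..., 3]
    return np.stack([p_pat, p_mat], axis=-1)


def call_alleles(
    beliefs: np.ndarray, cfg: PeelConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Hard-call gamete alleles where the probability clears the threshold.

    Returns (phase, p1): phase is int8 with -1 where uncalled, p1 the
    per-gamete allele-1 probabilities.
    """
    cfg = cfg or PeelConfig()
    p1 = allele_probabilities(beliefs)
    phase = np.full(p1.shape, MISSING_ALLELE, dtype=np.int8)
    phase[p1 > cfg.call_threshold] = 1
    phase[p1 < 1 - cfg.call_threshold] = 0
    return phase, p1


def impute_unmapped(
    ped: Pedigree,
    geno: GenotypeMatrix,
    cfg: PeelConfig | None = None,
    allele_freq: np.ndarray | None = None,
):
    """Peeling-only imputation: no haplotype information.

    Runs the segregation analysis per locus, hard-calls confident
    alleles, applies the single-locus fill-in rules to a fixed point, and
    recalculates probabilities for whatever is left.  Used for unmapped
    SNP and as the pedigree-only baseline mode.

    Returns an :class:`~pedimpute.imputation.ImputationResult`.
    """
    from . import imputation  # deferred: imputation imports this module

    return imputation.run_pipeline(
        ped, geno, imputation.ImputeConfig(peel=cfg or PeelConfig()),
        unmapped_only=True, allele_freq=allele_freq,
    )
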