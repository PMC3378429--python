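"""Gene-dropping simulator: pedigrees, LD-structured founder haplotypes,
Mendelian transmission with recombination, and masking scenarios.

The generator produces the study conditions every pipeline stage is
tested under: a multi-generation livestock-style pedigree, founder
haplotypes with blocky linkage disequilibrium (a first-order Markov
copula along the chromosome), gamete transmission with Poisson crossover
counts, and low-density masking of a test cohort at the panel densities
used for evaluating imputation (99/95/90/85% of SNP masked).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import genotypes as gio
from .genotypes import GenotypeMatrix, MISSING_GENO
from .pedigree import Pedigree, from_records


@dataclass
class SimConfig:
    """Study-design knobs for the simulator.

    The defaults define the standard fixture: a 6-generation pedigree of
    ~1500 animals on a 1 Morgan chromosome of 1000 SNP, all parents
    genotyped at high density and the youngest 500 animals forming the
    low-density test cohort.
    """

    n_founders: int = 100
    n_generations: int = 6  # including the founder generation
    offspring_per_generation: int = 280
    litter_size: int = 2
    n_snp: int = 1000
    morgans: float = 1.0
    ld_decay: float = 0.95  # P(adjacent SNP share their latent uniform)
    maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0
    hd_assignment: str = "parents"  # parents | sires | random_parents | all
    hd_fraction: float = 0.5  # used by random_parents
    n_test: int = 500  # youngest animals masked to low density
    mask_fraction: float = 0.85
    avoid_full_sib_mating: bool = True


@dataclass
class TruthSet:
    """Ground truth from a gene-dropping run."""

    ped: Pedigree
    phase: np.ndarray  # (n_ind, n_snp, 2) int8, fully resolved
    crossovers: list[list[np.ndarray]]  # per individual, per gamete
    allele_freq: np.ndarray  # drawn founder frequencies
    sex: np.ndarray  # 0 = male, 1 = female

    @property
    def genotypes(self) -> np.ndarray:
        return self.phase.sum(axis=2).astype(np.int8)


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Discrete-generation pedigree; returns (Pedigree, sex array).

    Each non-founder receives a sire and dam sampled from the previous
    generation; full-sib matings are avoided when configured.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    records: list[tuple[str, str, str]] = []
    sex: dict[str, int] = {}
    prev: list[str] = []
    counter = 0
    for f in range(cfg.n_founders):
        name = f"F{f}"
        records.append((name, "0", "0"))
        sex[name] = f % 2
        prev.append(name)
    parent_pair: dict[str, tuple[str, str]] = {}
    for g in range(1, cfg.n_generations):
        males = [a for a in prev if sex[a] == 0]
        females = [a for a in prev if sex[a] == 1]
        n_matings = max(1, cfg.offspring_per_generation // cfg.litter_size)
        cur: list[str] = []
        for m in range(n_matings):
            for _ in range(40):
                s = males[rng.integers(len(males))]
                d = females[rng.integers(len(females))]
                if not cfg.avoid_full_sib_mating:
                    break
                if parent_pair.get(s) is None or parent_pair.get(s) != parent_pair.get(d):
                    break
                if parent_pair.get(s) is None and parent_pair.get(d) is None:
                    break
            for _ in range(cfg.litter_size):
                name = f"G{g}N{counter}"
                counter += 1
                records.append((name, s, d))
                sex[name] = int(rng.integers(2))
                parent_pair[name] = (s, d)
                cur.append(name)
        prev = cur
    ped = from_records(records)
    sex_arr = np.array([sex[a] for a in ped.ids], dtype=np.int8)
    return ped, sex_arr


def simulate_founder_haplotypes(
    cfg: SimConfig, n_haplotypes: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Founder haplotypes with blocky LD.

    Per-SNP allele-1 frequencies are drawn uniformly from ``maf_range``.
    Each haplotype is generated by thresholding a chain of latent
    uniforms in which position j reuses position j-1's uniform with
    probability ``ld_decay`` — marginal frequencies are exact and
    adjacent SNP are positively correlated in blocks.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    freq = rng.uniform(lo, hi, size=cfg.n_snp)
    u = rng.uniform(size=(n_haplotypes, cfg.n_snp))
    keep = rng.uniform(size=(n_haplotypes, cfg.n_snp)) < cfg.ld_decay
    keep[:, 0] = False
    for j in range(1, cfg.n_snp):
        u[:, j] = np.where(keep[:, j], u[:, j - 1], u[:, j])
    haps = (u < freq).astype(np.int8)
    return haps, freq


def _transmit(
    parent_phase: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: recombine the parent's two strands.

    Crossover count ~ Poisson(morgans) at uniform positions on the SNP
    axis; returns (gamete, crossover positions as fractional indices).
    """
    n_snp = parent_phase.shape[0]
    n_cross = rng.poisson(cfg.morgans)
    cross = np.sort(rng.uniform(0, n_snp, size=n_cross))
    strand = np.full(n_snp, rng.integers(2), dtype=np.int8)
    for c in cross:
        strand[int(np.ceil(c)):] ^= 1
    gamete = parent_phase[np.arange(n_snp), strand]
    return gamete, cross


def gene_drop(
    ped: Pedigree,
    founder_haps: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    sex: np.ndarray | None = None,
    allele_freq: np.ndarray | None = None,
) -> TruthSet:
    """Drop founder haplotypes through the pedigree with recombination."""
    rng = rng or np.random.default_rng(cfg.seed)
    n, n_snp = ped.n, founder_haps.shape[1]
    phase = np.zeros((n, n_snp, 2), dtype=np.int8)
    crossovers: list[list[np.ndarray]] = [[] for _ in range(n)]
    next_founder_hap = 0
    for i in range(n):
        for gam, parent in ((0, ped.sire[i]), (1, ped.dam[i])):
            if parent < 0:
                phase[i, :, gam] = founder_haps[next_founder_hap % founder_haps.shape[0]]
                next_founder_hap += 1
                crossovers[i].append(np.zeros(0))
            else:
                gamete, cross = _transmit(phase[parent], cfg, rng)
                phase[i, :, gam] = gamete
                crossovers[i].append(cross)
    if allele_freq is None:
        allele_freq = founder_haps.mean(axis=0)
    if sex is None:
        sex = np.zeros(n, dtype=np.int8)
    return TruthSet(
        ped=ped, phase=phase, crossovers=crossovers,
        allele_freq=np.asarray(allele_freq), sex=sex,
    )


def select_hd(truth: TruthSet, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Indices of animals genotyped at high density under the scenario's
    assignment rule, excluding the test cohort."""
    ped = truth.ped
    n = ped.n
    is_parent = np.zeros(n, dtype=bool)
    is_parent[ped.sire[ped.sire >= 0]] = True
    is_parent[ped.dam[ped.dam >= 0]] = True
    test = test_cohort(ped, cfg)
    in_test = np.zeros(n, dtype=bool)
    in_test[test] = True
    if cfg.hd_assignment == "all":
        hd = ~in_test
    elif cfg.hd_assignment == "parents":
        hd = is_parent & ~in_test
    elif cfg.hd_assignment == "sires":
        hd = is_parent & (truth.sex == 0) & ~in_test
    elif cfg.hd_assignment == "random_parents":
        hd = is_parent & ~in_test & (rng.uniform(size=n) < cfg.hd_fraction)
    else:
        raise ValueError(f"unknown hd_assignment: {cfg.hd_assignment!r}")
    return np.nonzero(hd)[0]


def test_cohort(ped: Pedigree, cfg: SimConfig) -> np.ndarray:
    """The youngest ``n_test`` animals without recorded offspring.

    Mirrors the use case of selection candidates genotyped at low
    density: the cohort consists of the most recently born non-parents,
    so the ancestor generations remain available for high-density
    genotyping.
    """
    is_parent = np.zeros(ped.n, dtype=bool)
    is_parent[ped.sire[ped.sire >= 0]] = True
    is_parent[ped.dam[ped.dam >= 0]] = True
    candidates = np.nonzero(~is_parent)[0]
    return candidates[-cfg.n_test:] if cfg.n_test else candidates[:0]


@dataclass
class Scenario:
    """One masking scenario derived from a truth set."""

    geno: GenotypeMatrix
    hd_idx: np.ndarray
    test_idx: np.ndarray
    panel: gio.PanelDesign
    truth: TruthSet


def apply_scenario(truth: TruthSet, cfg: SimConfig) -> Scenario:
    """Build the observed data for one scenario: HD animals keep full
    genotypes, test animals keep only the low-density panel SNP, and all
    other animals are ungenotyped."""
    rng = np.random.default_rng(cfg.seed + 1)
    ped = truth.ped
    hd_idx = select_hd(truth, cfg, rng)
    test_idx = test_cohort(ped, cfg)
    values = np.full((ped.n, cfg.n_snp), MISSING_GENO, dtype=np.int8)
    values[hd_idx] = truth.genotypes[hd_idx]
    values[test_idx] = truth.genotypes[test_idx]
    geno = GenotypeMatrix(
        values=values,
        snp_ids=[f"snp{j}" for j in range(cfg.n_snp)],
        genotyped=np.zeros(ped.n, dtype=bool),
        mapped=np.ones(cfg.n_snp, dtype=bool),
        positions=np.arange(cfg.n_snp, dtype=float),
    )
    geno.genotyped[hd_idx] = True
    geno.genotyped[test_idx] = True
    panel = gio.design_low_density_panel(geno, cfg.mask_fraction, hd_idx)
    gio.apply_panel(geno, panel, test_idx)
    return Scenario(geno=geno, hd_idx=hd_idx, test_idx=test_idx, panel=panel, truth=truth)


def simulate(cfg: SimConfig) -> Scenario:
    """Full simulation: pedigree -> founder haplotypes -> gene drop ->
    masking scenario, all reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    ped, sex = simulate_pedigree(cfg, rng)
    n_base = int(np.sum((ped.sire < 0) & (ped.dam < 0)))
    haps, freq = simulate_founder_haplotypes(cfg, 2 * n_base, rng)
    truth = gene_drop(ped, haps, cfg, rng, sex=sex, allele_freq=freq)
    return apply_scenario(truth, cfg)


def write_files(scenario: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Emit the pedigree/genotype/map files consumed by the CLI plus a
    truth file for evaluation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped = scenario.truth.ped
    paths = {
        "pedigree": out / "pedigree.txt",
        "genotypes": out / "genotypes.txt",
        "map": out / "snp_map.txt",
        "truth": out / "true_genotypes.txt",
    }
    with open(paths["pedigree"], "w") as fh:
        for i, ind in enumerate(ped.ids):
            s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else "0"
            d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else "0"
            fh.write(f"{ind} {s} {d}\n")
    g = scenario.geno
    with open(paths["genotypes"], "w") as fh:
        for i in np.nonzero(g.genotyped)[0]:
            row = np.where(g.values[i] == MISSING_GENO, 9, g.values[i])
            fh.write(ped.ids[i] + " " + " ".join(map(str, row)) + "\n")
    with open(paths["map"], "w") as fh:
        for j, sid in enumerate(g.snp_ids):
            fh.write(f"{sid} 1 {int(g.positions[j])}\n")
    with open(paths["truth"], "w") as fh:
        tg = scenario.truth.genotypes
        for i, ind in enumerate(ped.ids):
            fh.write(ind + " " + " ".join(map(str, tg[i])) + "\n")
    return paths
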