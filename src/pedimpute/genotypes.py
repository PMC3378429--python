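"""Genotype/phase containers, file I/O, SNP editing and panel design.

Genotypes are biallelic, coded 0/1/2 with 3 for missing; phased alleles
are coded 0/1 with -1 for unresolved in memory and 9 on disk.  The
genotype matrix is aligned to the pedigree: one row per pedigree
individual (topological index order), ungenotyped individuals all-missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pedigree import Pedigree

MISSING_GENO = 3
MISSING_ALLELE = -1
DISK_MISSING_ALLELE = 9


@dataclass
class GenotypeMatrix:
    """Individuals x SNP genotype codes in {0, 1, 2, 3}; 3 = missing.

    ``genotyped`` marks individuals that appeared in the genotype file
    (an all-missing row still counts as genotyped); ``mapped`` marks SNP
    with a known map position.
    """

    values: np.ndarray  # (n_ind, n_snp) int8
    snp_ids: list[str]
    genotyped: np.ndarray  # (n_ind,) bool
    mapped: np.ndarray  # (n_snp,) bool
    positions: np.ndarray | None = None  # (n_snp,) float, map order

    @property
    def n_ind(self) -> int:
        return self.values.shape[0]

    @property
    def n_snp(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(),
            list(self.snp_ids),
            self.genotyped.copy(),
            self.mapped.copy(),
            None if self.positions is None else self.positions.copy(),
        )

    def call_rate(self) -> np.ndarray:
        """Per-individual fraction of non-missing SNP."""
        return (self.values != MISSING_GENO).mean(axis=1)


@dataclass
class PanelDesign:
    """A low-density panel: the mapped SNP retained after masking."""

    retained_snp: np.ndarray  # sorted SNP indices
    masked_fraction: float


def load_genotypes(
    path: str | Path,
    ped: Pedigree,
    missing_code: int = DISK_MISSING_ALLELE,
    strict: bool = False,
    on_unknown_id: str = "warn",
) -> GenotypeMatrix:
    """Read a whitespace-delimited genotype file: id then one code per SNP.

    Codes outside {0, 1, 2} become missing (3); with ``strict`` any code
    other than {0, 1, 2, missing_code} raises.  Rows whose id is not in
    the pedigree raise or warn-and-skip per ``on_unknown_id``
    ("error" | "warn").
    """
    raw_ids: list[str] = []
    rows: list[np.ndarray] = []
    width = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            codes = np.array(parts[1:], dtype=np.int64)
            if width is None:
                width = codes.size
            elif codes.size != width:
                raise ValueError(f"{path}: ragged genotype row at line {ln}")
            raw_ids.append(parts[0])
            rows.append(codes)
    if width is None:
        raise ValueError(f"{path}: empty genotype file")
    raw = np.vstack(rows)
    bad = ~np.isin(raw, (0, 1, 2, missing_code))
    if strict and bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid genotype code {raw[i, j]} for {raw_ids[i]} at SNP {j}"
        )
    raw[bad | (raw == missing_code)] = MISSING_GENO

    n_snp = width
    values = np.full((ped.n, n_snp), MISSING_GENO, dtype=np.int8)
    genotyped = np.zeros(ped.n, dtype=bool)
    for ind, row in zip(raw_ids, raw):
        if ind not in ped.index:
            if on_unknown_id == "error":
                raise KeyError(f"{path}: genotyped id {ind!r} not in pedigree")
            warnings.warn(f"genotyped id {ind!r} not in pedigree; row skipped")
            continue
        i = ped.index[ind]
        values[i] = row.astype(np.int8)
        genotyped[i] = True
    return GenotypeMatrix(
        values=values,
        snp_ids=[f"snp{j}" for j in range(n_snp)],
        genotyped=genotyped,
        mapped=np.ones(n_snp, dtype=bool),
    )


def load_snp_map(path: str | Path, geno: GenotypeMatrix) -> None:
    """Attach a map (snp_id, chromosome, position) to ``geno`` in place.

    SNP with chromosome "0" are flagged unmapped and excluded from the
    haplotype-based steps; file order must match genotype column order.
    """
    ids, chroms, pos = [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0])
            chroms.append(parts[1])
            pos.append(float(parts[2]))
    if len(ids) != geno.n_snp:
        raise ValueError(
            f"map has {len(ids)} SNP but genotype file has {geno.n_snp}"
        )
    geno.snp_ids = ids
    geno.mapped = np.array([c != "0" for c in chroms])
    geno.positions = np.array(pos)


def split_density(
    geno: GenotypeMatrix, ped: Pedigree, hd_threshold: float = 0.9
) -> tuple[set[str], set[str]]:
    """Split genotyped individuals into high-density and low-density sets
    by their fraction of non-missing SNP (>= threshold -> HD)."""
    if not 0 < hd_threshold <= 1:
        raise ValueError("hd_threshold must be in (0, 1]")
    rate = geno.call_rate()
    hd = geno.genotyped & (rate >= hd_threshold)
    ld = geno.genotyped & ~hd
    return (
        {ped.ids[i] for i in np.nonzero(hd)[0]},
        {ped.ids[i] for i in np.nonzero(ld)[0]},
    )


def check_mendelian(
    ped: Pedigree, geno: GenotypeMatrix
) -> tuple[list[tuple[str, str, int]], GenotypeMatrix]:
    """Find opposing-homozygote conflicts between parents and offspring.

    A conflict is parent hom 0 with offspring hom 2 (or vice versa) at the
    same SNP.  Returns the conflict list (individual, parent, snp) and a
    cleaned copy in which both members of each conflict are set missing.
    """
    g = geno.values
    conflicts: list[tuple[str, str, int]] = []
    clean = geno.copy()
    for c in range(ped.n):
        for p in (ped.sire[c], ped.dam[c]):
            if p < 0:
                continue
            bad = ((g[c] == 0) & (g[p] == 2)) | ((g[c] == 2) & (g[p] == 0))
            for j in np.nonzero(bad)[0]:
                conflicts.append((ped.ids[c], ped.ids[p], int(j)))
                clean.values[c, j] = MISSING_GENO
                clean.values[p, j] = MISSING_GENO
    return conflicts, clean


def allele_frequencies(
    geno: GenotypeMatrix, individuals: np.ndarray | None = None
) -> np.ndarray:
    """Frequency of allele 1 per SNP from non-missing genotypes.

    ``individuals`` restricts the estimate (typically to the HD set).
    SNP with no data get 0.5; estimates are clipped away from 0 and 1.
    """
    g = geno.values if individuals is None else geno.values[individuals]
    obs = g != MISSING_GENO
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, (g * obs).sum(axis=0) / np.maximum(2 * n, 1), 0.5)
    return np.clip(p, 1e-4, 1 - 1e-4)


def edit_snp(
    geno: GenotypeMatrix,
    maf_min: float = 0.01,
    max_missing_rate: float = 0.1,
) -> np.ndarray:
    """Routine SNP editing: boolean mask of SNP passing a minimum MAF and a
    maximum missing rate (computed over genotyped individuals)."""
    g = geno.values[geno.genotyped]
    if g.shape[0] == 0:
        return np.ones(geno.n_snp, dtype=bool)
    p = allele_frequencies(geno, geno.genotyped)
    maf = np.minimum(p, 1 - p)
    missing_rate = (g == MISSING_GENO).mean(axis=0)
    return (maf >= maf_min) & (missing_rate <= max_missing_rate)


def design_low_density_panel(
    geno: GenotypeMatrix,
    masked_fraction: float,
    hd_individuals: np.ndarray | None = None,
    window: int = 5,
) -> PanelDesign:
    """Choose the SNP retained on a low-density panel.

    The mapped SNP are tiled into contiguous ``window``-SNP windows (a
    short final window is allowed).  Enough evenly spaced windows are
    selected to reach ``round((1 - masked_fraction) * n_mapped)`` retained
    SNP, and from each selected window the SNP with the highest minor
    allele frequency is taken (ties to the lower index).  If the target
    exceeds the window count, further rounds take each window's
    next-best-MAF SNP.  MAF is computed from HD individuals when given.
    """
    if not 0 <= masked_fraction < 1:
        raise ValueError("masked_fraction must be in [0, 1)")
    mapped_idx = np.nonzero(geno.mapped)[0]
    n_mapped = mapped_idx.size
    if masked_fraction == 0:
        return PanelDesign(retained_snp=mapped_idx, masked_fraction=0.0)
    target = int(round((1 - masked_fraction) * n_mapped))
    if target < 1:
        raise ValueError(
            f"masked_fraction {masked_fraction} leaves no retained SNP"
        )
    p = allele_frequencies(geno, hd_individuals)
    maf = np.minimum(p, 1 - p)

    windows = [
        mapped_idx[k : k + window] for k in range(0, n_mapped, window)
    ]
    n_win = len(windows)
    # rank SNP within each window by (-maf, index)
    ranked = [w[np.lexsort((w, -maf[w]))] for w in windows]
    retained: list[int] = []
    depth = 0
    while len(retained) < target:
        remaining = target - len(retained)
        eligible = [r for r in ranked if len(r) > depth]
        if not eligible:
            break
        if remaining >= len(eligible):
            chosen = range(len(eligible))
        else:
            # evenly spaced window selection
            chosen = np.round(
                np.linspace(0, len(eligible) - 1, remaining)
            ).astype(int)
        for w in chosen:
            retained.append(int(eligible[w][depth]))
        depth += 1
    retained_arr = np.array(sorted(set(retained)), dtype=np.int64)
    return PanelDesign(retained_snp=retained_arr, masked_fraction=masked_fraction)


def apply_panel(geno: GenotypeMatrix, panel: PanelDesign, individuals: np.ndarray) -> None:
    """Mask, in place, all SNP outside the panel for the given individuals."""
    drop = np.ones(geno.n_snp, dtype=bool)
    drop[panel.retained_snp] = False
    geno.values[np.ix_(individuals, np.nonzero(drop)[0])] = MISSING_GENO


# ---------------------------------------------------------------------------
# output files

def write_outputs(
    phase: np.ndarray,
    probs: np.ndarray,
    out_dir: str | Path,
    ids: list[str],
) -> dict[str, Path]:
    """Write the three result files.

    * ``phased_alleles.txt`` — two rows per individual (paternal then
      maternal); 0/1 calls, 9 where unresolved.
    * ``allele_probs.txt`` — same layout, P(allele = 1) to 4 decimals.
    * ``dosages.txt`` — one row per individual, expected allele-1 count
      in [0, 2].
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phase": out_dir / "phased_alleles.txt",
        "probs": out_dir / "allele_probs.txt",
        "dosage": out_dir / "dosages.txt",
    }
    disk_phase = np.where(phase == MISSING_ALLELE, DISK_MISSING_ALLELE, phase)
    with open(paths["phase"], "w") as fh:
        for i, ind in enumerate(ids):
            for gam in (0, 1):
                fh.write(ind + " " + " ".join(map(str, disk_phase[i, :, gam])) + "\n")
    with open(paths["probs"], "w") as fh:
        for i, ind in enumerate(ids):
            for gam in (0, 1):
                fh.write(
                    ind + " " + " ".join(f"{v:.4f}" for v in probs[i, :, gam]) + "\n"
                )
    dosage = probs.sum(axis=2)
    with open(paths["dosage"], "w") as fh:
        for i, ind in enumerate(ids):
            fh.write(ind + " " + " ".join(f"{v:.4f}" for v in dosage[i]) + "\n")
    return paths


def read_phase(path: str | Path, ped: Pedigree, n_snp: int) -> np.ndarray:
    """Read a phased-allele file (two rows per individual) back into an
    (n_ind, n_snp, 2) int8 array with -1 for unresolved.  Inverse of the
    phase file written by :func:`write_outputs`."""
    phase = np.full((ped.n, n_snp, 2), MISSING_ALLELE, dtype=np.int8)
    slot: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ind = parts[0]
            row = np.array(parts[1:], dtype=np.int8)
            if row.size != n_snp:
                raise ValueError(f"{path}: row for {ind} has {row.size} SNP")
            gam = slot.get(ind, 0)
            if gam > 1:
                raise ValueError(f"{path}: more than two rows for {ind}")
            row[row == DISK_MISSING_ALLELE] = MISSING_ALLELE
            phase[ped.index[ind], :, gam] = row
            slot[ind] = gam + 1
    return phase
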