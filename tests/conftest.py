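"""Shared fixtures: small deterministic pedigrees and simulations."""

from __future__ import annotations

import numpy as np
import pytest

from pedimpute import genotypes as gio
from pedimpute.pedigree import Pedigree, from_records
from pedimpute.simulate import SimConfig, Scenario, simulate


@pytest.fixture
def trio_ped() -> Pedigree:
    return from_records([("A", "0", "0"), ("B", "0", "0"), ("C", "A", "B")])


@pytest.fixture
def three_gen_ped() -> Pedigree:
    # founders A,B,E,F; middle C(AxB), D(ExF); grandchild G(CxD)
    return from_records(
        [
            ("A", "0", "0"),
            ("B", "0", "0"),
            ("E", "0", "0"),
            ("F", "0", "0"),
            ("C", "A", "B"),
            ("D", "E", "F"),
            ("G", "C", "D"),
        ]
    )


def make_geno(ped: Pedigree, rows: dict[str, list[int]], n_snp: int) -> gio.GenotypeMatrix:
    """GenotypeMatrix aligned to a pedigree from per-id genotype lists."""
    values = np.full((ped.n, n_snp), gio.MISSING_GENO, dtype=np.int8)
    genotyped = np.zeros(ped.n, dtype=bool)
    for ind, row in rows.items():
        values[ped.index[ind]] = row
        genotyped[ped.index[ind]] = True
    return gio.GenotypeMatrix(
        values=values,
        snp_ids=[f"s{j}" for j in range(n_snp)],
        genotyped=genotyped,
        mapped=np.ones(n_snp, dtype=bool),
        positions=np.arange(n_snp, dtype=float),
    )


@pytest.fixture(scope="session")
def small_scenario() -> Scenario:
    """A desk-sized simulation used by several module tests."""
    cfg = SimConfig(
        seed=7,
        n_founders=24,
        n_generations=4,
        offspring_per_generation=60,
        n_snp=240,
        n_test=40,
        mask_fraction=0.85,
    )
    return simulate(cfg)


def random_tree_pedigree(rng: np.random.Generator, n_max: int = 8):
    """A random loop-free pedigree (each mating used once, each parent
    consumed), as (records, n)."""
    n = int(rng.integers(2, n_max + 1))
    records, avail = [], []
    for i in range(n):
        s = d = "0"
        if len(avail) >= 2 and rng.random() < 0.7:
            pair = rng.choice(len(avail), size=2, replace=False)
            s, d = avail[pair[0]], avail[pair[1]]
            for x in sorted(map(int, pair), reverse=True):
                avail.pop(x)
        records.append((str(i), s, d))
        avail.append(str(i))
    return records
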