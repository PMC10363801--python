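"""Variance of the SNP-by-SNP inbreeding coefficient under contrasting
genome architectures.

Because realized inbreeding is produced by Mendelian sampling of large
linked genome blocks, its dispersion among individuals of identical pedigree
depends strongly on genetic map length: a short genome (few Morgans) yields
few independently segregating segments and therefore a wide spread of
realized F around the pedigree expectation, while a long genome averages
over many segments. This module quantifies that effect by simulating a
neutral random-mating base population on a configurable architecture,
forming replicate full-sib families (one offspring of a full-sib mating per
family, pedigree F = 0.25) and an equal number of unrelated non-inbred
individuals (offspring of independent unrelated base pairs, pedigree F = 0),
then reporting the standard deviation of the correlation-of-uniting-gametes
F within each group, computed against the group's own sample allele
frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Chromosome, GenomeConfig, MutationModel
from .markers import f_yan
from .simulate import Population, _gamete, simulate_base_population

__all__ = [
    "ArchitectureSpec",
    "VarianceReport",
    "drosophila_like",
    "mammal_like",
    "run_variance_study",
    "simulate_f_distributions",
]

_NEUTRAL = MutationModel(u=0.0, lethal_rate=0.0)


@dataclass(frozen=True)
class ArchitectureSpec:
    """One genome architecture to study.

    ``marker_count`` is the number of segregating neutral SNPs to analyse;
    the base population is seeded with an excess of linkage-equilibrium SNPs
    so that at least this many survive the burn-in drift (short-fall falls
    back to all segregating sites with a warning). Both sexes recombine:
    map lengths are taken as sex-averaged.
    """

    label: str
    genome: GenomeConfig
    base_n: int = 1000
    burn_in: int = 100
    marker_count: int = 10_000
    n_families: int = 500
    init_excess: float = 2.0

    def __post_init__(self) -> None:
        if self.n_families < 50:
            raise ValueError("need >= 50 replicate families to report an SD")
        if self.marker_count < 1000:
            raise ValueError("need >= 1000 markers")
        if not self.genome.male_recombination:
            raise ValueError(
                "architecture maps are sex-averaged: both sexes must recombine"
            )


def drosophila_like(**overrides) -> ArchitectureSpec:
    """Two autosomes of 0.5 Morgan each (short-genome scenario)."""
    genome = GenomeConfig(
        chromosomes=(Chromosome(50_000_000, 0.5), Chromosome(50_000_000, 0.5)),
        male_recombination=True,
    )
    return ArchitectureSpec(label="drosophila_like", genome=genome, **overrides)


def mammal_like(**overrides) -> ArchitectureSpec:
    """Twenty chromosomes of one Morgan each (long-genome scenario)."""
    genome = GenomeConfig(
        chromosomes=tuple(Chromosome(100_000_000, 1.0) for _ in range(20)),
        male_recombination=True,
    )
    return ArchitectureSpec(label="mammal_like", genome=genome, **overrides)


@dataclass(frozen=True)
class VarianceReport:
    """Per-architecture F_YAN distribution summaries as a tidy table with
    columns architecture, group, mean_f, sd_f, n, n_markers."""

    table: pd.DataFrame

    def sd(self, label: str, group: str) -> float:
        t = self.table
        row = t[(t.architecture == label) & (t.group == group)]
        return float(row.sd_f.iloc[0])

    def mean(self, label: str, group: str) -> float:
        t = self.table
        row = t[(t.architecture == label) & (t.group == group)]
        return float(row.mean_f.iloc[0])


def _offspring_dosage(
    pop: Population,
    pedigree_fn,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dosage vector of one individual produced by ``pedigree_fn``."""
    egg, sperm = pedigree_fn(rng)
    return egg.astype(np.int16) + sperm.astype(np.int16)


def simulate_f_distributions(
    spec: ArchitectureSpec, seed=None
) -> tuple[np.ndarray, np.ndarray, int]:
    """F_YAN values for full-sib offspring and for unrelated non-inbred
    individuals under one architecture.

    Returns ``(f_fullsib, f_unrelated, n_markers_used)``; each F vector is
    computed against its own group's sample frequencies.
    """
    rng = np.random.default_rng(seed)
    base = simulate_base_population(
        spec.genome,
        _NEUTRAL,
        n=spec.base_n,
        generations=spec.burn_in,
        seed=rng.integers(2**31),
        n_marker_loci=int(spec.marker_count * spec.init_excess),
    )
    n_seg = base.n_loci
    if n_seg < spec.marker_count:
        warnings.warn(
            f"only {n_seg} SNPs segregate after burn-in "
            f"(requested {spec.marker_count}); using all of them"
        )
        keep = np.arange(n_seg)
    else:
        keep = np.sort(rng.choice(n_seg, size=spec.marker_count, replace=False))
    base._take_loci(keep)

    slices = base.chrom_slices()
    maps = np.asarray([c.map_length_morgans for c in base.genome.chromosomes])
    H = base.haplotypes
    pos_m = base.loci_pos_m
    males = np.flatnonzero(base.sex)
    females = np.flatnonzero(~base.sex)

    def gamete(parent_haps, r):
        return _gamete(parent_haps[0], parent_haps[1], pos_m, slices, maps, True, r)

    def hap_pair(idx):
        return H[2 * idx], H[2 * idx + 1]

    fs_rows = np.empty((spec.n_families, base.n_loci), dtype=np.int16)
    un_rows = np.empty((spec.n_families, base.n_loci), dtype=np.int16)
    for fam in range(spec.n_families):
        dad = males[rng.integers(males.size)]
        mom = females[rng.integers(females.size)]
        # two full sibs, then one offspring of their mating (F_PED = 0.25)
        sib1 = (gamete(hap_pair(mom), rng), gamete(hap_pair(dad), rng))
        sib2 = (gamete(hap_pair(mom), rng), gamete(hap_pair(dad), rng))
        child = (gamete(sib1, rng), gamete(sib2, rng))
        fs_rows[fam] = child[0].astype(np.int16) + child[1].astype(np.int16)
        # one unrelated non-inbred individual from an independent pair
        dad_u = males[rng.integers(males.size)]
        mom_u = females[rng.integers(females.size)]
        un_rows[fam] = (
            gamete(hap_pair(mom_u), rng).astype(np.int16)
            + gamete(hap_pair(dad_u), rng).astype(np.int16)
        )
    f_fs = f_yan(fs_rows.astype(float))
    f_un = f_yan(un_rows.astype(float))
    return f_fs, f_un, base.n_loci


def run_variance_study(specs: list[ArchitectureSpec], seed=None) -> VarianceReport:
    """Run the study for every architecture and tabulate means and SDs."""
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        f_fs, f_un, n_markers = simulate_f_distributions(
            spec, seed=rng.integers(2**31)
        )
        for group, values in (("fullsib_offspring", f_fs), ("unrelated", f_un)):
            rows.append(
                {
                    "architecture": spec.label,
                    "group": group,
                    "mean_f": float(np.mean(values)),
                    "sd_f": float(np.std(values, ddof=1)),
                    "n": int(values.size),
                    "n_markers": n_markers,
                }
            )
    return VarianceReport(pd.DataFrame(rows))
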