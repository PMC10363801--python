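"""Forward-in-time simulator of the full-sib breeding-design experiment.

The simulated life cycle is: adults mate at random (uniformly), zygotes
undergo multiplicative viability selection — heterozygote factor (1 - h s),
homozygote factor (1 - s) across deleterious loci — and the survivors form
the next generation of N adults (N/2 of each sex). New deleterious mutations
arise at a haploid genomic rate U per gamete; neutral marker loci can be
seeded at initialisation with frequencies drawn from a neutral 1/x site
frequency spectrum in linkage equilibrium, after which burn-in generations
of random mating build up map-dependent linkage disequilibrium.

Crossovers follow a Poisson process per chromosome on the genetic map
(Haldane model, no interference); when the genome disables male
recombination, male meiosis transmits whole chromosomes with independent
assortment, as in *Drosophila melanogaster*.

Two breeding schemes are derived from the base population, mirroring the
experimental design:

* non-inbred scheme — circular mating among founder families for two
  generations, so the generation-2 breeding pairs are non-inbred (F_PED = 0)
  and mutually unrelated;
* inbred scheme — full-sib mating for two generations, so the generation-2
  pair members have F_PED = 0.25 and are full sibs whose coancestry is 0.375.

Phenotypes: pupae productivity P of a breeding pair is a Poisson count around
kappa times the geometric mean of the two parents' viabilities (times a
lognormal environmental factor), so the expected log P declines linearly in
pedigree F with slope equal to the inbreeding load implied by the mutation
model. Competitive fitness W pools four pairs: W = wild / (curly + 1), with
the wild count driven by the mean viability of the eight parents and curly
counts drawn independently (the competitor stock carries no focal genetics).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeConfig, MutationModel
from .markers import MarkerPanel

__all__ = [
    "Population",
    "PhenotypeRecord",
    "TraitParams",
    "simulate_base_population",
    "breed_schemes",
    "assign_phenotypes",
    "export_cohort",
    "inbreeding_load",
]


# ---------------------------------------------------------------------------
# population container


@dataclass
class Population:
    """Diploid individuals with dense haplotypes over current segregating loci.

    Individual ``i`` owns haplotype rows ``2 i`` and ``2 i + 1``. Loci are
    sorted by (chromosome, position); ``loci_s == 0`` marks neutral markers.
    """

    genome: GenomeConfig
    loci_chrom: np.ndarray  # (L,) int chromosome index
    loci_pos_bp: np.ndarray  # (L,) int64
    loci_pos_m: np.ndarray  # (L,) float genetic position, Morgans
    loci_s: np.ndarray  # (L,) float selection coefficient
    loci_h: np.ndarray  # (L,) float dominance
    haplotypes: np.ndarray  # (2 N, L) uint8
    sex: np.ndarray  # (N,) bool, True = male
    ids: list = field(default_factory=list)
    pedigree: list = field(default_factory=list)  # (id, sire, dam) records

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            self.ids = [f"base_{i}" for i in range(self.n_individuals)]
        if len(self.pedigree) == 0:
            self.pedigree = [(iid, None, None) for iid in self.ids]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def dosages(self, indices=None) -> np.ndarray:
        """Alt-allele dosage matrix (individuals x loci)."""
        H = self.haplotypes
        d = H[0::2].astype(np.int16) + H[1::2].astype(np.int16)
        return d if indices is None else d[np.asarray(indices)]

    def log_viability(self) -> np.ndarray:
        """Per-individual natural-log viability over deleterious loci
        (multiplicative fitness); -inf for lethal homozygotes."""
        sel = self.loci_s > 0
        if not np.any(sel):
            return np.zeros(self.n_individuals)
        d = self.dosages()[:, sel].astype(np.int8)
        s = self.loci_s[sel]
        h = self.loci_h[sel]
        log_het = np.log1p(-h * s)
        # lethal homozygotes (s = 1) get -inf without propagating 0 * inf
        lethal = s >= 1.0
        log_hom = np.where(lethal, 0.0, np.log1p(-np.where(lethal, 0.0, s)))
        out = (d == 1) @ log_het + (d == 2) @ log_hom
        if lethal.any():
            out[np.any((d == 2) & lethal, axis=1)] = -np.inf
        return out

    def viability(self) -> np.ndarray:
        return np.exp(self.log_viability())

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def marker_mask(self) -> np.ndarray:
        return self.loci_s == 0.0

    def chrom_slices(self) -> list[tuple[int, int]]:
        out = []
        for c in range(self.genome.n_chromosomes):
            idx = np.flatnonzero(self.loci_chrom == c)
            out.append((int(idx[0]), int(idx[-1]) + 1) if idx.size else (0, 0))
        return out

    def drop_monomorphic(self) -> None:
        freq = self.allele_frequencies()
        keep = (freq > 0.0) & (freq < 1.0)
        self._take_loci(keep)

    def _take_loci(self, mask_or_index) -> None:
        self.loci_chrom = self.loci_chrom[mask_or_index]
        self.loci_pos_bp = self.loci_pos_bp[mask_or_index]
        self.loci_pos_m = self.loci_pos_m[mask_or_index]
        self.loci_s = self.loci_s[mask_or_index]
        self.loci_h = self.loci_h[mask_or_index]
        self.haplotypes = self.haplotypes[:, mask_or_index]

    def panel(self, indices=None) -> MarkerPanel:
        """Marker-panel skeleton (frequencies of the counted alt allele; the
        group-specific minor-allele recode happens downstream)."""
        idx = np.arange(self.n_loci) if indices is None else np.asarray(indices)
        freq = self.haplotypes[:, idx].mean(axis=0)
        labels = np.asarray([f"chr{c + 2}" for c in self.loci_chrom[idx]], dtype=object)
        p = np.minimum(np.clip(freq, 1e-9, None), 1.0 - np.clip(freq, None, 1.0 - 1e-9))
        return MarkerPanel(labels, self.loci_pos_bp[idx], np.clip(p, 1e-9, 0.5))


# ---------------------------------------------------------------------------
# meiosis


def _gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    pos_m: np.ndarray,
    chrom_slices: list[tuple[int, int]],
    map_lengths: np.ndarray,
    recombine: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a parent's two haplotypes."""
    out = np.empty_like(hap_a)
    for c, (a, b) in enumerate(chrom_slices):
        if a == b:
            continue
        k = rng.poisson(map_lengths[c]) if recombine else 0
        start = rng.integers(2)
        if k == 0:
            out[a:b] = hap_a[a:b] if start == 0 else hap_b[a:b]
        else:
            points = np.sort(rng.uniform(0.0, map_lengths[c], size=k))
            src = (start + np.searchsorted(points, pos_m[a:b])) % 2
            out[a:b] = np.where(src == 0, hap_a[a:b], hap_b[a:b])
    return out


def make_offspring(
    pop: Population,
    mother_idx: int,
    father_idx: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype pair (maternal gamete, paternal gamete) for one zygote."""
    sl = pop.chrom_slices()
    maps = np.asarray([c.map_length_morgans for c in pop.genome.chromosomes])
    H = pop.haplotypes
    egg = _gamete(
        H[2 * mother_idx], H[2 * mother_idx + 1], pop.loci_pos_m, sl, maps, True, rng
    )
    sperm = _gamete(
        H[2 * father_idx],
        H[2 * father_idx + 1],
        pop.loci_pos_m,
        sl,
        maps,
        pop.genome.male_recombination,
        rng,
    )
    return egg, sperm


# ---------------------------------------------------------------------------
# base population


def _init_marker_loci(
    genome: GenomeConfig, n_markers: int, n_haplotypes: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neutral markers in linkage equilibrium with 1/x SFS frequencies."""
    lengths = np.asarray([c.physical_length_bp for c in genome.chromosomes], dtype=float)
    chrom = rng.choice(genome.n_chromosomes, size=n_markers, p=lengths / lengths.sum())
    pos = np.empty(n_markers, dtype=np.int64)
    for c in range(genome.n_chromosomes):
        m = chrom == c
        pos[m] = _sample_unique_positions(int(lengths[c]), int(m.sum()), rng)
    qmin = 1.0 / n_haplotypes
    qmax = 1.0 - qmin
    q = qmin * (qmax / qmin) ** rng.random(n_markers)  # density proportional to 1/q
    alleles = (rng.random((n_haplotypes, n_markers)) < q).astype(np.uint8)
    return chrom, pos, alleles


def _sample_unique_positions(
    length: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k distinct 1-based positions on [1, length] (collision re-draw)."""
    if k > length:
        raise ValueError("more loci requested than positions available")
    pos = np.unique(rng.integers(1, length + 1, size=k))
    while pos.size < k:
        extra = rng.integers(1, length + 1, size=k - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return rng.permutation(pos)[:k] if pos.size > k else pos


def _sort_loci(pop: Population) -> None:
    order = np.lexsort((pop.loci_pos_bp, pop.loci_chrom))
    pop._take_loci(order)


def simulate_base_population(
    genome: GenomeConfig,
    mutation: MutationModel,
    n: int = 100,
    generations: int = 100,
    seed=None,
    n_marker_loci: int = 0,
) -> Population:
    """Evolve a random-mating population of ``n`` diploids for ``generations``
    generations under mutation, multiplicative viability selection and drift.

    ``n_marker_loci`` neutral SNPs (1/x frequency spectrum, linkage
    equilibrium) are seeded before the burn-in; loci fixed or lost along the
    way are dropped.
    """
    if n <= 0 or n % 2:
        raise ValueError("census size must be a positive even number")
    if generations < 0:
        raise ValueError("generations must be non-negative")
    rng = np.random.default_rng(seed)
    if n_marker_loci > 0:
        chrom, pos, haps = _init_marker_loci(genome, n_marker_loci, 2 * n, rng)
    else:
        chrom = np.empty(0, dtype=np.int64)
        pos = np.empty(0, dtype=np.int64)
        haps = np.zeros((2 * n, 0), dtype=np.uint8)
    lengths = np.asarray([c.physical_length_bp for c in genome.chromosomes], dtype=float)
    maps = np.asarray([c.map_length_morgans for c in genome.chromosomes])
    pos_m = maps[chrom] * (pos / lengths[chrom]) if pos.size else np.empty(0)
    sex = np.zeros(n, dtype=bool)
    sex[: n // 2] = True
    pop = Population(
        genome=genome,
        loci_chrom=chrom,
        loci_pos_bp=pos,
        loci_pos_m=pos_m,
        loci_s=np.zeros(pos.size),
        loci_h=np.zeros(pos.size),
        haplotypes=haps,
        sex=sex,
    )
    _sort_loci(pop)
    for _ in range(generations):
        _advance_generation(pop, mutation, rng)
    pop.drop_monomorphic()
    return pop


def _advance_generation(
    pop: Population, mutation: MutationModel, rng: np.random.Generator
) -> None:
    n = pop.n_individuals
    males = np.flatnonzero(pop.sex)
    females = np.flatnonzero(~pop.sex)
    sl = pop.chrom_slices()
    maps = np.asarray([c.map_length_morgans for c in pop.genome.chromosomes])
    H = pop.haplotypes
    selected = np.any(pop.loci_s > 0)
    if selected:
        log_w = pop.log_viability()
    new = np.empty_like(H)
    made = 0
    while made < n:
        mom = females[rng.integers(females.size)]
        dad = males[rng.integers(males.size)]
        egg = _gamete(H[2 * mom], H[2 * mom + 1], pop.loci_pos_m, sl, maps, True, rng)
        sperm = _gamete(
            H[2 * dad],
            H[2 * dad + 1],
            pop.loci_pos_m,
            sl,
            maps,
            pop.genome.male_recombination,
            rng,
        )
        if selected:
            w = _zygote_viability(egg, sperm, pop.loci_s, pop.loci_h)
            if rng.random() >= w:
                continue
        new[2 * made] = egg
        new[2 * made + 1] = sperm
        made += 1
    pop.haplotypes = new
    _mutate(pop, mutation, rng)
    pop.drop_monomorphic()


def _zygote_viability(
    egg: np.ndarray, sperm: np.ndarray, s: np.ndarray, h: np.ndarray
) -> float:
    sel = s > 0
    if not np.any(sel):
        return 1.0
    d = egg[sel].astype(np.int8) + sperm[sel].astype(np.int8)
    het = d == 1
    hom = d == 2
    if not (het.any() or hom.any()):
        return 1.0
    w = float(np.prod(1.0 - h[sel][het] * s[sel][het]) * np.prod(1.0 - s[sel][hom]))
    return max(w, 0.0)


def _mutate(pop: Population, mutation: MutationModel, rng: np.random.Generator) -> None:
    if mutation.total_rate <= 0:
        return
    n_hap = pop.haplotypes.shape[0]
    n_new = rng.poisson(n_hap * mutation.total_rate)
    if n_new == 0:
        return
    lengths = np.asarray(
        [c.physical_length_bp for c in pop.genome.chromosomes], dtype=float
    )
    maps = np.asarray([c.map_length_morgans for c in pop.genome.chromosomes])
    chrom = rng.choice(pop.genome.n_chromosomes, size=n_new, p=lengths / lengths.sum())
    pos = (rng.random(n_new) * lengths[chrom]).astype(np.int64) + 1
    # avoid position collisions with existing loci on the same chromosome
    for _ in range(10):
        clash = np.zeros(n_new, dtype=bool)
        for c in np.unique(chrom):
            m = chrom == c
            clash[m] = np.isin(pos[m], pop.loci_pos_bp[pop.loci_chrom == c])
        if not clash.any():
            break
        pos[clash] = (rng.random(int(clash.sum())) * lengths[chrom[clash]]).astype(
            np.int64
        ) + 1
    s, h = mutation.draw_effects(n_new, rng)
    carriers = rng.integers(0, n_hap, size=n_new)
    cols = np.zeros((n_hap, n_new), dtype=np.uint8)
    cols[carriers, np.arange(n_new)] = 1
    pop.loci_chrom = np.concatenate([pop.loci_chrom, chrom])
    pop.loci_pos_bp = np.concatenate([pop.loci_pos_bp, pos])
    pop.loci_pos_m = np.concatenate([pop.loci_pos_m, maps[chrom] * pos / lengths[chrom]])
    pop.loci_s = np.concatenate([pop.loci_s, s])
    pop.loci_h = np.concatenate([pop.loci_h, h])
    pop.haplotypes = np.concatenate([pop.haplotypes, cols], axis=1)
    _sort_loci(pop)


def inbreeding_load(q: np.ndarray, s: np.ndarray, h: np.ndarray) -> float:
    """Closed-form inbreeding load B of a set of deleterious loci.

    With multiplicative fitness, the expected log viability of an individual
    with inbreeding coefficient F is linear in F with slope -B, where

        B = sum_k p_k q_k [2 log(1 - h_k s_k) - log(1 - s_k)]

    and q_k is the deleterious-allele frequency. Requires s < 1 (lethals have
    no finite log-scale load).
    """
    q = np.asarray(q, dtype=float)
    s = np.asarray(s, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(s >= 1.0):
        raise ValueError("closed-form log-scale load requires s < 1")
    p = 1.0 - q
    return float(np.sum(p * q * (2.0 * np.log1p(-h * s) - np.log1p(-s))))


# ---------------------------------------------------------------------------
# breeding schemes


@dataclass
class Cohort:
    """Generation-2 breeding pairs of one scheme, with full ancestry.

    ``population`` holds every individual created for the scheme (all
    generations); ``pair_indices`` lists (male_index, female_index) of the
    generation-2 breeding pairs within it.
    """

    scheme: str
    population: Population
    pair_indices: list[tuple[int, int]]
    pair_ids: list[str]


def _draw_founder_pairs(
    base: Population, n_families: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    males = np.flatnonzero(base.sex)
    females = np.flatnonzero(~base.sex)
    if n_families > min(males.size, females.size):
        raise ValueError("base population too small for the requested pairs")
    m = rng.choice(males, size=n_families, replace=False)
    f = rng.choice(females, size=n_families, replace=False)
    return list(zip(m.tolist(), f.tolist()))


class _SchemeBuilder:
    """Accumulates scheme individuals into one Population with pedigree."""

    def __init__(self, base: Population, scheme: str, rng: np.random.Generator):
        self.base = base
        self.scheme = scheme
        self.rng = rng
        self.haps: list[np.ndarray] = []
        self.sex: list[bool] = []
        self.ids: list[str] = []
        self.pedigree: list[tuple] = []
        self._founder_map: dict[int, int] = {}
        self._slices = base.chrom_slices()
        self._maps = np.asarray(
            [c.map_length_morgans for c in base.genome.chromosomes]
        )

    def add_founder(self, base_idx: int) -> int:
        if base_idx in self._founder_map:
            return self._founder_map[base_idx]
        idx = len(self.ids)
        self.haps.append(self.base.haplotypes[2 * base_idx])
        self.haps.append(self.base.haplotypes[2 * base_idx + 1])
        self.sex.append(bool(self.base.sex[base_idx]))
        iid = f"{self.scheme}_f{idx}"
        self.ids.append(iid)
        self.pedigree.append((iid, None, None))
        self._founder_map[base_idx] = idx
        return idx

    def add_child(self, mother: int, father: int, male: bool, tag: str) -> int:
        """Create one viable offspring of two scheme members (lethal
        homozygotes are re-drawn; no other viability selection is applied, so
        pedigree F maps exactly onto the built-in load)."""
        base = self.base
        for _ in range(200):
            egg = _gamete(
                self.haps[2 * mother],
                self.haps[2 * mother + 1],
                base.loci_pos_m,
                self._slices,
                self._maps,
                True,
                self.rng,
            )
            sperm = _gamete(
                self.haps[2 * father],
                self.haps[2 * father + 1],
                base.loci_pos_m,
                self._slices,
                self._maps,
                base.genome.male_recombination,
                self.rng,
            )
            if _zygote_viability(egg, sperm, base.loci_s, base.loci_h) > 0.0:
                break
        else:  # pragma: no cover - would need absurd lethal load
            raise RuntimeError("could not draw a viable offspring")
        idx = len(self.ids)
        self.haps.append(egg)
        self.haps.append(sperm)
        self.sex.append(male)
        iid = f"{self.scheme}_{tag}"
        self.ids.append(iid)
        self.pedigree.append((iid, self.ids[father], self.ids[mother]))
        return idx

    def _as_population(self) -> Population:
        return Population(
            genome=self.base.genome,
            loci_chrom=self.base.loci_chrom,
            loci_pos_bp=self.base.loci_pos_bp,
            loci_pos_m=self.base.loci_pos_m,
            loci_s=self.base.loci_s,
            loci_h=self.base.loci_h,
            haplotypes=np.asarray(self.haps),
            sex=np.asarray(self.sex, dtype=bool),
            ids=list(self.ids),
            pedigree=list(self.pedigree),
        )

    def build(self, pairs: list[tuple[int, int]], scheme: str) -> Cohort:
        pop = self._as_population()
        return Cohort(
            scheme=scheme,
            population=pop,
            pair_indices=pairs,
            pair_ids=[f"{scheme}_pair{i}" for i in range(len(pairs))],
        )


def breed_schemes(
    base: Population, n_pairs: int, seed=None
) -> tuple[Cohort, Cohort, pd.DataFrame]:
    """Derive the non-inbred and inbred cohorts and the joint pedigree table.

    Returns (non_inbred cohort, inbred cohort, pedigree DataFrame with
    columns id, sire, dam, sex; founders carry '0' parents).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    # Circular (non-inbred) scheme. Four founder families feed each
    # generation-2 pair (female from vial 4i, male from vial 4i+2, with vial
    # j pairing a daughter of family j with a son of family j+1), so every
    # generation-2 adult has unrelated parents and all pairwise kinships
    # among generation-2 adults are exactly zero.
    m = 4 * n_pairs
    founders = _draw_founder_pairs(base, m + n_pairs, rng)
    ni = _SchemeBuilder(base, "noninbred", rng)
    fam = [
        (ni.add_founder(dad), ni.add_founder(mom)) for dad, mom in founders[:m]
    ]
    t1_pairs: dict[int, tuple[int, int]] = {}
    for j in {4 * i for i in range(n_pairs)} | {4 * i + 2 for i in range(n_pairs)}:
        dad_j, mom_j = fam[j]
        dad_next, mom_next = fam[(j + 1) % m]
        daughter = ni.add_child(mom_j, dad_j, False, f"t1f_{j}")
        son = ni.add_child(mom_next, dad_next, True, f"t1m_{j}")
        t1_pairs[j] = (son, daughter)
    t2_pairs = []
    for i in range(n_pairs):
        son_f, daughter_f = t1_pairs[4 * i]
        son_m, daughter_m = t1_pairs[4 * i + 2]
        f2 = ni.add_child(daughter_f, son_f, False, f"t2f_{i}")
        m2 = ni.add_child(daughter_m, son_m, True, f"t2m_{i}")
        t2_pairs.append((m2, f2))
    noninbred = ni.build(t2_pairs, "noninbred")

    ib = _SchemeBuilder(base, "inbred", rng)
    ib_pairs = []
    for i, (dad, mom) in enumerate(founders[m : m + n_pairs]):
        d0, m0 = ib.add_founder(dad), ib.add_founder(mom)
        s1 = ib.add_child(m0, d0, True, f"t1m_{i}")
        f1 = ib.add_child(m0, d0, False, f"t1f_{i}")
        s2 = ib.add_child(f1, s1, True, f"t2m_{i}")
        f2 = ib.add_child(f1, s1, False, f"t2f_{i}")
        ib_pairs.append((s2, f2))
    inbred = ib.build(ib_pairs, "inbred")

    rows = []
    for cohort in (noninbred, inbred):
        pop = cohort.population
        for (iid, sire, dam), male in zip(pop.pedigree, pop.sex):
            rows.append(
                {
                    "id": iid,
                    "sire": sire if sire is not None else "0",
                    "dam": dam if dam is not None else "0",
                    "sex": "M" if male else "F",
                }
            )
    return noninbred, inbred, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class TraitParams:
    """Trait-generation parameters.

    kappa : baseline pupae count of a load-free pair (Poisson mean scale).
    sigma_env : SD of the lognormal environmental factor on both traits.
    kappa_wild : baseline wild-type offspring count of a load-free W vial.
    lambda_curly : Poisson mean of the competitor (Curly) count, independent
        of focal genotypes.
    """

    kappa: float = 100.0
    sigma_env: float = 0.35
    kappa_wild: float = 90.0
    lambda_curly: float = 44.0

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.kappa_wild < 0 or self.lambda_curly < 0:
            raise ValueError("baseline counts must be non-negative")
        if self.sigma_env < 0:
            raise ValueError("sigma_env must be non-negative")


@dataclass(frozen=True)
class PhenotypeRecord:
    pair_id: str
    scheme: str
    p: int
    w: float | None
    contributing_parent_ids: tuple[str, ...]
    sequenced_designate: bool


def assign_phenotypes(
    cohort: Cohort,
    trait_params: TraitParams = TraitParams(),
    group_size: int = 4,
    seed=None,
) -> list[PhenotypeRecord]:
    """Draw P for every breeding pair and W for every group of ``group_size``
    pairs (the W value is attached to the group's sequenced-designate pair)."""
    if len(cohort.pair_indices) % group_size:
        raise ValueError("group_size must divide the number of pairs")
    rng = np.random.default_rng(seed)
    pop = cohort.population
    log_w_all = pop.log_viability()
    records: list[PhenotypeRecord] = []
    tp = trait_params
    n_groups = len(cohort.pair_indices) // group_size
    for g in range(n_groups):
        group = list(range(g * group_size, (g + 1) * group_size))
        parent_idx = [
            i for pair in group for i in cohort.pair_indices[pair]
        ]
        mean_log_v = float(np.mean(log_w_all[parent_idx]))
        eps_w = rng.normal(0.0, tp.sigma_env)
        lam_wild = tp.kappa_wild * math.exp(mean_log_v + eps_w)
        wild = rng.poisson(lam_wild)
        curly = rng.poisson(tp.lambda_curly)
        w_value = wild / (curly + 1)
        for slot, pair in enumerate(group):
            male, female = cohort.pair_indices[pair]
            pair_log_v = 0.5 * (log_w_all[male] + log_w_all[female])
            eps = rng.normal(0.0, tp.sigma_env)
            p = int(rng.poisson(tp.kappa * math.exp(pair_log_v + eps)))
            records.append(
                PhenotypeRecord(
                    pair_id=cohort.pair_ids[pair],
                    scheme=cohort.scheme,
                    p=p,
                    w=float(w_value) if slot == 0 else None,
                    contributing_parent_ids=tuple(
                        pop.ids[i] for i in parent_idx
                    )
                    if slot == 0
                    else (pop.ids[male], pop.ids[female]),
                    sequenced_designate=slot == 0,
                )
            )
    return records


def competitive_fitness(wild: int, curly: int) -> float:
    """W = wild / (curly + 1)."""
    if wild < 0 or curly < 0:
        raise ValueError("offspring counts must be non-negative")
    return wild / (curly + 1)


# ---------------------------------------------------------------------------
# export


def export_cohort(
    cohorts: list[Cohort],
    n_sequenced_per_scheme: int = 17,
    marker_count: int | None = None,
    phenotypes: list[PhenotypeRecord] | None = None,
    group_size: int = 4,
    seed=None,
):
    """Genotype the sequenced designates (one male per designate pair).

    Returns ``(dosage matrix, MarkerPanel, sample ids, groups, pair_ids)``
    where rows are the sequenced males of each cohort in order. Only loci
    segregating among the sequenced samples are emitted; if ``marker_count``
    exceeds the available segregating loci, all are emitted with a warning.
    """
    if marker_count is not None and marker_count <= 0:
        raise ValueError("marker_count must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    sample_ids: list[str] = []
    groups: list[str] = []
    pair_ids: list[str] = []
    ref_pop = cohorts[0].population
    for cohort in cohorts:
        designates = [
            i for i in range(len(cohort.pair_indices)) if i % group_size == 0
        ]
        if phenotypes is not None:
            by_pair = {r.pair_id: r for r in phenotypes if r.scheme == cohort.scheme}
            designates = [
                i
                for i in designates
                if by_pair.get(cohort.pair_ids[i]) is None
                or by_pair[cohort.pair_ids[i]].p > 0
            ]
        if n_sequenced_per_scheme > len(designates):
            raise ValueError(
                "not enough designate pairs to sequence the requested males"
            )
        chosen = rng.choice(
            np.asarray(designates), size=n_sequenced_per_scheme, replace=False
        )
        for i in sorted(chosen.tolist()):
            male, _ = cohort.pair_indices[i]
            d = cohort.population.dosages([male])[0]
            rows.append(d)
            sample_ids.append(cohort.population.ids[male])
            groups.append(cohort.scheme)
            pair_ids.append(cohort.pair_ids[i])
    X = np.asarray(rows, dtype=float)
    freq = X.mean(axis=0) / 2.0
    seg = np.flatnonzero((freq > 0) & (freq < 1))
    if marker_count is not None:
        if marker_count > seg.size:
            warnings.warn(
                f"requested {marker_count} markers but only {seg.size} segregate; "
                "emitting all segregating loci"
            )
        else:
            seg = np.sort(rng.choice(seg, size=marker_count, replace=False))
    X = X[:, seg]
    labels = np.asarray(
        [f"chr{c + 2}" for c in ref_pop.loci_chrom[seg]], dtype=object
    )
    freq_seg = X.mean(axis=0) / 2.0
    p = np.minimum(freq_seg, 1.0 - freq_seg)
    panel = MarkerPanel(labels, ref_pop.loci_pos_bp[seg], np.clip(p, 1e-9, 0.5))
    return X, panel, sample_ids, groups, pair_ids
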