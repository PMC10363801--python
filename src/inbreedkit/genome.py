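"""Genome architecture and mutational-model configuration.

A :class:`GenomeConfig` describes the chromosome structure used both by the
forward simulator (physical positions for markers, map lengths for crossover
placement) and by the ROH machinery (``l_auto``, the physical length of the
autosomal genome covered by markers, which is the denominator of F_ROH).

A :class:`MutationModel` describes the deleterious-mutation process: the
haploid genomic mutation rate U, the distribution of homozygous selection
coefficients s, the dominance rule h(s), and an optional extra class of fully
recessive lethals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Chromosome",
    "GenomeConfig",
    "MutationModel",
    "drosophila_autosomes",
]


@dataclass(frozen=True)
class Chromosome:
    """One autosome: physical length in bp and genetic map length in Morgans."""

    physical_length_bp: int
    map_length_morgans: float

    def __post_init__(self) -> None:
        if self.physical_length_bp <= 0:
            raise ValueError("chromosome physical length must be positive")
        if self.map_length_morgans < 0:
            raise ValueError("chromosome map length must be non-negative")


@dataclass(frozen=True)
class GenomeConfig:
    """Chromosome structure of the simulated genome.

    Parameters
    ----------
    chromosomes
        Autosomes as (physical bp, Morgans) pairs.
    male_recombination
        If False, male meiosis is achiasmate (whole chromosomes are
        transmitted intact), as in *Drosophila melanogaster*. Map lengths are
        then interpreted as female map lengths.
    l_auto
        Physical length (bp) of the autosomal genome covered by markers —
        the F_ROH denominator. Defaults to the summed chromosome lengths.
    """

    chromosomes: tuple[Chromosome, ...]
    male_recombination: bool = True
    l_auto: int | None = None

    def __post_init__(self) -> None:
        if len(self.chromosomes) == 0:
            raise ValueError("genome must contain at least one chromosome")
        chroms = tuple(
            c if isinstance(c, Chromosome) else Chromosome(*c)
            for c in self.chromosomes
        )
        object.__setattr__(self, "chromosomes", chroms)
        total = sum(c.physical_length_bp for c in chroms)
        if self.l_auto is None:
            object.__setattr__(self, "l_auto", total)
        elif not 0 < self.l_auto <= total:
            raise ValueError("l_auto must lie in (0, total physical length]")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def total_physical_bp(self) -> int:
        return sum(c.physical_length_bp for c in self.chromosomes)

    @property
    def total_map_morgans(self) -> float:
        return sum(c.map_length_morgans for c in self.chromosomes)


def drosophila_autosomes() -> GenomeConfig:
    """Drosophila-like autosomal genome used as the default emulation target.

    Two major autosomes covering 119 Mb of marker-accessible sequence with a
    sex-averaged-equivalent female map of ~1 Morgan per arm pair and no male
    recombination.
    """
    return GenomeConfig(
        chromosomes=(
            Chromosome(60_000_000, 1.08),
            Chromosome(59_000_000, 1.07),
        ),
        male_recombination=False,
        l_auto=119_000_000,
    )


def _default_h_rule(s: np.ndarray) -> np.ndarray:
    """Dominance declining with effect size, h = 0.5 * exp(-13 s).

    Gives h ~ 0.25 for mild deleterious effects (s ~ 0.05) and nearly
    recessive severe mutations, matching mutation-accumulation consensus for
    Drosophila (mean h around 0.2-0.3 for detectable mutations).
    """
    return 0.5 * np.exp(-13.0 * np.asarray(s, dtype=float))


@dataclass(frozen=True)
class MutationModel:
    """Deleterious-mutation process for the forward simulator.

    Parameters
    ----------
    u
        Haploid genomic deleterious mutation rate per generation (detectable,
        non-lethal class). The Drosophila median estimate is ~0.061.
    mean_s
        Mean homozygous selection coefficient; s is drawn from an exponential
        truncated at 1 (Drosophila median s ~ 0.11).
    h_rule
        Callable mapping an array of s values to dominance coefficients h.
    lethal_rate
        Haploid rate of recessive lethals (s = 1); ~0.015 in Drosophila.
    lethal_h
        Dominance of lethals (slight heterozygous effect; 0.02 by default).
    """

    u: float = 0.061
    mean_s: float = 0.11
    h_rule: Callable[[np.ndarray], np.ndarray] = field(default=_default_h_rule)
    lethal_rate: float = 0.015
    lethal_h: float = 0.02

    def __post_init__(self) -> None:
        if self.u < 0 or self.lethal_rate < 0:
            raise ValueError("mutation rates must be non-negative")
        if not 0 < self.mean_s <= 1:
            raise ValueError("mean_s must lie in (0, 1]")

    @property
    def total_rate(self) -> float:
        return self.u + self.lethal_rate

    def draw_effects(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw (s, h) for ``n`` new mutations, mixing the two classes."""
        is_lethal = rng.random(n) < (
            self.lethal_rate / self.total_rate if self.total_rate > 0 else 0.0
        )
        # exponential truncated to (0, 1): redraw the rare tail above 1
        s = rng.exponential(self.mean_s, size=n)
        while np.any(s >= 1.0):
            big = s >= 1.0
            s[big] = rng.exponential(self.mean_s, size=int(big.sum()))
        s[is_lethal] = 1.0
        h = np.asarray(self.h_rule(s), dtype=float)
        h[is_lethal] = self.lethal_h
        if np.any((h < 0) | (h > 1)):
            raise ValueError("h_rule produced dominance outside [0, 1]")
        return s, h


NEUTRAL = MutationModel(u=0.0, mean_s=0.11, lethal_rate=0.0)
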