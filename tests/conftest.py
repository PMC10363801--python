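"""Shared fixtures: small genomes, a neutral base population and replicate
breeding-experiment simulations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from inbreedkit.genome import Chromosome, GenomeConfig, MutationModel
from inbreedkit.pedigree import Pedigree
from inbreedkit.regression import id_regression
from inbreedkit.simulate import (
    TraitParams,
    assign_phenotypes,
    breed_schemes,
    inbreeding_load,
    simulate_base_population,
)

NEUTRAL = MutationModel(u=0.0, lethal_rate=0.0)


def small_genome(n_chrom: int = 2, morgans: float = 0.5, bp: int = 30_000_000,
                 male_recombination: bool = True) -> GenomeConfig:
    return GenomeConfig(
        chromosomes=tuple(Chromosome(bp, morgans) for _ in range(n_chrom)),
        male_recombination=male_recombination,
    )


@pytest.fixture(scope="session")
def neutral_base():
    """Large-ish neutral base population on a short two-chromosome genome,
    used wherever a realistic standing-variation background is needed."""
    return simulate_base_population(
        small_genome(), NEUTRAL, n=400, generations=60, seed=20240901,
        n_marker_loci=6000,
    )


@pytest.fixture(scope="session")
def double_fullsib_pedigree():
    """Unrelated founders; full-sib mating at t=1; the resulting full sibs
    form the t=2 breeding pair whose child is the t=3 progeny."""
    return Pedigree(
        [
            ("gpa", None, None),
            ("gma", None, None),
            ("t1m", "gpa", "gma"),
            ("t1f", "gpa", "gma"),
            ("t2m", "t1m", "t1f"),
            ("t2f", "t1m", "t1f"),
            ("t3", "t2m", "t2f"),
        ]
    )


# mild, fixed-dominance deleterious model: the load is spread over many
# small-effect loci, so desk-scale replicate means are well behaved
MILD_MUTATION = MutationModel(
    u=0.3,
    mean_s=0.04,
    lethal_rate=0.0,
    h_rule=lambda s: np.full_like(np.asarray(s, dtype=float), 0.3),
)


@pytest.fixture(scope="session")
def load_replicates():
    """Replicate breeding experiments with a built-in inbreeding load.

    Each replicate simulates a base population under the mild mutation
    model, breeds both schemes, assigns productivities, and fits the pooled
    regression of log P on pedigree F. Returns a list of
    (slope, bootstrap CI, closed-form load B) tuples.
    """
    rng = np.random.default_rng(77)
    genome = small_genome(morgans=0.55, male_recombination=False)
    out = []
    for _ in range(50):
        base = simulate_base_population(
            genome, MILD_MUTATION, n=200, generations=60,
            seed=int(rng.integers(2**31)),
        )
        sel = base.loci_s > 0
        q = base.allele_frequencies()[sel]
        b_load = inbreeding_load(q, base.loci_s[sel], base.loci_h[sel])
        noninbred, inbred, _ = breed_schemes(
            base, 16, seed=int(rng.integers(2**31))
        )
        f_vals, log_p = [], []
        for cohort, f_ped in ((noninbred, 0.0), (inbred, 0.25)):
            records = assign_phenotypes(
                cohort,
                TraitParams(kappa=300.0, sigma_env=0.05),
                seed=int(rng.integers(2**31)),
            )
            for rec in records:
                if rec.p > 0:
                    f_vals.append(f_ped)
                    log_p.append(np.log(rec.p))
        res = id_regression(
            f_vals, log_p, n_boot=500, n_perm=0, seed=int(rng.integers(2**31))
        )
        out.append((res.slope, res.ci_bootstrap, b_load))
    return out
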