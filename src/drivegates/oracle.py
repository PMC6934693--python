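"""Brute-force genotype-enumeration oracle and finite-population check.

Re-derives each variant's one-generation update by explicitly enumerating
post-drive-action genotype classes from a random union of gametes, instead
of using the closed-form recursions in :mod:`drivegates.models`.  The two
routes are kept independent so the enumeration can serve as ground truth
in tests.  A Wright–Fisher binomial sampler provides a finite-population
sanity check on the infinite-population (deterministic) assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    DegeneratePopulationError,
    DriveParams,
    EffectiveParams,
    ModelVariant,
    het_fitness,
)

__all__ = [
    "GenotypePool",
    "enumerate_pool",
    "oracle_next_frequency",
    "oracle_step",
    "wright_fisher_step",
]


@dataclass(frozen=True)
class GenotypePool:
    """Post-drive-action genotype masses and their fitness weights.

    The four masses (drive homozygote DD, heterozygote DW, wild-type
    homozygote WW, lethal) sum to one.  Lethal mass carries no fitness
    weight — those zygotes leave no offspring.
    """

    freq_DD: float
    freq_DW: float
    freq_WW: float
    freq_lethal: float
    fitness_DD: float
    fitness_DW: float
    fitness_WW: float

    def __post_init__(self) -> None:
        for name in ("freq_DD", "freq_DW", "freq_WW", "freq_lethal"):
            if getattr(self, name) < -1e-15:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)!r}")
        total = self.freq_DD + self.freq_DW + self.freq_WW + self.freq_lethal
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"genotype masses must sum to 1, got {total!r}")


def enumerate_pool(
    q_D: float,
    params: DriveParams,
    variant: ModelVariant = ModelVariant.STANDARD,
    eff: EffectiveParams | None = None,
) -> GenotypePool:
    """Enumerate surviving genotype classes after drive action.

    Starts from Hardy–Weinberg zygote frequencies (q_D^2, 2 q_W q_D,
    q_W^2) and walks the probability tree of drive action per genotype:

    * heterozygote (one drive, one wild-type copy): self-cleavage of the
      drive (prob. E) and cleavage-plus-conversion of the target (prob. e)
      act independently, giving lethal ``E*e``, wild-type homozygote
      ``E*(1-e)`` (the wild-type gene is copied back over the excised
      drive), drive homozygote ``(1-E)*e`` (conversion with the drive
      intact) and unchanged heterozygote ``(1-E)*(1-e)``;
    * drive homozygote: both copies excised with probability ``E**2``
      (lethal, no template for repair), otherwise restored to DD;
    * wild-type homozygote: untouched.

    For non-self-cleaving variants ``E = 0``; the inducible variants swap
    in their population-averaged efficiency or fitness.
    """
    if eff is None:
        eff = EffectiveParams(e_eff=params.e_W, f_eff=params.f, E=params.e_D)
    if variant is ModelVariant.SELF_CLEAVING:
        e, f, E = params.e_W, params.f, eff.E
    elif variant is ModelVariant.INDUCIBLE_EFFICIENCY:
        e, f, E = eff.e_eff, params.f, 0.0
    elif variant is ModelVariant.INDUCIBLE_FITNESS:
        e, f, E = params.e_W, eff.f_eff, 0.0
    else:
        e, f, E = params.e_W, params.f, 0.0

    q_W = 1.0 - q_D
    hom_D = q_D * q_D
    het = 2.0 * q_W * q_D
    hom_W = q_W * q_W

    return GenotypePool(
        freq_DD=hom_D * (1.0 - E * E) + het * (1.0 - E) * e,
        freq_DW=het * (1.0 - E) * (1.0 - e),
        freq_WW=hom_W + het * E * (1.0 - e),
        freq_lethal=hom_D * E * E + het * E * e,
        fitness_DD=f,
        fitness_DW=het_fitness(f, params.h),
        fitness_WW=1.0,
    )


def oracle_next_frequency(pool: GenotypePool) -> float:
    """Next-generation drive frequency as a fitness-weighted allele count.

    ``(w_DD * DD + w_DW * DW / 2) / (w_DD * DD + w_DW * DW + w_WW * WW)``.

    Raises
    ------
    DegeneratePopulationError
        If no surviving fitness-weighted mass remains (all-lethal pool).
    """
    wbar = (
        pool.fitness_DD * pool.freq_DD
        + pool.fitness_DW * pool.freq_DW
        + pool.fitness_WW * pool.freq_WW
    )
    if wbar <= 1e-12:
        raise DegeneratePopulationError(
            f"surviving fitness-weighted mass {wbar!r} is non-positive; "
            "the enumerated population is entirely lethal or fitness-free"
        )
    q = (pool.fitness_DD * pool.freq_DD + pool.fitness_DW * pool.freq_DW / 2.0) / wbar
    # round-off can push an exact-boundary result a few ulp outside [0, 1]
    return min(1.0, max(0.0, q))


def oracle_step(
    q_D: float,
    params: DriveParams,
    variant: ModelVariant = ModelVariant.STANDARD,
    eff: EffectiveParams | None = None,
) -> float:
    """Enumeration-based one-generation update (convenience wrapper)."""
    return oracle_next_frequency(enumerate_pool(q_D, params, variant, eff))


def wright_fisher_step(
    q_D: float,
    population_size: int,
    params: DriveParams,
    variant: ModelVariant = ModelVariant.STANDARD,
    eff: EffectiveParams | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """One generation with binomial sampling of 2N alleles.

    The deterministic next frequency (via the enumeration oracle) becomes
    the success probability of a binomial draw over ``2 * population_size``
    allele copies, modeling genetic drift in a finite population.
    Reproducible for a fixed integer seed; an existing
    :class:`numpy.random.Generator` may be passed to chain draws.
    """
    if population_size < 2:
        raise ValueError(f"population_size must be >= 2, got {population_size!r}")
    p = oracle_next_frequency(enumerate_pool(q_D, params, variant, eff))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_alleles = 2 * population_size
    return float(rng.binomial(n_alleles, p)) / n_alleles
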