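"""Core parameter containers and single-generation allele-frequency updates.

The population model tracks a single biallelic locus with a wild-type allele
(W) and a gene-drive allele (D) in an infinite, randomly mating population
with non-overlapping generations.  Drive conversion acts in heterozygotes:
with probability ``e_W`` the drive cleaves the wild-type homolog and copies
itself across via homology-directed repair, turning the individual into a
drive homozygote before selection.  Failed conversion leaves an ordinary
heterozygote; no resistance alleles arise.

Fitness is relative to wild-type (fixed at 1): drive homozygotes have
fitness ``f`` and heterozygotes ``(1 - h) + f*h`` with dominance ``h``
(0.5 = codominance).

Three reversal mechanisms are modeled on top of the standard recursion:

* inducible efficiency — an external signal switches conversion efficiency
  from ``e_W`` to ``e_W_induced`` in the responding fraction ``alpha`` of
  the population;
* inducible fitness — the signal switches drive-homozygote fitness from
  ``f`` to ``f_induced`` in the responding fraction;
* self-cleaving drive — the drive carries a regulated guide-RNA cassette
  targeting the drive cassette itself.  Self-cleavage fires at the basal
  ("leaky") rate ``e_D`` before induction and ``e_D_induced`` after.  In a
  heterozygote, excising the drive with the wild-type homolog intact
  restores a wild-type homozygote; cleaving both the drive and the target
  (or both drive copies in a drive homozygote) is lethal.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "DegeneratePopulationError",
    "ModelVariant",
    "DriveParams",
    "InductionSettings",
    "AlleleState",
    "EffectiveParams",
    "het_fitness",
    "effective_params",
    "step_standard",
    "step_inducible_efficiency",
    "step_inducible_fitness",
    "step_self_cleaving",
    "step",
    "mean_fitness",
    "MEAN_FITNESS_TOL",
]

#: Mean fitness at or below this value is treated as a collapsed population.
MEAN_FITNESS_TOL = 1e-12


class DegeneratePopulationError(RuntimeError):
    """Raised when mean fitness is (numerically) zero.

    The frequency recursion divides by mean fitness; when every surviving
    genotype class has zero mass — e.g. a pure drive-homozygote population
    undergoing certain self-cleavage — allele frequencies are undefined.
    Biologically this corner is population extinction, which a pure
    frequency model cannot represent, so it surfaces as an error instead of
    a frequency.
    """

    def __init__(self, message: str, generation: int | None = None):
        super().__init__(message)
        self.generation = generation


class ModelVariant(str, Enum):
    """Selects which update rule applies and which parameters it reads."""

    STANDARD = "standard"
    INDUCIBLE_EFFICIENCY = "inducible_efficiency"
    INDUCIBLE_FITNESS = "inducible_fitness"
    SELF_CLEAVING = "self_cleaving"


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class DriveParams:
    """All per-scenario model parameters.

    Parameters
    ----------
    e_W
        Probability that the drive cleaves the wild-type target allele and
        copies itself onto it (conversion efficiency), pre-induction.
    f
        Fitness of the drive homozygote relative to wild-type (= 1).
    h
        Degree of dominance of the drive's fitness effect in heterozygotes;
        heterozygote fitness is ``(1 - h) + f*h``.  Default 0.5.
    e_W_induced
        Conversion efficiency in signal-responding individuals.
    f_induced
        Drive-homozygote fitness in signal-responding individuals.
    e_D
        Basal ("leaky") self-cleavage probability before induction.
    e_D_induced
        Self-cleavage probability in signal-responding individuals.
    """

    e_W: float
    f: float
    h: float = 0.5
    e_W_induced: float = 0.0
    f_induced: float = 1.0
    e_D: float = 0.0
    e_D_induced: float = 0.0

    def __post_init__(self) -> None:
        for name in ("e_W", "f", "h", "e_W_induced", "f_induced", "e_D", "e_D_induced"):
            _check_unit(name, getattr(self, name))


@dataclass(frozen=True)
class InductionSettings:
    """When and how strongly the external signal is applied.

    ``alpha`` is the fraction of individuals that respond to the signal in
    each generation once it is on.  The signal switches on in full at
    ``start_generation`` and stays on at the same level in every subsequent
    generation.
    """

    alpha: float = 0.0
    start_generation: int = 0
    enabled: bool = False

    def __post_init__(self) -> None:
        _check_unit("alpha", self.alpha)
        if self.start_generation < 0 or int(self.start_generation) != self.start_generation:
            raise ValueError(
                f"start_generation must be a non-negative integer, got {self.start_generation!r}"
            )

    def alpha_at(self, generation: int) -> float:
        """Effective responding fraction for the transition leaving `generation`."""
        if self.enabled and generation >= self.start_generation:
            return self.alpha
        return 0.0


@dataclass(frozen=True)
class AlleleState:
    """Drive allele frequency at one generation; q_W is always 1 - q_D."""

    q_D: float
    generation: int

    def __post_init__(self) -> None:
        _check_unit("q_D", self.q_D)
        if self.generation < 0:
            raise ValueError(f"generation must be non-negative, got {self.generation!r}")

    @property
    def q_W(self) -> float:
        return 1.0 - self.q_D


@dataclass(frozen=True)
class EffectiveParams:
    """Population-averaged parameters for one transition.

    With responding fraction ``alpha``:
    ``e_eff = alpha*e_W_induced + (1-alpha)*e_W``,
    ``f_eff = alpha*f_induced + (1-alpha)*f``,
    ``E = (1-alpha)*e_D + alpha*e_D_induced``.
    Each variant's step consumes only the component it modulates.
    """

    e_eff: float
    f_eff: float
    E: float


def het_fitness(f: float, h: float) -> float:
    """Heterozygote fitness ``(1 - h) + f*h`` for dominance ``h``."""
    _check_unit("f", f)
    _check_unit("h", h)
    return (1.0 - h) + f * h


def effective_params(
    params: DriveParams,
    induction: InductionSettings,
    generation: int,
    variant: ModelVariant = ModelVariant.STANDARD,
) -> EffectiveParams:
    """Effective parameter bundle for the transition leaving `generation`.

    Before ``start_generation`` (or with induction disabled) the responding
    fraction is exactly zero, so the bundle reduces to the baseline
    parameters.  `variant` is accepted for interface symmetry; all three
    components are always computed and the caller consumes the relevant one.
    """
    if generation < 0:
        raise ValueError(f"generation must be non-negative, got {generation!r}")
    a = induction.alpha_at(generation)
    return EffectiveParams(
        e_eff=a * params.e_W_induced + (1.0 - a) * params.e_W,
        f_eff=a * params.f_induced + (1.0 - a) * params.f,
        E=(1.0 - a) * params.e_D + a * params.e_D_induced,
    )


def _guard(wbar: float, context: str) -> None:
    if wbar <= MEAN_FITNESS_TOL:
        raise DegeneratePopulationError(
            f"mean fitness {wbar!r} is non-positive ({context}); "
            "the population has collapsed and frequencies are undefined"
        )


def _clamp01(x: float) -> float:
    # round-off can push an exact-boundary result a few ulp outside [0, 1]
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def _step_conversion(q_D: float, e: float, f: float, h: float) -> float:
    # Shared body of the standard / inducible-efficiency / inducible-fitness
    # recursions: drive conversion at rate e, drive-homozygote fitness f.
    q_W = 1.0 - q_D
    converted = q_D * q_D + 2.0 * q_W * q_D * e  # drive-homozygote mass incl. converted hets
    hets = q_W * q_D * (1.0 - e)  # surviving heterozygote mass / 2
    w_het = (1.0 - h) + f * h
    numerator = f * converted + w_het * hets
    denominator = 1.0 - (1.0 - f) * converted - (h - f * h) * 2.0 * hets
    _guard(denominator, f"q_D={q_D}, e={e}, f={f}, h={h}")
    return _clamp01(numerator / denominator)


def step_standard(q_D: float, params: DriveParams) -> float:
    """One generation of the standard (uninduced) drive recursion.

    Random union of gametes, conversion of a fraction ``e_W`` of
    heterozygotes into drive homozygotes, then selection with mean-fitness
    normalization:

        q_D' = [f (q_D^2 + 2 q_W q_D e_W) + ((1-h)+f h) q_W q_D (1-e_W)]
               / [1 - (1-f)(q_D^2 + 2 q_W q_D e_W) - (h - f h) 2 q_W q_D (1-e_W)]

    Raises
    ------
    DegeneratePopulationError
        If mean fitness (the denominator) is numerically zero.
    """
    _check_unit("q_D", q_D)
    return _step_conversion(q_D, params.e_W, params.f, params.h)


def step_inducible_efficiency(q_D: float, params: DriveParams, e_eff: float) -> float:
    """Standard recursion with conversion efficiency replaced by ``e_eff``.

    ``e_eff`` is the population-averaged efficiency
    ``alpha*e_W_induced + (1-alpha)*e_W``; with ``e_eff == e_W`` this equals
    :func:`step_standard` bit for bit.
    """
    _check_unit("q_D", q_D)
    _check_unit("e_eff", e_eff)
    return _step_conversion(q_D, e_eff, params.f, params.h)


def step_inducible_fitness(q_D: float, params: DriveParams, f_eff: float) -> float:
    """Standard recursion with drive fitness replaced by ``f_eff``.

    ``f_eff`` substitutes for ``f`` in every occurrence, including inside
    the heterozygote fitness ``(1 - h) + f_eff*h``.
    """
    _check_unit("q_D", q_D)
    _check_unit("f_eff", f_eff)
    return _step_conversion(q_D, params.e_W, f_eff, params.h)


def step_self_cleaving(q_D: float, params: DriveParams, E: float) -> float:
    """One generation of the self-cleaving drive recursion.

    ``E`` is the population-averaged self-cleavage probability
    ``(1-alpha)*e_D + alpha*e_D_induced``.  Genotype bookkeeping after
    zygote formation and drive action:

    * drive homozygotes: both copies excised with probability ``E**2``
      (lethal), otherwise the genotype is restored to a drive homozygote
      via homology-directed repair;
    * heterozygotes: target and drive are cleaved independently —
      both cleaved (``E*e_W``) is lethal; drive only (``E*(1-e_W)``)
      restores a wild-type homozygote; target only (``(1-E)*e_W``) converts
      to a drive homozygote; neither (``(1-E)*(1-e_W)``) stays heterozygous.

    Surviving pools are weighted by fitness (f, (1-h)+f h, 1) and the next
    drive frequency is the weighted drive-allele count over mean fitness.
    With ``E == 0`` this equals :func:`step_standard` exactly.
    """
    _check_unit("q_D", q_D)
    _check_unit("E", E)
    if E == 0.0:
        # reduce through the shared body so the identity with the standard
        # recursion holds bit for bit, not merely to round-off
        return _step_conversion(q_D, params.e_W, params.f, params.h)
    q_W = 1.0 - q_D
    e_W, f, h = params.e_W, params.f, params.h
    dd = q_D * q_D * (1.0 - E * E) + 2.0 * q_W * q_D * (1.0 - E) * e_W
    dw = 2.0 * q_W * q_D * (1.0 - E) * (1.0 - e_W)
    ww = q_W * q_W + 2.0 * q_W * q_D * E * (1.0 - e_W)
    w_het = (1.0 - h) + f * h
    wbar = f * dd + w_het * dw + ww
    _guard(wbar, f"q_D={q_D}, E={E}, e_W={e_W}, f={f}, h={h}")
    return _clamp01((f * dd + w_het * dw / 2.0) / wbar)


def step(
    q_D: float,
    params: DriveParams,
    variant: ModelVariant,
    eff: EffectiveParams,
) -> float:
    """Dispatch to the variant's update rule with its effective parameter."""
    if variant is ModelVariant.STANDARD:
        return step_standard(q_D, params)
    if variant is ModelVariant.INDUCIBLE_EFFICIENCY:
        return step_inducible_efficiency(q_D, params, eff.e_eff)
    if variant is ModelVariant.INDUCIBLE_FITNESS:
        return step_inducible_fitness(q_D, params, eff.f_eff)
    if variant is ModelVariant.SELF_CLEAVING:
        return step_self_cleaving(q_D, params, eff.E)
    raise ValueError(f"unknown variant {variant!r}")


def mean_fitness(
    q_D: float,
    params: DriveParams,
    variant: ModelVariant,
    eff: EffectiveParams | None = None,
) -> float:
    """Mean fitness (the recursion denominator) for the selected variant.

    Exposed for diagnostics and degenerate-population guarding; never
    raises — callers decide what a non-positive value means.
    """
    _check_unit("q_D", q_D)
    if eff is None:
        eff = EffectiveParams(e_eff=params.e_W, f_eff=params.f, E=params.e_D)
    q_W = 1.0 - q_D
    h = params.h
    if variant is ModelVariant.SELF_CLEAVING:
        e_W, f, E = params.e_W, params.f, eff.E
        dd = q_D * q_D * (1.0 - E * E) + 2.0 * q_W * q_D * (1.0 - E) * e_W
        dw = 2.0 * q_W * q_D * (1.0 - E) * (1.0 - e_W)
        ww = q_W * q_W + 2.0 * q_W * q_D * E * (1.0 - e_W)
        return f * dd + ((1.0 - h) + f * h) * dw + ww
    if variant is ModelVariant.INDUCIBLE_EFFICIENCY:
        e, f = eff.e_eff, params.f
    elif variant is ModelVariant.INDUCIBLE_FITNESS:
        e, f = params.e_W, eff.f_eff
    else:
        e, f = params.e_W, params.f
    converted = q_D * q_D + 2.0 * q_W * q_D * e
    hets = q_W * q_D * (1.0 - e)
    return 1.0 - (1.0 - f) * converted - (h - f * h) * 2.0 * hets
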