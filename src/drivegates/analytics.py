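"""Closed-form invasion diagnostics.

Linearizing each recursion around a vanishing drive frequency gives the
per-generation multiplication factor of rare drive alleles,

    lambda = 2 f e + ((1 - h) + f h) (1 - e)

for the conversion-based variants (with the variant's effective efficiency
and fitness), and ``(1 - E)`` times that expression for the self-cleaving
variant.  A rare drive invades iff lambda > 1.  This linearization is a
diagnostic derived in this package; the simpler literature heuristic
``f (e_W + 1) > 1`` is reported alongside it, never conflated — the two
boundaries coincide at ``e_W = 1, h = 0.5`` and differ elsewhere.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .models import (
    DriveParams,
    EffectiveParams,
    ModelVariant,
    het_fitness,
)

__all__ = [
    "InvasionReport",
    "invasion_growth_factor",
    "heuristic_favorability",
    "invasion_report",
]


@dataclass(frozen=True)
class InvasionReport:
    """Invasion diagnostics for one parameter set."""

    growth_factor: float
    favored: bool
    heuristic_value: float
    heuristic_favored: bool
    variant: ModelVariant
    params: DriveParams

    def to_dict(self) -> dict:
        d = {
            "growth_factor": self.growth_factor,
            "favored": self.favored,
            "boundary": self.growth_factor == 1.0,
            "heuristic_value": self.heuristic_value,
            "heuristic_favored": self.heuristic_favored,
            "heuristic_boundary": self.heuristic_value == 1.0,
            "variant": self.variant.value,
            "params": asdict(self.params),
        }
        return d


def invasion_growth_factor(
    params: DriveParams,
    variant: ModelVariant = ModelVariant.STANDARD,
    eff: EffectiveParams | None = None,
) -> float:
    """Per-generation growth factor of a rare drive allele.

    Obtained from the first-order expansion of the variant's recursion at
    q_D -> 0: a rare drive allele almost always pairs with a wild-type
    one, contributing two drive alleles (weight f) when converted and one
    (heterozygote weight) when not; self-cleavage discards a fraction E of
    those contributions outright.
    """
    if eff is None:
        eff = EffectiveParams(e_eff=params.e_W, f_eff=params.f, E=params.e_D)
    if variant is ModelVariant.SELF_CLEAVING:
        core = 2.0 * params.f * params.e_W + het_fitness(params.f, params.h) * (1.0 - params.e_W)
        return (1.0 - eff.E) * core
    if variant is ModelVariant.INDUCIBLE_EFFICIENCY:
        e, f = eff.e_eff, params.f
    elif variant is ModelVariant.INDUCIBLE_FITNESS:
        e, f = params.e_W, eff.f_eff
    else:
        e, f = params.e_W, params.f
    return 2.0 * f * e + het_fitness(f, params.h) * (1.0 - e)


def heuristic_favorability(f: float, e_W: float) -> tuple[float, str]:
    """Literature favorability index ``f * (e_W + 1)`` and its verdict.

    Returns the index and one of ``"favored"`` (> 1), ``"not_favored"``
    (< 1) or ``"boundary"`` (= 1); the knife-edge case is reported as its
    own category rather than assigned to either side.
    """
    value = f * (e_W + 1.0)
    if value > 1.0:
        verdict = "favored"
    elif value < 1.0:
        verdict = "not_favored"
    else:
        verdict = "boundary"
    return value, verdict


def invasion_report(
    params: DriveParams,
    variant: ModelVariant = ModelVariant.STANDARD,
    eff: EffectiveParams | None = None,
) -> InvasionReport:
    """Bundle the linearized growth factor with the literature heuristic."""
    lam = invasion_growth_factor(params, variant, eff)
    heur, _ = heuristic_favorability(params.f, params.e_W)
    return InvasionReport(
        growth_factor=lam,
        favored=lam > 1.0,
        heuristic_value=heur,
        heuristic_favored=heur > 1.0,
        variant=variant,
        params=params,
    )
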