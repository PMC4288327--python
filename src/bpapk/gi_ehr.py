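"""Gastrointestinal absorption, presystemic gut-wall conjugation, and the
rat enterohepatic recirculation (EHR) loop.

Oral doses enter the stomach, empty first-order into the gut lumen, and are
taken up into enterocytes.  Inside enterocytes BPA is either conjugated
(the dominant fate at low doses — presystemic first-pass extraction) or
escapes unconjugated into portal blood.  In the rat, enterocyte conjugate
is transferred instantaneously to the systemic conjugate pool as part of a
composite first-order term; in monkey and human it accumulates in an
explicit enterocyte conjugate pool and effluxes first-order into systemic
circulation.

The rat EHR loop: hepatically formed conjugate is excreted into bile
(capacity-limited), moves through a short transit chain to the terminal
small intestine, and is deconjugated by gut bacteria.  The liberated BPA
partitions at the rate level: 90% re-enters enterocytes and is
re-conjugated into the systemic conjugate pool, a calibrated fraction is
reabsorbed to portal blood as parent, and the remainder leaves in feces
unconjugated.  The 90/10 split is exact by construction at every instant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import AbsorptionParams, EhrParams, MetabolismParams

__all__ = [
    "oral_absorption_rates",
    "enterocyte_split",
    "biliary_excretion_rate",
    "EhrFluxes",
    "ehr_loop_fluxes",
]


def oral_absorption_rates(
    stomach: float, lumen: float, a: AbsorptionParams
) -> tuple[float, float]:
    """First-order transfer fluxes (nmol/h) along the absorption chain.

    Returns ``(stomach_to_lumen, lumen_to_enterocyte)``.  Both transfers
    conserve mass: what leaves one pool enters the next.
    """
    return a.k_gastric_emptying * stomach, a.k_lumen_uptake * lumen


@dataclass
class EnterocyteFluxes:
    """Fate of enterocyte BPA, all in nmol/h."""

    to_portal_parent: float
    conjugated: float
    conjugate_to_systemic: float  # rat: equals `conjugated` (instantaneous transfer)


def enterocyte_split(
    enterocyte_parent: float,
    m: MetabolismParams,
    species: str,
    enterocyte_conjugate: float = 0.0,
) -> EnterocyteFluxes:
    """Partition enterocyte BPA between portal escape and conjugation.

    Rat: the composite first-order constant conjugates BPA and delivers the
    conjugate directly to the systemic conjugate pool, so
    ``conjugate_to_systemic == conjugated`` and the enterocyte conjugate
    pool is never populated.  Monkey/human: conjugation feeds the
    enterocyte conjugate pool, which effluxes first-order (MRP3-like
    basolateral transport) at ``k_enterocyte_conjugate_efflux``;
    ``conjugate_to_systemic`` is that efflux.
    """
    if enterocyte_parent < 0:
        raise ValueError("enterocyte amount must be non-negative")
    if species == "rat":
        if m.k_gut_composite is None:
            raise ValueError("rat metabolism requires k_gut_composite")
        conj = m.k_gut_composite * enterocyte_parent
        return EnterocyteFluxes(
            to_portal_parent=m.k_enterocyte_passthrough * enterocyte_parent,
            conjugated=conj,
            conjugate_to_systemic=conj,
        )
    if m.k_gut_metabolism is None or m.k_enterocyte_conjugate_efflux is None:
        raise ValueError(f"{species} metabolism requires gut conjugation + efflux constants")
    return EnterocyteFluxes(
        to_portal_parent=m.k_enterocyte_passthrough * enterocyte_parent,
        conjugated=m.k_gut_metabolism * enterocyte_parent,
        conjugate_to_systemic=m.k_enterocyte_conjugate_efflux * enterocyte_conjugate,
    )


def biliary_excretion_rate(c_conjugate: float, e: EhrParams) -> float:
    """Capacity-limited (Michaelis–Menten) biliary excretion, nmol/h.

    Acts on the central conjugate concentration (nmol/L), so systemically
    circulating conjugate recirculates through bile.
    """
    if c_conjugate < 0:
        raise ValueError("conjugate concentration must be non-negative")
    return e.vmax_biliary * c_conjugate / (e.km_biliary + c_conjugate)


@dataclass
class EhrFluxes:
    """Instantaneous EHR-loop fluxes, nmol/h."""

    transit_out: list[float]  # outflow of each transit compartment
    deconjugation: float  # terminal conjugate -> liberated parent
    reconjugated: float  # 90% of deconjugation, to systemic conjugate pool
    reabsorbed_parent: float  # to portal blood (liver) as parent
    fecal_parent: float  # unconjugated BPA to feces
    fecal_conjugate: float  # unconverted conjugate to feces


def ehr_loop_fluxes(
    transit: list[float], terminal_conjugate: float, e: EhrParams
) -> EhrFluxes:
    """Evaluate the loop fluxes for the current transit-chain state.

    The deconjugation flux is partitioned at the rate level, making the
    re-conjugated : (reabsorbed + fecal) split exactly
    ``fraction_reconjugated : 1 - fraction_reconjugated`` at every instant
    and therefore exact in cumulative terms at any horizon.
    """
    transit_out = [e.k_transit * a for a in transit]
    deconj = e.k_deconjugation * terminal_conjugate
    return EhrFluxes(
        transit_out=transit_out,
        deconjugation=deconj,
        reconjugated=e.fraction_reconjugated * deconj,
        reabsorbed_parent=e.fraction_reabsorbed_parent * deconj,
        fecal_parent=e.fraction_fecal_parent * deconj,
        fecal_conjugate=e.k_fecal * terminal_conjugate,
    )
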