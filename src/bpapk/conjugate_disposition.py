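"""Systemic disposition of total BPA conjugates (BPA-c).

Monkey and human use a single well-stirred conjugate compartment; the rat
uses a central compartment with two slowly exchanging peripheral
compartments, which produces the prolonged terminal phase of circulating
conjugate.  Elimination is urinary: glomerular filtration of conjugate at
``urinary_clearance`` on the central concentration, opposed in the monkey
by a capacity-limited (Michaelis–Menten) renal reabsorption flux that
returns filtered conjugate to the central pool.  Reabsorption is capped at
the filtration flux, so the urine rate can never go negative.  Human
simulations carry no renal reabsorption.
"""

from __future__ import annotations

from .parameters import ConjugateParams

__all__ = ["renal_handling_rate", "peripheral_exchange_rates"]


def renal_handling_rate(c_central: float, c: ConjugateParams) -> tuple[float, float]:
    """Return ``(to_urine, reabsorbed)`` fluxes in nmol/h.

    Filtration is linear in the central conjugate concentration (nmol/L);
    reabsorption (monkey only) is Michaelis–Menten in the same
    concentration and capped at the filtration flux.
    """
    if c_central < 0:
        raise ValueError("conjugate concentration must be non-negative")
    filtration = c.urinary_clearance * c_central
    if c.renal_reabsorption is None:
        return filtration, 0.0
    vmax = c.renal_reabsorption["vmax"]
    km = c.renal_reabsorption["km"]
    reabsorbed = vmax * c_central / (km + c_central)
    if reabsorbed > filtration:
        reabsorbed = filtration
    return filtration - reabsorbed, reabsorbed


def peripheral_exchange_rates(
    amounts: list[float], c: ConjugateParams
) -> list[float]:
    """Net central→peripheral exchange flux for each peripheral pool, nmol/h.

    Exchange is symmetric: a distribution clearance ``CLd`` (L/h) acts on
    the concentration difference between the central pool and each
    peripheral pool, so no mass is created or destroyed by distribution.
    """
    c_central = amounts[0] / c.volumes[0]
    fluxes = []
    for i, cld in enumerate(c.inter_compartment_rates, start=1):
        c_per = amounts[i] / c.volumes[i]
        fluxes.append(cld * (c_central - c_per))
    return fluxes
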