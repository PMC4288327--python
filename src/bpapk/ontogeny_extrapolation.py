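"""Life-stage and cross-species derivation of parameter sets.

Adult sets are transformed to immature stages with standard allometric
conventions — volumes proportional to body weight, flows and capacity
(Vmax-type) terms to body weight^0.75, first-order rate constants to
body weight^-0.25 — followed by maturation fractions from the ontogeny
table: hepatic conjugation capacity, gut-wall conjugation, and (rat)
biliary MRP2-mediated excretion each carry their own fraction-of-adult.

The newborn-human model is the newborn (PND5) monkey model with human
physiology substituted, first-order constants rescaled by the body-weight
ratio to the -1/4 power, renal reabsorption of conjugate removed, and the
scaled monkey gut metabolism term carried over.
"""

from __future__ import annotations

from dataclasses import replace

from .parameters import (
    ChemicalProps,
    ModelParameters,
    OntogenyTable,
    Physiology,
    load_adult_parameter_set,
    validate_parameters,
)

__all__ = ["scale_for_age", "extrapolate_monkey_to_human"]

_VOL_EXP = 1.0
_FLOW_EXP = 0.75
_RATE_EXP = -0.25


def _scale_physiology(ph: Physiology, bw_ratio: float) -> Physiology:
    vol = bw_ratio ** _VOL_EXP
    flow = bw_ratio ** _FLOW_EXP
    return Physiology(
        body_weight=ph.body_weight * bw_ratio,
        cardiac_output=ph.cardiac_output * flow,
        tissue_volumes={k: v * vol for k, v in ph.tissue_volumes.items()},
        tissue_flows={k: v * flow for k, v in ph.tissue_flows.items()},
        bile_flow=ph.bile_flow * flow,
        glomerular_filtration=ph.glomerular_filtration * flow,
    )


def scale_for_age(p: ModelParameters, table: OntogenyTable,
                  life_stage: str) -> ModelParameters:
    """Derive a life-stage parameter set from another stage of the same species.

    Typically called with the adult set as source.  Scaling is
    compositional: the source stage's own table row (fraction and body
    weight) is divided out, so adult→PND5 equals adult→PND21→PND5 for a
    consistent table.
    """
    if table.species != p.species:
        raise ValueError(f"table is for {table.species}, parameters for {p.species}")
    target = table.row(life_stage)
    source = table.row(p.life_stage)

    bw_ratio = float(target["body_weight"]) / float(source["body_weight"])
    flow = bw_ratio ** _FLOW_EXP
    rate = bw_ratio ** _RATE_EXP
    hep_frac = float(target["hepatic_fraction_of_adult"]) / float(
        source["hepatic_fraction_of_adult"])
    gut_frac = float(target["gut_fraction_of_adult"]) / float(
        source["gut_fraction_of_adult"])
    mrp2_frac = float(target["mrp2_fraction_of_adult"]) / float(
        source["mrp2_fraction_of_adult"])

    out = p.copy()
    out.life_stage = life_stage
    out.physiology = _scale_physiology(p.physiology, bw_ratio)

    m = out.metabolism
    if m.hepatic_mode == "michaelis_menten":
        m.vmax_hepatic = m.vmax_hepatic * flow * hep_frac
    else:
        m.k_hepatic = m.k_hepatic * rate * hep_frac
    if m.k_gut_composite is not None:
        m.k_gut_composite = m.k_gut_composite * rate * gut_frac
    if m.k_gut_metabolism is not None:
        m.k_gut_metabolism = m.k_gut_metabolism * rate * gut_frac
    if m.k_enterocyte_conjugate_efflux is not None:
        m.k_enterocyte_conjugate_efflux *= rate
    m.k_enterocyte_passthrough *= rate

    out.absorption.k_gastric_emptying *= rate
    out.absorption.k_lumen_uptake *= rate

    c = out.conjugate
    c.volumes = [v * bw_ratio for v in c.volumes]
    c.inter_compartment_rates = [r * flow for r in c.inter_compartment_rates]
    c.urinary_clearance *= flow
    c.fecal_clearance *= flow
    if c.renal_reabsorption is not None:
        c.renal_reabsorption = {
            "vmax": c.renal_reabsorption["vmax"] * flow,
            "km": c.renal_reabsorption["km"],
        }

    if out.ehr is not None:
        e = out.ehr
        e.vmax_biliary = e.vmax_biliary * flow * mrp2_frac
        e.k_transit *= rate
        e.k_deconjugation *= rate
        e.k_fecal *= rate

    for key, frac in (("hepatic", hep_frac), ("gut", gut_frac), ("mrp2", mrp2_frac)):
        out.provenance[f"ontogeny.{key}_fraction"] = (
            f"derived ({p.life_stage}->{life_stage}, fraction {frac:.4g})")
    report = validate_parameters(out)
    if not report.ok:
        raise ValueError(f"scaled set {p.species}/{life_stage} invalid:\n{report}")
    return out


def extrapolate_monkey_to_human(monkey: ModelParameters,
                                human_physiology: Physiology,
                                life_stage: str,
                                chemical: ChemicalProps | None = None,
                                ) -> ModelParameters:
    """Build a human parameter set from a calibrated monkey set.

    Human physiology replaces monkey physiology; every first-order
    constant is rescaled by (BW_human / BW_monkey)^-0.25; conjugate
    distribution volumes follow body weight and clearances body
    weight^0.75; renal reabsorption of conjugate is removed.  Partition
    coefficients default to the packaged adult-human values (fat:blood
    3.3 from vial equilibration with human tissue).
    """
    if monkey.species != "monkey":
        raise ValueError(f"source species must be monkey, got {monkey.species}")
    bw_ratio = human_physiology.body_weight / monkey.physiology.body_weight
    rate = bw_ratio ** _RATE_EXP
    flow = bw_ratio ** _FLOW_EXP

    if chemical is None:
        chemical = load_adult_parameter_set("human").chemical

    out = monkey.copy()
    out.species = "human"
    out.life_stage = life_stage
    out.physiology = human_physiology
    out.chemical = chemical

    m = out.metabolism
    m.k_hepatic *= rate
    m.k_gut_metabolism *= rate
    m.k_enterocyte_conjugate_efflux *= rate
    m.k_enterocyte_passthrough *= rate
    out.absorption.k_gastric_emptying *= rate
    out.absorption.k_lumen_uptake *= rate

    c = out.conjugate
    c.volumes = [v * bw_ratio for v in c.volumes]
    c.urinary_clearance *= flow
    c.fecal_clearance = 0.0
    c.renal_reabsorption = None  # no direct support for renal recycling in humans

    out.provenance["extrapolation"] = (
        f"monkey {monkey.life_stage} -> human {life_stage}, "
        f"rates x (BW ratio)^-0.25 = {rate:.4g}")
    out.provenance["conjugate.renal_reabsorption"] = "removed for human"
    report = validate_parameters(out)
    if not report.ok:
        raise ValueError(f"extrapolated human/{life_stage} set invalid:\n{report}")
    return out
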