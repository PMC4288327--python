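"""Parameter sets for the BPA PBPK model family.

Each (species, life stage) pair is described by a :class:`ModelParameters`
object bundling physiology (volumes, blood flows), chemical properties
(molecular weights, tissue:blood partition coefficients), metabolic
constants (hepatic and gut conjugation), the rat enterohepatic-recirculation
constants, and the systemic disposition of total BPA conjugates (BPA-c).

Adult sets for rat, monkey and human ship as YAML files under
``data/parameter_sets``; immature life stages are derived from the adult
set via the ontogeny tables (``data/ontogeny``) and allometric scaling, see
:mod:`bpapk.ontogeny_extrapolation`.

Internal units: amounts nmol, volumes L, flows L/h, time h, concentrations
nmol/L.  Mass concentrations (μg/L) appear only at the reporting boundary.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import pandas as pd
import yaml

__all__ = [
    "Physiology",
    "ChemicalProps",
    "MetabolismParams",
    "AbsorptionParams",
    "EhrParams",
    "ConjugateParams",
    "OntogenyTable",
    "ModelParameters",
    "ValidationReport",
    "available_parameter_sets",
    "load_parameter_set",
    "load_adult_parameter_set",
    "load_ontogeny_table",
    "validate_parameters",
    "fold_difference_report",
    "parameters_to_dict",
    "parameters_from_dict",
]

SPECIES = ("rat", "monkey", "human")

#: tissues that must appear in the volume map
VOLUME_KEYS = (
    "venous_blood",
    "arterial_blood",
    "liver",
    "fat",
    "richly_perfused",
    "slowly_perfused",
    "enterocyte",
    "gut_lumen",
)

#: flows that must sum to cardiac output
FLOW_KEYS = ("liver_arterial", "gut_portal", "fat", "richly_perfused", "slowly_perfused")

#: tissues requiring a partition coefficient
PC_KEYS = ("liver", "fat", "richly_perfused", "slowly_perfused")


@dataclass
class Physiology:
    """Body weight, cardiac output, tissue volumes and perfusion flows.

    Volumes in L, flows in L/h, body weight in kg.  ``gut_lumen`` is a
    capacity (the lumen is modelled as an amount pool, not a perfused
    tissue).
    """

    body_weight: float
    cardiac_output: float
    tissue_volumes: dict[str, float]
    tissue_flows: dict[str, float]
    bile_flow: float
    glomerular_filtration: float


@dataclass
class ChemicalProps:
    """Molecular weights and tissue:blood partition coefficients.

    ``molecular_weight_parent`` defaults to deuterated BPA (d6-BPA,
    234.33 g/mol), the tracer used in the kinetic studies the models were
    built on; native BPA is 228.29 g/mol.  Because the model is linear at
    tracer doses, dose metrics expressed in μg/L are insensitive to which
    of the two is used.
    """

    molecular_weight_parent: float
    molecular_weight_conjugate: float
    partition_coefficients: dict[str, float]
    log_kow: float = 3.3


@dataclass
class MetabolismParams:
    """Hepatic and gut-wall conjugation constants.

    Rat hepatic conjugation is Michaelis–Menten (``vmax_hepatic`` nmol/h,
    ``km_hepatic`` nmol/L, from in vitro–to–in vivo extrapolation); monkey
    and human use a first-order constant ``k_hepatic`` (/h) applied to the
    liver venous concentration.  Gut-wall conjugation in the rat is a
    composite first-order term (``k_gut_composite``) that conjugates
    enterocyte BPA and delivers the conjugate instantaneously to the
    portal/systemic conjugate pool; monkey/human conjugate into an explicit
    enterocyte conjugate pool (``k_gut_metabolism``) that empties into
    systemic circulation at ``k_enterocyte_conjugate_efflux``.
    ``k_enterocyte_passthrough`` is the first-order escape of unconjugated
    BPA from enterocytes into portal blood (all species); the gut-wall
    extraction ratio is k_gut/(k_gut + k_passthrough).
    ``fraction_hepatic_conjugate_to_bile`` (rat) routes hepatically formed
    BPA-c to bile, with the small remainder entering systemic circulation.
    """

    hepatic_mode: str  # "michaelis_menten" | "first_order"
    vmax_hepatic: Optional[float] = None
    km_hepatic: Optional[float] = None
    k_hepatic: Optional[float] = None
    k_gut_composite: Optional[float] = None
    k_gut_metabolism: Optional[float] = None
    k_enterocyte_conjugate_efflux: Optional[float] = None
    k_enterocyte_passthrough: float = 0.0
    fraction_hepatic_conjugate_to_bile: Optional[float] = None


@dataclass
class AbsorptionParams:
    """Oral absorption: gastric emptying and gut-lumen uptake (both /h)."""

    k_gastric_emptying: float
    k_lumen_uptake: float


@dataclass
class EhrParams:
    """Rat enterohepatic recirculation loop.

    Biliary excretion of BPA-c is capacity-limited (``vmax_biliary``
    nmol/h, ``km_biliary`` nmol/L, acting on the central conjugate pool).
    Bile passes through ``n_transit`` first-order transit compartments
    (``k_transit`` /h) to the terminal small intestine, where bacteria
    deconjugate BPA-c at ``k_deconjugation``.  Of the liberated BPA,
    ``fraction_reconjugated`` (0.90) re-enters enterocytes and is
    re-conjugated to the systemic conjugate pool, ``fraction_reabsorbed_parent``
    is reabsorbed to portal blood as parent, and the remainder is excreted
    in feces unconjugated.  Unconverted terminal conjugate passes to feces
    at ``k_fecal``.
    """

    vmax_biliary: float
    km_biliary: float
    n_transit: int
    k_transit: float
    k_deconjugation: float
    fraction_reconjugated: float
    fraction_reabsorbed_parent: float
    k_fecal: float

    @property
    def fraction_fecal_parent(self) -> float:
        return 1.0 - self.fraction_reconjugated - self.fraction_reabsorbed_parent


@dataclass
class ConjugateParams:
    """Systemic disposition of total BPA conjugates.

    One central compartment (monkey, human) or central plus two peripheral
    compartments (rat).  Elimination is urinary (``urinary_clearance``
    L/h on the central concentration), optionally opposed in the monkey by
    capacity-limited renal reabsorption (Michaelis–Menten return from the
    filtration flux), plus a small first-order fecal clearance
    (``fecal_clearance``, monkey) standing in for minor non-urinary loss.
    """

    n_compartments: int
    volumes: list[float]
    inter_compartment_rates: list[float]
    urinary_clearance: float
    renal_reabsorption: Optional[dict[str, float]] = None  # {"vmax", "km"}
    fecal_clearance: float = 0.0


@dataclass
class OntogenyTable:
    """Maturation fractions by life stage for one species."""

    species: str
    frame: pd.DataFrame  # columns: life_stage, body_weight, hepatic_..., gut_..., mrp2_...

    def stages(self) -> list[str]:
        return list(self.frame["life_stage"])

    def row(self, life_stage: str) -> pd.Series:
        m = self.frame[self.frame["life_stage"] == life_stage]
        if m.empty:
            raise KeyError(
                f"unknown life stage {life_stage!r} for {self.species}; "
                f"available: {', '.join(self.stages())}"
            )
        return m.iloc[0]


@dataclass
class ModelParameters:
    """Complete parameterization of one (species, life stage) model."""

    species: str
    life_stage: str
    physiology: Physiology
    chemical: ChemicalProps
    metabolism: MetabolismParams
    absorption: AbsorptionParams
    conjugate: ConjugateParams
    ehr: Optional[EhrParams] = None
    provenance: dict[str, str] = field(default_factory=dict)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


@dataclass
class ValidationReport:
    """List of invariant violations; empty means the set is valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)

    def to_json(self) -> dict:
        return {"ok": self.ok, "violations": list(self.violations)}

    def __str__(self) -> str:
        if self.ok:
            return "parameter set valid (no violations)"
        return "parameter set INVALID:\n" + "\n".join(f"  - {v}" for v in self.violations)


# ---------------------------------------------------------------------------
# Loading


def _data_dir():
    return resources.files("bpapk") / "data"


def available_parameter_sets() -> dict[str, list[str]]:
    """Map species -> life stages that :func:`load_parameter_set` accepts."""
    out: dict[str, list[str]] = {}
    for sp in SPECIES:
        stages = ["adult"]
        try:
            tab = load_ontogeny_table(sp)
            stages = [s for s in tab.stages() if s != "adult"] + ["adult"]
        except FileNotFoundError:
            pass
        if sp == "human":
            stages.append("newborn")
        out[sp] = stages
    return out


def load_adult_parameter_set(species: str) -> ModelParameters:
    """Load the packaged adult YAML set for a species."""
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}; available: {', '.join(SPECIES)}")
    path = _data_dir() / "parameter_sets" / f"{species}_adult.yaml"
    with resources.as_file(path) as p:
        if not p.exists():
            raise FileNotFoundError(f"no packaged parameter file for {species} adult: {p}")
        raw = yaml.safe_load(p.read_text())
    params = parameters_from_dict(raw)
    report = validate_parameters(params)
    if not report.ok:
        raise ValueError(f"packaged set {species}/adult fails validation:\n{report}")
    return params


def load_parameter_set(species: str, life_stage: str) -> ModelParameters:
    """Return a validated ModelParameters for (species, life_stage).

    Adult sets are read from the packaged YAML files.  Immature rat and
    monkey stages are derived from the adult set through the packaged
    ontogeny table (allometric scaling plus maturation fractions).  The
    human "newborn" set is the newborn-monkey (PND5) model extrapolated to
    newborn-human physiology.
    """
    from . import ontogeny_extrapolation as ont  # deferred: avoid import cycle

    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}; available: {', '.join(SPECIES)}")
    if life_stage == "adult":
        return load_adult_parameter_set(species)
    if species == "human":
        if life_stage == "newborn":
            monkey = load_parameter_set("monkey", "PND5")
            newborn_phys = load_newborn_human_physiology()
            return ont.extrapolate_monkey_to_human(monkey, newborn_phys, "newborn")
        raise KeyError("unknown human life stage %r; available: newborn, adult" % life_stage)
    table = load_ontogeny_table(species)
    if life_stage not in table.stages():
        raise KeyError(
            f"unknown life stage {life_stage!r} for {species}; "
            f"available: {', '.join(table.stages())}"
        )
    adult = load_adult_parameter_set(species)
    return ont.scale_for_age(adult, table, life_stage)


def load_ontogeny_table(species: str) -> OntogenyTable:
    """Load the packaged maturation table (rat or monkey)."""
    path = _data_dir() / "ontogeny" / f"{species}.csv"
    with resources.as_file(path) as p:
        if not p.exists():
            raise FileNotFoundError(f"no ontogeny table for {species}")
        frame = pd.read_csv(p)
    required = {
        "life_stage",
        "body_weight",
        "hepatic_fraction_of_adult",
        "gut_fraction_of_adult",
        "mrp2_fraction_of_adult",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"ontogeny table for {species} missing columns: {sorted(missing)}")
    return OntogenyTable(species=species, frame=frame)


def load_newborn_human_physiology() -> Physiology:
    """Newborn-human physiology used by the monkey-to-human extrapolation."""
    path = _data_dir() / "parameter_sets" / "human_newborn_physiology.yaml"
    with resources.as_file(path) as p:
        raw = yaml.safe_load(p.read_text())
    return Physiology(**raw["physiology"])


# ---------------------------------------------------------------------------
# Serialization (round-trip YAML)


def parameters_to_dict(p: ModelParameters) -> dict:
    d: dict = {
        "schema_version": 1,
        "species": p.species,
        "life_stage": p.life_stage,
        "physiology": {
            "body_weight": p.physiology.body_weight,
            "cardiac_output": p.physiology.cardiac_output,
            "tissue_volumes": dict(p.physiology.tissue_volumes),
            "tissue_flows": dict(p.physiology.tissue_flows),
            "bile_flow": p.physiology.bile_flow,
            "glomerular_filtration": p.physiology.glomerular_filtration,
        },
        "chemical": {
            "molecular_weight_parent": p.chemical.molecular_weight_parent,
            "molecular_weight_conjugate": p.chemical.molecular_weight_conjugate,
            "partition_coefficients": dict(p.chemical.partition_coefficients),
            "log_kow": p.chemical.log_kow,
        },
        "metabolism": {k: v for k, v in vars(p.metabolism).items() if v is not None},
        "absorption": dict(vars(p.absorption)),
        "conjugate": {
            "n_compartments": p.conjugate.n_compartments,
            "volumes": list(p.conjugate.volumes),
            "inter_compartment_rates": list(p.conjugate.inter_compartment_rates),
            "urinary_clearance": p.conjugate.urinary_clearance,
            "fecal_clearance": p.conjugate.fecal_clearance,
        },
        "provenance": dict(p.provenance),
    }
    if p.conjugate.renal_reabsorption is not None:
        d["conjugate"]["renal_reabsorption"] = dict(p.conjugate.renal_reabsorption)
    if p.ehr is not None:
        d["ehr"] = dict(vars(p.ehr))
    return d


def parameters_from_dict(raw: dict) -> ModelParameters:
    try:
        phys = Physiology(**raw["physiology"])
        chem = ChemicalProps(**raw["chemical"])
        metab = MetabolismParams(**raw["metabolism"])
        absorb = AbsorptionParams(**raw["absorption"])
        conj = ConjugateParams(**raw["conjugate"])
        ehr = EhrParams(**raw["ehr"]) if "ehr" in raw else None
    except (KeyError, TypeError) as exc:
        raise ValueError(f"parameter schema violation: {exc}") from exc
    return ModelParameters(
        species=raw["species"],
        life_stage=raw["life_stage"],
        physiology=phys,
        chemical=chem,
        metabolism=metab,
        absorption=absorb,
        conjugate=conj,
        ehr=ehr,
        provenance=raw.get("provenance", {}),
    )


def save_parameter_set(p: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(p), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Validation


def validate_parameters(p: ModelParameters) -> ValidationReport:
    """Check every structural and numeric invariant; return a report.

    The report lists each violated invariant with the offending parameter
    named; an empty report means the set is internally consistent.
    """
    rep = ValidationReport()
    ph = p.physiology

    if p.species not in SPECIES:
        rep.add(f"species: unknown species {p.species!r}")

    for key in VOLUME_KEYS:
        if key not in ph.tissue_volumes:
            rep.add(f"tissue_volumes: missing tissue {key!r}")
        elif ph.tissue_volumes[key] <= 0:
            rep.add(f"tissue_volumes[{key}]: must be > 0, got {ph.tissue_volumes[key]}")
    for key in FLOW_KEYS:
        if key not in ph.tissue_flows:
            rep.add(f"tissue_flows: missing flow {key!r}")
        elif ph.tissue_flows[key] <= 0:
            rep.add(f"tissue_flows[{key}]: must be > 0, got {ph.tissue_flows[key]}")
    if ph.body_weight <= 0:
        rep.add(f"body_weight: must be > 0, got {ph.body_weight}")
    if ph.cardiac_output <= 0:
        rep.add(f"cardiac_output: must be > 0, got {ph.cardiac_output}")

    if all(k in ph.tissue_flows for k in FLOW_KEYS):
        total_flow = sum(ph.tissue_flows[k] for k in FLOW_KEYS)
        if not math.isclose(total_flow, ph.cardiac_output, rel_tol=1e-9):
            rep.add(
                "tissue_flows: sum of perfusion flows "
                f"({total_flow:.6g} L/h) != cardiac_output ({ph.cardiac_output:.6g} L/h)"
            )
    if all(k in ph.tissue_volumes for k in VOLUME_KEYS):
        # density 1 kg/L; lumen capacity excluded from the anatomical budget
        vol = sum(v for k, v in ph.tissue_volumes.items() if k != "gut_lumen")
        if vol > ph.body_weight * (1 + 1e-9):
            rep.add(
                f"tissue_volumes: total {vol:.4g} L exceeds body weight "
                f"{ph.body_weight:.4g} kg at density 1 kg/L"
            )

    pcs = p.chemical.partition_coefficients
    for key in PC_KEYS:
        if key not in pcs:
            rep.add(f"partition_coefficients: missing tissue {key!r}")
        elif pcs[key] <= 0:
            rep.add(f"partition_coefficients[{key}]: must be > 0, got {pcs[key]}")
    if "fat" in pcs and not (1.0 <= pcs["fat"] <= 20.0):
        rep.add(f"partition_coefficients[fat]: expected within [1, 20], got {pcs['fat']}")

    m = p.metabolism
    if m.hepatic_mode == "michaelis_menten":
        if m.vmax_hepatic is None or m.km_hepatic is None:
            rep.add("metabolism: michaelis_menten mode requires vmax_hepatic and km_hepatic")
        else:
            if m.vmax_hepatic <= 0:
                rep.add(f"metabolism.vmax_hepatic: must be > 0, got {m.vmax_hepatic}")
            if m.km_hepatic <= 0:
                rep.add(f"metabolism.km_hepatic: must be > 0, got {m.km_hepatic}")
    elif m.hepatic_mode == "first_order":
        if m.k_hepatic is None or m.k_hepatic <= 0:
            rep.add("metabolism.k_hepatic: first_order mode requires k_hepatic > 0")
    else:
        rep.add(f"metabolism.hepatic_mode: unknown mode {m.hepatic_mode!r}")

    if p.species == "rat":
        if m.k_gut_composite is None or m.k_gut_composite < 0:
            rep.add("metabolism.k_gut_composite: rat requires k_gut_composite >= 0")
        if m.fraction_hepatic_conjugate_to_bile is None:
            rep.add("metabolism.fraction_hepatic_conjugate_to_bile: required for rat")
        elif not (0.99 <= m.fraction_hepatic_conjugate_to_bile <= 1.0):
            rep.add(
                "metabolism.fraction_hepatic_conjugate_to_bile: must be >= 0.99 "
                "(less than 1% of hepatic BPA-c enters systemic circulation), got "
                f"{m.fraction_hepatic_conjugate_to_bile}"
            )
        if p.ehr is None:
            rep.add("ehr: rat parameter set requires enterohepatic recirculation block")
    else:
        if p.ehr is not None:
            rep.add(f"ehr: must be absent for {p.species}")
        if m.k_gut_metabolism is None or m.k_gut_metabolism < 0:
            rep.add(f"metabolism.k_gut_metabolism: {p.species} requires k_gut_metabolism >= 0")
        if m.k_enterocyte_conjugate_efflux is None or m.k_enterocyte_conjugate_efflux <= 0:
            rep.add(
                f"metabolism.k_enterocyte_conjugate_efflux: {p.species} requires a value > 0"
            )

    if p.ehr is not None:
        e = p.ehr
        for name in ("vmax_biliary", "km_biliary", "k_transit", "k_deconjugation", "k_fecal"):
            if getattr(e, name) < 0:
                rep.add(f"ehr.{name}: must be >= 0, got {getattr(e, name)}")
        if e.n_transit < 0:
            rep.add(f"ehr.n_transit: must be >= 0, got {e.n_transit}")
        split = e.fraction_reconjugated + e.fraction_reabsorbed_parent + e.fraction_fecal_parent
        if not math.isclose(split, 1.0, rel_tol=0, abs_tol=1e-12):
            rep.add("ehr: deconjugated-parent fractions do not sum to 1")
        if not (0 <= e.fraction_reabsorbed_parent <= 1 - e.fraction_reconjugated):
            rep.add(
                "ehr.fraction_reabsorbed_parent: must lie in "
                f"[0, {1 - e.fraction_reconjugated:.3g}], got {e.fraction_reabsorbed_parent}"
            )

    c = p.conjugate
    expected_n = 3 if p.species == "rat" else 1
    if c.n_compartments != expected_n:
        rep.add(
            f"conjugate.n_compartments: {p.species} model uses {expected_n}, got {c.n_compartments}"
        )
    if len(c.volumes) != c.n_compartments:
        rep.add(
            f"conjugate.volumes: expected {c.n_compartments} entries, got {len(c.volumes)}"
        )
    if any(v <= 0 for v in c.volumes):
        rep.add("conjugate.volumes: all volumes must be > 0")
    if len(c.inter_compartment_rates) != max(c.n_compartments - 1, 0):
        rep.add(
            "conjugate.inter_compartment_rates: expected "
            f"{max(c.n_compartments - 1, 0)} distribution clearances, got "
            f"{len(c.inter_compartment_rates)}"
        )
    if c.urinary_clearance < 0:
        rep.add(f"conjugate.urinary_clearance: must be >= 0, got {c.urinary_clearance}")
    if c.fecal_clearance < 0:
        rep.add(f"conjugate.fecal_clearance: must be >= 0, got {c.fecal_clearance}")
    if p.species == "monkey":
        if c.renal_reabsorption is None:
            rep.add("conjugate.renal_reabsorption: required for monkey")
        else:
            if c.renal_reabsorption.get("vmax", -1) < 0:
                rep.add("conjugate.renal_reabsorption.vmax: must be >= 0")
            if c.renal_reabsorption.get("km", 0) <= 0:
                rep.add("conjugate.renal_reabsorption.km: must be > 0")
    elif c.renal_reabsorption is not None:
        rep.add(f"conjugate.renal_reabsorption: must be absent for {p.species}")

    if p.absorption.k_gastric_emptying < 0 or p.absorption.k_lumen_uptake < 0:
        rep.add("absorption: rate constants must be >= 0")

    return rep


# ---------------------------------------------------------------------------
# Ontogeny fold differences


def fold_difference_report(table: OntogenyTable) -> dict[str, float]:
    """Hepatic-capacity fold difference of each life stage versus the adult.

    The hepatic conjugation capacity at a stage is the maturation fraction
    times the adult capacity scaled allometrically (body weight to the 3/4
    power) to that stage's body weight.  The fold difference is
    adult capacity / stage capacity, so the adult row reports exactly 1 and
    immature stages report values > 1.
    """
    frame = table.frame
    adult = frame[frame["life_stage"] == "adult"]
    if adult.empty:
        raise ValueError(f"ontogeny table for {table.species} has no adult row")
    bw_adult = float(adult.iloc[0]["body_weight"])
    out: dict[str, float] = {}
    for _, row in frame.iterrows():
        scaled = (float(row["body_weight"]) / bw_adult) ** 0.75
        capacity = float(row["hepatic_fraction_of_adult"]) * scaled
        out[str(row["life_stage"])] = 1.0 / capacity
    return out
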