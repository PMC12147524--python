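"""Mass bookkeeping for the pic-borane reduction cascade of 5-formylcytosine.

Pic-borane (2-picoline borane) reduces an f5C base embedded in an RNA oligo
through three successive chemical steps:

1. 3,4-reduction of the pyrimidine ring      (f5C  -> DHf5C, net +H2)
2. deformylation, formyl replaced by H       (DHf5C -> DHC,  net -CO)
3. deamination, exocyclic NH2 replaced by OH (DHC  -> DHU,  net -NH2 +OH)

The end product dihydrouracil (DHU) is read as T by reverse transcriptase,
which is what turns the modification into a C-to-T sequencing signature.
This module tracks the elemental mass deltas of each step so that MALDI-TOF
peaks of reduction intermediates can be predicted from the intact-probe mass
and observed peaks can be assigned to species.

Masses are carried on two scales: ``avg`` (standard average atomic masses)
and ``mono`` (monoisotopic).  All operations work on mass deltas applied to
a supplied starting mass; de novo oligo mass computation from sequence is
out of scope.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Step",
    "Label",
    "ReactionStep",
    "OligoSpecies",
    "REDUCTION_34",
    "DEFORMYLATION",
    "DEAMINATION",
    "CASCADE",
    "apply_reaction",
    "apply_cascade",
    "predict_peaks",
    "assign_peak",
    "round_dalton",
]

# Average atomic masses (IUPAC standard atomic weights, 4-5 sig figs) and
# monoisotopic masses of the relevant elements.
_AVG = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}
_MONO = {"H": 1.0078250319, "C": 12.0, "N": 14.0030740052, "O": 15.9949146221}


class Step(enum.Enum):
    REDUCTION_34 = "reduction_34"
    DEFORMYLATION = "deformylation"
    DEAMINATION = "deamination"


class Label(enum.Enum):
    F5C = "f5C"
    DHF5C = "DHf5C"
    DHC = "DHC"
    DHU = "DHU"


def _delta(formula: dict[str, int], table: dict[str, float]) -> float:
    return sum(n * table[el] for el, n in formula.items())


@dataclass(frozen=True)
class ReactionStep:
    """One step of the reduction cascade as a signed elemental delta."""

    name: Step
    formula_delta: dict[str, int]

    @property
    def mass_delta_avg(self) -> float:
        return _delta(self.formula_delta, _AVG)

    @property
    def mass_delta_mono(self) -> float:
        return _delta(self.formula_delta, _MONO)

    def mass_delta(self, scale: str) -> float:
        if scale == "avg":
            return self.mass_delta_avg
        if scale == "mono":
            return self.mass_delta_mono
        raise ValueError(f"unknown mass scale {scale!r}; expected 'avg' or 'mono'")


#: 3,4-reduction saturates the C3=C4 bond: two hydrogens are added.
REDUCTION_34 = ReactionStep(Step.REDUCTION_34, {"H": 2})
#: Deformylation swaps CHO for H: net loss of one CO unit.
DEFORMYLATION = ReactionStep(Step.DEFORMYLATION, {"C": -1, "O": -1})
#: Deamination swaps NH2 for OH: net -N -H +O.
DEAMINATION = ReactionStep(Step.DEAMINATION, {"N": -1, "H": -1, "O": 1})

#: The cascade in its observed order (deformylation precedes deamination).
CASCADE: tuple[ReactionStep, ...] = (REDUCTION_34, DEFORMYLATION, DEAMINATION)

# label before -> (legal step, label after)
_SUCCESSOR: dict[Label, tuple[ReactionStep, Label]] = {
    Label.F5C: (REDUCTION_34, Label.DHF5C),
    Label.DHF5C: (DEFORMYLATION, Label.DHC),
    Label.DHC: (DEAMINATION, Label.DHU),
}


class CascadeOrderError(ValueError):
    """Raised when a reduction step is applied out of cascade order."""


class PeakAmbiguityError(ValueError):
    """Raised when more than one candidate species lies within tolerance."""


@dataclass(frozen=True)
class OligoSpecies:
    """An oligo carrying the base at one stage of the reduction cascade."""

    label: Label
    mass: float
    provenance: tuple[Step, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"species mass must be strictly positive, got {self.mass}")


def round_dalton(mass: float) -> int:
    """Round to the nearest integer Dalton, half away from zero.

    Matches the convention of printed MALDI peak labels (1555, 1557, ...).
    """
    return int(math.floor(mass + 0.5)) if mass >= 0 else -int(math.floor(-mass + 0.5))


def apply_reaction(
    species: OligoSpecies, step: ReactionStep, scale: str = "avg"
) -> OligoSpecies:
    """Apply one cascade step to *species*, returning the product species.

    The step must be the legal successor of the species' current stage
    (f5C -> DHf5C -> DHC -> DHU); anything else raises
    :class:`CascadeOrderError` naming the expected step.
    """
    if species.label is Label.DHU:
        raise CascadeOrderError(
            "DHU is the cascade end product; no further step applies"
        )
    expected, next_label = _SUCCESSOR[species.label]
    if step.name is not expected.name:
        raise CascadeOrderError(
            f"{step.name.name} cannot be applied to {species.label.value}; "
            f"expected {expected.name.name}"
        )
    return OligoSpecies(
        label=next_label,
        mass=species.mass + step.mass_delta(scale),
        provenance=species.provenance + (step.name,),
    )


def apply_cascade(
    species: OligoSpecies, steps: list[ReactionStep] | tuple[ReactionStep, ...] = (),
    scale: str = "avg",
) -> OligoSpecies:
    """Apply a sequence of steps in order; an empty sequence is the identity."""
    for step in steps:
        species = apply_reaction(species, step, scale=scale)
    return species


def cascade_species(start_mass: float, scale: str = "avg") -> list[OligoSpecies]:
    """All four cascade species (f5C, DHf5C, DHC, DHU) from a start mass."""
    out = [OligoSpecies(Label.F5C, start_mass)]
    for step in CASCADE:
        out.append(apply_reaction(out[-1], step, scale=scale))
    return out


def predict_peaks(
    start_mass: float, condition: str, scale: str = "avg"
) -> list[tuple[Label, float]]:
    """Predict the MALDI peak set for a reduction condition.

    ``low`` (25 degC): the reaction stalls after 3,4-reduction — the major
    product is DHf5C, with residual intact f5C and a minor deformylated DHC
    intermediate.  ``high`` (70 degC): the cascade runs to completion and
    DHU is the sole product.
    """
    if not start_mass > 0:
        raise ValueError(f"start mass must be positive, got {start_mass}")
    species = {s.label: s for s in cascade_species(start_mass, scale=scale)}
    cond = condition.lower()
    if cond in ("low", "low_temp"):
        keep = [Label.F5C, Label.DHF5C, Label.DHC]
    elif cond in ("high", "high_temp"):
        keep = [Label.DHU]
    else:
        raise ValueError(f"unknown condition {condition!r}; expected 'low' or 'high'")
    return [(lab, species[lab].mass) for lab in keep]


def assign_peak(
    observed_mz: float, candidates: list[OligoSpecies], tol: float
) -> Label | None:
    """Assign an observed m/z to the unique candidate within *tol* Daltons.

    Returns ``None`` when no candidate is within tolerance and raises
    :class:`PeakAmbiguityError` when the assignment is not unique, so that
    a symmetric tie can never be broken silently.
    """
    if not tol > 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    hits = [c for c in candidates if abs(c.mass - observed_mz) <= tol]
    if not hits:
        return None
    if len(hits) > 1:
        names = ", ".join(f"{c.label.value}@{c.mass:.3f}" for c in hits)
        raise PeakAmbiguityError(
            f"m/z {observed_mz} matches multiple candidates within {tol} Da: {names}"
        )
    return hits[0].label
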