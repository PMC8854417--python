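"""Derivation of analysis traits from raw linear SEM measurements.

The compound eye is approximated as a spherical shell: with W the eye width
in anterior view and L the mean of eye height and lateral eye width, the
shell area is

    E_area = 2*pi*W * (L**2 + W**2) / (2*W) = pi * (L**2 + W**2),

i.e. a hemisphere of radius L when all three chords coincide.  Ommatidia
are regular hexagons of measured circumradius r (half the apex-to-apex
diameter) with area 2.598 * r**2; the ommatidium count is the eye area
divided by the mean ommatidial area; and the mean interommatidial angle of
a hexagonally packed hemispheric eye is

    delta_gamma = sqrt(K / OM_number)   [degrees]

with K = 23818 deg^2 by default.  Body mass follows the brachyceran
allometry mass[mg] = 0.655 * H_width[mm]**2.526.

Derivations are applied per specimen and then averaged into species means
with standard errors (sd/sqrt(n)); because the count is a ratio, the mean
of per-specimen counts differs from the ratio of mean areas by a Jensen
gap of the order of the squared specimen-level coefficient of variation.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
import pandas as pd

from .io_fixtures import SpeciesTraitTable, SpecimenMeasurements

#: hexagonal-packing constant of the hemispheric-eye angle formula, deg^2
DELTA_GAMMA_CONSTANT = 23818.0

#: brachyceran head-width allometry: mass[mg] = a * H_width[mm] ** b
BODY_MASS_COEF = 0.655
BODY_MASS_EXP = 2.526

_HEX_AREA_CONSTANT = 2.598  # rounded 3*sqrt(3)/2; kept as fixed constant


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not (np.asarray(v) > 0).all():
            raise ValueError(f"{name} must be strictly positive, got {v!r}")


def eye_area(E_widthA: float, E_height: float, E_widthL: float) -> float:
    """Spherical-shell eye area (um^2) from the three eye chords (um)."""
    _require_positive(E_widthA=E_widthA, E_height=E_height, E_widthL=E_widthL)
    W = np.asarray(E_widthA, dtype=float)
    L = (np.asarray(E_height, dtype=float) + np.asarray(E_widthL, dtype=float)) / 2.0
    out = 2.0 * np.pi * W * (L**2 + W**2) / (2.0 * W)
    return float(out) if np.isscalar(E_widthA) else out


def ommatidium_area(hex_diameter: float) -> float:
    """Hexagonal facet area (um^2) from the apex-to-apex diameter (um)."""
    _require_positive(hex_diameter=hex_diameter)
    radius = np.asarray(hex_diameter, dtype=float) / 2.0
    out = _HEX_AREA_CONSTANT * radius**2
    return float(out) if np.isscalar(hex_diameter) else out


def ommatidia_number(E_area: float, mean_OM_area: float) -> float:
    """Real-valued ommatidium count: eye area / mean facet area."""
    _require_positive(E_area=E_area, mean_OM_area=mean_OM_area)
    out = np.asarray(E_area, dtype=float) / np.asarray(mean_OM_area, dtype=float)
    return float(out) if np.isscalar(E_area) else out


def interommatidial_angle(
    OM_number: float, constant: float = DELTA_GAMMA_CONSTANT
) -> float:
    """Mean interommatidial angle (degrees) of an eye with ``OM_number`` facets."""
    _require_positive(OM_number=OM_number, constant=constant)
    out = np.sqrt(constant / np.asarray(OM_number, dtype=float))
    return float(out) if np.isscalar(OM_number) else out


def body_mass(H_width_mm: float) -> float:
    """Dry body mass (mg) from head width (mm) via the brachyceran allometry."""
    _require_positive(H_width_mm=H_width_mm)
    out = BODY_MASS_COEF * np.asarray(H_width_mm, dtype=float) ** BODY_MASS_EXP
    return float(out) if np.isscalar(H_width_mm) else out


def relative_trait(trait: float, H_width: float):
    """Size-relative trait value: trait / head width x 100 (dimensionless)."""
    _require_positive(H_width=H_width)
    out = np.asarray(trait, dtype=float) / np.asarray(H_width, dtype=float) * 100.0
    return float(out) if np.isscalar(trait) else out


def derive_specimen(
    specimen: SpecimenMeasurements,
    delta_gamma_constant: float = DELTA_GAMMA_CONSTANT,
) -> dict[str, float]:
    """All derivable analysis traits of one specimen (missing -> absent key)."""
    out: dict[str, float] = {}
    for name in ("H_width", "OC_diameter", "F_length", "P_length", "A_length"):
        v = getattr(specimen, name)
        if v is not None:
            out[name] = v
    if all(k in out for k in ("F_length", "P_length", "A_length")):
        out["ANT_length"] = out["F_length"] + out["P_length"] + out["A_length"]
    eye_ok = all(
        getattr(specimen, k) is not None for k in ("E_widthA", "E_height", "E_widthL")
    )
    if eye_ok:
        out["E_area"] = eye_area(
            specimen.E_widthA, specimen.E_height, specimen.E_widthL
        )
    if specimen.OM_diameters:
        out["OM_area"] = float(
            np.mean([ommatidium_area(d) for d in specimen.OM_diameters])
        )
    if eye_ok and specimen.OM_diameters:
        out["OM_number"] = ommatidia_number(out["E_area"], out["OM_area"])
        out["delta_gamma"] = interommatidial_angle(
            out["OM_number"], constant=delta_gamma_constant
        )
    if "H_width" in out:
        out["body_mass"] = body_mass(out["H_width"] / 1000.0)
    return out


def aggregate_species(
    specimens: list[SpecimenMeasurements],
    delta_gamma_constant: float = DELTA_GAMMA_CONSTANT,
) -> SpeciesTraitTable:
    """Species means and standard errors of per-specimen derived traits.

    Each specimen is first converted to its derived traits and only then
    averaged (the trait derivations are nonlinear, so the order matters).
    SE = sd/sqrt(n) with ddof=1; reported as missing when n = 1.
    """
    if not specimens:
        raise ValueError("no specimens")
    by_species: dict[str, list[dict[str, float]]] = defaultdict(list)
    for sp in specimens:
        derived = derive_specimen(sp, delta_gamma_constant=delta_gamma_constant)
        if not derived:
            continue
        by_species[sp.species_id].append(derived)
    if not by_species:
        raise ValueError("no species with usable specimens")

    rows = {}
    for species, records in by_species.items():
        traits = sorted({k for r in records for k in r})
        row = {}
        for trait in traits:
            vals = np.array([r[trait] for r in records if trait in r], dtype=float)
            row[f"{trait}_mean"] = float(vals.mean())
            row[f"{trait}_se"] = (
                float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
            row[f"{trait}_n"] = len(vals)
        rows[species] = row
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "species_id"
    return SpeciesTraitTable(df)
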