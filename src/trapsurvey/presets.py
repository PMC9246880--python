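"""Species presets and the standard / alternative survey designs.

Two well-studied target insects are bundled:

* **leek moth** (*Acrolepiopsis assectella*) — a weak flyer, D = 500 m²/day,
  surveyed with highly attractive pheromone sticky-wing traps
  (1/λ = 20 m, with 10 m as a conservative alternative), standard 8-km
  square grid at a uniform ~13.9 traps/km² (900 traps), unit cost $28 per
  trap per 30-day survey.
* **Medfly** (*Ceratitis capitata*) — a moderate disperser, D = 5,000 m²/day,
  trimedlure traps (1/λ = 10 m), standard 14.5-km square grid with variable
  band densities 38.6/18.9/9.7/7.7/3.5 traps/km², unit cost $26.

The printed standard trap totals used for costing (900 and 1,700) are kept
alongside the constructed layouts; the Medfly band structure itself sums to
1,660 traps, and both totals are surfaced in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .grids import Band, GridDesign

#: default circular band outer radii (m): core disc 0.8 km, annuli to 2.4 / 4.0 km
CIRCULAR_RADII_M = (800.0, 2400.0, 4000.0)

#: uniform densities tested for the leek moth grid (traps per km²)
SWEEP_DENSITIES = (3.5, 6.2, 9.7, 13.9, 18.9, 24.7, 31.3, 38.6)


@dataclass(frozen=True)
class SpeciesPreset:
    """Bundled movement, trap and cost parameters for one target insect."""

    name: str
    D: float                      # diffusion coefficient, m²/day
    lam_inv_m: float              # default trap attraction length, m
    unit_cost_usd: float          # per trap per 30-day survey
    standard_grid: GridDesign
    containment_grid: GridDesign
    printed_standard_traps: int   # trap total the published costing uses
    alt_lam_inv_m: float | None = None


def _square(side_cells: int, densities: tuple[float, ...], lam_inv: float) -> GridDesign:
    bands = tuple(Band(i + 1, d) for i, d in enumerate(densities))
    return GridDesign(shape="square", side_cells=side_cells, bands=bands,
                      trap_attractiveness_m=lam_inv)


def circular_design(diameter_km: float, densities: tuple[float, ...],
                    lam_inv: float) -> GridDesign:
    """Circular design with the default core/annulus radii out to diameter/2."""
    radius_m = diameter_km * 1000.0 / 2.0
    radii = tuple(r for r in CIRCULAR_RADII_M if r < radius_m) + (radius_m,)
    radii = tuple(dict.fromkeys(radii))  # drop a duplicate outer edge
    if len(densities) != len(radii):
        raise ValueError(
            f"{diameter_km}-km circle has {len(radii)} bands, "
            f"got {len(densities)} densities")
    bands = tuple(Band(i + 1, d) for i, d in enumerate(densities))
    return GridDesign(shape="circular", bands=bands, band_radii_m=radii,
                      trap_attractiveness_m=lam_inv)


def perimeter_design(inner_m: float, width_m: float, density: float,
                     lam_inv: float) -> GridDesign:
    return GridDesign(shape="perimeter", bands=(Band(1, density),),
                      perimeter_inner_m=inner_m, perimeter_width_m=width_m,
                      trap_attractiveness_m=lam_inv)


#: containment tests use a deliberately high attractiveness so that any
#: egressing insect is very likely to register
CONTAINMENT_LAM_INV_M = 30.0

LEEK_MOTH = SpeciesPreset(
    name="leek_moth",
    D=500.0,
    lam_inv_m=20.0,
    alt_lam_inv_m=10.0,
    unit_cost_usd=28.0,
    standard_grid=_square(5, (13.9, 13.9, 13.9), 20.0),
    containment_grid=perimeter_design(4000.0, 1600.0, 13.9, CONTAINMENT_LAM_INV_M),
    printed_standard_traps=900,
)

MEDFLY = SpeciesPreset(
    name="medfly",
    D=5000.0,
    lam_inv_m=10.0,
    unit_cost_usd=26.0,
    standard_grid=_square(9, (38.6, 18.9, 9.7, 7.7, 3.5), 10.0),
    containment_grid=perimeter_design(7240.0, 1600.0, 38.6, CONTAINMENT_LAM_INV_M),
    printed_standard_traps=1700,
)

SPECIES: dict[str, SpeciesPreset] = {p.name: p for p in (LEEK_MOTH, MEDFLY)}


def medfly_alternatives(lam_inv: float = MEDFLY.lam_inv_m) -> dict[str, GridDesign]:
    """The four circular alternatives to the standard Medfly grid.

    All keep the default core density (38.6 traps/km²); they differ in
    diameter and outer-band density.
    """
    return {
        "alternative_1": circular_design(4.8, (38.6, 18.9), lam_inv),
        "alternative_2": circular_design(4.8, (38.6, 13.9), lam_inv),
        "alternative_3": circular_design(4.8, (38.6, 9.7), lam_inv),
        "alternative_4": GridDesign(
            shape="circular", bands=(Band(1, 38.6), Band(2, 6.2)),
            band_radii_m=(800.0, 3200.0), trap_attractiveness_m=lam_inv),
    }
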