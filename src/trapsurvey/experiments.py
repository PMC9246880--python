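"""Survey-evaluation experiments: band contributions, density sweeps,
containment tests, and the cost / return-on-investment comparison of
alternative grid designs.

Each experiment wraps the Monte-Carlo capture engine around a family of
layouts derived from a base design and returns tidy DataFrames shaped like
the corresponding published summary tables.  ROI is defined as the capture
percentage obtained per $1,000 of trap purchase-and-servicing cost:

    ROI = 100 · p(capture) / (total_cost / 1000)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .capture import SimConfig, SimResult, run_simulation
from .dispersal import DispersalParams
from .grids import GridDesign, TrapLayout, build_layout
from .presets import SpeciesPreset


@dataclass(frozen=True)
class CostModel:
    """Unit cost of buying and servicing one trap for a 30-day survey."""

    unit_cost_usd: float

    def __post_init__(self) -> None:
        if self.unit_cost_usd < 0:
            raise ValueError("unit cost must be >= 0")


@dataclass(frozen=True)
class CostReport:
    """Trap count, total cost, capture probability and ROI for one design."""

    n_traps: int
    total_cost_usd: float
    p_capture: float
    roi: float


def cost_roi(n_traps: int, cost_model: CostModel, p_capture: float) -> CostReport:
    """Cost and ROI of a design/result pair.

    ROI is capture percentage points per $1,000 spent; it is undefined (and
    raises) for a free survey that still captures something.
    """
    if n_traps < 0 or not 0.0 <= p_capture <= 1.0:
        raise ValueError("n_traps must be >= 0 and p_capture in [0, 1]")
    total = n_traps * cost_model.unit_cost_usd
    if total == 0:
        if p_capture > 0:
            raise ZeroDivisionError("ROI undefined: zero cost with nonzero p(capture)")
        roi = 0.0
    else:
        roi = 100.0 * p_capture / (total / 1000.0)
    return CostReport(n_traps=n_traps, total_cost_usd=total,
                      p_capture=p_capture, roi=roi)


def solitary_band_run(design: GridDesign, band_id: int, disp: DispersalParams,
                      cfg: SimConfig) -> SimResult:
    """Simulate a grid with only one band's traps deployed.

    Outbreaks are still sampled in the core region, so the result isolates
    that band's contribution to overall capture.
    """
    return run_simulation(build_layout(design.solitary(band_id)), disp, cfg)


def band_contribution_table(design: GridDesign, disp: DispersalParams,
                            cfg: SimConfig,
                            uniform_density: float | None = None) -> pd.DataFrame:
    """Full grid, each band solitary, and optionally a uniform-density grid.

    Mirrors the published band-decomposition table: one row for the full
    standard grid, one per solitary band, and (if ``uniform_density`` is
    given) one for the grid with that density everywhere.
    """
    rows = []
    full = run_simulation(build_layout(design), disp, cfg)
    total_area = sum(design.band_area_km2(b.band_id) for b in design.bands)
    rows.append({"description": "standard full grid", "band": "all",
                 "n_traps": len(build_layout(design)),
                 "area_km2": total_area,
                 "p_capture": full.p_capture_final,
                 "ci95": full.ci95_halfwidth})
    for band in design.bands:
        res = solitary_band_run(design, band.band_id, disp, cfg)
        rows.append({"description": "solitary band", "band": str(band.band_id),
                     "n_traps": len(build_layout(design.solitary(band.band_id))),
                     "area_km2": design.band_area_km2(band.band_id),
                     "p_capture": res.p_capture_final,
                     "ci95": res.ci95_halfwidth})
    if uniform_density is not None:
        uni = design.with_uniform_density(uniform_density)
        res = run_simulation(build_layout(uni), disp, cfg)
        rows.append({"description": f"uniform density {uniform_density}",
                     "band": "all", "n_traps": len(build_layout(uni)),
                     "area_km2": total_area,
                     "p_capture": res.p_capture_final,
                     "ci95": res.ci95_halfwidth})
    return pd.DataFrame(rows)


def density_sweep(design_template: GridDesign, densities, disp: DispersalParams,
                  cfg: SimConfig, vary_band: int | None = None) -> pd.DataFrame:
    """p(capture) across trap densities.

    With ``vary_band=None`` the whole grid takes each density uniformly (the
    leek-moth protocol); with a band id, only that band's density varies
    while the others keep their template values (the Medfly protocol).
    """
    rows = []
    for density in densities:
        if density < 0:
            raise ValueError("densities must be >= 0")
        if vary_band is None:
            design = design_template.with_uniform_density(density)
        else:
            design = design_template.with_band_density(vary_band, density)
        layout = build_layout(design)
        res = run_simulation(layout, disp, cfg)
        rows.append({"density_per_km2": density, "n_traps": len(layout),
                     "p_capture": res.p_capture_final,
                     "ci95": res.ci95_halfwidth})
    return pd.DataFrame(rows)


def containment_test(species: SpeciesPreset, cfg: SimConfig,
                     D: float | None = None) -> SimResult:
    """Egress-detection probability on the species' perimeter-only ring.

    The ring (1.6 km wide, high-attractiveness traps) sits just outside the
    standard grid; p(capture) on it estimates the chance that any insect
    leaves the surveyed area and is noticed doing so.
    """
    disp = DispersalParams(D=species.D if D is None else D)
    return run_simulation(build_layout(species.containment_grid), disp, cfg)


@dataclass(frozen=True)
class DesignOption:
    """A named design entered in a comparison; ``cost_traps`` optionally
    overrides the constructed trap count for costing (used to reproduce the
    published standard-grid budgets, which quote 900 / 1,700 traps)."""

    name: str
    design: GridDesign
    cost_traps: int | None = None


def compare_designs(options: list[DesignOption], disp: DispersalParams,
                    cfg: SimConfig, cost_model: CostModel,
                    baseline: str | None = None) -> pd.DataFrame:
    """Simulate each design and rank by ROI.

    Emits per design the constructed trap count, p(capture), total cost,
    fractional cost reduction versus the named baseline (default: the first
    option) and ROI; sorted by decreasing ROI.
    """
    if not options:
        raise ValueError("at least one design required")
    baseline = baseline or options[0].name
    if baseline not in {o.name for o in options}:
        raise ValueError(f"baseline {baseline!r} not among the options")
    rows = []
    for opt in options:
        layout = build_layout(opt.design)
        res = run_simulation(layout, disp, cfg)
        costing_traps = opt.cost_traps if opt.cost_traps is not None else len(layout)
        report = cost_roi(costing_traps, cost_model, res.p_capture_final)
        rows.append({"design": opt.name, "n_traps": len(layout),
                     "cost_traps": costing_traps,
                     "p_capture": res.p_capture_final,
                     "ci95": res.ci95_halfwidth,
                     "cost_usd": report.total_cost_usd,
                     "roi": report.roi})
    table = pd.DataFrame(rows)
    base_cost = float(table.loc[table["design"] == baseline, "cost_usd"].iloc[0])
    if base_cost > 0:
        table["cost_reduction"] = 1.0 - table["cost_usd"] / base_cost
    else:
        table["cost_reduction"] = 0.0
    return table.sort_values("roi", ascending=False, ignore_index=True)


def format_table(table: pd.DataFrame) -> pd.DataFrame:
    """Reporting precision: p(capture) to 2 decimals, costs to whole dollars,
    ROI to 1 decimal."""
    out = table.copy()
    for col, nd in (("p_capture", 2), ("roi", 1)):
        if col in out:
            out[col] = out[col].round(nd)
    for col in ("cost_usd",):
        if col in out:
            out[col] = out[col].round(0).astype(int)
    return out
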