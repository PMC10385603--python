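"""Binding and quality-control assay arithmetic.

Covers the radioimmunoconjugate QC chain: immunoreactive fraction from an
antigen-coated magnetic-bead assay, radiochemical purity from thin-layer
chromatography signals, the one-site specific-binding saturation fit for
the dissociation constant Kd, and cellular uptake / blocking metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IGG_MW_G_PER_MOL",
    "BeadAssayResult",
    "SaturationBindingAssay",
    "CellUptakeMeasurement",
    "immunoreactive_fraction",
    "radiochemical_purity",
    "fit_one_site_kd",
    "cellular_uptake",
    "blocking_fraction",
    "ugml_to_nm",
    "nm_to_ugml",
]

IGG_MW_G_PER_MOL = 150_000.0  # whole IgG molecular weight used for unit conversion
PURITY_PASS_THRESHOLD_PCT = 98.0


def ugml_to_nm(conc_ug_per_ml: float, mw_g_per_mol: float = IGG_MW_G_PER_MOL) -> float:
    """Antibody concentration, ug/mL -> nM (1 ug/mL of IgG ~ 6.67 nM)."""
    return conc_ug_per_ml / mw_g_per_mol * 1e6


def nm_to_ugml(conc_nm: float, mw_g_per_mol: float = IGG_MW_G_PER_MOL) -> float:
    return conc_nm * mw_g_per_mol / 1e6


@dataclass(frozen=True)
class BeadAssayResult:
    """Counts split between antigen beads and supernatant for one replicate."""

    beads_cpm: float
    supernatant_cpm: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.beads_cpm < 0 or self.supernatant_cpm < 0:
            raise ValueError("counts must be nonnegative")
        if self.beads_cpm + self.supernatant_cpm <= 0:
            raise ValueError("total counts must be positive")


@dataclass
class SaturationBindingAssay:
    """Signal vs antibody concentration for the one-site binding fit."""

    concentrations_nm: list[float]
    signals: list[float]
    kd_nm: float | None = None
    bmax: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_nm, float)
        if c.size != len(self.signals):
            raise ValueError("concentrations and signals must match in length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class CellUptakeMeasurement:
    """Cell-bound vs deposited activity for one well."""

    deposited_activity: float
    cell_bound_activity: float
    cell_count: float
    timepoint_h: float
    condition: str = "tracer"  # tracer | blocked | bsa_control

    def __post_init__(self) -> None:
        if self.cell_count <= 0:
            raise ValueError("cell count must be positive")
        if not 0 <= self.cell_bound_activity <= self.deposited_activity:
            raise ValueError("bound activity must lie in [0, deposited]")


def immunoreactive_fraction(result: BeadAssayResult) -> float:
    """Percent of counts on the antigen beads relative to total counts."""
    total = result.beads_cpm + result.supernatant_cpm
    return 100.0 * result.beads_cpm / total


def radiochemical_purity(origin_signal: float, total_signal: float
                         ) -> tuple[float, bool]:
    """Percent of lane signal in the bound species; pass flag at >= 98%."""
    if total_signal <= 0:
        raise ValueError("total signal must be positive")
    if origin_signal < 0 or origin_signal > total_signal:
        raise ValueError("origin signal must lie in [0, total]")
    pct = 100.0 * origin_signal / total_signal
    return pct, pct >= PURITY_PASS_THRESHOLD_PCT


def _one_site(c: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    return bmax * c / (kd + c)


def fit_one_site_kd(assay: SaturationBindingAssay) -> tuple[float, float]:
    """Least-squares fit of B(c) = Bmax*c/(Kd + c); returns (Kd, Bmax).

    A linear nonspecific term is deliberately not included: the saturation
    curve is specific binding only.
    """
    c = np.asarray(assay.concentrations_nm, float)
    y = np.asarray(assay.signals, float)
    if c.size < 3:
        raise ValueError("need at least 3 concentrations for the one-site fit")
    b0 = float(np.max(y)) or 1.0
    k0 = float(np.median(c))
    try:
        popt, _ = curve_fit(_one_site, c, y, p0=[b0, k0],
                            bounds=([0.0, 1e-12], [np.inf, np.inf]),
                            maxfev=20_000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"one-site fit failed to converge (p0 Bmax={b0:.3g}, Kd={k0:.3g}): {exc}"
        ) from exc
    bmax, kd = float(popt[0]), float(popt[1])
    assay.kd_nm, assay.bmax = kd, bmax
    return kd, bmax


def cellular_uptake(m: CellUptakeMeasurement) -> float:
    """Percent of deposited activity bound, per million cells."""
    if m.deposited_activity <= 0:
        raise ValueError("deposited activity must be positive")
    return 100.0 * m.cell_bound_activity / m.deposited_activity / (m.cell_count / 1e6)


def blocking_fraction(uptake_tracer: float, uptake_blocked: float) -> float:
    """Percent reduction of uptake under antigen blocking."""
    if uptake_tracer <= 0:
        raise ValueError("tracer uptake must be positive")
    return 100.0 * (1.0 - uptake_blocked / uptake_tracer)
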