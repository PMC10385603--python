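"""Radionuclide decay data and decay arithmetic.

Copper-64 decays by positron emission (17.4%), beta-minus emission (39.0%)
and electron capture (44%).  For internal dosimetry we only need
branch-averaged quantities: the physical half-life, and the mean energy
emitted per decay split into a non-penetrating component (beta particles
plus Auger/conversion electrons, absorbed locally at the mm scale) and a
penetrating photon component (annihilation quanta and gammas).

The bundled Cu-64 record lives in ``data/cu64.json``; every dosimetric
result in the package is traceable to the constants in that file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "RadionuclideData",
    "load_nuclide",
    "cu64",
    "decay_factor",
    "decay_correct",
    "mean_energy_per_decay",
]


@dataclass(frozen=True)
class RadionuclideData:
    """Branch-averaged nuclear data for one radionuclide.

    Energies are in MeV per decay, averaged over the full decay scheme
    (i.e. already weighted by branching fractions).
    """

    name: str
    half_life_h: float
    branch_beta_plus: float
    branch_beta_minus: float
    branch_ec: float
    mean_energy_np_mev: float
    mean_energy_photon_mev: float
    source_citation: str = ""

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be positive")
        for b in (self.branch_beta_plus, self.branch_beta_minus, self.branch_ec):
            if not 0.0 <= b <= 1.0:
                raise ValueError("branching fractions must lie in [0, 1]")
        total = self.branch_beta_plus + self.branch_beta_minus + self.branch_ec
        # printed branch fractions are kept verbatim, so allow 1% slack
        if not 0.99 <= total <= 1.01:
            raise ValueError(f"branching fractions sum to {total:.4f}, expected ~1")
        if self.mean_energy_np_mev < 0 or self.mean_energy_photon_mev < 0:
            raise ValueError("mean energies must be nonnegative")

    @property
    def lambda_phys_per_h(self) -> float:
        """Physical decay constant in h^-1."""
        return math.log(2.0) / self.half_life_h


def load_nuclide(resource_name: str = "cu64.json") -> RadionuclideData:
    """Load a bundled nuclide record from the package data directory."""
    text = resources.files("theradose.data").joinpath(resource_name).read_text()
    return RadionuclideData(**json.loads(text))


def cu64() -> RadionuclideData:
    """The bundled Cu-64 record used throughout the package."""
    return load_nuclide("cu64.json")


def decay_factor(t_h: float, nuclide: RadionuclideData) -> float:
    """Fraction of activity remaining after ``t_h`` hours: 2**(-t/T1/2)."""
    if t_h < 0:
        raise ValueError("elapsed time must be nonnegative")
    return 2.0 ** (-t_h / nuclide.half_life_h)


def decay_correct(measured_activity_mbq: float, t_since_injection_h: float,
                  nuclide: RadionuclideData) -> float:
    """Rescale a measured activity to its value at injection time."""
    if measured_activity_mbq < 0:
        raise ValueError("activity must be nonnegative")
    return measured_activity_mbq / decay_factor(t_since_injection_h, nuclide)


def mean_energy_per_decay(nuclide: RadionuclideData, mode: str = "nonpenetrating") -> float:
    """Mean emitted energy per decay in MeV.

    mode="nonpenetrating" returns the electron component only (betas plus
    Auger/conversion electrons); mode="all" adds the photon component.
    """
    if mode == "nonpenetrating":
        return nuclide.mean_energy_np_mev
    if mode == "all":
        return nuclide.mean_energy_np_mev + nuclide.mean_energy_photon_mev
    raise ValueError(f"unknown energy mode {mode!r}; use 'nonpenetrating' or 'all'")
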