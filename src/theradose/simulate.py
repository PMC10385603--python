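"""Seeded synthetic cohorts with the statistical structure of the study.

Every generator is a pure function of (config, seed): the same inputs give
bit-identical output.  A single root seed spawns fixed per-generator
substreams so modules can be regenerated independently.

Distributional choices (all config-overridable through the parameters):

* %ID/g per mouse: normal truncated at zero (means +/- SD are reported,
  negative uptake is impossible);
* tumour doubling time and measurement noise: lognormal (multiplicative
  biology);
* survival event times: log-logistic (heavy right tail matches long
  survivors), with a cure fraction censored at the study horizon;
* bead-assay counts: binomial partition of the total counts.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .assays import BeadAssayResult, SaturationBindingAssay
from .biodistribution import CPM_PER_MBQ, BiodistributionRecord
from .config import GrowthParams, SurvivalParams, SyntheticConfig
from .efficacy import STUDY_HORIZON_DAYS, SurvivalRecord, TumourGrowthSeries
from .nuclide import RadionuclideData, cu64, decay_factor

__all__ = [
    "gen_biodistribution",
    "gen_tumour_growth",
    "gen_survival",
    "gen_survival_from_growth",
    "gen_bead_assay",
    "gen_saturation_binding",
]

# fixed substream tags so each generator has an independent stream per seed
_STREAMS = {"biodist": 11, "growth": 23, "survival": 37, "bead": 53, "binding": 71}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def _truncnorm_at_zero(mean: float, sd: float, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def gen_biodistribution(config: SyntheticConfig, seed: int,
                        group: str = "healthy",
                        nuclide: RadionuclideData | None = None,
                        ) -> list[BiodistributionRecord]:
    """Synthetic per-mouse biodistribution records for one group.

    Per-mouse %ID/g is drawn truncated-normal from the organ/timepoint
    table, rescaled proportionally if the whole-body injected-dose budget
    (sum over organs of %ID/g x organ mass) exceeds 100%, and back-converted
    to counter cpm given masses, efficiency and physical decay at sacrifice.
    """
    nuclide = nuclide or cu64()
    rng = _rng(seed, "biodist")
    bp = config.biodist
    organs = bp.organs(group)
    records: list[BiodistributionRecord] = []
    for t in bp.timepoints(group):
        cells = {o: bp.cell(group, o, t) for o in organs}
        n = cells[organs[0]].n
        for i in range(n):
            mouse_id = f"{group}_t{t:g}_m{i}"
            injected = max(1e-6, float(rng.normal(bp.injected_mbq_mean, bp.injected_mbq_sd)))
            tail = bp.tail_remainder_fraction * injected
            pidg = {o: float(_truncnorm_at_zero(cells[o].mean_pid_g,
                                                cells[o].sd_pid_g, 1, rng)[0])
                    for o in organs}
            total_pct = sum(pidg[o] * bp.organ_masses_g[o] for o in organs)
            if total_pct > 100.0:
                scale = 100.0 / total_pct
                pidg = {o: v * scale for o, v in pidg.items()}
            for o in organs:
                mass = bp.organ_masses_g[o]
                injected_corr = injected - tail
                activity_at_injection = pidg[o] / 100.0 * injected_corr * mass
                measured = activity_at_injection * decay_factor(t, nuclide)
                cpm = measured * bp.counter_efficiency * CPM_PER_MBQ
                records.append(BiodistributionRecord(
                    mouse_id=mouse_id, group=group, organ=o, timepoint_h=t,
                    organ_mass_g=mass, organ_cpm=cpm,
                    counter_efficiency=bp.counter_efficiency,
                    injected_activity_mbq=injected, tail_remainder_mbq=tail,
                    sacrifice_time_h=t,
                ))
    return records


def _measurement_days(p: GrowthParams) -> np.ndarray:
    return np.arange(p.first_dose_day, p.last_day + 1e-9, p.measurement_interval_days)


def _volume_curve(p: GrowthParams, dt_days: float, days: np.ndarray) -> np.ndarray:
    """Noiseless volume trajectory: exponential growth, treatment-modified
    doubling time, and post-second-dose exponential regression then regrowth."""
    v = np.empty_like(days)
    growing = days <= p.second_dose_day
    v[growing] = p.v0_mm3 * 2.0 ** ((days[growing] - p.first_dose_day) / dt_days)
    v2 = p.v0_mm3 * 2.0 ** ((p.second_dose_day - p.first_dose_day) / dt_days)
    after = ~growing
    if p.regression_fraction > 0:
        dt_after = days[after] - p.second_dose_day
        shrink = np.exp(np.log(1.0 - p.regression_fraction)
                        * np.minimum(dt_after, p.regression_duration_days)
                        / p.regression_duration_days)
        regrow = 2.0 ** (np.maximum(0.0, dt_after - p.regression_duration_days) / dt_days)
        v[after] = v2 * shrink * regrow
    else:
        v[after] = v2 * 2.0 ** ((days[after] - p.second_dose_day) / dt_days)
    return v


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if sd == 0:
        return math.log(mean), 0.0
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def gen_tumour_growth(config: SyntheticConfig, seed: int,
                      group: str = "treated") -> list[TumourGrowthSeries]:
    """Synthetic calliper trajectories for one subcutaneous-model group.

    Dimensions are back-solved as equal cube roots so that the calliper
    volume formula reproduces the simulated volume exactly.
    """
    rng = _rng(seed, "growth")
    p = config.growth[group]
    mu, sig = _lognormal_params(p.dt_mean_days, p.dt_sd_days)
    days = _measurement_days(p)
    series = []
    for i in range(p.n):
        dt = float(rng.lognormal(mu, sig))
        v = _volume_curve(p, dt, days)
        if p.noise_cv > 0:
            nmu, nsig = _lognormal_params(1.0, p.noise_cv)
            v = v * rng.lognormal(nmu, nsig, size=days.size)
        dim = (v / (3.14 / 6.0)) ** (1.0 / 3.0)
        series.append(TumourGrowthSeries(
            mouse_id=f"{group}_m{i}", group=group, days=days.tolist(),
            length_mm=dim.tolist(), width_mm=dim.tolist(), height_mm=dim.tolist(),
        ))
    return series


def _sample_loglogistic(alpha: float, beta: float, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(size=size)
    return alpha * (u / (1.0 - u)) ** (1.0 / beta)


def gen_survival(config: SyntheticConfig, seed: int,
                 group: str = "repeated_35") -> list[SurvivalRecord]:
    """Synthetic time-to-event records for one therapy group.

    Event times are log-logistic with the configured median and shape;
    a configured cure fraction (and any event time beyond the horizon)
    is censored at 100 days.
    """
    rng = _rng(seed, "survival")
    p: SurvivalParams = config.survival[group]
    cured = rng.uniform(size=p.n) < p.cure_fraction
    t = _sample_loglogistic(p.median_days, p.shape, p.n, rng)
    records = []
    for i in range(p.n):
        if cured[i] or t[i] > STUDY_HORIZON_DAYS:
            records.append(SurvivalRecord(f"{group}_m{i}", group,
                                          STUDY_HORIZON_DAYS, 0, "study_end"))
        else:
            records.append(SurvivalRecord(f"{group}_m{i}", group,
                                          float(t[i]), 1, "paralysis"))
    return records


def gen_survival_from_growth(config: SyntheticConfig, seed: int,
                             group: str = "saline") -> list[SurvivalRecord]:
    """Alternative mode: derive events from growth via the sacrifice rules."""
    from .efficacy import apply_sacrifice_rules

    series = gen_tumour_growth(config, seed, group)
    return [
        apply_sacrifice_rules(s.mouse_id, s.group, s.days, s.volumes_mm3)
        for s in series
    ]


def gen_bead_assay(truth_fraction: float, total_cpm: float, n_replicates: int,
                   seed: int) -> list[BeadAssayResult]:
    """Binomial partition of total counts between beads and supernatant."""
    if not 0.0 <= truth_fraction <= 1.0:
        raise ValueError("truth fraction must be in [0, 1]")
    if total_cpm <= 0 or n_replicates < 1:
        raise ValueError("total counts and replicates must be positive")
    rng = _rng(seed, "bead")
    total = int(round(total_cpm))
    beads = rng.binomial(total, truth_fraction, size=n_replicates)
    return [BeadAssayResult(float(b), float(total - b), replicate_id=f"rep{i}")
            for i, b in enumerate(beads)]


def gen_saturation_binding(kd_nm: float, bmax: float,
                           conc_grid_nm: np.ndarray | list[float],
                           noise_cv: float, seed: int) -> SaturationBindingAssay:
    """One-site specific-binding signal with multiplicative lognormal noise."""
    if kd_nm <= 0 or bmax <= 0:
        raise ValueError("kd and bmax must be positive")
    rng = _rng(seed, "binding")
    c = np.asarray(conc_grid_nm, float)
    signal = bmax * c / (kd_nm + c)
    if noise_cv > 0:
        mu, sig = _lognormal_params(1.0, noise_cv)
        signal = signal * rng.lognormal(mu, sig, size=c.size)
    return SaturationBindingAssay(concentrations_nm=c.tolist(),
                                  signals=signal.tolist())
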