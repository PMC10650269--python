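"""Synthetic data with known ground truth for every pipeline stage.

Everything the pipeline consumes can be generated here: competitive
co-amplifications, gel lanes (as 1-D profiles), competitor dilution series,
cumulative gas curves and factorial batch-culture tables.  Each generator
is a pure function of its parameters and the seed, and returns the ground
truth alongside the data so that every downstream estimate can be checked
by parameter recovery.

The PCR model is deliberately minimal: both templates amplify with a shared
efficiency for a fixed cycle count, and when the summed product exceeds a
total-product plateau both are rescaled by a common factor.  This preserves
the initial molar ratio exactly — the property competitive PCR relies on.
Band signal is proportional to dsDNA *mass* (ethidium stains base pairs,
not molecules), which is what makes the raw-vs-molar intensity mode choice
downstream a real one.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assays import AmpliconPair, AmpliconSpec
from .densitometry import LaneProfile
from .gas import DEFAULT_TIME_GRID, GasCurve, gas_model
from .quantify import mass_from_copies

# Migration model: peak position linear in -log10(length), spanning
# fragments from 1000 bp (near the well) to 50 bp (near the dye front).
_MIGRATION_LOG_MAX = math.log10(1000.0)
_MIGRATION_LOG_MIN = math.log10(50.0)
_MIGRATION_MARGIN = 0.10  # fraction of profile length kept clear at each end


@dataclass
class SimConfig:
    """Knobs of the synthetic world.

    The defaults are the study conditions: 11 ten-fold competitor
    dilutions, 34/30 PCR cycles (taken from the assay pair when
    ``pcr_cycles`` is None), the 11-point gas recording grid, band
    densitometry noise CV 0.1 and gas noise 2 mL.
    """

    seed: int = 0
    n_dilutions: int = 11
    dilution_base: float = 10.0
    competitor_stock: float = 1e9  # copies per reaction at the first lane
    pcr_cycles: int | None = None
    pcr_efficiency: float = 0.9
    plateau_total_copies: float = 1e12
    intensity_noise_cv: float = 0.1
    gas_noise_sd: float = 2.0
    gas_clip_monotone: bool = False
    time_grid: tuple = DEFAULT_TIME_GRID
    # gel rendering
    profile_points: int = 512
    profile_length_mm: float = 100.0
    band_sigma_mm: float = 1.2
    gel_gain: float = 100.0  # densitometry units per ng of dsDNA
    baseline_height: float = 5.0
    profile_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.dilution_base <= 1:
            raise ValueError("dilution_base must exceed 1")
        if not 0 < self.pcr_efficiency <= 1:
            raise ValueError("pcr_efficiency must lie in (0, 1]")
        for name in ("intensity_noise_cv", "gas_noise_sd", "profile_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.time_grid = tuple(float(t) for t in self.time_grid)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """What the generator actually injected, stored next to every dataset."""

    true_target_copies: float | None = None
    true_log10_copies_per_ml: float | None = None
    true_V: float | None = None
    true_k: float | None = None
    group_effects: dict = field(default_factory=dict)


def simulate_competitive_pcr(
    target_copies: float,
    competitor_copies: float,
    pair: AmpliconPair,
    cfg: SimConfig,
) -> tuple[float, float]:
    """Co-amplify target and competitor; return product masses in ng.

    Both templates grow as N·(1+e)^c.  If the summed product copies exceed
    the plateau, both are rescaled by one common factor so the sum equals
    the plateau — the molar ratio is untouched.  Mass is copies × length ×
    650 / N_A × 10⁹ ng.
    """
    if target_copies < 0 or competitor_copies < 0:
        raise ValueError("template copy numbers must be non-negative")
    if target_copies == 0 and competitor_copies == 0:
        return 0.0, 0.0
    cycles = cfg.pcr_cycles if cfg.pcr_cycles is not None else pair.cycles
    growth = (1.0 + cfg.pcr_efficiency) ** cycles
    n_target = target_copies * growth
    n_comp = competitor_copies * growth
    total = n_target + n_comp
    if cfg.plateau_total_copies and total > cfg.plateau_total_copies:
        scale = cfg.plateau_total_copies / total
        n_target *= scale
        n_comp *= scale
    return (
        mass_from_copies(n_target, pair.target.length_bp),
        mass_from_copies(n_comp, pair.competitor.length_bp),
    )


def migration_position(length_bp: float, cfg: SimConfig) -> float:
    """Pseudo-migration: peak center linear in -log10(length).

    Shorter fragments land farther along the profile.  Only the ordering
    and separation matter downstream.
    """
    frac = (_MIGRATION_LOG_MAX - math.log10(length_bp)) / (
        _MIGRATION_LOG_MAX - _MIGRATION_LOG_MIN
    )
    lo = _MIGRATION_MARGIN * cfg.profile_length_mm
    hi = (1.0 - _MIGRATION_MARGIN) * cfg.profile_length_mm
    return lo + frac * (hi - lo)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return 1.0
    s = math.sqrt(math.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(-0.5 * s * s, s)))


def render_gel_lane(
    band_masses: list[tuple[AmpliconSpec, float]],
    cfg: SimConfig,
    lane_id: str = "lane",
    rng: np.random.Generator | None = None,
) -> tuple[LaneProfile, dict]:
    """Render bands into a 1-D lane profile with baseline and noise.

    Each band is a Gaussian peak centred at its migration position with
    area = gel_gain × mass × a unit-mean lognormal factor (CV =
    ``intensity_noise_cv``).  A gentle positive baseline and white noise
    are added.  Returns the profile and a ground-truth dict with the
    *realized* (post-noise) band areas, centers, the peak sigma, and an
    overlap flag raised when two centers sit closer than 3σ.
    """
    if any(mass < 0 for _, mass in band_masses):
        raise ValueError("band masses must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    L = cfg.profile_length_mm
    x = np.linspace(0.0, L, cfg.profile_points)
    sigma = cfg.band_sigma_mm

    baseline = cfg.baseline_height * (1.0 + 0.25 * x / L + 0.2 * np.exp(-2.0 * x / L))
    y = baseline.copy()
    areas, centers = [], []
    for spec, mass in band_masses:
        center = migration_position(spec.length_bp, cfg)
        area = cfg.gel_gain * mass * _lognormal_factor(rng, cfg.intensity_noise_cv)
        y += area * np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
        areas.append(area)
        centers.append(center)
    if cfg.profile_noise_sd > 0:
        y = y + rng.normal(0.0, cfg.profile_noise_sd, size=y.shape)

    overlap = any(
        abs(c1 - c2) < 3 * sigma
        for i, c1 in enumerate(centers)
        for c2 in centers[i + 1 :]
    )
    truth = {"areas": areas, "centers": centers, "sigma": sigma, "overlap": overlap}
    return LaneProfile(lane_id, x, y), truth


@dataclass
class SimulatedSeries:
    """A full synthetic competitor dilution series."""

    points: pd.DataFrame  # lane_id, competitor_copies, target/competitor_intensity
    profiles: list
    truth: GroundTruth
    lane_truths: list

    def profiles_frame(self) -> pd.DataFrame:
        """Long-format lane_profiles table (lane_id, position, intensity)."""
        frames = [
            pd.DataFrame(
                {"lane_id": p.lane_id, "position": p.positions, "intensity": p.intensities}
            )
            for p in self.profiles
        ]
        return pd.concat(frames, ignore_index=True)


def simulate_dilution_series(
    true_target_copies: float,
    pair: AmpliconPair,
    cfg: SimConfig,
) -> SimulatedSeries:
    """Simulate one cPCR titration of a fixed target against a dilution ladder.

    Competitor copies run from ``competitor_stock`` down by
    ``dilution_base`` per lane for ``n_dilutions`` lanes.  Each reaction is
    co-amplified and rendered to a gel lane; the intensity table holds the
    same realized band areas that are drawn into the profiles, so profile
    densitometry and the table agree up to integration error.
    """
    if cfg.n_dilutions < 3:
        raise ValueError("need at least 3 dilutions")
    if true_target_copies < 0:
        raise ValueError("target copies must be non-negative")
    rng = np.random.default_rng(cfg.seed)
    rows, profiles, lane_truths = [], [], []
    for i in range(cfg.n_dilutions):
        comp = cfg.competitor_stock / cfg.dilution_base**i
        m_t, m_c = simulate_competitive_pcr(true_target_copies, comp, pair, cfg)
        lane_id = f"{pair.taxon}_d{i:02d}"
        profile, truth = render_gel_lane(
            [(pair.target, m_t), (pair.competitor, m_c)], cfg, lane_id=lane_id, rng=rng
        )
        rows.append(
            {
                "lane_id": lane_id,
                "competitor_copies": comp,
                "target_intensity": truth["areas"][0],
                "competitor_intensity": truth["areas"][1],
            }
        )
        profiles.append(profile)
        lane_truths.append(truth)
    return SimulatedSeries(
        points=pd.DataFrame(rows),
        profiles=profiles,
        truth=GroundTruth(true_target_copies=float(true_target_copies)),
        lane_truths=lane_truths,
    )


def simulate_gas_curve(
    true_V: float,
    true_k: float,
    cfg: SimConfig,
    syringe_id: str = "syringe",
    rng: np.random.Generator | None = None,
) -> tuple[GasCurve, GroundTruth]:
    """Noisy cumulative gas curve y = V(1 - e^(-kt)) on the recording grid."""
    if true_V <= 0 or true_k <= 0:
        raise ValueError("V and k must be positive")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.time_grid, dtype=float)
    y = gas_model(t, true_V, true_k)
    if cfg.gas_noise_sd > 0:
        y = y + rng.normal(0.0, cfg.gas_noise_sd, size=t.shape)
    if cfg.gas_clip_monotone:
        y = np.maximum.accumulate(y)
    curve = GasCurve(syringe_id, t, y, blank_corrected=True)
    return curve, GroundTruth(true_V=float(true_V), true_k=float(true_k))


def simulate_gas_experiment(
    truths: dict[str, tuple[float, float]],
    cfg: SimConfig,
    n_blanks: int = 3,
    blank_V: float = 8.0,
    blank_k: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Tidy gas log for several substrate syringes plus blank syringes.

    ``truths`` maps syringe_id → (V, k).  Observed substrate volumes are
    model + blank drift + noise; blank syringes record drift + noise, so
    blank-corrected assembly recovers the drift-free curve in expectation.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.time_grid, dtype=float)
    drift = gas_model(t, blank_V, blank_k)
    rows = []
    for sid, (V, k) in truths.items():
        y = gas_model(t, V, k) + drift + rng.normal(0.0, cfg.gas_noise_sd, size=t.shape)
        for ti, yi in zip(t, y):
            rows.append({"syringe_id": sid, "is_blank": False, "time_h": ti, "volume_ml": yi})
    for b in range(n_blanks):
        y = drift + rng.normal(0.0, cfg.gas_noise_sd, size=t.shape)
        for ti, yi in zip(t, y):
            rows.append(
                {"syringe_id": f"blank{b}", "is_blank": True, "time_h": ti, "volume_ml": yi}
            )
    truth = {
        "syringes": {sid: {"V": V, "k": k} for sid, (V, k) in truths.items()},
        "blank": {"V": blank_V, "k": blank_k},
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Factorial batch-culture dataset
# ---------------------------------------------------------------------------

#: Default response model for the 2 species × 3 treatments × 3 runs design:
#: overall mean, additive species/treatment shifts and residual SD, with
#: magnitudes matching typical goat/camel batch-culture incubations.
DEFAULT_RESPONSES: dict[str, dict] = {
    "ph": {"mu": 6.4, "species": {"goat": -0.2, "camel": 0.2}, "treatment": {}, "sd": 0.12},
    "nh3_mg_dl": {
        "mu": 30.9,
        "species": {"goat": 8.2, "camel": -8.2},
        "treatment": {1: -1.1, 2: -0.4, 3: 1.5},
        "sd": 2.0,
    },
    "mp_mg_ml": {
        "mu": 135.5,
        "species": {"goat": -22.4, "camel": 22.4},
        "treatment": {1: -14.5, 2: -9.5, 3: 21.0},
        "sd": 15.0,
    },
    "vfa_total_mm_ml": {"mu": 2.2, "species": {"goat": 0.3, "camel": -0.3}, "treatment": {}, "sd": 0.12},
    "acetate_mm_ml": {"mu": 0.45, "species": {}, "treatment": {}, "sd": 0.07},
    "propionate_mm_ml": {"mu": 0.2, "species": {}, "treatment": {}, "sd": 0.035},
    "butyrate_mm_ml": {"mu": 0.32, "species": {}, "treatment": {}, "sd": 0.05},
    "gas_ml": {"mu": 93.0, "species": {"goat": 13.6, "camel": -13.6}, "treatment": {1: 1.5, 2: 1.0, 3: -2.5}, "sd": 4.0},
    "methanogen_log10": {
        "mu": 4.95,
        "species": {"goat": 0.35, "camel": -0.35},
        "treatment": {},
        "sd": 0.25,
    },
    "protozoa_log10": {
        "mu": 5.05,
        "species": {"goat": 0.35, "camel": -0.35},
        "treatment": {},
        "sd": 0.25,
    },
}

#: Residual correlation between methanogen and protozoa log10 abundances,
#: reflecting the protozoa-associated methanogen symbiosis.
DEFAULT_POPULATION_RHO = 0.46


def simulate_culture_dataset(
    cfg: SimConfig,
    responses: dict[str, dict] | None = None,
    species: tuple = ("goat", "camel"),
    treatments: tuple = (1, 2, 3),
    n_runs: int = 3,
    reps_per_cell: int = 3,
    time_h: float = 24.0,
    run_sd: float = 0.0,
    population_rho: float = DEFAULT_POPULATION_RHO,
    ddm: dict | None = None,
    ndfd: dict | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Factorial culture table: μ + treatment + species + run(random) + residual.

    Each record also carries substrate/residue masses consistent with the
    species-level dry-matter (``ddm``) and NDF (``ndfd``) degradabilities,
    so the degradability bookkeeping can be exercised end to end.  Returns
    the table and a :class:`GroundTruth` whose ``group_effects`` holds the
    injected effect maps.
    """
    responses = responses if responses is not None else DEFAULT_RESPONSES
    ddm = ddm if ddm is not None else {"goat": 0.25, "camel": 0.30}
    ndfd = ndfd if ndfd is not None else {"goat": 0.44, "camel": 0.44}
    rng = np.random.default_rng(cfg.seed)

    run_effects = {
        (resp, r): (rng.normal(0.0, run_sd) if run_sd > 0 else 0.0)
        for resp in responses
        for r in range(1, n_runs + 1)
    }
    rho = float(np.clip(population_rho, -0.999, 0.999))
    rows = []
    for sp in species:
        for tr in treatments:
            for run in range(1, n_runs + 1):
                for rep in range(reps_per_cell):
                    rec = {"species": sp, "treatment": tr, "run": run, "rep": rep, "time_h": time_h}
                    # correlated residuals for the two populations
                    z1, z2 = rng.standard_normal(2)
                    pop_z = {"methanogen_log10": z1, "protozoa_log10": rho * z1 + math.sqrt(1 - rho**2) * z2}
                    for resp, spec_ in responses.items():
                        mean = (
                            spec_["mu"]
                            + spec_.get("species", {}).get(sp, 0.0)
                            + spec_.get("treatment", {}).get(tr, 0.0)
                            + run_effects[(resp, run)]
                        )
                        z = pop_z.get(resp, rng.standard_normal())
                        rec[resp] = mean + spec_["sd"] * z
                    substrate = 500.0 + (rng.normal(0.0, 3.0) if cfg.gas_noise_sd > 0 else 0.0)
                    d = float(np.clip(ddm[sp] + (rng.normal(0, 0.01) if cfg.gas_noise_sd > 0 else 0.0), 0, 1))
                    nd = float(np.clip(ndfd[sp] + (rng.normal(0, 0.02) if cfg.gas_noise_sd > 0 else 0.0), 0, 1))
                    rec["substrate_in_mg"] = substrate
                    rec["residue_mg"] = substrate * (1.0 - d)
                    rec["ndf_in_mg"] = substrate * 0.48
                    rec["ndf_residue_mg"] = substrate * 0.48 * (1.0 - nd)
                    rows.append(rec)
    truth = GroundTruth(
        group_effects={
            resp: {"species": dict(spec_.get("species", {})), "treatment": dict(spec_.get("treatment", {})), "mu": spec_["mu"]}
            for resp, spec_ in responses.items()
        }
    )
    return pd.DataFrame(rows), truth
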