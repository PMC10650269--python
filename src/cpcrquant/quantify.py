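"""Competitive-PCR quantification: from a competitor dilution series to copy numbers.

The core of the method.  An unknown target is co-amplified against a serial
dilution of a known competitor.  Because both templates share primers and
amplify with the same efficiency, the molar ratio of the two products equals
the ratio of starting copies.  Plotting

    y = log10(target intensity / competitor intensity)
    x = log10(competitor copies added)

gives a straight line of slope -1; the *equivalence point* — the x where the
line crosses y = 0, i.e. where the two bands are equally abundant — reveals
the starting copy number of the target.  Scaled by the template volume and
the extract dilution chain, that becomes copies per mL of culture fluid.

Two intensity modes are supported.  Ethidium staining scales with dsDNA
*mass*, so the raw band-intensity ratio of fragments of unequal length is
biased by the length ratio L_target/L_competitor relative to the molar
ratio.  ``mode="molar"`` divides each intensity by its fragment length
before ratioing and removes that bias; ``mode="raw"`` uses intensities as
densitometry reports them.  The bias between the two modes is exactly the
length ratio (0.18 log10 at most for the assays shipped here).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assays import AmpliconPair
from .densitometry import LaneProfile, quantify_lane
from .exceptions import BandShortfallError, InsufficientDataError, InvalidTitrationError

#: Avogadro's number, molecules per mole.
AVOGADRO = 6.022e23
#: Mean molar mass of a double-stranded base pair, g/mol/bp.
MEAN_BP_MASS = 650.0
#: Nanograms per gram.
NG_PER_G = 1e9

#: Minimum |slope| for a calibration to count as a real titration.
MIN_ABS_SLOPE = 0.1


def copies_from_mass(amount_ng: float, length_bp: float) -> float:
    """Convert a dsDNA mass to molecule copies.

    copies = amount_ng × N_A / (length × 10⁹ ng/g × 650 g/mol/bp)

    Linear in ``amount_ng`` and inversely proportional to ``length_bp``.
    """
    if length_bp <= 0:
        raise ValueError(f"fragment length must be positive, got {length_bp}")
    if amount_ng < 0:
        raise ValueError(f"mass must be non-negative, got {amount_ng}")
    return amount_ng * AVOGADRO / (length_bp * NG_PER_G * MEAN_BP_MASS)


def mass_from_copies(copies: float, length_bp: float) -> float:
    """Exact inverse of :func:`copies_from_mass`: copy number to mass in ng."""
    if length_bp <= 0:
        raise ValueError(f"fragment length must be positive, got {length_bp}")
    if copies < 0:
        raise ValueError(f"copy number must be non-negative, got {copies}")
    return copies * length_bp * NG_PER_G * MEAN_BP_MASS / AVOGADRO


@dataclass
class DilutionPoint:
    """One cPCR reaction of the dilution series."""

    competitor_copies: float
    target_intensity: float
    competitor_intensity: float
    lane_id: str = ""

    @property
    def usable(self) -> bool:
        """A point is usable for the log-ratio fit only if both bands are present."""
        return (
            self.competitor_copies > 0
            and self.target_intensity > 0
            and self.competitor_intensity > 0
        )


@dataclass
class CalibrationFit:
    """Fitted log-ratio vs log-copies line and its equivalence point."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    equivalence_copies: float
    mode: str
    extrapolated: bool = False


@dataclass
class PopulationEstimate:
    """Final enumeration: log10 copies per mL of culture fluid, with provenance."""

    taxon: str
    log10_copies_per_ml: float
    copies_per_ml: float
    equivalence_copies: float
    provenance: list = field(default_factory=list)


def _as_points(points: Iterable) -> list[DilutionPoint]:
    out = []
    for p in points:
        if isinstance(p, DilutionPoint):
            out.append(p)
        else:  # mapping / namedtuple-ish row
            out.append(
                DilutionPoint(
                    competitor_copies=float(p["competitor_copies"]),
                    target_intensity=float(p["target_intensity"]),
                    competitor_intensity=float(p["competitor_intensity"]),
                    lane_id=str(p.get("lane_id", "")),
                )
            )
    return out


def build_calibration(
    points: Iterable[DilutionPoint] | pd.DataFrame,
    mode: str = "raw",
    pair: AmpliconPair | None = None,
) -> CalibrationFit:
    """Fit the titration line and locate the equivalence point.

    Ordinary least squares of y = log10(target/competitor intensity) on
    x = log10(competitor copies) over the usable points.  In ``"molar"``
    mode each intensity is first divided by its fragment length (requires
    ``pair``).  The equivalence point is 10^(-intercept/slope), where the
    fitted line crosses y = 0.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 usable points.
    InvalidTitrationError
        Slope >= 0 or |slope| < 0.1 — no competition signal.
    """
    if isinstance(points, pd.DataFrame):
        points = points.to_dict("records")
    pts = [p for p in _as_points(points) if p.usable]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need >= 3 usable dilution points, got {len(pts)}"
        )
    if mode not in ("raw", "molar"):
        raise ValueError(f"mode must be 'raw' or 'molar', got {mode!r}")
    if mode == "molar" and pair is None:
        raise ValueError("molar mode needs the AmpliconPair for fragment lengths")

    x = np.log10([p.competitor_copies for p in pts])
    ti = np.array([p.target_intensity for p in pts], dtype=float)
    ci = np.array([p.competitor_intensity for p in pts], dtype=float)
    if mode == "molar":
        ti = ti / pair.target.length_bp
        ci = ci / pair.competitor.length_bp
    y = np.log10(ti / ci)

    fit = stats.linregress(x, y)
    if not np.isfinite(fit.slope) or fit.slope >= 0 or abs(fit.slope) < MIN_ABS_SLOPE:
        raise InvalidTitrationError(
            f"slope {fit.slope:.4g} is not a valid titration "
            f"(need finite slope <= -{MIN_ABS_SLOPE})"
        )
    x_eq = -fit.intercept / fit.slope
    extrapolated = bool(x_eq < x.min() or x_eq > x.max())
    return CalibrationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(pts),
        equivalence_copies=float(10.0**x_eq),
        mode=mode,
        extrapolated=extrapolated,
    )


def copies_per_ml(
    fit: CalibrationFit,
    template_volume_ml: float,
    extract_dilution_chain: Sequence[float],
    taxon: str = "",
) -> PopulationEstimate:
    """Scale an equivalence point to copies per mL of culture fluid.

    copies/mL = equivalence_copies / template_volume × ∏(chain factors)

    The chain is mandatory: every fold factor between culture fluid and the
    PCR template (extract dilutions, elution concentration) must be given
    explicitly, as a possibly-unit list — there is no silent default.
    """
    if template_volume_ml <= 0:
        raise ValueError("template volume must be positive")
    if extract_dilution_chain is None or len(extract_dilution_chain) == 0:
        raise ValueError(
            "extract_dilution_chain is required; pass [1.0] for an undiluted extract"
        )
    chain = [float(f) for f in extract_dilution_chain]
    if any(f <= 0 for f in chain):
        raise ValueError(f"all chain factors must be positive, got {chain}")

    value = fit.equivalence_copies / template_volume_ml
    provenance = [
        {"factor": "equivalence_copies_per_reaction", "value": fit.equivalence_copies},
        {"factor": "per_template_volume_ml", "value": 1.0 / template_volume_ml},
    ]
    for i, f in enumerate(chain):
        value *= f
        provenance.append({"factor": f"chain_{i}", "value": f})
    return PopulationEstimate(
        taxon=taxon,
        log10_copies_per_ml=math.log10(value),
        copies_per_ml=value,
        equivalence_copies=fit.equivalence_copies,
        provenance=provenance,
    )


def enumerate_population(
    profiles_or_intensities: Sequence[LaneProfile] | pd.DataFrame,
    series_meta: pd.DataFrame,
    pair: AmpliconPair,
    template_volume_ml: float,
    extract_dilution_chain: Sequence[float],
    mode: str = "raw",
) -> tuple[PopulationEstimate, CalibrationFit, pd.DataFrame]:
    """Full enumeration: densitometry (if needed) → calibration → copies per mL.

    ``profiles_or_intensities`` is either a list of :class:`LaneProfile`
    (quantified here, lanes whose bands cannot be resolved are dropped with
    a flag) or a band-intensity table with columns ``lane_id``,
    ``target_intensity``, ``competitor_intensity``.  ``series_meta`` maps
    ``lane_id`` to ``competitor_copies``.

    Returns the estimate, the calibration fit, and the per-lane calibration
    table (x, y and usability flags) ready for plotting.
    """
    meta = series_meta.set_index(series_meta["lane_id"].astype(str))
    rows = []
    if isinstance(profiles_or_intensities, pd.DataFrame):
        for _, r in profiles_or_intensities.iterrows():
            rows.append(
                {
                    "lane_id": str(r["lane_id"]),
                    "target_intensity": float(r["target_intensity"]),
                    "competitor_intensity": float(r["competitor_intensity"]),
                    "flag": "",
                }
            )
    else:
        for profile in profiles_or_intensities:
            try:
                tgt, comp = quantify_lane(profile, pair)
                rows.append(
                    {
                        "lane_id": str(profile.lane_id),
                        "target_intensity": tgt.net_intensity,
                        "competitor_intensity": comp.net_intensity,
                        "flag": "overlap" if (tgt.overlap or comp.overlap) else "",
                    }
                )
            except BandShortfallError:
                rows.append(
                    {
                        "lane_id": str(profile.lane_id),
                        "target_intensity": 0.0,
                        "competitor_intensity": 0.0,
                        "flag": "band_shortfall",
                    }
                )
    table = pd.DataFrame(rows)
    if not set(table["lane_id"]).issubset(set(meta.index)):
        missing = sorted(set(table["lane_id"]) - set(meta.index))
        raise ValueError(f"lanes without series metadata: {missing}")
    table["competitor_copies"] = [
        float(meta.loc[lid, "competitor_copies"]) for lid in table["lane_id"]
    ]

    points = _as_points(table.to_dict("records"))
    table["usable"] = [p.usable for p in points]
    with np.errstate(divide="ignore", invalid="ignore"):
        table["log10_competitor_copies"] = np.log10(table["competitor_copies"])
        table["log10_intensity_ratio"] = np.log10(
            table["target_intensity"] / table["competitor_intensity"]
        )

    fit = build_calibration(points, mode=mode, pair=pair)
    estimate = copies_per_ml(
        fit, template_volume_ml, extract_dilution_chain, taxon=pair.taxon
    )
    return estimate, fit, table
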