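"""Synthetic multicenter SMILE cohorts with quantile-matched marginals.

Published multicenter summaries report each center's feature distributions
only as median (P25, P75) plus sex proportions and eye counts; no per-eye
data are deposited.  This module turns such summaries (a
:class:`CenterProfile` per center) into full per-eye cohorts so that every
downstream stage — discretization, information-gain ranking, two-stage
selection, outcome metrics — can be exercised and validated end to end.

Construction, per eye
---------------------
1.  Quantile-matched marginals (median-glued two-piece normal, below) for
    age, sphere (SD), cylinder (CD), corneal thickness (CCT) and mean
    curvature (Km); uniform ranges for optical zone, cap thickness and laser
    energy.
2.  SE := SD + CD/2.  The SD and CD draws are coupled through a latent
    normal with band-wise location shifts over SD-quantile bands (mapped
    back through the exact mixture CDF so the CD marginal stays exact); the
    shifts are calibrated once per profile so the derived SE median and
    quartiles also match their targets.
3.  K1 := Km - u, K2 := Km + u with u ~ Uniform(0, k_spread).
4.  Attempted correction := |SE| + nomogram, nomogram ~ U(0, 0.13|SE| + 0.2);
    maximum lenticule thickness := round(attempted * OZ^2 / 3) um (Munnerlyn
    approximation — a generator heuristic only, never used in analysis);
    RST := CCT - cap - Max (eyes with negative RST are resampled).
5.  UDVA is a noisy logistic function of |SE|; CDVA is 1.0 or 1.2 decimal.
6.  Postoperative SE := intercept + sum of signed coefficients on
    z-standardized features + Gaussian noise (:class:`EffectSpec`); the
    default coefficient signs follow the reported correlation directions
    (positive: SD, SE, UDVA, RST; negative: K1, Km, Max, CCT, nomogram).
7.  Postoperative CDVA gains/losses are drawn so no eye loses two or more
    lines; postoperative UDVA degrades with the residual SE.

Quantile matching
-----------------
``sample_quantile_matched`` inverts a *median-glued two-piece normal*: each
half is a half-normal centred on the median with scale (median-P25)/0.6745
below and (P75-median)/0.6745 above (0.6745 = Phi^-1(0.75)).  Its quartiles
and median equal the targets exactly for any monotone triple, however skewed.
"""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import least_squares
from scipy.special import ndtr, ndtri

from .data_model import COLUMNS, FEATURE_NAMES, Cohort

__all__ = [
    "EffectSpec",
    "CenterProfile",
    "TwoPieceNormal",
    "sample_quantile_matched",
    "generate_center",
    "generate_multicenter",
    "default_profiles",
    "load_profile",
    "default_effect_spec",
    "planted_effect_spec",
    "REFERENCE_BASE_FEATURES",
]

_Q75 = 0.6744897501960817  # Phi^-1(0.75)

#: Default signed coefficients (D per 1 SD of feature) of the postoperative-SE
#: linear predictor; signs follow the reported correlation directions.
_DEFAULT_COEFFICIENTS: dict[str, float] = {
    "pre_sd": +0.06,
    "pre_se": +0.06,
    "pre_udva": +0.02,
    "rst": +0.04,
    "pre_k1": -0.02,
    "pre_km": -0.04,
    "max_lenticule": -0.08,
    "pre_cct": -0.06,
    "nomogram": -0.03,
}

#: Mutually weakly-dependent features used as the base set in planted-effect
#: validation designs (see docs/methods.md): none is a near-duplicate of
#: another, so a single amplified coefficient stays identifiable.
REFERENCE_BASE_FEATURES: tuple[str, ...] = (
    "age", "pre_iop", "pre_axis", "pre_udva",
    "pre_cct", "optical_zone", "cap_thickness", "laser_energy",
)

_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "optical_zone": (6.2, 7.0),
    "cap_thickness": (110.0, 140.0),
    "laser_energy": (125.0, 145.0),
}

_DEFAULT_GAIN_PROBS: dict[int, float] = {-1: 0.05, 0: 0.45, 1: 0.35, 2: 0.15}


class EffectSpec(BaseModel):
    """Linear predictor of postoperative SE over z-standardized features."""

    coefficients: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_COEFFICIENTS))
    noise_sd: float = Field(default=0.18, ge=0.0)
    intercept: float = 0.0

    @field_validator("coefficients")
    @classmethod
    def _known_features(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"effect coefficients on unknown features: {sorted(unknown)}")
        return v


def default_effect_spec() -> EffectSpec:
    """The default correlation-signed effect model."""
    return EffectSpec()


def planted_effect_spec(
    planted: str | Sequence[str],
    base: float = 0.05,
    factor: float = 3.0,
    noise_sd: float = 0.15,
    intercept: float = -0.30,
) -> EffectSpec:
    """Effect model for planted-recovery experiments.

    The planted feature(s) get coefficient ``factor * base``; the remaining
    members of :data:`REFERENCE_BASE_FEATURES` get ``base``.  Restricting the
    base set to mutually weakly-dependent features keeps the planted contrast
    well defined (near-duplicate groups such as K1/K2/Km would otherwise
    stack their base effects; see docs/methods.md).

    The default intercept emulates a mild systematic undercorrection so the
    three-class outcome index is monotone in the linear predictor; with the
    outcome centred exactly on target, the symmetric accuracy classes fold
    the predictor (mirrored values give identical class distributions) and a
    linear effect becomes nearly invisible to any class-based statistic.
    """
    planted_set = {planted} if isinstance(planted, str) else set(planted)
    unknown = planted_set - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown planted features: {sorted(unknown)}")
    coeff = {f: base for f in REFERENCE_BASE_FEATURES if f not in planted_set}
    coeff.update({f: factor * base for f in planted_set})
    return EffectSpec(coefficients=coeff, noise_sd=noise_sd, intercept=intercept)


class CenterProfile(BaseModel):
    """Distributional parameters defining one simulated center.

    ``marginals`` maps feature name to ``(median, p25, p75)``; ``ranges``
    maps a surgical design parameter to its uniform ``(low, high)`` range.
    ``k_spread`` is the half-range of K2 - K1 in diopters.
    """

    name: str
    n_eyes: int = Field(ge=1)
    male_fraction: float = Field(ge=0.0, le=1.0)
    marginals: dict[str, tuple[float, float, float]]
    ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(_DEFAULT_RANGES))
    k_spread: float = Field(default=1.5, gt=0.0)
    effect: EffectSpec = Field(default_factory=EffectSpec)
    cdva_gain_probs: dict[int, float] = Field(
        default_factory=lambda: dict(_DEFAULT_GAIN_PROBS))

    @model_validator(mode="after")
    def _check(self) -> "CenterProfile":
        required = {"age", "pre_sd", "pre_cd", "pre_se", "pre_cct", "pre_km"}
        missing = required - set(self.marginals)
        if missing:
            raise ValueError(f"profile {self.name!r} lacks marginals {sorted(missing)}")
        for feat, (med, p25, p75) in self.marginals.items():
            if not (p25 <= med <= p75):
                raise ValueError(
                    f"profile {self.name!r}, {feat}: need p25 <= median <= p75, "
                    f"got {med} ({p25}, {p75})")
        for par, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"profile {self.name!r}, {par}: range low > high")
        if any(g < -1 for g in self.cdva_gain_probs):
            raise ValueError("cdva_gain_probs must not allow losses of 2+ lines")
        total = sum(self.cdva_gain_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cdva_gain_probs must sum to 1")
        return self


class TwoPieceNormal:
    """Median-glued two-piece normal with exact (P25, median, P75).

    Each half is a half-normal centred on the median; a draw falls in either
    half with probability 1/2, so the quantile function is
    ``median + s_lo * Phi^-1(u)`` for u < 1/2 and ``median + s_up * Phi^-1(u)``
    above, with ``s_lo = (median - p25)/0.6745`` and
    ``s_up = (p75 - median)/0.6745``.
    """

    def __init__(self, median: float, p25: float, p75: float) -> None:
        if not (p25 <= median <= p75):
            raise ValueError("need p25 <= median <= p75")
        self.median = float(median)
        self.s_lo = (median - p25) / _Q75
        self.s_up = (p75 - median) / _Q75

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u >= 1)):
            raise ValueError("u must be in (0, 1)")
        z = ndtri(u)
        scale = np.where(u < 0.5, self.s_lo, self.s_up)
        out = self.median + scale * z
        return float(out) if out.ndim == 0 else out

    def rvs(self, n: int, rng: np.random.Generator):
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.s_lo == 0.0 and self.s_up == 0.0:
            return np.full(n, self.median)
        return self.ppf(rng.uniform(np.nextafter(0.0, 1.0), 1.0, size=n))


def sample_quantile_matched(
    median: float, p25: float, p75: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values whose P25/median/P75 converge to the given targets."""
    return TwoPieceNormal(median, p25, p75).rvs(n, rng)


# --------------------------------------------------------------------------
# refraction coupling calibration
#
# SD and CD are coupled through a latent normal whose location is shifted by
# a band-specific amount a_k over six SD-quantile bands; the latent value is
# mapped back to a uniform through the exact mixture CDF
# F(z) = sum_k pi_k Phi(z - a_k), so the CD marginal stays exactly
# quantile-matched while the band shifts reshape the distribution of the
# derived SE.  The six shifts are calibrated once per profile (deterministic
# fixed-sample least squares) so the SE median and quartiles hit the
# profile's targets.

_BAND_EDGES = np.array([0.10, 0.25, 0.50, 0.75, 0.90])
_BAND_PROBS = np.diff(np.concatenate(([0.0], _BAND_EDGES, [1.0])))


def _couple_cd(
    u1: np.ndarray, eps: np.ndarray, shifts: np.ndarray,
    dist_cd: "TwoPieceNormal",
) -> np.ndarray:
    """CD draws coupled to the SD uniforms ``u1`` via band shifts."""
    band = np.searchsorted(_BAND_EDGES, u1)
    z2 = shifts[band] + eps
    u2 = (_BAND_PROBS[None, :] * ndtr(z2[:, None] - shifts[None, :])).sum(axis=1)
    return np.minimum(dist_cd.ppf(np.clip(u2, 1e-12, 1.0 - 1e-12)), 0.0)


@functools.lru_cache(maxsize=64)
def _calibrated_band_shifts(
    sd_q: tuple[float, float, float],
    cd_q: tuple[float, float, float],
    se_q: tuple[float, float, float],
) -> tuple[float, ...]:
    """Band shifts such that SE = SD + CD/2 reproduces its target quantiles."""
    dist_sd = TwoPieceNormal(*sd_q)
    dist_cd = TwoPieceNormal(*cd_q)
    cal = np.random.default_rng(987654321)
    n = 200_000
    u1 = cal.random(n)
    eps = cal.standard_normal(n)
    sd = dist_sd.ppf(np.clip(u1, 1e-12, 1.0 - 1e-12))
    targets = np.asarray(se_q, dtype=float)          # (median, p25, p75)
    scale = max(se_q[2] - se_q[1], 1e-6)

    def residuals(shifts: np.ndarray) -> np.ndarray:
        se = sd + _couple_cd(u1, eps, shifts, dist_cd) / 2.0
        q = np.quantile(se, [0.5, 0.25, 0.75])
        return np.concatenate(((q - targets) / scale, 0.01 * shifts))

    sol = least_squares(residuals, np.zeros(_BAND_PROBS.size), diff_step=0.05)
    return tuple(float(v) for v in sol.x)


# --------------------------------------------------------------------------
# cohort generation

def _sample_pre_surgical(
    profile: CenterProfile, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw n eyes' preoperative and surgical-design values (no outcomes)."""
    m = profile.marginals
    tiny = np.nextafter(0.0, 1.0)

    sex = np.where(rng.random(n) < profile.male_fraction, "male", "female")
    laterality = np.where(rng.random(n) < 0.5, "right", "left")
    age = np.maximum(TwoPieceNormal(*m["age"]).rvs(n, rng), 1.0)

    # refraction triple: SD and CD coupled so the derived SE also matches
    shifts = np.asarray(_calibrated_band_shifts(
        tuple(m["pre_sd"]), tuple(m["pre_cd"]), tuple(m["pre_se"])))
    u1 = rng.random(n)
    eps = rng.standard_normal(n)
    pre_sd = TwoPieceNormal(*m["pre_sd"]).ppf(np.clip(u1, tiny, 1 - 1e-12))
    pre_cd = _couple_cd(u1, eps, shifts, TwoPieceNormal(*m["pre_cd"]))
    pre_se = pre_sd + pre_cd / 2.0

    pre_axis = rng.uniform(0.0, 180.0, n)
    pre_iop = np.clip(rng.normal(15.5, 2.5, n), 8.0, 30.0)

    pre_km = TwoPieceNormal(*m["pre_km"]).rvs(n, rng)
    u = rng.uniform(0.0, profile.k_spread, n)
    pre_k1 = pre_km - u
    pre_k2 = pre_km + u

    pre_cct = TwoPieceNormal(*m["pre_cct"]).rvs(n, rng)
    oz_lo, oz_hi = profile.ranges["optical_zone"]
    cap_lo, cap_hi = profile.ranges["cap_thickness"]
    en_lo, en_hi = profile.ranges["laser_energy"]
    optical_zone = rng.uniform(oz_lo, oz_hi, n)
    cap_thickness = rng.uniform(cap_lo, cap_hi, n)
    laser_energy = rng.uniform(en_lo, en_hi, n)

    nomogram = rng.uniform(0.0, 1.0, n) * (0.13 * np.abs(pre_se) + 0.2)
    attempted = np.abs(pre_se) + nomogram
    max_lenticule = np.rint(attempted * optical_zone ** 2 / 3.0)
    rst = pre_cct - cap_thickness - max_lenticule

    # UDVA: noisy logistic decline with the magnitude of the refractive error
    udva = 1.05 / (1.0 + np.exp(0.8 * (np.abs(pre_se) - 2.2)))
    udva = np.clip(udva * np.exp(rng.normal(0.0, 0.25, n)), 0.01, None)
    pre_cdva = np.where(rng.random(n) < 0.6, 1.0, 1.2)
    pre_udva = np.minimum(udva, pre_cdva)

    return {
        "sex": sex, "laterality": laterality, "age": age,
        "pre_sd": pre_sd, "pre_cd": pre_cd, "pre_axis": pre_axis,
        "pre_se": pre_se, "pre_udva": pre_udva, "pre_cdva": pre_cdva,
        "pre_iop": pre_iop, "pre_k1": pre_k1, "pre_k2": pre_k2,
        "pre_km": pre_km, "pre_cct": pre_cct,
        "cap_thickness": cap_thickness, "optical_zone": optical_zone,
        "laser_energy": laser_energy, "max_lenticule": max_lenticule,
        "rst": rst, "nomogram": nomogram,
    }


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _encode(columns: Mapping[str, np.ndarray], feature: str) -> np.ndarray:
    if feature == "sex":
        return (columns["sex"] == "male").astype(float)
    if feature == "laterality":
        return (columns["laterality"] == "right").astype(float)
    return np.asarray(columns[feature], dtype=float)


def generate_center(
    profile: CenterProfile, rng: np.random.Generator, n_eyes: int | None = None
) -> Cohort:
    """Generate one center's cohort; every record satisfies the eye-record
    invariants (SE identity, K ordering, RST identity).

    Eyes whose residual stromal thickness comes out negative are resampled
    (bounded retries).  ``n_eyes`` overrides the profile's count.
    """
    n = int(n_eyes if n_eyes is not None else profile.n_eyes)
    if n < 1:
        raise ValueError("n_eyes must be >= 1")
    cols = _sample_pre_surgical(profile, n, rng)
    for _ in range(100):
        bad = cols["rst"] < 0.0
        if not bad.any():
            break
        redraw = _sample_pre_surgical(profile, int(bad.sum()), rng)
        for key, arr in cols.items():
            arr[bad] = redraw[key]
    else:
        raise RuntimeError(
            f"profile {profile.name!r}: could not achieve non-negative RST")

    effect = profile.effect
    post_se = np.full(n, float(effect.intercept))
    for feature, coeff in effect.coefficients.items():
        post_se += coeff * _standardize(_encode(cols, feature))
    post_se += rng.normal(0.0, effect.noise_sd, n)

    gains = np.array(sorted(profile.cdva_gain_probs))
    probs = np.array([profile.cdva_gain_probs[g] for g in gains], dtype=float)
    gain = rng.choice(gains, size=n, p=probs / probs.sum())
    logmar_cdva_post = -np.log10(cols["pre_cdva"]) - 0.1 * gain
    post_cdva = np.power(10.0, -logmar_cdva_post)

    blur = 0.35 * np.maximum(np.abs(post_se) - 0.25, 0.0)
    extra = np.where(rng.random(n) < 0.9, 0.0,
                     np.abs(rng.normal(0.0, 0.05, n)))
    post_udva = np.power(10.0, -(logmar_cdva_post + blur + extra))

    df = pd.DataFrame({
        "center_id": np.full(n, profile.name, dtype=object),
        **{k: v for k, v in cols.items()},
        "post_se_3m": post_se,
        "post_udva": post_udva,
        "post_cdva": post_cdva,
    })
    return Cohort(df=df[list(COLUMNS)])


def generate_multicenter(
    profiles: Sequence[CenterProfile],
    rng: np.random.Generator | int,
) -> dict[str, Cohort]:
    """Independent cohorts, one per profile, with center labels stamped.

    Each center draws from its own named substream of the given seed or
    generator, so a center's cohort is reproducible independently of the
    other profiles in the run.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate center names: {names}")
    if not profiles:
        raise ValueError("need at least one profile")
    streams = rng.spawn(len(profiles))
    return {
        p.name: generate_center(p, stream)
        for p, stream in zip(profiles, streams)
    }


# --------------------------------------------------------------------------
# shipped profiles

def load_profile(source: str | Path | Mapping) -> CenterProfile:
    """Load a center profile from a YAML/JSON file path or a mapping."""
    if isinstance(source, Mapping):
        return CenterProfile.model_validate(source)
    with open(source, "r", encoding="utf-8") as fh:
        return CenterProfile.model_validate(yaml.safe_load(fh))


def default_profiles() -> list[CenterProfile]:
    """The three shipped center profiles (A, B, C)."""
    out = []
    for name in ("center_a", "center_b", "center_c"):
        text = (resources.files("smileig") / "profiles" / f"{name}.yaml").read_text()
        out.append(CenterProfile.model_validate(yaml.safe_load(text)))
    return out
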