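"""Synthetic multi-hospital perioperative cohort generator.

Three default hospital profiles ("A", "S", "E") mimic the marginal feature
distributions, category frequencies, emergency rates and rare 30-day
mortality prevalences of three large surgical cohorts.  Laboratory values
are drawn from a block-correlated multivariate normal (labs ordered within
the same panel correlate strongly), the outcome follows a per-site logistic
model on the standardized/encoded feature scale, and missingness is injected
MCAR at per-feature rates.  Every generation step is a pure function of
(profile, n, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from . import schema

__all__ = [
    "ContSpec",
    "HospitalProfile",
    "default_profiles",
    "perturb_coefficients",
    "calibrate_intercept",
    "sample_cohort",
    "inject_missingness",
    "encode_standardized",
    "write_cohort_csv",
    "read_cohort_csv",
]


@dataclass(frozen=True)
class ContSpec:
    """Generative parameters for one continuous feature (truncated normal)."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if self.lower >= self.upper:
            raise ValueError("lower bound must be below upper bound")


def _bounds(mean: float, sd: float, floor: float) -> tuple[float, float]:
    # mean +/- 5 sd, clipped at a physiologic floor; avoids absurd values only
    return (max(mean - 5.0 * sd, floor), mean + 5.0 * sd)


@dataclass
class HospitalProfile:
    """Generative parameters for one synthetic site."""

    site_id: str
    n_default: int
    cont_specs: dict[str, ContSpec]
    sex_p: float
    surgery_probs: dict[str, float]
    anesthesia_probs: dict[str, float]
    emergency_p: float
    lab_corr: np.ndarray
    beta: np.ndarray
    intercept: float
    target_prevalence: float
    miss_rates: dict[str, float] = field(default_factory=dict)
    heterogeneity_tau: float = 0.0

    def validate(self) -> None:
        for name, probs in (
            ("surgery_probs", self.surgery_probs),
            ("anesthesia_probs", self.anesthesia_probs),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"{name} sums to {total!r}, expected 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has negative entries")
        corr = np.asarray(self.lab_corr, dtype=float)
        k = len(schema.LABS)
        if corr.shape != (k, k):
            raise ValueError(f"lab_corr must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("lab_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("lab_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("lab_corr must be positive semi-definite")
        if not (0.0 < self.target_prevalence <= 0.05):
            raise ValueError("target_prevalence must be in (0, 0.05]")
        for feat, rate in self.miss_rates.items():
            if not (0.0 <= rate <= 0.10):
                raise ValueError(f"miss_rate[{feat}]={rate} outside [0, 0.10]")
        if len(self.beta) != schema.N_ENCODED:
            raise ValueError(
                f"beta length {len(self.beta)} != {schema.N_ENCODED}"
            )
        missing = set(schema.CONT_FEATURES) - set(self.cont_specs)
        if missing:
            raise ValueError(f"cont_specs missing features: {sorted(missing)}")

    # --- JSON (de)serialization -------------------------------------------

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["lab_corr"] = np.asarray(self.lab_corr).tolist()
        d["beta"] = np.asarray(self.beta).tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HospitalProfile":
        d = json.loads(text)
        d["cont_specs"] = {k: ContSpec(**v) for k, v in d["cont_specs"].items()}
        d["lab_corr"] = np.asarray(d["lab_corr"], dtype=float)
        d["beta"] = np.asarray(d["beta"], dtype=float)
        return cls(**d)


# ---------------------------------------------------------------------------
# Default profiles
# ---------------------------------------------------------------------------

# Per-site (mean, sd) for the continuous features.  Keys: site label ->
# feature -> (mean, sd).  Floors applied when deriving truncation bounds.
_CONT_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "S": {
        "age": (55.9, 16.1), "bmi": (24.6, 3.9),
        "wbc": (6.6, 3.0), "hb": (13.1, 1.8), "plt": (239.8, 73.5),
        "na": (140.2, 2.7), "k": (4.2, 0.4), "bun": (15.5, 8.1),
        "cr": (1.0, 1.1), "alb": (4.2, 0.5), "got": (24.4, 36.7),
        "gpt": (23.4, 32.5), "glu": (110.8, 30.5), "pt_inr": (1.0, 0.1),
        "aptt": (31.6, 4.6),
    },
    "A": {
        "age": (54.2, 15.9), "bmi": (24.2, 3.7),
        "wbc": (6.7, 2.4), "hb": (12.8, 1.9), "plt": (247.1, 72.7),
        "na": (139.8, 2.4), "k": (4.3, 0.3), "bun": (14.8, 6.8),
        "cr": (0.9, 0.7), "alb": (3.8, 0.5), "got": (25.0, 33.7),
        "gpt": (22.7, 32.3), "glu": (113.3, 36.9), "pt_inr": (1.0, 0.1),
        "aptt": (27.0, 3.3),
    },
    "E": {
        "age": (48.5, 17.1), "bmi": (23.8, 3.8),
        "wbc": (7.5, 3.9), "hb": (13.1, 1.9), "plt": (245.6, 72.0),
        "na": (140.7, 3.0), "k": (4.2, 0.4), "bun": (13.7, 6.9),
        "cr": (0.9, 0.7), "alb": (4.1, 0.6), "got": (26.5, 95.0),
        "gpt": (25.1, 50.9), "glu": (198.3, 243.9), "pt_inr": (1.0, 0.4),
        "aptt": (26.9, 5.4),
    },
}

_FLOORS: dict[str, float] = {"age": 18.0, "bmi": 10.0, "pt_inr": 0.5}
_DEFAULT_FLOOR = 0.01  # labs are strictly positive quantities

_SITE_N: dict[str, int] = {"S": 46_956, "A": 162_184, "E": 131_867}

# Category counts (surgery categories have an implicit "other" remainder;
# anesthesia counts sum to n exactly for S and A).
_SURGERY_COUNTS: dict[str, list[int]] = {
    #        general  oto     uro     ortho   gyn     plastic
    "S": [13_487, 4_537, 4_738, 6_736, 4_956, 1_862],
    "A": [60_613, 15_270, 20_551, 24_480, 31_691, 6_213],
    "E": [40_611, 14_279, 9_117, 23_486, 26_509, 9_788],
}
_ANESTHESIA_COUNTS: dict[str, list[int]] = {
    #        general   neuroaxial  mac    regional
    "S": [36_060, 5_052, 5_792, 52],
    "A": [149_542, 11_281, 0, 1_361],
    "E": [100_223, 10_716, 4_985, 509],
}
_SEX_FEMALE: dict[str, int] = {"S": 26_236, "A": 94_413, "E": 79_232}
_EMERGENCY: dict[str, int] = {"S": 3_456, "A": 8_876, "E": 4_208}
_MORTALITY: dict[str, int] = {"S": 156, "A": 306, "E": 316}

# Default per-feature MCAR missingness rates (bounded by the observed
# 0.00%-7.63% range; BMI, anesthesia type and glucose are the worst).
_DEFAULT_MISS_RATES: dict[str, dict[str, float]] = {
    "S": {"bmi": 0.005, "glu": 0.01, "alb": 0.01, "pt_inr": 0.02,
          "aptt": 0.02},
    "A": {"bmi": 0.002, "glu": 0.005, "alb": 0.008, "pt_inr": 0.01,
          "aptt": 0.01},
    "E": {"bmi": 0.0763, "anesthesia_type": 0.05, "glu": 0.03,
          "alb": 0.02, "pt_inr": 0.02, "aptt": 0.02},
}

#: default coefficient vector on the standardized/encoded scale; a few strong
#: predictors (age, albumin, emergency surgery) so discrimination is
#: non-trivial.  Package defaults, not estimates from any real cohort.
_BASE_BETA_MAP: dict[str, float] = {
    "age": 1.2,
    "bmi": -0.2,
    "wbc": 0.3,
    "hb": -0.3,
    "plt": -0.2,
    "na": -0.2,
    "k": 0.1,
    "bun": 0.3,
    "cr": 0.4,
    "alb": -1.0,
    "got": 0.15,
    "gpt": 0.1,
    "glu": 0.2,
    "pt_inr": 0.3,
    "aptt": 0.1,
    "sex": -0.1,
    "surgery_general": 0.3,
    "surgery_otolaryngologic": -0.2,
    "surgery_urologic": -0.1,
    "surgery_orthopedic": 0.0,
    "surgery_gynecological": -0.3,
    "surgery_plastic": -0.2,
    "surgery_other": 0.1,
    "anesthesia_general": 0.2,
    "anesthesia_neuroaxial": -0.1,
    "anesthesia_mac": -0.2,
    "anesthesia_regional": -0.1,
    "anesthesia_other": 0.0,
    "emergency": 1.0,
}


def base_beta() -> np.ndarray:
    """Default coefficient vector in :data:`schema.ENCODED_COLUMNS` order."""
    return np.array([_BASE_BETA_MAP[c] for c in schema.ENCODED_COLUMNS])


def default_lab_corr(within: float = 0.75) -> np.ndarray:
    """Block compound-symmetry correlation over the 13 labs: ``within`` inside
    each panel, zero across panels (positive semi-definite by construction)."""
    k = len(schema.LABS)
    corr = np.eye(k)
    idx = {lab: i for i, lab in enumerate(schema.LABS)}
    for block in schema.LAB_BLOCKS:
        for a in block:
            for b in block:
                if a != b:
                    corr[idx[a], idx[b]] = within
    return corr


def _category_probs(counts: list[int], cats: list[str], n: int) -> dict[str, float]:
    """Counts -> probabilities with an 'other' remainder, renormalized so the
    vector sums to one even when printed counts/percentages are inconsistent."""
    rem = max(n - sum(counts), 0)
    raw = np.array(counts + [rem], dtype=float)
    raw /= raw.sum()
    return dict(zip(cats, raw))


def _build_profile(site: str) -> HospitalProfile:
    n = _SITE_N[site]
    cont_specs = {
        feat: ContSpec(m, s, *_bounds(m, s, _FLOORS.get(feat, _DEFAULT_FLOOR)))
        for feat, (m, s) in _CONT_PARAMS[site].items()
    }
    profile = HospitalProfile(
        site_id=site,
        n_default=n,
        cont_specs=cont_specs,
        sex_p=_SEX_FEMALE[site] / n,
        surgery_probs=_category_probs(
            _SURGERY_COUNTS[site], schema.SURGERY_CATEGORIES, n
        ),
        anesthesia_probs=_category_probs(
            _ANESTHESIA_COUNTS[site], schema.ANESTHESIA_CATEGORIES, n
        ),
        emergency_p=_EMERGENCY[site] / n,
        lab_corr=default_lab_corr(),
        beta=base_beta(),
        intercept=0.0,  # replaced by calibration below
        target_prevalence=_MORTALITY[site] / n,
        miss_rates=dict(_DEFAULT_MISS_RATES[site]),
        heterogeneity_tau=0.0,
    )
    return profile


def default_profiles(calibrate: bool = True, n_mc: int = 20_000,
                     seed: int = 1234) -> dict[str, HospitalProfile]:
    """The three default site profiles keyed ``"A"``, ``"S"``, ``"E"``.

    With ``calibrate=True`` (default) each intercept is set so the simulated
    outcome prevalence matches the site's target prevalence.
    """
    profiles = {}
    for i, site in enumerate(("A", "S", "E")):
        prof = _build_profile(site)
        if calibrate:
            prof.intercept = calibrate_intercept(
                prof, prof.target_prevalence, n_mc=n_mc, seed=seed + i
            )
        prof.validate()
        profiles[site] = prof
    return profiles


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def perturb_coefficients(base_beta: np.ndarray, tau: float,
                         seed: int) -> np.ndarray:
    """Add iid N(0, tau^2) noise to each coefficient (site heterogeneity)."""
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    base = np.asarray(base_beta, dtype=float)
    if tau == 0:
        return base.copy()
    rng = np.random.default_rng(seed)
    return base + rng.normal(0.0, tau, size=base.shape)


def _sample_raw_features(profile: HospitalProfile, n: int,
                         rng: np.random.Generator) -> pd.DataFrame:
    labs = schema.LABS
    corr = np.asarray(profile.lab_corr, dtype=float)
    try:
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(labs)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("lab_corr is not a valid correlation matrix") from exc
    z = rng.standard_normal((n, len(labs))) @ chol.T
    data: dict[str, np.ndarray] = {}
    for j, lab in enumerate(labs):
        spec = profile.cont_specs[lab]
        vals = spec.mean + spec.sd * z[:, j]
        data[lab] = np.clip(vals, spec.lower, spec.upper)
    for feat in ("age", "bmi"):
        spec = profile.cont_specs[feat]
        a = (spec.lower - spec.mean) / spec.sd
        b = (spec.upper - spec.mean) / spec.sd
        data[feat] = stats.truncnorm.rvs(
            a, b, loc=spec.mean, scale=spec.sd, size=n, random_state=rng
        )
    data["sex"] = np.where(
        rng.random(n) < profile.sex_p, "female", "male"
    )
    data["surgery_type"] = rng.choice(
        schema.SURGERY_CATEGORIES, size=n,
        p=[profile.surgery_probs[c] for c in schema.SURGERY_CATEGORIES],
    )
    data["anesthesia_type"] = rng.choice(
        schema.ANESTHESIA_CATEGORIES, size=n,
        p=[profile.anesthesia_probs[c] for c in schema.ANESTHESIA_CATEGORIES],
    )
    data["emergency"] = (rng.random(n) < profile.emergency_p).astype(int)
    df = pd.DataFrame(data)
    return df[schema.FEATURE_COLUMNS]


def encode_standardized(df: pd.DataFrame,
                        profile: HospitalProfile) -> np.ndarray:
    """Encode raw features on the generative model's scale: continuous
    features z-scored with the profile's nominal mean/sd, categoricals
    one-hot with the fixed vocabulary.  Columns follow
    :data:`schema.ENCODED_COLUMNS`."""
    n = len(df)
    X = np.zeros((n, schema.N_ENCODED))
    col = {c: i for i, c in enumerate(schema.ENCODED_COLUMNS)}
    for feat in schema.CONT_FEATURES:
        spec = profile.cont_specs[feat]
        X[:, col[feat]] = (df[feat].to_numpy(float) - spec.mean) / spec.sd
    X[:, col["sex"]] = (df["sex"] == "female").astype(float)
    for c in schema.SURGERY_CATEGORIES:
        X[:, col[f"surgery_{c}"]] = (df["surgery_type"] == c).astype(float)
    for c in schema.ANESTHESIA_CATEGORIES:
        X[:, col[f"anesthesia_{c}"]] = (df["anesthesia_type"] == c).astype(float)
    X[:, col["emergency"]] = df["emergency"].to_numpy(float)
    return X


def calibrate_intercept(profile: HospitalProfile, target_prevalence: float,
                        n_mc: int = 20_000, seed: int = 0,
                        max_steps: int = 100) -> float:
    """Intercept making the Monte-Carlo mean of sigmoid(b + beta.x) match the
    target prevalence, found by bisection (the mean is monotone in b)."""
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target_prevalence must be in (0, 1)")
    beta = np.asarray(profile.beta, dtype=float)
    if not np.any(beta):
        return float(logit(target_prevalence))
    rng = np.random.default_rng(seed)
    X = encode_standardized(_sample_raw_features(profile, n_mc, rng), profile)
    eta = X @ beta

    def prev(b: float) -> float:
        return float(np.mean(expit(b + eta)))

    lo, hi = -40.0, 40.0
    if not (prev(lo) <= target_prevalence <= prev(hi)):
        raise RuntimeError("intercept calibration failed: target not bracketed")
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        if prev(mid) < target_prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    b = 0.5 * (lo + hi)
    if abs(prev(b) - target_prevalence) > 0.10 * target_prevalence:
        raise RuntimeError(
            "intercept calibration did not converge; misspecified profile?"
        )
    return float(b)


def sample_cohort(profile: HospitalProfile, n: int, seed: int) -> pd.DataFrame:
    """Draw a complete cohort table (no missing cells) for one site."""
    if n < 1:
        raise ValueError("n must be >= 1")
    profile.validate()
    rng = np.random.default_rng(seed)
    df = _sample_raw_features(profile, n, rng)
    X = encode_standardized(df, profile)
    p = expit(profile.intercept + X @ np.asarray(profile.beta, dtype=float))
    df["outcome"] = rng.binomial(1, p)
    df["site"] = profile.site_id
    return df[schema.COLUMNS]


def inject_missingness(table: pd.DataFrame, miss_rates: dict[str, float],
                       seed: int) -> pd.DataFrame:
    """Independently blank each eligible cell with its feature's MCAR rate.

    The outcome and site columns are never eligible.
    """
    for feat, rate in miss_rates.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"miss rate for {feat} outside [0,1]: {rate}")
        if feat in ("outcome", "site"):
            raise ValueError(f"{feat} is not eligible for missingness")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for feat in schema.FEATURE_COLUMNS:
        rate = miss_rates.get(feat, 0.0)
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        if out[feat].dtype.kind in "iu":
            out[feat] = out[feat].astype(float)
        out.loc[mask, feat] = np.nan
    return out


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """One row per patient, header row, UTF-8, empty string for missing."""
    table.to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site": str, "sex": str, "surgery_type": str,
                                  "anesthesia_type": str})
    missing = set(schema.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df[schema.COLUMNS]
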