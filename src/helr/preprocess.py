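"""Cohort preprocessing: per-site median imputation, per-site standardization
(computed before any encryption step), fixed-vocabulary one-hot encoding,
6:2:2 splitting and missingness diagnostics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema

__all__ = [
    "StandardizationParams",
    "DesignMatrix",
    "SplitIndices",
    "impute_median",
    "standardize_per_site",
    "one_hot_encode",
    "prepare_design",
    "split_622",
    "missingness_diagnostics",
]

_CATEGORICAL = list(schema.CATEGORICAL_VOCABS) + schema.BINARY_FEATURES


@dataclass
class StandardizationParams:
    """Per-(site, continuous feature) mean and sd, estimated on observed
    values at that site.  Reused verbatim in scoring mode so test data never
    contribute to the parameters."""

    params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )

    def get(self, site: str, feature: str) -> tuple[float, float]:
        return self.params[site][feature]

    def to_json(self) -> str:
        return json.dumps(self.params, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StandardizationParams":
        raw = json.loads(text)
        return cls({s: {f: tuple(v) for f, v in d.items()}
                    for s, d in raw.items()})

    def checksum(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


@dataclass
class DesignMatrix:
    """Model-ready numeric matrix with its column schema, outcome and site."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    site: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape != (len(self.y), len(self.columns)):
            raise ValueError("X shape inconsistent with columns/outcome")
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing entries")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(self.X[idx], list(self.columns), self.y[idx],
                            self.site[idx])


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k).tolist()
                           for k in ("train", "val", "test")})

    @classmethod
    def from_json(cls, text: str) -> "SplitIndices":
        d = json.loads(text)
        return cls(*(np.asarray(d[k], dtype=int)
                     for k in ("train", "val", "test")))


def impute_median(table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing continuous cells by the per-site median of observed
    values and missing categorical cells by the per-site modal category."""
    out = table.copy()
    for site, idx in out.groupby("site").groups.items():
        block = out.loc[idx]
        for feat in schema.CONT_FEATURES:
            col = block[feat]
            if col.isna().all():
                raise ValueError(
                    f"feature {feat!r} entirely missing at site {site!r}"
                )
            if col.isna().any():
                out.loc[idx, feat] = col.fillna(float(col.median()))
        for feat in _CATEGORICAL:
            col = block[feat]
            if col.isna().all():
                raise ValueError(
                    f"feature {feat!r} entirely missing at site {site!r}"
                )
            if col.isna().any():
                mode = col.mode(dropna=True).iloc[0]
                out.loc[idx, feat] = col.fillna(mode)
    if out["emergency"].notna().all():
        out["emergency"] = out["emergency"].astype(int)
    return out


def standardize_per_site(
    table: pd.DataFrame,
    params: StandardizationParams | None = None,
) -> tuple[pd.DataFrame, StandardizationParams]:
    """z-score every continuous feature within its site.

    When ``params`` is supplied (scoring mode) the stored means/sds are
    reused; otherwise they are computed from the table and returned.
    Imputation must have been applied first.
    """
    for feat in schema.CONT_FEATURES:
        if table[feat].isna().any():
            raise ValueError(f"feature {feat!r} still has missing values; "
                             "impute before standardizing")
    out = table.copy()
    fitted = params is None
    if fitted:
        params = StandardizationParams()
    for site, idx in out.groupby("site").groups.items():
        if fitted:
            site_params = {}
            for feat in schema.CONT_FEATURES:
                vals = out.loc[idx, feat].to_numpy(float)
                mean = float(vals.mean())
                sd = float(vals.std(ddof=0))
                if sd <= 0:
                    raise ValueError(
                        f"zero within-site sd for {feat!r} at site {site!r}"
                    )
                site_params[feat] = (mean, sd)
            params.params[str(site)] = site_params
        for feat in schema.CONT_FEATURES:
            mean, sd = params.get(str(site), feat)
            out.loc[idx, feat] = (out.loc[idx, feat] - mean) / sd
    return out, params


def one_hot_encode(table: pd.DataFrame) -> DesignMatrix:
    """Encode a standardized table into the fixed model-matrix schema.

    Every categorical keeps its full indicator group (no reference category
    dropped; the ridge penalty absorbs the redundancy).
    """
    n = len(table)
    cols = schema.ENCODED_COLUMNS
    pos = {c: i for i, c in enumerate(cols)}
    X = np.zeros((n, len(cols)))
    for feat in schema.CONT_FEATURES:
        X[:, pos[feat]] = table[feat].to_numpy(float)
    for feat, vocab in schema.CATEGORICAL_VOCABS.items():
        observed = table[feat].astype(str)
        unseen = set(observed.unique()) - set(vocab)
        if unseen:
            raise ValueError(f"unseen categories in {feat!r}: {sorted(unseen)}")
        if feat == "sex":
            X[:, pos["sex"]] = (observed == "female").astype(float)
        else:
            prefix = feat.split("_")[0]
            for cat in vocab:
                X[:, pos[f"{prefix}_{cat}"]] = (observed == cat).astype(float)
    X[:, pos["emergency"]] = table["emergency"].to_numpy(float)
    y = table["outcome"].to_numpy(int)
    site = table["site"].to_numpy(str)
    return DesignMatrix(X, list(cols), y, site)


def prepare_design(
    table: pd.DataFrame,
    params: StandardizationParams | None = None,
) -> tuple[DesignMatrix, StandardizationParams]:
    """impute -> standardize -> encode, returning the fitted (or reused)
    standardization parameters."""
    imputed = impute_median(table)
    standardized, params = standardize_per_site(imputed, params)
    return one_hot_encode(standardized), params


def split_622(n: int, seed: int) -> SplitIndices:
    """6:2:2 train/validation/test split by seeded uniform shuffle.

    Validation and test sizes are round(0.2 n) each; training takes the
    remainder.  Unstratified.
    """
    if n < 5:
        raise ValueError("n must be >= 5 for a 6:2:2 split")
    n_val = round(0.2 * n)
    n_test = round(0.2 * n)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(
        train=np.sort(perm[: n - n_val - n_test]),
        val=np.sort(perm[n - n_val - n_test: n - n_test]),
        test=np.sort(perm[n - n_test:]),
    )


def missingness_diagnostics(table: pd.DataFrame,
                            threshold: float = 0.7) -> dict:
    """Missingness report: per-feature missing rates, pairwise Pearson
    correlations of the missingness indicators and of observed feature
    values, and the pairs at or above the flag threshold."""
    feats = schema.FEATURE_COLUMNS
    miss = table[feats].isna()
    rates = miss.mean().to_dict()
    miss_f = miss.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        miss_corr = miss_f.corr()
    numeric = table[schema.CONT_FEATURES].apply(
        pd.to_numeric, errors="coerce"
    )
    value_corr = numeric.corr()
    flagged = []
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            r = miss_corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                flagged.append((a, b, float(r)))
    return {
        "miss_rates": rates,
        "miss_corr": miss_corr,
        "value_corr": value_corr,
        "flagged_pairs": flagged,
        "threshold": threshold,
    }
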