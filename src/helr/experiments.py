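"""Experiment orchestration: the cross-site validation matrix, the model
adaptation curves (donor hospital's encrypted data plus growing increments
of the host hospital's own data), and the ciphertext/plaintext parity study.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .he import HEContext, KeyPair, RefreshAuthority, keygen
from .lr import TrainConfig, predict_proba, train_plaintext
from .metrics import bootstrap_evaluate
from .preprocess import DesignMatrix, SplitIndices, prepare_design, split_622
from .secure import decrypt_weights, merge_encrypted, pack_dataset, \
    train_encrypted

logger = logging.getLogger("helr")

__all__ = [
    "ExperimentConfig",
    "ParityReport",
    "build_site_data",
    "run_cross_site_matrix",
    "run_adaptation",
    "run_parity",
]

DEFAULT_SCHEDULE = [0, 1000, 3000, 6000, 10_000, 15_000, 20_000]
EXTENDED_SCHEDULE = DEFAULT_SCHEDULE + [30_000]


@dataclass
class ExperimentConfig:
    """Everything one experiment run needs; serializable and hashable so
    every output artifact can be stamped."""

    n_per_site: dict[str, int] = field(
        default_factory=lambda: {"A": 4000, "S": 2000, "E": 3000}
    )
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=3, sigmoid_mode="poly"))
    he: dict = field(default_factory=dict)     # HEContext keyword overrides
    bootstrap_B: int = 20
    schedule: list[int] = field(default_factory=lambda: list(DEFAULT_SCHEDULE))
    seed: int = 0
    outdir: str = "helr_out"
    use_encryption: bool = True
    heterogeneity_tau: float = 0.0
    prevalence: float | None = None    # desk-scale outcome-rate override
    cohort_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sched = list(self.schedule)
        if sched and (sched[0] != 0 or sorted(set(sched)) != sched):
            raise ValueError("schedule must be strictly increasing and "
                             "start at 0")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class ParityReport:
    """Absolute differences between encrypted-pipeline and plaintext-pipeline
    predicted probabilities on one fixed test set."""

    mean_abs_diff: float
    min_abs_diff: float
    max_abs_diff: float
    n: int
    context_params: dict
    config_hash: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_abs_diff <= self.mean_abs_diff
                <= self.max_abs_diff):
            raise ValueError("parity report must satisfy 0 <= min <= mean "
                             "<= max")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Data assembly
# ---------------------------------------------------------------------------


@dataclass
class SiteData:
    design: DesignMatrix
    split: SplitIndices

    @property
    def train(self) -> DesignMatrix:
        return self.design.subset(self.split.train)

    @property
    def val(self) -> DesignMatrix:
        return self.design.subset(self.split.val)

    @property
    def test(self) -> DesignMatrix:
        return self.design.subset(self.split.test)


def build_site_data(config: ExperimentConfig) -> dict[str, SiteData]:
    """Generate (or load), preprocess and split each site's cohort.

    Each hospital is preprocessed on its own full table (imputation and
    standardization are site-local, applied before any encryption) and then
    split 6:2:2 site-locally, so every training combination is evaluated
    against fixed per-site test partitions.
    """
    profiles = synth.default_profiles()
    sites: dict[str, SiteData] = {}
    for i, (site, n) in enumerate(sorted(config.n_per_site.items())):
        if site in config.cohort_paths:
            table = synth.read_cohort_csv(config.cohort_paths[site])
        else:
            prof = profiles[site]
            if config.prevalence is not None:
                prof.target_prevalence = config.prevalence
            if config.heterogeneity_tau > 0:
                prof.beta = synth.perturb_coefficients(
                    prof.beta, config.heterogeneity_tau,
                    seed=config.seed * 31 + i,
                )
            if config.heterogeneity_tau > 0 or config.prevalence is not None:
                prof.intercept = synth.calibrate_intercept(
                    prof, prof.target_prevalence, seed=config.seed * 31 + i
                )
            table = synth.sample_cohort(prof, n, seed=config.seed * 101 + i)
            table = synth.inject_missingness(
                table, prof.miss_rates, seed=config.seed * 101 + i + 50
            )
        design, _ = prepare_design(table)
        split = split_622(design.n, seed=config.seed * 7 + i)
        sites[site] = SiteData(design, split)
    return sites


def _concat_design(parts: list[DesignMatrix]) -> DesignMatrix:
    cols = parts[0].columns
    return DesignMatrix(
        np.vstack([p.X for p in parts]),
        list(cols),
        np.concatenate([p.y for p in parts]),
        np.concatenate([p.site for p in parts]),
    )


# ---------------------------------------------------------------------------
# Trainer factories
# ---------------------------------------------------------------------------


@dataclass
class HESetup:
    context: HEContext
    keys: KeyPair
    authority: RefreshAuthority


def make_he_setup(config: ExperimentConfig) -> HESetup:
    context = HEContext(**config.he)
    keys = keygen(context, seed=config.seed + 99)
    return HESetup(context, keys, RefreshAuthority(keys))


def plaintext_trainer(config: ExperimentConfig, columns: list[str]):
    def trainer(X, y, replicate_seed, sites=None):
        tc = dataclasses.replace(config.train, seed=replicate_seed)
        weights, _ = train_plaintext(X, y, tc, columns=columns)
        return lambda Xt: predict_proba(weights, Xt)
    return trainer


def encrypted_trainer(config: ExperimentConfig, columns: list[str],
                      setup: HESetup):
    """Each participating site packs/encrypts its own rows; the packs are
    merged without decryption and trained on ciphertext."""
    def trainer(X, y, replicate_seed, sites=None):
        tc = dataclasses.replace(config.train, seed=replicate_seed,
                                 sigmoid_mode="poly")
        if sites is None:
            sites = np.full(len(y), "merged")
        sites = np.asarray(sites, dtype=str)
        packs = []
        for site in sorted(set(sites)):
            idx = np.flatnonzero(sites == site)
            matrix = DesignMatrix(X[idx], list(columns), y[idx], sites[idx])
            packs.append(pack_dataset(matrix, setup.context, setup.keys,
                                      batch_size=tc.batch_size))
        pack = merge_encrypted(packs)
        enc = train_encrypted(pack, tc, setup.context, setup.authority)
        weights = decrypt_weights(enc, setup.keys.secret_key)
        return lambda Xt: predict_proba(weights, Xt)
    return trainer


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def _stamp(df: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.config_hash()
    df["seed"] = config.seed
    return df


def run_cross_site_matrix(config: ExperimentConfig,
                          sites: dict[str, SiteData] | None = None,
                          ) -> pd.DataFrame:
    """All training combinations (singles trained in plaintext; merged
    combinations trained on ciphertext) evaluated by bootstrap on every
    site's fixed test partition.  Returns tidy rows:
    train_combo, test_site, metric, mean, ci_lo, ci_hi, B, seed."""
    sites = sites or build_site_data(config)
    if len(sites) < 2:
        raise ValueError("cross-site matrix needs at least 2 sites")
    names = sorted(sites)
    columns = sites[names[0]].design.columns
    test_sets = {s: (sites[s].test.X, sites[s].test.y) for s in names}
    setup = make_he_setup(config) if config.use_encryption else None

    combos: list[tuple[str, ...]] = [(s,) for s in names]
    for r in range(2, len(names) + 1):
        combos += list(combinations(names, r))

    rows = []
    for combo in combos:
        stage = "+".join(combo)
        merged = _concat_design([sites[s].train for s in combo])
        encrypted = len(combo) > 1 and config.use_encryption
        trainer = (encrypted_trainer(config, columns, setup) if encrypted
                   else plaintext_trainer(config, columns))
        logger.info("cross-site: training %s (%s, n=%d)", stage,
                    "ciphertext" if encrypted else "plaintext", merged.n)
        try:
            _, cis = bootstrap_evaluate(
                trainer, (merged.X, merged.y), test_sets,
                meta=merged.site if encrypted else None,
                B=config.bootstrap_B,
                seed=config.seed
                + int(hashlib.sha256(stage.encode()).hexdigest()[:6], 16)
                % 1000,
            )
        except Exception as exc:
            raise RuntimeError(f"cross-site stage {stage!r} failed") from exc
        for s in names:
            for metric in ("auroc", "auprc"):
                ci = cis[s][metric]
                rows.append({
                    "train_combo": stage,
                    "mode": "ciphertext" if encrypted else "plaintext",
                    "test_site": s,
                    "metric": metric,
                    "mean": ci.mean,
                    "ci_lo": ci.lower,
                    "ci_hi": ci.upper,
                    "B": config.bootstrap_B,
                })
    return _stamp(pd.DataFrame(rows), config)


def run_adaptation(config: ExperimentConfig, donor: str, host: str,
                   sites: dict[str, SiteData] | None = None,
                   ) -> pd.DataFrame:
    """Adaptation curve: for each host-data size in the schedule, merge the
    donor's full encrypted training set with a nested prefix of the host's
    training rows, train, and bootstrap-evaluate on the host's test set.

    Host subsets are prefixes of one seeded shuffle, so the rows used at any
    size contain all rows used at smaller sizes.  Returns boxplot-ready
    per-replicate rows: size, replicate, auroc, auprc."""
    sites = sites or build_site_data(config)
    donor_train = sites[donor].train
    host_train = sites[host].train
    host_test = sites[host].test
    if max(config.schedule) > host_train.n:
        raise ValueError(
            f"schedule max {max(config.schedule)} exceeds host training "
            f"rows {host_train.n}"
        )
    columns = donor_train.columns
    perm = np.random.default_rng(config.seed + 13).permutation(host_train.n)
    setup = make_he_setup(config) if config.use_encryption else None
    trainer = (encrypted_trainer(config, columns, setup)
               if config.use_encryption
               else plaintext_trainer(config, columns))
    rows = []
    for size in config.schedule:
        parts = [donor_train]
        if size > 0:
            parts.append(host_train.subset(np.sort(perm[:size])))
        merged = _concat_design(parts)
        logger.info("adaptation: donor=%s host=%s size=%d (n=%d)", donor,
                    host, size, merged.n)
        result, _ = bootstrap_evaluate(
            trainer, (merged.X, merged.y),
            {host: (host_test.X, host_test.y)},
            meta=merged.site if config.use_encryption else None,
            B=config.bootstrap_B, seed=config.seed + size,
        )
        for b in range(config.bootstrap_B):
            rows.append({
                "donor": donor,
                "host": host,
                "size": size,
                "replicate": b,
                "auroc": result.auroc[host][b],
                "auprc": result.auprc[host][b],
            })
    return _stamp(pd.DataFrame(rows), config)


def run_parity(config: ExperimentConfig,
               sites: dict[str, SiteData] | None = None) -> ParityReport:
    """Train the plaintext mirror and the encrypted model with identical
    seeds/config/batch order on the merged training data, score the merged
    held-out test set with both decrypted weight vectors, and report the
    absolute prediction differences."""
    if config.train.sigmoid_mode != "poly":
        raise ValueError("parity requires sigmoid_mode='poly' in both arms")
    sites = sites or build_site_data(config)
    names = sorted(sites)
    train = _concat_design([sites[s].train for s in names])
    test = _concat_design([sites[s].test for s in names])
    setup = make_he_setup(config)

    plain_w, _ = train_plaintext(train.X, train.y, config.train,
                                 columns=train.columns)
    pack = pack_dataset(train, setup.context, setup.keys,
                        batch_size=config.train.batch_size)
    enc = train_encrypted(pack, config.train, setup.context, setup.authority)
    enc_w = decrypt_weights(enc, setup.keys.secret_key)

    p_plain = predict_proba(plain_w, test.X)
    p_enc = predict_proba(enc_w, test.X)
    diffs = np.abs(p_plain - p_enc)
    logger.info("parity: refreshes=%d, mean|diff|=%.3e, max|diff|=%.3e",
                setup.authority.refresh_count, diffs.mean(), diffs.max())
    return ParityReport(
        mean_abs_diff=float(diffs.mean()),
        min_abs_diff=float(diffs.min()),
        max_abs_diff=float(diffs.max()),
        n=len(diffs),
        context_params={
            "ring_dim": setup.context.ring_dim,
            "scale": setup.context.scale,
            "level_budget": setup.context.level_budget,
        },
        config_hash=config.config_hash(),
        seed=config.seed,
    )
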