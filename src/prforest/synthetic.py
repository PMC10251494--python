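"""Seeded synthetic cohorts emulating an early-MS clinical trial table.

The generator produces a tabular cohort with the structure the rest of
the package expects: strictly positive, right-skewed volumetric features
drawn log-normally per latent class (smaller deep-gray-matter volumes
and larger lesion volume in the positive class), an independent binary
treatment arm, and a confirmed/post hoc label mechanism with latent
truth.  Post hoc subjects always carry the nominal label "stable",
whatever their latent class — that asymmetry is the whole point.

Nothing here is fit to real data; the class-conditional effect sizes
are calibration knobs chosen so that a forest given oracle labels
reaches a mean AUC in roughly the 0.75-0.85 range at the default cohort
size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .dataset import DEFAULT_CLASS_NAMES, LabelStatus, UncertainDataset

__all__ = [
    "FeatureSpec",
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "cohort_to_csv",
    "csv_to_dataset",
    "default_truth_path",
]

RESERVED_COLUMNS = ("sample_id", "label", "label_status", "p_stable")


class FeatureSpec(BaseModel):
    """Class-conditional generative spec for one feature.

    ``lognormal`` features have median ``stable_median`` (mm^3) in the
    stable class and log-scale sd ``sigma_log``; the positive class
    shifts the log-mean by ``effect_size * sigma_log`` (standardized
    effect, negative = atrophy).  ``bernoulli`` features are binary with
    per-class rates.
    """

    name: str
    family: Literal["lognormal", "bernoulli"]
    stable_median: float = Field(default=1000.0, gt=0)
    sigma_log: float = Field(default=0.12, gt=0)
    effect_size: float = 0.0
    rate: float = Field(default=0.5, ge=0, le=1)
    positive_rate: Optional[float] = Field(default=None, ge=0, le=1)

    @field_validator("effect_size")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not np.isfinite(v):
            raise ValueError("effect_size must be finite")
        return v

    def log_mu(self, positive: bool) -> float:
        mu = float(np.log(self.stable_median))
        if positive:
            mu += self.effect_size * self.sigma_log
        return mu


def default_features(treatment_assignment_rate: float = 0.5) -> list[FeatureSpec]:
    """The study-shaped 10-feature default: 8 DGM volumes, lesion volume, arm."""
    dgm = [
        ("L_thalamus", 6200.0, -0.75),
        ("R_thalamus", 6200.0, -0.75),
        ("L_putamen", 4300.0, -0.375),
        ("R_putamen", 4300.0, -0.375),
        ("L_caudate", 3500.0, -0.325),
        ("R_caudate", 3500.0, -0.325),
        ("L_pallidum", 1500.0, -0.275),
        ("R_pallidum", 1500.0, -0.275),
    ]
    feats = [
        FeatureSpec(name=n, family="lognormal", stable_median=m,
                    sigma_log=0.12, effect_size=e)
        for n, m, e in dgm
    ]
    feats.append(
        FeatureSpec(name="BOD", family="lognormal", stable_median=1675.15,
                    sigma_log=1.0, effect_size=1.1)
    )
    feats.append(
        FeatureSpec(name="mino", family="bernoulli",
                    rate=treatment_assignment_rate)
    )
    return feats


class SyntheticConfig(BaseModel):
    """Generative parameters for a synthetic cohort."""

    n_confirmed_positive: int = Field(default=81, ge=0)
    n_confirmed_stable: int = Field(default=29, ge=0)
    n_posthoc: int = Field(default=32, ge=0)
    latent_positive_rate_posthoc: float = Field(default=0.5, ge=0, le=1)
    treatment_assignment_rate: float = Field(default=0.5, ge=0, le=1)
    features: Optional[list[FeatureSpec]] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if self.n_confirmed_positive + self.n_confirmed_stable + self.n_posthoc == 0:
            raise ValueError("cohort size must be positive")
        return self

    def resolved_features(self) -> list[FeatureSpec]:
        if self.features is not None:
            return self.features
        return default_features(self.treatment_assignment_rate)

    @property
    def n_total(self) -> int:
        return self.n_confirmed_positive + self.n_confirmed_stable + self.n_posthoc


@dataclass
class SyntheticCohort:
    """A generated cohort plus its hidden per-sample latent truth."""

    dataset: UncertainDataset
    latent: np.ndarray  # class index per sample, hidden from learners
    config: SyntheticConfig


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> SyntheticCohort:
    """Draw a cohort; deterministic given the (config, seed) pair.

    Confirmed strata have latent class fixed by construction; the post
    hoc stratum's latent class is Bernoulli(latent_positive_rate_posthoc)
    but its *nominal* label is always "stable".
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_pos, n_stab, n_post = (
        config.n_confirmed_positive, config.n_confirmed_stable, config.n_posthoc
    )
    n = config.n_total
    latent = np.concatenate([
        np.ones(n_pos, dtype=np.int64),
        np.zeros(n_stab, dtype=np.int64),
        (rng.random(n_post) < config.latent_positive_rate_posthoc).astype(np.int64),
    ])
    nominal = np.concatenate([
        np.ones(n_pos, dtype=np.int64),
        np.zeros(n_stab + n_post, dtype=np.int64),
    ])
    confirmed = np.concatenate([
        np.ones(n_pos + n_stab, dtype=bool),
        np.zeros(n_post, dtype=bool),
    ])
    feats = config.resolved_features()
    X = np.empty((n, len(feats)))
    pos = latent == 1
    for j, f in enumerate(feats):
        if f.family == "lognormal":
            mu = np.where(pos, f.log_mu(True), f.log_mu(False))
            X[:, j] = np.exp(rng.normal(mu, f.sigma_log))
        else:
            rate = np.where(
                pos, f.rate if f.positive_rate is None else f.positive_rate, f.rate
            )
            X[:, j] = (rng.random(n) < rate).astype(float)
    dataset = UncertainDataset(
        X,
        nominal,
        confirmed=confirmed,
        sample_ids=[f"subj-{i:04d}" for i in range(n)],
        feature_names=[f.name for f in feats],
        class_names=DEFAULT_CLASS_NAMES,
    )
    return SyntheticCohort(dataset=dataset, latent=latent, config=config)


# ---------------------------------------------------------------------------
# CSV round trip


class CohortParseError(ValueError):
    """A schema or value problem in a cohort CSV, with location info."""


def default_truth_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_truth" + p.suffix)


def cohort_to_csv(cohort: SyntheticCohort, path, truth_path=None) -> tuple[Path, Path]:
    """Write the modeling table and a separate latent-truth sidecar.

    Latent truth never enters the modeling table.  Floats are written
    with 17 significant digits so the round trip is lossless.  The
    ``p_stable`` column is included only when some pmf is genuinely
    soft.
    """
    path = Path(path)
    truth_path = default_truth_path(path) if truth_path is None else Path(truth_path)
    ds = cohort.dataset
    df = pd.DataFrame(ds.X, columns=ds.feature_names)
    df.insert(0, "sample_id", ds.sample_ids)
    df["label"] = [ds.class_names[c] for c in ds.nominal]
    df["label_status"] = np.where(
        ds.confirmed, LabelStatus.CONFIRMED, LabelStatus.POSTHOC
    )
    one_hot = np.isclose(ds.PMF.max(axis=1), 1.0)
    if not one_hot.all():
        df["p_stable"] = ds.PMF[:, 0]
    df.to_csv(path, index=False, float_format="%.17g")
    truth = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "latent_class": [ds.class_names[c] for c in cohort.latent],
        }
    )
    truth.to_csv(truth_path, index=False)
    return path, truth_path


def csv_to_dataset(
    path,
    feature_names: Sequence[str] | None = None,
    class_names: Sequence[str] = DEFAULT_CLASS_NAMES,
) -> UncertainDataset:
    """Load a cohort CSV into an :class:`UncertainDataset`.

    Required columns: ``sample_id``, ``label``, ``label_status``; all
    remaining columns are features unless ``feature_names`` is given, in
    which case columns outside the schema trigger a warning and are
    ignored.  An optional ``p_stable`` column supplies soft pmfs for
    post hoc samples; when absent, pmfs are one-hot on the nominal label
    (a probabilistic policy applied later synthesizes the soft pmfs).
    """
    path = Path(path)
    # round_trip parsing: the default fast parser can be off by one ulp
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("sample_id", "label", "label_status"):
        if col not in df.columns:
            raise CohortParseError(f"{path}: missing required column {col!r}")
    class_names = list(class_names)
    bad = ~df["label"].isin(class_names)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header + 1-based
        raise CohortParseError(
            f"{path}, line {line}: unknown label {df['label'][bad].iloc[0]!r}"
        )
    bad = ~df["label_status"].isin(list(LabelStatus.VALID))
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise CohortParseError(
            f"{path}, line {line}: unknown label_status "
            f"{df['label_status'][bad].iloc[0]!r}"
        )
    if feature_names is None:
        feat_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    else:
        feat_cols = list(feature_names)
        missing = [c for c in feat_cols if c not in df.columns]
        if missing:
            raise CohortParseError(f"{path}: missing feature column(s) {missing}")
        unknown = [
            c for c in df.columns if c not in RESERVED_COLUMNS and c not in feat_cols
        ]
        if unknown:
            warnings.warn(f"{path}: ignoring unknown column(s) {unknown}")
    X = np.empty((len(df), len(feat_cols)))
    for j, c in enumerate(feat_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any() or col.isna().any():
            line = int(df.index[col.isna()][0]) + 2
            raise CohortParseError(
                f"{path}, line {line}: non-numeric or missing value in column {c!r}"
            )
        X[:, j] = col.to_numpy(dtype=float)
    nominal = np.array([class_names.index(l) for l in df["label"]], dtype=np.int64)
    confirmed = (df["label_status"] == LabelStatus.CONFIRMED).to_numpy()
    PMF = None
    if "p_stable" in df.columns:
        p = pd.to_numeric(df["p_stable"], errors="coerce").to_numpy(dtype=float)
        if np.isnan(p).any():
            line = int(np.flatnonzero(np.isnan(p))[0]) + 2
            raise CohortParseError(f"{path}, line {line}: bad value in 'p_stable'")
        if len(class_names) != 2:
            raise CohortParseError("'p_stable' requires exactly two classes")
        PMF = np.column_stack([p, 1.0 - p])
    return UncertainDataset(
        X,
        nominal,
        PMF=PMF,
        confirmed=confirmed,
        sample_ids=df["sample_id"].astype(str).tolist(),
        feature_names=feat_cols,
        class_names=class_names,
    )
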