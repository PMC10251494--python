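"""Containers for tabular data with uncertain features and class labels.

A sample carries, besides its feature vector, a per-feature uncertainty
(standard deviation, in the feature's own units; 0 means exactly known)
and a probability mass function over the class labels.  Samples whose
outcome was adjudicated after the fact ("post hoc") are flagged so that
evaluation can be restricted to confirmed outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "LabelStatus",
    "UncertainSample",
    "UncertainDataset",
    "DEFAULT_CLASS_NAMES",
]

PMF_ATOL = 1e-9

#: Study default: index 0 is the stable class, index 1 the positive class.
DEFAULT_CLASS_NAMES = ("stable", "new_disease_activity")


class LabelStatus:
    """Enumeration of label provenance flags."""

    CONFIRMED = "confirmed"
    POSTHOC = "posthoc"

    VALID = frozenset({CONFIRMED, POSTHOC})


@dataclass(frozen=True)
class UncertainSample:
    """A single subject: features, uncertainties, label pmf and provenance.

    Attributes
    ----------
    sample_id : str
        Opaque unique identifier.
    features : ndarray, shape (d,)
        Feature values (e.g. volumes in mm^3, binary flags in {0, 1}).
    feature_uncertainties : ndarray, shape (d,)
        Non-negative standard deviations, same units as the features.
        Zero means the value is exactly known.
    label_pmf : ndarray, shape (K,)
        Probability mass function over the classes; sums to 1.
    label_status : str
        ``"confirmed"`` or ``"posthoc"``.  Confirmed samples must carry a
        one-hot pmf.
    nominal_class : int
        Index of the recorded (nominal) class label.
    """

    sample_id: str
    features: np.ndarray
    feature_uncertainties: np.ndarray
    label_pmf: np.ndarray
    label_status: str
    nominal_class: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        object.__setattr__(
            self, "feature_uncertainties",
            np.asarray(self.feature_uncertainties, dtype=float),
        )
        object.__setattr__(self, "label_pmf", np.asarray(self.label_pmf, dtype=float))
        _validate_sample(self)


def _validate_sample(s: UncertainSample) -> None:
    if s.label_status not in LabelStatus.VALID:
        raise ValueError(f"unknown label_status {s.label_status!r}")
    if np.any(s.feature_uncertainties < 0):
        raise ValueError(f"sample {s.sample_id}: negative feature uncertainty")
    pmf = s.label_pmf
    if np.any(pmf < -PMF_ATOL) or abs(pmf.sum() - 1.0) > PMF_ATOL:
        raise ValueError(f"sample {s.sample_id}: label_pmf must be non-negative and sum to 1")
    if s.label_status == LabelStatus.CONFIRMED and not np.isclose(pmf.max(), 1.0, atol=PMF_ATOL):
        raise ValueError(f"sample {s.sample_id}: confirmed samples need a one-hot label_pmf")
    if not 0 <= s.nominal_class < pmf.size:
        raise ValueError(f"sample {s.sample_id}: nominal_class out of range")


class UncertainDataset:
    """An ordered collection of :class:`UncertainSample` with array backing.

    The canonical storage is columnar (``X``, ``DX``, ``PMF`` ...) so the
    learners can operate on contiguous arrays; ``samples`` offers a
    per-subject view for inspection and round-tripping.
    """

    def __init__(
        self,
        X: np.ndarray,
        nominal: np.ndarray,
        *,
        DX: np.ndarray | None = None,
        PMF: np.ndarray | None = None,
        confirmed: np.ndarray | None = None,
        sample_ids: Sequence[str] | None = None,
        feature_names: Sequence[str] | None = None,
        class_names: Sequence[str] = DEFAULT_CLASS_NAMES,
    ) -> None:
        self.X = np.ascontiguousarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, d = self.X.shape
        K = len(class_names)
        if K < 2:
            raise ValueError("need at least two classes")
        self.nominal = np.asarray(nominal, dtype=np.int64)
        if self.nominal.shape != (n,):
            raise ValueError("nominal labels must be one per sample")
        if n and (self.nominal.min() < 0 or self.nominal.max() >= K):
            raise ValueError("nominal class index out of range")
        self.DX = (
            np.zeros((n, d)) if DX is None else np.ascontiguousarray(DX, dtype=float)
        )
        if self.DX.shape != (n, d):
            raise ValueError("DX shape must match X")
        if np.any(self.DX < 0):
            raise ValueError("feature uncertainties must be non-negative")
        self.confirmed = (
            np.ones(n, dtype=bool) if confirmed is None
            else np.asarray(confirmed, dtype=bool)
        )
        if self.confirmed.shape != (n,):
            raise ValueError("confirmed flags must be one per sample")
        if PMF is None:
            PMF = np.zeros((n, K))
            PMF[np.arange(n), self.nominal] = 1.0
        self.PMF = np.ascontiguousarray(PMF, dtype=float)
        if self.PMF.shape != (n, K):
            raise ValueError("PMF shape must be (n_samples, n_classes)")
        self.sample_ids = (
            [f"s{i:04d}" for i in range(n)] if sample_ids is None
            else [str(s) for s in sample_ids]
        )
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids must be one per sample")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        self.feature_names = (
            [f"f{j}" for j in range(d)] if feature_names is None
            else [str(f) for f in feature_names]
        )
        if len(self.feature_names) != d:
            raise ValueError("feature_names must be one per feature")
        self.class_names = [str(c) for c in class_names]
        self._validate_pmfs()

    # -- construction ----------------------------------------------------

    @classmethod
    def from_samples(
        cls,
        samples: Iterable[UncertainSample],
        feature_names: Sequence[str] | None = None,
        class_names: Sequence[str] = DEFAULT_CLASS_NAMES,
    ) -> "UncertainDataset":
        samples = list(samples)
        if not samples:
            raise ValueError("cannot build a dataset from zero samples")
        X = np.stack([s.features for s in samples])
        DX = np.stack([s.feature_uncertainties for s in samples])
        PMF = np.stack([s.label_pmf for s in samples])
        return cls(
            X,
            np.array([s.nominal_class for s in samples]),
            DX=DX,
            PMF=PMF,
            confirmed=np.array(
                [s.label_status == LabelStatus.CONFIRMED for s in samples]
            ),
            sample_ids=[s.sample_id for s in samples],
            feature_names=feature_names,
            class_names=class_names,
        )

    # -- views -----------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def __len__(self) -> int:
        return self.n_samples

    def sample(self, i: int) -> UncertainSample:
        return UncertainSample(
            sample_id=self.sample_ids[i],
            features=self.X[i].copy(),
            feature_uncertainties=self.DX[i].copy(),
            label_pmf=self.PMF[i].copy(),
            label_status=(
                LabelStatus.CONFIRMED if self.confirmed[i] else LabelStatus.POSTHOC
            ),
            nominal_class=int(self.nominal[i]),
        )

    def __iter__(self) -> Iterator[UncertainSample]:
        return (self.sample(i) for i in range(self.n_samples))

    def subset(self, indices: Sequence[int] | np.ndarray) -> "UncertainDataset":
        """A new dataset restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=np.int64)
        return UncertainDataset(
            self.X[idx],
            self.nominal[idx],
            DX=self.DX[idx],
            PMF=self.PMF[idx],
            confirmed=self.confirmed[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=self.feature_names,
            class_names=self.class_names,
        )

    def replace_pmf(self, PMF: np.ndarray, confirmed: np.ndarray | None = None) -> "UncertainDataset":
        return UncertainDataset(
            self.X,
            self.nominal,
            DX=self.DX,
            PMF=PMF,
            confirmed=self.confirmed if confirmed is None else confirmed,
            sample_ids=self.sample_ids,
            feature_names=self.feature_names,
            class_names=self.class_names,
        )

    def class_index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"unknown class {name!r}; classes are {self.class_names}")

    def equals(self, other: "UncertainDataset") -> bool:
        """Exact field-by-field equality (used by round-trip tests)."""
        return (
            self.sample_ids == other.sample_ids
            and self.feature_names == other.feature_names
            and self.class_names == other.class_names
            and np.array_equal(self.X, other.X)
            and np.array_equal(self.DX, other.DX)
            and np.array_equal(self.PMF, other.PMF)
            and np.array_equal(self.nominal, other.nominal)
            and np.array_equal(self.confirmed, other.confirmed)
        )

    # -- validation ------------------------------------------------------

    def _validate_pmfs(self) -> None:
        sums = self.PMF.sum(axis=1)
        if np.any(self.PMF < -PMF_ATOL) or np.any(np.abs(sums - 1.0) > PMF_ATOL):
            raise ValueError("every label_pmf must be non-negative and sum to 1")
        conf = self.confirmed
        if conf.any():
            if not np.allclose(self.PMF[conf].max(axis=1), 1.0, atol=PMF_ATOL):
                raise ValueError("confirmed samples must carry one-hot label pmfs")
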