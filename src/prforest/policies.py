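"""Label-handling policies for cohorts with uncertain (post hoc) labels.

Three policies are compared throughout: *exclude* drops the uncertain
samples, *naive* accepts their nominal labels as correct, and
*probabilistic* keeps them with a probability mass function that places
``posthoc_probability`` on the nominal label and the remainder on the
other class(es).  Confirmed samples are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import UncertainDataset

__all__ = ["LabelPolicy", "POLICY_NAMES", "apply_policy"]

POLICY_NAMES = ("exclude", "naive", "probabilistic")


@dataclass(frozen=True)
class LabelPolicy:
    """A named policy; ``posthoc_probability`` is used only by ``probabilistic``."""

    name: str
    posthoc_probability: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in POLICY_NAMES:
            raise ValueError(f"policy must be one of {POLICY_NAMES}, got {self.name!r}")
        if not 0.0 < self.posthoc_probability <= 1.0:
            raise ValueError("posthoc_probability must lie in (0, 1]")


def apply_policy(dataset: UncertainDataset, policy: LabelPolicy) -> UncertainDataset:
    """Apply a label policy, returning a new dataset.

    * ``exclude``: only confirmed samples survive, with one-hot pmfs.
    * ``naive``: all samples survive; post hoc samples get a one-hot pmf
      at their nominal label.
    * ``probabilistic``: all samples survive; post hoc samples get mass
      ``posthoc_probability`` on their nominal label, the remainder
      spread over the other class(es).  With ``posthoc_probability=1``
      this coincides exactly with ``naive``.

    Raises
    ------
    ValueError
        If the resulting training set has a class with no confirmed
        sample (e.g. exclusion emptied a class).
    """
    n, K = dataset.PMF.shape
    if policy.name == "exclude":
        out = dataset.subset(np.flatnonzero(dataset.confirmed))
        out = out.replace_pmf(_one_hot(out.nominal, K))
    else:
        PMF = _one_hot(dataset.nominal, K)
        if policy.name == "probabilistic":
            post = ~dataset.confirmed
            p = policy.posthoc_probability
            off = (1.0 - p) / (K - 1)
            soft = np.full((int(post.sum()), K), off)
            soft[np.arange(soft.shape[0]), dataset.nominal[post]] = p
            PMF[post] = soft
        out = dataset.replace_pmf(PMF)
    conf_classes = set(out.nominal[out.confirmed].tolist())
    missing = [c for i, c in enumerate(out.class_names) if i not in conf_classes]
    if missing:
        raise ValueError(
            f"policy {policy.name!r} left no confirmed sample for class(es) "
            f"{missing}"
        )
    return out


def _one_hot(nominal: np.ndarray, K: int) -> np.ndarray:
    PMF = np.zeros((nominal.size, K))
    PMF[np.arange(nominal.size), nominal] = 1.0
    return PMF
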