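"""Bundled case-study datasets and a seeded synthetic-data generator.

Two published case-study samples ship with the package as plain-text
single-column files so that every analysis and test runs offline:

``bladder_cancer_128``
    Remission times (months) of 128 bladder-cancer patients.
``bank_waiting_100``
    Waiting times (minutes) before service of 100 bank customers.

Each load is verified against frozen transcription constants (size,
extremes, total) so a corrupted data file fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np

from .core import ELGParams, Sample, elg_rvs
from .fit import CensoredSample

__all__ = ["NamedDataset", "load_dataset", "generate_synthetic", "DATASET_IDS"]

# id -> (n, min, max, sum) frozen at transcription time.
_CHECKS = {
    "bladder_cancer_128": (128, 0.08, 79.05, 1198.80),
    "bank_waiting_100": (100, 0.8, 38.5, 987.70),
}

_SOURCES = {
    "bladder_cancer_128": "remission times (months) of 128 bladder cancer patients",
    "bank_waiting_100": "waiting times (minutes) before service of 100 bank customers",
}

DATASET_IDS = tuple(sorted(_CHECKS))


@dataclass(frozen=True)
class NamedDataset:
    id: str
    times: Sample
    source: str


def load_dataset(dataset_id: str) -> NamedDataset:
    """Load a bundled dataset by id, verifying the transcription checksums."""
    if dataset_id not in _CHECKS:
        raise KeyError(f"unknown dataset id {dataset_id!r}; known ids: {DATASET_IDS}")
    ref = resources.files("elgdist") / "data" / f"{dataset_id}.txt"
    values = np.array([float(line) for line in ref.read_text().split()])
    n, lo, hi, total = _CHECKS[dataset_id]
    if len(values) != n:
        raise RuntimeError(f"{dataset_id}: expected {n} values, found {len(values)}")
    if not (
        np.isclose(values.min(), lo)
        and np.isclose(values.max(), hi)
        and np.isclose(values.sum(), total, atol=1e-9)
    ):
        raise RuntimeError(f"{dataset_id}: transcription checksum mismatch")
    return NamedDataset(id=dataset_id, times=Sample(values), source=_SOURCES[dataset_id])


class SyntheticData(NamedTuple):
    """Generated data plus the ground truth that produced it."""

    data: "Sample | CensoredSample"
    truth: ELGParams
    seed: int | None
    scheme: dict | None


def generate_synthetic(
    params: ELGParams,
    n: int,
    seed: int | None = None,
    censoring: dict | None = None,
) -> SyntheticData:
    """Draw a reproducible sample, optionally censored.

    ``censoring`` schemes:

    - ``None``: complete sample.
    - ``{"type": "right_fixed", "time": c}``: observations above ``c`` are
      right-censored at ``c``.
    - ``{"type": "right_random", "rate": lam}``: each observation is
      right-censored at an independent Exp(lam) time.
    """
    rng = np.random.default_rng(seed)
    sample = elg_rvs(n, params, rng=rng)
    if censoring is None:
        return SyntheticData(sample, params, seed, None)

    x = sample.times
    kind = censoring.get("type")
    if kind == "right_fixed":
        c = float(censoring["time"])
        if c <= 0:
            raise ValueError("censoring time must be positive")
        censor_at = np.full(n, c)
    elif kind == "right_random":
        lam = float(censoring["rate"])
        if lam <= 0:
            raise ValueError("censoring rate must be positive")
        censor_at = rng.exponential(1.0 / lam, size=n)
    else:
        raise ValueError(f"unknown censoring scheme {censoring!r}")

    observed = x <= censor_at
    data = CensoredSample(
        exact=x[observed],
        right_censored=censor_at[~observed],
    )
    return SyntheticData(data, params, seed, dict(censoring))
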