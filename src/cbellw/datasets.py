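"""Bundled lifetime data sets and descriptive statistics.

Five complete (uncensored) positive samples ship with the package as plain
one-column CSV files: daily COVID-19 death counts, head & neck cancer
survival under radiotherapy, bladder cancer remission times, acute bone
cancer survival, and the classical Guinea pig tuberculosis survival data.
Each load is guarded by a transcription checksum (sample size and mean) so
a corrupted file can never silently feed the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .distribution import rvs

__all__ = ["Dataset", "DATASET_NAMES", "load", "describe", "make_fixture", "read_sample"]

# name -> (expected n, expected mean to 2 dp, source note)
_REGISTRY: dict[str, tuple[int, float, str]] = {
    "covid19": (89, 18.72, "daily confirmed COVID-19 death counts"),
    "head_neck": (58, 226.17, "head & neck cancer survival times under radiotherapy"),
    "bladder": (128, 9.37, "bladder cancer remission times in months"),
    "bone": (73, 3.76, "acute bone cancer survival times in days"),
    "guinea_pigs": (72, 1.77, "Guinea pig survival times after tubercle bacilli infection"),
}

DATASET_NAMES = tuple(_REGISTRY)


class DataIntegrityError(RuntimeError):
    """A bundled data file failed its transcription checksum."""


@dataclass(frozen=True)
class Dataset:
    name: str
    values: np.ndarray = field(repr=False)
    source_note: str = ""

    @property
    def n(self) -> int:
        return len(self.values)


def read_sample(path) -> np.ndarray:
    """Read a one-column numeric sample.

    Accepts CSV or whitespace-separated text; an optional single header
    line and '#' comment lines are tolerated.  Anything else raises.
    """
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            for token in line.replace(",", " ").split():
                try:
                    values.append(float(token))
                except ValueError:
                    if lineno <= 2 and not values:
                        continue  # header line
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric token {token!r}"
                    ) from None
    if not values:
        raise ValueError(f"{path}: no numeric data found")
    return np.asarray(values, dtype=float)


def load(name: str) -> Dataset:
    """Load a bundled data set by name, enforcing its checksums."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown dataset {name!r}; available: {DATASET_NAMES}")
    n_exp, mean_exp, note = _REGISTRY[name]
    ref = resources.files("cbellw") / "data" / f"{name}.csv"
    with resources.as_file(ref) as path:
        values = read_sample(path)
    if len(values) != n_exp:
        raise DataIntegrityError(f"{name}: n={len(values)} but expected {n_exp}")
    if abs(round(float(np.mean(values)), 2) - mean_exp) > 0.01:
        raise DataIntegrityError(
            f"{name}: mean={np.mean(values):.4f} but expected {mean_exp} +- 0.01"
        )
    return Dataset(name=name, values=values, source_note=note)


def describe(data) -> dict:
    """Descriptive summary: n, min, Q1, median, mean, Q3, max, sd, skewness, kurtosis.

    Skewness is the moment coefficient sqrt(b1); kurtosis is the raw b2
    (not excess).  For a singleton sample sd/skewness/kurtosis are NaN.
    """
    x = np.asarray(data.values if isinstance(data, Dataset) else data, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    out = {
        "n": int(x.size),
        "min": float(x.min()),
        "q1": float(np.percentile(x, 25)),
        "median": float(np.median(x)),
        "mean": float(x.mean()),
        "q3": float(np.percentile(x, 75)),
        "max": float(x.max()),
    }
    if x.size > 1:
        out["sd"] = float(np.std(x, ddof=1))
        out["skewness"] = float(stats.skew(x, bias=True))
        out["kurtosis"] = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        out["sd"] = out["skewness"] = out["kurtosis"] = float("nan")
    return out


def describe_frame(names=DATASET_NAMES) -> pd.DataFrame:
    """Descriptive table over the bundled data sets, one row per set."""
    rows = {name: describe(load(name)) for name in names}
    return pd.DataFrame(rows).T


def make_fixture(params, n: int, seed: int) -> Dataset:
    """Seeded synthetic CBellW sample wrapped as a Dataset (for tests/demos)."""
    values = rvs(n, params, seed=seed)
    return Dataset(name=f"synthetic_seed{seed}", values=values, source_note="synthetic CBellW draw")
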