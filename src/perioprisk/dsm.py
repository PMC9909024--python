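"""Intraoperative-monitoring featurization: the data statistical method (DSM).

Each monitored vital sign is summarised by the minutes it spends outside its
clinical normal range plus seven population moments: max, min, mean mu,
variance sigma^2 (divisor T, the population form), standard deviation,
skewness and kurtosis. Kurtosis is the raw fourth standardised moment
E[((X-mu)/sigma)^4] — a Gaussian sample gives ~3, not 0 (this is NOT excess
kurtosis). A constant series has sigma = 0; skewness and kurtosis are then
defined as 0 so downstream classifiers never see non-finite features.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

#: fixed per-attribute column order of the flattened feature block
STAT_ORDER = (
    "abnormal_minutes",
    "max",
    "min",
    "mean",
    "variance",
    "std",
    "skewness",
    "kurtosis",
)


@dataclass(frozen=True)
class RangeCatalogue:
    """Attribute name -> closed normal interval [lower, upper].

    Values on the boundary count as normal. The catalogue is data, not code:
    the default is shipped as ``data/ranges_table1.yaml`` (15 vital signs).
    """

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for attr, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {attr!r} must have lower < upper, got [{lo}, {hi}]")

    def __contains__(self, attr: str) -> bool:
        return attr in self.ranges

    def __getitem__(self, attr: str) -> tuple[float, float]:
        return self.ranges[attr]

    def __len__(self) -> int:
        return len(self.ranges)

    @classmethod
    def from_yaml(cls, path) -> "RangeCatalogue":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({str(k): (float(v[0]), float(v[1])) for k, v in raw.items()})

    @classmethod
    def default(cls) -> "RangeCatalogue":
        """The shipped 15-attribute intraoperative normal-range catalogue."""
        ref = importlib.resources.files("perioprisk.data") / "ranges_table1.yaml"
        raw = yaml.safe_load(ref.read_text())
        return cls({str(k): (float(v[0]), float(v[1])) for k, v in raw.items()})


@dataclass
class SeriesStats:
    """Population moments plus out-of-range duration for one monitored series."""

    max: float
    min: float
    mean: float
    variance: float
    std: float
    skewness: float
    kurtosis: float
    abnormal_minutes: float = 0.0
    T: int = 0

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in STAT_ORDER], dtype=float)


def moments(values) -> SeriesStats:
    """Population moments of a series: mu, sigma^2 (divisor T), std, skew, kurtosis.

    mu = (1/T) sum x_i ; sigma^2 = (1/T) sum (x_i - mu)^2 ;
    skewness = (1/T) sum (x_i - mu)^3 / sigma^3 ;
    kurtosis = (1/T) sum (x_i - mu)^4 / sigma^4 (raw, non-excess).
    A degenerate series (sigma = 0) returns skewness = kurtosis = 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("moments of an empty series are undefined; use the absence flag instead")
    mu = x.mean()
    dev = x - mu
    var = np.mean(dev**2)
    std = np.sqrt(var)
    # a constant series is degenerate even when the rounded mean differs from
    # the common value by one ulp (which would fake unit skewness)
    if std == 0.0 or x.max() == x.min():
        skew = kurt = 0.0
    else:
        # standardize before raising to powers: dividing by std**4 underflows
        # for near-constant series long before z**4 does
        z = dev / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    return SeriesStats(
        max=float(x.max()),
        min=float(x.min()),
        mean=float(mu),
        variance=float(var),
        std=float(std),
        skewness=skew,
        kurtosis=kurt,
        T=int(x.size),
    )


def abnormal_minutes(
    t,
    values,
    normal_range: tuple[float, float],
    sampling_interval: float | None = None,
) -> float:
    """Minutes a monitored series spends outside its closed normal interval.

    Each sample is attributed a duration: with ``sampling_interval`` given,
    that fixed interval (regular-sampling fast path); otherwise the gap to the
    next timestamp, with the final sample receiving the median gap (a lone
    sample counts one minute). Samples with value strictly below the lower or
    strictly above the upper bound are abnormal; boundary values are normal.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(values, dtype=float)
    lo, hi = normal_range
    if not lo < hi:
        raise ValueError(f"normal range must have lower < upper, got [{lo}, {hi}]")
    if t.size == 0:
        return 0.0
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    out = (v < lo) | (v > hi)
    if sampling_interval is not None:
        return float(out.sum() * sampling_interval)
    if t.size == 1:
        weights = np.array([1.0])
    else:
        gaps = np.diff(t)
        weights = np.append(gaps, np.median(gaps))
    return float(weights[out].sum())


def series_features(
    t,
    values,
    normal_range: tuple[float, float],
    sampling_interval: float | None = None,
) -> SeriesStats:
    """Full DSM block for one series: abnormal duration + the seven moments."""
    stats = moments(values)
    stats.abnormal_minutes = abnormal_minutes(t, values, normal_range, sampling_interval)
    return stats


def extract_dsm_features(
    cohort,
    catalogue: RangeCatalogue | None = None,
    attributes: list[str] | None = None,
    sampling_interval: float | None = None,
    return_presence: bool = False,
):
    """Patients x (8 * n_attributes) DSM feature matrix for a cohort.

    Column order is fixed per attribute: ``{attr}__abnormal_minutes``,
    ``__max``, ``__min``, ``__mean``, ``__variance``, ``__std``,
    ``__skewness``, ``__kurtosis``. Absent series produce an all-zero block;
    ``return_presence`` additionally returns the 0/1 presence matrix.
    """
    if catalogue is None:
        catalogue = RangeCatalogue.default()
    if attributes is None:
        attributes = list(cohort.monitoring_attributes)
    missing = [a for a in attributes if a not in catalogue]
    if missing:
        raise KeyError(f"monitored attribute(s) missing from range catalogue: {missing}")

    cols = [f"{a}__{s}" for a in attributes for s in STAT_ORDER]
    mat = np.zeros((len(cohort.records), len(cols)))
    presence = np.zeros((len(cohort.records), len(attributes)), dtype=int)
    for i, rec in enumerate(cohort.records):
        for j, attr in enumerate(attributes):
            series = rec.monitoring.get(attr)
            if series is None or len(series[0]) == 0:
                continue
            t, v = series
            stats = series_features(t, v, catalogue[attr], sampling_interval)
            mat[i, j * 8 : (j + 1) * 8] = stats.as_vector()
            presence[i, j] = 1
    index = [r.patient_id for r in cohort.records]
    feats = pd.DataFrame(mat, index=index, columns=cols)
    if return_presence:
        return feats, pd.DataFrame(presence, index=index, columns=attributes)
    return feats
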