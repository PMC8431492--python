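"""Per-recording movement features: lag-1 autocorrelations and averaged variance.

Three feature families are computed from each of the 11 skeleton parameter
series s = (s(1), ..., s(T)):

* ``acf_orig_*`` — the lag-1 autocorrelation coefficient of s;
* ``acf_diff_*`` — the lag-1 autocorrelation coefficient of the first
  differences s'(t) = s(t+1) - s(t);
* ``avgvar_*`` — the mean of per-window population variances over
  consecutive non-overlapping windows of size W (trailing remainder frames
  are discarded).

The autocorrelation at lag tau is the Pearson correlation between the
overlapping pairs (s(t), s(t+tau)), each sub-series centred by its own mean.
A "stationary" estimator (common mean, full-series variance) is available
behind ``AnalysisConfig.acf_estimator`` for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, SeriesTooShortError, UndefinedACFError
from .skeleton_geometry import PARAMETER_NAMES, ParameterSeries

DEFAULT_WINDOW = 30

#: Canonical 33-feature order: 11 acf-original, 11 acf-differenced, 11 avgvar.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{family}_{param}"
    for family in ("acf_orig", "acf_diff", "avgvar")
    for param in PARAMETER_NAMES
)


@dataclass
class AnalysisConfig:
    """Feature-extraction settings.

    ``window_size`` is the averaged-variance window W (>= 2); ``lag`` is the
    autocorrelation lag tau (default 1).  Window variances always use the
    population denominator.
    """

    window_size: int = DEFAULT_WINDOW
    lag: int = 1
    acf_estimator: str = "pearson"

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ConfigError("window_size must be >= 2")
        if self.lag < 1:
            raise ConfigError("lag must be >= 1")
        if self.acf_estimator not in ("pearson", "stationary"):
            raise ConfigError(f"unknown acf_estimator: {self.acf_estimator!r}")


def difference(values: Sequence[float]) -> np.ndarray:
    """First differences: element i is s(i+1) - s(i); length T - 1."""
    s = np.asarray(values, dtype=float)
    if s.size < 2:
        raise SeriesTooShortError("differencing requires at least 2 values")
    return np.diff(s)


def acf_lag(values: Sequence[float], tau: int = 1, *, estimator: str = "pearson") -> float:
    """Autocorrelation coefficient at lag ``tau``, in [-1, 1].

    ``estimator="pearson"`` correlates the T - tau overlapping pairs with
    per-sub-series means; ``"stationary"`` uses the classical common-mean,
    full-series-variance estimator.
    """
    s = np.asarray(values, dtype=float)
    if tau < 1:
        raise ConfigError("lag must be >= 1")
    n = s.size - tau
    if n < 2:
        raise SeriesTooShortError(
            f"need T - tau >= 2, got T={s.size}, tau={tau}"
        )
    x, y = s[:-tau], s[tau:]
    if estimator == "pearson":
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        if denom == 0.0:
            raise UndefinedACFError(
                "zero variance in an overlapping sub-series; ACF undefined"
            )
        r = float((xc @ yc) / denom)
    elif estimator == "stationary":
        c = s - s.mean()
        denom = float(c @ c)
        if denom == 0.0:
            raise UndefinedACFError("constant series; ACF undefined")
        r = float((c[:-tau] @ c[tau:]) / denom)
    else:
        raise ConfigError(f"unknown estimator: {estimator!r}")
    return min(1.0, max(-1.0, r))


def first_acf_original(values: Sequence[float], *, estimator: str = "pearson") -> float:
    """Lag-1 autocorrelation of the original series."""
    return acf_lag(values, 1, estimator=estimator)


def first_acf_differenced(values: Sequence[float], *, estimator: str = "pearson") -> float:
    """Lag-1 autocorrelation of the first-differenced series (needs T >= 4)."""
    s = np.asarray(values, dtype=float)
    if s.size < 4:
        raise SeriesTooShortError("differenced ACF requires T >= 4")
    return acf_lag(difference(s), 1, estimator=estimator)


def averaged_variance(values: Sequence[float], window_size: int) -> float:
    """Mean of per-window population variances over non-overlapping windows.

    The series is cut into I = floor(T / W) consecutive windows of length W;
    trailing remainder frames are discarded.
    """
    if window_size < 2:
        raise ConfigError("window_size must be >= 2")
    s = np.asarray(values, dtype=float)
    n_windows = s.size // window_size
    if n_windows < 1:
        raise SeriesTooShortError(
            f"series length {s.size} shorter than window {window_size}"
        )
    windows = s[: n_windows * window_size].reshape(n_windows, window_size)
    variances = windows.var(axis=1, ddof=0)
    # a bitwise-constant window has exactly zero variance; guard against the
    # ~1e-29 residue float mean-subtraction can leave
    constant = np.ptp(windows, axis=1) == 0.0
    variances[constant] = 0.0
    return float(variances.mean())


@dataclass
class FeatureVector:
    """The 33 named per-recording features; undefined entries are NaN."""

    subject_id: str
    session_label: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise InputError("feature vector must hold the 33 canonical features in order")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[name] for name in FEATURE_NAMES])


def extract_features(
    series_list: Sequence[ParameterSeries],
    cfg: AnalysisConfig | None = None,
) -> FeatureVector:
    """Assemble the 33-feature vector from the 11 parameter series.

    An undefined ACF (constant series) becomes a NaN feature with a warning
    rather than an error, so one frozen parameter cannot abort a cohort run.
    Series shorter than the preconditions raise :class:`SeriesTooShortError`.
    """
    cfg = cfg or AnalysisConfig()
    names = [s.parameter_name for s in series_list]
    if sorted(names) != sorted(PARAMETER_NAMES):
        raise InputError(
            f"expected exactly the 11 canonical parameter series, got {names}"
        )
    by_name = {s.parameter_name: s for s in series_list}
    first = series_list[0]
    values: dict[str, float] = {}
    for feature in FEATURE_NAMES:
        family = next(
            fam for fam in ("acf_orig", "acf_diff", "avgvar")
            if feature.startswith(fam + "_")
        )
        param = feature[len(family) + 1 :]
        s = by_name[param].values
        if family == "avgvar":
            values[feature] = averaged_variance(s, cfg.window_size)
            continue
        try:
            if family == "acf_orig":
                values[feature] = acf_lag(s, cfg.lag, estimator=cfg.acf_estimator)
            else:
                values[feature] = acf_lag(
                    difference(s), cfg.lag, estimator=cfg.acf_estimator
                )
        except UndefinedACFError:
            warnings.warn(
                f"{first.subject_id}/{first.session_label}: {feature} undefined "
                "(zero-variance series); recorded as missing",
                stacklevel=2,
            )
            values[feature] = float("nan")
    return FeatureVector(first.subject_id, first.session_label, values)


def features_to_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame: subject_id, session, 33 feature columns."""
    rows = [
        {"subject_id": v.subject_id, "session": v.session_label, **v.values}
        for v in vectors
    ]
    return pd.DataFrame(rows, columns=["subject_id", "session", *FEATURE_NAMES])


def write_feature_csv(vectors: Sequence[FeatureVector], path: str | Path) -> Path:
    path = Path(path)
    features_to_frame(vectors).to_csv(path, index=False)
    return path


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "session", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    return df
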