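"""The eDNA-adapted predictive multimetric fish index.

The index follows the reference-condition approach: for each metric, a
regression fitted on least-disturbed reference sites predicts the value
expected at a site given eight environmental descriptors (catchment area,
slope, width, two air temperatures, rainfall, hydrological regime and
dominant sediment).  Species-count metrics use a log-link Poisson
regression; proportion metrics a logit-link binomial regression (quasi
when no denominator is available).

Each observed metric is turned into an ecological quality ratio (EQR) by
a probability transform of the standardised link-scale residual:

    z   = (g(observed) - g(expected)) / sigma_m
    EQR = Phi(z)      if disturbance decreases the metric
        = 1 - Phi(z)  if disturbance increases it

where g is log(y + 1/2) for counts and the (clipped) logit for
proportions, sigma_m the residual spread of the metric among reference
sites on the same scale and Phi the standard normal CDF.  EQRs are
clipped to [0.001, 0.999].  An undisturbed site therefore scores about
0.5 on every metric, whichever way the metric responds to pressure.

The index is the mean of the k lowest metric EQRs (by default the lowest
half: 5 of 10 for the ten-metric variant, 3 of 6 for the six-metric
variant restricted to relative-abundance metrics).  Scores are mapped to
the five ecological status classes by strictly decreasing boundaries,
which are river-type specific; class boundaries can also be calibrated
from the reference-site score distribution.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_fixtures import (
    ENV_CATEGORICAL,
    ENV_CONTINUOUS,
    TraitTable,
    ValidationError,
    validate_env,
)
from .vocab import (
    DEFAULT_BOUNDARIES,
    STATUS_CLASSES,
    MetricDef,
    index_metrics,
)
from .guild_metrics import index_metric_vector

logger = logging.getLogger(__name__)

EQR_CLIP = (0.001, 0.999)
_PROP_EPS = 1e-3
#: Residual spreads below this are flagged degenerate and floored.
_SIGMA_FLOOR = 1e-6

#: Fixed affine rescaling of the continuous descriptors (offset, scale on
#: the transformed variable).  Constants, not data moments, so that a
#: serialized model is independent of the sample it was fitted on.
_CONTINUOUS_TRANSFORMS = {
    "area_km2": ("log", 7.0, 2.0),
    "slope_pm": ("log", 0.5, 1.5),
    "width_m": ("log", 3.0, 1.0),
    "temp_site_c": ("id", 11.0, 2.0),
    "temp_catchment_c": ("id", 10.0, 2.0),
    "rainfall_mm": ("id", 1200.0, 400.0),
}


def count_link(y) -> np.ndarray:
    """Link-scale transform for species counts: log(y + 1/2)."""
    return np.log(np.asarray(y, dtype=float) + 0.5)


def prop_link(p) -> np.ndarray:
    """Link-scale transform for proportions: logit, clipped away from 0/1."""
    p = np.clip(np.asarray(p, dtype=float), _PROP_EPS, 1.0 - _PROP_EPS)
    return np.log(p / (1.0 - p))


def metric_link(values, family: str) -> np.ndarray:
    return count_link(values) if family == "poisson" else prop_link(values)


@dataclass(frozen=True)
class EnvEncoder:
    """Environmental descriptors -> fixed design matrix.

    Continuous descriptors are log-transformed where spanning orders of
    magnitude and affinely rescaled with fixed constants; categorical
    descriptors are dummy-coded against declared reference levels.
    """

    levels: Mapping[str, tuple]  # categorical -> ordered levels (first = reference)

    @classmethod
    def from_env(cls, env: pd.DataFrame) -> "EnvEncoder":
        levels = {
            c: tuple(sorted(env[c].astype(str).unique())) for c in ENV_CATEGORICAL
        }
        return cls(levels)

    @property
    def columns(self) -> list[str]:
        cols = ["intercept"] + [f"z_{c}" for c in ENV_CONTINUOUS]
        for c in ENV_CATEGORICAL:
            cols += [f"{c}[{lv}]" for lv in self.levels[c][1:]]
        return cols

    def transform(self, env: pd.DataFrame) -> pd.DataFrame:
        validate_env(env)
        X = pd.DataFrame(index=env.index)
        X["intercept"] = 1.0
        for c in ENV_CONTINUOUS:
            kind, offset, scale = _CONTINUOUS_TRANSFORMS[c]
            v = env[c].astype(float)
            if kind == "log":
                v = np.log(v)
            X[f"z_{c}"] = (v - offset) / scale
        for c in ENV_CATEGORICAL:
            known = set(self.levels[c])
            seen = set(env[c].astype(str))
            unknown = seen - known
            if unknown:
                raise ValidationError(
                    f"unknown {c} level(s) {sorted(unknown)}; declared levels {sorted(known)}"
                )
            for lv in self.levels[c][1:]:
                X[f"{c}[{lv}]"] = (env[c].astype(str) == lv).astype(float)
        return X[self.columns]


@dataclass
class ModelEntry:
    """Fitted reference model for one metric."""

    metric: MetricDef
    coef: pd.Series
    sigma: float
    deviance: float
    degenerate: bool = False

    def expected(self, X: pd.DataFrame) -> np.ndarray:
        eta = X.to_numpy() @ self.coef.to_numpy()
        if self.metric.family == "poisson":
            return np.exp(eta)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class ReferenceModelSet:
    """Per-metric reference models plus the shared design encoder."""

    encoder: EnvEncoder
    entries: Mapping[str, ModelEntry]
    diagnostics: dict = field(default_factory=dict)

    def __getitem__(self, metric_name: str) -> ModelEntry:
        return self.entries[metric_name]

    def __contains__(self, metric_name: str) -> bool:
        return metric_name in self.entries

    def expected(self, metric_name: str, env: pd.DataFrame) -> pd.Series:
        X = self.encoder.transform(env)
        return pd.Series(self.entries[metric_name].expected(X), index=env.index)

    def to_json(self, path) -> None:
        payload = {
            "levels": {k: list(v) for k, v in self.encoder.levels.items()},
            "metrics": {
                name: {
                    "def": list(e.metric),
                    "coef": {k: float(v) for k, v in e.coef.items()},
                    "sigma": e.sigma,
                    "deviance": e.deviance,
                    "degenerate": e.degenerate,
                }
                for name, e in self.entries.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ReferenceModelSet":
        with open(path) as fh:
            payload = json.load(fh)
        encoder = EnvEncoder({k: tuple(v) for k, v in payload["levels"].items()})
        entries = {}
        for name, rec in payload["metrics"].items():
            entries[name] = ModelEntry(
                metric=MetricDef(*rec["def"]),
                coef=pd.Series(rec["coef"]),
                sigma=float(rec["sigma"]),
                deviance=float(rec["deviance"]),
                degenerate=bool(rec["degenerate"]),
            )
        return cls(encoder, entries)


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        constant = [c for c in X.columns if c != "intercept" and X[c].nunique() == 1]
        corr = X.drop(columns="intercept").corr().abs()
        pairs = [
            (a, b)
            for i, a in enumerate(corr.index)
            for b in corr.columns[i + 1:]
            if corr.loc[a, b] > 0.999999
        ]
        raise ValidationError(
            f"singular design matrix (rank {rank} < {arr.shape[1]}); "
            f"constant columns: {constant}; collinear pairs: {pairs}"
        )


def fit_reference_models(
    metrics: pd.DataFrame,
    env: pd.DataFrame,
    variant: str = "10FI",
    denominators: pd.Series | pd.DataFrame | None = None,
    min_sites_per_predictor: int = 10,
) -> ReferenceModelSet:
    """Fit per-metric reference-condition models on reference sites.

    ``metrics`` holds one column per index metric (counts for the
    species-count metrics, proportions in [0, 1] for the others) and may
    carry a ``_n_resolved`` column used as the binomial denominator when
    ``denominators`` is not given.  ``env`` holds the eight environmental
    descriptors for the same sites.
    """
    defs = index_metrics(variant)
    missing = [m.name for m in defs if m.name not in metrics.columns]
    if missing:
        raise ValidationError(f"metric table lacks columns {missing}")
    if not metrics.index.equals(env.index):
        raise ValidationError("metric and environmental tables index different sites")
    if metrics[[m.name for m in defs]].isna().any().any():
        raise ValidationError("metric table contains missing values")
    encoder = EnvEncoder.from_env(env)
    X = encoder.transform(env)
    n, p = X.shape
    if n < min_sites_per_predictor * p:
        raise ValidationError(
            f"under-determined reference set: {n} sites for {p} encoded predictors "
            f"(need >= {min_sites_per_predictor * p})"
        )
    _check_design(X)

    if denominators is None and "_n_resolved" in metrics.columns:
        denominators = metrics["_n_resolved"]

    entries: dict[str, ModelEntry] = {}
    diagnostics: dict[str, dict] = {}
    for mdef in defs:
        y = metrics[mdef.name].to_numpy(dtype=float)
        if mdef.family == "poisson":
            if np.any(np.abs(y - np.round(y)) > 1e-9):
                raise ValidationError(f"{mdef.name}: count metric has non-integer values")
            model = sm.GLM(y, X, family=sm.families.Poisson())
        else:
            if np.any((y < 0) | (y > 1)):
                raise ValidationError(f"{mdef.name}: proportions must lie in [0, 1]")
            if denominators is not None:
                if isinstance(denominators, pd.DataFrame):
                    w = denominators[mdef.name].to_numpy(dtype=float)
                else:
                    w = np.asarray(denominators, dtype=float)
            else:
                w = np.ones(n)
            model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
        res = model.fit()
        mu = np.asarray(res.fittedvalues, dtype=float)
        resid = metric_link(y, mdef.family) - metric_link(mu, mdef.family)
        sigma = float(np.std(resid, ddof=1))
        degenerate = sigma < _SIGMA_FLOOR
        if degenerate:
            logger.warning("%s: residual spread ~0; metric flagged degenerate", mdef.name)
            sigma = _SIGMA_FLOOR
        entries[mdef.name] = ModelEntry(
            metric=mdef,
            coef=pd.Series(np.asarray(res.params, dtype=float), index=X.columns),
            sigma=sigma,
            deviance=float(res.deviance),
            degenerate=degenerate,
        )
        diagnostics[mdef.name] = {
            "deviance": float(res.deviance),
            "df_resid": float(res.df_resid),
            "bse": {k: float(v) for k, v in zip(X.columns, np.asarray(res.bse))},
        }
        logger.info("%s: deviance %.1f on %d df", mdef.name, res.deviance, res.df_resid)
    return ReferenceModelSet(encoder, entries, diagnostics)


def compute_eqr(observed: float, entry: ModelEntry, expected: float) -> float:
    """EQR of one observed metric value against its reference expectation."""
    if entry.metric.family == "binomial" and not (0.0 <= observed <= 1.0):
        raise ValidationError(
            f"{entry.metric.name}: observed proportion {observed} outside [0, 1]"
        )
    if entry.metric.family == "poisson" and observed < 0:
        raise ValidationError(f"{entry.metric.name}: observed count {observed} negative")
    z = float(
        (metric_link(observed, entry.metric.family) - metric_link(expected, entry.metric.family))
        / entry.sigma
    )
    phi = stats.norm.cdf(z)
    eqr = phi if entry.metric.orientation == "decreases" else 1.0 - phi
    return float(np.clip(eqr, *EQR_CLIP))


def aggregate_index(eqrs: Mapping[str, float], k: int | None = None) -> tuple[float, list[str]]:
    """Mean of the k lowest metric EQRs (default: the lowest half).

    Returns the score and the names of the aggregated metrics.  Ordering
    is deterministic: metrics are sorted by (EQR, name) before the cut.
    """
    if not eqrs:
        raise ValidationError("empty EQR vector")
    if k is None:
        k = math.ceil(len(eqrs) / 2)
    if not 1 <= k <= len(eqrs):
        raise ValidationError(f"k={k} outside [1, {len(eqrs)}]")
    ranked = sorted(eqrs.items(), key=lambda kv: (kv[1], kv[0]))
    selected = ranked[:k]
    score = float(np.mean([v for _, v in selected]))
    return score, [name for name, _ in selected]


def classify(
    score: float,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> tuple[str, str]:
    """Map an index score in [0, 1] to a status class and good/degraded flag.

    Boundaries are (High/Good, Good/Moderate, Moderate/Poor, Poor/Bad),
    strictly decreasing; a score exactly on a boundary takes the better
    class (closed lower bound).
    """
    b = tuple(float(x) for x in boundaries)
    if len(b) != 4 or any(b[i] <= b[i + 1] for i in range(3)):
        raise ValidationError(f"boundaries must be four strictly decreasing values, got {b}")
    if not 0.0 <= score <= 1.0:
        raise ValidationError(f"index score {score} outside [0, 1]")
    cls = STATUS_CLASSES[-1]
    for name, bound in zip(STATUS_CLASSES, b):
        if score >= bound:
            cls = name
            break
    dichotomy = "good" if cls in ("High", "Good") else "degraded"
    return cls, dichotomy


def calibrate_boundaries(
    reference_scores: Sequence[float],
    good_quantile: float = 0.01,
    high_quantile: float = 0.25,
    floor: float = 0.005,
) -> tuple[float, float, float, float]:
    """Class boundaries anchored on the reference-site score distribution.

    The Good/Moderate boundary is set at a low quantile of the index
    scores of (least-disturbed) reference sites, so that almost all
    reference sites classify as at least Good; the High/Good boundary at
    an upper quantile; the remaining boundaries split the interval below
    Good evenly.  The Good boundary is guarded away from the index's
    clip floor (it must stay strictly above the lowest attainable score
    to be able to classify anything as degraded).
    """
    scores = np.asarray(reference_scores, dtype=float)
    if scores.size < 20:
        raise ValidationError("need >= 20 reference scores to calibrate boundaries")
    b_good = max(float(np.quantile(scores, good_quantile)), floor)
    b_high = float(np.quantile(scores, high_quantile))
    if b_high <= b_good:
        b_high = b_good + 1e-6
    return (b_high, b_good, 2.0 * b_good / 3.0, b_good / 3.0)


@dataclass
class EqrAssessment:
    """Full assessment record for one site."""

    site: object
    variant: str
    eqrs: dict
    selected: list
    score: float
    status: str
    dichotomy: str
    audit: pd.DataFrame  # per metric: observed, expected, z-free audit trail

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"index score {self.score} outside [0, 1]")


def edna_fish_index(
    sample: pd.Series,
    traits: TraitTable,
    models: ReferenceModelSet,
    env_row: pd.Series | pd.DataFrame,
    variant: str = "6FI",
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
    k: int | None = None,
    min_abundance: float = 0.0,
) -> EqrAssessment:
    """Assess one sample: metrics -> EQRs -> aggregated index -> class.

    ``sample`` is a taxon -> abundance row (reads or individuals);
    ``env_row`` the site's environmental descriptors.  The audit trail
    records observed and expected values and the EQR of every metric.
    """
    defs = index_metrics(variant)
    missing = [m.name for m in defs if m.name not in models]
    if missing:
        raise ValidationError(f"model set lacks metrics {missing}")
    env = env_row.to_frame().T if isinstance(env_row, pd.Series) else env_row
    observed = {
        m.name: v.value
        for m, v in zip(defs, index_metric_vector(sample, traits, variant, min_abundance))
    }
    records, eqrs = [], {}
    for mdef in defs:
        entry = models[mdef.name]
        exp = float(models.expected(mdef.name, env).iloc[0])
        eqr = compute_eqr(observed[mdef.name], entry, exp)
        eqrs[mdef.name] = eqr
        records.append(
            {
                "metric": mdef.name,
                "unit": mdef.unit,
                "orientation": mdef.orientation,
                "observed": observed[mdef.name],
                "expected": exp,
                "sigma": entry.sigma,
                "eqr": eqr,
            }
        )
    score, selected = aggregate_index(eqrs, k)
    status, dichotomy = classify(score, boundaries)
    return EqrAssessment(
        site=sample.name,
        variant=variant,
        eqrs=eqrs,
        selected=selected,
        score=score,
        status=status,
        dichotomy=dichotomy,
        audit=pd.DataFrame.from_records(records, index="metric"),
    )
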