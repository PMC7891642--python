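"""Method-comparison statistics and the review-table summariser.

Covers the inferential machinery of the eDNA-versus-electrofishing
comparison: Poisson GLMs for richness metrics (method effect after a
river-stretch effect), negative-binomial GLMs with a log-total-individuals
offset for counts underlying relative-abundance metrics, the Yates
continuity-corrected chi-square test of association between two
good/degraded classifications, and the summary statistics of the
cross-method review of the 198 assessment metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .io_fixtures import ReviewTable, ValidationError

logger = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention used for reported shares)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AssociationResult:
    table: tuple
    statistic: float
    df: int
    p_value: float


@dataclass
class ComparisonFit:
    response: str
    family: str  # "poisson-log" | "negbin-log"
    params: pd.Series
    bse: pd.Series
    method_effect: float        # log rate-ratio of eDNA vs TEF
    method_rate_ratio: float
    method_p_value: float
    deviance: float
    converged: bool
    fallback: str | None = None


@dataclass(frozen=True)
class ReviewSummary:
    """Derived counts and percentage shares of the metric review table.

    All shares are recomputed from the counts (round-half-up, 1 decimal);
    no stored percentage can disagree with its count pair.
    """

    total: int
    unit_counts: dict
    unit_shares: dict
    richness_relabund_relbiomass: int
    density_biomass: int
    trait_based: int
    trait_based_share: float
    taxonomy_based: int
    taxonomy_based_share: float
    guild_family_shares: dict = field(default_factory=dict)
    compatible: int = 0
    compatible_share: float = 0.0


def yates_chi_square(table) -> AssociationResult:
    """Yates continuity-corrected chi-square on a 2x2 contingency table.

    statistic = N * max(0, |ad - bc| - N/2)^2 / (r1 r2 c1 c2), df = 1.
    The correction is clamped at zero so near-independent tables cannot
    be inflated.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(np.abs(arr - np.round(arr)) > 1e-9):
        raise ValidationError("contingency counts must be non-negative integers")
    a, b, c, d = arr.astype(float).ravel()
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValidationError(f"zero margin in contingency table {arr.tolist()}")
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    statistic = n * num**2 / np.prod(margins)
    p = float(stats.chi2.sf(statistic, df=1))
    return AssociationResult(tuple(map(tuple, arr.astype(int))), float(statistic), 1, p)


def pearson_chi_square(table) -> AssociationResult:
    """Uncorrected Pearson chi-square on a 2x2 table (for cross-checks)."""
    arr = np.asarray(table, dtype=float)
    a, b, c, d = arr.ravel()
    n = arr.sum()
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValidationError(f"zero margin in contingency table {arr.tolist()}")
    statistic = n * (a * d - b * c) ** 2 / np.prod(margins)
    return AssociationResult(
        tuple(map(tuple, arr.astype(int))), float(statistic), 1,
        float(stats.chi2.sf(statistic, df=1)),
    )


def fit_method_comparison(
    data: pd.DataFrame,
    family: str = "poisson-log",
    response: str = "value",
) -> ComparisonFit:
    """Test the eDNA-vs-TEF difference in a metric after a stretch effect.

    ``data`` is long-format with integer ``value`` (a count), ``method``
    ("eDNA"/"TEF") and ``stretch`` columns; for ``family="negbin-log"`` a
    ``total`` column supplies the per-sample total number of individuals,
    entering as a log offset to control for sample size.  The
    negative-binomial dispersion is estimated by maximum likelihood; if
    the fit does not converge the model falls back to quasi-Poisson with
    a logged warning.
    """
    for col in (response, "method", "stretch"):
        if col not in data.columns:
            raise ValidationError(f"comparison data lacks column {col!r}")
    if data["method"].nunique() < 2 or data["stretch"].nunique() < 2:
        raise ValidationError("need >= 2 methods and >= 2 stretches represented")
    y = data[response].to_numpy(dtype=float)
    if np.any(np.abs(y - np.round(y)) > 1e-9) or np.any(y < 0):
        raise ValidationError(f"{response!r} must hold non-negative integer counts")
    formula = f"{response} ~ C(method, Treatment(reference='TEF')) + C(stretch)"
    method_term = "C(method, Treatment(reference='TEF'))[T.eDNA]"

    offset = None
    if family == "negbin-log":
        if "total" not in data.columns:
            raise ValidationError("negbin-log requires a 'total' column for the offset")
        if (data["total"] <= 0).any():
            raise ValidationError("offset totals must be positive")
        offset = np.log(data["total"].to_numpy(dtype=float))
    elif family != "poisson-log":
        raise ValidationError(f"unknown family {family!r}")

    fallback = None
    if family == "poisson-log":
        res = smf.glm(formula, data, family=sm.families.Poisson()).fit()
        converged = res.converged
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nb = smf.negativebinomial(formula, data, offset=offset).fit(disp=0, maxiter=200)
            if not nb.mle_retvals.get("converged", False):
                raise RuntimeError("negative-binomial ML did not converge")
            alpha = float(nb.params["alpha"])
            res = smf.glm(
                formula, data,
                family=sm.families.NegativeBinomial(alpha=max(alpha, 1e-8)),
                offset=offset,
            ).fit()
            converged = res.converged
        except Exception as err:  # singular/non-converged NB
            logger.warning("negative-binomial fit failed (%s); quasi-Poisson fallback", err)
            fallback = "quasi-poisson"
            res = smf.glm(formula, data, family=sm.families.Poisson(), offset=offset).fit(
                scale="X2"
            )
            converged = res.converged

    params = res.params
    bse = res.bse
    if method_term not in params.index:
        raise ValidationError("method term missing from fitted model")
    effect = float(params[method_term])
    p = float(res.pvalues[method_term])
    return ComparisonFit(
        response=response,
        family=family,
        params=params,
        bse=bse,
        method_effect=effect,
        method_rate_ratio=float(np.exp(effect)),
        method_p_value=p,
        deviance=float(res.deviance),
        converged=bool(converged),
        fallback=fallback,
    )


_UNIT_LABELS = {
    "species_richness": "Species richness",
    "relative_abundance": "Relative abundance",
    "relative_biomass": "Relative biomass",
    "density": "Density",
    "biomass": "Biomass",
    "expert_judgment": "Expert judgment",
}


def summarize_review(review: ReviewTable) -> ReviewSummary:
    """Derived totals and shares of the metric-classification table.

    Reports, among others: the share of metrics expressed in units
    computable from eDNA samples (species richness or relative
    abundance), the trait-based share, and the distribution of
    trait-based metrics over guild families.
    """
    counts = review.counts
    total = review.grand_total
    unit_counts = {u: int(v) for u, v in review.unit_totals().items()}
    unit_shares = {u: round_half_up(100.0 * v / total) for u, v in unit_counts.items()}
    trait_rows = review.categories[review.categories == "trait"].index
    trait_based = int(counts.loc[trait_rows].to_numpy().sum())
    taxonomy = int(counts.loc["Taxonomy-based"].sum()) if "Taxonomy-based" in counts.index else 0
    guild_family_shares = {
        row: round_half_up(100.0 * counts.loc[row].sum() / trait_based)
        for row in trait_rows
    }
    compatible = unit_counts.get("species_richness", 0) + unit_counts.get(
        "relative_abundance", 0
    )
    return ReviewSummary(
        total=total,
        unit_counts=unit_counts,
        unit_shares=unit_shares,
        richness_relabund_relbiomass=compatible + unit_counts.get("relative_biomass", 0),
        density_biomass=unit_counts.get("density", 0) + unit_counts.get("biomass", 0),
        trait_based=trait_based,
        trait_based_share=round_half_up(100.0 * trait_based / total),
        taxonomy_based=taxonomy,
        taxonomy_based_share=round_half_up(100.0 * taxonomy / total),
        guild_family_shares=guild_family_shares,
        compatible=compatible,
        compatible_share=round_half_up(100.0 * compatible / total),
    )
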