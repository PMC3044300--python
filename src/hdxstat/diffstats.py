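"""Per-peptide differential exchange statistics.

Two complementary tests decide whether a peptide exchanges differently
between the two protein states:

* a paired t-test on the per-timepoint differences between states, which
  removes the shared time trend (exchange is strongly time-dependent, so an
  unpaired test across the time course would be dominated by it);
* an ordinary least squares fit of

      Y = b0 + bT*X_time + bG*X_group + bTG*X_time*X_group

  (an ANCOVA with interaction), with the group effect summarized by the
  contrast L = bG + bTG * t*, evaluated at the mean fitted time by default.
  With the interaction off, L reduces to the intercept difference bG.

Group coding is 0 for state_a and 1 for state_b, so a positive estimate
means state_b exchanges more (higher centroid or percent-D). On a balanced
complete design the two estimates coincide exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DesignRankError,
    EmptyDatasetError,
    HdxError,
    InsufficientDataError,
    PairingError,
)
from .peaklist import ExchangeDataset
from .uptake import CorrectionSettings, UptakeObservation, build_uptake_series, response_value

logger = logging.getLogger(__name__)

PAIRED_T = "paired_t"
REGRESSION = "regression"
METHODS = (PAIRED_T, REGRESSION)

#: Smallest p-value printed by display helpers; full precision is kept in
#: the result objects and tables.
P_DISPLAY_FLOOR = 1e-16


@dataclass(frozen=True)
class ModelSpec:
    """Analysis configuration shared by both statistical methods.

    ``eval_time`` is either the string ``"mean"`` (contrast at the mean of
    the transformed fitted times) or a fixed time in seconds. ``min_time_s``
    drops early timepoints where exchange is too limited to be informative.
    """

    response: str = "percentD"
    time_transform: str = "identity"
    include_interaction: bool = True
    eval_time: str | float = "mean"
    alpha: float = 0.05
    min_time_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.response not in ("mz", "percentD"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.time_transform not in ("identity", "log10"):
            raise ValueError(f"unknown time_transform {self.time_transform!r}")

    def transform_time(self, t: np.ndarray | float):
        if self.time_transform == "identity":
            return t
        arr = np.asarray(t, dtype=float)
        if np.any(arr <= 0):
            raise ValueError(
                "log10 time transform requires strictly positive times; set min_time_s > 0"
            )
        out = np.log10(arr)
        return float(out) if np.isscalar(t) or out.ndim == 0 else out


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of the time x group model for one peptide.

    ``cov`` is the coefficient covariance sigma2 * (X'X)^-1 in the order
    (b0, bT, bG, bTG); without the interaction the last row/column is
    absent and ``beta_TG`` is zero.
    """

    beta0: float
    beta_T: float
    beta_G: float
    beta_TG: float
    cov: np.ndarray
    df_resid: int
    sigma2: float
    include_interaction: bool
    n: int

    @property
    def params(self) -> np.ndarray:
        p = [self.beta0, self.beta_T, self.beta_G]
        if self.include_interaction:
            p.append(self.beta_TG)
        return np.array(p)


@dataclass(frozen=True)
class DifferentialResult:
    """Point estimate, CI and p-value for one peptide under one method."""

    peptide_id: str
    method: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    n: int
    response: str
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"{self.peptide_id}: CI [{self.ci_low}, {self.ci_high}] does not bracket "
                f"estimate {self.estimate}"
            )
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"{self.peptide_id}: p-value {self.p_value} outside [0, 1]")


def _split_states(
    observations: Sequence[UptakeObservation], state_a: str, state_b: str
) -> tuple[list[UptakeObservation], list[UptakeObservation]]:
    series_a = [o for o in observations if o.state == state_a]
    series_b = [o for o in observations if o.state == state_b]
    return series_a, series_b


def paired_differences(
    series_a: Sequence[UptakeObservation],
    series_b: Sequence[UptakeObservation],
    response: str = "percentD",
) -> np.ndarray:
    """Per-timepoint differences state_b - state_a, replicates averaged
    within each state x timepoint first, returned in increasing-time order."""
    def cell_means(series):
        cells: dict[float, list[float]] = {}
        for o in series:
            cells.setdefault(o.time_s, []).append(response_value(o, response))
        return {t: float(np.mean(v)) for t, v in cells.items()}

    means_a = cell_means(series_a)
    means_b = cell_means(series_b)
    shared = sorted(set(means_a) & set(means_b))
    if not shared:
        raise PairingError("the two series share no timepoint")
    if set(means_a) != set(means_b):
        raise PairingError(
            f"timepoint sets differ: {sorted(means_a)} vs {sorted(means_b)}"
        )
    if len(shared) < 2:
        raise InsufficientDataError("fewer than 2 shared timepoints; paired test undefined")
    return np.array([means_b[t] - means_a[t] for t in shared])


def paired_t_test(
    diffs: np.ndarray,
    alpha: float = 0.05,
    peptide_id: str = "",
    response: str = "percentD",
) -> DifferentialResult:
    """Two-sided one-sample t-test of the paired differences against zero.

    estimate = mean(d); t = mean / (sd / sqrt(n)) with the sample standard
    deviation (n-1 denominator); df = n - 1; CI at level 1 - alpha.
    A zero-variance difference vector never crashes: all-zero differences
    give p = 1 with a zero-width CI, a nonzero constant difference is
    flagged and reported with p = 0.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise InsufficientDataError("paired t-test needs at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return DifferentialResult(
                peptide_id=peptide_id, method=PAIRED_T, estimate=0.0, ci_low=0.0,
                ci_high=0.0, p_value=1.0, df=df, n=n, response=response,
            )
        logger.warning("%s: zero-variance nonzero differences; degenerate t-test", peptide_id)
        return DifferentialResult(
            peptide_id=peptide_id, method=PAIRED_T, estimate=mean, ci_low=mean,
            ci_high=mean, p_value=0.0, df=df, n=n, response=response,
        )
    se = sd / math.sqrt(n)
    t_stat = mean / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    half = float(stats.t.ppf(1 - alpha / 2, df)) * se
    return DifferentialResult(
        peptide_id=peptide_id, method=PAIRED_T, estimate=mean, ci_low=mean - half,
        ci_high=mean + half, p_value=p, df=df, n=n, response=response,
    )


def design_matrix(
    times: np.ndarray, groups: np.ndarray, spec: ModelSpec
) -> np.ndarray:
    """Build the (intercept, time, group[, time x group]) design matrix."""
    x_time = np.asarray(spec.transform_time(times), dtype=float)
    x_group = np.asarray(groups, dtype=float)
    cols = [np.ones_like(x_time), x_time, x_group]
    if spec.include_interaction:
        cols.append(x_time * x_group)
    return np.column_stack(cols)


def fit_linear_model(
    observations: Sequence[UptakeObservation],
    spec: ModelSpec,
    state_a: str,
    state_b: str,
) -> RegressionFit:
    """Ordinary least squares fit of the time x group model.

    Observations from both states enter individually (replicates are not
    pre-averaged); the group indicator is 0 for ``state_a`` and 1 for
    ``state_b``.
    """
    series_a, series_b = _split_states(observations, state_a, state_b)
    if not series_a or not series_b:
        raise InsufficientDataError("both groups must be present for the regression")
    obs = list(series_a) + list(series_b)
    times = np.array([o.time_s for o in obs], dtype=float)
    groups = np.array([0.0] * len(series_a) + [1.0] * len(series_b))
    y = np.array([response_value(o, spec.response) for o in obs], dtype=float)
    if np.unique(times).size < 2:
        raise InsufficientDataError("regression needs at least 2 distinct timepoints")
    X = design_matrix(times, groups, spec)
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"{n} observations cannot identify {p} coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        term = "time x group interaction" if spec.include_interaction else "group"
        raise DesignRankError(f"design matrix is rank deficient (collinear {term} term)")

    res = sm.OLS(y, X).fit()
    params = res.params
    return RegressionFit(
        beta0=float(params[0]),
        beta_T=float(params[1]),
        beta_G=float(params[2]),
        beta_TG=float(params[3]) if spec.include_interaction else 0.0,
        cov=np.asarray(res.cov_params()),
        df_resid=int(res.df_resid),
        sigma2=float(res.mse_resid),
        include_interaction=spec.include_interaction,
        n=n,
    )


def group_contrast(
    fit: RegressionFit,
    spec: ModelSpec,
    times: np.ndarray,
    peptide_id: str = "",
) -> DifferentialResult:
    """Group-effect contrast L = bG + bTG * t* with a t-based CI and p-value.

    ``times`` are the raw fitted time values; t* is their transformed mean
    when ``spec.eval_time == "mean"``, otherwise the transformed user value
    (extrapolation beyond the fitted range only warns).
    """
    x_time = np.asarray(spec.transform_time(np.asarray(times, dtype=float)))
    if spec.eval_time == "mean":
        t_star = float(np.mean(x_time))
    else:
        t_star = float(spec.transform_time(float(spec.eval_time)))
        if t_star < x_time.min() or t_star > x_time.max():
            logger.warning(
                "%s: evaluation time %s outside fitted range; extrapolating", peptide_id, t_star
            )
    if fit.include_interaction:
        c = np.array([0.0, 0.0, 1.0, t_star])
    else:
        c = np.array([0.0, 0.0, 1.0])
    estimate = float(c @ fit.params)
    var = float(c @ fit.cov @ c)
    df = fit.df_resid
    # An (numerically) exact fit has no residual scale to test against:
    # treat it like the zero-variance paired case instead of dividing
    # rounding error by rounding error.
    scale = max(1.0, float(np.max(np.abs(fit.params))))
    if fit.sigma2 < (1e-10 * scale) ** 2:
        estimate = 0.0 if abs(estimate) < 1e-8 * scale else estimate
        var = 0.0
    if var <= 0:
        p = 1.0 if estimate == 0.0 else 0.0
        if estimate != 0.0:
            logger.warning("%s: zero contrast variance; degenerate regression test", peptide_id)
        return DifferentialResult(
            peptide_id=peptide_id, method=REGRESSION, estimate=estimate, ci_low=estimate,
            ci_high=estimate, p_value=p, df=df, n=fit.n, response=spec.response,
        )
    se = math.sqrt(var)
    t_stat = estimate / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    half = float(stats.t.ppf(1 - spec.alpha / 2, df)) * se
    return DifferentialResult(
        peptide_id=peptide_id, method=REGRESSION, estimate=estimate, ci_low=estimate - half,
        ci_high=estimate + half, p_value=p, df=df, n=fit.n, response=spec.response,
    )


def adjust_pvalues(
    results: Sequence[DifferentialResult], method: str = "benjamini_hochberg"
) -> list[DifferentialResult]:
    """Fill ``adjusted_p`` across a result collection.

    ``benjamini_hochberg`` applies the FDR step-up with monotonicity
    enforcement, separately within each statistical method so the two
    method families are corrected over their own peptide sets; ``none``
    copies the raw p-values.
    """
    if method not in ("none", "benjamini_hochberg"):
        raise ValueError(f"unknown adjustment {method!r}")
    if not results:
        return []
    if method == "none":
        return [dataclasses.replace(r, adjusted_p=r.p_value) for r in results]
    out: list[DifferentialResult | None] = [None] * len(results)
    for fam in {r.method for r in results}:
        idx = [i for i, r in enumerate(results) if r.method == fam]
        pvals = np.array([results[i].p_value for i in idx])
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        for i, adj in zip(idx, adjusted):
            out[i] = dataclasses.replace(results[i], adjusted_p=float(adj))
    return list(out)  # type: ignore[arg-type]


def analyze_peptide(
    observations: Sequence[UptakeObservation],
    spec: ModelSpec,
    state_a: str,
    state_b: str,
    methods: Sequence[str] = METHODS,
    peptide_id: str = "",
) -> list[DifferentialResult]:
    """Run the requested methods on one peptide's uptake observations."""
    results: list[DifferentialResult] = []
    series_a, series_b = _split_states(observations, state_a, state_b)
    for m in methods:
        if m == PAIRED_T:
            diffs = paired_differences(series_a, series_b, spec.response)
            results.append(paired_t_test(diffs, spec.alpha, peptide_id, spec.response))
        elif m == REGRESSION:
            fit = fit_linear_model(observations, spec, state_a, state_b)
            times = np.array([o.time_s for o in observations], dtype=float)
            results.append(group_contrast(fit, spec, times, peptide_id))
        else:
            raise ValueError(f"unknown method {m!r}")
    return results


def analyze_dataset(
    dataset: ExchangeDataset,
    spec: ModelSpec = ModelSpec(),
    methods: Sequence[str] = METHODS,
    corrections: CorrectionSettings = CorrectionSettings(),
    n_exchangeable: Mapping[str, int] | None = None,
    adjust: str = "none",
) -> list[DifferentialResult]:
    """Differential analysis of every peptide in the dataset.

    Peptides that fail a method's preconditions (too few timepoints, missing
    references, degenerate designs) are logged and skipped; they never abort
    the batch. Raises :class:`EmptyDatasetError` on an empty dataset.
    """
    if not dataset.peptides:
        raise EmptyDatasetError("dataset contains no peptides")
    series = build_uptake_series(
        dataset,
        response=spec.response,
        min_time_s=spec.min_time_s,
        corrections=corrections,
        n_exchangeable=n_exchangeable,
    )
    results: list[DifferentialResult] = []
    for pid, obs in series.items():
        for m in methods:
            try:
                results.extend(
                    analyze_peptide(obs, spec, dataset.state_a, dataset.state_b, (m,), pid)
                )
            except HdxError as exc:
                logger.warning("peptide %r skipped for %s: %s", pid, m, exc)
    return adjust_pvalues(results, "benjamini_hochberg" if adjust == "bh" else "none")


def format_pvalue(p: float) -> str:
    """Display helper: p-values below 1e-16 print as '< 1e-16'."""
    return f"< {P_DISPLAY_FLOOR:g}" if p < P_DISPLAY_FLOOR else f"{p:.4g}"
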