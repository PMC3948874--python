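"""Statistical analysis of evolution runs.

The centrepiece is the avoidance model: did predators evolve to avoid eating
poisonous prey, as a function of the poison level?  A run counts as *under
predation pressure* when its final poisonous-prey abundance falls below a
cutoff (default 800, i.e. 80% of the class cap); "avoided" is the complement.
:class:`AvoidanceLogit` fits the run-level logistic model

    P(avoided) = logit^{-1}(beta_0 + beta_1 * poison_level)

by maximum likelihood and its :meth:`~AvoidanceLogit.fit` returns an
:class:`AvoidanceLogitResults` carrying the coefficients, the predicted
curve, a stratified case-resampling bootstrap band, and a ``summary()``
table.  Complete separation and all-identical outcomes are flagged as
degenerate fits, with the curve replaced by the empirical step function.

Also here: replicate-level bootstrap summaries of the population
trajectories, the mimic display-proportion series, and the imperfect-mimicry
ratio (mean final proportion of mimics displaying poisonous under
low-fidelity perception divided by the same quantity under perfect
perception, with a run-resampling bootstrap CI).

The headline fit goes through statsmodels; the bootstrap loops refit with an
internal Newton/IRLS on per-level aggregated binomial counts, which agrees
with statsmodels to near machine precision (asserted by the test suite) and
is orders of magnitude faster over thousands of resamples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
import statsmodels.api as sm

from .sim import RunRecord

OUTCOME_COLUMNS = ["poison_level", "final_poison_abundance", "under_pressure",
                   "predator_count_final"]

PRESSURE_CUTOFF = 800  # organisms; 80% of the class cap of 1,000


@dataclass(frozen=True)
class RunOutcome:
    """Binary outcome of one evolution run at one poison level."""

    poison_level: float
    final_poison_abundance: int
    under_pressure: bool
    predator_count_final: int = 0

    @property
    def avoided(self) -> bool:
        """Predators evolved to avoid poisonous prey (escaped pressure)."""
        return not self.under_pressure


def classify_predation_pressure(final_abundance: int, cutoff: int = PRESSURE_CUTOFF) -> bool:
    """True iff the poisonous subpopulation ended strictly below ``cutoff``
    (still being consumed by predators)."""
    if final_abundance < 0:
        raise ValueError(f"abundance must be >= 0, got {final_abundance}")
    return final_abundance < cutoff


def outcomes_from_records(records: list[RunRecord], cutoff: int = PRESSURE_CUTOFF) -> pd.DataFrame:
    """Classify a batch of runs into the outcome table the avoidance model
    consumes."""
    rows = []
    for rec in records:
        p = rec.config.get("poison_level")
        ab = int(rec.final_abundance[2])
        rows.append((p, ab, classify_predation_pressure(ab, cutoff), rec.final_predators))
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


def outcomes_to_frame(outcomes) -> pd.DataFrame:
    """Normalize a list of :class:`RunOutcome` (or a ready frame) to the
    outcome table."""
    if isinstance(outcomes, pd.DataFrame):
        missing = set(OUTCOME_COLUMNS) - set(outcomes.columns)
        if missing:
            raise ValueError(f"outcome frame lacks column(s): {sorted(missing)}")
        return outcomes.reset_index(drop=True)
    return pd.DataFrame(
        [(o.poison_level, o.final_poison_abundance, o.under_pressure,
          o.predator_count_final) for o in outcomes],
        columns=OUTCOME_COLUMNS,
    )


def filter_runs_min_predators(outcomes, min_predators: int = 100):
    """Keep runs whose final predator count reached ``min_predators`` (used
    for low conversion-efficiency treatments where predators often failed to
    establish)."""
    df = outcomes_to_frame(outcomes)
    return df[df["predator_count_final"] >= min_predators].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Logistic fit internals
# ---------------------------------------------------------------------------

def _aggregate(levels: np.ndarray, y: np.ndarray):
    """Collapse run-level Bernoulli outcomes to per-level binomial counts
    (an equivalent likelihood)."""
    ux = np.unique(levels)
    k = np.array([y[levels == v].sum() for v in ux], dtype=float)
    n = np.array([(levels == v).sum() for v in ux], dtype=float)
    return ux.astype(float), k, n


def _irls_logit(x, k, n, max_iter=60, tol=1e-12):
    """Newton/IRLS MLE of (intercept, slope) for binomial counts ``k`` of
    ``n`` at covariate ``x``.  Returns (beta, converged)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = n * mu * (1.0 - mu)
        grad = X.T @ (k - n * mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 1e6:
            return beta, False
        if np.abs(step).max() < tol:
            return beta, True
    return beta, False


def _separation(levels: np.ndarray, y: np.ndarray) -> bool:
    """Complete separation: a threshold on poison level splits the outcomes
    perfectly (no level carries both outcomes on the wrong side)."""
    ones = levels[y == 1]
    zeros = levels[y == 0]
    if len(ones) == 0 or len(zeros) == 0:
        return True  # all-identical outcomes: no MLE either
    return ones.min() > zeros.max() or ones.max() < zeros.min()


@dataclass
class AvoidanceLogitResults:
    """Fitted avoidance-vs-poison-level logistic model.

    Attributes
    ----------
    params : ndarray
        ``[intercept, slope]`` on the logit scale (slope per unit poison
        level).
    bse : ndarray or None
        Coefficient standard errors (from the statsmodels fit; ``None`` for
        degenerate fits).
    degenerate : bool
        True when the MLE does not exist (all-identical outcomes or complete
        separation); the curve is then the empirical per-level step.
    grid, curve : ndarray
        Poison-level grid and the predicted probability of avoidance on it.
    """

    model: "AvoidanceLogit"
    params: np.ndarray | None
    bse: np.ndarray | None
    degenerate: bool
    grid: np.ndarray
    curve: np.ndarray
    n_obs: int
    _sm_results: object = None

    def predict(self, poison_levels) -> np.ndarray:
        """Predicted avoidance probability at the given poison levels."""
        x = np.asarray(poison_levels, dtype=float)
        if not self.degenerate:
            return expit(self.params[0] + self.params[1] * x)
        return self.model._empirical_step(x)

    def bootstrap_band(self, n_boot: int = 10_000, level: float = 0.95,
                       seed: int | None = None, grid=None):
        """Percentile bootstrap confidence band for the curve; see
        :func:`bootstrap_curve_ci`."""
        return bootstrap_curve_ci(self.model.outcomes, n_boot=n_boot,
                                  level=level, seed=seed,
                                  grid=self.grid if grid is None else grid,
                                  point_results=self)

    def summary(self) -> str:
        lines = [
            "Avoidance logistic model (P(predators avoid poisonous prey) ~ poison level)",
            "=" * 74,
            f"n runs: {self.n_obs}    poison levels: {len(np.unique(self.model.levels))}",
        ]
        if self.degenerate:
            lines.append("DEGENERATE FIT: complete separation or constant outcomes;")
            lines.append("curve shown is the empirical per-level step function.")
        else:
            lines.append(f"{'':12s}{'coef':>12s}{'std err':>12s}")
            names = ["intercept", "slope"]
            for i, name in enumerate(names):
                se = self.bse[i] if self.bse is not None else float("nan")
                lines.append(f"{name:12s}{self.params[i]:12.4f}{se:12.4f}")
            lines.append(f"poison level at P(avoid)=0.5: "
                         f"{-self.params[0] / self.params[1]:.4f}")
        return "\n".join(lines)


class AvoidanceLogit:
    """Run-level logistic model of predator avoidance versus poison level.

    Parameters
    ----------
    outcomes : DataFrame or list of RunOutcome
        One row per evolution run; the response is ``NOT under_pressure``.
    """

    def __init__(self, outcomes):
        df = outcomes_to_frame(outcomes)
        if len(df) == 0:
            raise ValueError("no outcomes provided")
        self.outcomes = df
        self.levels = df["poison_level"].to_numpy(dtype=float)
        self.y = (~df["under_pressure"].to_numpy(dtype=bool)).astype(int)

    @classmethod
    def from_records(cls, records: list[RunRecord], cutoff: int = PRESSURE_CUTOFF):
        return cls(outcomes_from_records(records, cutoff))

    def _empirical_step(self, x) -> np.ndarray:
        """Per-level empirical avoidance frequency, extended to arbitrary
        poison levels by nearest observed level (the degenerate-fit curve)."""
        ux, k, n = _aggregate(self.levels, self.y)
        freq = k / n
        x = np.atleast_1d(np.asarray(x, dtype=float))
        idx = np.abs(x[:, None] - ux[None, :]).argmin(axis=1)
        return freq[idx]

    def fit(self, grid_size: int = 200) -> AvoidanceLogitResults:
        """Maximum-likelihood fit; degenerate data yield a flagged result
        with the empirical step curve instead of diverging coefficients."""
        if len(np.unique(self.levels)) < 2:
            raise ValueError("need outcomes at >= 2 distinct poison levels")
        grid = np.linspace(self.levels.min(), self.levels.max(), grid_size)
        if _separation(self.levels, self.y):
            return AvoidanceLogitResults(
                model=self, params=None, bse=None, degenerate=True,
                grid=grid, curve=self._empirical_step(grid), n_obs=len(self.y),
            )
        ux, k, n = _aggregate(self.levels, self.y)
        glm = sm.GLM(np.column_stack([k, n - k]),
                     sm.add_constant(ux), family=sm.families.Binomial())
        res = glm.fit()
        params = np.asarray(res.params, dtype=float)
        return AvoidanceLogitResults(
            model=self, params=params, bse=np.asarray(res.bse, dtype=float),
            degenerate=False, grid=grid,
            curve=expit(params[0] + params[1] * grid), n_obs=len(self.y),
            _sm_results=res,
        )


def fit_avoidance_logistic(outcomes, grid_size: int = 200) -> AvoidanceLogitResults:
    """Fit the avoidance-vs-poison-level logistic model (model-object API:
    :class:`AvoidanceLogit`)."""
    return AvoidanceLogit(outcomes).fit(grid_size=grid_size)


@dataclass
class CurveBand:
    """Percentile bootstrap band for the avoidance curve."""

    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int
    n_skipped: int
    high_skip_warning: bool


def bootstrap_curve_ci(outcomes, n_boot: int = 10_000, level: float = 0.95,
                       seed: int | None = None, grid=None,
                       point_results: AvoidanceLogitResults | None = None) -> CurveBand:
    """Stratified case-resampling bootstrap band for the avoidance curve.

    Runs are resampled with replacement *within each poison level* and the
    model refit (internal IRLS); the band is the percentile envelope of the
    refitted curves, widened if necessary to contain the point curve.
    Resamples with no finite MLE (separation) are skipped and counted; if
    more than 10% are skipped ``high_skip_warning`` is set.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    df = outcomes_to_frame(outcomes)
    levels = df["poison_level"].to_numpy(dtype=float)
    y = (~df["under_pressure"].to_numpy(dtype=bool)).astype(int)
    ux, k, n = _aggregate(levels, y)
    if grid is None:
        grid = np.linspace(levels.min(), levels.max(), 200)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    n_int = n.astype(int)
    curves = np.empty((n_boot, len(grid)))
    m = 0
    skipped = 0
    for _ in range(n_boot):
        # within-level resample of Bernoulli outcomes ~ Binomial(n, k/n)
        kb = rng.binomial(n_int, k / n).astype(float)
        pure = (kb == 0) | (kb == n)
        if pure.all():
            ones = ux[kb > 0]
            zeros = ux[kb < n]
            if len(ones) == 0 or len(zeros) == 0 or \
                    ones.min() > zeros.max() or ones.max() < zeros.min():
                skipped += 1
                continue
        beta, ok = _irls_logit(ux, kb, n)
        if not ok:
            skipped += 1
            continue
        curves[m] = expit(beta[0] + beta[1] * grid)
        m += 1
    if m == 0:
        raise RuntimeError("all bootstrap resamples were degenerate")
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(curves[:m], alpha, axis=0)
    upper = np.quantile(curves[:m], 1.0 - alpha, axis=0)
    if point_results is None:
        point_results = fit_avoidance_logistic(df)
    point = point_results.predict(grid)
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    return CurveBand(grid=grid, lower=lower, upper=upper, n_boot=n_boot,
                     n_skipped=skipped,
                     high_skip_warning=skipped > 0.1 * n_boot)


# ---------------------------------------------------------------------------
# Trajectory summaries (population means with replicate-bootstrap bands)
# ---------------------------------------------------------------------------

SERIES_NAMES = ("non-poisonous", "mimic", "poisonous", "predator")


def trajectory_summary(records: list[RunRecord], n_boot: int = 10_000,
                       level: float = 0.95, seed: int | None = None) -> pd.DataFrame:
    """Mean abundance trajectory per series with a replicate-level bootstrap
    band (whole runs are resampled, n_boot times).

    Returns a tidy frame (update, series, mean, lower, upper).  A single
    record yields zero-width bands.
    """
    if not records:
        raise ValueError("no records")
    updates = records[0].updates
    for rec in records[1:]:
        if not np.array_equal(rec.updates, updates):
            raise ValueError("records do not share a recording grid")
    R = len(records)
    data = np.stack([
        np.column_stack([rec.abundance, rec.predators]) for rec in records
    ])  # (R, T, 4)
    mean = data.mean(axis=0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, R, size=(n_boot, R))
    W = np.zeros((n_boot, R))
    for b in range(n_boot):  # resample weight matrix: boot mean = W @ data
        W[b] = np.bincount(idx[b], minlength=R)
    W /= R
    flat = data.reshape(R, -1)
    boot_means = W @ flat  # (n_boot, T*4)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(boot_means, alpha, axis=0).reshape(mean.shape)
    hi = np.quantile(boot_means, 1.0 - alpha, axis=0).reshape(mean.shape)
    lo = np.minimum(lo, mean)
    hi = np.maximum(hi, mean)
    frames = []
    for s, name in enumerate(SERIES_NAMES):
        frames.append(pd.DataFrame({
            "update": updates, "series": name, "mean": mean[:, s],
            "lower": lo[:, s], "upper": hi[:, s],
        }))
    return pd.concat(frames, ignore_index=True)


def mimic_display_proportions(record: RunRecord) -> pd.DataFrame:
    """Per-update proportions of mimic-class organisms displaying each class.

    Proportions sum to 1 where defined; updates with no mimics alive are
    reported as missing (NaN), not zero.
    """
    totals = record.displays.sum(axis=1).astype(float)
    props = np.full_like(record.displays, np.nan, dtype=float)
    ok = totals > 0
    props[ok] = record.displays[ok] / totals[ok, None]
    return pd.DataFrame({
        "update": record.updates,
        "displays_non_poisonous": props[:, 0],
        "displays_mimic": props[:, 1],
        "displays_poisonous": props[:, 2],
    })


# ---------------------------------------------------------------------------
# Imperfect-mimicry ratio
# ---------------------------------------------------------------------------

@dataclass
class RatioEstimate:
    """Ratio of mean final poisonous-display proportions: low-fidelity over
    perfect-fidelity populations."""

    ratio: float
    ci95: tuple[float, float]
    n_boot: int
    poison_level: float | None = None
    undefined: bool = False


def _final_poison_display(records: list[RunRecord]) -> np.ndarray:
    vals = np.array([rec.final_display_proportions()[2] for rec in records])
    return vals[~np.isnan(vals)]


def imperfect_mimicry_ratio(low_fidelity_runs: list[RunRecord],
                            perfect_runs: list[RunRecord],
                            n_boot: int = 1_000, level: float = 0.95,
                            seed: int | None = None,
                            poison_level: float | None = None) -> RatioEstimate:
    """Ratio (low-fidelity / perfect) of the mean per-run final proportion of
    mimic-class organisms displaying poisonous, with a percentile CI from
    resampling whole runs in both groups.

    Runs with no mimics alive at the end carry no proportion and are
    excluded.  A zero perfect-group mean leaves the ratio undefined
    (flagged, NaN).
    """
    a = _final_poison_display(low_fidelity_runs)
    b = _final_poison_display(perfect_runs)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both run groups must contain runs with surviving mimics")
    if b.mean() == 0:
        return RatioEstimate(ratio=float("nan"), ci95=(float("nan"), float("nan")),
                             n_boot=n_boot, poison_level=poison_level, undefined=True)
    point = a.mean() / b.mean()
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    num = a[ia].mean(axis=1)
    den = b[ib].mean(axis=1)
    ok = den > 0
    ratios = num[ok] / den[ok]
    alpha = (1.0 - level) / 2.0
    lo = float(np.quantile(ratios, alpha))
    hi = float(np.quantile(ratios, 1.0 - alpha))
    return RatioEstimate(ratio=float(point), ci95=(min(lo, point), max(hi, point)),
                         n_boot=n_boot, poison_level=poison_level)
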