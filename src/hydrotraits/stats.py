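"""Statistical layer: trait ANOVA, paired comparisons, and GLM model selection.

Trait differences between species are tested with one-way ANOVA plus Tukey's
HSD, summarised as a compact letter display (groups sharing a letter are not
significantly different).  Trait-damage relationships are screened two ways:
single-predictor ordinary least squares, and an exhaustive search over
Gaussian log-link GLMs with up to ``max_k`` predictors, ranked by AIC.

Model ranking follows the information-theoretic convention: delta AIC is each
model's AIC minus the minimum, Akaike weights are
``exp(-delta/2) / sum(exp(-delta/2))``, models within delta <= 2 have similar
support, and the best model is the lowest-AIC fit whose predictors show no
strong collinearity (every variance inflation factor <= a threshold,
default 10).  VIF is taken as 1 by convention for single-predictor models.

Because damage responses are bounded percentages while the log link requires
positive responses, responses are clamped into [0.5, 99.5] before fitting
(the clamp is recorded on the fit).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.outliers_influence import variance_inflation_factor

RESPONSE_CLAMP = (0.5, 99.5)


# ---------------------------------------------------------------------------
# ANOVA + Tukey compact letter display
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    letters: dict[str, str]


def _compact_letters(groups: list[str], differ: set[frozenset]) -> dict[str, str]:
    """Greedy insert-and-absorb compact letter display.

    ``differ`` holds the significantly different pairs.  Each letter denotes
    a clique of mutually non-different groups; every non-different pair ends
    up sharing at least one letter and no different pair shares any.
    """
    cliques: list[set[str]] = []
    for g in groups:
        placed = False
        for clique in cliques:
            if all(frozenset((g, other)) not in differ for other in clique):
                clique.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    # ensure every non-different pair shares a clique
    for g1, g2 in itertools.combinations(groups, 2):
        if frozenset((g1, g2)) in differ:
            continue
        if not any(g1 in c and g2 in c for c in cliques):
            merged = {g1, g2}
            for other in groups:
                if other in (g1, g2):
                    continue
                if (frozenset((other, g1)) not in differ
                        and frozenset((other, g2)) not in differ):
                    merged.add(other)
            cliques.append(merged)
    # absorb cliques contained in others
    cliques = [
        c for i, c in enumerate(cliques)
        if not any(i != j and c < other for j, other in enumerate(cliques))
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, clique in zip(alphabet, cliques):
        for g in clique:
            letters[g] += letter
    return letters


def anova_tukey(values_by_group: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with all-pairs Tukey HSD and a compact letter display.

    Requires at least two groups with at least two values each and positive
    pooled within-group variance.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("need at least 2 values per group")
    pooled_var = np.concatenate([a - a.mean() for a in arrays]).var()
    if pooled_var <= 0:
        raise ValueError("zero pooled within-group variance")
    f_stat, p_value = _sps.f_oneway(*arrays)

    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    tukey = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    differ = set()
    for (g1, g2), reject in zip(
        itertools.combinations(sorted(groups), 2), tukey.reject
    ):
        if reject:
            differ.add(frozenset((g1, g2)))
    # keep the caller's group order for letter assignment, sorted by mean
    ordered = sorted(groups, key=lambda g: np.mean(values_by_group[g]))
    letters = _compact_letters(ordered, differ)
    return AnovaResult(f_stat=float(f_stat), p_value=float(p_value), letters=letters)


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t-test on per-individual differences.

    Identical vectors give (t=0, p=1); a constant nonzero shift with zero
    variance of differences is degenerate and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise ValueError("zero variance of differences with nonzero shift: t undefined")
    t, p = _sps.ttest_rel(x, y)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# single-trait linear models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LMResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def fit_lm_single(x, y) -> LMResult:
    """OLS of y on a single predictor; r^2 is the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.allclose(x.std(), 0.0):
        raise ValueError("zero variance in predictor")
    res = _sps.linregress(x, y)
    return LMResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# exhaustive GLM selection
# ---------------------------------------------------------------------------

def enumerate_models(predictors: list[str], max_k: int = 3) -> list[tuple[str, ...]]:
    """All predictor subsets of size 1..max_k, in deterministic order.

    Subsets are emitted by increasing size, lexicographically in the order
    the predictors are given.  With p predictors and max_k >= p this yields
    2^p - 1 formulas.
    """
    if not predictors:
        raise ValueError("need at least one predictor")
    out: list[tuple[str, ...]] = []
    for k in range(1, min(max_k, len(predictors)) + 1):
        out.extend(itertools.combinations(predictors, k))
    return out


@dataclass
class GLMFit:
    """One Gaussian log-link GLM fit with its selection diagnostics."""

    formula: tuple[str, ...]
    coefficients: dict[str, float]
    coefficient_se: dict[str, float]
    aic: float
    mcfadden_r2: float
    deviance_explained: float
    vif: dict[str, float]
    n: int
    converged: bool = True
    saturated: bool = False
    response_clamped: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None
    delta_aic: float = float("nan")
    akaike_weight: float = float("nan")

    @property
    def max_vif(self) -> float:
        return max(self.vif.values()) if self.vif else float("nan")


def fit_glm(
    y,
    X: pd.DataFrame,
    formula: tuple[str, ...] | None = None,
    clamp: tuple[float, float] | None = RESPONSE_CLAMP,
) -> GLMFit:
    """Gaussian-family, log-link GLM of a damage metric on trait predictors.

    Fits by iteratively reweighted least squares (statsmodels).  Reports AIC
    from the Gaussian log-likelihood with estimated dispersion, McFadden
    R^2 = 1 - llf_model / llf_null, deviance explained = 1 - residual/null
    deviance, and per-predictor VIFs computed from the linear design (1 by
    convention for a single predictor).  Responses are clamped into
    ``clamp`` before fitting so the log link is well-defined at 0 and 100.

    Fits with one or fewer residual degrees of freedom are flagged
    ``saturated`` ("saturated-regime"): they are produced, but their
    near-unity fit statistics carry little information.
    """
    if formula is None:
        formula = tuple(X.columns)
    y = np.asarray(y, dtype=float)
    n, k = len(y), len(formula)
    X = X.loc[:, list(formula)].astype(float) if k else pd.DataFrame(index=range(n))
    if n <= k + 1:
        raise ValueError(f"n = {n} observations cannot identify {k} predictors + intercept")

    clamped = False
    if clamp is not None:
        lo, hi = clamp
        y_fit = np.clip(y, lo, hi)
        clamped = bool(np.any(y_fit != y))
    else:
        y_fit = y
    if np.any(y_fit <= 0):
        raise ValueError("log link requires positive responses after clamping")

    if k:
        exog = sm.add_constant(X, has_constant="add")
    else:
        exog = pd.DataFrame({"const": np.ones(n)})
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError(f"singular design for formula {formula}")

    model = sm.GLM(y_fit, exog, family=sm.families.Gaussian(sm.families.links.Log()))
    converged = True
    try:
        res = model.fit(maxiter=200)
        converged = bool(getattr(res, "converged", True))
    except Exception as err:  # non-convergence of IRLS
        raise RuntimeError(f"GLM fit failed for formula {formula}: {err}") from err

    null_model = sm.GLM(
        y_fit, np.ones((n, 1)), family=sm.families.Gaussian(sm.families.links.Log())
    )
    null_res = null_model.fit()
    llf, llf_null = float(res.llf), float(null_res.llf)
    mcfadden = 1.0 - llf / llf_null if llf_null != 0 else float("nan")
    dev_expl = 1.0 - float(res.deviance) / float(null_res.deviance)

    if k == 0:
        vif = {}
    elif k == 1:
        vif = {formula[0]: 1.0}
    else:
        arr = exog.to_numpy()
        cols = list(exog.columns)
        vif = {
            name: float(variance_inflation_factor(arr, cols.index(name)))
            for name in formula
        }

    coef = dict(zip(exog.columns, map(float, res.params)))
    se = dict(zip(exog.columns, map(float, res.bse)))
    return GLMFit(
        formula=formula,
        coefficients=coef,
        coefficient_se=se,
        aic=float(res.aic),
        mcfadden_r2=float(mcfadden),
        deviance_explained=float(np.clip(dev_expl, 0.0, 1.0)),
        vif=vif,
        n=n,
        converged=converged,
        saturated=(n - (k + 1)) <= 1,
        response_clamped=clamped,
    )


@dataclass
class ModelRanking:
    fits: list[GLMFit] = field(default_factory=list)
    best: GLMFit | None = None

    @property
    def similar_support(self) -> list[GLMFit]:
        """Models with delta AIC <= 2 among non-excluded fits."""
        return [f for f in self.fits if not f.excluded and f.delta_aic <= 2.0]


def _assign_weights(fits: list[GLMFit]) -> None:
    active = [f for f in fits if not f.excluded]
    if not active:
        raise ValueError("all models excluded")
    aic_min = min(f.aic for f in active)
    rel = np.array([np.exp(-(f.aic - aic_min) / 2.0) for f in active])
    weights = rel / rel.sum()
    for f, w in zip(active, weights):
        f.delta_aic = f.aic - aic_min
        f.akaike_weight = float(w)
    for f in fits:
        if f.excluded:
            f.delta_aic = f.aic - aic_min
            f.akaike_weight = float("nan")


def rank_models(fits: list[GLMFit]) -> ModelRanking:
    """Sort fits by AIC and assign delta AIC and Akaike weights.

    Weights are computed over non-excluded fits and sum to 1.  Ties on AIC
    break towards fewer predictors, then lexicographic formula order.
    """
    if not fits:
        raise ValueError("no fits to rank")
    ordered = sorted(fits, key=lambda f: (f.aic, len(f.formula), f.formula))
    _assign_weights(ordered)
    return ModelRanking(fits=ordered, best=None)


def select_best(ranking: ModelRanking, vif_threshold: float = 10.0) -> GLMFit:
    """Lowest-AIC fit whose every VIF is within the collinearity threshold.

    Fits ranked above the winner that violate the threshold are marked
    excluded with the offending VIFs in the reason; weights are then
    recomputed over the surviving fits.  Raises (listing the max VIFs) when
    no fit passes.
    """
    if not ranking.fits:
        raise ValueError("empty ranking")
    best = None
    for fit in ranking.fits:
        if fit.excluded:
            continue
        bad = {k: v for k, v in fit.vif.items() if np.isfinite(v) and v > vif_threshold}
        if bad:
            fit.excluded = True
            fit.exclusion_reason = (
                "VIF > " + f"{vif_threshold:g}: "
                + ", ".join(f"{k}={v:.1f}" for k, v in bad.items())
            )
            continue
        best = fit
        break
    if best is None:
        worst = {f.formula: f.max_vif for f in ranking.fits}
        raise ValueError(f"no model passes VIF <= {vif_threshold}; max VIFs: {worst}")
    _assign_weights(ranking.fits)
    ranking.best = best
    return best


def run_model_selection(
    y,
    traits: pd.DataFrame,
    predictors: list[str] | None = None,
    max_k: int = 3,
    vif_threshold: float = 10.0,
    clamp: tuple[float, float] | None = RESPONSE_CLAMP,
) -> ModelRanking:
    """Exhaustive GLM search: enumerate, fit, rank, and select the best model."""
    if predictors is None:
        predictors = list(traits.columns)
    fits = []
    for formula in enumerate_models(predictors, max_k=max_k):
        try:
            fits.append(fit_glm(y, traits, formula=formula, clamp=clamp))
        except ValueError:
            continue  # singular designs are skipped, not ranked
    ranking = rank_models(fits)
    select_best(ranking, vif_threshold=vif_threshold)
    return ranking


def ranking_table(ranking: ModelRanking) -> pd.DataFrame:
    """Tidy summary of a model ranking (one row per fitted formula)."""
    return pd.DataFrame(
        {
            "formula": ["+".join(f.formula) for f in ranking.fits],
            "k": [len(f.formula) for f in ranking.fits],
            "aic": [f.aic for f in ranking.fits],
            "delta_aic": [f.delta_aic for f in ranking.fits],
            "akaike_weight": [f.akaike_weight for f in ranking.fits],
            "mcfadden_r2": [f.mcfadden_r2 for f in ranking.fits],
            "deviance_explained": [f.deviance_explained for f in ranking.fits],
            "max_vif": [f.max_vif for f in ranking.fits],
            "saturated": [f.saturated for f in ranking.fits],
            "excluded": [f.excluded for f in ranking.fits],
            "reason": [f.exclusion_reason or "" for f in ranking.fits],
        }
    )
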