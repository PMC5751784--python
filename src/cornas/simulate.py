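"""Fragment-sampling simulator and the power/robustness studies built on it.

Sequencing is modelled as drawing ``S`` fragments uniformly without
replacement from a pool of ``N``; a gene with true count ``k`` then shows
a Hypergeometric(N, k, S) observed count. The literal construction —
shuffle the fragment indices and count how many of the first S belong to
the gene — is kept as :func:`fisher_yates_observed_count` for small pools
and used as a test oracle; the production sampler draws the
hypergeometric directly, which is distributionally identical and does not
require materialising 3e8 indices.

Because coverage ``b = S/N`` is the governing parameter (for k << N), the
power studies run on a proportionally scaled population (default
N = 3e6 instead of 3e8) with identical behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .deg import DEFAULT_ALPHA, DEFAULT_PHI, _fold_bounds, _validate_rule_params
from .errors import CoverageError, ParameterError
from .evaluation import roc_auc

__all__ = [
    "SimulationScenario",
    "EFFECT_SCENARIOS",
    "sample_observed_count",
    "fisher_yates_observed_count",
    "mean_variance_study",
    "default_k_grid",
    "run_test1",
    "run_pcr_efficiency_study",
]

#: effect name -> (fold change, maximum true count at full scale).
#: The three scenarios jointly cover 10000 + 6666 + 5000 = 21666 genes at
#: full scale: no effect (false-positive study), 1.5-fold (weak) and
#: 2-fold (strong).
EFFECT_SCENARIOS = {
    "none": (1.0, 10_000),
    "weak": (1.5, 6_666),
    "strong": (2.0, 5_000),
}

FULL_SCALE_POPULATION = 300_000_000
DEFAULT_SCALED_POPULATION = 3_000_000


@dataclass(frozen=True)
class SimulationScenario:
    """One power-study scenario: a fold change applied over a range of
    true counts at a fixed coverage."""

    effect: str
    fold: float
    max_true_count: int
    coverage: float
    population_N: int = FULL_SCALE_POPULATION
    iterations: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.effect not in EFFECT_SCENARIOS:
            raise ParameterError(
                f"effect must be one of {sorted(EFFECT_SCENARIOS)}, got {self.effect!r}"
            )
        expected_fold, _ = EFFECT_SCENARIOS[self.effect]
        if self.fold != expected_fold:
            raise ParameterError(
                f"effect {self.effect!r} implies fold {expected_fold}, got {self.fold}"
            )
        if not (0.0 < self.coverage < 1.0):
            raise CoverageError(f"coverage {self.coverage!r} outside (0, 1)")
        if self.fold * self.max_true_count > self.population_N:
            raise ParameterError(
                f"fold x max_true_count = {self.fold * self.max_true_count:g} "
                f"exceeds population N = {self.population_N}"
            )
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")

    @classmethod
    def from_effect(
        cls,
        effect: str,
        coverage: float,
        population_N: int = FULL_SCALE_POPULATION,
        iterations: int = 100,
        seed: int | None = None,
        max_true_count: int | None = None,
    ) -> "SimulationScenario":
        fold, default_max = EFFECT_SCENARIOS[effect]
        return cls(
            effect=effect,
            fold=fold,
            max_true_count=default_max if max_true_count is None else max_true_count,
            coverage=coverage,
            population_N=population_N,
            iterations=iterations,
            seed=seed,
        )

    @property
    def reads_S(self) -> int:
        return int(round(self.coverage * self.population_N))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _validate_k_S_N(k, S: int, N: int) -> np.ndarray:
    k = np.asarray(k)
    if np.any(k < 1) or np.any(k > N):
        raise ParameterError(f"true count k must satisfy 1 <= k <= N={N}")
    if not (1 <= S <= N):
        raise ParameterError(f"reads S must satisfy 1 <= S <= N={N}")
    return k


def sample_observed_count(k, S: int, N: int, rng) -> np.ndarray:
    """Observed count(s) for true count(s) ``k``: Hypergeometric(N, k, S).

    ``k`` may be scalar or array; with ``size`` semantics delegated to the
    generator, pass an array of repeated k values for repeated draws.
    Extremes behave as expected: k = N gives x = S always (every sampled
    fragment belongs to the gene); S = N gives x = k (exhaustive
    sequencing).
    """
    k = _validate_k_S_N(k, S, N)
    rng = _as_rng(rng)
    return rng.hypergeometric(k, N - k, S)


def fisher_yates_observed_count(k: int, S: int, N: int, rng) -> int:
    """Literal shuffle construction of one observed count (test oracle).

    Shuffles the N fragment indices and counts how many of the first S
    belong to the gene (indices 0..k-1). Only sensible for small N.
    """
    _validate_k_S_N(k, S, N)
    rng = _as_rng(rng)
    pi = rng.permutation(N)[:S]
    return int(np.count_nonzero(pi < k))


def mean_variance_study(
    coverages: Iterable[float],
    k_values: Iterable[int],
    iterations: int = 2000,
    population_N: int = DEFAULT_SCALED_POPULATION,
    seed=None,
) -> pd.DataFrame:
    """Empirical mean/variance of observed counts across coverages.

    Returns one row per (coverage, true count) cell with the empirical
    mean, variance and mean-variance ratio ``m_hat``. Expected behaviour:
    mean ~= b*k, m_hat ~= 1/(1-b), and variance < mean everywhere
    (underdispersion, because sampling is without replacement).
    """
    rng = _as_rng(seed)
    rows = []
    for b in coverages:
        if not (0.0 < b < 1.0):
            raise CoverageError(f"coverage {b!r} outside (0, 1)")
        S = int(round(b * population_N))
        for k in k_values:
            x = sample_observed_count(
                np.full(iterations, int(k)), S, population_N, rng
            )
            mean = float(np.mean(x))
            var = float(np.var(x, ddof=1))
            rows.append(
                {
                    "b": b,
                    "k": int(k),
                    "mean": mean,
                    "variance": var,
                    "m_hat": mean / var if var > 0 else np.inf,
                }
            )
    return pd.DataFrame(rows)


def default_k_grid(max_true_count: int, points_per_decade: int = 30) -> np.ndarray:
    """Log-spaced integer grid of true counts from 1 to max_true_count."""
    if max_true_count < 1:
        raise ParameterError("max_true_count must be >= 1")
    n = max(2, int(np.ceil(np.log10(max_true_count) * points_per_decade)))
    grid = np.round(np.logspace(0.0, np.log10(max_true_count), n)).astype(int)
    return np.unique(grid)


def _treatment_counts(k: np.ndarray, fold: float) -> np.ndarray:
    # round-half-to-even, matching numpy's default rounding
    return np.round(fold * k).astype(int)


def _simulate_pair(
    k_grid: np.ndarray,
    fold: float,
    S: int,
    N: int,
    iterations: int,
    rng: np.random.Generator,
):
    """Observed-count matrices (n_k, iterations) for the two samples.

    The two samples are drawn independently (no coupling between their
    sequencing runs is assumed).
    """
    k1 = k_grid[:, None]
    k2 = _treatment_counts(k_grid, fold)[:, None]
    shape = (len(k_grid), iterations)
    x1 = rng.hypergeometric(k1, N - k1, S, size=shape)
    x2 = rng.hypergeometric(k2, N - k2, S, size=shape)
    return x1, x2


def run_test1(
    scenario: SimulationScenario,
    alpha: float = DEFAULT_ALPHA,
    phi: float = DEFAULT_PHI,
    k_grid: Sequence[int] | None = None,
    rng=None,
) -> pd.DataFrame:
    """Per-true-count DEG call rates for one scenario.

    For each true count k on the grid, sample 1 has true count k and
    sample 2 has round(fold x k); observed counts are drawn independently
    at the scenario coverage and the decision rule applied per iteration.
    The returned frame has one row per k with the relative call frequency:
    ``call_rate`` counts direction-correct calls only (for fold > 1) or
    any call (fold = 1, where every call is a false positive); ``any_call_rate``
    counts calls in either direction. Under no effect the call rate is the
    FPR; under weak/strong effects it is the TPR (sensitivity).
    """
    _validate_rule_params(alpha, phi)
    rng = _as_rng(scenario.seed if rng is None else rng)
    if k_grid is None:
        k_grid = default_k_grid(scenario.max_true_count)
    k_grid = np.asarray(k_grid, dtype=int)
    if np.any(k_grid < 1) or np.any(
        _treatment_counts(k_grid, scenario.fold) > scenario.population_N
    ):
        raise ParameterError("k grid outside [1, N/fold]")

    N, S = scenario.population_N, scenario.reads_S
    x1, x2 = _simulate_pair(k_grid, scenario.fold, S, N, scenario.iterations, rng)
    mu0, mu1, _, _, fold_bound, hi1 = _fold_bounds(
        x1, scenario.coverage, x2, scenario.coverage, alpha
    )
    called = (fold_bound >= phi) & (mu0 != mu1)
    correct = called & hi1 if scenario.fold > 1.0 else called
    return pd.DataFrame(
        {
            "b": scenario.coverage,
            "k": k_grid,
            "k_treatment": _treatment_counts(k_grid, scenario.fold),
            "call_rate": correct.mean(axis=1),
            "any_call_rate": called.mean(axis=1),
            "iterations": scenario.iterations,
        }
    )


# ---------------------------------------------------------------------------
# PCR-efficiency robustness study


def _sweep_cutoffs(
    phi_sweep: np.ndarray, alpha_sweep: np.ndarray, phi_fixed: float, alpha_fixed: float
):
    """The ROC cut-off sweep: fixed alpha with phi descending, then fixed
    phi with alpha descending."""
    cuts = [(alpha_fixed, float(p)) for p in phi_sweep]
    cuts += [(float(a), phi_fixed) for a in alpha_sweep]
    return cuts


def run_pcr_efficiency_study(
    expected_coverages: Sequence[float] = (0.5, 0.25, 0.1, 0.01),
    efficiencies: Sequence[float] = (1.0, 0.95, 0.90, 0.85, 0.80),
    population_N: int = DEFAULT_SCALED_POPULATION,
    iterations: int = 50,
    points_per_decade: int = 8,
    pcr_cycles: int = 14,
    phi_sweep: Sequence[float] | None = None,
    alpha_sweep: Sequence[float] | None = None,
    seed=None,
):
    """ROC robustness of the caller to mis-specified PCR efficiency.

    Observed counts are generated once per expected coverage at the true
    coverage (perfect amplification). The caller is then re-run assuming
    each efficiency: an efficiency e < 1 means only ``((1+e)/2)**cycles``
    of the nominal fragment population was present, so the assumed
    coverage is inflated to ``b / retention``. Cells where that exceeds 1
    are skipped with a warning (the method is not recommended there).

    FPR comes from the no-effect scenario and TPR (direction-aware) from
    the strong-effect scenario; the ROC cut-off sweep holds alpha = 0.99
    while phi descends 1.5 -> 0.75, then holds phi = 0.75 while alpha
    descends 0.99 -> 0.01. AUC is the raw trapezoid over the swept points
    augmented with (0,0) and (1,1).

    Returns ``(summary, curves)``: a frame with one row per (expected
    coverage, efficiency) holding the assumed coverage and AUC, and a dict
    mapping (expected_coverage, efficiency) -> ROC point frame.
    """
    from .coverage import pcr_retention  # local import to avoid cycle at module load

    rng = _as_rng(seed)
    if phi_sweep is None:
        phi_sweep = np.linspace(1.5, 0.75, 16)
    if alpha_sweep is None:
        alpha_sweep = np.linspace(0.99, 0.01, 15)
    cutoffs = _sweep_cutoffs(np.asarray(phi_sweep), np.asarray(alpha_sweep), 0.75, 0.99)

    rows = []
    curves: dict[tuple[float, float], pd.DataFrame] = {}
    for b_true in expected_coverages:
        if not (0.0 < b_true < 1.0):
            raise CoverageError(f"coverage {b_true!r} outside (0, 1)")
        S = int(round(b_true * population_N))
        k_fp = default_k_grid(EFFECT_SCENARIOS["none"][1], points_per_decade)
        k_tp = default_k_grid(EFFECT_SCENARIOS["strong"][1], points_per_decade)
        xf1, xf2 = _simulate_pair(k_fp, 1.0, S, population_N, iterations, rng)
        xt1, xt2 = _simulate_pair(k_tp, 2.0, S, population_N, iterations, rng)

        for eff in efficiencies:
            retention = pcr_retention(eff, pcr_cycles)
            b_assumed = b_true / retention
            if b_assumed >= 1.0:
                warnings.warn(
                    f"expected coverage {b_true} at efficiency {eff:.0%} gives "
                    f"assumed coverage {b_assumed:.2f} >= 1; cell skipped",
                    UserWarning,
                    stacklevel=2,
                )
                rows.append(
                    {
                        "expected_coverage": b_true,
                        "efficiency": eff,
                        "assumed_coverage": b_assumed,
                        "auc": np.nan,
                        "skipped": True,
                    }
                )
                continue
            pts = []
            for a, p in cutoffs:
                _, _, _, _, fb_f, _ = _fold_bounds(xf1, b_assumed, xf2, b_assumed, a)
                mu0, mu1, _, _, fb_t, hi1 = _fold_bounds(
                    xt1, b_assumed, xt2, b_assumed, a
                )
                fpr = float((fb_f >= p).mean())
                tpr = float(((fb_t >= p) & hi1 & (mu0 != mu1)).mean())
                pts.append({"alpha": a, "phi": p, "fpr": fpr, "tpr": tpr})
            curve = pd.DataFrame(pts)
            curves[(b_true, eff)] = curve
            rows.append(
                {
                    "expected_coverage": b_true,
                    "efficiency": eff,
                    "assumed_coverage": b_assumed,
                    "auc": roc_auc(list(zip(curve["fpr"], curve["tpr"]))),
                    "skipped": False,
                }
            )
    return pd.DataFrame(rows), curves
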