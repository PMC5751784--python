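"""The differential-expression decision rule.

For a control/treatment pair of unreplicated samples, each gene's true
count has an (approximately gamma) posterior in each sample. The gene is
called differentially expressed at credibility ``alpha`` and fold-change
threshold ``phi`` when the (1-alpha)/2 quantile of the higher-mean
posterior is at least ``phi`` times the (1+alpha)/2 quantile of the
lower-mean posterior:

    p+_{(1-alpha)/2} / p-_{(1+alpha)/2} >= phi.

At the defaults alpha = 0.99 and phi = 1.5 this compares the 0.5th
percentile of the higher posterior against the 99.5th percentile of the
lower one, so a call carries a 0.995^2 ~= 0.99 joint probability that the
true counts differ by at least 1.5-fold. The rule is a per-gene
credibility statement — no multiple-testing adjustment is applied, and no
normalisation or transcript-length information is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

from .errors import CountTableError, ParameterError
from .gp_model import _gamma_moments, _gamma_shape_scale

__all__ = ["DEFAULT_ALPHA", "DEFAULT_PHI", "DEGCall", "call_gene", "call_table", "calls_to_frame"]

DEFAULT_ALPHA = 0.99
DEFAULT_PHI = 1.5


@dataclass(frozen=True)
class DEGCall:
    """Per-gene decision record.

    ``lower_high`` is the (1-alpha)/2 quantile of the higher-mean
    posterior, ``upper_low`` the (1+alpha)/2 quantile of the lower-mean
    one; ``fold_bound = lower_high / upper_low`` is compared against
    ``phi``. The record keeps both posterior means and the bound so calls
    can be re-thresholded without recomputation.
    """

    gene_id: str
    x_control: int
    x_treatment: int
    mean_control: float
    mean_treatment: float
    lower_high: float
    upper_low: float
    fold_bound: float
    direction: str  # 'up' | 'down' | 'none'
    alpha: float
    phi: float

    @property
    def joint_credibility(self) -> float:
        """Probability that both true counts fall on the called side of
        their respective percentile bounds: ((1+alpha)/2)^2."""
        return ((1.0 + self.alpha) / 2.0) ** 2


def _validate_rule_params(alpha: float, phi: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if phi <= 0:
        raise ParameterError(f"phi must be positive, got {phi}")


def _fold_bounds(x0, b0, x1, b1, alpha):
    """Vectorised decision quantities.

    Returns (mean0, mean1, lower_high, upper_low, fold_bound,
    treatment_is_higher) as arrays broadcast over the inputs.
    """
    mu0, _ = _gamma_moments(x0, b0)
    mu1, _ = _gamma_moments(x1, b1)
    a0, s0 = _gamma_shape_scale(x0, b0)
    a1, s1 = _gamma_shape_scale(x1, b1)
    q_lo = (1.0 - alpha) / 2.0
    q_hi = (1.0 + alpha) / 2.0
    hi1 = mu1 > mu0
    lower_high = np.where(
        hi1,
        _gamma_dist.ppf(q_lo, a1, scale=s1),
        _gamma_dist.ppf(q_lo, a0, scale=s0),
    )
    upper_low = np.where(
        hi1,
        _gamma_dist.ppf(q_hi, a0, scale=s0),
        _gamma_dist.ppf(q_hi, a1, scale=s1),
    )
    return mu0, mu1, lower_high, upper_low, lower_high / upper_low, hi1


def call_gene(
    x0: int,
    b0: float,
    x1: int,
    b1: float,
    alpha: float = DEFAULT_ALPHA,
    phi: float = DEFAULT_PHI,
    gene_id: str = "gene",
) -> DEGCall:
    """Apply the decision rule to one gene.

    Sample 0 is the control, sample 1 the treatment. A gene with exactly
    tied posterior means is never called (the rule requires a strictly
    larger mean on one side). Genes with x = 0 are processed normally —
    the posterior is defined at zero observed count and no minimum-count
    filter is applied.
    """
    _validate_rule_params(alpha, phi)
    for x, name in ((x0, "control"), (x1, "treatment")):
        if int(x) != x or x < 0:
            raise CountTableError(
                f"gene {gene_id!r}: {name} count must be a non-negative integer, got {x}"
            )
    mu0, mu1, lower_high, upper_low, fold_bound, hi1 = _fold_bounds(
        int(x0), b0, int(x1), b1, alpha
    )
    mu0, mu1 = float(mu0), float(mu1)
    fold_bound = float(fold_bound)
    if mu0 == mu1:
        direction = "none"
    elif fold_bound >= phi:
        direction = "up" if bool(hi1) else "down"
    else:
        direction = "none"
    return DEGCall(
        gene_id=gene_id,
        x_control=int(x0),
        x_treatment=int(x1),
        mean_control=mu0,
        mean_treatment=mu1,
        lower_high=float(lower_high),
        upper_low=float(upper_low),
        fold_bound=fold_bound,
        direction=direction,
        alpha=alpha,
        phi=phi,
    )


def call_table(
    counts,
    control_id: str,
    treatment_id: str,
    coverages,
    alpha: float = DEFAULT_ALPHA,
    phi: float = DEFAULT_PHI,
) -> list[DEGCall]:
    """Apply the decision rule to every gene of a count table.

    ``counts`` is a :class:`cornas.io.CountMatrix` (or anything with the
    same ``gene_ids`` / ``sample_ids`` / ``counts`` attributes).
    ``coverages`` maps sample id -> coverage (floats or
    :class:`cornas.coverage.CoverageSpec`). Gene order is preserved.
    """
    _validate_rule_params(alpha, phi)
    for sid in (control_id, treatment_id):
        if sid not in counts.sample_ids:
            raise CountTableError(
                f"sample {sid!r} not found in count table "
                f"(available: {', '.join(counts.sample_ids)})"
            )

    def _cov(sid: str) -> float:
        c = coverages[sid]
        return c.coverage_b if hasattr(c, "coverage_b") else float(c)

    b0, b1 = _cov(control_id), _cov(treatment_id)
    j0 = counts.sample_ids.index(control_id)
    j1 = counts.sample_ids.index(treatment_id)
    x0 = counts.counts[:, j0]
    x1 = counts.counts[:, j1]
    if len(x0) == 0:
        return []

    mu0, mu1, lower_high, upper_low, fold_bound, hi1 = _fold_bounds(x0, b0, x1, b1, alpha)
    called = (fold_bound >= phi) & (mu0 != mu1)
    out = []
    for i, gid in enumerate(counts.gene_ids):
        if not called[i]:
            direction = "none"
        else:
            direction = "up" if hi1[i] else "down"
        out.append(
            DEGCall(
                gene_id=gid,
                x_control=int(x0[i]),
                x_treatment=int(x1[i]),
                mean_control=float(mu0[i]),
                mean_treatment=float(mu1[i]),
                lower_high=float(lower_high[i]),
                upper_low=float(upper_low[i]),
                fold_bound=float(fold_bound[i]),
                direction=direction,
                alpha=alpha,
                phi=phi,
            )
        )
    return out


def calls_to_frame(calls: Sequence[DEGCall]) -> pd.DataFrame:
    """Tabulate decision records, one row per gene."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "x_control": [c.x_control for c in calls],
            "x_treatment": [c.x_treatment for c in calls],
            "mean_control": [c.mean_control for c in calls],
            "mean_treatment": [c.mean_treatment for c in calls],
            "lower_high": [c.lower_high for c in calls],
            "upper_low": [c.upper_low for c in calls],
            "fold_bound": [c.fold_bound for c in calls],
            "call": [c.direction for c in calls],
        }
    )
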