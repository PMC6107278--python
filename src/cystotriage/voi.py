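"""Value-of-information analysis from a PSA sample.

EVPI (expected value of perfect information) is the mean over draws of the
best achievable net benefit minus the net benefit of the best strategy on
average.  EVPPI (partial, for a parameter subset) is estimated by the
regression approach: the conditional-expected net benefit of each strategy
given the subset is a smooth function of those parameters, estimated by
flexible least squares on the PSA sample; EVPPI is then the mean of the
fitted maxima minus the maximum of the fitted means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer

from .sensitivity import PSASample

__all__ = ["evpi", "evppi", "VOIResult", "voi_table"]


def evpi(sample: PSASample, wtp: float) -> float:
    """Per-patient expected value of perfect information at ``wtp``."""
    nb = sample.net_benefit(wtp)
    if nb.shape[0] == 0:
        raise ValueError("empty PSA sample")
    return float(nb.max(axis=1).mean() - nb.mean(axis=0).max())


def _design_matrix(x: np.ndarray, n: int) -> np.ndarray:
    """Smooth regression basis for the subset, capped relative to sqrt(n).

    Additive cubic splines for up to three parameters; second-order
    polynomial (with interactions) above that.
    """
    p = x.shape[1]
    if p <= 3:
        budget = max(4, int(np.sqrt(n) / max(p, 1)))
        n_knots = int(np.clip(budget, 4, 12))
        st = SplineTransformer(degree=3, n_knots=n_knots, include_bias=False)
        return st.fit_transform(x)
    pf = PolynomialFeatures(degree=2, include_bias=False)
    return pf.fit_transform(x)


@dataclass
class VOIResult:
    wtp: float
    evpi: float
    evppi: dict = field(default_factory=dict)  # subset label -> value
    basis_size: dict = field(default_factory=dict)
    residual_var: dict = field(default_factory=dict)


def evppi(sample: PSASample, subset, wtp: float) -> float:
    """Regression-based EVPPI for the named parameter subset.

    Constant columns are dropped with a warning; an all-constant subset has
    zero information value.  Ordinary least squares with an intercept keeps
    each strategy's fitted mean equal to its sample mean exactly.
    """
    subset = list(subset)
    missing = [s for s in subset if s not in sample.draws.columns]
    if missing:
        raise KeyError(f"parameters not in the PSA draws: {missing}")
    x = sample.draws[subset].to_numpy(dtype=float)
    keep = x.std(axis=0) > 0
    if not keep.all():
        dropped = [s for s, k in zip(subset, keep) if not k]
        warnings.warn(f"dropping constant PSA columns {dropped}")
        x = x[:, keep]
    if x.shape[1] == 0:
        return 0.0
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    nb = sample.net_benefit(wtp)
    n = nb.shape[0]
    design = _design_matrix(x, n)
    fitted = np.empty_like(nb)
    for j in range(nb.shape[1]):
        model = LinearRegression().fit(design, nb[:, j])
        fitted[:, j] = model.predict(design)
    # the estimator can dip a hair below zero for uninformative subsets
    return max(0.0, float(fitted.max(axis=1).mean() - fitted.mean(axis=0).max()))


def voi_table(sample: PSASample, subsets: dict, wtp: float) -> VOIResult:
    """EVPI plus EVPPI for each named subset at one WTP."""
    result = VOIResult(wtp=wtp, evpi=evpi(sample, wtp))
    nb = sample.net_benefit(wtp)
    for label, names in subsets.items():
        result.evppi[label] = evppi(sample, names, wtp)
        x = sample.draws[list(names)].to_numpy(dtype=float)
        keep = x.std(axis=0) > 0
        result.basis_size[label] = int(
            _design_matrix((x[:, keep] - x[:, keep].mean(0)) / x[:, keep].std(0),
                           nb.shape[0]).shape[1]) if keep.any() else 0
        result.residual_var[label] = float(np.var(nb.max(axis=1)))
    return result
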