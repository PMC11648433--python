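"""Model-based reference-gene stability ranking (NormFinder).

The model treats log2 expression of candidate gene i in sample j of group g as

    y_igj = alpha_ig + beta_gj + eps_igj,    eps ~ N(0, sigma2_ig)

where ``beta_gj`` is a sample effect (amount of material) common to all genes
and ``alpha_ig`` a gene-and-group effect.  A good reference gene has both a
small intragroup variance sigma2_ig and a small intergroup bias (its alpha
differs little between groups).  The stability value combines the two on the
log2 scale: per group, the shrunken absolute intergroup bias plus the sampling
standard deviation of the gene effect, averaged over groups; lower is more
stable.

Estimation is method-of-moments on the two-way layout:

* sample effects are removed by subtracting each sample's mean over genes;
* the naive per-gene residual variance ``s2_ig`` is biased because the
  subtracted sample mean contains a share of every gene's noise; the unbiased
  intragroup variance is ``(k * s2_ig - sbar2_g) / (k - 2)`` with
  ``sbar2_g = sum_i s2_ig / (k - 1)`` (k = number of candidates, hence the
  k >= 3 requirement);
* the intergroup variance of the biases is estimated from the spread of the
  per-gene group effects after removing their sampling variance, floored at
  zero, and used to shrink each observed bias.

Absolute stability values are implementation-defined up to this model; the
ranking they induce is the contract.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["normfinder_stability"]


def normfinder_stability(
    data: pd.DataFrame,
    groups: Optional[pd.Series] = None,
    already_log: bool = False,
) -> pd.Series:
    """Stability value per candidate probe; lower = more stable.

    Parameters
    ----------
    data:
        Lanes x candidate-probes counts (linear scale unless ``already_log``).
        Needs >= 3 candidates and >= 2 lanes per group.
    groups:
        Per-lane group labels aligned with ``data.index``.  ``None`` or a
        single distinct label triggers the single-group variant (intragroup
        variance only), which is noted via a warning.
    """
    vals = pd.DataFrame(data).astype(float)
    if vals.shape[1] < 3:
        raise ValueError("NormFinder needs at least 3 candidate probes")
    if not already_log:
        if (vals <= 0).any().any():
            warnings.warn(
                "non-positive counts replaced by 0.5 before log2", stacklevel=2
            )
            vals = vals.where(vals > 0, 0.5)
        vals = np.log2(vals)

    if groups is None:
        labels = pd.Series(["__all__"] * len(vals), index=vals.index)
    else:
        labels = pd.Series(groups).loc[vals.index].astype(str)
    group_names = list(dict.fromkeys(labels))
    k = vals.shape[1]

    z = {}      # per-group gene effects (gene-major Series)
    sigma2 = {} # per-group unbiased intragroup variances
    c = {}      # sampling variance of the gene effects
    for g in group_names:
        sub = vals.loc[labels == g]
        n_g = len(sub)
        if n_g < 2:
            raise ValueError(f"group {g!r} has fewer than 2 lanes")
        d = sub.sub(sub.mean(axis=1), axis=0)  # remove per-sample amount
        z_g = d.mean(axis=0)
        s2 = d.var(axis=0, ddof=1)
        sbar2 = s2.sum() / (k - 1)
        sig2 = ((k * s2 - sbar2) / (k - 2)).clip(lower=0.0)
        z[g], sigma2[g], c[g] = z_g, sig2, sig2 / n_g

    if len(group_names) < 2:
        warnings.warn(
            "single group: NormFinder falls back to intragroup variance only",
            stacklevel=2,
        )
        rho = np.sqrt(sigma2[group_names[0]])
        rho.name = "stability"
        return rho

    G = len(group_names)
    zmat = pd.DataFrame(z)            # genes x groups
    cmat = pd.DataFrame(c)
    w = zmat.sub(zmat.mean(axis=1), axis=0)  # per-gene group effects
    # intergroup variance of the biases, sampling variance removed, floored
    gamma2 = max(
        0.0,
        float(
            (np.square(w).to_numpy().sum() - (G - 1) / G * cmat.to_numpy().sum())
            / (k * (G - 1))
        ),
    )
    shrink = gamma2 / (gamma2 + cmat)
    bias = (w * shrink).abs()
    # shrunken |bias| plus the sampling SD of the gene effect: intergroup and
    # intragroup variation enter on the same (log2) scale
    rho = (bias + np.sqrt(cmat)).mean(axis=1)
    rho.name = "stability"
    return rho
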