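"""Post-chain statistics: ACF, effective sample size, summary tables,
correlation matrices and credible bands for model predictions.

Summary tables follow the layout mean (s.d.), t-stat, p-value per
parameter, with moments computed on the physical scale after
back-transforming the draws.  The p-value is the empirical two-sided
tail fraction of the posterior relative to zero, with a
normal-approximation floor 2*Phi(-|t|) when no draw crosses zero.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sampler import Chain
from .likelihood import ForwardModel, ParameterTransform

__all__ = [
    "autocorrelation",
    "effective_sample_size",
    "summarize",
    "correlation_matrix",
    "credible_band",
    "physical_draws",
]


def autocorrelation(samples: np.ndarray, max_lag: int | None = None,
                    use_fft: bool = True) -> tuple[np.ndarray, float]:
    """Normalized autocorrelation of a scalar series.

    Uses the biased (divide by n) estimator; ACF(0) = 1 exactly.  Returns
    (acf, bound) where ``bound = 1.96/sqrt(n)`` is the 95% significance
    level for the zero-autocorrelation hypothesis.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("need a 1-D series of at least 10 samples")
    n = x.size
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    xc = x - x.mean()
    var = float(xc @ xc) / n
    if var == 0.0:
        raise ValueError("zero-variance series has no autocorrelation")
    if use_fft:
        m = 1 << (2 * n - 1).bit_length()
        f = np.fft.rfft(xc, m)
        ac = np.fft.irfft(f * np.conj(f), m)[: max_lag + 1].real / n
    else:
        ac = np.array([xc[: n - k] @ xc[k:] for k in range(max_lag + 1)]) / n
    return ac / var, 1.96 / np.sqrt(n)


def effective_sample_size(samples: np.ndarray) -> tuple[float, float]:
    """ESS via the ACF with Geyer initial-positive-sequence truncation.

    ESS = n / (1 + 2 sum rho_k) where the sum runs over the leading lags
    for which the pairwise sums Gamma_m = rho_{2m} + rho_{2m+1} stay
    positive.  Returns (ESS, ESS/n).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    rho, _ = autocorrelation(x)
    n = x.size
    # Geyer initial positive sequence on pair sums starting at lags (1, 2)
    tau = 1.0
    m = 1
    while m + 1 < rho.size:
        pair = rho[m] + rho[m + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        m += 2
    ess = min(float(n), n / tau)
    return ess, ess / n


def physical_draws(
    chain: Chain,
    transform: ParameterTransform | None = None,
    burn_in: int | None = None,
) -> np.ndarray:
    """Post-burn-in draws mapped back to the physical scale."""
    b = chain.burn_in_index if burn_in is None else burn_in
    draws = chain.draws[b:]
    if transform is not None:
        draws = transform.to_physical(draws)
    return draws


def summarize(
    chain: Chain | np.ndarray,
    burn_in: int | None = None,
    transform: ParameterTransform | None = None,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-parameter summary table: mean, s.d., t-stat, p-value.

    Moments are sample moments of the post-burn-in draws on the physical
    scale.  t = mean / s.d.; p is the empirical two-sided tail fraction
    relative to zero, floored by the normal approximation 2*Phi(-|t|)
    when no draw crosses zero.  A zero-s.d. (degenerate) parameter gets
    p = 0 and is flagged.
    """
    if isinstance(chain, Chain):
        draws = physical_draws(chain, transform, burn_in)
    else:
        draws = np.asarray(chain, dtype=float)
        if burn_in:
            draws = draws[burn_in:]
    n, N = draws.shape
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    rows = []
    for i in range(N):
        if sd[i] == 0.0:
            rows.append((mean[i], 0.0, np.inf, 0.0, True))
            continue
        t = mean[i] / sd[i]
        frac_le = np.mean(draws[:, i] <= 0.0)
        frac_ge = np.mean(draws[:, i] >= 0.0)
        p_emp = 2.0 * min(frac_le, frac_ge)
        p_norm = 2.0 * stats.norm.sf(abs(t))
        p = p_emp if p_emp > 0.0 else p_norm
        rows.append((mean[i], sd[i], t, min(p, 1.0), False))
    idx = list(names) if names is not None else [f"x{i}" for i in range(N)]
    return pd.DataFrame(rows, columns=["mean", "sd", "t_stat", "p_value",
                                       "degenerate"], index=idx)


def correlation_matrix(
    chain: Chain | np.ndarray,
    burn_in: int | None = None,
    transform: ParameterTransform | None = None,
    names: Sequence[str] | None = None,
    derived: Mapping[str, Callable[[np.ndarray], np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Pearson correlations of post-burn-in draws (physical scale).

    ``derived`` maps extra column names to callables evaluated on the
    (n, N) draw matrix, e.g. a total-thickness column ``d_ps + d_ptba``.
    """
    if isinstance(chain, Chain):
        draws = physical_draws(chain, transform, burn_in)
    else:
        draws = np.asarray(chain, dtype=float)
        if burn_in:
            draws = draws[burn_in:]
    if draws.shape[1] < 2 and not derived:
        raise ValueError("need at least two parameters")
    cols = list(names) if names is not None else [f"x{i}" for i in
                                                 range(draws.shape[1])]
    mat = draws
    if derived:
        extra = np.column_stack([np.asarray(fn(draws), float)
                                 for fn in derived.values()])
        mat = np.hstack([draws, extra])
        cols = cols + list(derived.keys())
    corr = np.corrcoef(mat, rowvar=False)
    return pd.DataFrame(corr, index=cols, columns=cols)


def credible_band(
    chain: Chain,
    model: ForwardModel,
    abscissa: np.ndarray,
    burn_in: int | None = None,
    transform: ParameterTransform | None = None,
    percentiles: Sequence[float] = (2.5, 50.0, 97.5),
    thin: int = 1,
) -> pd.DataFrame:
    """Pointwise posterior percentile envelope of the model prediction.

    Evaluates the forward model at every ``thin``-th post-burn-in draw
    (physical scale, residual-variance column dropped) and returns the
    2.5/50/97.5 percentile curves.
    """
    draws = physical_draws(chain, transform, burn_in)[::thin]
    theta = draws[:, :-1]  # drop sigma2
    preds = np.atleast_2d(model.predict(theta, np.asarray(abscissa, float)))
    bands = np.percentile(preds, percentiles, axis=0)
    out = {"abscissa": np.asarray(abscissa, float)}
    for p, row in zip(percentiles, bands):
        out[f"p{p:g}"] = row
    return pd.DataFrame(out)
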