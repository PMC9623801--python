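"""Chain-quality and model-comparison diagnostics.

Three diagnostics reported for the fitted model:

* effective sample size (ESS), the equivalent number of independent
  draws, ``N / (1 + 2 * sum_k rho_k)`` with the autocorrelation sum
  truncated by the initial-positive-sequence rule;
* the Raftery-Lewis run-length diagnostic, giving the iterations
  needed to estimate a stated quantile to stated accuracy with stated
  probability via the two-state Markov-chain method; and
* the deviance information criterion (DIC) with the conditional
  (given random effects) deviance focus, the convention of standard
  multilevel software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from calfgrowth.model import DesignMatrixBundle, PosteriorChain


# ---------------------------------------------------------------------------
# effective sample size
# ---------------------------------------------------------------------------


def _autocorrelations(x: np.ndarray) -> np.ndarray:
    """Sample autocorrelations at all lags via FFT."""
    n = x.size
    xd = x - x.mean()
    size = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xd, size)
    acov = np.fft.irfft(f * np.conjugate(f), size)[:n].real / n
    return acov / acov[0]


def effective_sample_size(series: np.ndarray) -> float:
    """ESS of one scalar chain, capped at the chain length.

    Uses the initial-positive-sequence truncation: autocorrelations are
    summed in lag pairs ``rho_{2m} + rho_{2m+1}`` for as long as the
    pair sums stay positive.  A constant series is degenerate and is
    reported as fully independent (ESS = N) with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series must have at least 10 draws")
    n = x.size
    if np.allclose(x, x[0]):
        warnings.warn(
            "constant series: ESS undefined, reporting N", stacklevel=2
        )
        return float(n)
    rho = _autocorrelations(x)
    # pair sums Gamma_m = rho_{2m} + rho_{2m+1}; Gamma_0 = 1 + rho_1
    tau = 0.0
    m = 0
    while 2 * m + 1 < n:
        gamma = rho[2 * m] + rho[2 * m + 1]
        if gamma <= 0.0:
            break
        tau += 2.0 * gamma
        m += 1
    tau -= 1.0  # correct for rho_0 counted twice
    tau = max(tau, 1e-12)
    return float(min(n / tau, n))


# ---------------------------------------------------------------------------
# Raftery-Lewis
# ---------------------------------------------------------------------------


@dataclass
class RafteryLewisResult:
    """Run-length requirements for one quantile of one chain."""

    n_min: int  # minimum iterations were the chain independent
    n_required: int  # burn-in plus post-burn-in iterations required
    burn_in_required: int
    thinning_k: int
    dependence_factor: float  # n_required / n_min


def _markov_order_bic(z: np.ndarray) -> float:
    """BIC comparing a second-order to a first-order binary Markov chain.

    Negative values favour the first-order model.  Computed from the
    G^2 likelihood-ratio statistic on transition triples with 2 degrees
    of freedom.
    """
    trip = z[:-2] * 4 + z[1:-1] * 2 + z[2:]
    counts = np.bincount(trip, minlength=8).astype(float).reshape(2, 2, 2)
    g2 = 0.0
    for j in range(2):
        pair_prev = counts[:, j, :].sum(axis=1)  # n_{i j .}
        pair_next = counts[:, j, :].sum(axis=0)  # n_{. j l}
        tot = counts[:, j, :].sum()
        if tot == 0:
            continue
        for i in range(2):
            for l in range(2):
                obs = counts[i, j, l]
                if obs == 0:
                    continue
                exp = pair_prev[i] * pair_next[l] / tot
                g2 += 2.0 * obs * math.log(obs / exp)
    return g2 - 2.0 * math.log(max(counts.sum(), 1.0))


def raftery_lewis(
    series: np.ndarray,
    q: float = 0.025,
    r: float = 0.005,
    s: float = 0.95,
    eps: float = 0.001,
) -> RafteryLewisResult:
    """Raftery-Lewis run-length diagnostic for the q-quantile.

    The series is binarised at its empirical ``q``-quantile; the
    smallest thinning ``k`` at which the binary chain is adequately
    first-order Markov is found by BIC; the fitted two-state transition
    probabilities then give the burn-in and run length needed to
    estimate the quantile to within ``r`` with probability ``s``.
    ``n_min = ceil(z^2 q (1-q) / r^2)`` depends only on ``(q, r, s)``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if not 0.0 < r < min(q, 1.0 - q):
        raise ValueError("r must be in (0, min(q, 1-q))")
    if not 0.0 < s < 1.0:
        raise ValueError("s must be in (0, 1)")
    x = np.asarray(series, dtype=float)
    z_crit = stats.norm.ppf((1.0 + s) / 2.0)
    n_min = int(math.ceil((z_crit / r) ** 2 * q * (1.0 - q)))
    if x.size < 100:
        raise ValueError(
            f"series of length {x.size} is too short for transition "
            "estimation; at least 100 draws are required"
        )

    cut = np.quantile(x, q)
    z = (x <= cut).astype(int)

    k = 1
    while True:
        zk = z[::k]
        if zk.size < 50:
            # fall back to the largest k with enough data
            k = max(k - 1, 1)
            zk = z[::k]
            break
        if _markov_order_bic(zk) < 0:
            break
        k += 1

    ones = zk[:-1] == 1
    zeros = ~ones
    trans = zk[1:]
    n0 = int(zeros.sum())
    n1 = int(ones.sum())
    alpha = float(trans[zeros].sum()) / n0 if n0 else 0.5  # P(0 -> 1)
    beta = float((1 - trans[ones]).sum()) / n1 if n1 else 0.5  # P(1 -> 0)
    alpha = min(max(alpha, 1e-8), 1 - 1e-8)
    beta = min(max(beta, 1e-8), 1 - 1e-8)

    lam = abs(1.0 - alpha - beta)
    absum = alpha + beta
    m_star = math.ceil(
        math.log(eps * absum / max(alpha, beta)) / math.log(lam)
    ) if lam > 0 else 1
    burn = max(int(m_star), 1) * k
    n_post = (
        math.ceil(
            alpha * beta * (2.0 - absum) / absum**3 * (z_crit / r) ** 2
        )
        * k
    )
    n_required = burn + int(n_post)
    return RafteryLewisResult(
        n_min=n_min,
        n_required=n_required,
        burn_in_required=burn,
        thinning_k=k,
        dependence_factor=n_required / n_min,
    )


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------


@dataclass
class DicResult:
    dic: float
    p_d: float
    mean_deviance: float


def dic(chain: PosteriorChain, design: DesignMatrixBundle) -> DicResult:
    """Deviance information criterion, conditional on random effects.

    ``mean_deviance`` averages the per-draw conditional deviances
    stored with the chain; the plug-in deviance is evaluated at the
    posterior means of the fixed effects, random effects and residual
    variance.  ``p_d = mean_deviance - plug_in``; ``dic = mean_deviance
    + p_d``.
    """
    if not np.all(np.isfinite(chain.deviance)):
        bad = int(np.flatnonzero(~np.isfinite(chain.deviance))[0])
        raise ValueError(f"non-finite deviance at stored draw {bad}")
    means = chain.posterior_means()
    beta = [means["alpha"]]
    if "beta_age" in means:
        beta.append(means["beta_age"])
    if "beta_age2" in means:
        beta.append(means["beta_age2"])
    fitted = design.X @ np.asarray(beta)
    if chain.posterior_mean_v is not None:
        fitted = fitted + chain.posterior_mean_v[design.rec_practice]
    if chain.posterior_mean_u is not None:
        fitted = (
            fitted
            + chain.posterior_mean_u[design.rec_farm, 0]
            + chain.posterior_mean_u[design.rec_farm, 1] * design.age
        )
    var_e = means["var_residual"]
    sse = float(np.sum((design.y - fitted) ** 2))
    d_hat = design.n_records * math.log(2.0 * math.pi * var_e) + sse / var_e
    d_bar = float(chain.deviance.mean())
    p_d = d_bar - d_hat
    return DicResult(dic=d_bar + p_d, p_d=p_d, mean_deviance=d_bar)
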