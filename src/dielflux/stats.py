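"""Daily proportional statistics and beta-regression ANOVA across sites.

Daily proportional migration *intensity* is a phase's mean traffic rate
divided by the sum of the phase mean rates of that diel day; proportional
migration *traffic* divides total traffic instead.  Both lie in [0, 1] and
sum to 1 over the phases of a day.

Site comparisons use "ANOVA with beta distributions": a beta regression with
a group (site) factor, mean/precision parametrization
(a = mu*phi, b = (1-mu)*phi), logit mean link, a common precision phi, and
maximum likelihood.  The omnibus test is the likelihood-ratio statistic
2(l_full - l_null) ~ chi2(g-1); post-hoc tests are two-group LRTs for every
unordered site pair, Holm-corrected within the family of C(g, 2) tests of
one diel phase.  Proportions are first pulled off the {0, 1} boundary with
the compression y' = (y (N-1) + 0.5) / N, N the number of days with values
for the phase.

The beta likelihood depends on the data only through the per-group
sufficient statistics (sum log y, sum log(1-y), n), so fits are solved by a
damped Newton iteration that is vectorized over many independent problems;
this is what makes the 1000-replicate calibration simulations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, polygamma, psi
from scipy.stats import chi2

from dielflux.solar import PHASES

__all__ = [
    "BetaGroupFit",
    "PairwiseTestResult",
    "daily_proportions",
    "compress_proportion",
    "fit_beta_groups",
    "omnibus_test",
    "pairwise_posthoc",
    "holm_adjust",
]

_PHI_MAX = 1e8
_MU_EPS = 1e-10
_LL_TOL = 1e-8


# ---------------------------------------------------------------------------
# daily proportions and compression


def daily_proportions(phase_aggregates: pd.DataFrame) -> pd.DataFrame:
    """Per-day phase shares of mean rate (intensity) and total traffic.

    A diel day is complete when none of its phase aggregates is missing (a
    no-night day legitimately has three phases).  Incomplete or all-zero days
    get NaN proportions and ``complete=False``; otherwise each measure's
    shares sum to 1.

    Raises ``ValueError`` on negative rates or totals.
    """
    df = phase_aggregates
    if (df["mean_rate"].dropna() < 0).any() or (df["total_traffic"].dropna() < 0).any():
        raise ValueError("negative phase aggregate")
    rows = []
    for (site, day), grp in df.groupby(["site_id", "anchor_date"], sort=True):
        rates = grp["mean_rate"].to_numpy(float)
        totals = grp["total_traffic"].to_numpy(float)
        complete = not (np.isnan(rates).any() or np.isnan(totals).any())
        rate_sum = rates.sum() if complete else np.nan
        tot_sum = totals.sum() if complete else np.nan
        ok = complete and rate_sum > 0 and tot_sum > 0
        for i, phase in enumerate(grp["phase"]):
            rows.append(
                {
                    "site_id": site,
                    "anchor_date": day,
                    "phase": phase,
                    "prop_intensity": rates[i] / rate_sum if ok else np.nan,
                    "prop_traffic": totals[i] / tot_sum if ok else np.nan,
                    "complete": bool(ok),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["site_id", "anchor_date", "phase", "prop_intensity", "prop_traffic", "complete"],
    )


def compress_proportion(y, N: int):
    """Shrink proportions off the {0, 1} boundary: y' = (y (N-1) + 0.5) / N.

    ``N`` is the sample size (days with values for the phase).  Maps [0, 1]
    into (0, 1), is strictly increasing, fixes y = 0.5, and tends to the
    identity pointwise on (0, 1) as N grows.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    y_arr = np.asarray(y, dtype=float)
    if np.any((y_arr < 0) | (y_arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = (y_arr * (N - 1) + 0.5) / N
    return float(out) if np.isscalar(y) else out


# ---------------------------------------------------------------------------
# beta likelihood on sufficient statistics


def _suff_stats(values: np.ndarray) -> tuple[float, float, int, float]:
    return (
        float(np.log(values).sum()),
        float(np.log1p(-values).sum()),
        int(values.size),
        float(values.mean()),
    )


def _loglik(mu, phi, T1, T2, n):
    """Beta log-likelihood from sufficient statistics; sums over last axis."""
    a = mu * phi[..., None]
    b = (1.0 - mu) * phi[..., None]
    ll = (a - 1.0) * T1 + (b - 1.0) * T2 - n * (gammaln(a) + gammaln(b) - gammaln(phi[..., None]))
    return ll.sum(axis=-1)


def _newton_common_phi(T1, T2, n, mu0, phi0, max_iter: int = 200):
    """Damped Newton MLE of (mu_1..mu_g, phi), batched over axis 0.

    The Hessian is arrow-shaped (group means are conditionally independent
    given phi), so each step costs O(g) per problem.
    Returns (mu, phi, loglik, converged).
    """
    B, g = T1.shape
    mu = np.clip(np.array(mu0, dtype=float), 1e-4, 1.0 - 1e-4)
    phi = np.full(B, float(phi0)) if np.isscalar(phi0) else np.array(phi0, dtype=float)
    ll = _loglik(mu, phi, T1, T2, n)
    converged = np.zeros(B, dtype=bool)

    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        a = mu * phi[:, None]
        b = (1.0 - mu) * phi[:, None]
        A = T1 - n * psi(a)
        Bb = T2 - n * psi(b)
        pa = n * polygamma(1, a)
        pb = n * polygamma(1, b)

        g_mu = phi[:, None] * (A - Bb)
        g_phi = (mu * A + (1.0 - mu) * Bb + n * psi(phi[:, None])).sum(axis=1)

        d_mu = -(phi[:, None] ** 2) * (pa + pb)  # d2l/dmu2 (diagonal)
        c = (A - Bb) + phi[:, None] * (-pa * mu + pb * (1.0 - mu))  # d2l/dmu dphi
        d_phi = (-(mu**2) * pa - ((1.0 - mu) ** 2) * pb + n * polygamma(1, phi[:, None])).sum(axis=1)

        # arrow solve of H step = -grad (H negative definite near optimum)
        d_mu_safe = np.where(np.abs(d_mu) > 1e-300, d_mu, -1e-300)
        inv_d = 1.0 / d_mu_safe
        schur = d_phi - (c * c * inv_d).sum(axis=1)
        schur = np.where(np.abs(schur) > 1e-300, schur, -1e-300)
        step_phi = -(g_phi - (c * inv_d * g_mu).sum(axis=1)) / schur
        step_mu = -(g_mu + c * step_phi[:, None]) * inv_d

        # fall back to gradient ascent when the Newton direction is not ascent
        ascent = (step_mu * g_mu).sum(axis=1) + step_phi * g_phi
        bad = ascent <= 0
        if bad.any():
            scale = 1.0 / (1.0 + np.abs(g_phi[bad]))
            step_mu[bad] = g_mu[bad] * scale[:, None]
            step_phi[bad] = g_phi[bad] * scale

        # damped line search in the constrained domain
        lam = np.ones(B)
        new_mu = mu.copy()
        new_phi = phi.copy()
        new_ll = ll.copy()
        todo = active.copy()
        for _bt in range(40):
            if not todo.any():
                break
            trial_mu = np.clip(mu[todo] + lam[todo, None] * step_mu[todo], _MU_EPS, 1 - _MU_EPS)
            trial_phi = np.clip(phi[todo] + lam[todo] * step_phi[todo], 1e-6, _PHI_MAX)
            trial_ll = _loglik(trial_mu, trial_phi, T1[todo], T2[todo], n[todo])
            better = trial_ll >= ll[todo] - 1e-12
            idx = np.flatnonzero(todo)
            ok_idx = idx[better]
            new_mu[ok_idx] = trial_mu[better]
            new_phi[ok_idx] = trial_phi[better]
            new_ll[ok_idx] = trial_ll[better]
            todo[ok_idx] = False
            lam[todo] *= 0.5

        improved = new_ll - ll
        converged |= active & (np.abs(improved) < _LL_TOL) & ~todo
        converged |= active & todo  # line search stalled: accept current point
        mu, phi, ll = new_mu, new_phi, new_ll
    return mu, phi, ll, converged


def _fit_batch(T1, T2, n, mean0, phi_starts=(1.0, 10.0, 100.0)):
    """Multi-start common-phi beta MLE, batched over axis 0 of (B, g) stats."""
    best = None
    for phi0 in phi_starts:
        mu, phi, ll, conv = _newton_common_phi(T1, T2, n, mean0, phi0)
        if best is None:
            best = [mu, phi, ll, conv]
        else:
            upd = ll > best[2] + 1e-12
            for k, arr in enumerate((mu, phi, ll, conv)):
                best[k] = np.where(upd[:, None] if arr.ndim == 2 else upd, arr, best[k])
    return tuple(best)


# ---------------------------------------------------------------------------
# public fitting / testing API


@dataclass(frozen=True)
class BetaGroupFit:
    """Common-precision beta MLE for grouped proportions."""

    groups: tuple[str, ...]
    mu: np.ndarray  # fitted group means, in `groups` order
    phi: float
    loglik: float
    n_per_group: np.ndarray
    converged: bool

    def mean_of(self, group: str) -> float:
        return float(self.mu[self.groups.index(group)])


@dataclass(frozen=True)
class PairwiseTestResult:
    """Post-hoc two-group beta LRT for one site pair within one phase family."""

    phase: str
    site_a: str
    site_b: str
    effect_size: float  # signed mu_a - mu_b; magnitude in effect_size_abs
    p_raw: float
    p_holm: float
    significant: bool

    @property
    def effect_size_abs(self) -> float:
        return abs(self.effect_size)


def _check_values(values: np.ndarray) -> None:
    if np.any((values <= 0.0) | (values >= 1.0)):
        raise ValueError(
            "values must lie strictly in (0, 1); apply compress_proportion first"
        )


def _grouped_stats(values, group_labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    _check_values(values)
    groups = tuple(dict.fromkeys(labels.tolist()))  # first-appearance order
    stats = [_suff_stats(values[labels == grp]) for grp in groups]
    T1, T2, n, mean = (np.array(x, dtype=float) for x in zip(*stats))
    return groups, T1, T2, n, mean


def fit_beta_groups(values, group_labels) -> BetaGroupFit:
    """Maximum-likelihood beta fit with one mean per group and a common phi.

    Values must lie strictly in (0, 1) (compressed proportions) with at least
    two observations per group.  Multi-start on phi (1, 10, 100) with the
    group arithmetic means as initial mu.
    """
    groups, T1, T2, n, mean = _grouped_stats(values, group_labels)
    if (n < 2).any():
        raise ValueError("each group needs at least 2 values")
    mu, phi, ll, conv = _fit_batch(T1[None], T2[None], n[None], mean[None])
    return BetaGroupFit(
        groups=tuple(str(grp) for grp in groups),
        mu=mu[0],
        phi=float(phi[0]),
        loglik=float(ll[0]),
        n_per_group=n.astype(int),
        converged=bool(conv[0]),
    )


def omnibus_test(values, group_labels) -> dict:
    """Likelihood-ratio ANOVA across all groups.

    statistic = 2 (l_full - l_null) with the null collapsing all groups to a
    single mean; df = g - 1; p from the chi-square upper tail.
    """
    groups, T1, T2, n, mean = _grouped_stats(values, group_labels)
    if (n < 2).any():
        raise ValueError("each group needs at least 2 values")
    _, _, ll_full, conv_f = _fit_batch(T1[None], T2[None], n[None], mean[None])
    pooled_mean = float((mean * n).sum() / n.sum())
    _, _, ll_null, conv_n = _fit_batch(
        np.array([[T1.sum()]]), np.array([[T2.sum()]]), np.array([[n.sum()]]),
        np.array([[pooled_mean]]),
    )
    stat = max(0.0, 2.0 * float(ll_full[0] - ll_null[0]))
    df = len(groups) - 1
    return {
        "statistic": stat,
        "df": df,
        "p": float(chi2.sf(stat, df)),
        "converged": bool(conv_f[0] and conv_n[0]),
    }


def pairwise_posthoc(
    values, group_labels, alpha: float = 0.05, phase: str = ""
) -> list[PairwiseTestResult]:
    """Two-group beta LRT for every unordered group pair, Holm-corrected.

    The Holm family is the C(g, 2) tests passed in one call (one diel phase).
    Effect size is the signed difference of the fitted pair means
    (mu_a - mu_b); report its magnitude when direction is irrelevant.
    All pairs are fitted in one vectorized Newton batch.
    """
    groups, T1, T2, n, mean = _grouped_stats(values, group_labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (n < 2).any():
        raise ValueError("each group needs at least 2 values")
    pairs = list(combinations(range(len(groups)), 2))
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])

    T1f = np.column_stack([T1[ia], T1[ib]])
    T2f = np.column_stack([T2[ia], T2[ib]])
    nf = np.column_stack([n[ia], n[ib]])
    m0f = np.column_stack([mean[ia], mean[ib]])
    mu_f, _, ll_full, _ = _fit_batch(T1f, T2f, nf, m0f)

    T1n = (T1[ia] + T1[ib])[:, None]
    T2n = (T2[ia] + T2[ib])[:, None]
    nn = (n[ia] + n[ib])[:, None]
    m0n = ((mean[ia] * n[ia] + mean[ib] * n[ib]) / (n[ia] + n[ib]))[:, None]
    _, _, ll_null, _ = _fit_batch(T1n, T2n, nn, m0n)

    stat = np.maximum(0.0, 2.0 * (ll_full - ll_null))
    p_raw = chi2.sf(stat, 1)
    p_adj = holm_adjust(p_raw)

    return [
        PairwiseTestResult(
            phase=phase,
            site_a=str(groups[a]),
            site_b=str(groups[b]),
            effect_size=float(mu_f[k, 0] - mu_f[k, 1]),
            p_raw=float(p_raw[k]),
            p_holm=float(p_adj[k]),
            significant=bool(p_adj[k] < alpha),
        )
        for k, (a, b) in enumerate(pairs)
    ]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original input order.

    Sort ascending; adj_(i) = min(1, max_{j<=i} (m-j+1) p_(j)).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj = np.minimum(1.0, np.maximum.accumulate(scaled))
    out = np.empty(m)
    out[order] = adj
    return out


def posthoc_table(results: Sequence[PairwiseTestResult], measure: str) -> pd.DataFrame:
    """Pairwise results as a frame with the posthoc.csv schema."""
    return pd.DataFrame(
        [
            {
                "measure": measure,
                "phase": r.phase,
                "site_a": r.site_a,
                "site_b": r.site_b,
                "effect_size": r.effect_size,
                "p_raw": r.p_raw,
                "p_holm": r.p_holm,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "measure",
            "phase",
            "site_a",
            "site_b",
            "effect_size",
            "p_raw",
            "p_holm",
            "significant",
        ],
    )
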