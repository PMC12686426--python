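"""Zero-inflated beta-binomial background model and coverage-aware FDR.

Somatic mitochondrial variants are confirmed per cell by testing each cell's
alt-read count against background noise learned from reference
(non-epithelial) cells. The background at a variant is modeled as a mixture

    P(X = x | n) = pi * 1{x = 0} + (1 - pi) * BetaBin(x; n, mu, rho)

with zero-inflation weight ``pi``, beta-binomial mean ``mu`` and
overdispersion ``rho`` (``alpha = mu (1-rho)/rho``, ``beta = (1-mu)(1-rho)/rho``).
The per-cell p-value is the upper-tail probability P(X >= x) under the fitted
mixture, so a cell with no alt reads always has p = 1.

False discoveries are controlled with an empirical null: reference-cell
p-values provide the null distribution, cells are stratified into coverage
quantile bins (deep and shallow cells have very different attainable
p-values), and within each bin a plug-in FDR estimate is converted to
per-cell q-values by a step-up rule. A variant is reported when its number of
significant cells, after subtracting the expected false positives at the FDR
level, still reaches the minimum (default three).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import betabinom, binom

from .io_formats import AlleleCountMatrix, CellAnnotation

__all__ = [
    "ZIBBParams",
    "zibb_loglik",
    "fit_zibb_background",
    "zibb_tail_p",
    "empirical_fdr",
    "call_cells",
]

_EPS = 1e-6


@dataclass
class ZIBBParams:
    """Fitted background-noise parameters for one variant."""

    variant_id: str
    pi: float
    mu: float
    rho: float
    n_ref_cells: int
    loglik: float
    converged: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi outside [0, 1]")
        if not 0.0 < self.mu < 1.0:
            raise ValueError("mu outside (0, 1)")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho outside (0, 1)")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood not finite")

    def beta_params(self) -> tuple[float, float]:
        t = (1.0 - self.rho) / self.rho
        return self.mu * t, (1.0 - self.mu) * t


def zibb_loglik(x: np.ndarray, n: np.ndarray, pi: float, mu: float, rho: float) -> float:
    """Log-likelihood of the zero-inflated beta-binomial mixture."""
    x = np.asarray(x, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    t = (1.0 - rho) / rho
    a, b = mu * t, (1.0 - mu) * t
    logbb = betabinom.logpmf(x, n, a, b)
    zero = x == 0
    with np.errstate(divide="ignore"):
        log_pi = math.log(pi) if pi > 0 else -np.inf
        log_1mpi = math.log1p(-pi) if pi < 1 else -np.inf
    ll = np.where(
        zero,
        np.logaddexp(log_pi, log_1mpi + logbb),
        log_1mpi + logbb,
    )
    return float(ll.sum())


_MULTISTARTS = ((0.3, 0.05), (0.5, 0.05), (0.7, 0.1), (0.9, 0.05), (0.99, 0.2))


def fit_zibb_background(
    m: AlleleCountMatrix,
    ann: CellAnnotation,
    variant_id: str,
    min_ref_cells: int = 50,
) -> ZIBBParams:
    """Maximum-likelihood (pi, mu, rho) over reference cells at one variant.

    Only reference cells with coverage > 0 inform the fit (a cell without
    coverage contributes nothing). Optimization is bounded L-BFGS-B from five
    deterministic starting points; ties are broken by best log-likelihood and
    then by the lowest zero-inflation weight. An all-zero variant is flagged
    degenerate with ``pi`` at its upper bound.
    """
    j = m.variant_index(variant_id)
    idx = ann.indexed()
    ref = [c for c in m.cell_ids if c in idx.index and idx.loc[c, "is_reference"]]
    rows = [m.cell_ids.index(c) for c in ref]
    x = m.alt_counts[rows, j]
    n = m.coverage[rows, j]
    keep = n > 0
    x, n = x[keep], n[keep]
    if len(x) < min_ref_cells:
        raise ValueError(
            f"only {len(x)} reference cells with coverage at {variant_id!r}; "
            f"need at least {min_ref_cells}"
        )

    if (x == 0).all():
        pi_hat = 1.0 - _EPS
        mu_hat, rho_hat = 1e-4, 0.05
        ll = zibb_loglik(x, n, pi_hat, mu_hat, rho_hat)
        return ZIBBParams(variant_id, pi_hat, mu_hat, rho_hat, len(x), ll,
                          converged=True, degenerate=True)

    nonzero_af = x[x > 0] / n[x > 0]
    mu_start = float(np.clip(np.mean(nonzero_af) * (x > 0).mean(), 1e-4, 0.4))

    bounds = [(_EPS, 1.0 - _EPS)] * 3

    def nll(theta):
        pi, mu, rho = theta
        return -zibb_loglik(x, n, pi, mu, rho)

    best = None
    for pi0, rho0 in _MULTISTARTS:
        res = minimize(nll, x0=(pi0, mu_start, rho0), method="L-BFGS-B", bounds=bounds)
        key = (round(float(res.fun), 9), float(res.x[0]))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    pi_hat, mu_hat, rho_hat = (float(v) for v in res.x)
    return ZIBBParams(
        variant_id,
        pi_hat,
        mu_hat,
        rho_hat,
        int(len(x)),
        float(-res.fun),
        converged=bool(res.success),
    )


def zibb_tail_p(x, n, params: ZIBBParams, tail_model: str = "zibb"):
    """Upper-tail P(X >= x) under the fitted background mixture.

    ``tail_model='zibb'`` uses the beta-binomial component; ``'zib'`` uses a
    plain binomial with success probability ``mu`` (a simpler tail for the
    same fitted zero/non-zero split). Accepts scalars or arrays; P(X >= 0)
    is always 1.
    """
    x = np.asarray(x, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if (x < 0).any():
        raise ValueError("negative alt count")
    if (x > n).any():
        raise ValueError("alt count exceeds coverage")
    if tail_model == "zibb":
        a, b = params.beta_params()
        with np.errstate(invalid="ignore"):
            tail = betabinom.sf(x - 1, n, a, b)
    elif tail_model == "zib":
        tail = binom.sf(x - 1, n, params.mu)
    else:
        raise ValueError(f"unknown tail model {tail_model!r}")
    p = np.where(x == 0, 1.0, (1.0 - params.pi) * tail)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def _merge_deficient_bins(
    test_bin: np.ndarray, null_bin: np.ndarray, n_bins: int, min_null: int
) -> tuple[np.ndarray, np.ndarray]:
    """Merge coverage bins holding fewer than ``min_null`` null cells into a
    neighbor (rightward, leftward for the last bin) until all bins qualify."""
    test_bin, null_bin = test_bin.copy(), null_bin.copy()
    while True:
        bins = sorted(set(test_bin) | set(null_bin))
        if len(bins) <= 1:
            break
        counts = {b: int((null_bin == b).sum()) for b in bins}
        deficient = [b for b in bins if counts[b] < min_null]
        if not deficient:
            break
        b = deficient[0]
        pos = bins.index(b)
        target = bins[pos + 1] if pos + 1 < len(bins) else bins[pos - 1]
        test_bin[test_bin == b] = target
        null_bin[null_bin == b] = target
    return test_bin, null_bin


def empirical_fdr(
    test_p: np.ndarray,
    test_cov: np.ndarray,
    null_p: np.ndarray,
    null_cov: np.ndarray,
    n_bins: int = 4,
    min_null_per_bin: int = 20,
) -> np.ndarray:
    """Per-cell q-values from an empirical null, stratified by coverage.

    Cells are binned by quantiles of the test-cell coverage; within each bin,
    for every observed test p-value t,

        FDR(t) = [ (#null p <= t) / N_null * N_test ] / max(1, #test p <= t)

    and the q-value of a cell is the minimum FDR over thresholds at or above
    its own p-value (step-up), clipped to [0, 1].
    """
    test_p = np.asarray(test_p, dtype=float)
    null_p = np.asarray(null_p, dtype=float)
    test_cov = np.asarray(test_cov, dtype=float)
    null_cov = np.asarray(null_cov, dtype=float)
    if null_p.size == 0:
        raise ValueError("empty null p-value set")
    if test_p.size == 0:
        return np.empty(0)

    edges = np.quantile(test_cov, np.linspace(0, 1, n_bins + 1))
    inner = edges[1:-1]
    test_bin = np.searchsorted(inner, test_cov, side="right")
    null_bin = np.searchsorted(inner, null_cov, side="right")
    test_bin, null_bin = _merge_deficient_bins(test_bin, null_bin, n_bins, min_null_per_bin)

    q = np.empty_like(test_p)
    for b in np.unique(test_bin):
        tmask = test_bin == b
        nmask = null_bin == b
        tp = test_p[tmask]
        np_ = np.sort(null_p[nmask]) if nmask.any() else np.sort(null_p)
        n_test, n_null = len(tp), len(np_)
        order = np.argsort(tp, kind="stable")
        tp_sorted = tp[order]
        n_null_le = np.searchsorted(np_, tp_sorted, side="right")
        n_test_le = np.arange(1, n_test + 1)
        # resolve ties: every tied p shares the largest #test <= t
        n_test_le = (
            pd.Series(n_test_le).groupby(tp_sorted).transform("max").to_numpy()
        )
        fdr = (n_null_le / n_null * n_test) / np.maximum(1, n_test_le)
        qs = np.minimum.accumulate(fdr[::-1])[::-1]
        out = np.empty(n_test)
        out[order] = np.clip(qs, 0.0, 1.0)
        q[tmask] = out
    return q


def call_cells(
    m: AlleleCountMatrix,
    ann: CellAnnotation,
    params_by_variant: dict[str, ZIBBParams],
    fdr_level: float = 0.05,
    min_sig_cells: int = 3,
    tail_model: str = "zibb",
    n_bins: int = 4,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cell variant calls and the list of reportable variants.

    Epithelial cells are the tested population; reference cells provide the
    empirical null. A cell is significant when its coverage-stratified
    q-value is at or below ``fdr_level``. A variant is reported when
    ``#significant - ceil(fdr_level * #significant) >= min_sig_cells`` — the
    expected false positives at the FDR level are deducted before the
    minimum-cell rule is applied.
    """
    idx = ann.indexed()
    missing = [c for c in m.cell_ids if c not in idx.index]
    if missing:
        raise KeyError(f"cells in matrix absent from annotation: {missing[:5]}")
    flags = idx.loc[m.cell_ids]
    epi_rows = np.flatnonzero(flags["is_epithelial"].to_numpy())
    ref_rows = np.flatnonzero(flags["is_reference"].to_numpy())
    cells = np.asarray(m.cell_ids, dtype=object)

    tables = []
    significant_variants: list[str] = []
    for vid in m.variant_ids:
        if vid not in params_by_variant:
            raise KeyError(f"no fitted background parameters for variant {vid!r}")
        params = params_by_variant[vid]
        j = m.variant_index(vid)
        x_t, n_t = m.alt_counts[epi_rows, j], m.coverage[epi_rows, j]
        x_n, n_n = m.alt_counts[ref_rows, j], m.coverage[ref_rows, j]
        p_t = np.atleast_1d(zibb_tail_p(x_t, n_t, params, tail_model))
        p_n = np.atleast_1d(zibb_tail_p(x_n, n_n, params, tail_model))
        q_t = empirical_fdr(p_t, n_t.astype(float), p_n, n_n.astype(float), n_bins=n_bins)
        sig = q_t <= fdr_level
        s = int(sig.sum())
        if s - math.ceil(fdr_level * s) >= min_sig_cells:
            significant_variants.append(vid)
        tables.append(
            pd.DataFrame(
                {
                    "variant_id": vid,
                    "cell_id": cells[epi_rows],
                    "alt": x_t,
                    "coverage": n_t,
                    "p_value": p_t,
                    "q_value": q_t,
                    "significant": sig,
                }
            )
        )
    calls = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=["variant_id", "cell_id", "alt", "coverage", "p_value", "q_value", "significant"]
        )
    )
    return calls, significant_variants
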