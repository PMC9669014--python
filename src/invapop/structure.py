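"""Ordination and admixture-style clustering of SNP genotypes.

PCA on the mean-imputed, column-centred genotype matrix, and a
simplified sNMF-class admixture estimator: the one-hot genotype
encoding is factorised into individual ancestry coefficients Q (rows on
the probability simplex) and ancestral genotype-class frequencies G by
alternating non-negative least squares. K is chosen by the
cross-entropy criterion — mean negative log predicted probability of
held-out masked genotypes.

This is a documented re-implementation of the algorithm *class*, not of
the published sNMF software: no sparsity prior by default, missing
entries excluded from the fit loss (not imputed), and a capped
alternating loop with a tolerance-based stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .io_filters import MISSING, GenotypeMatrix

__all__ = ["PcaResult", "AdmixtureResult", "pca", "admixture", "select_k"]

_PROB_CLIP = (1e-6, 1.0)


@dataclass
class PcaResult:
    coords: np.ndarray  # (n_individuals, n_components) scores
    var_explained: np.ndarray  # fraction of total variance per component


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray  # (n_individuals, K), rows on the simplex
    G: np.ndarray  # (K, n_sites, 3) ancestral genotype-class frequencies
    cross_entropy: float | None = None
    loss: float = np.nan
    run_losses: list = field(default_factory=list)
    best_run: int = 0
    converged: bool = True


def pca(gm: GenotypeMatrix, n_components: int | None = None, scale: bool = False) -> PcaResult:
    """PCA of the genotype matrix (individuals as observations).

    Missing genotypes are imputed with the per-site mean, columns are
    centred (and optionally scaled to unit variance), and scores come
    from the SVD of the imputed matrix. Deterministic up to the sign of
    each axis.
    """
    if gm.n_individuals < 2 or gm.n_sites < 2:
        raise ValueError("PCA requires >= 2 individuals and >= 2 sites")
    x = gm.genotypes.astype(float)
    miss = gm.genotypes == MISSING
    x[miss] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    inds = np.where(miss)
    x[inds] = col_mean[inds[1]]
    x -= col_mean
    if scale:
        sd = x.std(axis=0)
        x /= np.where(sd > 0, sd, 1.0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    k = n_components or min(gm.n_individuals, gm.n_sites)
    return PcaResult(coords=u[:, :k] * s[:k], var_explained=frac[:k])


# ----------------------------------------------------------------------
# admixture
# ----------------------------------------------------------------------


def _one_hot(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encode genotypes; returns (X (n, L, 3), observed mask (n, L))."""
    n, L = genotypes.shape
    obs = genotypes != MISSING
    x = np.zeros((n, L, 3))
    for g in (0, 1, 2):
        x[..., g] = (genotypes == g) & obs
    return x, obs


def _fit_once(
    x: np.ndarray,
    obs: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    ridge: float,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    n, L, _ = x.shape
    q = rng.dirichlet(np.ones(K), size=n)
    g = np.full((K, L, 3), 1.0 / 3.0)
    prev = np.inf
    converged = False
    eye = ridge * np.eye(K)
    for _ in range(max_iter):
        # G step: per-site least squares on rows observed at that site
        for site in range(L):
            rows = obs[:, site]
            if not rows.any():
                continue
            qs = q[rows]
            a = qs.T @ qs + eye
            b = qs.T @ x[rows, site, :]
            try:
                sol = np.linalg.solve(a, b)
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(a, b, rcond=None)[0]
            sol = np.clip(sol, 0.0, None)
            norm = sol.sum(axis=1, keepdims=True)
            g[:, site, :] = np.where(norm > 0, sol / np.maximum(norm, 1e-12), 1.0 / 3.0)
        # Q step: NNLS per individual over its observed sites, then simplex
        for i in range(n):
            cols = obs[i]
            if not cols.any():
                q[i] = 1.0 / K
                continue
            a = g[:, cols, :].reshape(K, -1).T  # (3*L_obs, K)
            b = x[i, cols, :].ravel()
            sol, _ = nnls(a, b)
            total = sol.sum()
            q[i] = sol / total if total > 0 else 1.0 / K
        # masked-entry loss
        pred = np.einsum("ik,klg->ilg", q, g)
        loss = float(np.sum(obs[..., None] * (x - pred) ** 2))
        if prev - loss < tol * max(1.0, abs(prev)) and np.isfinite(prev):
            converged = True
            break
        prev = loss
    return q, g, loss, converged


def admixture(
    gm: GenotypeMatrix,
    K: int,
    n_runs: int = 100,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-5,
    ridge: float = 0.0,
) -> AdmixtureResult:
    """Estimate ancestry coefficients for ``K`` clusters.

    Runs ``n_runs`` random restarts of the alternating NNLS factorisation
    and keeps the run with the lowest in-sample loss. Rows of Q sum to 1;
    missing genotypes do not contribute to the loss.
    """
    if not 1 <= K <= gm.n_individuals:
        raise ValueError("K must be in [1, n_individuals]")
    x, obs = _one_hot(gm.genotypes)
    best = None
    losses = []
    for run in range(n_runs):
        rng = np.random.default_rng([int(seed), int(K), run])
        q, g, loss, conv = _fit_once(x, obs, K, rng, max_iter, tol, ridge)
        losses.append(loss)
        if best is None or loss < best[2]:
            best = (q, g, loss, conv, run)
    q, g, loss, conv, run = best
    return AdmixtureResult(
        K=K, Q=q, G=g, loss=loss, run_losses=losses, best_run=run, converged=conv
    )


def _predict_proba(q_row: np.ndarray, g_site: np.ndarray) -> np.ndarray:
    """Predicted genotype-class probabilities for one (indiv, site) cell."""
    p = q_row @ g_site  # (3,)
    p = np.clip(p, *_PROB_CLIP)
    return p / p.sum()


def cross_entropy(
    gm: GenotypeMatrix,
    result: AdmixtureResult,
    mask: np.ndarray,
) -> float:
    """Mean negative log predicted probability of the masked genotypes."""
    rows, cols = np.where(mask)
    vals = []
    for i, l in zip(rows, cols):
        g_true = gm.genotypes[i, l]
        if g_true == MISSING:
            continue
        p = _predict_proba(result.Q[i], result.G[:, l, :])
        vals.append(-np.log(p[g_true]))
    if not vals:
        raise ValueError("mask contains no called genotypes")
    return float(np.mean(vals))


def select_k(
    gm: GenotypeMatrix,
    k_range=range(1, 11),
    masked_fraction: float = 0.05,
    n_reps: int = 5,
    n_runs: int = 3,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[dict, int]:
    """Choose K by held-out masked-genotype cross-entropy.

    For each replicate a random ``masked_fraction`` of called genotype
    entries is hidden, the factorisation is fitted on the rest for every
    K in ``k_range``, and the held-out entries are scored. Returns the
    per-K mean cross-entropy and the minimising K (used only to find the
    K with best predictive accuracy, not an absolute truth).
    """
    if not 0.0 < masked_fraction < 1.0:
        raise ValueError("masked_fraction must be in (0, 1)")
    scores: dict = {int(k): [] for k in k_range}
    for rep in range(n_reps):
        rng = np.random.default_rng([int(seed), rep])
        called = gm.genotypes != MISSING
        mask = (rng.random(gm.genotypes.shape) < masked_fraction) & called
        if not mask.any():
            continue
        hidden = gm.genotypes.copy()
        hidden[mask] = MISSING
        gm_train = GenotypeMatrix(
            genotypes=hidden,
            site_chrom=gm.site_chrom,
            site_pos=gm.site_pos,
            individual_ids=gm.individual_ids,
            pop_labels=gm.pop_labels,
        )
        for k in scores:
            res = admixture(
                gm_train, k, n_runs=n_runs, seed=_mix(seed, rep, k), **fit_kwargs
            )
            scores[k].append(cross_entropy(gm, res, mask))
    means = {k: float(np.mean(v)) for k, v in scores.items() if v}
    best = min(means, key=means.get)
    return means, best


def _mix(seed: int, rep: int, k: int) -> int:
    return int(np.random.default_rng([int(seed), rep, k]).integers(0, 2**31 - 1))
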