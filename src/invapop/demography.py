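"""Single-population demographic inference from the folded SFS.

Four piecewise population-size histories (backwards in time from the
present) are compared:

* ``A`` — constant size ``N_CUR`` (null model, no free parameters);
* ``B`` — ``N_CUR`` until ``T_BOT`` generations ago, ancestral size
  ``N_ANC`` before that (instantaneous size reduction at invasion);
* ``C`` — as B, but the recent epoch changes exponentially,
  ``N(t) = N_CUR * exp(G_R * t)``; with the backwards-time sign
  convention a *negative* ``G_R`` shrinks the size going into the past,
  i.e. a forward-in-time expansion after the bottleneck;
* ``D`` — full bottleneck: ``N_CUR`` until ``T_ENDBOT``, bottleneck size
  ``N_BOT`` on ``[T_ENDBOT, T_BOT)``, ``N_ANC`` before ``T_BOT``.

``N_CUR`` is fixed (supplied by the user, typically from pi/(4 mu));
the free parameters are searched within bounds by cyclic bounded
one-dimensional (Brent-style) line search maximising a multinomial
composite log-likelihood over folded-SFS classes. The expected SFS is
Monte-Carlo over coalescent *times* only: genealogy times are simulated
by time-rescaling the Kingman death chain through the piecewise size
function, while the branch-size distribution (the probability that a
branch present while k lineages remain subtends i of the 2n sampled
copies, C(2n-i-1, k-2)/C(2n-1, k-1)) is applied analytically. A fixed
matrix of standard exponentials per optimisation replicate (common
random numbers) makes the likelihood surface deterministic, so line
search is well behaved.

Model comparison uses AIC = 2k - 2 lnL, AIC differences, Akaike
weights, and the fraction of optimisation replicates in which each
model attains the lowest AIC; parameter uncertainty comes from a
parametric bootstrap re-fit started at the point estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

__all__ = [
    "DemographicModel",
    "FoldedSFS",
    "ModelFitResult",
    "BootstrapCI",
    "MODEL_FREE_PARAMS",
    "size_trajectory",
    "build_epochs",
    "simulate_sfs",
    "expected_folded_sfs",
    "neutral_folded_proportions",
    "composite_lnl",
    "fit_model",
    "model_selection",
    "parametric_bootstrap",
    "generations_to_years",
    "reduction_fraction",
    "read_sfs",
    "write_sfs",
]

MODEL_FREE_PARAMS: dict = {
    "A": (),
    "B": ("N_ANC", "T_BOT"),
    "C": ("N_ANC", "T_BOT", "G_R"),
    "D": ("N_ANC", "N_BOT", "T_BOT", "T_ENDBOT"),
}

_DEFAULT_BOUNDS: dict = {
    "N_ANC": (1e3, 1e7),
    "N_BOT": (1e1, 1e6),
    "T_BOT": (50.0, 1000.0),
    "T_ENDBOT": (1.0, 999.0),
    "G_R": (-1e-3, 1e-3),
}

#: floor applied to expected class probabilities before the log
PROB_FLOOR = 1e-8


@dataclass
class DemographicModel:
    """One of the four piecewise size histories with search bounds."""

    model_id: str
    n_cur: float
    bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_FREE_PARAMS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.n_cur <= 0:
            raise ValueError("n_cur must be positive")
        merged = {
            k: tuple(self.bounds.get(k, _DEFAULT_BOUNDS[k]))
            for k in MODEL_FREE_PARAMS[self.model_id]
        }
        for k, (lo, hi) in merged.items():
            if not lo < hi:
                raise ValueError(f"bounds for {k} must satisfy lower < upper")
        self.bounds = merged

    @property
    def free_params(self) -> tuple:
        return MODEL_FREE_PARAMS[self.model_id]

    @property
    def k(self) -> int:
        """Number of free parameters (for AIC)."""
        return len(self.free_params)


@dataclass
class FoldedSFS:
    """Folded site frequency spectrum for one population sample.

    ``counts[j]`` is the number of SNPs whose minor allele is present in
    ``j`` of the ``2 * n_individuals`` gene copies, for j = 1..n;
    ``counts[0]`` optionally holds the monomorphic-site count (excluded
    from the likelihood).
    """

    counts: np.ndarray
    n_individuals: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) != self.n_individuals + 1:
            raise ValueError("counts must have length n_individuals + 1")
        if (self.counts < 0).any():
            raise ValueError("SFS counts must be non-negative")

    @property
    def n_snps(self) -> int:
        return int(self.counts[1:].sum())

    @property
    def proportions(self) -> np.ndarray:
        """Polymorphic-class proportions (classes 1..n)."""
        return self.counts[1:] / self.n_snps


@dataclass
class ModelFitResult:
    """Best-replicate fit of one model to an observed folded SFS."""

    model: DemographicModel
    params_hat: dict
    lnl: float
    aic: float
    delta_aic: float = np.nan
    weight: float = np.nan
    selection_freq: float = np.nan
    rep_lnls: list = field(default_factory=list)
    rep_params: list = field(default_factory=list)

    @property
    def rep_aics(self) -> np.ndarray:
        return 2.0 * self.model.k - 2.0 * np.asarray(self.rep_lnls)


@dataclass
class BootstrapCI:
    """Percentile 95% parametric-bootstrap intervals per parameter."""

    intervals: dict  # name -> (low, high)
    n_boot: int
    n_success: int
    replicates: pd.DataFrame | None = None


# ----------------------------------------------------------------------
# size histories
# ----------------------------------------------------------------------


def build_epochs(model: DemographicModel, params: dict) -> list[tuple]:
    """Piecewise epochs ``(t0, t1, N0, rate)`` with N(t)=N0*exp(rate*(t-t0)).

    Times are generations before present; the final epoch is unbounded
    with zero rate. Raises on non-positive sizes or inconsistent times.
    """
    n_cur = float(model.n_cur)
    mid = model.model_id
    if mid == "A":
        epochs = [(0.0, math.inf, n_cur, 0.0)]
    elif mid == "B":
        t_bot, n_anc = float(params["T_BOT"]), float(params["N_ANC"])
        epochs = [(0.0, t_bot, n_cur, 0.0), (t_bot, math.inf, n_anc, 0.0)]
    elif mid == "C":
        t_bot, n_anc = float(params["T_BOT"]), float(params["N_ANC"])
        g_r = float(params["G_R"])
        epochs = [(0.0, t_bot, n_cur, g_r), (t_bot, math.inf, n_anc, 0.0)]
    else:  # D
        t_bot, t_end = float(params["T_BOT"]), float(params["T_ENDBOT"])
        n_anc, n_bot = float(params["N_ANC"]), float(params["N_BOT"])
        if not t_end < t_bot:
            raise ValueError("model D requires T_ENDBOT < T_BOT")
        epochs = [
            (0.0, t_end, n_cur, 0.0),
            (t_end, t_bot, n_bot, 0.0),
            (t_bot, math.inf, n_anc, 0.0),
        ]
    for t0, t1, n0, rate in epochs:
        if n0 <= 0 or not t0 < t1:
            raise ValueError("invalid epoch (non-positive size or empty span)")
    return epochs


def size_trajectory(model: DemographicModel, params: dict):
    """Return N(t), the diploid size t generations before present."""
    epochs = build_epochs(model, params)

    def n_of_t(t):
        t = np.asarray(t, dtype=float)
        out = np.empty(t.shape)
        for t0, t1, n0, rate in epochs:
            sel = (t >= t0) & (t < t1)
            out[sel] = n0 * np.exp(rate * (t[sel] - t0))
        return out if out.ndim else float(out)

    return n_of_t


# ----------------------------------------------------------------------
# coalescent times by time rescaling
# ----------------------------------------------------------------------


def _epoch_intensity(u: np.ndarray, t1: float, t0: float, n0: float, rate: float):
    """Per-pair coalescent intensity integral of 1/(2N(s)) from u to t1."""
    if rate == 0.0:
        if math.isinf(t1):
            return np.full_like(u, np.inf)
        return (t1 - u) / (2.0 * n0)
    eu = np.exp(-rate * (u - t0))
    if math.isinf(t1):
        return eu / (2.0 * n0 * rate) if rate > 0 else np.full_like(u, np.inf)
    e1 = math.exp(-rate * (t1 - t0))
    return (eu - e1) / (2.0 * n0 * rate)


def _advance(epochs: list[tuple], t_cur: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Invert the cumulative pair intensity: find t with Lambda(t_cur,t)=x."""
    t_cur = np.array(t_cur, dtype=float, copy=True)
    t_new = np.empty_like(t_cur)
    rem = x.astype(float).copy()
    done = np.zeros(t_cur.shape, dtype=bool)
    for t0, t1, n0, rate in epochs:
        active = ~done & (t_cur < t1)
        if not active.any():
            continue
        u = np.clip(t_cur[active], t0, t1)
        cap = _epoch_intensity(u, t1, t0, n0, rate)
        r = rem[active]
        fin = r <= cap
        if rate == 0.0:
            sol = u + 2.0 * n0 * r
        else:
            eu = np.exp(-rate * (u - t0))
            val = eu - 2.0 * n0 * rate * r
            with np.errstate(invalid="ignore", divide="ignore"):
                sol = t0 - np.log(np.maximum(val, 1e-300)) / rate
        idx = np.flatnonzero(active)
        t_new[idx[fin]] = sol[fin]
        done[idx[fin]] = True
        rem[idx[~fin]] = r[~fin] - cap[~fin]
        # unfinished walkers resume at the start of the next epoch
        t_cur[idx[~fin]] = t1
    if not done.all():
        raise RuntimeError("time rescaling failed to terminate (bad epochs?)")
    return t_new


def _level_times_numba():
    """Build (once) the jitted level-times kernel; None if numba is absent."""
    global _LEVEL_TIMES_KERNEL
    if _LEVEL_TIMES_KERNEL is not None:
        return _LEVEL_TIMES_KERNEL
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba present in target envs
        return None

    @njit(cache=False)
    def kernel(eps, exps, out):  # pragma: no cover - compiled
        n_levels, b = exps.shape
        m = n_levels + 1
        n_ep = eps.shape[0]
        for j in range(b):
            t = 0.0
            for row in range(n_levels):
                k = m - row
                rem = exps[row, j] / (k * (k - 1) / 2.0)
                t_new = t
                for e in range(n_ep):
                    t0, t1, n0, rate = eps[e, 0], eps[e, 1], eps[e, 2], eps[e, 3]
                    if t >= t1:
                        continue
                    u = t if t > t0 else t0
                    if rate == 0.0:
                        cap = (t1 - u) / (2.0 * n0)
                        if rem <= cap:
                            t_new = u + 2.0 * n0 * rem
                            break
                        rem -= cap
                    else:
                        eu = np.exp(-rate * (u - t0))
                        if t1 == np.inf:
                            cap = eu / (2.0 * n0 * rate) if rate > 0 else np.inf
                        else:
                            e1 = np.exp(-rate * (t1 - t0))
                            cap = (eu - e1) / (2.0 * n0 * rate)
                        if rem <= cap:
                            val = eu - 2.0 * n0 * rate * rem
                            if val < 1e-300:
                                val = 1e-300
                            t_new = t0 - np.log(val) / rate
                            break
                        rem -= cap
                out[row, j] = t_new - t
                t = t_new

    _LEVEL_TIMES_KERNEL = kernel
    return kernel


_LEVEL_TIMES_KERNEL = None


def _simulate_level_times(
    epochs: list[tuple], n_copies: int, exponentials: np.ndarray
) -> np.ndarray:
    """Durations T_k of the k-lineage stages, k = n_copies..2.

    ``exponentials`` has shape (n_copies - 1, B): one standard
    exponential per coalescence event per replicate. Returns an array of
    the same shape (row 0 is the n_copies-lineage stage). Uses a
    numba-compiled kernel when available; the pure-numpy path computes
    the identical recursion.
    """
    n_levels, b = exponentials.shape
    if n_levels != n_copies - 1:
        raise ValueError("exponentials must have n_copies - 1 rows")
    kernel = _level_times_numba()
    if kernel is not None:
        eps = np.array([list(e) for e in epochs], dtype=float)
        out = np.empty_like(exponentials)
        kernel(eps, np.ascontiguousarray(exponentials), out)
        return out
    t_cur = np.zeros(b)
    out = np.empty_like(exponentials)
    for row, k in enumerate(range(n_copies, 1, -1)):
        pairs = k * (k - 1) / 2.0
        t_next = _advance(epochs, t_cur, exponentials[row] / pairs)
        out[row] = t_next - t_cur
        t_cur = t_next
    return out


def _branch_class_matrix(n_copies: int) -> np.ndarray:
    """W[row, i-1] = k * P(branch at level k subtends i leaves).

    Rows follow the level order of :func:`_simulate_level_times`
    (k = n_copies..2); P(i | k) = C(m-i-1, k-2) / C(m-1, k-1).
    """
    m = n_copies
    ks = np.arange(m, 1, -1, dtype=float)[:, None]
    i = np.arange(1, m, dtype=float)[None, :]
    with np.errstate(invalid="ignore", over="ignore"):
        logp = (
            gammaln(m - i)
            - gammaln(ks - 1.0)
            - gammaln(m - i - ks + 2.0)
            - (gammaln(m) - gammaln(ks) - gammaln(m - ks + 1.0))
        )
        p = np.where(m - i - 1 >= ks - 2, np.exp(logp), 0.0)
    return ks * p


def _fold(unfolded: np.ndarray, n_individuals: int) -> np.ndarray:
    """Fold derived classes 1..2n-1 into minor classes 1..n (last axis)."""
    m = 2 * n_individuals
    folded = unfolded[..., : n_individuals].copy()
    folded[..., : n_individuals - 1] += unfolded[..., m - 2 : n_individuals - 1 : -1]
    return folded


def neutral_folded_proportions(n_individuals: int) -> np.ndarray:
    """Closed-form folded SFS proportions under constant size.

    Classes j = 1..n, proportional to (1/j + 1/(2n-j)) / (1 + [j == n]).
    """
    m = 2 * n_individuals
    j = np.arange(1, n_individuals + 1, dtype=float)
    w = 1.0 / j + 1.0 / (m - j)
    w[-1] /= 2.0
    return w / w.sum()


def expected_folded_sfs(
    model: DemographicModel,
    params: dict,
    n_individuals: int,
    n_sims: int = 10_000,
    exponentials: np.ndarray | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Monte-Carlo expected folded-SFS class probabilities (classes 1..n).

    Simulates ``n_sims`` genealogy time vectors, converts each to
    per-class expected branch lengths analytically (topology integrated
    out), averages the lengths over genealogies and normalises — i.e.
    E[L_i] / E[L_total], the class distribution of a SNP drawn from
    loci *conditioned on segregating*, which is how one-SNP-per-locus
    RAD spectra arise (longer genealogies are more likely to carry the
    retained SNP). Under constant size this converges to the classical
    1/i spectrum.
    """
    m = 2 * n_individuals
    if exponentials is None:
        rng = np.random.default_rng(seed)
        exponentials = rng.standard_exponential((m - 1, n_sims))
    epochs = build_epochs(model, params)
    t = _simulate_level_times(epochs, m, exponentials)
    w = _branch_class_matrix(m)
    lengths = (t.mean(axis=1) @ w)  # mean branch length per derived class
    return _fold(lengths / lengths.sum(), n_individuals)


def simulate_sfs(
    model: DemographicModel,
    params: dict,
    n_individuals: int,
    n_snps: int,
    seed: int | None = None,
) -> FoldedSFS:
    """Simulate a folded SFS: one SNP on each of ``n_snps`` independent loci.

    A pool of ``n_snps`` independent genealogies is simulated; each SNP
    mutation is then placed proportionally to branch length across the
    pooled (genealogy, lineage-count level) measure — the length-biased
    sampling that arises when loci enter the dataset conditioned on
    carrying a SNP — and its branch-size class is drawn from the
    exchangeable-topology distribution and folded.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 diploid individuals")
    m = 2 * n_individuals
    rng = np.random.default_rng(seed)
    epochs = build_epochs(model, params)
    exps = rng.standard_exponential((m - 1, n_snps))
    t = _simulate_level_times(epochs, m, exps)  # (levels, B)
    ks = np.arange(m, 1, -1, dtype=float)
    level_len = (ks[:, None] * t).ravel(order="C")  # pooled (level, tree) cells
    cdf = np.cumsum(level_len)
    u = rng.random(n_snps) * cdf[-1]
    cell = np.searchsorted(cdf, u)
    lvl = cell // t.shape[1]  # row index into levels

    w = _branch_class_matrix(m)
    class_cdf = np.cumsum(w / w.sum(axis=1, keepdims=True), axis=1)
    derived = np.empty(n_snps, dtype=np.int64)
    for row in np.unique(lvl):
        sel = lvl == row
        derived[sel] = (
            np.searchsorted(class_cdf[row], rng.random(int(sel.sum()))) + 1
        )
    minor = np.minimum(derived, m - derived)
    counts = np.bincount(minor, minlength=n_individuals + 1)
    return FoldedSFS(counts=counts, n_individuals=n_individuals)


# ----------------------------------------------------------------------
# composite likelihood and fitting
# ----------------------------------------------------------------------


def composite_lnl(obs: FoldedSFS, expected_proportions: np.ndarray) -> float:
    """Multinomial composite log-likelihood over polymorphic classes (nats).

    Expected class probabilities are floored at ``PROB_FLOOR`` and
    renormalised; the monomorphic class is excluded.
    """
    counts = obs.counts[1:].astype(float)
    if counts.sum() == 0:
        raise ValueError("observed SFS has no polymorphic sites")
    p = np.maximum(np.asarray(expected_proportions, dtype=float), PROB_FLOOR)
    p = p / p.sum()
    return float(np.sum(counts * np.log(p)))


def _effective_bounds(model: DemographicModel, params: dict, name: str):
    lo, hi = model.bounds[name]
    if model.model_id == "D":
        if name == "T_ENDBOT":
            hi = min(hi, params["T_BOT"] - 1.0)
        elif name == "T_BOT":
            lo = max(lo, params["T_ENDBOT"] + 1.0)
    return lo, hi


def _random_start(model: DemographicModel, rng: np.random.Generator) -> dict:
    """Random start in bounds; log-uniform for sizes, uniform otherwise."""
    start = {}
    for name in model.free_params:
        lo, hi = model.bounds[name]
        if name.startswith("N_"):
            start[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            start[name] = float(rng.uniform(lo, hi))
    if model.model_id == "D" and start["T_ENDBOT"] >= start["T_BOT"]:
        start["T_ENDBOT"] = max(1.0, start["T_BOT"] / 2.0)
    return start


def fit_model(
    obs: FoldedSFS,
    model: DemographicModel,
    n_cycles: int = 40,
    n_sims: int = 10_000,
    n_reps: int = 10,
    seed: int = 0,
    maxiter_1d: int = 20,
    tol: float = 1e-3,
    start: dict | None = None,
) -> ModelFitResult:
    """Maximise the composite likelihood by cyclic bounded line search.

    Each of ``n_reps`` replicates draws its own random start (the first
    uses ``start`` when given, e.g. for bootstrap re-fits) and its own
    fixed standard-exponential matrix of ``n_sims`` genealogies (common
    random numbers, so the objective is deterministic within a
    replicate). Per cycle, each free parameter is optimised by bounded
    scalar (Brent-style) search; cycling stops early once a full cycle
    improves the log-likelihood by less than ``tol``. The best replicate
    is reported; AIC = 2k - 2 lnL.
    """
    n = obs.n_individuals
    m = 2 * n
    rep_lnls: list[float] = []
    rep_params: list[dict] = []
    master = np.random.default_rng([int(seed), 0xD1F])
    for rep in range(n_reps):
        rng = np.random.default_rng([int(seed), rep])
        exps = rng.standard_exponential((m - 1, n_sims))

        def lnl_of(params: dict) -> float:
            probs = expected_folded_sfs(
                model, params, n, exponentials=exps
            )
            return composite_lnl(obs, probs)

        if model.k == 0:
            rep_lnls.append(lnl_of({}))
            rep_params.append({})
            continue
        params = (
            dict(start)
            if (start is not None and rep == 0)
            else _random_start(model, master)
        )
        current = lnl_of(params)
        for _cycle in range(n_cycles):
            before = current
            for name in model.free_params:
                lo, hi = _effective_bounds(model, params, name)
                if not lo < hi:
                    continue

                def neg(v: float, _name=name) -> float:
                    trial = dict(params)
                    trial[_name] = float(v)
                    try:
                        return -lnl_of(trial)
                    except ValueError:
                        return np.inf

                res = minimize_scalar(
                    neg,
                    bounds=(lo, hi),
                    method="bounded",
                    options={"maxiter": maxiter_1d, "xatol": (hi - lo) * 1e-4},
                )
                if np.isfinite(res.fun) and -res.fun > current:
                    params[name] = float(res.x)
                    current = -res.fun
            if current - before < tol:
                break
        if not np.isfinite(current):
            warnings.warn(f"non-finite lnL in replicate {rep}", stacklevel=2)
        rep_lnls.append(current)
        rep_params.append(params)
    best = int(np.nanargmax(rep_lnls))
    lnl = float(rep_lnls[best])
    return ModelFitResult(
        model=model,
        params_hat=dict(rep_params[best]),
        lnl=lnl,
        aic=2.0 * model.k - 2.0 * lnl,
        rep_lnls=rep_lnls,
        rep_params=rep_params,
    )


def model_selection(fits: dict) -> pd.DataFrame:
    """AIC table with differences, Akaike weights and selection frequency.

    ``fits`` maps model id -> :class:`ModelFitResult` obtained on the
    *same* observed SFS. ``selection_freq`` is the fraction of replicate
    runs (paired by replicate index) in which each model attains the
    lowest AIC; ``joint_support`` flags all models within 3 AIC units of
    the best.
    """
    if len(fits) < 2:
        raise ValueError("model selection requires >= 2 fitted models")
    ids = list(fits)
    aics = np.array([fits[i].aic for i in ids])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    n_rep = min(len(fits[i].rep_lnls) for i in ids)
    rep_aics = np.vstack([fits[i].rep_aics[:n_rep] for i in ids])
    winners = rep_aics.argmin(axis=0)
    sel = np.array([(winners == k).mean() for k in range(len(ids))])
    for k, i in enumerate(ids):
        fits[i].delta_aic = float(delta[k])
        fits[i].weight = float(w[k])
        fits[i].selection_freq = float(sel[k])
    return pd.DataFrame(
        {
            "model": ids,
            "k": [fits[i].model.k for i in ids],
            "lnL": [fits[i].lnl for i in ids],
            "AIC": aics,
            "delta_AIC": delta,
            "weight": w,
            "selection_freq": sel,
            "joint_support": delta < 3.0,
        }
    )


def parametric_bootstrap(
    model: DemographicModel,
    params_hat: dict,
    n_individuals: int,
    n_snps: int,
    n_boot: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    **fit_kwargs,
) -> BootstrapCI:
    """Percentile parametric-bootstrap CIs for the fitted parameters.

    Simulates ``n_boot`` folded SFS datasets at ``params_hat`` with the
    same sample size and SNP count as the data, re-fits each starting
    from ``params_hat`` (single replicate per bootstrap dataset), and
    takes the 2.5/97.5 percentiles per parameter. Replicates whose
    re-fit yields a non-finite likelihood are dropped; at least 80% must
    succeed.
    """
    fit_kwargs.setdefault("n_reps", 1)
    fit_kwargs.setdefault("n_cycles", 3)
    rows = []
    for b in range(n_boot):
        boot_obs = simulate_sfs(
            model, params_hat, n_individuals, n_snps, seed=_subseed(seed, b)
        )
        fit = fit_model(
            boot_obs,
            model,
            seed=_subseed(seed, n_boot + b),
            start=dict(params_hat),
            **fit_kwargs,
        )
        if np.isfinite(fit.lnl):
            rows.append(fit.params_hat)
        else:
            warnings.warn(f"bootstrap replicate {b} dropped (refit failed)",
                          stacklevel=2)
    if len(rows) < 0.8 * n_boot:
        raise RuntimeError(
            f"only {len(rows)}/{n_boot} bootstrap replicates succeeded"
        )
    table = pd.DataFrame(rows)
    intervals = {
        name: (
            float(np.percentile(table[name], 100 * alpha / 2)),
            float(np.percentile(table[name], 100 * (1 - alpha / 2))),
        )
        for name in model.free_params
    }
    return BootstrapCI(
        intervals=intervals, n_boot=n_boot, n_success=len(rows), replicates=table
    )


def _subseed(seed: int, k: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.default_rng([int(seed), int(k)]).integers(0, 2**31 - 1))


# ----------------------------------------------------------------------
# unit conversions
# ----------------------------------------------------------------------


def generations_to_years(g: float, gen_per_year: float = 5.5) -> tuple[float, int]:
    """Convert generations before present to years (raw and rounded)."""
    if gen_per_year <= 0:
        raise ValueError("gen_per_year must be positive")
    years = g / gen_per_year
    return years, int(round(years))


def reduction_fraction(n_cur: float, n_anc: float) -> float:
    """Fractional loss of effective size relative to the ancestral value."""
    if n_anc <= 0:
        raise ValueError("n_anc must be positive")
    return 1.0 - n_cur / n_anc


# ----------------------------------------------------------------------
# SFS text I/O (single-line whitespace format with a sample-size header)
# ----------------------------------------------------------------------


def write_sfs(sfs: FoldedSFS, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# folded SFS n_individuals={sfs.n_individuals} "
                 f"classes=0..{sfs.n_individuals}\n")
        fh.write(" ".join(str(int(c)) for c in sfs.counts) + "\n")


def read_sfs(path) -> FoldedSFS:
    with open(path) as fh:
        header = fh.readline()
        if "n_individuals=" not in header:
            raise ValueError("SFS file lacks an n_individuals header")
        n = int(header.split("n_individuals=")[1].split()[0])
        counts = np.array(fh.readline().split(), dtype=np.int64)
    return FoldedSFS(counts=counts, n_individuals=n)
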