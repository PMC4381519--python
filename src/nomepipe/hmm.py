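"""Two-state beta-binomial hidden Markov model over ordered GCH sites.

One sample replicate's GCH methylation calls (methylated count, read total
per site) form the observation series. State 0 is methyltransferase
*protected* (MPR-like, low GpC methylation), state 1 is *accessible*
(MAR-like, high GpC methylation). Each state emits counts from a
beta-binomial; transitions between consecutive GCH sites are homogeneous,
and the series is broken into independent chains wherever consecutive sites
are farther apart than ``max_gap`` (or on a chromosome change), so that no
state information is propagated across site deserts.

Fitting is EM with a forward-backward E-step in log space and a
method-of-moments emission M-step; decoding is Viterbi with deterministic
tie-breaking toward the protected state. Decoded paths are assembled into
MAR/MPR segments requiring at least three same-state GCH sites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

PROTECTED, ACCESSIBLE = 0, 1
STATE_NAMES = {PROTECTED: "MPR", ACCESSIBLE: "MAR"}


# ---------------------------------------------------------------------------
# Emission density
# ---------------------------------------------------------------------------

def beta_binomial_logpmf(k, n, alpha: float, beta: float):
    """Log pmf of the beta-binomial distribution, evaluated via log-gamma.

    Vectorized over ``k``/``n``. ``alpha = beta = 1`` gives the uniform
    distribution 1/(n+1) on 0..n; ``n = 0`` gives log 1 = 0.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    out = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + gammaln(k + alpha) + gammaln(n - k + beta) - gammaln(n + alpha + beta)
        + gammaln(alpha + beta) - gammaln(alpha) - gammaln(beta)
    )
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaBinomialHMMParams:
    """Parameters of the two-state model.

    ``alpha``/``beta`` are per-state emission shapes ordered (protected,
    accessible); the accessible emission mean must exceed the protected one
    (identifiability ordering). ``max_gap`` is the inter-site distance (bp)
    at which the observation series is broken into independent chains.
    """

    alpha: tuple[float, float]
    beta: tuple[float, float]
    transition: tuple[tuple[float, float], tuple[float, float]]
    initial: tuple[float, float]
    max_gap: int = 500

    def __post_init__(self) -> None:
        a, b = np.asarray(self.alpha, float), np.asarray(self.beta, float)
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("emission shapes must be positive")
        tr = np.asarray(self.transition, float)
        if tr.shape != (2, 2) or np.any(tr < 0):
            raise ValueError("transition must be a non-negative 2x2 matrix")
        if np.any(np.abs(tr.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition rows must sum to 1")
        init = np.asarray(self.initial, float)
        if init.shape != (2,) or abs(init.sum() - 1.0) > 1e-12 or np.any(init < 0):
            raise ValueError("initial must be a length-2 distribution")
        means = a / (a + b)
        if not means[ACCESSIBLE] > means[PROTECTED]:
            raise ValueError("accessible emission mean must exceed protected mean")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")

    @property
    def emission_means(self) -> tuple[float, float]:
        a, b = np.asarray(self.alpha), np.asarray(self.beta)
        return tuple(a / (a + b))

    def to_dict(self) -> dict:
        return {
            "alpha": [float(x) for x in self.alpha],
            "beta": [float(x) for x in self.beta],
            "transition": [[float(x) for x in r] for r in self.transition],
            "initial": [float(x) for x in self.initial],
            "max_gap": int(self.max_gap),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BetaBinomialHMMParams":
        return cls(
            alpha=tuple(d["alpha"]), beta=tuple(d["beta"]),
            transition=tuple(tuple(r) for r in d["transition"]),
            initial=tuple(d["initial"]), max_gap=int(d.get("max_gap", 500)),
        )


def default_init_params(max_gap: int = 500) -> BetaBinomialHMMParams:
    """Generic starting point: protected mean 0.10, accessible mean 0.70."""
    return BetaBinomialHMMParams(
        alpha=(0.5, 3.5), beta=(4.5, 1.5),
        transition=((0.99, 0.01), (0.05, 0.95)),
        initial=(0.9, 0.1), max_gap=max_gap,
    )


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

def chain_slices(calls: pd.DataFrame, max_gap: int) -> list[tuple[int, int]]:
    """Index ranges of independent chains (split on chrom change or gap > max_gap)."""
    if len(calls) == 0:
        return []
    pos = calls["pos"].to_numpy()
    chrom = calls["chrom"].to_numpy()
    breaks = [0]
    for t in range(1, len(calls)):
        if chrom[t] != chrom[t - 1] or pos[t] - pos[t - 1] > max_gap:
            breaks.append(t)
    breaks.append(len(calls))
    return [(breaks[i], breaks[i + 1]) for i in range(len(breaks) - 1)]


# ---------------------------------------------------------------------------
# Numeric kernels (pure-python loops; JIT-compiled when numba is available)
# ---------------------------------------------------------------------------

def _lse2(x: float, y: float) -> float:
    m = x if x > y else y
    return m + math.log(math.exp(x - m) + math.exp(y - m))


def _estep_chain(e0, e1, p, invn, la00, la01, la10, la11, li0, li1, out):
    """Forward-backward over one chain, accumulating sufficient statistics.

    out layout: [0]=ll, [1:5]=xi(00,01,10,11), [5:7]=initial gamma,
    [7:11]=state0 (sum w, sum w*p, sum w*p^2, sum w/n),
    [11:15]=state1 (same), all over sites with n > 0 for the emission stats.
    """
    T = e0.shape[0]
    f0 = np.empty(T)
    f1 = np.empty(T)
    f0[0] = li0 + e0[0]
    f1[0] = li1 + e1[0]
    for t in range(1, T):
        x = f0[t - 1] + la00
        y = f1[t - 1] + la10
        m = x if x > y else y
        f0[t] = m + math.log(math.exp(x - m) + math.exp(y - m)) + e0[t]
        x = f0[t - 1] + la01
        y = f1[t - 1] + la11
        m = x if x > y else y
        f1[t] = m + math.log(math.exp(x - m) + math.exp(y - m)) + e1[t]
    x = f0[T - 1]
    y = f1[T - 1]
    m = x if x > y else y
    ll = m + math.log(math.exp(x - m) + math.exp(y - m))
    out[0] += ll
    b0 = 0.0
    b1 = 0.0
    g0 = math.exp(f0[T - 1] - ll)
    g1 = math.exp(f1[T - 1] - ll)
    if invn[T - 1] > 0.0:
        pt = p[T - 1]
        out[7] += g0; out[8] += g0 * pt; out[9] += g0 * pt * pt; out[10] += g0 * invn[T - 1]
        out[11] += g1; out[12] += g1 * pt; out[13] += g1 * pt * pt; out[14] += g1 * invn[T - 1]
    for t in range(T - 2, -1, -1):
        y0 = e0[t + 1] + b0
        y1 = e1[t + 1] + b1
        out[1] += math.exp(f0[t] + la00 + y0 - ll)
        out[2] += math.exp(f0[t] + la01 + y1 - ll)
        out[3] += math.exp(f1[t] + la10 + y0 - ll)
        out[4] += math.exp(f1[t] + la11 + y1 - ll)
        x = la00 + y0
        y = la01 + y1
        m = x if x > y else y
        nb0 = m + math.log(math.exp(x - m) + math.exp(y - m))
        x = la10 + y0
        y = la11 + y1
        m = x if x > y else y
        nb1 = m + math.log(math.exp(x - m) + math.exp(y - m))
        b0 = nb0
        b1 = nb1
        g0 = math.exp(f0[t] + b0 - ll)
        g1 = math.exp(f1[t] + b1 - ll)
        if invn[t] > 0.0:
            pt = p[t]
            out[7] += g0; out[8] += g0 * pt; out[9] += g0 * pt * pt; out[10] += g0 * invn[t]
            out[11] += g1; out[12] += g1 * pt; out[13] += g1 * pt * pt; out[14] += g1 * invn[t]
    out[5] += g0
    out[6] += g1


def _forward_ll_chain(e0, e1, la00, la01, la10, la11, li0, li1) -> float:
    T = e0.shape[0]
    f0 = li0 + e0[0]
    f1 = li1 + e1[0]
    for t in range(1, T):
        x = f0 + la00
        y = f1 + la10
        m = x if x > y else y
        n0 = m + math.log(math.exp(x - m) + math.exp(y - m)) + e0[t]
        x = f0 + la01
        y = f1 + la11
        m = x if x > y else y
        f1 = m + math.log(math.exp(x - m) + math.exp(y - m)) + e1[t]
        f0 = n0
    m = f0 if f0 > f1 else f1
    return m + math.log(math.exp(f0 - m) + math.exp(f1 - m))


def _viterbi_chain(e0, e1, la00, la01, la10, la11, li0, li1, path):
    """Max a posteriori path; ties broken toward the protected state (0)."""
    T = e0.shape[0]
    ptr0 = np.empty(T, dtype=np.int8)
    ptr1 = np.empty(T, dtype=np.int8)
    d0 = li0 + e0[0]
    d1 = li1 + e1[0]
    for t in range(1, T):
        x = d0 + la00
        y = d1 + la10
        if x >= y:
            n0 = x + e0[t]; ptr0[t] = 0
        else:
            n0 = y + e0[t]; ptr0[t] = 1
        x = d0 + la01
        y = d1 + la11
        if x >= y:
            n1 = x + e1[t]; ptr1[t] = 0
        else:
            n1 = y + e1[t]; ptr1[t] = 1
        d0 = n0
        d1 = n1
    s = 0 if d0 >= d1 else 1
    path[T - 1] = s
    for t in range(T - 1, 0, -1):
        s = ptr0[t] if s == 0 else ptr1[t]
        path[t - 1] = s


try:  # optional JIT acceleration; the pure-python kernels are the reference
    import numba as _numba

    _estep_chain = _numba.njit(cache=False)(_estep_chain)
    _forward_ll_chain = _numba.njit(cache=False)(_forward_ll_chain)
    _viterbi_chain = _numba.njit(cache=False)(_viterbi_chain)
except ImportError:  # pragma: no cover
    pass


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: BetaBinomialHMMParams
    loglik: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def _emission_logprobs(k, n, params: BetaBinomialHMMParams):
    e0 = beta_binomial_logpmf(k, n, params.alpha[0], params.beta[0])
    e1 = beta_binomial_logpmf(k, n, params.alpha[1], params.beta[1])
    return np.asarray(e0, float), np.asarray(e1, float)


def _mom_shapes(sw, swp, swp2, swinv, old: tuple[float, float]) -> tuple[float, float]:
    """Method-of-moments beta shapes from responsibility-weighted count moments.

    The observed variance of per-site fractions decomposes into the latent
    beta variance plus binomial sampling noise E[theta(1-theta)]/n; solving the
    weighted moment equations for the beta variance gives the shapes.
    """
    if sw < 1e-8:
        return old
    mu = min(max(swp / sw, 1e-4), 1 - 1e-4)
    s2 = swp2 / sw
    c = min(swinv / sw, 0.99)
    var = (s2 - mu * mu - (mu - mu * mu) * c) / (1.0 - c)
    vmax = mu * (1 - mu)
    var = min(max(var, 1e-8), 0.999 * vmax)
    conc = vmax / var - 1.0
    conc = min(max(conc, 0.05), 1e4)
    return mu * conc, (1 - mu) * conc


def _run_estep(chains, e0, e1, p, invn, params) -> np.ndarray:
    la = np.log(np.asarray(params.transition) + 1e-300)
    li = np.log(np.asarray(params.initial) + 1e-300)
    out = np.zeros(15)
    for s, e in chains:
        _estep_chain(
            e0[s:e], e1[s:e], p[s:e], invn[s:e],
            la[0, 0], la[0, 1], la[1, 0], la[1, 1], li[0], li[1], out,
        )
    return out


def _total_ll(chains, e0, e1, params) -> float:
    la = np.log(np.asarray(params.transition) + 1e-300)
    li = np.log(np.asarray(params.initial) + 1e-300)
    return sum(
        _forward_ll_chain(e0[s:e], e1[s:e], la[0, 0], la[0, 1], la[1, 0], la[1, 1],
                          li[0], li[1])
        for s, e in chains
    )


def _normalize_order(params: BetaBinomialHMMParams) -> BetaBinomialHMMParams:
    means = np.asarray(params.alpha) / (np.asarray(params.alpha) + np.asarray(params.beta))
    if means[ACCESSIBLE] > means[PROTECTED]:
        return params
    tr = np.asarray(params.transition)[::-1, ::-1]
    return BetaBinomialHMMParams(
        alpha=params.alpha[::-1], beta=params.beta[::-1],
        transition=tuple(tuple(r) for r in tr),
        initial=params.initial[::-1], max_gap=params.max_gap,
    )


def _updated(params, stats, transitions_only: bool) -> BetaBinomialHMMParams:
    xi = stats[1:5].reshape(2, 2)
    rows = xi.sum(axis=1)
    tr = np.asarray(params.transition, float).copy()
    for i in range(2):
        if rows[i] > 1e-12:
            tr[i] = xi[i] / rows[i]
    tr = np.clip(tr, 1e-9, None)
    tr /= tr.sum(axis=1, keepdims=True)
    init = stats[5:7]
    init = init / init.sum() if init.sum() > 0 else np.asarray(params.initial)
    init = np.clip(init, 1e-9, None)
    init /= init.sum()
    if transitions_only:
        alpha, beta = params.alpha, params.beta
    else:
        a0, b0 = _mom_shapes(*stats[7:11], (params.alpha[0], params.beta[0]))
        a1, b1 = _mom_shapes(*stats[11:15], (params.alpha[1], params.beta[1]))
        alpha, beta = (a0, a1), (b0, b1)
    cand = BetaBinomialHMMParams.__new__(BetaBinomialHMMParams)
    object.__setattr__(cand, "alpha", tuple(alpha))
    object.__setattr__(cand, "beta", tuple(beta))
    object.__setattr__(cand, "transition", tuple(tuple(r) for r in tr))
    object.__setattr__(cand, "initial", tuple(init))
    object.__setattr__(cand, "max_gap", params.max_gap)
    return cand


def fit_hmm(
    calls: pd.DataFrame,
    init: Optional[BetaBinomialHMMParams] = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    seed: Optional[int] = None,
) -> FitResult:
    """Fit the two-state model to one replicate's GCH series by EM.

    The E-step is exact forward-backward; the M-step updates transitions and
    initial probabilities exactly and the emission shapes by responsibility-
    weighted method of moments. Because the moment update is not guaranteed
    to increase the likelihood, each iteration is guarded: if the full update
    would lower the log-likelihood, the iteration falls back to the exact
    transition-only update (a generalized EM step) and fitting stops. The
    recorded log-likelihood trace is therefore non-decreasing.

    ``seed`` is accepted for interface stability; the default initialization
    is deterministic so it is unused.
    """
    if len(calls) < 100:
        raise ValueError("need at least 100 GCH sites to fit the model")
    params = _normalize_order(init or default_init_params())
    k = calls["n_meth"].to_numpy(float)
    n = calls["n_total"].to_numpy(float)
    if not (n > 0).any():
        warnings.warn("all sites have zero coverage; returning initial params")
        return FitResult(params=params, loglik=[], converged=False, n_iter=0)
    if not (k > 0).any():
        warnings.warn("all methylated counts are zero; emission fit degenerate")
    p = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    invn = np.where(n > 0, 1.0 / np.maximum(n, 1), 0.0)
    chains = chain_slices(calls, params.max_gap)
    lls: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        e0, e1 = _emission_logprobs(k, n, params)
        stats = _run_estep(chains, e0, e1, p, invn, params)
        ll = stats[0]
        lls.append(ll)
        if len(lls) > 1 and abs(ll - lls[-2]) <= tol * max(abs(ll), 1.0):
            converged = True
            break
        cand = _updated(params, stats, transitions_only=False)
        ce0, ce1 = _emission_logprobs(k, n, cand)
        if _total_ll(chains, ce0, ce1, cand) >= ll - 1e-9 * max(abs(ll), 1.0):
            params = cand
        else:
            params = _updated(params, stats, transitions_only=True)
            converged = True
            break
    else:
        warnings.warn(
            f"EM did not converge after {max_iter} iterations "
            f"(last LL change {lls[-1] - lls[-2]:.3g})" if len(lls) > 1 else
            f"EM did not converge after {max_iter} iterations"
        )
    return FitResult(params=_normalize_order(params), loglik=lls,
                     converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# Decoding and segmentation
# ---------------------------------------------------------------------------

def viterbi_decode(calls: pd.DataFrame, params: BetaBinomialHMMParams) -> np.ndarray:
    """Joint MAP state path per chain (0 = protected/MPR, 1 = accessible/MAR)."""
    if len(calls) == 0:
        return np.empty(0, dtype=np.int8)
    k = calls["n_meth"].to_numpy(float)
    n = calls["n_total"].to_numpy(float)
    e0, e1 = _emission_logprobs(k, n, params)
    la = np.log(np.asarray(params.transition) + 1e-300)
    li = np.log(np.asarray(params.initial) + 1e-300)
    path = np.empty(len(calls), dtype=np.int8)
    for s, e in chain_slices(calls, params.max_gap):
        _viterbi_chain(e0[s:e], e1[s:e], la[0, 0], la[0, 1], la[1, 0], la[1, 1],
                       li[0], li[1], path[s:e])
    return path


SEGMENT_COLUMNS = [
    "chrom", "start", "end", "state", "n_sites", "n_meth", "n_total",
    "is_mononucleosome", "chain_id",
]

#: Segment end = last member GCH position + 2, covering the GC dinucleotide.
DINUCLEOTIDE_SPAN = 2


def assemble_segments(
    path: np.ndarray,
    calls: pd.DataFrame,
    params: Optional[BetaBinomialHMMParams] = None,
    min_sites: int = 3,
    max_gap: int = 500,
    mono_len: tuple[int, int] = (100, 200),
) -> pd.DataFrame:
    """Assemble a decoded state path into MAR/MPR segments.

    Maximal same-state runs shorter than ``min_sites`` are absorbed into the
    flanking run whose state has the higher total emission likelihood for the
    absorbed sites (ties and chain-terminal runs go to the preceding /
    only neighbor); adjacent same-state runs then merge, so segments tile the
    chain and alternate states. A chain with fewer than ``min_sites`` sites
    yields no segments. MPR segments of 100-200 bp flanked by MARs on both
    sides are flagged ``is_mononucleosome``.

    ``params`` supplies the emission likelihoods for the absorption rule;
    because runs alternate, both flanks of an interior short run share a
    state and the comparison degenerates to the preceding-run tie-break, so
    ``params`` may be omitted.
    """
    if len(path) != len(calls):
        raise ValueError("path and calls are misaligned")
    if len(calls) == 0:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    gap = params.max_gap if params is not None else max_gap
    if params is not None:
        k = calls["n_meth"].to_numpy(float)
        n = calls["n_total"].to_numpy(float)
        e0, e1 = _emission_logprobs(k, n, params)
    else:
        e0 = e1 = np.zeros(len(calls))
    pos = calls["pos"].to_numpy()
    chrom = calls["chrom"].to_numpy()
    nm = calls["n_meth"].to_numpy()
    nt = calls["n_total"].to_numpy()
    records = []
    for chain_id, (s, e) in enumerate(chain_slices(calls, gap)):
        runs: list[list[int]] = []  # [state, start, stop)
        for t in range(s, e):
            if runs and runs[-1][0] == path[t]:
                runs[-1][2] = t + 1
            else:
                runs.append([int(path[t]), t, t + 1])
        # absorb short runs (leftmost-shortest first)
        while len(runs) > 1:
            lens = [r[2] - r[1] for r in runs]
            short = [i for i, L in enumerate(lens) if L < min_sites]
            if not short:
                break
            i = min(short, key=lambda j: (lens[j], j))
            lo, hi = runs[i][1], runs[i][2]
            neighbors = [j for j in (i - 1, i + 1) if 0 <= j < len(runs)]
            if len(neighbors) == 2 and runs[neighbors[0]][0] != runs[neighbors[1]][0]:
                ll_by_state = {
                    runs[j][0]: float(np.sum((e0, e1)[runs[j][0]][lo:hi]))
                    for j in neighbors
                }
                # prefer higher emission likelihood; ties -> preceding run
                prev_state = runs[neighbors[0]][0]
                best = max(
                    ll_by_state, key=lambda st: (ll_by_state[st], st == prev_state)
                )
            else:
                best = runs[neighbors[0]][0]
            runs[i][0] = best
            merged: list[list[int]] = []
            for r in runs:
                if merged and merged[-1][0] == r[0]:
                    merged[-1][2] = r[2]
                else:
                    merged.append(r)
            runs = merged
        if len(runs) == 1 and runs[0][2] - runs[0][1] < min_sites:
            continue
        for r in runs:
            lo, hi = r[1], r[2]
            records.append({
                "chrom": chrom[lo],
                "start": int(pos[lo]),
                "end": int(pos[hi - 1]) + DINUCLEOTIDE_SPAN,
                "state": STATE_NAMES[r[0]],
                "n_sites": hi - lo,
                "n_meth": int(nm[lo:hi].sum()),
                "n_total": int(nt[lo:hi].sum()),
                "is_mononucleosome": False,
                "chain_id": chain_id,
            })
    seg = pd.DataFrame(records, columns=SEGMENT_COLUMNS)
    if len(seg):
        length = seg["end"] - seg["start"]
        prev_mar = seg["state"].shift(1).eq("MAR") & seg["chain_id"].shift(1).eq(seg["chain_id"])
        next_mar = seg["state"].shift(-1).eq("MAR") & seg["chain_id"].shift(-1).eq(seg["chain_id"])
        seg["is_mononucleosome"] = (
            seg["state"].eq("MPR")
            & length.ge(mono_len[0]) & length.le(mono_len[1])
            & prev_mar & next_mar
        )
    return seg


def segment_chain(
    calls: pd.DataFrame,
    params: BetaBinomialHMMParams,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Decode and assemble in one step (per-replicate segmentation)."""
    path = viterbi_decode(calls, params)
    return assemble_segments(path, calls, params=params, min_sites=min_sites)


# ---------------------------------------------------------------------------
# Simulation directly from the model (for parameter-recovery checks)
# ---------------------------------------------------------------------------

def sample_series(
    params: BetaBinomialHMMParams,
    n_sites: int,
    mean_depth: float = 30.0,
    seed: int = 0,
    spacing: int = 20,
    chrom: str = "chrH",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample (calls, states) from the generative model on a regular grid."""
    rng = np.random.default_rng(seed)
    tr = np.asarray(params.transition)
    states = np.empty(n_sites, dtype=np.int8)
    states[0] = rng.choice(2, p=np.asarray(params.initial))
    for t in range(1, n_sites):
        states[t] = rng.choice(2, p=tr[states[t - 1]])
    a = np.asarray(params.alpha)[states]
    b = np.asarray(params.beta)[states]
    theta = rng.beta(a, b)
    total = rng.poisson(mean_depth, size=n_sites)
    meth = rng.binomial(total, theta)
    calls = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(n_sites, dtype=np.int64) * spacing,
        "strand": "+",
        "context": "GCH",
        "n_meth": meth,
        "n_total": total,
    })
    return calls, states
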