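"""Desk-scale bilinear dynamic causal modeling (DCM).

Neural dynamics follow the bilinear state equation

    dz/dt = (A + sum_j u_j B_j) z + C u

over k = 4 nodes ([temporal, prefrontal] x [left, right hemisphere]) driven
by m = 8 condition inputs ([good, bad, novel, familiar] x [left, right
hemifield]). Each node's neural state passes through a balloon-type
hemodynamic model (vasodilatory signal, flow, volume, deoxyhemoglobin);
because the MION contrast agent tracks cerebral blood volume the readout is
the sign-inverted volume excursion y = -eps * (v - 1).

Nine candidate architectures cross three input schemes (contralateral
visual input to the temporal nodes, to the prefrontal nodes, or to both)
with three self-connection modulation schemes (none; good/novel; all four
conditions). All models share the fixed connectivity mask A (reciprocal
temporal <-> prefrontal within each hemisphere) and modulation of the
forward and backward inter-regional connections by the Good and Novel
inputs, and A is common to the GB and NF task segments.

Inversion is MAP estimation under zero-mean Gaussian shrinkage priors with
a Laplace (Gauss-Newton) approximation to the log model evidence; models
are compared by fixed-effects Bayesian selection over the evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .synth import ScanDesign

NODES = ("temporal_L", "temporal_R", "prefrontal_L", "prefrontal_R")
INPUTS = (
    "good_left", "good_right", "bad_left", "bad_right",
    "novel_left", "novel_right", "familiar_left", "familiar_right",
)
K = 4
M = 8

#: balloon-model constants (canonical prior means), fixed during inversion
KAPPA, GAMMA, TAU, ALPHA, E0 = 0.65, 0.41, 0.98, 0.32, 0.34

PRIOR_VAR = 0.25                   # shrinkage variance on free parameters
SELF_DECAY_PRIOR = 0.5             # prior mean of -A_ii, 1/s

# inter-regional (forward/backward) edges as (target, source) index pairs
_INTER_EDGES = (
    (2, 0),   # temporal_L -> prefrontal_L (forward)
    (0, 2),   # prefrontal_L -> temporal_L (backward)
    (3, 1),   # temporal_R -> prefrontal_R
    (1, 3),   # prefrontal_R -> temporal_R
)
#: inputs whose presentation modulates inter-regional connections
_MODULATING = ("good_left", "good_right", "novel_left", "novel_right")

#: contralateral target node per scheme: left-hemifield input drives the
#: right-hemisphere node and vice versa
_CONTRA_TEMPORAL = {"left": 1, "right": 0}
_CONTRA_PREFRONTAL = {"left": 3, "right": 2}


# ---------------------------------------------------------------------------
# model grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DcmModel:
    """One architecture: boolean masks for free entries of A, B_j, C.

    The diagonal of A is always free but parameterized as -exp(theta) so
    self-connections stay negative (stability prior).
    """

    name: str
    input_scheme: str               # temporal | prefrontal | double
    self_mod_scheme: str            # simple | GN | GBNF
    a_off: tuple[tuple[int, int], ...]
    b_entries: tuple[tuple[int, int, int], ...]   # (input, target, source)
    c_entries: tuple[tuple[int, int], ...]        # (node, input)

    @property
    def n_free(self) -> int:
        # 4 diagonal A + off-diagonal A + B + C + epsilon
        return 4 + len(self.a_off) + len(self.b_entries) + len(self.c_entries) + 1

    @property
    def parameter_names(self) -> list[str]:
        names = [f"A_{NODES[i]}_{NODES[i]}" for i in range(K)]
        names += [f"A_{NODES[i]}_{NODES[j]}" for i, j in self.a_off]
        names += [f"B[{INPUTS[u]}]_{NODES[i]}_{NODES[j]}" for u, i, j in self.b_entries]
        names += [f"C_{NODES[i]}_{INPUTS[u]}" for i, u in self.c_entries]
        names += ["epsilon"]
        return names

    def prior_mean(self) -> np.ndarray:
        theta = np.zeros(self.n_free)
        theta[:4] = np.log(SELF_DECAY_PRIOR)
        return theta

    def build(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """Materialize (A, B, C, epsilon) from a free-parameter vector."""
        A = np.zeros((K, K))
        B = np.zeros((M, K, K))
        C = np.zeros((K, M))
        k = 0
        for i in range(K):
            A[i, i] = -np.exp(theta[k]); k += 1
        for i, j in self.a_off:
            A[i, j] = theta[k]; k += 1
        for u, i, j in self.b_entries:
            B[u, i, j] = theta[k]; k += 1
        for i, u in self.c_entries:
            C[i, u] = theta[k]; k += 1
        eps = float(np.exp(theta[k]))
        return A, B, C, eps


def enumerate_models() -> list[DcmModel]:
    """The 3 x 3 grid of candidate architectures (9 models).

    Good and Novel presentations modulate the forward and backward
    connections of the hemisphere contralateral to the stimulated
    hemifield — the pathway the input drives; modulation of the undriven
    hemisphere's connections would be unidentifiable.
    """
    models = []
    mod_inputs = [INPUTS.index(u) for u in _MODULATING]
    b_inter = []
    for u in mod_inputs:
        hemi = INPUTS[u].rsplit("_", 1)[1]
        # left-hemifield stimuli drive the right hemisphere
        edges = ((3, 1), (1, 3)) if hemi == "left" else ((2, 0), (0, 2))
        b_inter.extend((u, i, j) for i, j in edges)
    b_inter = tuple(b_inter)
    for input_scheme in ("temporal", "prefrontal", "double"):
        c_entries: list[tuple[int, int]] = []
        for u, name in enumerate(INPUTS):
            hemi = name.rsplit("_", 1)[1]
            if input_scheme in ("temporal", "double"):
                c_entries.append((_CONTRA_TEMPORAL[hemi], u))
            if input_scheme in ("prefrontal", "double"):
                c_entries.append((_CONTRA_PREFRONTAL[hemi], u))
        for self_scheme in ("simple", "GN", "GBNF"):
            if self_scheme == "simple":
                b_self: tuple = ()
            elif self_scheme == "GN":
                b_self = tuple((u, i, i) for u in mod_inputs for i in range(K))
            else:
                b_self = tuple((u, i, i) for u in range(M) for i in range(K))
            models.append(
                DcmModel(
                    name=f"{input_scheme}/{self_scheme}",
                    input_scheme=input_scheme,
                    self_mod_scheme=self_scheme,
                    a_off=_INTER_EDGES,
                    b_entries=b_inter + b_self,
                    c_entries=tuple(c_entries),
                )
            )
    return models


def example_parameters(model: DcmModel, seed: int = 0) -> np.ndarray:
    """A plausible stable ground-truth parameter vector for simulations:
    moderate self-decay, excitatory forward and weakly inhibitory backward
    connections (negative prefrontal->temporal feedback), small seeded
    jitter on the modulations and inputs."""
    rng = np.random.default_rng(seed)
    theta = model.prior_mean()
    k = 4
    for idx, (i, j) in enumerate(model.a_off):
        forward = i in (2, 3)      # target is a prefrontal node
        theta[k + idx] = 0.30 if forward else -0.15
    base = k + len(model.a_off)
    for idx, (u, i, j) in enumerate(model.b_entries):
        if i == j:                  # self-modulation entries
            theta[base + idx] = rng.normal(0.0, 0.05)
        else:
            sign = 1.0 if i in (2, 3) else -1.0
            theta[base + idx] = sign * 0.20 + rng.normal(0.0, 0.05)
    base += len(model.b_entries)
    for idx in range(len(model.c_entries)):
        theta[base + idx] = 0.20 + rng.normal(0.0, 0.03)
    theta[-1] = 0.0                 # epsilon = 1
    return theta


# ---------------------------------------------------------------------------
# inputs from scan designs
# ---------------------------------------------------------------------------

def dcm_inputs(
    designs: list[ScanDesign], n_sub: int = 16
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Condition boxcars at the integration step for concatenated runs.

    Returns (patterns, pattern_idx, n_volumes, dt): ``patterns`` holds the
    distinct input vectors (rows, shape (P, m)), ``pattern_idx`` maps each
    fine integration step to a row, and dt = TR / n_sub.
    """
    trs = {d.tr_s for d in designs}
    if len(trs) != 1:
        raise ValueError("all designs must share a TR")
    tr = trs.pop()
    dt = tr / n_sub
    cols = []
    for d in designs:
        for t in d.block_types:
            u = np.zeros(M)
            if t != "base":
                u[INPUTS.index(t)] = 1.0
            cols.extend([u] * (d.trs_per_block * n_sub))
    U = np.array(cols)
    patterns, idx = np.unique(U, axis=0, return_inverse=True)
    n_vols = sum(d.n_volumes for d in designs)
    return patterns, idx.astype(np.int64), n_vols, dt


# ---------------------------------------------------------------------------
# forward model (numba)
# ---------------------------------------------------------------------------

_LOG1ME0 = np.log(1.0 - E0)


@njit(cache=True, fastmath=True)
def _deriv(y, Mm, cu, k, dy):
    """Stage derivative of the stacked state y = [z, s, f, v, q] per node.

    Outflow v**(1/alpha) and oxygen extraction 1-(1-E0)**(1/f) are written
    with a single pow/exp each; v**(1/alpha - 1) reuses the pow result.
    """
    ia = 1.0 / ALPHA
    for i in range(k):
        acc = cu[i]
        for j in range(k):
            acc += Mm[i, j] * y[j]
        z = y[i]
        s = y[k + i]
        f = max(y[2 * k + i], 1e-6)
        v = max(y[3 * k + i], 1e-6)
        q = y[4 * k + i]
        pv = v ** ia
        extraction = 1.0 - np.exp(_LOG1ME0 / f)
        dy[i] = acc
        dy[k + i] = z - KAPPA * s - GAMMA * (f - 1.0)
        dy[2 * k + i] = s
        dy[3 * k + i] = (f - pv) / TAU
        dy[4 * k + i] = (f * extraction / E0 - pv / v * q) / TAU


@njit(cache=True)
def _integrate(M_stack, cu_stack, pattern_idx, n_vols, n_sub, dt, eps):
    """RK4 integration of the bilinear neural + balloon system.

    State per node: neural z, vasodilatory signal s, flow f, volume v,
    deoxyhemoglobin q. The input pattern (hence the modulated connectivity
    matrix) is constant within each fine step. Output: (n_vols, K) MION
    readout -eps*(v-1) sampled at the end of each TR.
    """
    k = M_stack.shape[1]
    n_state = 5 * k
    y = np.zeros(n_state)
    for i in range(k):
        y[2 * k + i] = 1.0   # flow
        y[3 * k + i] = 1.0   # volume
        y[4 * k + i] = 1.0   # deoxyhemoglobin
    k1 = np.empty(n_state)
    k2 = np.empty(n_state)
    k3 = np.empty(n_state)
    k4 = np.empty(n_state)
    yt = np.empty(n_state)
    out = np.empty((n_vols, k))
    step = 0
    for vol in range(n_vols):
        for _ in range(n_sub):
            p = pattern_idx[step]
            Mm = M_stack[p]
            cu = cu_stack[p]
            _deriv(y, Mm, cu, k, k1)
            for i in range(n_state):
                yt[i] = y[i] + 0.5 * dt * k1[i]
            _deriv(yt, Mm, cu, k, k2)
            for i in range(n_state):
                yt[i] = y[i] + 0.5 * dt * k2[i]
            _deriv(yt, Mm, cu, k, k3)
            for i in range(n_state):
                yt[i] = y[i] + dt * k3[i]
            _deriv(yt, Mm, cu, k, k4)
            for i in range(n_state):
                y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            step += 1
        for i in range(k):
            out[vol, i] = -eps * (y[3 * k + i] - 1.0)
        # divergence guard: an unstable parameter set blows up the neural
        # states; cap the output so the objective stays finite and large
        if abs(y[0]) > 1.0e8 or abs(y[3 * k]) > 1.0e8:
            for rest in range(vol, n_vols):
                for i in range(k):
                    out[rest, i] = 1.0e6
            break
    return out


@njit(cache=True)
def _stability_penalty(M_stack):
    """Smooth hinge on the largest real eigenvalue part of every modulated
    connectivity matrix; keeps the optimizer inside the stable region."""
    pen = 0.0
    worst = -1e30
    for p in range(M_stack.shape[0]):
        lam = np.linalg.eigvals(M_stack[p].astype(np.complex128))
        m = np.max(lam.real)
        if m > worst:
            worst = m
        if m > -0.01:
            pen += 1.0e4 * (m + 0.01) ** 2
    return pen, worst


def _pattern_matrices(A, B, C, patterns):
    P = patterns.shape[0]
    M_stack = np.empty((P, K, K))
    cu_stack = np.empty((P, K))
    for p in range(P):
        M_stack[p] = A + np.tensordot(patterns[p], B, axes=(0, 0))
        cu_stack[p] = C @ patterns[p]
    return M_stack, cu_stack


def simulate_dcm(
    model: DcmModel,
    theta: np.ndarray,
    designs: list[ScanDesign],
    n_sub: int = 16,
    seed: int | None = None,
    snr: float | None = None,
) -> np.ndarray:
    """Node observations (n_volumes, 4) for given free parameters.

    Raises on an unstable system (some modulated connectivity matrix with
    an eigenvalue of nonnegative real part under extreme inputs). With
    ``seed`` and ``snr`` set, adds white observation noise with standard
    deviation std(signal)/snr.
    """
    A, B, C, eps = model.build(np.asarray(theta, float))
    patterns, idx, n_vols, dt = dcm_inputs(designs, n_sub)
    M_stack, cu_stack = _pattern_matrices(A, B, C, patterns)
    for p in range(patterns.shape[0]):
        lam = np.linalg.eigvals(M_stack[p])
        worst = lam[np.argmax(lam.real)]
        if worst.real >= 0:
            raise ValueError(
                f"unstable system: eigenvalue {worst:.4f} for input pattern {patterns[p]}"
            )
    y = _integrate(M_stack, cu_stack, idx, n_vols, n_sub, dt, eps)
    if seed is not None and snr is not None:
        rng = np.random.default_rng(seed)
        sigma = y.std() / snr
        y = y + rng.normal(0.0, sigma, y.shape)
    return y


# ---------------------------------------------------------------------------
# inversion: MAP + Laplace
# ---------------------------------------------------------------------------

@njit(cache=True)
def _neg_log_posterior(
    theta,
    a_off, b_entries, c_entries,
    patterns, pattern_idx, data, n_sub, dt,
    prior_mean, prior_prec,
):
    k = 4
    m = patterns.shape[1]
    A = np.zeros((k, k))
    B = np.zeros((m, k, k))
    C = np.zeros((k, m))
    t = 0
    for i in range(k):
        A[i, i] = -np.exp(min(theta[t], 5.0)); t += 1
    for e in range(a_off.shape[0]):
        A[a_off[e, 0], a_off[e, 1]] = theta[t]; t += 1
    for e in range(b_entries.shape[0]):
        B[b_entries[e, 0], b_entries[e, 1], b_entries[e, 2]] = theta[t]; t += 1
    for e in range(c_entries.shape[0]):
        C[c_entries[e, 0], c_entries[e, 1]] = theta[t]; t += 1
    eps = np.exp(min(theta[t], 5.0))

    P = patterns.shape[0]
    M_stack = np.empty((P, k, k))
    cu_stack = np.empty((P, k))
    for p in range(P):
        Mp = A.copy()
        for j in range(m):
            if patterns[p, j] != 0.0:
                Mp += patterns[p, j] * B[j]
        M_stack[p] = Mp
        cu_stack[p] = C @ patterns[p]

    pen, _ = _stability_penalty(M_stack)
    n_vols = data.shape[0]
    y = _integrate(M_stack, cu_stack, pattern_idx, n_vols, n_sub, dt, eps)
    sse = 0.0
    for i in range(n_vols):
        for j in range(k):
            d = y[i, j] - data[i, j]
            sse += d * d
    N = n_vols * k
    if not np.isfinite(sse) or sse <= 0.0:
        return 1.0e12
    sigma2 = sse / N
    nll = 0.5 * N * (np.log(2.0 * np.pi * sigma2) + 1.0)
    prior = 0.0
    for i in range(theta.shape[0]):
        d = theta[i] - prior_mean[i]
        prior += 0.5 * prior_prec[i] * d * d
    return nll + prior + pen


@njit(cache=True)
def _grad_fd(
    theta,
    a_off, b_entries, c_entries,
    patterns, pattern_idx, data, n_sub, dt,
    prior_mean, prior_prec,
):
    f0 = _neg_log_posterior(
        theta, a_off, b_entries, c_entries, patterns, pattern_idx, data,
        n_sub, dt, prior_mean, prior_prec,
    )
    d = theta.shape[0]
    g = np.empty(d)
    h = 1.0e-6
    for i in range(d):
        th = theta.copy()
        th[i] += h
        fi = _neg_log_posterior(
            th, a_off, b_entries, c_entries, patterns, pattern_idx, data,
            n_sub, dt, prior_mean, prior_prec,
        )
        g[i] = (fi - f0) / h
    return f0, g


@dataclass
class DcmFit:
    model: DcmModel
    theta: np.ndarray               # MAP free parameters
    log_evidence: float
    fitted: np.ndarray              # (n_vols, 4) model prediction at MAP
    sigma2: float
    posterior_cov: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    neg_log_posterior: float = np.nan

    @property
    def parameters(self) -> dict[str, float]:
        A, B, C, eps = self.model.build(self.theta)
        out = dict(zip(self.model.parameter_names, self.theta))
        out["epsilon"] = eps
        for i in range(K):
            out[f"A_{NODES[i]}_{NODES[i]}"] = A[i, i]
        return out


def fit_dcm(
    data: np.ndarray,
    model: DcmModel,
    designs: list[ScanDesign],
    seed: int = 0,
    n_starts: int = 8,
    n_sub: int = 16,
    maxiter: int = 150,
) -> DcmFit:
    """MAP inversion with seeded multi-start L-BFGS and Laplace evidence.

    The observation-noise variance is profiled out (maximum likelihood);
    the Laplace evidence uses a Gauss-Newton Hessian of the log joint.
    """
    data = np.asarray(data, float)
    d = model.n_free
    if data.size < 10 * d:
        raise ValueError(
            f"data has {data.size} points, need >= {10 * d} for {d} free parameters"
        )
    patterns, idx, n_vols, dt = dcm_inputs(designs, n_sub)
    if n_vols != data.shape[0]:
        raise ValueError("data length does not match the designs")

    a_off = np.array(model.a_off, np.int64).reshape(-1, 2)
    b_ent = np.array(model.b_entries, np.int64).reshape(-1, 3)
    c_ent = np.array(model.c_entries, np.int64).reshape(-1, 2)
    prior_mean = model.prior_mean()
    prior_prec = np.full(d, 1.0 / PRIOR_VAR)
    args = (a_off, b_ent, c_ent, patterns, idx, data, n_sub, dt, prior_mean, prior_prec)

    rng = np.random.default_rng(seed)
    best = None
    n_ok = 0
    for s in range(n_starts):
        x0 = prior_mean.copy()
        if s > 0:
            x0 = x0 + rng.normal(0.0, 0.1, d)
        res = minimize(
            lambda th: _grad_fd(th, *args),
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-5, "maxls": 8},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        return DcmFit(
            model=model, theta=prior_mean, log_evidence=-np.inf,
            fitted=np.zeros_like(data), sigma2=np.nan, converged=False,
        )
    theta = best.x

    A, B, C, eps = model.build(theta)
    M_stack, cu_stack = _pattern_matrices(A, B, C, patterns)
    fitted = _integrate(M_stack, cu_stack, idx, n_vols, n_sub, dt, eps)
    resid = fitted - data
    N = data.size
    sigma2 = float((resid**2).sum() / N)

    # Gauss-Newton Hessian: J^T J / sigma2 + prior precision
    J = np.empty((N, d))
    h = 1e-5
    for i in range(d):
        th = theta.copy()
        th[i] += h
        Ai, Bi, Ci, ei = model.build(th)
        Ms, cs = _pattern_matrices(Ai, Bi, Ci, patterns)
        yi = _integrate(Ms, cs, idx, n_vols, n_sub, dt, ei)
        J[:, i] = (yi - fitted).ravel() / h
    H = J.T @ J / sigma2 + np.diag(prior_prec)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        logdet = np.inf
    nll = 0.5 * N * (np.log(2.0 * np.pi * sigma2) + 1.0)
    dprior = theta - prior_mean
    log_prior = -0.5 * float(prior_prec @ dprior**2) - 0.5 * d * np.log(
        2.0 * np.pi * PRIOR_VAR
    )
    log_evidence = -nll + log_prior + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet
    try:
        post_cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:   # pragma: no cover
        post_cov = None
    return DcmFit(
        model=model,
        theta=theta,
        log_evidence=float(log_evidence),
        fitted=fitted,
        sigma2=sigma2,
        posterior_cov=post_cov,
        converged=n_ok > 0,
        neg_log_posterior=float(best.fun),
    )


# ---------------------------------------------------------------------------
# model selection and edge summaries
# ---------------------------------------------------------------------------

def model_select(fits: list[DcmFit]) -> tuple[DcmFit, dict]:
    """Fixed-effects Bayesian model selection over the fitted grid.

    Posterior model probabilities are the softmax of log evidences under a
    uniform model prior; ties break toward the model with fewer free
    parameters. Flagged (non-converged) fits are excluded with a warning.
    """
    import warnings

    valid = [f for f in fits if f.converged and np.isfinite(f.log_evidence)]
    if len(valid) < len(fits):
        warnings.warn(f"excluding {len(fits) - len(valid)} flagged fits")
    if not valid:
        raise ValueError("no valid fits to select among")
    ev = np.array([f.log_evidence for f in valid])
    w = np.exp(ev - ev.max())
    prob = w / w.sum()
    order = sorted(
        range(len(valid)), key=lambda i: (-ev[i], valid[i].model.n_free)
    )
    best = valid[order[0]]
    table = {
        f.model.name: {
            "log_evidence": float(f.log_evidence),
            "probability": float(p),
            "n_free": f.model.n_free,
        }
        for f, p in zip(valid, prob)
    }
    return best, table


def summarize_edges(fit: DcmFit, conditions: tuple[str, ...] = ("good", "novel")) -> dict:
    """Effective inter-regional weights per condition in contra/ipsi form.

    For each condition the effective weight of a directed edge during a
    left (right) presentation is the A entry plus that input's B entry;
    weights are averaged across left/right presentations after relabeling
    hemispheres as contralateral/ipsilateral to the stimulus.
    """
    A, B, _, _ = fit.model.build(fit.theta)
    uidx = {name: i for i, name in enumerate(INPUTS)}
    # edge roles per presentation side: hemisphere contralateral to a left
    # stimulus is the right one
    out = {}
    for cond in conditions:
        edges = {}
        for direction, pairs in (
            ("temporal->prefrontal", {"L": (2, 0), "R": (3, 1)}),
            ("prefrontal->temporal", {"L": (0, 2), "R": (1, 3)}),
        ):
            for role in ("contra", "ipsi"):
                vals = []
                for side, contra_h in (("left", "R"), ("right", "L")):
                    hemi = contra_h if role == "contra" else ("L" if contra_h == "R" else "R")
                    i, j = pairs[hemi]
                    u = uidx[f"{cond}_{side}"]
                    vals.append(A[i, j] + B[u, i, j])
                edges[f"{direction}:{role}"] = float(np.mean(vals))
        out[cond] = edges
    signs = {
        cond: {k: ("-" if v < 0 else "+") for k, v in edges.items()}
        for cond, edges in out.items()
    }
    return {"weights": out, "signs": signs}
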