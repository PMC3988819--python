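"""Likelihoods and maximum-likelihood fitting of Brownian-motion and
single/multi-regime Ornstein-Uhlenbeck trait models on non-ultrametric
trees, with per-tip measurement error.

Model families
--------------
BM1    Brownian motion: rate ``beta`` and root value ``Z0``.
OU1    single-optimum OU: attraction ``alpha``, rate ``beta``, optimum ``theta``.
OUM    multi-regime optima ``theta_r``; shared ``alpha`` and ``beta``.
OUMV   multi-regime ``theta_r`` and rates ``beta_r``; shared ``alpha``.
OUMA   multi-regime ``theta_r`` and attractions ``alpha_r``; shared ``beta``.
OUMVA  all three regime-specific.

The root state is non-stationary and fixed: either aliased to the basal
regime's optimum (``root_equals_basal_theta``) or a separate parameter
(``separate_Z0``). Conditional on the variance parameters, the optima and
root value enter the expectation linearly and are solved by generalized
least squares; their standard errors come from the GLS covariance.

All covariance/mean computations use a single forward recursion along the
tree in which every exponential has a non-positive argument, so arbitrarily
strong attraction and the near-BM limit (``alpha -> 0``) are both handled
stably (``expm1`` for the small-``alpha`` regime).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import linalg, optimize

from .errors import NumericalError, ValidationError
from .io_core import TraitVector
from .seeding import rng_for
from .tree import CalibratedTree, RegimeMap, single_regime_map

FAMILIES = ("BM1", "OU1", "OUM", "OUMV", "OUMA", "OUMVA")
ROOT_MODES = ("root_equals_basal_theta", "separate_Z0")

_ALPHA_MIN = 1e-6  # 1/Ma; below this OU is numerically indistinguishable from BM
_ALPHA_MAX = 10.0
_BETA_MIN = 1e-10
_BETA_MAX = 10.0
_PENALTY = 1e10  # objective value for infeasible variance parameters


# ---------------------------------------------------------------------------
# Structure: everything about (tree, painting) that parameters don't change
# ---------------------------------------------------------------------------

class OUStructure:
    """Preprocessed tree + regime painting for fast repeated likelihoods."""

    def __init__(self, tree: CalibratedTree, regime_map: Optional[RegimeMap] = None):
        if regime_map is None:
            regime_map = single_regime_map(tree)
        regime_map.validate()
        if regime_map.tree is not tree:
            raise ValidationError("regime map is bound to a different tree instance")
        self.tree = tree
        self.rmap = regime_map
        self.regimes = list(regime_map.regimes)
        self.n_regimes = len(self.regimes)
        r_index = {lab: j for j, lab in enumerate(self.regimes)}
        self.root_regime_idx = r_index[regime_map.root_regime]

        nodes = list(tree.preorder())
        # preorder ids coincide with preorder position (Tree.reindex)
        self.n_nodes = len(nodes)
        self.parent_idx = np.array(
            [-1] + [n.parent.id for n in nodes[1:]], dtype=np.intp
        )
        # flattened branch segments, parent-side first within each branch;
        # branch b corresponds to node index b+1
        dts, regs, ptr = [], [], [0]
        for n in nodes[1:]:
            for s0, e0, lab in regime_map.segments[n.id]:
                dts.append(e0 - s0)
                regs.append(r_index[lab])
            ptr.append(len(dts))
        self.seg_dt = np.asarray(dts, dtype=float)
        self.seg_reg = np.asarray(regs, dtype=np.intp)
        self.seg_ptr = np.asarray(ptr, dtype=np.intp)
        self.seg_branch = np.repeat(
            np.arange(self.n_nodes - 1), np.diff(self.seg_ptr)
        )

        self.tips = tree.tips()
        self.tip_order = [t.label for t in self.tips]
        self.tip_idx = np.array([t.id for t in self.tips], dtype=np.intp)
        self.n = len(self.tips)
        self.mrca_idx = _mrca_index_matrix(tree, self.tips)
        self.S = tree.shared_times(self.tip_order)  # BM covariance, unit rate

    # -- parameter expansion -------------------------------------------------
    def expand(self, values: Union[float, Mapping[str, float]]) -> np.ndarray:
        if isinstance(values, Mapping):
            try:
                return np.array([float(values[r]) for r in self.regimes])
            except KeyError as exc:
                raise ValidationError(f"missing parameter for regime {exc}") from exc
        return np.full(self.n_regimes, float(values))

    # -- core recursion ------------------------------------------------------
    def moments(self, alpha: np.ndarray, beta: np.ndarray):
        """Per-node accumulated attraction ``A``, path variance ``Vs`` and
        mean-weight rows ``W`` (columns: Z0, then one per regime).

        Along each branch segment of duration dt in regime r the state
        transforms as ``X_end = f X_start + (1-f) theta_r`` in expectation
        (``f = exp(-alpha_r dt)``) with innovation variance
        ``(beta_r / 2 alpha_r)(1 - f^2)``.
        """
        if np.any(alpha <= 0):
            raise ValidationError("OU recursion requires alpha > 0 (use BM for alpha = 0)")
        adt = alpha[self.seg_reg] * self.seg_dt
        cs = np.cumsum(adt)
        end_cs = cs[self.seg_ptr[1:] - 1]
        suffix = end_cs[self.seg_branch] - cs  # attraction below each segment
        decay_after = np.exp(-suffix)
        w_contrib = -np.expm1(-adt) * decay_after
        vs_contrib = (
            -(beta[self.seg_reg] / (2.0 * alpha[self.seg_reg]))
            * np.expm1(-2.0 * adt)
            * decay_after**2
        )
        nb = self.n_nodes - 1
        a_branch = np.add.reduceat(adt, self.seg_ptr[:-1]) if nb else np.zeros(0)
        g_branch = np.zeros(nb)
        np.add.at(g_branch, self.seg_branch, vs_contrib)
        h_branch = np.zeros((nb, self.n_regimes))
        np.add.at(h_branch, (self.seg_branch, self.seg_reg), w_contrib)
        f_branch = np.exp(-a_branch)

        A = np.zeros(self.n_nodes)
        Vs = np.zeros(self.n_nodes)
        W = np.zeros((self.n_nodes, 1 + self.n_regimes))
        W[0, 0] = 1.0
        parent = self.parent_idx
        for b in range(nb):
            i = b + 1
            p = parent[i]
            A[i] = A[p] + a_branch[b]
            Vs[i] = Vs[p] * f_branch[b] ** 2 + g_branch[b]
            W[i] = W[p] * f_branch[b]
            W[i, 1:] += h_branch[b]
        return A, Vs, W

    def covariance(self, alpha: np.ndarray, beta: np.ndarray,
                   se: Optional[np.ndarray] = None) -> np.ndarray:
        A, Vs, _ = self.moments(alpha, beta)
        E = A[self.tip_idx]
        V = np.exp(2.0 * A[self.mrca_idx] - E[:, None] - E[None, :]) * Vs[self.mrca_idx]
        if se is not None:
            V = V + np.diag(np.asarray(se, dtype=float) ** 2)
        return V

    def mean_weights(self, alpha: np.ndarray, beta: Optional[np.ndarray] = None) -> np.ndarray:
        if beta is None:
            beta = np.ones(self.n_regimes)
        _, _, W = self.moments(alpha, beta)
        return W[self.tip_idx]


def _mrca_index_matrix(tree: CalibratedTree, tips) -> np.ndarray:
    idx = {t.label: i for i, t in enumerate(tips)}
    n = len(tips)
    M = np.empty((n, n), dtype=np.intp)
    for t in tips:
        M[idx[t.label], idx[t.label]] = t.id
    below: dict[int, list[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[node.id] = [node.label]
            continue
        groups = [below[c.id] for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        M[idx[a], idx[b]] = node.id
                        M[idx[b], idx[a]] = node.id
        below[node.id] = [x for g in groups for x in g]
    return M


# ---------------------------------------------------------------------------
# Public likelihood primitives
# ---------------------------------------------------------------------------

def bm_loglik(
    tree: CalibratedTree,
    traits: TraitVector,
    beta: float,
    z0: float,
    mserr: bool = True,
) -> float:
    """Log-likelihood of Brownian motion: y ~ N(Z0 1, beta * S (+ diag se^2))
    with S the shared root-to-MRCA path-time matrix."""
    if beta <= 0:
        raise ValidationError("beta must be > 0")
    order = [t.label for t in tree.tips()]
    y, se = traits.arrays(order)
    S = tree.shared_times(order)
    V = beta * S
    if mserr:
        V = V + np.diag(se**2)
    r = y - z0
    return _mvn_loglik(V, r)


def _mvn_loglik(V: np.ndarray, resid: np.ndarray) -> float:
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise NumericalError(f"covariance not positive-definite: {exc}") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = float(resid @ linalg.cho_solve(cf, resid))
    n = len(resid)
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


def ou_mean_weights(
    tree: CalibratedTree,
    regime_map: RegimeMap,
    alpha: Union[float, Mapping[str, float]],
) -> tuple[list[str], list[str], np.ndarray]:
    """Per-tip weights of (Z0, theta_r, ...) in the OU expectation.

    Returns ``(tip_order, column_names, weights)``; every row sums to 1.
    The Z0 weight of tip i is ``exp(-A_i(T_i))`` (accumulated attraction on
    its root path) and each regime's weight telescopes over the path
    segments painted with that regime.
    """
    struct = OUStructure(tree, regime_map)
    a = struct.expand(alpha)
    W = struct.mean_weights(a)
    return struct.tip_order, ["Z0"] + struct.regimes, W


def ou_covariance(
    tree: CalibratedTree,
    regime_map: RegimeMap,
    alpha: Union[float, Mapping[str, float]],
    beta: Union[float, Mapping[str, float]],
    se: Optional[Sequence[float]] = None,
) -> tuple[list[str], np.ndarray]:
    """Analytic tip covariance of the (possibly multi-regime) OU process.

    ``V_ij = exp(-(A_i - A_u) - (A_j - A_u)) * Vs_u`` with ``u`` the MRCA,
    ``A`` the accumulated attraction along root paths and ``Vs_u`` the
    variance accumulated along the shared root-to-MRCA path. ``se`` adds
    measurement variance to the diagonal.
    """
    struct = OUStructure(tree, regime_map)
    a, b = struct.expand(alpha), struct.expand(beta)
    if np.any(a <= 0):
        raise ValidationError("alpha must be > 0 in OU covariance; use BM for alpha = 0")
    if np.any(b <= 0):
        raise ValidationError("beta must be > 0")
    se_arr = None if se is None else np.asarray(se, dtype=float)
    return struct.tip_order, struct.covariance(a, b, se_arr)


# ---------------------------------------------------------------------------
# Model specification and fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A model family plus regime painting, root treatment and error switch."""

    family: str
    regime_map: Optional[RegimeMap] = None
    root_mode: str = "root_equals_basal_theta"
    mserr: bool = True
    name: Optional[str] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown model family {self.family!r}")
        if self.root_mode not in ROOT_MODES:
            raise ValidationError(f"unknown root mode {self.root_mode!r}")
        if self.family in ("OUM", "OUMV", "OUMA", "OUMVA"):
            if self.regime_map is None or len(self.regime_map.regimes) < 2:
                raise ValidationError(f"{self.family} requires a regime map with >= 2 regimes")
        if self.name is None:
            tag = self.family
            if self.regime_map is not None and self.family not in ("BM1", "OU1"):
                tag += f"_{len(self.regime_map.regimes)}"
            if self.root_mode == "separate_Z0":
                tag += "_root"
            self.name = tag


@dataclass
class FitResult:
    """Maximum-likelihood fit of one ModelSpec on one calibrated tree."""

    name: str
    family: str
    root_mode: str
    regimes: list[str]
    n: int
    k: int
    lnL: float
    aicc: float
    alpha: dict[str, float]
    beta: dict[str, float]
    theta: dict[str, float]
    theta_se: dict[str, float]
    z0: Optional[float]
    z0_se: Optional[float]
    converged: bool
    n_starts_converged: int = 0
    #: full-information standard errors (joint observed information over
    #: variance and mean parameters); unlike the conditional GLS ``theta_se``
    #: these propagate the uncertainty in alpha and beta
    theta_se_full: dict[str, float] = field(default_factory=dict)
    z0_se_full: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "family": self.family,
            "root_mode": self.root_mode,
            "regimes": self.regimes,
            "n": self.n,
            "k": self.k,
            "lnL": self.lnL,
            "AICc": self.aicc,
            "alpha": self.alpha,
            "beta": self.beta,
            "theta": self.theta,
            "theta_se": self.theta_se,
            "Z0": self.z0,
            "Z0_se": self.z0_se,
            "theta_se_full": self.theta_se_full,
            "Z0_se_full": self.z0_se_full,
            "converged": self.converged,
        }


def _family_structure(family: str):
    """(alpha shared?, beta shared?) per family."""
    return {
        "OU1": (True, True),
        "OUM": (True, True),
        "OUMV": (True, False),
        "OUMA": (False, True),
        "OUMVA": (False, False),
    }[family]


def fit_model(
    spec: ModelSpec,
    tree: CalibratedTree,
    traits: TraitVector,
    seed: int = 0,
    n_starts: int = 8,
) -> FitResult:
    """Fit one model by bounded multi-start optimization of the profile
    likelihood over log-transformed variance parameters; optima/root value
    solved by GLS conditional on (alpha, beta), with standard errors from
    the GLS covariance. Reproducible under a fixed seed."""
    order = [t.label for t in tree.tips()]
    missing = [t for t in order if t not in traits.values]
    if missing:
        raise ValidationError(f"traits missing for tips: {missing[:5]}...")
    y, se_arr = traits.arrays(order)
    se = se_arr if spec.mserr else None
    n = len(y)

    if spec.family == "BM1":
        return _fit_bm(spec, tree, y, se, seed, n_starts)

    if spec.family == "OU1":
        struct = OUStructure(tree, single_regime_map(tree, label="all"))
    else:
        struct = OUStructure(tree, spec.regime_map)
    alpha_shared, beta_shared = _family_structure(spec.family)
    R = struct.n_regimes
    n_a = 1 if alpha_shared else R
    n_b = 1 if beta_shared else R

    fold_root = spec.root_mode == "root_equals_basal_theta"
    col_root = struct.root_regime_idx + 1  # column of the basal regime in W

    def design(Wfull: np.ndarray) -> np.ndarray:
        if fold_root:
            W = Wfull[:, 1:].copy()
            W[:, struct.root_regime_idx] += Wfull[:, 0]
            return W
        return Wfull

    def unpack(x: np.ndarray):
        a = np.exp(x[:n_a])
        b = np.exp(x[n_a:])
        alpha = np.full(R, a[0]) if alpha_shared else a
        beta = np.full(R, b[0]) if beta_shared else b
        return alpha, beta

    def build_vw(x: np.ndarray):
        alpha, beta = unpack(x)
        A, Vs, Wfull = struct.moments(alpha, beta)
        E = A[struct.tip_idx]
        V = np.exp(2.0 * A[struct.mrca_idx] - E[:, None] - E[None, :]) * Vs[struct.mrca_idx]
        if se is not None:
            V = V + np.diag(se**2)
        return V, design(Wfull[struct.tip_idx])

    def neg_loglik(x: np.ndarray) -> float:
        V, W = build_vw(x)
        out = _profile_gls(V, W, y)
        if out is None:
            return _PENALTY  # finite: keeps quasi-Newton finite differences sane
        return -out[0]

    k = n_a + n_b + (R if fold_root else R + 1)
    if n < k + 2:
        raise ValidationError(f"need at least k+2 = {k + 2} tips for {spec.name}")

    depth = tree.max_depth()
    x_best, f_best, n_ok = _multistart(
        neg_loglik, n_a, n_b, y, depth, seed, n_starts, spec.name
    )
    if x_best is None:
        return _failed_result(spec, struct, n, k)

    alpha, beta = unpack(x_best)
    V, W = build_vw(x_best)
    lnL, coef, coef_cov = _profile_gls(V, W, y)
    gls_se = np.sqrt(np.diag(coef_cov))
    se_full = _joint_hessian_se(build_vw, y, x_best, coef)
    se_full = gls_se if se_full is None else np.maximum(se_full, gls_se)

    theta = {}
    theta_se = {}
    theta_se_full = {}
    if fold_root:
        for j, lab in enumerate(struct.regimes):
            theta[lab] = float(coef[j])
            theta_se[lab] = float(gls_se[j])
            theta_se_full[lab] = float(se_full[j])
        root_lab = struct.rmap.root_regime
        z0, z0_se, z0_se_full = theta[root_lab], theta_se[root_lab], theta_se_full[root_lab]
    else:
        z0, z0_se, z0_se_full = float(coef[0]), float(gls_se[0]), float(se_full[0])
        for j, lab in enumerate(struct.regimes):
            theta[lab] = float(coef[j + 1])
            theta_se[lab] = float(gls_se[j + 1])
            theta_se_full[lab] = float(se_full[j + 1])

    return FitResult(
        name=spec.name,
        family=spec.family,
        root_mode=spec.root_mode,
        regimes=struct.regimes,
        n=n,
        k=k,
        lnL=float(lnL),
        aicc=aicc(float(lnL), k, n),
        alpha={lab: float(alpha[j]) for j, lab in enumerate(struct.regimes)},
        beta={lab: float(beta[j]) for j, lab in enumerate(struct.regimes)},
        theta=theta,
        theta_se=theta_se,
        z0=z0,
        z0_se=z0_se,
        converged=True,
        n_starts_converged=n_ok,
        theta_se_full=theta_se_full,
        z0_se_full=z0_se_full,
    )


def _fit_bm(spec, tree, y, se, seed, n_starts) -> FitResult:
    order = [t.label for t in tree.tips()]
    S = tree.shared_times(order)
    n = len(y)
    ones = np.ones((n, 1))

    def build_vw(x):
        V = float(np.exp(x[0])) * S
        if se is not None:
            V = V + np.diag(se**2)
        return V, ones

    def neg_loglik(x):
        out = _profile_gls(build_vw(x)[0], ones, y)
        return _PENALTY if out is None else -out[0]

    depth = tree.max_depth()
    x_best, f_best, n_ok = _multistart(neg_loglik, 0, 1, y, depth, seed, n_starts, spec.name)
    if x_best is None:
        return _failed_result(spec, None, n, 2)
    beta = float(np.exp(x_best[0]))
    V, _ = build_vw(x_best)
    lnL, coef, coef_cov = _profile_gls(V, ones, y)
    z0_se = float(np.sqrt(coef_cov[0, 0]))
    se_full = _joint_hessian_se(build_vw, y, x_best, coef)
    z0_se_full = z0_se if se_full is None else float(max(se_full[0], z0_se))
    return FitResult(
        name=spec.name, family="BM1", root_mode=spec.root_mode, regimes=[],
        n=n, k=2, lnL=float(lnL), aicc=aicc(float(lnL), 2, n),
        alpha={}, beta={"all": beta}, theta={}, theta_se={},
        z0=float(coef[0]), z0_se=z0_se,
        converged=True, n_starts_converged=n_ok, z0_se_full=z0_se_full,
    )


def _failed_result(spec, struct, n, k) -> FitResult:
    regimes = struct.regimes if struct is not None else []
    return FitResult(
        name=spec.name, family=spec.family, root_mode=spec.root_mode,
        regimes=regimes, n=n, k=k, lnL=float("nan"), aicc=float("nan"),
        alpha={}, beta={}, theta={}, theta_se={}, z0=None, z0_se=None,
        converged=False, n_starts_converged=0,
    )


def _joint_hessian_se(build_vw, y: np.ndarray, x_var: np.ndarray,
                      coef: np.ndarray) -> Optional[np.ndarray]:
    """Standard errors of the mean parameters from the joint observed
    information over (log variance parameters, mean parameters).

    The conditional GLS covariance treats (alpha, beta) as known and can
    understate the optimum uncertainty when alpha is weakly identified (the
    theta/alpha likelihood ridge); inverting the full Hessian propagates
    that uncertainty. Central differences with fixed steps (0.05 on log
    variance parameters, 0.01 on mean parameters). Returns None when the
    information matrix is not positive-definite at the optimum.
    """
    m = len(x_var)
    p0 = np.concatenate([x_var, coef])
    steps = np.concatenate([np.full(m, 0.05), np.full(len(coef), 0.01)])

    def negll(p):
        V, W = build_vw(p[:m])
        try:
            cf = linalg.cho_factor(V, lower=True)
        except (linalg.LinAlgError, ValueError):
            return np.nan
        r = y - W @ p[m:]
        n = len(y)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        quad = float(r @ linalg.cho_solve(cf, r))
        return 0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)

    npar = len(p0)
    H = np.empty((npar, npar))
    for i in range(npar):
        for j in range(i, npar):
            hi, hj = steps[i], steps[j]
            pp = p0.copy(); pp[i] += hi; pp[j] += hj
            pm = p0.copy(); pm[i] += hi; pm[j] -= hj
            mp = p0.copy(); mp[i] -= hi; mp[j] += hj
            mm = p0.copy(); mm[i] -= hi; mm[j] -= hj
            H[i, j] = H[j, i] = (negll(pp) - negll(pm) - negll(mp) + negll(mm)) / (
                4.0 * hi * hj
            )
    if not np.all(np.isfinite(H)):
        return None
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)[m:]
    if np.any(d <= 0):
        return None
    return np.sqrt(d)


def _profile_gls(V: np.ndarray, W: np.ndarray, y: np.ndarray):
    """lnL, GLS coefficients and their covariance for y ~ N(W c, V)."""
    try:
        cf = linalg.cho_factor(V, lower=True)
    except (linalg.LinAlgError, ValueError):
        return None
    Vi_W = linalg.cho_solve(cf, W)
    Vi_y = linalg.cho_solve(cf, y)
    XtViX = W.T @ Vi_W
    # a numerically singular design (e.g. Z0 and theta columns collapsing in
    # the alpha -> 0 limit of a separate-root model) is unidentifiable
    if np.linalg.cond(XtViX) > 1e12:
        return None
    try:
        coef_cov = linalg.inv(XtViX)
    except linalg.LinAlgError:
        return None
    coef = coef_cov @ (W.T @ Vi_y)
    r = y - W @ coef
    quad = float(r @ linalg.cho_solve(cf, r))
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    n = len(y)
    lnL = -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)
    if not np.isfinite(lnL):
        return None
    return lnL, coef, coef_cov


def _multistart(neg_loglik, n_a, n_b, y, depth, seed, n_starts, tag):
    """Seeded multi-start bounded quasi-Newton over log parameters.

    Alpha starts span phylogenetic half-lives from 1 Ma to 10x tree depth;
    beta starts scale the trait variance by the tree depth, jittered.
    """
    rng = rng_for(seed, "fit", tag)
    var_y = max(float(np.var(y)), 1e-8)
    beta0 = var_y / depth
    half_lives = np.geomspace(1.0, 10.0 * depth, n_starts)
    bounds = [(math.log(_ALPHA_MIN), math.log(_ALPHA_MAX))] * n_a + [
        (math.log(_BETA_MIN), math.log(_BETA_MAX))
    ] * n_b
    best_x, best_f, n_ok = None, np.inf, 0
    for s in range(n_starts):
        a0 = math.log(2.0) / half_lives[s]
        x0 = np.concatenate(
            [
                np.log(np.full(n_a, a0)) + 0.2 * rng.standard_normal(n_a),
                np.log(np.full(n_b, beta0)) + 0.4 * rng.standard_normal(n_b),
            ]
        )
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = optimize.minimize(
                neg_loglik, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
            )
        except (NumericalError, FloatingPointError):
            continue
        if np.isfinite(res.fun) and res.fun < 0.1 * _PENALTY:
            n_ok += 1
            if res.fun < best_f:
                best_f, best_x = res.fun, res.x
    return best_x, best_f, n_ok


# ---------------------------------------------------------------------------
# Information criteria and derived quantities
# ---------------------------------------------------------------------------

def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValidationError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(scores: Sequence[float]) -> np.ndarray:
    """Normalized relative likelihoods exp(-delta/2) / sum."""
    s = np.asarray(scores, dtype=float)
    delta = s - np.nanmin(s)
    w = np.exp(-0.5 * delta)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


def half_life(alpha: float) -> float:
    """Phylogenetic half-life ln(2)/alpha (Ma): the time an OU process takes
    to erase half the phylogenetic covariance between sister lineages."""
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    return math.inf if alpha == 0 else math.log(2.0) / alpha


def trend_coefficient(alpha: float, theta: float, theta_se: float = 0.0):
    """Equivalent BM trend coefficient mu = alpha * theta (log10(m)/Ma) with
    bounds alpha * (theta -+ 2 se); the alpha -> 0 limit of an OU model with
    a distant optimum is BM with constant drift mu."""
    mu = alpha * theta
    return mu, alpha * (theta - 2.0 * theta_se), alpha * (theta + 2.0 * theta_se)


def theta_meters(theta_log10_m: float) -> float:
    """Back-transform a log10-metre optimum to metres."""
    return 10.0 ** theta_log10_m


def derived_quantities(fit: FitResult) -> dict:
    """Half-lives, trend coefficients and metre-scale optima for one fit."""
    out = {"half_life": {}, "mu": {}, "mu_lo": {}, "mu_hi": {}, "theta_m": {}}
    for lab in fit.regimes:
        a = fit.alpha.get(lab)
        th = fit.theta.get(lab)
        if a is not None:
            out["half_life"][lab] = half_life(a)
        if a is not None and th is not None:
            mu, lo, hi = trend_coefficient(a, th, fit.theta_se.get(lab, 0.0))
            out["mu"][lab] = mu
            out["mu_lo"][lab] = lo
            out["mu_hi"][lab] = hi
        if th is not None:
            out["theta_m"][lab] = theta_meters(th)
    if fit.z0 is not None:
        out["Z0_m"] = theta_meters(fit.z0)
    return out
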