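"""Multispecies occupancy model with multivariate-Bernoulli latent states.

The joint presence/absence vector z_i of S species at site i takes one of
2^S states. Each state's probability is a softmax over sums of *natural
parameters*: first-order terms f_s (one per species), second-order terms
f_jk (one per pair), with the all-absent state as the zero reference and
all orders above two fixed at zero. Natural parameters and per-species
detection probabilities are linear in covariates (logit scale for
detection). The observed-data likelihood marginalizes the latent state:

    L_i = sum_z  Psi_z(i) * prod_s  [ z_s = 1 : prod_t p_sit^y (1-p_sit)^(1-y)
                                      z_s = 0 : 1{no detections of s at i} ]

with occasions lacking effort contributing nothing. Fitting is by maximum
likelihood (L-BFGS with the analytic score, obtained by posterior-weighting
the complete-data score over states); the covariance of the estimates is
the inverse of the numerically differentiated observed information.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp

from .camdata import CovariateTable, DetectionHistory, LOCKDOWN_LEVELS, apply_moments
from .design import build_design

__all__ = [
    "StateSpace", "ModelStructure", "FittedMSOM",
    "enumerate_states", "state_probs", "marginal_occupancy",
    "conditional_occupancy", "detection_prob", "site_neg_loglik",
    "fit_msom", "predict_occupancy",
]


# ---------------------------------------------------------------------------
# State space


@dataclass(frozen=True)
class StateSpace:
    """The 2^S joint presence/absence states, in binary-counting order.

    Species s (0-based) is bit s, so state index b has species s present
    iff (b >> s) & 1. State 0 is the all-absent vector.
    """

    S: int
    states: np.ndarray  # (2^S, S) of 0/1

    def __len__(self) -> int:
        return 2 ** self.S

    def index_of(self, z) -> int:
        z = np.asarray(z, dtype=int)
        return int((z << np.arange(self.S)).sum())


def enumerate_states(S: int) -> StateSpace:
    if not (1 <= S <= 10):
        raise ValueError("S must be between 1 and 10")
    idx = np.arange(2 ** S)[:, None]
    states = (idx >> np.arange(S)[None, :]) & 1
    return StateSpace(S, states.astype(np.int8))


def natural_param_keys(S: int) -> list[str]:
    """Canonical ordering of natural-parameter labels: f1..fS, then pairs."""
    keys = [f"f{i + 1}" for i in range(S)]
    keys += [f"f{i + 1}{j + 1}" for i, j in itertools.combinations(range(S), 2)]
    return keys


def _key_species(key: str) -> tuple[int, ...]:
    return tuple(int(c) - 1 for c in key[1:])


def _inclusion_matrix(space: StateSpace, keys: list[str]) -> np.ndarray:
    """(2^S, n_keys) indicator: natural parameter `key` enters state z's sum."""
    cols = []
    for key in keys:
        inc = np.ones(len(space))
        for s in _key_species(key):
            inc = inc * space.states[:, s]
        cols.append(inc)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Structures


@dataclass
class ModelStructure:
    """Symbolic model specification.

    ``occ`` maps natural-parameter labels ('f1', 'f12', ...) to covariate
    term lists (intercept implicit); a value of None (or a missing
    second-order key) fixes that parameter to zero. All first-order keys
    must be present. ``det`` maps each species to its detection term list.
    """

    species: tuple[str, ...]
    occ: dict[str, list[str] | None]
    det: dict[str, list[str]]
    label: str = ""

    def __post_init__(self):
        S = len(self.species)
        keys = set(natural_param_keys(S))
        for k in self.occ:
            if k not in keys:
                raise ValueError(f"unknown natural parameter {k!r} for S={S}")
        for i in range(S):
            if self.occ.get(f"f{i + 1}") is None:
                raise ValueError(f"first-order parameter f{i + 1} must be modelled")
        for sp in self.species:
            if sp not in self.det:
                raise ValueError(f"no detection formula for species {sp!r}")

    @classmethod
    def from_formulas(cls, species: tuple[str, ...], formulas: list[str],
                      label: str = "") -> "ModelStructure":
        """Build a structure from formula strings.

        Natural parameters are declared as ``"f1 ~ veg + ele + I(ele^2)"``
        (an omitted second-order key stays fixed at 0) and detection as
        ``"det.marten ~ jdate + I(jdate^2)"``; ``"~ 1"`` is intercept-only.
        """
        from .design import parse_formula
        occ: dict[str, list[str] | None] = {}
        det: dict[str, list[str]] = {}
        for f in formulas:
            lhs, terms = parse_formula(f)
            if lhs.startswith("det."):
                det[lhs[4:]] = terms
            else:
                occ[lhs] = terms
        for sp in species:
            det.setdefault(sp, [])
        return cls(tuple(species), occ, det, label=label)

    @property
    def free_keys(self) -> list[str]:
        return [k for k in natural_param_keys(len(self.species))
                if self.occ.get(k) is not None]

    def describe(self) -> str:
        occ = "; ".join(f"{k} ~ 1 + {' + '.join(v)}" if v else f"{k} ~ 1"
                        for k, v in self.occ.items() if v is not None)
        return f"{self.label or 'structure'}: {occ}"


# ---------------------------------------------------------------------------
# Elementary probability operations


def state_probs(f: dict[str, float] | np.ndarray, space: StateSpace) -> np.ndarray:
    """Softmax state probabilities from natural-parameter values.

    ``f`` is a dict keyed by 'f1'...'f12'... (missing keys are zero) or an
    array aligned with ``natural_param_keys``. The all-absent state has
    linear predictor 0.
    """
    keys = natural_param_keys(space.S)
    if isinstance(f, dict):
        vals = np.array([float(f.get(k, 0.0)) for k in keys])
    else:
        vals = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("natural parameters must be finite")
    eta = _inclusion_matrix(space, keys) @ vals
    psi = np.exp(eta - logsumexp(eta))
    return psi / psi.sum()


def marginal_occupancy(psi: np.ndarray, s: int, space: StateSpace) -> float:
    """P(species s present) = sum of state probabilities with z_s = 1."""
    if not (0 <= s < space.S):
        raise ValueError(f"species index {s} out of range")
    return float(psi @ space.states[:, s])


def conditional_occupancy(psi: np.ndarray, s: int, given: tuple[int, bool],
                          space: StateSpace) -> float:
    """P(species s present | species s' present/absent)."""
    sp, present = given
    if not (0 <= s < space.S and 0 <= sp < space.S):
        raise ValueError("species index out of range")
    cond = space.states[:, sp] == (1 if present else 0)
    denom = float(psi[cond].sum())
    if denom <= 0:
        raise ValueError("conditioning event has probability zero")
    num = float(psi[cond & (space.states[:, s] == 1)].sum())
    return num / denom


def site_neg_loglik(y_i: np.ndarray, psi_i: np.ndarray, p_i: np.ndarray,
                    mask: np.ndarray | None = None) -> float:
    """Negative log marginal likelihood of one site's detection history.

    ``y_i``: (S, T) with NaN marking no-effort occasions; ``psi_i``: state
    simplex of length 2^S; ``p_i``: (S, T) detection probabilities. An
    explicit effort ``mask`` (True = active) may be supplied; a detection
    on a masked-out occasion is rejected as corrupted input. Detections
    are conditionally independent across species and occasions given the
    latent state.
    """
    y_i = np.asarray(y_i, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    S, T = y_i.shape
    space = enumerate_states(S)
    if mask is not None:
        if np.any((y_i == 1) & ~mask):
            raise ValueError("detection recorded on a no-effort occasion")
        y_i = np.where(mask, y_i, np.nan)
    mask = ~np.isnan(y_i)
    log_lik_detected = np.zeros(S)
    any_det = np.zeros(S, dtype=bool)
    for s in range(S):
        m = mask[s]
        ys, ps = y_i[s, m], p_i[s, m]
        with np.errstate(divide="ignore"):
            log_lik_detected[s] = np.sum(ys * np.log(ps) + (1 - ys) * np.log1p(-ps))
        any_det[s] = bool((ys == 1).any())
    terms = np.full(len(space), -np.inf)
    for zi, z in enumerate(space.states):
        lc = 0.0
        ok = True
        for s in range(S):
            if z[s]:
                lc += log_lik_detected[s]
            elif any_det[s]:
                ok = False
                break
        if ok and psi_i[zi] > 0:
            terms[zi] = np.log(psi_i[zi]) + lc
    return float(-logsumexp(terms))


# ---------------------------------------------------------------------------
# Design preparation


class _Prepared:
    """Design matrices and response arrays for one structure on one dataset."""

    def __init__(self, history: DetectionHistory, cov: CovariateTable,
                 structure: ModelStructure):
        if tuple(history.species_order) != tuple(structure.species):
            raise ValueError("structure species do not match the detection history")
        self.structure = structure
        self.species = tuple(structure.species)
        S = len(self.species)
        self.space = enumerate_states(S)
        self.keys = structure.free_keys
        self.incl = _inclusion_matrix(self.space, self.keys)
        self.y = history.y
        self.mask = history.mask
        n, T = self.mask.shape

        self.Xocc: dict[str, np.ndarray] = {}
        self.occ_names: dict[str, list[str]] = {}
        for key in self.keys:
            X, names = build_design(cov.site, structure.occ[key])
            self.Xocc[key] = X
            self.occ_names[key] = names

        flat = self._occasion_frame(cov, n, T)
        self.Xdet: list[np.ndarray] = []
        self.det_names: list[list[str]] = []
        for sp in self.species:
            X, names = build_design(flat, structure.det[sp])
            self.Xdet.append(X)
            self.det_names.append(names)

        self.slices: dict[str, slice] = {}
        pos = 0
        for key in self.keys:
            k = self.Xocc[key].shape[1]
            self.slices[key] = slice(pos, pos + k)
            pos += k
        for s, sp in enumerate(self.species):
            k = self.Xdet[s].shape[1]
            self.slices[f"det:{sp}"] = slice(pos, pos + k)
            pos += k
        self.K = pos
        self.param_names = []
        for key in self.keys:
            self.param_names += [f"{key}:{nm}" for nm in self.occ_names[key]]
        for s, sp in enumerate(self.species):
            self.param_names += [f"det.{sp}:{nm}" for nm in self.det_names[s]]

        self.yf = np.nan_to_num(self.y, nan=0.0)
        self.any_det = ((self.yf == 1) & self.mask[None]).any(axis=2)  # (S, n)

    def _occasion_frame(self, cov: CovariateTable, n: int, T: int) -> pd.DataFrame:
        cols: dict[str, object] = {}
        if "jdate" in cov.occasion:
            j = cov.occasion["jdate"]
            if np.isnan(j[self.mask]).any():
                raise ValueError("missing Julian date on an active occasion")
            cols["jdate"] = np.nan_to_num(j, nan=0.0).ravel()
        if "lockdown" in cov.occasion:
            codes = cov.occasion["lockdown"].copy().ravel()
            codes[codes < 0] = 0  # off-effort filler; masked out of the likelihood
            cols["lockdown"] = pd.Categorical.from_codes(codes, categories=list(LOCKDOWN_LEVELS))
            cols["lockdown_num"] = codes.astype(float)
        return pd.DataFrame(cols, index=range(n * T))

    # -- likelihood ---------------------------------------------------------

    def occ_linear(self, beta: np.ndarray) -> np.ndarray:
        """(n, n_keys) natural-parameter values per site."""
        return np.column_stack([self.Xocc[k] @ beta[self.slices[k]] for k in self.keys])

    def log_psi(self, beta: np.ndarray) -> np.ndarray:
        eta = self.occ_linear(beta) @ self.incl.T          # (n, 2^S)
        return eta - logsumexp(eta, axis=1, keepdims=True)

    def det_linear(self, beta: np.ndarray) -> np.ndarray:
        """(S, n, T) detection linear predictors."""
        n, T = self.mask.shape
        return np.stack([
            (self.Xdet[s] @ beta[self.slices[f"det:{sp}"]]).reshape(n, T)
            for s, sp in enumerate(self.species)])

    def nll_grad(self, beta: np.ndarray) -> tuple[float, np.ndarray]:
        n, T = self.mask.shape
        S = len(self.species)
        Z = self.space.states.astype(float)                # (2^S, S)

        eta = self.occ_linear(beta) @ self.incl.T
        log_psi = eta - logsumexp(eta, axis=1, keepdims=True)

        lp = self.det_linear(beta)                         # (S, n, T)
        m = self.mask[None]
        logA = np.where(m, self.yf * log_expit(lp) + (1 - self.yf) * log_expit(-lp), 0.0)
        logA = logA.sum(axis=2)                            # (S, n)

        logC = logA.T @ Z.T                                # (n, 2^S)
        impossible = (self.any_det.T.astype(float) @ (1.0 - Z.T)) > 0
        logC = np.where(impossible, -np.inf, logC)

        joint = log_psi + logC
        site_ll = logsumexp(joint, axis=1)
        nll = -float(site_ll.sum())

        # posterior over states and the score
        w = np.exp(joint - site_ll[:, None])               # (n, 2^S)
        psi = np.exp(log_psi)
        diff = (w - psi) @ self.incl                       # (n, n_keys)
        grad = np.zeros(self.K)
        for ki, key in enumerate(self.keys):
            grad[self.slices[key]] = -(self.Xocc[key].T @ diff[:, ki])
        post = w @ Z                                       # (n, S) P(z_s=1 | data)
        p = expit(lp)
        resid = np.where(m, self.yf - p, 0.0)              # (S, n, T)
        for s, sp in enumerate(self.species):
            rw = (post[:, s][:, None] * resid[s]).ravel()
            grad[self.slices[f"det:{sp}"]] = -(self.Xdet[s].T @ rw)
        return nll, grad

    def nll(self, beta: np.ndarray) -> float:
        return self.nll_grad(beta)[0]


# ---------------------------------------------------------------------------
# Fitted model


@dataclass
class FittedMSOM:
    structure: ModelStructure
    species: tuple[str, ...]
    beta: np.ndarray
    param_names: list[str]
    loglik: float
    K: int
    aic: float
    vcov: np.ndarray | None
    convergence: dict
    moments: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_sites: int = 0

    @property
    def label(self) -> str:
        return self.structure.label if self.structure is not None else ""

    def se(self) -> np.ndarray:
        if self.vcov is None:
            return np.full(self.K, np.nan)
        return np.sqrt(np.clip(np.diag(self.vcov), 0, None))

    def coef_table(self) -> pd.DataFrame:
        se = self.se()
        return pd.DataFrame({"estimate": self.beta, "se": se,
                             "z": self.beta / se}, index=self.param_names)

    def to_dict(self) -> dict:
        return {
            "label": self.structure.label,
            "species": list(self.species),
            "occ": {k: v for k, v in self.structure.occ.items()},
            "det": {k: v for k, v in self.structure.det.items()},
            "beta": self.beta.tolist(),
            "param_names": self.param_names,
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "loglik": self.loglik, "K": self.K, "aic": self.aic,
            "moments": {k: list(v) for k, v in self.moments.items()},
            "convergence": {k: (v if not isinstance(v, np.generic) else v.item())
                            for k, v in self.convergence.items()},
            "n_sites": self.n_sites,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def detection_prob(structure: ModelStructure, beta: np.ndarray,
                   history: DetectionHistory, cov: CovariateTable) -> np.ndarray:
    """(S, n, T) detection probabilities implied by a coefficient vector."""
    prep = _Prepared(history, cov, structure)
    if len(beta) != prep.K:
        raise ValueError(f"expected {prep.K} coefficients, got {len(beta)}")
    return expit(prep.det_linear(np.asarray(beta, dtype=float)))


def fit_msom(history: DetectionHistory, cov: CovariateTable,
             structure: ModelStructure, *, start: np.ndarray | None = None,
             max_restarts: int = 5, gtol: float = 1e-3, seed: int = 0,
             compute_vcov: bool = True) -> FittedMSOM:
    """Maximum-likelihood fit of a multispecies occupancy structure.

    Starts at beta = 0 (or ``start``), with up to ``max_restarts`` jittered
    restarts if the gradient norm at the optimum exceeds ``gtol``. The
    covariance is the inverse observed information, computed by central
    differences of the analytic score; if the information matrix is
    singular the fit is returned with ``vcov=None``.
    """
    prep = _Prepared(history, cov, structure)
    rng = np.random.default_rng(seed)
    x0 = np.zeros(prep.K) if start is None else np.asarray(start, dtype=float)

    best = None
    n_tries = 0
    for attempt in range(max_restarts + 1):
        n_tries += 1
        res = minimize(prep.nll_grad, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "maxfun": 5000,
                                "ftol": 1e-13, "gtol": 1e-9})
        gnorm = float(np.max(np.abs(prep.nll_grad(res.x)[1])))
        if best is None or res.fun < best[0].fun - 1e-9:
            best = (res, gnorm)
        if gnorm < gtol:
            best = (res, gnorm) if res.fun <= best[0].fun + 1e-9 else best
            break
        x0 = best[0].x + rng.normal(scale=0.5, size=prep.K)
    res, gnorm = best
    if gnorm > 1e-2:
        raise RuntimeError(
            f"optimizer failed to converge for {structure.label or 'structure'}: "
            f"max|grad|={gnorm:.3g} after {n_tries} starts")

    loglik = -float(res.fun)
    vcov = None
    flag = "ok"
    if compute_vcov:
        H = _numeric_hessian(prep, res.x)
        try:
            vcov = np.linalg.inv(H)
            if np.any(np.diag(vcov) < -1e-8):
                flag = "information matrix not positive definite"
                vcov = None
            else:
                # numerical-symmetrization: project onto the PSD cone
                vcov = 0.5 * (vcov + vcov.T)
                evals, evecs = np.linalg.eigh(vcov)
                vcov = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        except np.linalg.LinAlgError:
            flag = "singular information matrix"
            vcov = None
    conv = {"grad_norm": gnorm, "n_starts": n_tries, "n_iter": int(res.nit),
            "status": flag}
    return FittedMSOM(structure, prep.species, res.x, prep.param_names, loglik,
                      prep.K, 2 * prep.K - 2 * loglik, vcov, conv,
                      dict(cov.moments), len(history.site_order))


def _numeric_hessian(prep: _Prepared, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    K = len(x)
    H = np.empty((K, K))
    for k in range(K):
        step = h * (1.0 + abs(x[k]))
        e = np.zeros(K)
        e[k] = step
        gp = prep.nll_grad(x + e)[1]
        gm = prep.nll_grad(x - e)[1]
        H[:, k] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Prediction


def _grid_quantities(fit: FittedMSOM, Xocc: dict[str, np.ndarray],
                     beta: np.ndarray, conditionals) -> np.ndarray:
    """Per-cell quantities stacked (n_cells, n_quant): state probs, marginals, conditionals."""
    S = len(fit.species)
    space = enumerate_states(S)
    keys = fit.structure.free_keys
    incl = _inclusion_matrix(space, keys)
    slices, pos = {}, 0
    for key in keys:
        k = Xocc[key].shape[1]
        slices[key] = slice(pos, pos + k)
        pos += k
    U = np.column_stack([Xocc[k] @ beta[slices[k]] for k in keys])
    eta = U @ incl.T
    psi = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))
    psi /= psi.sum(axis=1, keepdims=True)
    cols = [psi]
    marg = psi @ space.states.astype(float)
    cols.append(marg)
    for (s, sp, present) in conditionals:
        sel = space.states[:, sp] == (1 if present else 0)
        denom = psi[:, sel].sum(axis=1)
        num = psi[:, sel & (space.states[:, s] == 1)].sum(axis=1)
        cols.append((num / denom)[:, None])
    return np.column_stack(cols)


def predict_occupancy(fit: FittedMSOM, grid: pd.DataFrame, *,
                      standardized: bool = False,
                      conditionals: list[tuple[int, int, bool]] | None = None,
                      se_method: str = "delta", n_boot: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Predict state, marginal and conditional occupancy on a covariate grid.

    ``grid`` holds raw covariates (standardized with the fit-time moments
    unless ``standardized=True``). ``conditionals`` is a list of
    (species, given_species, given_present) index triples. SEs come from
    the delta method (numeric gradient through the softmax) by default, or
    from a parametric bootstrap of beta (``se_method='bootstrap'``).
    """
    site_df = grid if standardized else apply_moments(grid, fit.moments)
    keys = fit.structure.free_keys
    Xocc = {}
    occ_beta_len = 0
    for key in keys:
        X, names = build_design(site_df, fit.structure.occ[key])
        Xocc[key] = X
        occ_beta_len += X.shape[1]
    conditionals = conditionals or []
    q0 = _grid_quantities(fit, Xocc, fit.beta, conditionals)
    S = len(fit.species)
    names = [f"psi_{''.join(str(b) for b in z)}" for z in enumerate_states(S).states]
    names += [f"marginal_{sp}" for sp in fit.species]
    names += [f"cond_{fit.species[s]}_given_{fit.species[g]}_{'present' if pr else 'absent'}"
              for (s, g, pr) in conditionals]
    out = pd.DataFrame(q0, columns=names, index=site_df.index)

    if fit.vcov is None:
        for nm in names:
            out[f"se_{nm}"] = np.nan
        return out
    if se_method == "delta":
        K = len(fit.beta)
        grads = np.zeros((K,) + q0.shape)
        for k in range(K):
            h = 1e-6 * (1 + abs(fit.beta[k]))
            e = np.zeros(K)
            e[k] = h
            qp = _grid_quantities(fit, Xocc, fit.beta + e, conditionals)
            qm = _grid_quantities(fit, Xocc, fit.beta - e, conditionals)
            grads[k] = (qp - qm) / (2 * h)
        V = fit.vcov
        # var = g' V g per cell/quantity
        tmp = np.einsum("kij,kl->lij", grads, V)
        var = np.einsum("kij,kij->ij", grads, tmp)
        ses = np.sqrt(np.clip(var, 0, None))
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(fit.beta, fit.vcov, size=n_boot,
                                        method="svd")
        sims = np.stack([_grid_quantities(fit, Xocc, b, conditionals) for b in draws])
        ses = sims.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    for j, nm in enumerate(names):
        out[f"se_{nm}"] = ses[:, j]
    return out
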