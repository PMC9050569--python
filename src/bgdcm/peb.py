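"""Hierarchical (parametric empirical Bayes) group inference.

Subject-level posteriors enter a second-level linear model

    theta_i = (x_i' kron I) beta + eps_i,   eps_i ~ N(0, Sigma_b),

where x_i is a row of the group design matrix (intercept plus mean-centred
covariates) and Sigma_b a between-subject covariance parameterized by one
log-precision per parameter group (between-node couplings vs
self-connections).  Subject data enter only through their first-level
posterior/prior pairs: replacing a subject's prior with the second-level
implied prior N((x_i' kron I) beta, Sigma_b) has a closed-form effect on
the subject's model evidence (Bayesian model reduction), which makes the
second-level likelihood of beta Gaussian and the whole scheme fast.

On top of the fitted parent model, a greedy search over second-level
effects switches off parameters that do not contribute to the model
evidence; the final <= 256 reduced models are combined by Bayesian model
averaging with evidence (softmax free-energy) weights, which also yields a
posterior probability per effect.  Leave-one-out prediction of a covariate
refits the model without each subject and forms the predictive density of
the held-out covariate value from that subject's first-level posterior
under the trained group model, with no leakage from the test case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .invert import PosteriorDensity
from .network import ParamLayout, PriorDensity, build_bg_network

# Prior over the between-subject log precisions (per parameter group).
GAMMA_PRIOR_MEAN = 0.0
GAMMA_PRIOR_VAR = 4.0
GAMMA_BOUND = 8.0
#: Baseline between-subject precision floor (avoids degenerate collapse).
PRECISION_FLOOR = np.exp(-8.0)
#: Prior variance used to switch an effect off in reduced models.
SWITCH_OFF_VAR = 1e-8

MOTOR_COVARIATES = ["TMS", "age", "sex", "scanner"]
APATHY_COVARIATES = ["BAS", "BDI", "TMS", "age", "sex", "scanner"]


class RankError(ValueError):
    """The design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Group design: intercept plus covariate columns.

    ``raw`` holds the uncentred numeric columns (intercept first);
    ``matrix`` applies mean-centring to every flagged non-intercept column,
    so the intercept models the group average connectivity.
    """

    raw: np.ndarray
    labels: list
    centre: np.ndarray  # bool per column; intercept never centred

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        self.centre = np.asarray(self.centre, dtype=bool)
        if not np.allclose(self.raw[:, 0], 1.0):
            raise ValueError("first column must be the intercept")
        r = np.linalg.matrix_rank(self.matrix)
        if r < self.raw.shape[1]:
            raise RankError(self._describe_collinearity())

    def _describe_collinearity(self) -> str:
        X = self.matrix
        for i, j in combinations(range(X.shape[1]), 2):
            xi, xj = X[:, i], X[:, j]
            if np.allclose(xi, 0) or np.allclose(xj, 0):
                continue
            c = np.corrcoef(xi, xj)[0, 1] if (xi.std() and xj.std()) else 1.0
            if abs(c) > 1 - 1e-10:
                return (f"design is rank deficient: columns "
                        f"{self.labels[i]!r} and {self.labels[j]!r} are collinear")
        return "design is rank deficient"

    @property
    def matrix(self) -> np.ndarray:
        X = self.raw.copy()
        for j in range(1, X.shape[1]):
            if self.centre[j]:
                X[:, j] -= X[:, j].mean()
        return X

    @property
    def n_subjects(self) -> int:
        return self.raw.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.raw.shape[1]

    def drop_subject(self, i: int) -> "DesignMatrix":
        """Design without subject i, re-centred over the remaining rows."""
        keep = np.ones(self.n_subjects, dtype=bool)
        keep[i] = False
        return DesignMatrix(raw=self.raw[keep], labels=list(self.labels),
                            centre=self.centre.copy())


def _numeric_column(clinical, name: str) -> np.ndarray:
    col = clinical[name]
    if col.dtype.kind in "OUS":
        vals = col.astype(str).str.upper()
        uniq = sorted(vals.unique())
        if len(uniq) > 2:
            raise ValueError(f"cannot encode categorical covariate {name!r} "
                             f"with {len(uniq)} levels as one dummy")
        if set(uniq) <= {"F", "M"}:
            return (vals == "F").to_numpy(dtype=float)
        return (vals == uniq[-1]).to_numpy(dtype=float)  # 0/1 dummy
    return col.to_numpy(dtype=float)


def build_design(clinical, covariate_names: list, centre=None) -> DesignMatrix:
    """Build the second-level design from a clinical table.

    Categorical columns (sex, scanner site) are encoded as 0/1 dummies and
    then mean-centred like every other covariate; duplicate or collinear
    covariates raise a rank error naming the offending pair.
    """
    if clinical[covariate_names].isna().any().any():
        raise ValueError("missing covariate values")
    n = len(clinical)
    cols = [np.ones(n)]
    labels = ["mean"]
    for name in covariate_names:
        cols.append(_numeric_column(clinical, name))
        labels.append(name)
    flags = np.ones(len(cols), dtype=bool)
    flags[0] = False
    if centre is not None:
        flags[1:] = np.asarray(centre, dtype=bool)
    return DesignMatrix(raw=np.column_stack(cols), labels=labels, centre=flags)


# ---------------------------------------------------------------------------
# Bayesian model reduction (closed form)
# ---------------------------------------------------------------------------

@dataclass
class ReducedModel:
    """One reduced second-level model: which effects are on, its evidence
    gain over the full model, and its reduced posterior."""

    mask: np.ndarray  # bool per effect; True = on
    delta_f: float
    mean: np.ndarray
    covariance: np.ndarray


def bmr_reduce(post_mean, post_cov, prior_mean, prior_cov,
               red_mean, red_cov) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior and log-evidence change after swapping the prior.

    Given a Gaussian posterior obtained under ``prior``, returns the
    posterior (mean, covariance) under the reduced prior and the
    log-evidence difference Delta F, all in closed form:

        Pi_r  = Pi + Pi_r0 - Pi_0
        mu_r  = Pi_r^{-1} (Pi mu + Pi_r0 mu_r0 - Pi_0 mu_0)
        2 dF  = ln|Pi| + ln|Pi_r0| - ln|Pi_0| - ln|Pi_r|
                + mu_r' Pi_r mu_r - mu' Pi mu
                - mu_r0' Pi_r0 mu_r0 + mu_0' Pi_0 mu_0

    Raises if the reduced posterior precision is not positive definite
    (incompatible reduction).
    """
    post_mean = np.asarray(post_mean, float)
    if (np.array_equal(np.asarray(red_cov, float), np.asarray(prior_cov, float))
            and np.array_equal(np.asarray(red_mean, float),
                               np.asarray(prior_mean, float))):
        # unchanged prior: identical model, zero evidence change by definition
        return post_mean.copy(), np.asarray(post_cov, float).copy(), 0.0
    P = np.linalg.inv(np.asarray(post_cov, float))
    P0 = np.linalg.inv(np.asarray(prior_cov, float))
    Pr0 = np.linalg.inv(np.asarray(red_cov, float))
    prior_mean = np.asarray(prior_mean, float)
    red_mean = np.asarray(red_mean, float)

    Pr = P + Pr0 - P0
    ev = np.linalg.eigvalsh(Pr)
    if ev.min() <= 0:
        raise ValueError("incompatible reduction: reduced precision not positive definite")
    mu_r = np.linalg.solve(Pr, P @ post_mean + Pr0 @ red_mean - P0 @ prior_mean)

    def ld(M):
        s, v = np.linalg.slogdet(M)
        return v

    dF = 0.5 * (ld(P) + ld(Pr0) - ld(P0) - ld(Pr)) + 0.5 * (
        mu_r @ Pr @ mu_r - post_mean @ P @ post_mean
        - red_mean @ Pr0 @ red_mean + prior_mean @ P0 @ prior_mean)
    return mu_r, np.linalg.inv(Pr), float(dF)


# ---------------------------------------------------------------------------
# PEB estimation
# ---------------------------------------------------------------------------

def default_field(layout: ParamLayout) -> np.ndarray:
    """Default second-level field: between-node couplings + self-connections."""
    idx = np.r_[np.arange(layout.sl_coupling.start, layout.sl_coupling.stop),
                np.arange(layout.sl_self.start, layout.sl_self.stop)]
    return idx


@dataclass
class PEBResult:
    """Second-level posterior over design effects on model parameters."""

    beta: np.ndarray  # (c, p): covariate x parameter effects
    beta_covariance: np.ndarray  # (c*p, c*p), blocks ordered covariate-major
    beta_prior_var: np.ndarray  # (c*p,)
    gammas: np.ndarray  # between-subject log precisions
    free_energy: float
    covariate_labels: list
    param_labels: list
    field_indices: np.ndarray
    design: DesignMatrix | None = None
    _subject_terms: list = field(default_factory=list, repr=False)

    @property
    def n_cov(self) -> int:
        return self.beta.shape[0]

    @property
    def n_params(self) -> int:
        return self.beta.shape[1]

    def beta_vector(self) -> np.ndarray:
        return self.beta.ravel()

    def effect_label(self, flat_index: int) -> str:
        c, p = divmod(flat_index, self.n_params)
        return f"{self.covariate_labels[c]}:{self.param_labels[p]}"

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "beta_covariance": self.beta_covariance.tolist(),
            "beta_prior_var": self.beta_prior_var.tolist(),
            "gammas": self.gammas.tolist(),
            "free_energy": float(self.free_energy),
            "covariate_labels": list(self.covariate_labels),
            "param_labels": list(self.param_labels),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


def _subject_blocks(posteriors, priors: PriorDensity, fidx: np.ndarray):
    """Per-subject sufficient statistics over the field sub-block."""
    blocks = []
    m0 = priors.mean[fidx]
    pi0 = 1.0 / priors.var[fidx]
    P0 = np.diag(pi0)
    for post in posteriors:
        if post.mean.size != priors.dim:
            raise ValueError("posterior/prior parameter dimension mismatch")
        mu = post.mean[fidx]
        Sig = post.covariance[np.ix_(fidx, fidx)]
        Pi = np.linalg.inv(Sig)
        # guard: clip tiny negative eigenvalues of Pi - P0 from roundoff
        b = Pi @ mu - P0 @ m0
        s, ldPi = np.linalg.slogdet(Pi)
        const = 0.5 * (m0 @ P0 @ m0 - mu @ Pi @ mu) + 0.5 * ldPi
        blocks.append({"Pi": Pi, "b": b, "const": const})
    return blocks, m0, P0, pi0


def _gamma_groups(fidx: np.ndarray, layout: ParamLayout,
                  components: str = "per-param") -> np.ndarray:
    """Assignment of field parameters to between-subject precision components.

    "per-param" gives every parameter its own log precision (the default:
    a parameter with large unmodelled between-subject spread — e.g. an edge
    driven by a covariate absent from the design — then cannot inflate the
    apparent variability of the others).  "field-group" pools parameters
    into two components, between-node couplings vs the rest.
    """
    if components == "per-param":
        return np.arange(fidx.size)
    return (fidx >= layout.n_coupling).astype(int)


def peb_fit(posteriors, priors: PriorDensity, design: DesignMatrix,
            field_indices: np.ndarray | None = None,
            layout: ParamLayout | None = None,
            between_cov: np.ndarray | None = None,
            precision_components: str = "per-param",
            laplace_correction: bool = True) -> PEBResult:
    """Fit the second-level model to a cohort of subject posteriors.

    ``between_cov`` fixes the between-subject covariance (used by oracle
    tests); otherwise the log precisions of the two parameter groups are
    optimized by maximizing the second-level free energy, with the
    conditional posterior over beta available in closed form at each
    candidate.
    """
    if len(posteriors) < 2:
        raise ValueError("need at least 2 subjects")
    layout = layout or ParamLayout(build_bg_network())
    fidx = default_field(layout) if field_indices is None else np.asarray(field_indices)
    X = design.matrix
    if X.shape[0] != len(posteriors):
        raise ValueError("design rows must match number of subjects")

    blocks, m0, P0, pi0 = _subject_blocks(posteriors, priors, fidx)
    p = fidx.size
    c = X.shape[1]
    groups = _gamma_groups(fidx, layout, precision_components)
    n_groups = len(np.unique(groups))

    # Second-level prior on beta: the intercept (group mean) inherits the
    # first-level shrinkage variances; covariate-effect blocks are scaled by
    # the covariate's sample variance, so that one covariate SD moves a
    # coupling on the same prior scale as the group mean itself (this is
    # what z-scoring the covariates would do, while effects stay reported
    # per raw covariate unit).
    col_scale = np.ones(c)
    for j in range(1, c):
        v = X[:, j].var()
        col_scale[j] = 1.0 / v if v > 0 else 1.0
    beta_prior_var = np.concatenate([priors.var[fidx] * col_scale[j] for j in range(c)])
    Pb0 = np.diag(1.0 / beta_prior_var)

    def sigma_b_inv(gammas: np.ndarray) -> np.ndarray:
        prec = np.full(p, PRECISION_FLOOR)
        for g in range(n_groups):
            prec = prec + np.where(groups == g, np.exp(gammas[g]) * pi0, 0.0)
        return np.diag(prec)

    Pi_stack = np.stack([blk["Pi"] for blk in blocks])  # (n, p, p)
    b_stack = np.stack([blk["b"] for blk in blocks])    # (n, p)
    const_sum = float(sum(blk["const"] for blk in blocks))
    n_subj = len(blocks)
    sum_log_pi0 = float(np.sum(np.log(pi0)))

    def conditional(gammas_or_V):
        if between_cov is not None:
            Pb = np.linalg.inv(between_cov)
        else:
            Pb = sigma_b_inv(gammas_or_V)
        sgn, ldPb = np.linalg.slogdet(Pb)
        Pri = Pi_stack + (Pb - P0)[None]
        try:
            np.linalg.cholesky(Pri)
        except np.linalg.LinAlgError:
            return None  # incompatible reduction; signal to optimizer
        Ci = np.linalg.inv(Pri)
        ldPri = np.linalg.slogdet(Pri)[1]
        PbCi = Pb @ Ci  # broadcasts over subjects
        R = Pb[None] - PbCi @ Pb
        Cib = np.einsum("nij,nj->ni", Ci, b_stack)
        PbCb = np.einsum("ij,nj->ni", Pb, Cib)
        consts = (const_sum + 0.5 * n_subj * (ldPb - sum_log_pi0)
                  - 0.5 * ldPri.sum() + 0.5 * np.einsum("ni,ni->", b_stack, Cib))
        A = np.einsum("na,nb,nij->aibj", X, X, R).reshape(c * p, c * p) + Pb0
        r = np.einsum("na,ni->ai", X, PbCb).reshape(c * p)
        beta = np.linalg.solve(A, r)
        # s(beta_hat) = consts + 0.5 r'beta - log-normalizers of the prior
        s_val = consts + 0.5 * r @ beta - 0.5 * np.sum(np.log(beta_prior_var))
        sgn, ldA = np.linalg.slogdet(A)
        F = s_val - 0.5 * ldA
        return {"F": F, "beta": beta, "A": A, "Pb": Pb, "Cs": Ci, "Rs": R}

    if between_cov is not None:
        sol = conditional(None)
        gammas = np.array([])
        F = sol["F"]
    else:
        def neg_f(g):
            g = np.clip(g, -GAMMA_BOUND, GAMMA_BOUND)
            out = conditional(g)
            if out is None:
                return 1e12
            pen = 0.5 * np.sum((g - GAMMA_PRIOR_MEAN) ** 2) / GAMMA_PRIOR_VAR
            return -(out["F"] - pen)

        if n_groups <= 2:
            res = optimize.minimize(neg_f, x0=np.full(n_groups, 2.0),
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-3, "fatol": 1e-4,
                                             "maxiter": 400})
        else:
            res = optimize.minimize(
                neg_f, x0=np.full(n_groups, 2.0), method="L-BFGS-B",
                bounds=[(-GAMMA_BOUND, GAMMA_BOUND)] * n_groups,
                options={"maxiter": 200, "ftol": 1e-9, "eps": 1e-4})
        gammas = np.clip(res.x, -GAMMA_BOUND, GAMMA_BOUND)
        sol = conditional(gammas)
        f0 = -neg_f(gammas)
        F = f0
        if laplace_correction:
            # Laplace correction over the log precisions
            h = 0.05
            H = np.zeros((n_groups, n_groups))
            fa = np.array([-neg_f(gammas + h * np.eye(n_groups)[a])
                           for a in range(n_groups)])
            for a in range(n_groups):
                for b_ in range(a, n_groups):
                    gab = gammas.copy()
                    gab[a] += h
                    gab[b_] += h
                    H[a, b_] = H[b_, a] = (-neg_f(gab) + f0 - fa[a] - fa[b_]) / h ** 2
            H = -H
            ev = np.linalg.eigvalsh(H)
            F = f0 + 0.5 * n_groups * np.log(2 * np.pi)
            if ev.min() > 0:
                F -= 0.5 * float(np.linalg.slogdet(H)[1])

    beta_cov = np.linalg.inv(sol["A"])
    beta_cov = 0.5 * (beta_cov + beta_cov.T)
    return PEBResult(
        beta=sol["beta"].reshape(c, p),
        beta_covariance=beta_cov,
        beta_prior_var=beta_prior_var,
        gammas=gammas,
        free_energy=float(F),
        covariate_labels=list(design.labels),
        param_labels=[ParamLayout(layout.spec).names()[k] for k in fidx],
        field_indices=fidx,
        design=design,
        _subject_terms=[{"Pb": sol["Pb"], "C": sol["Cs"][i], "R": sol["Rs"][i],
                         "b": blocks[i]["b"]} for i in range(len(blocks))],
    )


# ---------------------------------------------------------------------------
# Greedy search and Bayesian model averaging
# ---------------------------------------------------------------------------

@dataclass
class BMAResult:
    """Model-averaged second-level effects."""

    means: np.ndarray  # (c, p)
    variances: np.ndarray  # (c, p)
    pp: np.ndarray  # (c, p), posterior probability each effect is present
    models_used: int
    covariate_labels: list
    param_labels: list
    searched: np.ndarray  # bool (c, p)

    def effect(self, covariate: str, param: str) -> dict:
        ci = self.covariate_labels.index(covariate)
        pi = self.param_labels.index(param)
        return {"mean": float(self.means[ci, pi]),
                "sd": float(np.sqrt(self.variances[ci, pi])),
                "pp": float(self.pp[ci, pi])}

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "pp": self.pp.tolist(),
            "models_used": int(self.models_used),
            "covariate_labels": list(self.covariate_labels),
            "param_labels": list(self.param_labels),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


def search_and_average(peb: PEBResult, effect_columns: list | None = None,
                       max_undecided: int = 8) -> BMAResult:
    """Greedy pruning of second-level effects plus exhaustive averaging.

    Candidate effects are every (covariate, parameter) element of beta for
    the searched covariate columns (default: all non-intercept columns).
    While more than ``max_undecided`` candidates remain, the single
    switch-off with the largest free-energy gain is committed (if any gain
    exists; otherwise the most clearly needed effects are fixed on).  The
    final <= 2^max_undecided reduced models are scored exhaustively and
    averaged with softmax free-energy weights; an effect's posterior
    probability is the summed weight of the models that retain it.
    """
    c, p = peb.beta.shape
    q = c * p
    mu = peb.beta_vector()
    Sig = peb.beta_covariance
    prior_mean = np.zeros(q)
    prior_cov = np.diag(peb.beta_prior_var)

    if effect_columns is None:
        effect_columns = [lab for lab in peb.covariate_labels[1:]]
    cand = [ci * p + pi for ci, lab in enumerate(peb.covariate_labels)
            if lab in effect_columns for pi in range(p)]

    if not cand:
        return BMAResult(means=peb.beta.copy(),
                         variances=np.diag(Sig).reshape(c, p).copy(),
                         pp=np.ones((c, p)), models_used=1,
                         covariate_labels=peb.covariate_labels,
                         param_labels=peb.param_labels,
                         searched=np.zeros((c, p), dtype=bool))

    cache = {}

    def evaluate(off: frozenset):
        if off not in cache:
            rc = np.diag(peb.beta_prior_var.copy())
            for j in off:
                rc[j, j] = SWITCH_OFF_VAR
            mr, Sr, dF = bmr_reduce(mu, Sig, prior_mean, prior_cov,
                                    prior_mean, rc)
            cache[off] = (mr, Sr, dF)
        return cache[off]

    pruned: set = set()
    remaining = list(cand)
    decided_on: set = set()
    while len(remaining) > max_undecided:
        base = evaluate(frozenset(pruned))[2]
        deltas = {j: evaluate(frozenset(pruned | {j}))[2] - base for j in remaining}
        best = max(deltas, key=deltas.get)
        if deltas[best] > 0:
            pruned.add(best)
            remaining.remove(best)
        else:
            remaining.sort(key=lambda j: deltas[j], reverse=True)
            decided_on.update(remaining[max_undecided:])
            remaining = remaining[:max_undecided]
            break

    # exhaustive scoring of the final model space
    models = []
    for r in range(len(remaining) + 1):
        for subset in combinations(remaining, r):
            off = frozenset(pruned | set(subset))
            mr, Sr, dF = evaluate(off)
            mask = np.ones(q, dtype=bool)
            mask[list(off)] = False
            models.append(ReducedModel(mask=mask, delta_f=dF, mean=mr, covariance=Sr))

    dFs = np.array([m.delta_f for m in models])
    w = np.exp(dFs - dFs.max())
    w /= w.sum()

    means = np.zeros(q)
    second = np.zeros(q)
    pp = np.zeros(q)
    for wi, m in zip(w, models):
        means += wi * m.mean
        second += wi * (np.diag(m.covariance) + m.mean ** 2)
        pp += wi * m.mask
    variances = np.maximum(second - means ** 2, 0.0)
    # effects outside the searched set are always on
    always_on = np.ones(q, dtype=bool)
    always_on[cand] = False
    pp[always_on] = 1.0

    return BMAResult(means=means.reshape(c, p), variances=variances.reshape(c, p),
                     pp=pp.reshape(c, p), models_used=len(models),
                     covariate_labels=peb.covariate_labels,
                     param_labels=peb.param_labels,
                     searched=~always_on.reshape(c, p))


# ---------------------------------------------------------------------------
# Leave-one-out covariate prediction
# ---------------------------------------------------------------------------

@dataclass
class LooResult:
    r: float
    p: float
    predictions: np.ndarray
    observed: np.ndarray
    flagged: bool = False  # constant predictions: correlation undefined

    def to_dict(self) -> dict:
        return {"r": float(self.r), "p": float(self.p),
                "predictions": self.predictions.tolist(),
                "observed": self.observed.tolist(),
                "flagged": bool(self.flagged)}


def loo_cv(posteriors, priors: PriorDensity, design: DesignMatrix,
           predict_column: str, field_indices: np.ndarray | None = None,
           layout: ParamLayout | None = None) -> LooResult:
    """Bayesian leave-one-out prediction of one covariate.

    For each subject the group model is refit without them; covariate
    columns are mean-centred once over the full cohort (the convention of
    the reference implementation — per-fold re-centring makes every
    fold's baseline anti-correlated with the held-out value by
    construction, biasing the null correlation negative), while the
    held-out subject's first-level posterior contributes nothing to the
    training fit.  The held-out
    covariate value is then treated as unknown with the training cohort's
    empirical Gaussian prior: the subject's first-level posterior induces a
    Gaussian pseudo-likelihood over their implied second-level parameters,
    and the second-level effect posterior is marginalized, so the
    likelihood's variance grows quadratically with the candidate covariate
    value (an uncertain effect cannot support extreme predictions).  The
    posterior over the covariate is evaluated on a grid and its mean is
    the prediction.  Returns the Pearson correlation between predictions
    and observed values with its one-tailed p-value.
    """
    n = len(posteriors)
    if n < 5:
        raise ValueError("leave-one-out requires at least 5 subjects")
    if predict_column not in design.labels:
        raise ValueError(f"unknown covariate {predict_column!r}")
    col = design.labels.index(predict_column)
    layout = layout or ParamLayout(build_bg_network())
    fidx = default_field(layout) if field_indices is None else np.asarray(field_indices)

    observed = design.raw[:, col].astype(float)
    preds = np.empty(n)
    p = fidx.size
    c = design.n_covariates
    Xc = design.matrix  # centred once over the full cohort
    xbar = design.raw[:, col].mean()
    xsd = max(design.raw[:, col].std(), 1e-6)
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        d_train = DesignMatrix(raw=Xc[keep], labels=list(design.labels),
                               centre=np.zeros(c, dtype=bool))
        peb = peb_fit([posteriors[j] for j in train_idx], priors, d_train,
                      field_indices=fidx, layout=layout,
                      laplace_correction=False)
        B = peb.beta  # (c, p)
        xc = Xc[i].copy()
        # pseudo-likelihood of this subject's implied group-level parameters
        blocks, m0, P0, pi0 = _subject_blocks([posteriors[i]], priors, fidx)
        Pb = peb._subject_terms[0]["Pb"]
        Pri = blocks[0]["Pi"] + Pb - P0
        Ci = np.linalg.inv(Pri)
        Ri = Pb - Pb @ Ci @ Pb
        Rinv = np.linalg.inv(Ri + 1e-10 * np.eye(p))
        eta_hat = Rinv @ (Pb @ Ci @ blocks[0]["b"])
        bvec = B[col]
        c0 = np.zeros(p)
        for j in range(c):
            if j != col:
                c0 += xc[j] * B[j]
        # effect-posterior covariance blocks entering the predictive variance
        Sb = peb.beta_covariance.reshape(c, p, c, p)
        xo = xc.copy()
        xo[col] = 0.0
        W0 = np.einsum("j,jakb,k->ab", xo, Sb, xo)
        W1 = np.einsum("akb,k->ab", Sb[col], xo)
        W1 = W1 + W1.T
        W2 = Sb[col, :, col, :]
        # grid over the unknown covariate (empirical cohort prior)
        grid = np.linspace(xbar - 4 * xsd, xbar + 4 * xsd, 161)
        logpost = np.empty(grid.size)
        for k, xg in enumerate(grid):
            u = xg - xbar
            mean = c0 + u * bvec
            cov = Rinv + W0 + u * W1 + u * u * W2
            d = eta_hat - mean
            sign, ld = np.linalg.slogdet(cov)
            logpost[k] = (-0.5 * (ld + d @ np.linalg.solve(cov, d))
                          - 0.5 * (u / xsd) ** 2)
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        preds[i] = float(w @ grid)

    ok = np.isfinite(preds)
    if ok.sum() < 3 or np.std(preds[ok]) < 1e-12 or np.std(observed[ok]) < 1e-12:
        return LooResult(r=float("nan"), p=float("nan"), predictions=preds,
                         observed=observed, flagged=True)
    res = stats.pearsonr(preds[ok], observed[ok], alternative="greater")
    return LooResult(r=float(res.statistic), p=float(res.pvalue),
                     predictions=preds, observed=observed)
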