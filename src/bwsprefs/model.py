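"""Conditional-logit (MaxDiff) estimation for best-worst scaling.

The default likelihood is the joint ordered-pair MaxDiff model: in a block
with items S, the probability of picking item i best and item j worst is

    P(i, j | S) = exp(u_i - u_j) / sum_{l != m in S} exp(u_l - u_m),

where u is the vector of latent item utilities.  Only utility differences
are identified, so estimation uses effects coding: utilities are
constrained to sum to zero, placing the average item at 0 — coefficients
are then directly comparable as "relative salience" scores with positive
and negative values around the grand mean.

A sequential best-then-worst alternative likelihood — best chosen by a
standard logit over the block, worst by an inverse logit over the
remaining items — is available via ``likelihood="sequential"`` for
sensitivity analysis.

The denominator of the MaxDiff likelihood factorizes: summing
``exp(u_l - u_m)`` over ordered pairs equals
``(sum_l exp(u_l)) * (sum_m exp(-u_m)) - k``, which keeps the
log-likelihood, its gradient and its Hessian cheap to evaluate exactly.
Optimization is quasi-Newton (BFGS) from a zero start with the analytic
gradient in the (v-1)-dimensional reduced space; there is no randomness.
Standard errors come from the observed information (inverse Hessian at
the optimum) mapped through the sum-to-zero constraint, and 95%
confidence intervals are the usual normal approximation beta +/- 1.96 se.

The module follows the statsmodels convention: ``MaxDiffModel(data).fit()``
returns a :class:`MaxDiffResults` carrying estimates, standard errors,
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .design import BIBDesign
from .scoring import BWSDataError, rank_items
from .simulate import ResponseSet, StudyDataset

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


class ConvergenceWarning(UserWarning):
    pass


class SeparationWarning(UserWarning):
    """An item was always best or always worst; its utility drifts to infinity."""


@dataclass(frozen=True)
class EstimationResult:
    """One item's row from a fitted model."""

    item_id: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    rank: int
    subgroup: str
    n_respondents: int
    loglik: float
    converged: bool


class MaxDiffModel:
    """Conditional-logit model for object-case best-worst data.

    Parameters
    ----------
    dataset : StudyDataset
        Complete responses attached to a questionnaire (apply the
        completeness filter first).
    likelihood : {"maxdiff", "sequential"}
        Joint ordered-pair likelihood (default) or sequential
        best-then-worst.
    subgroup : str
        Label stamped on the results (e.g. a phase of care).
    """

    def __init__(
        self,
        dataset: StudyDataset,
        likelihood: str = "maxdiff",
        subgroup: str = "overall",
    ):
        if likelihood not in ("maxdiff", "sequential"):
            raise ValueError(f"unknown likelihood {likelihood!r}")
        self.likelihood = likelihood
        self.subgroup = subgroup
        self.dataset = dataset
        q = dataset.questionnaire
        self.item_ids: tuple[str, ...] = q.item_ids
        self.v = len(self.item_ids)
        self.k = q.design.k
        self.n_respondents = len(dataset.responses)
        if self.n_respondents == 0:
            raise BWSDataError("no responses to fit")

        id_to_idx = {iid: i for i, iid in enumerate(self.item_ids)}
        blocks = np.asarray(q.design.blocks, dtype=int)
        obs_blocks, best_idx, worst_idx = [], [], []
        for resp in dataset.responses:
            for bi, pick in resp.picks.items():
                if pick is None:
                    raise BWSDataError(
                        f"respondent {resp.respondent_id!r} is incomplete; "
                        "apply the completeness filter before fitting"
                    )
                best, worst = pick
                blk = blocks[bi]
                b_i, w_i = id_to_idx[best], id_to_idx[worst]
                if b_i not in blk or w_i not in blk:
                    raise BWSDataError(
                        f"respondent {resp.respondent_id!r}, block {bi}: pick outside block"
                    )
                obs_blocks.append(blk)
                best_idx.append(b_i)
                worst_idx.append(w_i)
        self._blocks = np.asarray(obs_blocks, dtype=int)       # (n_obs, k)
        self._best = np.asarray(best_idx, dtype=int)
        self._worst = np.asarray(worst_idx, dtype=int)
        self.nobs = len(self._best)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        questionnaire,
        likelihood: str = "maxdiff",
        subgroup: str = "overall",
    ) -> "MaxDiffModel":
        """Build from long-format records (respondent_id, phase, block_id,
        best_item_id, worst_item_id), one row per answered block."""
        from .io import responses_from_frame

        dataset = responses_from_frame(df, questionnaire)
        return cls(dataset, likelihood=likelihood, subgroup=subgroup)

    # ---- likelihood --------------------------------------------------

    def loglike(self, beta: np.ndarray) -> float:
        """Log-likelihood at a full-length utility vector (shift-invariant)."""
        beta = np.asarray(beta, dtype=float)
        if self.likelihood == "maxdiff":
            return self._loglike_maxdiff(beta)
        return self._loglike_sequential(beta)

    def _loglike_maxdiff(self, beta: np.ndarray) -> float:
        bu = beta[self._blocks]
        sp = np.exp(bu).sum(axis=1)
        sm = np.exp(-bu).sum(axis=1)
        denom = sp * sm - self.k
        return float(np.sum(beta[self._best] - beta[self._worst] - np.log(denom)))

    def _loglike_sequential(self, beta: np.ndarray) -> float:
        bu = beta[self._blocks]
        eb = np.exp(bu)
        sp = eb.sum(axis=1)
        em = np.exp(-bu)
        sm = em.sum(axis=1) - np.exp(-beta[self._best])
        return float(
            np.sum(
                beta[self._best] - np.log(sp) - beta[self._worst] - np.log(sm)
            )
        )

    def score(self, beta: np.ndarray) -> np.ndarray:
        """Gradient of the log-likelihood with respect to the full beta."""
        beta = np.asarray(beta, dtype=float)
        g = np.zeros(self.v)
        np.add.at(g, self._best, 1.0)
        np.add.at(g, self._worst, -1.0)
        if self.likelihood == "maxdiff":
            bu = beta[self._blocks]
            a = np.exp(bu)                       # (n_obs, k)
            c = np.exp(-bu)
            sp = a.sum(axis=1, keepdims=True)
            sm = c.sum(axis=1, keepdims=True)
            denom = sp * sm - self.k
            contrib = (a * sm - c * sp) / denom  # d log denom / d u_m, m in block
            np.add.at(g, self._blocks, -contrib)
        else:
            bu = beta[self._blocks]
            a = np.exp(bu)
            c = np.exp(-bu)
            sp = a.sum(axis=1, keepdims=True)
            cb = np.exp(-beta[self._best])[:, None]
            sm = c.sum(axis=1, keepdims=True) - cb
            np.add.at(g, self._blocks, -a / sp)
            is_best = self._blocks == self._best[:, None]
            worst_term = np.where(is_best, 0.0, c / sm)
            np.add.at(g, self._blocks, worst_term)
            # the best item also enters sm through -exp(-u_best): that term's
            # derivative cancels exactly (handled by masking above)
        return g

    def hessian(self, beta: np.ndarray) -> np.ndarray:
        """Analytic Hessian of the log-likelihood (maxdiff); finite
        differences of the gradient for the sequential likelihood."""
        beta = np.asarray(beta, dtype=float)
        if self.likelihood != "maxdiff":
            return _fd_jacobian(self.score, beta)
        bu = beta[self._blocks]
        a = np.exp(bu)
        c = np.exp(-bu)
        sp = a.sum(axis=1, keepdims=True)
        sm = c.sum(axis=1, keepdims=True)
        denom = (sp * sm - self.k)                        # (n_obs, 1)
        dd = a * sm - c * sp                               # dD/du_m, (n_obs, k)
        # d2D/du_m du_n = -(a_m c_n + c_m a_n) for m != n;
        #                 a_m sm + c_m sp - 2 a_m c_m   for m == n
        H = np.zeros((self.v, self.v))
        n_obs, k = self._blocks.shape
        outer_dd = dd[:, :, None] * dd[:, None, :] / denom[:, :, None] ** 2
        cross = -(a[:, :, None] * c[:, None, :] + c[:, :, None] * a[:, None, :])
        diag = a * sm + c * sp - 2.0 * a * c
        d2 = cross.copy()
        idx = np.arange(k)
        d2[:, idx, idx] = diag
        # Hessian of -log D per obs: (dD dD^T)/D^2 - d2D/D
        per_obs = outer_dd - d2 / denom[:, :, None]
        rows = np.repeat(self._blocks, k, axis=1).reshape(n_obs, k, k)
        cols = rows.transpose(0, 2, 1)
        np.add.at(H, (rows.ravel(), cols.ravel()), per_obs.ravel())
        return H

    # ---- fitting -----------------------------------------------------

    def _reduction(self) -> np.ndarray:
        """Map from the (v-1)-dim free space to sum-to-zero full space."""
        T = np.vstack([np.eye(self.v - 1), -np.ones(self.v - 1)])
        return T

    def fit(self, tol: float = 1e-6, maxiter: int = 500) -> "MaxDiffResults":
        """Maximize the likelihood under the sum-to-zero constraint.

        Starts at beta = 0 (no random initialization).  Non-convergence
        returns a results object with ``converged=False`` plus a warning,
        never a silent success.  Items that were always best or always
        worst are flagged: their utilities drift to +/- infinity.
        """
        self._warn_separation()
        T = self._reduction()

        def neg_ll(x: np.ndarray) -> float:
            return -self.loglike(T @ x)

        def neg_grad(x: np.ndarray) -> np.ndarray:
            return -(T.T @ self.score(T @ x))

        res = optimize.minimize(
            neg_ll,
            np.zeros(self.v - 1),
            jac=neg_grad,
            method="BFGS",
            options={"gtol": tol, "maxiter": maxiter},
        )
        x = res.x
        # polish with Newton steps: BFGS can stall on precision loss with
        # the gradient still slightly above tol, and the Hessian is analytic.
        # An exhausted iteration budget is reported honestly, never polished.
        hit_maxiter = res.nit >= maxiter
        for _ in range(0 if hit_maxiter else 20):
            beta = T @ x
            grad_red = T.T @ self.score(beta)
            if np.linalg.norm(grad_red, ord=np.inf) <= tol:
                break
            H_red_step = T.T @ self.hessian(beta) @ T
            try:
                delta = np.linalg.solve(-H_red_step, grad_red)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(delta)):
                break
            x = x + delta
        beta = T @ x
        # honesty criterion is the gradient norm itself, not the optimizer's
        # status flag
        grad_norm = float(np.linalg.norm(T.T @ self.score(beta), ord=np.inf))
        converged = grad_norm <= tol
        if not converged:
            warnings.warn(
                f"optimizer did not converge (gradient norm {grad_norm:.3g} "
                f"after {res.nit} iterations)",
                ConvergenceWarning,
                stacklevel=2,
            )
        H_full = self.hessian(beta)
        H_red = T.T @ H_full @ T
        cov_red = np.linalg.inv(-H_red)
        cov_beta = T @ cov_red @ T.T
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
        return MaxDiffResults(
            model=self,
            params=pd.Series(beta, index=list(self.item_ids), name="beta"),
            bse=pd.Series(se, index=list(self.item_ids), name="se"),
            cov_params=pd.DataFrame(cov_beta, index=list(self.item_ids),
                                    columns=list(self.item_ids)),
            llf=self.loglike(beta),
            converged=converged,
            n_iter=int(res.nit),
        )

    def _warn_separation(self) -> None:
        avail = np.zeros(self.v, dtype=int)
        np.add.at(avail, self._blocks, 1)
        n_best = np.bincount(self._best, minlength=self.v)
        n_worst = np.bincount(self._worst, minlength=self.v)
        for i in range(self.v):
            if avail[i] and n_best[i] == avail[i]:
                warnings.warn(
                    f"item {self.item_ids[i]!r} was chosen best in every appearance; "
                    "its utility estimate drifts to +infinity",
                    SeparationWarning, stacklevel=3,
                )
            if avail[i] and n_worst[i] == avail[i]:
                warnings.warn(
                    f"item {self.item_ids[i]!r} was chosen worst in every appearance; "
                    "its utility estimate drifts to -infinity",
                    SeparationWarning, stacklevel=3,
                )


class MaxDiffResults:
    """Fitted utilities with uncertainties, in the statsmodels idiom.

    Attributes
    ----------
    params : pd.Series
        Sum-to-zero utility estimates (beta), indexed by item_id.
    bse : pd.Series
        Standard errors from the observed information.
    llf : float
        Maximized log-likelihood.
    """

    def __init__(self, model, params, bse, cov_params, llf, converged, n_iter):
        self.model = model
        self.params = params
        self.bse = bse
        self.cov_params = cov_params
        self.llf = llf
        self.converged = converged
        self.n_iter = n_iter
        self.subgroup = model.subgroup
        self.n_respondents = model.n_respondents
        self.nobs = model.nobs

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"ci_low": self.params - z * self.bse, "ci_high": self.params + z * self.bse}
        )

    @property
    def ranks(self) -> pd.Series:
        """1-based ranks, descending beta; ties broken by item_id."""
        order = sorted(self.params.index, key=lambda i: (-self.params[i], i))
        return pd.Series(
            {iid: rank for rank, iid in enumerate(order, start=1)}, name="rank"
        ).reindex(self.params.index)

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        df = pd.DataFrame(
            {
                "subgroup": self.subgroup,
                "item_id": self.params.index,
                "beta": self.params.values,
                "se": self.bse.values,
                "ci_low": ci["ci_low"].values,
                "ci_high": ci["ci_high"].values,
                "rank": self.ranks.values,
                "n": self.n_respondents,
                "loglik": self.llf,
                "converged": self.converged,
            }
        ).reset_index(drop=True)
        return df.sort_values("rank").reset_index(drop=True)

    def to_records(self) -> list[EstimationResult]:
        ci = self.conf_int()
        ranks = self.ranks
        return [
            EstimationResult(
                item_id=iid,
                beta=float(self.params[iid]),
                se=float(self.bse[iid]),
                ci_low=float(ci.loc[iid, "ci_low"]),
                ci_high=float(ci.loc[iid, "ci_high"]),
                rank=int(ranks[iid]),
                subgroup=self.subgroup,
                n_respondents=self.n_respondents,
                loglik=self.llf,
                converged=self.converged,
            )
            for iid in self.params.index
        ]

    def summary(self) -> str:
        lines = [
            "MaxDiff conditional-logit results",
            "=" * 64,
            f"subgroup: {self.subgroup}   respondents: {self.n_respondents}   "
            f"choice sets: {self.nobs}",
            f"likelihood: {self.model.likelihood}   log-likelihood: {self.llf:.3f}   "
            f"converged: {self.converged}",
            "-" * 64,
            f"{'item':<16}{'beta':>9}{'se':>8}{'[0.025':>9}{'0.975]':>9}{'rank':>6}",
            "-" * 64,
        ]
        ci = self.conf_int()
        ranks = self.ranks
        for iid in sorted(self.params.index, key=lambda i: ranks[i]):
            lines.append(
                f"{iid:<16}{self.params[iid]:>9.3f}{self.bse[iid]:>8.3f}"
                f"{ci.loc[iid, 'ci_low']:>9.3f}{ci.loc[iid, 'ci_high']:>9.3f}"
                f"{ranks[iid]:>6d}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_forest(self, ax=None):
        """Coefficient plot with 95% CI error bars, sorted by estimate."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * len(self.params) + 1))
        order = self.params.sort_values().index
        ci = self.conf_int().loc[order]
        y = np.arange(len(order))
        ax.errorbar(
            self.params[order], y,
            xerr=[self.params[order] - ci["ci_low"], ci["ci_high"] - self.params[order]],
            fmt="o", capsize=3,
        )
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(y, order)
        ax.set_xlabel("standardized score (beta)")
        ax.set_title(f"BWS utilities — {self.subgroup}")
        return ax


# ---- module-level conveniences --------------------------------------


def maxdiff_loglik(beta, dataset: StudyDataset) -> float:
    """Joint ordered-pair log-likelihood of complete responses at ``beta``.

    ``beta`` may be a full-length array (catalog order) or a mapping from
    item_id to utility.  Shift-invariant: adding a constant to all
    utilities leaves the value unchanged.
    """
    model = MaxDiffModel(dataset)
    if isinstance(beta, Mapping):
        beta = np.array([beta[i] for i in model.item_ids], dtype=float)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (model.v,):
        raise ValueError(f"beta must have length {model.v}")
    return model.loglike(beta)


def fit_maxdiff(
    dataset: StudyDataset,
    likelihood: str = "maxdiff",
    subgroup: str = "overall",
    tol: float = 1e-6,
    maxiter: int = 500,
) -> MaxDiffResults:
    """Fit the conditional-logit model to a complete-response dataset."""
    return MaxDiffModel(dataset, likelihood=likelihood, subgroup=subgroup).fit(
        tol=tol, maxiter=maxiter
    )


def fit_by_subgroup(
    dataset: StudyDataset, likelihood: str = "maxdiff", **fit_kw
) -> dict[str, MaxDiffResults]:
    """Independent fits per phase stratum; each satisfies the overall contract."""
    if not dataset.responses:
        raise ValueError("empty dataset: no subgroups to fit")
    phases = sorted(dataset.strata_counts)
    out: dict[str, MaxDiffResults] = {}
    for phase in phases:
        members = [r for r in dataset.responses if r.phase == phase]
        if not members:
            raise ValueError(f"subgroup {phase!r} is empty")
        out[phase] = fit_maxdiff(
            dataset.subset(members), likelihood=likelihood, subgroup=phase, **fit_kw
        )
    return out


@dataclass(frozen=True)
class ComparisonTable:
    """Per-phase top-m items plus per-item beta trajectories across phases."""

    top: pd.DataFrame            # rows rank 1..m, one column per phase, item_ids
    trajectories: pd.DataFrame   # index item_id, one column per phase, betas

    @property
    def phases(self) -> tuple[str, ...]:
        return tuple(self.top.columns)


def compare_subgroups(
    results: Mapping[str, MaxDiffResults], top_m: int = 4
) -> ComparisonTable:
    """Cross-tabulate subgroup fits: top-ranked items and beta trajectories."""
    if len(results) < 2:
        raise ValueError("need at least two subgroups to compare")
    phases = list(results)
    item_sets = {tuple(sorted(r.params.index)) for r in results.values()}
    if len(item_sets) != 1:
        raise ValueError("subgroup results cover different item catalogs")
    items = sorted(next(iter(item_sets)))
    if top_m > len(items):
        raise ValueError(f"top_m={top_m} exceeds the {len(items)}-item catalog")

    top = pd.DataFrame(index=pd.RangeIndex(1, top_m + 1, name="rank"))
    for phase in phases:
        ranks = results[phase].ranks
        by_rank = {int(v): k for k, v in ranks.items()}
        top[phase] = [by_rank[r] for r in range(1, top_m + 1)]

    traj = pd.DataFrame(
        {phase: results[phase].params.reindex(items) for phase in phases}
    )
    traj.index.name = "item_id"
    return ComparisonTable(top=top, trajectories=traj)


def _fd_jacobian(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    n = len(x)
    J = np.zeros((n, n))
    for i in range(n):
        step = np.zeros(n)
        step[i] = eps
        J[:, i] = (f(x + step) - f(x - step)) / (2 * eps)
    return 0.5 * (J + J.T)
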