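"""Additive B-spline regression of a child gene on its parents, and the
penalized marginal-likelihood score used for structure search.

Model
-----
For child gene ``j`` with parents ``pa_1 .. pa_q`` the expression of sample
``i`` is

    x_ij = m_1(pa_i1) + ... + m_q(pa_iq) + eps_j,   eps_j ~ N(0, sigma_j^2)

where each ``m_k`` is a cubic B-spline expansion with ``M`` coefficients
``gamma_k``. Coefficients are estimated by penalized least squares: a
second-order difference penalty per parent (smoothness, weight ``lambda``
picked from a small grid by the local score) plus a tiny ridge term that pins
the otherwise arbitrary constant split between additive components.

The smoothness penalty differences the coefficients against the Greville
abscissae spacing, so straight lines lie exactly in its nullspace even with
clamped (non-uniform) knots; smoothing therefore never biases a linear trend.

Scoring
-------
``local_log_score`` is the log marginal likelihood of the local model under a
Gaussian coefficient prior with precision proportional to the penalty — a
closed-form Laplace-type criterion: penalized fit term plus the
log-determinant complexity correction, with the residual variance plugged in.
Higher is better. Parentless children are scored as a Gaussian around the
sample mean.

Note on identifiability: because the additive components share constants,
individual edge contributions (ECv) carry an arbitrary per-component offset
fixed only by the ridge term. All downstream comparisons (ΔECv, edge t-tests,
clustering of centred profiles) difference these offsets out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg

from .splines import SplineBasis, build_basis, evaluate_basis, evaluate_spline

SIGMA2_FLOOR = 1e-12  # floor inside logs only; reported sigma2 is the raw RSS/n


@dataclass(frozen=True)
class ScoreConfig:
    """Hyperparameters shared by fitting and scoring.

    M : basis functions per parent (20 unless stated otherwise).
    lambda_grid : candidate smoothness weights; the best by local score wins.
    ridge_eps : tiny ridge pinning the additive-constant split.
    max_parents : cap on parent-set size during structure search.
    """

    M: int = 20
    lambda_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    ridge_eps: float = 1e-8
    max_parents: int = 3

    def __post_init__(self) -> None:
        if not self.lambda_grid or any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda_grid must be non-empty and positive")
        if self.ridge_eps <= 0:
            raise ValueError("ridge_eps must be > 0")


@dataclass
class LocalRegressionModel:
    """Fitted additive model for one child gene."""

    child: str
    parents: tuple[str, ...]
    bases: tuple[SplineBasis, ...]
    gamma: tuple[np.ndarray, ...]
    sigma2: float
    n_train: int
    intercept: float = 0.0  # used only when the child has no parents
    lam: float = 0.0

    @property
    def q(self) -> int:
        return len(self.parents)

    def component_value(self, k: int, x):
        """m_k evaluated at parent value(s) ``x`` (1-based parent index ``k``).

        This is the ECv kernel: the contribution of the k-th parent to the
        child's predicted expression, clamped to the training range.
        """
        if not 1 <= k <= self.q:
            raise IndexError(f"parent index {k} out of range 1..{self.q}")
        return evaluate_spline(self.bases[k - 1], self.gamma[k - 1], x)

    def predict(self, parent_values: Mapping[str, np.ndarray] | None = None):
        """Sum of component values (or the constant for parentless children)."""
        if self.q == 0:
            return self.intercept
        total = None
        for k, p in enumerate(self.parents, start=1):
            contrib = self.component_value(k, parent_values[p])
            total = contrib if total is None else total + contrib
        return total


def _difference_penalty(basis: SplineBasis) -> np.ndarray:
    """Second-order divided-difference penalty matrix ``P = D'D``.

    Differences are taken against the Greville abscissae so that coefficient
    vectors representing straight lines are annihilated exactly.
    """
    xi = basis.greville
    M = basis.M
    D = np.zeros((M - 2, M))
    for i in range(1, M - 1):
        hl = xi[i] - xi[i - 1]
        hr = xi[i + 1] - xi[i]
        D[i - 1, i - 1] = 1.0 / hl
        D[i - 1, i] = -(1.0 / hl + 1.0 / hr)
        D[i - 1, i + 1] = 1.0 / hr
    # scale to the mean spacing so lambda magnitudes are comparable across ranges
    D *= (basis.support_hi - basis.support_lo) / (M - 1)
    return D.T @ D


def _design(X, child: str, parents: Sequence[str], M: int):
    y = np.asarray(X.gene(child), dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError(f"need at least 2 samples to fit a local model, got {n}")
    bases, blocks, penalties = [], [], []
    for p in parents:
        v = np.asarray(X.gene(p), dtype=float)
        basis = build_basis(v, M)
        bases.append(basis)
        blocks.append(evaluate_basis(basis, v))
        penalties.append(_difference_penalty(basis))
    return y, bases, blocks, penalties


def _solve(y, blocks, penalties, lam, eps):
    B = np.hstack(blocks)
    K = scipy.linalg.block_diag(*[lam * P for P in penalties])
    K[np.diag_indices_from(K)] += eps
    A = B.T @ B + K
    c, low = scipy.linalg.cho_factor(A, lower=True)
    gamma = scipy.linalg.cho_solve((c, low), B.T @ y)
    resid = y - B @ gamma
    rss = float(resid @ resid)
    # log det A from the Cholesky factor; log det K separately (K is PD)
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
    sign, logdet_K = np.linalg.slogdet(K)
    pen = float(gamma @ (K @ gamma))
    return gamma, rss, pen, logdet_K, logdet_A


def _score_from_fit(n, rss, pen, logdet_K, logdet_A) -> float:
    sigma2 = max(rss / n, SIGMA2_FLOOR)
    return (
        -0.5 * n * np.log(2.0 * np.pi * sigma2)
        + 0.5 * (logdet_K - logdet_A)
        - (rss + pen) / (2.0 * sigma2)
    )


def _fit_best_lambda(y, blocks, penalties, cfg: ScoreConfig):
    best = None
    for lam in cfg.lambda_grid:
        gamma, rss, pen, ldK, ldA = _solve(y, blocks, penalties, lam, cfg.ridge_eps)
        score = _score_from_fit(len(y), rss, pen, ldK, ldA)
        if best is None or score > best[0]:
            best = (score, lam, gamma, rss)
    return best


def _constant_fit(y):
    mu = float(np.mean(y))
    rss = float(np.sum((y - mu) ** 2))
    return mu, rss


def fit_local_model(X, child: str, parents: Sequence[str], cfg: ScoreConfig | None = None) -> LocalRegressionModel:
    """Fit the additive B-spline regression of ``child`` on ``parents``.

    Parentless children get a constant model at the sample mean. The
    smoothness weight is chosen from ``cfg.lambda_grid`` by the local score.
    """
    cfg = cfg or ScoreConfig()
    parents = tuple(parents)
    if len(parents) > cfg.max_parents:
        raise ValueError(f"{len(parents)} parents exceeds max_parents={cfg.max_parents}")
    if not parents:
        y = np.asarray(X.gene(child), dtype=float)
        if len(y) < 2:
            raise ValueError("need at least 2 samples")
        mu, rss = _constant_fit(y)
        return LocalRegressionModel(
            child=child, parents=(), bases=(), gamma=(),
            sigma2=rss / len(y), n_train=len(y), intercept=mu,
        )
    y, bases, blocks, penalties = _design(X, child, parents, cfg.M)
    score, lam, gamma, rss = _fit_best_lambda(y, blocks, penalties, cfg)
    M = cfg.M
    gammas = tuple(gamma[k * M : (k + 1) * M].copy() for k in range(len(parents)))
    return LocalRegressionModel(
        child=child, parents=parents, bases=tuple(bases), gamma=gammas,
        sigma2=rss / len(y), n_train=len(y), lam=lam,
    )


def local_log_score(X, child: str, parents: Sequence[str], cfg: ScoreConfig | None = None) -> float:
    """Log marginal likelihood of the local model (higher is better)."""
    cfg = cfg or ScoreConfig()
    parents = tuple(parents)
    if len(parents) > cfg.max_parents:
        raise ValueError(f"{len(parents)} parents exceeds max_parents={cfg.max_parents}")
    y = np.asarray(X.gene(child), dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not parents:
        _, rss = _constant_fit(y)
        sigma2 = max(rss / n, SIGMA2_FLOOR)
        return float(-0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * n)
    _, _, blocks, penalties = _design(X, child, parents, cfg.M)
    score, *_ = _fit_best_lambda(y, blocks, penalties, cfg)
    return float(score)


# ---------------------------------------------------------------------------
# ModelSet: one fitted local model per network node


class ModelSet:
    """The fitted parameters of a whole network: one local model per child.

    The edge enumeration (``edges``) is the canonical column order of every
    ECv matrix derived from this set: children in lexicographic order, each
    child's parents in model order.
    """

    def __init__(self, models: Mapping[str, LocalRegressionModel]):
        self.models = dict(models)

    def __getitem__(self, child: str) -> LocalRegressionModel:
        return self.models[child]

    def __contains__(self, child: str) -> bool:
        return child in self.models

    @property
    def genes(self) -> list[str]:
        return sorted(self.models)

    @property
    def edges(self) -> list[tuple[str, str]]:
        out = []
        for child in self.genes:
            for p in self.models[child].parents:
                out.append((p, child))
        return out

    # -- serialization: plain JSON, exact float round-trip -------------------

    def to_dict(self) -> dict:
        doc = {}
        for child in self.genes:
            m = self.models[child]
            doc[child] = {
                "parents": list(m.parents),
                "knots": [b.knots.tolist() for b in m.bases],
                "support": [[b.support_lo, b.support_hi] for b in m.bases],
                "gamma": [g.tolist() for g in m.gamma],
                "sigma2": m.sigma2,
                "n_train": m.n_train,
                "intercept": m.intercept,
                "lambda": m.lam,
            }
        return doc

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelSet":
        models = {}
        for child, d in doc.items():
            bases = tuple(
                SplineBasis(knots=np.array(k), support_lo=s[0], support_hi=s[1])
                for k, s in zip(d["knots"], d["support"])
            )
            models[child] = LocalRegressionModel(
                child=child,
                parents=tuple(d["parents"]),
                bases=bases,
                gamma=tuple(np.array(g) for g in d["gamma"]),
                sigma2=d["sigma2"],
                n_train=d["n_train"],
                intercept=d.get("intercept", 0.0),
                lam=d.get("lambda", 0.0),
            )
        return cls(models)

    @classmethod
    def from_json(cls, source) -> "ModelSet":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


def fit_all_models(X, network, cfg: ScoreConfig | None = None) -> ModelSet:
    """Fit one local model per node of ``network`` (constant if parentless)."""
    cfg = cfg or ScoreConfig()
    missing = [g for g in network.genes if g not in X.genes]
    if missing:
        raise KeyError(f"network genes absent from expression matrix: {missing}")
    models = {}
    for gene in network.genes:
        parents = tuple(sorted(network.parents(gene)))
        models[gene] = fit_local_model(X, gene, parents, cfg)
    return ModelSet(models)
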