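"""Presence-background maximum-entropy model as an L1-penalised logistic fit.

Raw predictors are min-max scaled on the training table, expanded by feature
class (L: linear; LQ: + squares; LP: + pairwise products; LQP: both), and fit
by maximising the binomial log-likelihood under a per-feature L1 penalty

    lambda_j = rm * beta(class_j, n_presence) * sd_j / sqrt(n_presence)

where ``beta`` is the reference implementation's default per-class schedule,
piecewise-linearly interpolated over the presence count, and ``sd_j`` is the
feature's standard deviation over presence rows.  Zero-variance features are
always excluded (infinite penalty).  The intercept is unpenalised and the
output transform is logistic.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import Grid
from .terrain import VariableStack, layer_name, parse_layer_name

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("L", "LQ", "LP", "LQP")
FC_COMPLEXITY = {"L": 0, "LQ": 1, "LP": 2, "LQP": 3}

#: default per-class regularisation schedule: (presence-count knots, beta values)
DEFAULT_BETA_SCHEDULE: Dict[str, Tuple[Tuple[float, ...], Tuple[float, ...]]] = {
    "linear": ((10.0, 30.0, 100.0), (1.0, 0.2, 0.05)),
    "quadratic": ((10.0, 17.0, 30.0), (1.3, 0.8, 0.5)),
    "product": ((0.0, 10.0, 17.0, 30.0), (2.6, 1.6, 0.9, 0.55)),
}


def beta_for(feature_class: str, n_presence: int) -> float:
    """Interpolated default regularisation constant for a feature class."""
    knots, betas = DEFAULT_BETA_SCHEDULE[feature_class]
    return float(np.interp(n_presence, knots, betas))


@dataclass
class FeatureSpec:
    """Feature-class expansion applied to a set of base predictor columns."""

    fc: str
    base_columns: List[str]

    def __post_init__(self) -> None:
        if self.fc not in FEATURE_CLASSES:
            raise ValueError(f"fc must be one of {FEATURE_CLASSES}, got {self.fc!r}")
        self.base_columns = list(self.base_columns)

    @property
    def n_expanded(self) -> int:
        p = len(self.base_columns)
        n = p
        if "Q" in self.fc:
            n += p
        if "P" in self.fc:
            n += p * (p - 1) // 2
        return n

    def expanded_columns(self) -> Tuple[List[str], List[str]]:
        """(column names, feature class per column) after expansion."""
        names = list(self.base_columns)
        classes = ["linear"] * len(names)
        if "Q" in self.fc:
            names += [f"{c}^2" for c in self.base_columns]
            classes += ["quadratic"] * len(self.base_columns)
        if "P" in self.fc:
            for a, b in itertools.combinations(self.base_columns, 2):
                names.append(f"{a}*{b}")
                classes.append("product")
        return names, classes


@dataclass
class MaxentModel:
    """Fitted model: scaling, sparse coefficients and training metadata."""

    feature_spec: FeatureSpec
    rm: float
    coefficients: Dict[str, float]
    intercept: float
    feature_scaling: Dict[str, Tuple[float, float]]  # base column -> (min, max)
    training_meta: Dict[str, object] = field(default_factory=dict)

    @property
    def n_nonzero(self) -> int:
        return sum(1 for b in self.coefficients.values() if b != 0.0)

    # -- prediction ---------------------------------------------------------
    def _scale(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for c in self.feature_spec.base_columns:
            lo, hi = self.feature_scaling[c]
            span = hi - lo
            v = table[c].to_numpy(dtype=float)
            cols.append((v - lo) / span if span > 0 else np.zeros_like(v))
        return np.column_stack(cols)

    def design_matrix(self, table: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
        missing = [c for c in self.feature_spec.base_columns if c not in table.columns]
        if missing:
            raise KeyError(f"missing model features: {missing}")
        return expand_features(table, self.feature_spec, scaling=self.feature_scaling)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        X, names = self.design_matrix(table)
        beta = np.array([self.coefficients.get(nm, 0.0) for nm in names])
        return self.intercept + X @ beta

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Probability-scale predictions for feature-table rows."""
        return _sigmoid(self.linear_predictor(table))

    def predict_raster(self, stack: VariableStack) -> Grid:
        """Probability Grid over the layers named by the model's base columns.

        All required layers must share shape/transform; cells lacking any
        layer are masked.
        """
        keys = [parse_layer_name(c) for c in self.feature_spec.base_columns]
        grids = [stack[k] for k in keys]
        ref = grids[0]
        for g in grids[1:]:
            if g.shape != ref.shape or not np.allclose(g.transform, ref.transform):
                raise ValueError("model layers are not co-registered")
        valid = np.logical_and.reduce([g.valid_mask for g in grids])
        table = pd.DataFrame({layer_name(k): g.values[valid]
                              for k, g in zip(keys, grids)})
        probs = self.predict(table)
        out = np.full(ref.shape, np.nan)
        out[valid] = probs
        return Grid(values=out, transform=ref.transform, crs_id=ref.crs_id,
                    nodata_mask=~valid, source_tag=ref.source_tag)

    # -- serialisation ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "fc": self.feature_spec.fc,
            "base_columns": self.feature_spec.base_columns,
            "rm": self.rm,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "feature_scaling": {k: list(v) for k, v in self.feature_scaling.items()},
            "training_meta": self.training_meta,
            "output_transform": "logistic",
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        doc = json.loads(text)
        return cls(feature_spec=FeatureSpec(fc=doc["fc"], base_columns=doc["base_columns"]),
                   rm=doc["rm"], coefficients=doc["coefficients"],
                   intercept=doc["intercept"],
                   feature_scaling={k: tuple(v) for k, v in doc["feature_scaling"].items()},
                   training_meta=doc.get("training_meta", {}))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def expand_features(table: pd.DataFrame, spec: FeatureSpec,
                    scaling: Dict[str, Tuple[float, float]] | None = None,
                    ) -> Tuple[np.ndarray, List[str]]:
    """Expand base columns into the design matrix for a feature class.

    Linear terms are min-max scaled (scaling fit on ``table`` unless given);
    quadratic terms are squares of the scaled values and product terms the
    pairwise products.  Returns (matrix, column names).
    """
    for c in spec.base_columns:
        v = table[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in base column {c!r}")
    if scaling is None:
        scaling = fit_scaling(table, spec.base_columns)
    scaled = []
    for c in spec.base_columns:
        lo, hi = scaling[c]
        v = table[c].to_numpy(dtype=float)
        span = hi - lo
        scaled.append((v - lo) / span if span > 0 else np.zeros_like(v))
    S = np.column_stack(scaled)
    blocks = [S]
    if "Q" in spec.fc:
        blocks.append(S**2)
    if "P" in spec.fc:
        pairs = list(itertools.combinations(range(S.shape[1]), 2))
        if pairs:
            blocks.append(np.column_stack([S[:, i] * S[:, j] for i, j in pairs]))
    X = np.concatenate([b for b in blocks if b.size], axis=1) if blocks else S
    names, _ = spec.expanded_columns()
    assert X.shape[1] == len(names) == spec.n_expanded
    return X, names


def fit_scaling(table: pd.DataFrame, columns: Sequence[str]) -> Dict[str, Tuple[float, float]]:
    return {c: (float(table[c].min()), float(table[c].max())) for c in columns}


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: np.ndarray,
                 tol: float = 1e-7, max_iter: int = 10000,
                 ) -> Tuple[np.ndarray, float]:
    """Exact L1-penalised logistic fit via the positive/negative split.

    Minimises  (1/n) [ -loglik(beta0, beta) + sum_j lam_j |beta_j| ]  by
    writing beta = b+ - b- with b+, b- >= 0, which turns the penalty into a
    smooth linear term over a box; L-BFGS-B then solves the bound-constrained
    problem.  Features with non-finite lam are frozen at zero.  Convergence
    is verified against ``tol`` on the projected gradient; returns
    (beta, beta0) or raises with diagnostics.
    """
    from scipy.optimize import minimize

    n, p = X.shape
    active = np.flatnonzero(np.isfinite(lam))
    Xa = X[:, active]
    la = lam[active]
    pa = active.size

    def objective(theta: np.ndarray):
        beta0 = theta[0]
        bpos = theta[1:1 + pa]
        bneg = theta[1 + pa:]
        eta = beta0 + Xa @ (bpos - bneg)
        # -loglik = sum log(1 + e^eta) - y.eta, computed stably
        nll = float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)
        grad_eta = _sigmoid(eta) - y
        g = Xa.T @ grad_eta
        grad = np.concatenate(([grad_eta.sum()], g + la, -g + la)) / n
        return (nll + la @ (bpos + bneg)) / n, grad

    theta0 = np.zeros(1 + 2 * pa)
    mean_y = min(max(float(y.mean()), 1e-12), 1.0 - 1e-12)
    theta0[0] = math.log(mean_y / (1.0 - mean_y))
    bounds = [(None, None)] + [(0.0, None)] * (2 * pa)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                            "ftol": 1e-15, "gtol": tol / n})
    grad_ok = float(np.max(np.abs(_projected_gradient(res.x, res.jac, bounds)))) <= tol
    if not (res.success or grad_ok):
        raise RuntimeError(
            f"L1 logistic fit failed to converge: {res.message} "
            f"(nit={res.nit}, |pg|={np.max(np.abs(res.jac)):.3e})")
    beta = np.zeros(p)
    beta[active] = res.x[1:1 + pa] - res.x[1 + pa:]
    beta[np.abs(beta) < 1e-10] = 0.0
    beta, beta0 = _newton_polish(X, y, lam, beta, float(res.x[0]))
    return beta, beta0


def _newton_polish(X: np.ndarray, y: np.ndarray, lam: np.ndarray,
                   beta: np.ndarray, beta0: float, max_iter: int = 50,
                   gtol: float = 1e-12) -> Tuple[np.ndarray, float]:
    """Newton refinement on the active set (fixed signs) to machine precision.

    Within a fixed sign pattern the objective is smooth; a few Newton steps
    pin the optimum exactly, making fits deterministic under affine input
    rescaling.  Coefficients that try to cross zero are dropped instead.
    """
    n = X.shape[0]
    for _ in range(max_iter):
        act = np.flatnonzero(beta != 0.0)
        sign = np.sign(beta[act])
        Xa = X[:, act]
        eta = beta0 + Xa @ beta[act]
        p_hat = _sigmoid(eta)
        grad = np.concatenate(([np.sum(p_hat - y)],
                               Xa.T @ (p_hat - y) + lam[act] * sign))
        if np.max(np.abs(grad)) <= gtol * max(1.0, n):
            break
        w = np.clip(p_hat * (1.0 - p_hat), 1e-10, None)
        Xw = np.column_stack([np.ones(n), Xa]) * w[:, None]
        H = np.column_stack([np.ones(n), Xa]).T @ Xw
        H[np.diag_indices_from(H)] += 1e-12
        try:
            delta = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            break
        new0 = beta0 + delta[0]
        new = beta[act] + delta[1:]
        flipped = np.sign(new) * sign < 0
        new[flipped] = 0.0
        beta0 = new0
        beta[act] = new
    return beta, beta0


def _projected_gradient(theta: np.ndarray, grad: np.ndarray, bounds) -> np.ndarray:
    pg = grad.copy()
    for i, (lo, _hi) in enumerate(bounds):
        if lo is not None and theta[i] <= lo and grad[i] > 0:
            pg[i] = 0.0
    return pg


def fit_maxent(table: pd.DataFrame, spec: FeatureSpec, rm: float,
               label_column: str = "label", seed: int | None = None,
               tol: float = 1e-7, max_iter: int = 10000) -> MaxentModel:
    """Fit the presence-background model on a feature table.

    ``table`` must contain the base columns and a 0/1 ``label`` column with
    both classes present.  ``rm`` scales every per-feature penalty.
    """
    if rm <= 0:
        raise ValueError(f"rm must be > 0, got {rm}")
    y = table[label_column].to_numpy(dtype=float)
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both presence and background rows are required")
    scaling = fit_scaling(table, spec.base_columns)
    X, names = expand_features(table, spec, scaling=scaling)
    _, classes = spec.expanded_columns()

    m = int(y.sum())
    pres = y == 1
    sd_pres = X[pres].std(axis=0, ddof=0)
    sd_all = X.std(axis=0, ddof=0)
    lam = np.empty(X.shape[1])
    for j, cls in enumerate(classes):
        if sd_all[j] <= 0:
            lam[j] = np.inf  # zero-variance feature: always excluded
        else:
            # presence-sample spread, falling back to the overall spread when
            # the feature is degenerate over presences alone
            sd = sd_pres[j] if sd_pres[j] > 0 else sd_all[j]
            lam[j] = rm * beta_for(cls, m) * sd / math.sqrt(m)
    beta, beta0 = _l1_logistic(X, y, lam, tol=tol, max_iter=max_iter)
    coefficients = {nm: float(b) for nm, b in zip(names, beta)}
    return MaxentModel(feature_spec=spec, rm=float(rm), coefficients=coefficients,
                       intercept=float(beta0), feature_scaling=scaling,
                       training_meta={"n_presence": m, "n_background": int((y == 0).sum()),
                                      "seed": seed})


# ---------------------------------------------------------------------------
# FC x RM selection
# ---------------------------------------------------------------------------

def select_parameters(cv_summary: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum selection over (fc, rm) candidates.

    ``cv_summary`` needs columns fc, rm, mean_auc_test, mean_bic.  AUC is
    ranked descending (best = 1), BIC ascending; ranks are averaged over ties.
    The winner minimises rank_auc + rank_bic; ties break by higher mean AUC,
    then lower rm, then simpler fc.
    """
    required = {"fc", "rm", "mean_auc_test", "mean_bic"}
    missing = required - set(cv_summary.columns)
    if missing:
        raise ValueError(f"cv_summary lacks columns: {sorted(missing)}")
    if cv_summary[["mean_auc_test", "mean_bic"]].isna().any().any():
        raise ValueError("missing candidate metrics")
    df = cv_summary.copy().reset_index(drop=True)
    df["rank_auc"] = df["mean_auc_test"].rank(ascending=False, method="average")
    df["rank_bic"] = df["mean_bic"].rank(ascending=True, method="average")
    df["rank_sum"] = df["rank_auc"] + df["rank_bic"]
    order = df.assign(_fc=df["fc"].map(FC_COMPLEXITY)).sort_values(
        by=["rank_sum", "mean_auc_test", "rm", "_fc"],
        ascending=[True, False, True, True], kind="stable")
    winner_idx = order.index[0]
    df["winner"] = False
    df.loc[winner_idx, "winner"] = True
    return df
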