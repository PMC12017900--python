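"""Model evaluation: AUC/BIC, leave-one-reef-out CV, jackknife importance,
response curves, rank-based model-group comparison and habitat overlap."""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Grid
from .maxent import FeatureSpec, MaxentModel, fit_maxent

logger = logging.getLogger(__name__)

_PROB_EPS = 1e-12


def auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(pos > neg) with ties counted one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def bic(model: MaxentModel, table: pd.DataFrame, label_column: str = "label") -> float:
    """k*ln(n) - 2*lnL with k = nonzero coefficients + 1 and the unpenalised
    binomial log-likelihood at the fitted coefficients."""
    if len(table) == 0:
        raise ValueError("empty data")
    y = table[label_column].to_numpy(dtype=float)
    p = np.clip(model.predict(table), _PROB_EPS, 1.0 - _PROB_EPS)
    lnl = float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    k = model.n_nonzero + 1
    return k * np.log(len(table)) - 2.0 * lnl


# ---------------------------------------------------------------------------
# Leave-one-reef-out cross-validation
# ---------------------------------------------------------------------------

def loro_cv(table: pd.DataFrame, spec: FeatureSpec, rm: float,
            n_iterations: int = 10, seed: int | None = None,
            n_replicates: int = 3) -> pd.DataFrame:
    """Leave-one-reef-out CV, replicated background splits, over iterations.

    Per iteration and per reef with presences, the model trains on presences
    from every other reef plus a random 75% of background rows, and is tested
    on the held-out reef's presences against the remaining 25% of background;
    the background split is redrawn ``n_replicates`` times (triplicate by
    default).  Returns one row per (iteration, reef, replicate) with AUC_TEST
    (test split) and BIC (training fit).
    """
    pres = table[table["label"] == 1]
    bg = table[table["label"] == 0]
    reefs = sorted(pres["reef_id"].dropna().unique())
    if len(reefs) < 2:
        raise ValueError("need presences on at least 2 reefs")
    rng = np.random.default_rng(seed)
    records = []
    for it in range(n_iterations):
        for reef in reefs:
            test_pres = pres[pres["reef_id"] == reef]
            train_pres = pres[pres["reef_id"] != reef]
            if test_pres.empty:
                logger.info("loro_cv: reef %s has no presences; skipped", reef)
                continue
            for rep in range(n_replicates):
                perm = rng.permutation(len(bg))
                n_train = int(round(0.75 * len(bg)))
                bg_train = bg.iloc[perm[:n_train]]
                bg_test = bg.iloc[perm[n_train:]]
                train = pd.concat([train_pres, bg_train], ignore_index=True)
                test = pd.concat([test_pres, bg_test], ignore_index=True)
                model = fit_maxent(train, spec, rm)
                scores = model.predict(test)
                y_test = test["label"].to_numpy()
                records.append({
                    "fc": spec.fc, "rm": rm, "iteration": it, "reef_id": reef,
                    "replicate": rep,
                    "auc_test": auc(scores[y_test == 1], scores[y_test == 0]),
                    "bic": bic(model, train),
                    "n_train": len(train), "n_test": len(test),
                })
    return pd.DataFrame(records)


def summarize_cv(records: pd.DataFrame) -> pd.DataFrame:
    """Mean AUC_TEST / BIC per (fc, rm), ready for select_parameters."""
    return (records.groupby(["fc", "rm"], as_index=False)
            .agg(mean_auc_test=("auc_test", "mean"), mean_bic=("bic", "mean")))


# ---------------------------------------------------------------------------
# Jackknife variable importance
# ---------------------------------------------------------------------------

def _holdout_split(table: pd.DataFrame, rng: np.random.Generator,
                   train_frac: float = 0.75) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded 75/25 split, stratified by label."""
    train_idx, test_idx = [], []
    for _, sub in table.groupby("label"):
        perm = rng.permutation(sub.index.to_numpy())
        cut = int(round(train_frac * len(perm)))
        train_idx.extend(perm[:cut])
        test_idx.extend(perm[cut:])
    return table.loc[train_idx].reset_index(drop=True), table.loc[test_idx].reset_index(drop=True)


def _split_auc(train: pd.DataFrame, test: pd.DataFrame, spec: FeatureSpec,
               rm: float) -> float:
    model = fit_maxent(train, spec, rm)
    scores = model.predict(test)
    y = test["label"].to_numpy()
    return auc(scores[y == 1], scores[y == 0])


def jackknife(table: pd.DataFrame, spec: FeatureSpec, rm: float,
              seed: int | None = None, auc_threshold: float = 0.7) -> pd.DataFrame:
    """Per-variable AUC_ONLY / AUC_WITHOUT / AUC_TOTAL on a seeded holdout.

    AUC_TOTAL comes from a single full fit shared by every row; top_flag
    marks variables whose single-variable model exceeds ``auc_threshold``.
    """
    variables = spec.base_columns
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    rng = np.random.default_rng(seed)
    train, test = _holdout_split(table, rng)
    auc_total = _split_auc(train, test, spec, rm)
    rows = []
    for v in variables:
        only = FeatureSpec(fc=spec.fc, base_columns=[v])
        without = FeatureSpec(fc=spec.fc, base_columns=[c for c in variables if c != v])
        auc_only = _split_auc(train, test, only, rm)
        auc_without = _split_auc(train, test, without, rm)
        rows.append({"variable_key": v, "auc_only": auc_only,
                     "auc_without": auc_without, "auc_total": auc_total,
                     "top_flag": auc_only > auc_threshold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Response curves
# ---------------------------------------------------------------------------

@dataclass
class ResponseCurve:
    variable_key: str
    kind: str  # "marginal" | "individual"
    values: np.ndarray
    probabilities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variable_key": self.variable_key, "kind": self.kind,
                             "value": self.values, "probability": self.probabilities})


def response_curve(model: MaxentModel, table: pd.DataFrame, variable_key: str,
                   kind: str = "marginal", n_grid: int = 100) -> ResponseCurve:
    """Predicted probability along one variable's training range.

    marginal: other variables held at their training means; individual:
    predictions from a model refit on that variable alone.
    """
    if variable_key not in model.feature_spec.base_columns:
        raise KeyError(f"variable {variable_key!r} not in model")
    if kind not in ("marginal", "individual"):
        raise ValueError(f"bad curve kind {kind!r}")
    lo = float(table[variable_key].min())
    hi = float(table[variable_key].max())
    grid = np.linspace(lo, hi, n_grid)
    frame = pd.DataFrame({variable_key: grid})
    if kind == "marginal":
        for c in model.feature_spec.base_columns:
            if c != variable_key:
                frame[c] = float(table[c].mean())
        probs = model.predict(frame)
    else:
        solo = fit_maxent(table, FeatureSpec(fc=model.feature_spec.fc,
                                             base_columns=[variable_key]), model.rm)
        probs = solo.predict(frame)
    return ResponseCurve(variable_key=variable_key, kind=kind, values=grid,
                         probabilities=probs)


# ---------------------------------------------------------------------------
# Model-group comparison (Kruskal-Wallis + Dunn/Holm + letters)
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    kw_h: float
    kw_df: int
    kw_p: float
    dunn_pairs: pd.DataFrame  # group_a, group_b, z, p_raw, p_holm, significant
    letters: Dict[str, str]


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, never below the raw p)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _dunn_pairs(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    ranks = stats.rankdata(values)
    n = values.size
    # tie correction term for the Dunn z denominator
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[labels == g].mean() for g in names}
    sizes = {g: int((labels == g).sum()) for g in names}
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_holm"] = _holm(df["p_raw"].to_numpy()) if len(df) else []
    return df


def _letter_display(names: Sequence[str], distinct: set) -> Dict[str, str]:
    """Greedy insert-absorb compact letter display.

    Groups sharing a letter are statistically indistinguishable; ``distinct``
    holds frozensets of significantly different pairs.
    """
    cliques: List[set] = []
    for g in names:
        placed = False
        for clique in cliques:
            if all(frozenset((g, other)) not in distinct for other in clique):
                clique.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    # absorb cliques fully contained in another
    cliques = [c for i, c in enumerate(cliques)
               if not any(i != j and c < other for j, other in enumerate(cliques))]
    alphabet = string.ascii_lowercase
    letters = {g: "" for g in names}
    for i, clique in enumerate(cliques):
        for g in names:
            if g in clique:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def compare_model_groups(groups: Mapping[str, np.ndarray],
                         alpha: float = 0.05) -> ComparisonResult:
    """Kruskal-Wallis across groups with Dunn/Holm pairwise follow-up.

    Returns H, df, p, the adjusted pairwise table and a compact letter
    display; identical distributions share one letter.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]) or \
            len(np.unique(np.concatenate(arrays))) == 1:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    dunn = _dunn_pairs(dict(zip(names, arrays)))
    if len(dunn):
        dunn["significant"] = dunn["p_holm"] < alpha
        distinct = {frozenset((r.group_a, r.group_b))
                    for r in dunn.itertuples() if r.significant}
    else:
        distinct = set()
    letters = _letter_display(names, distinct)
    return ComparisonResult(kw_h=float(h), kw_df=len(names) - 1, kw_p=float(p),
                            dunn_pairs=dunn, letters=letters)


# ---------------------------------------------------------------------------
# Habitat overlap
# ---------------------------------------------------------------------------

DEFAULT_PROB_BINS = (0.0, 0.25, 0.50, 0.75, 1.0)


def habitat_overlap(pairs: Sequence[Tuple[Grid, Grid]] | Tuple[Grid, Grid],
                    suitable_classes: Iterable[float],
                    bins: Sequence[float] = DEFAULT_PROB_BINS) -> pd.DataFrame:
    """Suitable-habitat fraction per predicted-probability bin, across reefs.

    ``pairs`` is one (prediction, habitat-class) grid pair per reef.  Bins are
    closed on the right, with 0 assigned to the first bin.  Returns per-bin
    mean and standard error of the per-reef suitable fractions.
    """
    if isinstance(pairs, tuple) and isinstance(pairs[0], Grid):
        pairs = [pairs]  # type: ignore[list-item]
    suitable = set(suitable_classes)
    if not suitable:
        raise ValueError("suitable_classes must be non-empty")
    edges = np.asarray(bins, dtype=float)
    per_reef = []  # one row of per-bin fractions per reef
    for pred, habitat in pairs:  # type: ignore[union-attr]
        if pred.shape != habitat.shape or not np.allclose(pred.transform, habitat.transform):
            raise ValueError("prediction and habitat grids are misaligned")
        ok = pred.valid_mask & habitat.valid_mask
        p = pred.values[ok]
        h = habitat.values[ok]
        is_suit = np.isin(h, list(suitable))
        idx = np.digitize(p, edges[1:-1], right=True)  # (lo, hi] bins, 0 -> first
        fracs = []
        for b in range(len(edges) - 1):
            sel = idx == b
            fracs.append(float(is_suit[sel].mean()) if sel.any() else np.nan)
        per_reef.append(fracs)
    mat = np.asarray(per_reef)
    counts = np.sum(np.isfinite(mat), axis=0)
    mean = np.full(mat.shape[1], np.nan)
    se = np.full(mat.shape[1], np.nan)
    for b in range(mat.shape[1]):
        col = mat[np.isfinite(mat[:, b]), b]
        if col.size:
            mean[b] = col.mean()
        if col.size > 1:
            se[b] = col.std(ddof=1) / np.sqrt(col.size)
    return pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:],
        "mean_suitable_fraction": mean, "se_suitable_fraction": se,
        "n_reefs": counts,
    })
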