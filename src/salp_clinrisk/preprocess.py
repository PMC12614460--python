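"""Leakage-guarded preprocessing for the rupture-risk pipeline.

Implements the study's preprocessing contract: a stratified 64/16/20
train/validation/test split whose sizes follow largest-remainder allocation,
chained-equation imputation run separately within each partition, univariate
p < 0.05 feature screening (test chosen by variable kind and normality /
expected-count rules), minority oversampling by SMOTE, and standardization
whose parameters are fitted on the training partition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.neighbors import NearestNeighbors

from .cohort import OUTCOME_COLUMN

__all__ = [
    "SplitIndices",
    "ScalerParams",
    "largest_remainder",
    "split_cohort",
    "impute_chained",
    "screen_features",
    "smote_oversample",
    "apply_smote",
    "standardize",
    "infer_binary_columns",
]


# ---------------------------------------------------------------------------
# splitting

@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def as_dict(self) -> dict[str, list[int]]:
        return {
            "train": self.train.tolist(),
            "validation": self.validation.tolist(),
            "test": self.test.tolist(),
        }


def largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer allocation of n items to fractional shares.

    Floors each share, then hands the leftover units to the largest
    fractional remainders. For 774 rows at (0.64, 0.16, 0.20) this yields
    exactly (495, 124, 155).
    """
    raw = np.asarray(fractions, dtype=float) * n
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    short = n - int(sizes.sum())
    # stable tie-break: larger remainder first, earlier split wins ties
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        sizes[idx] += 1
    return sizes.tolist()


def split_cohort(
    cohort: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.64, 0.16, 0.20),
    seed: int = 0,
    outcome: str = OUTCOME_COLUMN,
) -> SplitIndices:
    """Stratified three-way split with largest-remainder size allocation.

    Events and non-events are allocated separately: event counts per split
    follow their own largest-remainder allocation, and non-events fill each
    split to its overall size, keeping per-split prevalence within one case
    of the global prevalence.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    y = cohort[outcome].to_numpy()
    n = len(cohort)
    sizes = largest_remainder(n, fractions)
    n_event = int((y == 1).sum())
    event_sizes = largest_remainder(n_event, fractions)
    nonevent_sizes = [s - e for s, e in zip(sizes, event_sizes)]
    if any(s < 0 for s in nonevent_sizes):
        raise ValueError("event allocation exceeds a split size; use fewer splits")

    rng = np.random.default_rng(seed)
    pos = rng.permutation(np.flatnonzero(y == 1))
    neg = rng.permutation(np.flatnonzero(y != 1))

    parts = []
    p0 = n0 = 0
    for e_k, m_k in zip(event_sizes, nonevent_sizes):
        idx = np.concatenate([pos[p0 : p0 + e_k], neg[n0 : n0 + m_k]])
        parts.append(np.sort(idx))
        p0 += e_k
        n0 += m_k
    return SplitIndices(*parts)


# ---------------------------------------------------------------------------
# imputation

def infer_binary_columns(df: pd.DataFrame, exclude: tuple[str, ...] = (OUTCOME_COLUMN,)) -> list[str]:
    """Columns whose observed values are a subset of {0, 1}."""
    out = []
    for col in df.columns:
        if col in exclude:
            continue
        vals = df[col].dropna().unique()
        if len(vals) and np.isin(vals, (0, 1)).all():
            out.append(col)
    return out


def impute_chained(
    partition: pd.DataFrame,
    n_cycles: int = 10,
    seed: int = 0,
    outcome: str = OUTCOME_COLUMN,
) -> pd.DataFrame:
    """Chained-equation imputation returning a single completed dataset.

    Missing cells are initialised at the column mean (mode for binary
    columns), then each incomplete variable in turn is re-imputed by a
    regression on all other variables — linear for continuous targets,
    logistic for binary ones — for ``n_cycles`` sweeps. Observed cells are
    never altered. The sweep order is the (seeded) shuffled order of
    incomplete columns, fixed across cycles; the regressions themselves are
    deterministic, so the result is reproducible for a fixed seed.
    """
    out = partition.copy()
    feature_cols = [c for c in out.columns if c != outcome]
    missing_mask = out[feature_cols].isna()
    incomplete = [c for c in feature_cols if missing_mask[c].any()]
    if not incomplete:
        return out
    complete_cols = [c for c in out.columns if not out[c].isna().any()]
    if not complete_cols:
        raise ValueError("need at least one fully observed column")
    for col in incomplete:
        if out[col].notna().sum() == 0:
            raise ValueError(f"column {col!r} has no observed values")

    binary_cols = set(infer_binary_columns(out, exclude=(outcome,)))
    # initial fill: mean / mode from observed cells
    for col in incomplete:
        observed = out[col].dropna()
        fill = observed.mode().iloc[0] if col in binary_cols else observed.mean()
        out[col] = out[col].fillna(fill)

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(incomplete))

    X_cols = {c: [f for f in out.columns if f != c] for c in incomplete}
    for _ in range(n_cycles):
        for col in order:
            obs = ~missing_mask[col].to_numpy()
            X = out[X_cols[col]].to_numpy(dtype=float)
            y = out[col].to_numpy(dtype=float)
            if col in binary_cols:
                if len(np.unique(y[obs])) < 2:
                    continue  # degenerate: keep mode fill
                model = LogisticRegression(max_iter=1000)
                model.fit(X[obs], y[obs])
                pred = model.predict(X[~obs])
            else:
                model = LinearRegression()
                model.fit(X[obs], y[obs])
                pred = model.predict(X[~obs])
            col_vals = out[col].to_numpy(dtype=float)
            col_vals[~obs] = pred
            out[col] = col_vals
    return out


# ---------------------------------------------------------------------------
# univariate screening

def _screen_continuous(x0: np.ndarray, x1: np.ndarray, alpha: float) -> tuple[str, float, float]:
    """Normality-gated two-group test: t if both groups pass Shapiro-Wilk."""
    normal = True
    for g in (x0, x1):
        if len(g) < 3 or np.ptp(g) == 0:
            normal = False
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal &= stats.shapiro(g).pvalue > alpha
    if normal:
        stat, p = stats.ttest_ind(x0, x1)
        return "t", float(stat), float(p)
    stat, p = stats.mannwhitneyu(x0, x1, alternative="two-sided")
    return "mann-whitney", float(stat), float(p)


def _screen_binary(x0: np.ndarray, x1: np.ndarray) -> tuple[str, float, float]:
    """Chi-square with Fisher's exact fallback when an expected count < 5."""
    table = np.array(
        [[(x0 == 0).sum(), (x0 == 1).sum()], [(x1 == 0).sum(), (x1 == 1).sum()]], dtype=float
    )
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        res = stats.fisher_exact(table)
        return "fisher", float(res[0]), float(res[1])
    chi2, p, _, _ = stats.chi2_contingency(table)
    return "chi-square", float(chi2), float(p)


def screen_features(
    train: pd.DataFrame,
    alpha: float = 0.05,
    top_k: int | None = None,
    outcome: str = OUTCOME_COLUMN,
) -> pd.DataFrame:
    """Univariate between-group screening on the (complete) training table.

    Continuous variables: Shapiro-Wilk normality per outcome group; both
    normal at ``alpha`` -> two-sample t-test, otherwise Mann-Whitney U.
    Binary variables: chi-square, switching to Fisher's exact when any
    expected cell count is below 5. A variable is selected when p < alpha;
    ``top_k`` additionally keeps only the k smallest selected p-values
    (the study reports nine variables entering its models).

    Returns a DataFrame with columns
    ``variable, kind, test, statistic, p_value, selected``.
    """
    if train.drop(columns=[outcome]).isna().any().any():
        raise ValueError("training table must be imputed before screening")
    y = train[outcome].to_numpy()
    binary_cols = set(infer_binary_columns(train, exclude=(outcome,)))
    rows = []
    for col in train.columns:
        if col == outcome:
            continue
        x = train[col].to_numpy(dtype=float)
        x0, x1 = x[y == 0], x[y == 1]
        kind = "binary" if col in binary_cols else "continuous"
        if np.ptp(x) == 0:
            warnings.warn(f"constant column {col!r}: marked unselected", stacklevel=2)
            rows.append((col, kind, "constant", np.nan, 1.0))
            continue
        if kind == "binary":
            test, stat, p = _screen_binary(x0, x1)
        else:
            test, stat, p = _screen_continuous(x0, x1, alpha)
        rows.append((col, kind, test, stat, p))
    result = pd.DataFrame(rows, columns=["variable", "kind", "test", "statistic", "p_value"])
    result["selected"] = result["p_value"] < alpha
    if top_k is not None:
        keep = result.loc[result["selected"]].nsmallest(top_k, "p_value")["variable"]
        result["selected"] = result["variable"].isin(set(keep))
    return result


# ---------------------------------------------------------------------------
# SMOTE

def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
    binary_columns: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to a balanced class ratio.

    Each synthetic row is x + u * (x_nn - x) for a minority row x, one of
    its ``k_neighbors`` nearest minority neighbours x_nn (Euclidean), and
    u ~ U(0, 1), so every synthetic coordinate lies between its two parents.
    Binary columns take the value of the nearer parent (threshold 0.5 after
    interpolation). Original rows are preserved and come first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = n_maj - n_min
    if n_new == 0:
        return X.copy(), y.copy()
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={k_neighbors}"
        )

    rng = np.random.default_rng(seed)
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self

    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    parents = X_min[base]
    partners = X_min[neigh[base, pick]]
    synth = parents + u[:, None] * (partners - parents)
    if binary_columns is not None and len(binary_columns):
        cols = np.asarray(binary_columns)
        # threshold 0.5 on the interpolated value == value of the nearer parent
        synth[:, cols] = (synth[:, cols] >= 0.5).astype(float)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def apply_smote(
    train: pd.DataFrame,
    k_neighbors: int = 5,
    seed: int = 0,
    outcome: str = OUTCOME_COLUMN,
) -> pd.DataFrame:
    """DataFrame wrapper over :func:`smote_oversample` for a training table."""
    feature_cols = [c for c in train.columns if c != outcome]
    binary_cols = infer_binary_columns(train, exclude=(outcome,))
    bin_idx = np.array([feature_cols.index(c) for c in binary_cols], dtype=int)
    X, y = smote_oversample(
        train[feature_cols].to_numpy(dtype=float),
        train[outcome].to_numpy(),
        k_neighbors=k_neighbors,
        seed=seed,
        binary_columns=bin_idx,
    )
    out = pd.DataFrame(X, columns=feature_cols)
    out[outcome] = y
    return out


# ---------------------------------------------------------------------------
# standardization

@dataclass(frozen=True)
class ScalerParams:
    """Per-variable centre/scale fitted on the training partition only."""

    center: pd.Series
    scale: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        cols = self.center.index
        out[cols] = (df[cols] - self.center) / self.scale
        return out


def standardize(
    train: pd.DataFrame,
    *others: pd.DataFrame,
    outcome: str = OUTCOME_COLUMN,
) -> tuple[ScalerParams, pd.DataFrame, ...]:
    """Fit z-score parameters on the training table; apply to all tables.

    Zero-variance columns get scale 1 (with a warning) so they pass through
    centred. Returns ``(params, train_t, *others_t)``.
    """
    feature_cols = [c for c in train.columns if c != outcome]
    center = train[feature_cols].mean()
    scale = train[feature_cols].std(ddof=0)
    zero = scale[scale == 0].index
    if len(zero):
        warnings.warn(f"zero-variance columns scaled by 1: {list(zero)}", stacklevel=2)
        scale[zero] = 1.0
    params = ScalerParams(center=center, scale=scale)
    return (params, params.transform(train), *(params.transform(df) for df in others))
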