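"""Empirical-Bayes moderated linear models for count-derived matrices.

Counts are filtered for detectable expression, normalised to log2 counts
per million (CPM), and each feature is fitted with ordinary least squares
under the intercept-free design ``~0 + treatment + cell_line``. Residual
variances are shrunk toward a common prior by the standard empirical-Bayes
scheme: the prior variance and its degrees of freedom are estimated by
method of moments on the log residual variances, and the posterior variance

    s2_post = (d_prior * s2_prior + d_res * s2_res) / (d_prior + d_res)

replaces the per-feature residual variance in t- and F-statistics, whose
null distributions gain d_prior degrees of freedom.

The model object follows the fit/Results convention: build a
:class:`ModeratedLinearModel` from a matrix and a sample sheet, call
``fit()`` with named contrasts, and read estimates off the returned
:class:`DifferentialResults`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.special import polygamma
from sklearn.cluster import KMeans

__all__ = [
    "filter_detectable",
    "normalize_log_cpm",
    "normalize_log_cpm_robust",
    "median_ratio_factors",
    "bh_adjust",
    "ModeratedLinearModel",
    "DifferentialResults",
    "ModerationState",
    "moderated_f_select",
    "zscore_by_group",
    "zscore_and_cluster",
    "score_signature",
]


# ---------------------------------------------------------------------------
# normalisation


def filter_detectable(counts: pd.DataFrame, min_samples: int = 2) -> pd.DataFrame:
    """Retain features with nonzero counts in at least ``min_samples`` samples."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    keep = (counts > 0).sum(axis=1) >= min_samples
    return counts.loc[keep]


def normalize_log_cpm(counts, prior_count: float = 0.5):
    """log2 counts per million: log2((c + prior) / (lib + 2*prior) * 1e6).

    The doubled prior in the denominator keeps zero-count values finite
    while leaving CPM invariant to scaling a library.
    """
    arr = np.asarray(counts, dtype=float)
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    cpm = (arr + prior_count) / (lib + 2 * prior_count) * 1e6
    out = np.log2(cpm)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def median_ratio_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors (relative library scale per sample).

    Computed on features positive in every sample, against their geometric
    mean; robust to a minority of strongly regulated features, which
    otherwise inflate library-size normalisation and bias fold changes
    toward zero (composition bias). Factors are scaled to geometric mean 1.
    """
    arr = np.asarray(counts, dtype=float)
    pos = (arr > 0).all(axis=1)
    if pos.sum() < 10:
        return np.ones(arr.shape[1])
    logc = np.log(arr[pos])
    ratios = logc - logc.mean(axis=1, keepdims=True)
    f = np.exp(np.median(ratios, axis=0))
    return f / np.exp(np.mean(np.log(f)))


def normalize_log_cpm_robust(counts, prior_count: float = 0.5):
    """log2 CPM against composition-corrected effective library sizes."""
    arr = np.asarray(counts, dtype=float)
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    f = median_ratio_factors(arr)
    eff = f * np.exp(np.mean(np.log(lib)))
    out = np.log2((arr + prior_count) / (eff + 2 * prior_count) * 1e6)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if len(p) and (np.any((p < 0) | (p > 1)) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d_res: float) -> tuple[float, float]:
    """Method-of-moments fit of (s2_prior, d_prior) on log residual variances.

    Models s2_g ~ s2_prior * F(d_res, d_prior) and matches the mean and
    variance of log(s2_g) via digamma/trigamma identities.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return float(np.mean(s2[ok])) if ok.any() else 1.0, np.inf
    z = np.log(s2[ok])
    e = z - polygamma(0, d_res / 2) + np.log(d_res / 2)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, d_res / 2))
    if evar <= 0:
        return float(np.exp(emean)), np.inf
    d_prior = 2.0 * _trigamma_inverse(evar)
    s2_prior = float(np.exp(emean + polygamma(0, d_prior / 2) - np.log(d_prior / 2)))
    return s2_prior, d_prior


@dataclass
class ModerationState:
    """Shrinkage hyperparameters and per-feature posterior variances."""

    s2_prior: float
    d_prior: float
    d_res: float
    s2_residual: np.ndarray
    s2_posterior: np.ndarray

    @property
    def df_total(self) -> float:
        return self.d_res + self.d_prior


def _parse_contrast(expr: str, columns: list[str]) -> np.ndarray:
    """Parse a linear contrast like "DTP - DMSO" or "0.5*A + 0.5*B - C"."""
    vec = np.zeros(len(columns))
    col_index = {c: i for i, c in enumerate(columns)}
    tokens = re.findall(r"([+-]?)\s*(?:([\d.]+)\s*\*\s*)?([A-Za-z_][\w.]*)", expr)
    if not tokens:
        raise ValueError(f"cannot parse contrast {expr!r}")
    for sign, coef, name in tokens:
        if name not in col_index:
            raise ValueError(
                f"unknown term {name!r} in contrast {expr!r}; "
                f"design columns are {columns}"
            )
        c = float(coef) if coef else 1.0
        vec[col_index[name]] = -c if sign == "-" else c
    return vec


class ModeratedLinearModel:
    """Per-feature linear model with empirical-Bayes variance moderation.

    Parameters
    ----------
    data
        feature x sample matrix (log2 CPM or any roughly Gaussian scale).
    sample_info
        One row per sample (aligned to ``data`` columns) with a
        ``treatment`` column and optionally a ``cell_line`` column; the
        design is the intercept-free ``~0 + treatment + cell_line``
        parameterisation (one indicator per treatment, cell-line offsets
        relative to the first line).
    """

    def __init__(self, data: pd.DataFrame, sample_info: pd.DataFrame):
        if list(data.columns) != list(sample_info.index):
            if len(data.columns) != len(sample_info):
                raise ValueError("data columns and sample_info must align")
            sample_info = sample_info.set_axis(data.columns, axis=0)
        self.data = data
        self.sample_info = sample_info
        self.design = self._build_design(sample_info)
        X = self.design.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                f"rank-deficient design ({rank} < {X.shape[1]}); "
                f"columns: {list(self.design.columns)}"
            )
        if X.shape[0] - X.shape[1] < 1:
            raise ValueError("no residual degrees of freedom")
        self._X = X
        self._XtX_inv = np.linalg.inv(X.T @ X)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, sample_info: pd.DataFrame,
                    prior_count: float = 0.5, min_detected: int = 2,
                    robust_norm: bool = True) -> "ModeratedLinearModel":
        """Filter detectable features, log-CPM-normalise, build the model.

        ``robust_norm`` uses median-of-ratios effective library sizes
        (composition-robust); plain library-size CPM otherwise.
        """
        counts = filter_detectable(counts, min_samples=min_detected)
        norm = normalize_log_cpm_robust if robust_norm else normalize_log_cpm
        return cls(norm(counts, prior_count), sample_info)

    @staticmethod
    def _build_design(sample_info: pd.DataFrame) -> pd.DataFrame:
        if "treatment" not in sample_info.columns:
            raise ValueError("sample_info needs a 'treatment' column")
        treat = pd.get_dummies(sample_info["treatment"], dtype=float)
        parts = [treat]
        if "cell_line" in sample_info.columns:
            lines = pd.get_dummies(sample_info["cell_line"], dtype=float,
                                   prefix="line", prefix_sep="_")
            if lines.shape[1] > 1:
                parts.append(lines.iloc[:, 1:])  # first line absorbed
        return pd.concat(parts, axis=1)

    def fit(self, contrasts: dict[str, str] | None = None,
            d_prior: float | None = None) -> "DifferentialResults":
        """Fit OLS per feature, moderate variances, evaluate contrasts.

        ``contrasts`` maps a label to an expression over design columns,
        e.g. ``{"DTP_vs_DMSO": "DTP - DMSO"}``. ``d_prior`` forces the
        prior degrees of freedom (0 disables moderation, ``np.inf`` fully
        pools variances); by default it is estimated from the data.
        """
        Y = self.data.to_numpy(dtype=float)
        X = self._X
        n, p = X.shape
        beta = Y @ (self._XtX_inv @ X.T).T  # features x p
        resid = Y - beta @ X.T
        d_res = n - p
        s2 = (resid ** 2).sum(axis=1) / d_res
        s2_prior, d_pri = estimate_prior(s2, d_res)
        if d_prior is not None:
            d_pri = float(d_prior)
        if np.isinf(d_pri):
            s2_post = np.full_like(s2, s2_prior)
        elif d_pri == 0:
            s2_post = s2.copy()
        else:
            s2_post = (d_pri * s2_prior + d_res * s2) / (d_pri + d_res)
        state = ModerationState(s2_prior=s2_prior, d_prior=d_pri, d_res=d_res,
                                s2_residual=s2, s2_posterior=s2_post)
        cvecs = {}
        for name, expr in (contrasts or {}).items():
            cvecs[name] = (np.asarray(expr, dtype=float)
                           if not isinstance(expr, str)
                           else _parse_contrast(expr, list(self.design.columns)))
        return DifferentialResults(self, beta, state, cvecs)


class DifferentialResults:
    """Estimates, moderated statistics, and diagnostics from a model fit."""

    def __init__(self, model: ModeratedLinearModel, beta: np.ndarray,
                 moderation: ModerationState, contrasts: dict[str, np.ndarray]):
        self.model = model
        self.beta = beta
        self.moderation = moderation
        self.contrasts = contrasts

    @property
    def features(self) -> pd.Index:
        return self.model.data.index

    def contrast_table(self, name: str) -> pd.DataFrame:
        """Per-feature log2 fold change, moderated t, p and BH FDR."""
        c = self.contrasts[name]
        est = self.beta @ c
        u = float(c @ self.model._XtX_inv @ c)
        mod = self.moderation
        se = np.sqrt(mod.s2_posterior * u)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / se
        df = mod.df_total
        if np.isfinite(df):
            p = 2 * stats.t.sf(np.abs(t), df)
        else:
            p = 2 * stats.norm.sf(np.abs(t))
        return pd.DataFrame(
            {
                "feature": self.features,
                "contrast": name,
                "log2fc": est,
                "t": t,
                "p": p,
                "fdr": bh_adjust(p),
            }
        ).set_index("feature")

    def all_contrasts(self) -> pd.DataFrame:
        return pd.concat([self.contrast_table(n) for n in self.contrasts])

    def f_table(self, names: list[str] | None = None) -> pd.DataFrame:
        """Moderated F over a set of contrasts (joint null: all zero)."""
        names = list(names or self.contrasts)
        C = np.column_stack([self.contrasts[n] for n in names])
        q = C.shape[1]
        M = np.linalg.inv(C.T @ self.model._XtX_inv @ C)
        B = self.beta @ C  # features x q
        num = np.einsum("ij,jk,ik->i", B, M, B)
        mod = self.moderation
        with np.errstate(divide="ignore", invalid="ignore"):
            F = num / (q * mod.s2_posterior)
        df = mod.df_total
        p = stats.f.sf(F, q, df) if np.isfinite(df) else stats.chi2.sf(q * F, q)
        return pd.DataFrame(
            {"feature": self.features, "F": F, "p": p, "fdr": bh_adjust(p)}
        ).set_index("feature")

    def summary(self, max_rows: int = 10) -> str:
        mod = self.moderation
        lines = [
            "Moderated linear model fit",
            f"  features: {len(self.features)}, samples: {self.model._X.shape[0]}, "
            f"design columns: {self.model._X.shape[1]}",
            f"  residual df: {mod.d_res:g}, prior df: {mod.d_prior:g}, "
            f"prior variance: {mod.s2_prior:.4g}",
        ]
        for name in self.contrasts:
            tab = self.contrast_table(name)
            n_sig = int((tab["fdr"] < 0.05).sum())
            lines.append(f"  contrast {name}: {n_sig} features at FDR < 0.05")
            top = tab.loc[tab["fdr"].sort_values(kind="mergesort").index]
            lines.append(top.head(max_rows).to_string())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cross-model selection, clustering, signatures


def moderated_f_select(f_tables: dict[str, pd.DataFrame], min_models: int = 3,
                       top_n: int = 2000, fdr_cut: float = 0.05) -> list[str]:
    """Features significant (FDR < cut) in >= min_models cell lines,
    ranked by their best FDR across lines and truncated to top_n."""
    if min_models > len(f_tables):
        raise ValueError("min_models exceeds number of cell lines")
    fdr = pd.DataFrame({line: t["fdr"] for line, t in f_tables.items()})
    n_sig = (fdr < fdr_cut).sum(axis=1)
    eligible = fdr.loc[n_sig >= min_models]
    best = eligible.min(axis=1).sort_values(kind="mergesort")
    return list(best.index[:top_n])


def zscore_by_group(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Z-score each feature within each sample group (e.g. per cell line);
    zero-variance rows map to 0."""
    out = matrix.copy().astype(float)
    for g in groups.unique():
        cols = groups.index[groups == g]
        block = out[cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=0)
        z = block.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
        out[cols] = z
    return out


def zscore_and_cluster(matrix: pd.DataFrame, groups: pd.Series, k: int,
                       seed: int = 0, n_init: int = 25,
                       average_replicates: bool = False) -> pd.DataFrame:
    """Z-score per group, K-means partition, hierarchical within-cluster order.

    Returns a per-feature table with columns ``cluster`` (0..k-1,
    relabelled by descending cluster size, ties by lowest original index)
    and ``order`` (global display order: by cluster, then complete-linkage
    Euclidean dendrogram leaf order within the cluster). With
    ``average_replicates=True`` the clustering runs on per-group means of
    the Z-scores instead of all samples.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if len(matrix) < k:
        raise ValueError("need at least K features")
    Z = zscore_by_group(matrix, groups)
    if average_replicates:
        Zc = pd.concat(
            {g: Z[groups.index[groups == g]].mean(axis=1) for g in groups.unique()},
            axis=1,
        )
    else:
        Zc = Z
    X = Zc.to_numpy()
    if k == 1:
        labels = np.zeros(len(X), dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, init="k-means++")
        labels = km.fit_predict(X)
    sizes = pd.Series(labels).value_counts()
    relabel = {old: new for new, old in
               enumerate(sorted(sizes.index, key=lambda c: (-sizes[c], c)))}
    labels = np.array([relabel[c] for c in labels])
    order = np.empty(len(X), dtype=int)
    pos = 0
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        if len(idx) > 2:
            leaf = leaves_list(linkage(X[idx], method="complete", metric="euclidean"))
            idx = idx[leaf]
        order[idx] = np.arange(pos, pos + len(idx))
        pos += len(idx)
    return pd.DataFrame({"cluster": labels, "order": order}, index=matrix.index)


def score_signature(matrix: pd.DataFrame, gene_set: list[str],
                    method: str = "mean_z") -> pd.Series:
    """Single-sample enrichment score of a gene set.

    ``mean_z`` (primary): per-sample mean of feature Z-scores (Z across
    samples) over the set. ``rank``: mean rank of set genes minus its
    expectation, scaled to [-1, 1].
    """
    present = [g for g in gene_set if g in matrix.index]
    missing = [g for g in gene_set if g not in matrix.index]
    if not present:
        raise ValueError(f"no gene-set members present; missing: {missing[:5]}")
    if method == "mean_z":
        mu = matrix.mean(axis=1)
        sd = matrix.std(axis=1, ddof=0).replace(0, np.nan)
        z = matrix.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
        score = z.loc[present].mean(axis=0)
    elif method == "rank":
        n = len(matrix)
        ranks = matrix.rank(axis=0)  # 1..n per sample
        expected = (n + 1) / 2
        half_range = (n - len(present)) / 2 or 1.0
        score = (ranks.loc[present].mean(axis=0) - expected) / half_range
    else:
        raise ValueError(f"unknown method {method!r}")
    score.name = f"signature_{method}"
    return score
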