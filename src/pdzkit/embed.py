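"""Statistics on protein-embedding matrices: PCA, per-component ANOVA with
Tukey HSD across PDZ groups, and Welch's t-test for single- vs multi-celled
labels.

This stage consumes pre-computed embedding matrices (one row per protein,
e.g. mean-pooled language-model representations); producing the embeddings is
upstream of this package. Post-hoc Tukey tests are run only for components
whose one-way ANOVA is significant at 0.05 — otherwise the pairwise entries
are left empty, matching the reporting convention this pipeline mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = ["EmbeddingMatrix", "PCAResult", "ComponentTests", "pca_scores",
           "group_tests", "summarize_tests"]

ANOVA_GATE = 0.05


@dataclass
class EmbeddingMatrix:
    """Embedding values plus per-protein labels.

    ``labels`` needs columns ``pdz_group`` (categorical) and ``cellularity``
    ("single"/"multi"), indexed like ``values`` rows.
    """

    values: np.ndarray
    ids: list[str]
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding matrix contains missing/non-finite values")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids length must match number of rows")
        missing = {"pdz_group", "cellularity"} - set(self.labels.columns)
        if missing:
            raise ValueError(f"labels missing columns {sorted(missing)}")


@dataclass
class PCAResult:
    scores: np.ndarray          # (n, k)
    pct_variance: np.ndarray    # (k,) percentage of variance explained
    loadings: np.ndarray        # (k, d)
    mean: np.ndarray
    scale: np.ndarray | None = None


@dataclass
class ComponentTests:
    pc_index: int               # 1-based
    pct_variance: float
    anova_p: float
    tukey_p: dict[tuple[str, str], float] = field(default_factory=dict)
    welch_p: float = np.nan
    skipped: bool = False
    skip_reason: str = ""


def pca_scores(em: EmbeddingMatrix, n_components: int = 10,
               scale: bool = False) -> PCAResult:
    """Centred PCA of the embedding rows (optional unit-variance scaling).

    Component signs follow the convention that the largest-magnitude loading
    of each component is positive, so scores are reproducible across runs.
    If the data rank is below ``n_components`` the decomposition is truncated
    with a warning rather than failing.
    """
    X = em.values.copy()
    mean = X.mean(axis=0)
    sd = None
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - mean) / sd
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    k = min(n_components, min(X.shape))
    if rank < k:
        import warnings
        warnings.warn(
            f"data rank {rank} < requested {n_components} components; truncating",
            stacklevel=2,
        )
        k = max(rank, 1)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return PCAResult(
        scores=scores,
        pct_variance=100.0 * pca.explained_variance_ratio_,
        loadings=loadings,
        mean=pca.mean_ if not scale else mean,
        scale=sd,
    )


def group_tests(pca: PCAResult, labels: pd.DataFrame,
                n_components: int | None = None) -> list[ComponentTests]:
    """Per-component group statistics.

    For each principal component: one-way ANOVA across PDZ groups (groups
    with fewer than 2 members are dropped; if fewer than 2 usable groups
    remain the component is flagged skipped), Tukey HSD pairwise p-values
    only when the ANOVA p < 0.05, and Welch's two-tailed t-test between
    single- and multi-celled proteins.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    k = pca.scores.shape[1] if n_components is None else min(n_components, pca.scores.shape[1])
    group = labels["pdz_group"].astype(str).to_numpy()
    cell = labels["cellularity"].astype(str).to_numpy()
    results: list[ComponentTests] = []
    for i in range(k):
        comp = pca.scores[:, i]
        ct = ComponentTests(pc_index=i + 1, pct_variance=float(pca.pct_variance[i]),
                            anova_p=np.nan)
        usable = [g for g in np.unique(group) if np.sum(group == g) >= 2]
        if len(usable) < 2:
            ct.skipped = True
            ct.skip_reason = "fewer than two PDZ groups with >=2 members"
        else:
            samples = [comp[group == g] for g in usable]
            with np.errstate(invalid="ignore", divide="ignore"):
                p = float(stats.f_oneway(*samples).pvalue)
            if np.isnan(p):  # zero within-group variance
                p = 1.0 if len({float(s[0]) for s in samples}) == 1 else 0.0
            ct.anova_p = p
            if ct.anova_p < ANOVA_GATE:
                keep = np.isin(group, usable)
                tk = pairwise_tukeyhsd(comp[keep], group[keep])
                pairs = [tuple(row[:2]) for row in tk.summary().data[1:]]
                ct.tukey_p = {(str(a), str(b)): float(pv)
                              for (a, b), pv in zip(pairs, tk.pvalues)}
        single = comp[cell == "single"]
        multi = comp[cell == "multi"]
        if single.size >= 2 and multi.size >= 2:
            ct.welch_p = float(stats.ttest_ind(single, multi, equal_var=False).pvalue)
        results.append(ct)
    return results


def summarize_tests(tests: list[ComponentTests]) -> pd.DataFrame:
    """Flatten ComponentTests into a tidy table (one row per component);
    Tukey columns hold '-' where the ANOVA gate was not passed."""
    pairs = sorted({p for t in tests for p in t.tukey_p})
    rows = []
    for t in tests:
        row = {
            "pc": t.pc_index,
            "pct_variance": t.pct_variance,
            "anova_p": t.anova_p,
            "welch_p": t.welch_p,
        }
        for p in pairs:
            row[f"tukey_{p[0]}_vs_{p[1]}"] = t.tukey_p.get(p, "-") if t.tukey_p else "-"
        rows.append(row)
    return pd.DataFrame(rows)
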