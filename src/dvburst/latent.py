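"""PCA latent-vector scoring of tissue specificity.

Samples from the three genotypes are decomposed by PCA; for each condition
a unit latent vector is drawn from the origin through the mean of that
condition's sample scores (restricted to the informative PCs).  Features
(genes or regions) are projected into the same space by the biplot
convention (loading x singular value) and their coordinate along each
condition's latent vector, standardized over all features, is that
feature's tissue-specificity z-score.  Features with z at or above the
cutoff (default 3) in some condition are classified as tissue-specific,
assigned to the condition of maximal z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .containers import CountTable
from .proseq import SizeFactors, size_factors_median_of_ratios


def transform_for_pca(table: CountTable, factors) -> pd.DataFrame:
    """log2(count / size_factor + 1), then center each feature across samples.

    ``factors`` may be a SizeFactors object or a plain sample -> factor
    mapping (used as given, without renormalization).
    """
    norm = table.counts.values / np.array([factors[s] for s in table.sample_ids])
    logged = np.log2(norm + 1.0)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=table.entity_ids, columns=table.sample_ids)


class LatentAxes:
    """Latent-axis model over a multi-condition count table.

    Parameters
    ----------
    table
        Counts, features x samples, with a condition per sample.
    factors
        Size factors; median-of-ratios on the table itself by default.

    ``fit`` performs the PCA, builds the per-condition unit vectors and
    returns a :class:`LatentAxesResults`.
    """

    def __init__(self, table: CountTable, factors: SizeFactors | None = None):
        if len(table.conditions) < 2:
            raise ValueError("need >= 2 conditions for latent-axis scoring")
        self.table = table
        self.factors = factors or size_factors_median_of_ratios(table)
        self.matrix = transform_for_pca(table, self.factors)  # features x samples

    def fit(self, pc_subset: list[int] | None = None) -> "LatentAxesResults":
        X = self.matrix.values.T  # samples x features, feature-centered
        n_samples = X.shape[0]
        if n_samples < 2:
            raise ValueError("need >= 2 samples")
        if not np.any(X):
            raise ValueError("degenerate all-zero matrix")
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        rank = int(np.sum(S > S[0] * 1e-12))
        U, S, Vt = U[:, :rank], S[:rank], Vt[:rank]
        # orient each PC so its largest-magnitude loading is positive
        for i in range(rank):
            j = np.argmax(np.abs(Vt[i]))
            if Vt[i, j] < 0:
                Vt[i] *= -1.0
                U[:, i] *= -1.0
        sample_scores = U * S  # samples x PCs
        loadings = Vt.T  # features x PCs
        var_explained = S**2 / np.sum(S**2)

        condition_of = {s: self.table.condition_of[s] for s in self.table.sample_ids}
        if pc_subset is None:
            pc_subset = _auto_pc_subset(sample_scores, self.table.sample_ids, condition_of)
        pc_subset = list(pc_subset)
        if not pc_subset or max(pc_subset) >= rank or min(pc_subset) < 0:
            raise ValueError(f"invalid pc_subset {pc_subset} for rank {rank}")

        unit_vectors: dict[str, np.ndarray] = {}
        for cond in self.table.conditions:
            idx = [i for i, s in enumerate(self.table.sample_ids) if condition_of[s] == cond]
            v = sample_scores[idx][:, pc_subset].mean(axis=0)
            norm = np.linalg.norm(v)
            if norm == 0:
                raise ValueError(f"condition {cond!r}: mean score at the origin")
            unit_vectors[cond] = v / norm

        return LatentAxesResults(
            model=self,
            sample_scores=pd.DataFrame(
                sample_scores,
                index=self.table.sample_ids,
                columns=[f"PC{i+1}" for i in range(rank)],
            ),
            feature_loadings=pd.DataFrame(
                loadings,
                index=self.table.entity_ids,
                columns=[f"PC{i+1}" for i in range(rank)],
            ),
            singular_values=S.copy(),
            variance_explained=var_explained.copy(),
            pc_subset=pc_subset,
            unit_vectors=unit_vectors,
        )


def _auto_pc_subset(
    scores: np.ndarray, sample_ids: list[str], condition_of: dict[str, str]
) -> list[int]:
    """Smallest leading PC set whose scores separate the condition means by
    at least twice the within-condition spread."""
    conditions = list(dict.fromkeys(condition_of[s] for s in sample_ids))
    groups = {
        c: np.array([i for i, s in enumerate(sample_ids) if condition_of[s] == c])
        for c in conditions
    }
    max_k = scores.shape[1]
    # C condition means span at most a (C-1)-dimensional space; fewer PCs
    # cannot separate all pairs, so start there
    min_k = min(max(1, len(conditions) - 1), max_k)
    for k in range(min_k, max_k + 1):
        sub = scores[:, :k]
        means = {c: sub[idx].mean(axis=0) for c, idx in groups.items()}
        within = max(
            float(np.sqrt(np.mean(np.sum((sub[idx] - means[c]) ** 2, axis=1))))
            for c, idx in groups.items()
        )
        between = min(
            float(np.linalg.norm(means[a] - means[b]))
            for i, a in enumerate(conditions)
            for b in conditions[i + 1 :]
        )
        if between > 0 and (within == 0 or between >= 2 * within):
            return list(range(k))
    return list(range(max_k))


@dataclass
class LatentAxesResults:
    """Fitted latent axes: PCA decomposition plus per-condition unit vectors."""

    model: LatentAxes
    sample_scores: pd.DataFrame
    feature_loadings: pd.DataFrame
    singular_values: np.ndarray
    variance_explained: np.ndarray
    pc_subset: list[int]
    unit_vectors: dict[str, np.ndarray]
    _z_cache: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    @property
    def conditions(self) -> list[str]:
        return list(self.unit_vectors)

    def feature_coordinates(self) -> np.ndarray:
        """Biplot-convention feature positions: loading x singular value,
        restricted to the PC subset."""
        L = self.feature_loadings.values[:, self.pc_subset]
        return L * self.singular_values[self.pc_subset]

    def score_features(self, condition: str) -> pd.DataFrame:
        """Raw latent score and z-score of every feature for one condition."""
        if condition not in self.unit_vectors:
            raise ValueError(f"unknown condition {condition!r}")
        if condition not in self._z_cache:
            raw = self.feature_coordinates() @ self.unit_vectors[condition]
            z = (raw - raw.mean()) / raw.std(ddof=0)
            self._z_cache[condition] = pd.DataFrame(
                {
                    "feature_id": self.feature_loadings.index,
                    "condition": condition,
                    "raw": raw,
                    "z": z,
                }
            )
        return self._z_cache[condition]

    def z_matrix(self) -> pd.DataFrame:
        """Features x conditions z-score matrix."""
        cols = {c: self.score_features(c)["z"].values for c in self.conditions}
        return pd.DataFrame(cols, index=self.feature_loadings.index)

    def classify(self, z_cutoff: float = 3.0) -> pd.Series:
        return classify_dv(self.z_matrix(), z_cutoff)

    def summary(self) -> str:
        ve = ", ".join(f"{v:.1%}" for v in self.variance_explained[:4])
        lines = [
            "Latent-axis model",
            "=" * 40,
            f"features: {self.feature_loadings.shape[0]}    "
            f"samples: {self.sample_scores.shape[0]}",
            f"variance explained (leading PCs): {ve}",
            f"PC subset used: {[i + 1 for i in self.pc_subset]}",
            f"conditions: {', '.join(self.conditions)}",
        ]
        zm = self.z_matrix()
        for c in self.conditions:
            lines.append(f"  {c}: {(zm[c] >= 3).sum()} features with z >= 3")
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Sample PC scores with the condition latent vectors (first two PCs
        of the subset)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        i = self.pc_subset[0]
        j = self.pc_subset[1] if len(self.pc_subset) > 1 else self.pc_subset[0]
        for cond in self.conditions:
            samples = [
                s
                for s in self.sample_scores.index
                if self.model.table.condition_of[s] == cond
            ]
            pts = self.sample_scores.loc[samples].values
            ax.scatter(pts[:, i], pts[:, j], label=cond)
            u = self.unit_vectors[cond]
            scale = np.abs(self.sample_scores.values[:, self.pc_subset]).max()
            ui = u[self.pc_subset.index(i)] if i in self.pc_subset else 0
            uj = u[self.pc_subset.index(j)] if j in self.pc_subset else 0
            ax.plot([0, scale * ui], [0, scale * uj], "--", alpha=0.6)
        ax.set_xlabel(f"PC{i+1}")
        ax.set_ylabel(f"PC{j+1}")
        ax.legend()
        return ax


def classify_dv(z_by_condition: pd.DataFrame, z_cutoff: float = 3.0) -> pd.Series:
    """Assign each feature to its argmax-z condition if max z >= cutoff.

    Exact ties break by the column order of ``z_by_condition``.
    """
    z = z_by_condition.values
    best = np.argmax(z, axis=1)  # first occurrence wins ties
    labels = np.where(
        z[np.arange(len(z)), best] >= z_cutoff,
        z_by_condition.columns.values[best],
        "none",
    )
    return pd.Series(labels, index=z_by_condition.index, name="label")


def roc_curve(scores: np.ndarray, positives: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and AUROC for a score vector and boolean positive labels.

    Thresholds sweep the unique scores (equal scores grouped at one
    threshold); the area uses the trapezoid rule.
    """
    positives = np.asarray(positives, dtype=bool)
    if not positives.any() or positives.all():
        raise ValueError("need at least one positive and one negative")
    fpr, tpr, _ = skmetrics.roc_curve(positives.astype(int), np.asarray(scores))
    auroc = float(skmetrics.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), auroc
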