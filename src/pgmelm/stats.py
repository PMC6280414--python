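"""Friedman omnibus test and Nemenyi post-hoc critical difference for
comparing k classifiers over N datasets.

Per dataset the methods are ranked 1 (best) .. k, ties sharing averaged
ranks.  The Friedman chi-square statistic

    chi2_F = 12 N / (k (k + 1)) * sum_j (R_j - (k + 1)/2)^2

is referred to a chi-square distribution with k - 1 degrees of freedom.
Two average ranks differ significantly when |R_i - R_j| exceeds the
Nemenyi critical difference CD = q_alpha * sqrt(k (k + 1) / (6 N)), with
q_alpha the alpha-level studentized-range quantile divided by sqrt(2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

# q_alpha = studentized range quantile (infinite df) / sqrt(2), k = 2..10
_NEMENYI_Q = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589,
           7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


@dataclass
class ScoreTable:
    """Datasets x methods score matrix (higher is better by default)."""

    scores: np.ndarray
    method_names: list[str]
    dataset_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D (datasets x methods)")
        n, k = self.scores.shape
        if k < 2 or n < 2:
            raise ValueError("need >= 2 methods and >= 2 datasets")
        if np.isnan(self.scores).any():
            raise ValueError("score table has missing entries")
        if len(self.method_names) != k:
            raise ValueError("method_names length mismatch")
        if not self.dataset_names:
            self.dataset_names = [f"dataset{i + 1}" for i in range(n)]

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        """Rows = datasets (first column = name), columns = methods."""
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns),
                   [str(i) for i in df.index])


@dataclass
class RankSummary:
    avg_ranks: np.ndarray
    statistic: float
    p_value: float
    method_names: list[str]
    n_datasets: int
    cd: float | None = None
    alpha: float | None = None

    def significant_pairs(self) -> list[tuple[str, str]]:
        """Method pairs whose average-rank difference exceeds CD."""
        if self.cd is None:
            raise ValueError("compute CD first (nemenyi_cd)")
        pairs = []
        k = len(self.method_names)
        for i in range(k):
            for j in range(i + 1, k):
                if abs(self.avg_ranks[i] - self.avg_ranks[j]) > self.cd:
                    pairs.append((self.method_names[i], self.method_names[j]))
        return pairs

    def to_json(self) -> str:
        return json.dumps({
            "methods": self.method_names,
            "avg_ranks": self.avg_ranks.tolist(),
            "friedman_chi2": self.statistic,
            "p_value": self.p_value,
            "n_datasets": self.n_datasets,
            "cd": self.cd,
            "alpha": self.alpha,
        }, indent=2)

    def cd_diagram_text(self) -> str:
        """Plain-text description of the critical-difference comparison."""
        order = np.argsort(self.avg_ranks)
        lines = [f"Average ranks (1 = best), CD = {self.cd}:"]
        for i in order:
            lines.append(f"  {self.method_names[i]}: {self.avg_ranks[i]:.4g}")
        if self.cd is not None:
            sig = self.significant_pairs()
            lines.append("Significantly different pairs: "
                         + (", ".join(f"{a} vs {b}" for a, b in sig) or "none"))
        return "\n".join(lines)


def friedman_test(table: ScoreTable, higher_is_better: bool = True) -> RankSummary:
    """Friedman test over the score table (ties get averaged ranks)."""
    n, k = table.scores.shape
    s = -table.scores if higher_is_better else table.scores
    ranks = np.vstack([rankdata(row) for row in s])  # 1 = best
    avg = ranks.mean(axis=0)
    stat = 12.0 * n / (k * (k + 1)) * float(np.sum((avg - (k + 1) / 2.0) ** 2))
    p = float(chi2.sf(stat, k - 1))
    return RankSummary(avg_ranks=avg, statistic=stat, p_value=p,
                       method_names=list(table.method_names), n_datasets=n)


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference for k methods over n datasets."""
    if k < 2 or n < 2:
        raise ValueError("need k >= 2 methods and n >= 2 datasets")
    if alpha not in _NEMENYI_Q:
        raise ValueError(
            f"alpha {alpha} not tabulated; supported: {sorted(_NEMENYI_Q)}"
        )
    qtab = _NEMENYI_Q[alpha]
    if k not in qtab:
        raise ValueError(f"k={k} outside tabulated range 2..10")
    return qtab[k] * np.sqrt(k * (k + 1) / (6.0 * n))


def compare_classifiers(table: ScoreTable, alpha: float = 0.05,
                        higher_is_better: bool = True) -> RankSummary:
    """Friedman test plus Nemenyi CD in one call."""
    summary = friedman_test(table, higher_is_better)
    summary.cd = float(nemenyi_cd(len(table.method_names),
                                  table.scores.shape[0], alpha))
    summary.alpha = alpha
    return summary
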