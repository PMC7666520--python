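"""Pairwise ROC discrimination of diagnostic groups by single features.

AUC uses the Mann–Whitney formulation with midrank tie handling: the
probability that a random subject of the positive group scores above a
random subject of the negative group (ties count half). The 95% CI and
the two-sided p-value against AUC = 0.5 come from the DeLong structural-
components variance estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = ["ROCResult", "roc_auc", "rank_discriminators"]


@dataclass
class ROCResult:
    feature: str
    pair: tuple[str, str]
    auc: float
    ci95: tuple[float, float]
    direction: str  # which group tends to larger values
    n_pos: int
    n_neg: int
    p_value: float

    @property
    def discrimination(self) -> float:
        """Orientation-free ranking score max(auc, 1 - auc)."""
        return max(self.auc, 1.0 - self.auc)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong variance of the AUC via structural components V10/V01."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = _midranks(allv)
    r_pos = _midranks(pos)
    r_neg = _midranks(neg)
    v10 = (r_all[:m] - r_pos) / n  # P(neg < pos_i) with ties half
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _auc_midrank(pos: np.ndarray, neg: np.ndarray) -> float:
    m, n = len(pos), len(neg)
    ranks = _midranks(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def roc_auc(
    values_pos,
    values_neg,
    feature: str = "",
    pair: tuple[str, str] = ("pos", "neg"),
    ci_method: str = "delong",
    n_boot: int = 2000,
    boot_seed: int = 0,
) -> ROCResult:
    """AUC for pos > neg with midrank ties, 95% CI and p-value.

    The AUC is reported for the fixed orientation "positive group scores
    higher" and may fall below 0.5; `direction` records which group has
    the larger mean. The CI is DeLong by default; ``ci_method="bootstrap"``
    uses a seeded stratified percentile bootstrap instead (the p-value
    always comes from the DeLong variance).
    """
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DomainError("both samples must be non-empty")
    m, n = len(pos), len(neg)
    pooled = np.concatenate([pos, neg])
    if np.ptp(pooled) == 0:
        warnings.warn("constant pooled sample: AUC degenerate at 0.5", stacklevel=2)
        return ROCResult(feature, pair, 0.5, (0.5, 0.5), "tie", m, n, 1.0)
    auc = _auc_midrank(pos, neg)
    var = _delong_variance(pos, neg, auc)
    se = np.sqrt(var)
    z = stats.norm.ppf(0.975)
    if ci_method == "bootstrap":
        rng = np.random.default_rng(boot_seed)
        boots = [
            _auc_midrank(
                pos[rng.integers(0, m, m)], neg[rng.integers(0, n, n)]
            )
            for _ in range(n_boot)
        ]
        lo, hi = (float(q) for q in np.quantile(boots, [0.025, 0.975]))
    elif ci_method == "delong":
        lo = float(np.clip(auc - z * se, 0.0, 1.0))
        hi = float(np.clip(auc + z * se, 0.0, 1.0))
    else:
        raise DomainError(f"unknown ci_method {ci_method!r}")
    if se > 0:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    if pos.mean() > neg.mean():
        direction = f"{pair[0]}>{pair[1]}"
    elif pos.mean() < neg.mean():
        direction = f"{pair[0]}<{pair[1]}"
    else:
        direction = "tie"
    return ROCResult(feature, pair, float(auc), (lo, hi), direction, m, n, p)


def rank_discriminators(
    features: pd.DataFrame,
    pair: tuple[str, str],
    top_k: int | None = 5,
    feature_columns: list[str] | None = None,
) -> list[ROCResult]:
    """Rank feature columns by max(AUC, 1-AUC) for one group pair.

    `features` needs 'group' plus numeric feature columns; ties in the
    ranking score break by feature name.
    """
    pos_label, neg_label = pair
    for g in pair:
        if (features["group"] == g).sum() < 2:
            raise KeyError(f"group {g!r} absent or has fewer than 2 subjects")
    if feature_columns is None:
        feature_columns = [
            c
            for c in features.columns
            if c not in ("subject_id", "group")
            and pd.api.types.is_numeric_dtype(features[c])
        ]
    results = []
    for col in feature_columns:
        pos = features.loc[features["group"] == pos_label, col].to_numpy()
        neg = features.loc[features["group"] == neg_label, col].to_numpy()
        results.append(roc_auc(pos, neg, feature=col, pair=pair))
    results.sort(key=lambda r: (-r.discrimination, r.feature))
    return results if top_k is None else results[:top_k]


def roc_results_to_frame(results: list[ROCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "pair": f"{r.pair[0]}:{r.pair[1]}",
                "auc": r.auc,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "direction": r.direction,
                "p_value": r.p_value,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
            }
            for r in results
        ]
    )
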