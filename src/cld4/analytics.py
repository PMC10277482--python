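"""Risk analytics on the engineered feature table.

Standardization (zero mean, unit sample sd per feature), PCA on the
standardized matrix (correlation PCA), pairwise Pearson correlations and
rule-based risk findings linking process-parameter features to product
quality.

Note on terminology: correlation values reported here are signed Pearson
r coefficients.  Signed values such as -0.5 are sometimes loosely labelled
"R^2" in the bioprocess literature; a coefficient of determination cannot
be negative, so the signed r is the quantity actually computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .features import FeatureTable

log = logging.getLogger(__name__)

TSB_BAND_EDGES = (7.0, 14.0)  # % boundaries: low [0,7), medium [7,14), high >=14


def standardize(table: FeatureTable | pd.DataFrame
                ) -> tuple[pd.DataFrame, list[str]]:
    """Per-column zero mean / unit sample sd; constant columns dropped.

    Returns the standardized matrix and the list of dropped columns.
    """
    df = table.values if isinstance(table, FeatureTable) else table
    if len(df) < 2:
        raise ValueError("need at least two rows to standardize")
    std = df.std(ddof=1)
    dropped = list(std.index[(std == 0) | std.isna()])
    if dropped:
        log.warning("dropping zero-variance features: %s", dropped)
    kept = df.drop(columns=dropped)
    return (kept - kept.mean()) / kept.std(ddof=1), dropped


@dataclass
class PCAResult:
    scores: pd.DataFrame        # clones x components
    loadings: pd.DataFrame      # features x components
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(standardized: pd.DataFrame, n_components: int | None = None
        ) -> PCAResult:
    """Principal components of a standardized matrix via SVD.

    Components are capped at the matrix rank.  Sign convention: the
    largest-magnitude loading of each component is positive, which makes
    scores and loadings deterministic.
    """
    x = standardized.to_numpy(dtype=float)
    if np.isnan(x).any():
        keep = ~np.isnan(x).any(axis=0)
        log.warning("PCA drops %d features with missing values",
                    int((~keep).sum()))
        standardized = standardized.loc[:, keep]
        x = standardized.to_numpy(dtype=float)
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
    k = rank if n_components is None else min(n_components, rank)
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # features x components
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=standardized.index,
                            columns=comp_names),
        loadings=pd.DataFrame(loadings, index=standardized.columns,
                              columns=comp_names),
        explained_variance_fraction=model.explained_variance_ratio_,
    )


@dataclass
class CorrelationResult:
    matrix: pd.DataFrame  # symmetric, unit diagonal, NaN where undefined

    def r(self, feature_a: str, feature_b: str) -> float:
        return float(self.matrix.loc[feature_a, feature_b])


def correlation_matrix(table: FeatureTable | pd.DataFrame,
                       min_observations: int = 3) -> CorrelationResult:
    """Pairwise Pearson correlations on pairwise-complete observations.

    Pairs with fewer than ``min_observations`` complete rows are masked.
    """
    df = table.values if isinstance(table, FeatureTable) else table
    corr = df.corr(method="pearson", min_periods=min_observations)
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationResult(matrix=corr)


def band_tsb(tsb_percent: float) -> str:
    """Classify a trisulfide-bond end point into low/medium/high bands.

    Bands are half-open, lower-inclusive: low [0, 7), medium [7, 14),
    high [14, inf).
    """
    if tsb_percent < 0:
        raise ValueError("TSB percentage cannot be negative")
    lo, hi = TSB_BAND_EDGES
    if tsb_percent < lo:
        return "low"
    if tsb_percent < hi:
        return "medium"
    return "high"


@dataclass(frozen=True)
class RiskFinding:
    process_feature: str
    quality_feature: str
    r: float
    direction: str            # "positive" | "negative"
    threshold: float
    message_id: str = "process_quality_correlation"

    def message(self) -> str:
        tendency = "higher" if self.r > 0 else "lower"
        return (f"{self.process_feature} correlates with "
                f"{self.quality_feature} (r = {self.r:+.2f}): clones with "
                f"higher {self.process_feature} tended toward {tendency} "
                f"{self.quality_feature}.")


def flag_risks(corr: CorrelationResult, process_features: list[str],
               quality_features: list[str], threshold: float = 0.7
               ) -> list[RiskFinding]:
    """One finding per process x quality feature pair with |r| >= threshold,
    sorted by |r| descending (ties broken by feature names)."""
    findings = []
    for p in process_features:
        for q in quality_features:
            if p not in corr.matrix.index or q not in corr.matrix.columns:
                continue
            r = corr.matrix.loc[p, q]
            if pd.isna(r) or abs(r) < threshold:
                continue
            findings.append(RiskFinding(
                process_feature=p, quality_feature=q, r=float(r),
                direction="positive" if r > 0 else "negative",
                threshold=threshold))
    findings.sort(key=lambda f: (-abs(f.r), f.process_feature,
                                 f.quality_feature))
    return findings


#: default feature groups used when flagging risks on the analytics plan
DEFAULT_PROCESS_FEATURES = [
    "pH:avg", "pH:std", "pH:time_above_sp", "pH:time_below_sp",
    "pH:avg:d0-7", "pH:avg:d7-14", "DO2:avg", "DO2:std",
    "Flow_O2:cumulative", "Flow_CO2:cumulative", "Base:cumulative",
]
DEFAULT_QUALITY_FEATURES = ["TSB:end_point"]
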