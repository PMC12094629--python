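"""Connection screening, standardization, PCA, and electrode engagement.

Connections (band × channel-pair values) whose group means differ at
p < 0.05 on a two-sample t-test are kept as features — deliberately
uncorrected for multiple comparisons, matching the lenient screening this
pipeline reproduces.  Selected features are z-scored and reduced by PCA to
the smallest component count reaching a cumulative explained-variance
target (default 99%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .connectivity import ConnectivityTensor

__all__ = [
    "two_sample_t",
    "FeatureMask",
    "MaskEntry",
    "select_features",
    "FeatureMatrix",
    "standardize_and_reduce",
    "engagement_map",
]

logger = logging.getLogger(__name__)


def two_sample_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test.

    Student's pooled-variance form by default (df = n_a + n_b − 2);
    ``equal_var=False`` gives Welch's variant.  Errors on degenerate
    zero-variance input rather than returning NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance: t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass(frozen=True)
class MaskEntry:
    """One selected connection: its band, pair, test statistics, direction."""

    band: str
    pair: tuple[str, str]
    t: float
    p: float
    direction: str  # "IA>HC" or "IA<HC"


@dataclass
class FeatureMask:
    """Connections passing the group-difference screen at level ``alpha``."""

    entries: list[MaskEntry]
    alpha: float
    column_indices: np.ndarray  # into the flattened (band, pair) feature axis

    def __len__(self) -> int:
        return len(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "band": e.band,
                    "chan_a": e.pair[0],
                    "chan_b": e.pair[1],
                    "t": e.t,
                    "p": e.p,
                    "direction": e.direction,
                }
                for e in self.entries
            ]
        )


def _group_split(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    ia = np.flatnonzero(labels == "IA")
    hc = np.flatnonzero(labels == "HC")
    if ia.size < 2 or hc.size < 2:
        raise ValueError("need at least 2 subjects in each group")
    return ia, hc


def group_t_statistics(
    tensor: ConnectivityTensor,
    labels,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-connection (t, p) over the flattened feature axis.

    Order IA − HC: positive t means higher connectivity in the IA group.
    Constant-valued connections yield NaN and are logged by the caller.
    """
    ia, hc = _group_split(labels)
    X = tensor.feature_matrix()
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # constant columns trigger scipy precision warnings; they come out
        # as NaN and are skipped explicitly by the caller
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(X[ia], X[hc], axis=0, equal_var=equal_var)
    return np.asarray(t), np.asarray(p)


def select_features(
    tensor: ConnectivityTensor,
    labels,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> FeatureMask:
    """Screen every (band, pair) connection by group t-test at ``alpha``.

    No multiple-comparison correction is applied.  Deterministic;
    connections constant across all subjects are skipped with a log entry.
    """
    t, p = group_t_statistics(tensor, labels, equal_var=equal_var)
    n_pairs = len(tensor.pair_labels)
    plabs = tensor.pair_labels
    entries: list[MaskEntry] = []
    cols: list[int] = []
    n_skipped = 0
    for col in range(t.size):
        if not np.isfinite(t[col]):
            n_skipped += 1
            continue
        if p[col] < alpha:
            b, pr = divmod(col, n_pairs)
            entries.append(
                MaskEntry(
                    band=tensor.band_names[b],
                    pair=plabs[pr],
                    t=float(t[col]),
                    p=float(p[col]),
                    direction="IA>HC" if t[col] > 0 else "IA<HC",
                )
            )
            cols.append(col)
    if n_skipped:
        logger.info(
            "select_features: skipped %d constant-valued connections",
            n_skipped,
        )
    return FeatureMask(
        entries=entries, alpha=alpha, column_indices=np.array(cols, dtype=int)
    )


@dataclass
class FeatureMatrix:
    """Standardized, PCA-reduced feature matrix with its fitted parameters."""

    values: np.ndarray  # subjects × retained components
    mean: np.ndarray
    sd: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int


def standardize_and_reduce(
    X: np.ndarray,
    fit_on: np.ndarray | None = None,
    var_target: float = 0.99,
) -> FeatureMatrix:
    """Z-score then PCA-reduce, fitting only on the ``fit_on`` row subset.

    Retains the smallest component count whose cumulative explained
    variance reaches ``var_target`` (capped at the rank); the fitted
    transform is applied to every row, so held-out subjects are projected
    with training-set parameters only.
    """
    X = np.asarray(X, dtype=float)
    if not 0 < var_target <= 1:
        raise ValueError("var_target must lie in (0, 1]")
    if fit_on is None:
        fit_on = np.arange(X.shape[0])
    fit_on = np.asarray(fit_on)
    if fit_on.size < 2:
        raise ValueError("need at least 2 subjects to fit")
    scaler = StandardScaler().fit(X[fit_on])
    # guard constant columns (zero variance) against division blowups
    scaler.scale_ = np.where(scaler.scale_ > 0, scaler.scale_, 1.0)
    Z = scaler.transform(X)
    pca = PCA(svd_solver="full").fit(Z[fit_on])
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    k = min(k, evr.size)
    return FeatureMatrix(
        values=(Z - pca.mean_) @ pca.components_[:k].T,
        mean=scaler.mean_,
        sd=scaler.scale_,
        components=pca.components_[:k],
        explained_variance_ratio=evr,
        n_components=k,
    )


def engagement_map(
    mask: FeatureMask,
    channel_labels,
    band_names,
) -> pd.DataFrame:
    """Per-electrode count of significant connections, per band.

    Each selected connection increments both endpoint electrodes, so a
    band's counts sum to twice its number of selected connections.
    """
    counts = pd.DataFrame(
        0, index=list(band_names), columns=list(channel_labels), dtype=int
    )
    for e in mask.entries:
        counts.loc[e.band, e.pair[0]] += 1
        counts.loc[e.band, e.pair[1]] += 1
    return counts
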