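"""Blockwise principal component analysis (bwPCA) of the FHRV features.

PCA is run separately within the three feature families -- time-domain,
frequency-domain and nonlinear -- on the correlation matrix (features
have heterogeneous units).  Components with eigenvalue above 1 are
retained (Kaiser rule; the dominant component is always kept), rotated
by Kaiser-normalized varimax when more than one survives, and labelled
by the features they correlate with.  Together with the two global
features kept unchanged (gestational week, mean FHR) the result is an
8-column reduced representation:

    week, mean_fhr, LIN_time, LIN_VLF_power, LIN_LF_HF, LIN_SVB,
    NL_variability, NL_complexity
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "BlockSpec",
    "BlockPCAResult",
    "BLOCKS",
    "REDUCED_COLUMNS",
    "varimax",
    "block_pca",
    "eigenvalue_spectrum",
    "assemble_reduced",
    "reduce_features",
]

TIME_FEATURES = ("STV", "SDev", "PPA")
FREQ_FEATURES = ("VLF", "LF", "HF", "TotalPower", "SVB", "pVLF", "pLF", "pHF")
NONLINEAR_FEATURES = ("SampEn", "SD1", "SD2", "HFD", "VIRR", "VIFHR")

REDUCED_COLUMNS = (
    "week", "mean_fhr",
    "LIN_time", "LIN_VLF_power", "LIN_LF_HF", "LIN_SVB",
    "NL_variability", "NL_complexity",
)

#: Features that define each named component, used for labelling.
_FREQ_DEFINING_SETS = {
    "LIN_VLF_power": ("VLF", "TotalPower"),
    "LIN_LF_HF": ("LF", "HF"),
    "LIN_SVB": ("SVB",),
}
_NONLINEAR_DEFINING_SETS = {
    "NL_variability": ("SD1", "SD2", "VIRR", "VIFHR"),
    "NL_complexity": ("SampEn", "HFD"),
}


@dataclasses.dataclass(frozen=True)
class BlockSpec:
    block_name: str
    member_features: tuple[str, ...]


BLOCKS = {
    "time": BlockSpec("time", TIME_FEATURES),
    "frequency": BlockSpec("frequency", FREQ_FEATURES),
    "nonlinear": BlockSpec("nonlinear", NONLINEAR_FEATURES),
}


@dataclasses.dataclass
class BlockPCAResult:
    """PCA of one feature block.

    ``eigenvalues`` is the full descending spectrum (sums to the block
    size); ``rotated_loadings`` and ``correlations`` are feature x
    component (they coincide for an orthogonal rotation, the latter
    computed directly from the data as Pearson coefficients);
    ``scores`` is records x components with unit sample variance.
    """

    block_name: str
    feature_names: tuple[str, ...]
    eigenvalues: np.ndarray
    retained_k: int
    rotated_loadings: np.ndarray
    scores: np.ndarray
    correlations: pd.DataFrame


def varimax(
    loadings: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    kaiser_normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Returns (rotated loadings, rotation matrix R) with rotated = A @ R.
    Rows are Kaiser-normalized (scaled to unit communality) while the
    rotation criterion is optimized, which leaves the returned pattern
    equal to A @ R exactly.
    """
    a = np.asarray(loadings, dtype=float)
    p, k = a.shape
    if k < 2:
        return a.copy(), np.eye(k)
    h = np.sqrt((a**2).sum(axis=1))
    h[h == 0] = 1.0
    a_n = a / h[:, None] if kaiser_normalize else a
    rot = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        lam = a_n @ rot
        u, s, vt = np.linalg.svd(
            a_n.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        d_new = s.sum()
        if d_new < d_old * (1 + tol):
            break
        d_old = d_new
    return a @ rot, rot


def block_pca(feature_table: pd.DataFrame, spec: BlockSpec) -> BlockPCAResult:
    """Correlation-matrix PCA of one block with Kaiser retention and
    varimax rotation.

    Features are z-scored; components with eigenvalue > 1 are retained
    (at least one); with >= 2 retained components the loadings are
    varimax-rotated and the scores rotated accordingly.  Components are
    ordered by explained variance after rotation and signed so that the
    largest-loading feature loads positively.
    """
    missing = [f for f in spec.member_features if f not in feature_table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    x = feature_table.loc[:, list(spec.member_features)].to_numpy(dtype=float)
    n, p = x.shape
    if n < 10:
        raise ValueError("block PCA requires at least 10 records")
    if not np.isfinite(x).all():
        raise ValueError(f"missing values in block '{spec.block_name}'")
    sd = x.std(axis=0, ddof=1)
    constant = [f for f in spec.member_features
                if np.ptp(x[:, spec.member_features.index(f)]) == 0]
    if constant:
        raise ValueError(f"constant feature column(s) {constant} in block '{spec.block_name}'")
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    k = max(int((eigvals > 1.0).sum()), 1)
    loadings = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    scores = z @ eigvecs[:, :k] / np.sqrt(eigvals[:k])
    if k >= 2:
        loadings, rot = varimax(loadings)
        scores = scores @ rot
        # Re-order by explained variance after rotation.
        ssq = (loadings**2).sum(axis=0)
        comp_order = np.argsort(ssq)[::-1]
        loadings = loadings[:, comp_order]
        scores = scores[:, comp_order]
    # Sign convention: dominant feature of each component loads positively.
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(k)]
    corr_fc = np.empty((p, k))
    for i in range(p):
        for j in range(k):
            corr_fc[i, j] = np.corrcoef(x[:, i], scores[:, j])[0, 1]
    correlations = pd.DataFrame(corr_fc, index=list(spec.member_features), columns=comp_names)
    return BlockPCAResult(
        block_name=spec.block_name,
        feature_names=spec.member_features,
        eigenvalues=eigvals,
        retained_k=k,
        rotated_loadings=loadings,
        scores=scores,
        correlations=correlations,
    )


def eigenvalue_spectrum(result: BlockPCAResult) -> list[tuple[int, float]]:
    """Descending (component index, eigenvalue) pairs for reporting."""
    return [(j + 1, float(v)) for j, v in enumerate(result.eigenvalues)]


def _assign_names(result: BlockPCAResult, defining_sets: dict[str, tuple[str, ...]]) -> dict[str, int]:
    """Match retained components to names by their mean absolute Pearson
    correlation with each defining feature set (optimal one-to-one
    assignment, which resolves ties in favour of the larger total)."""
    names = list(defining_sets)
    strength = np.zeros((len(names), result.retained_k))
    for i, name in enumerate(names):
        feats = list(defining_sets[name])
        strength[i] = result.correlations.loc[feats].abs().mean(axis=0).to_numpy()
    rows, cols = linear_sum_assignment(-strength)
    return {names[i]: int(j) for i, j in zip(rows, cols)}


def assemble_reduced(
    global_features: pd.DataFrame,
    time_result: BlockPCAResult,
    freq_result: BlockPCAResult,
    nonlinear_result: BlockPCAResult,
) -> pd.DataFrame:
    """Assemble the 8-column reduced table.

    Requires retained counts (1, 3, 2) for the time/frequency/nonlinear
    blocks -- the naming of components is undefined otherwise -- and
    standardizes every component column to mean 0, SD 1 over the corpus.
    Component naming is sign-invariant (absolute correlations only).
    """
    expected = {"time": (time_result, 1), "frequency": (freq_result, 3), "nonlinear": (nonlinear_result, 2)}
    for block, (res, want) in expected.items():
        if res.retained_k != want:
            raise ValueError(
                f"block '{block}' retained {res.retained_k} components, expected {want}; "
                "component naming is undefined"
            )
    for col in ("week", "mean_fhr"):
        if col not in global_features.columns:
            raise ValueError(f"global feature '{col}' missing")
    out = pd.DataFrame(index=global_features.index)
    out["week"] = global_features["week"].to_numpy()
    out["mean_fhr"] = global_features["mean_fhr"].to_numpy()

    def standardized(col: np.ndarray) -> np.ndarray:
        return (col - col.mean()) / col.std(ddof=1)

    out["LIN_time"] = standardized(time_result.scores[:, 0])
    for name, j in _assign_names(freq_result, _FREQ_DEFINING_SETS).items():
        out[name] = standardized(freq_result.scores[:, j])
    for name, j in _assign_names(nonlinear_result, _NONLINEAR_DEFINING_SETS).items():
        out[name] = standardized(nonlinear_result.scores[:, j])
    return out.loc[:, list(REDUCED_COLUMNS)]


def reduce_features(feature_table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, BlockPCAResult]]:
    """Run the full bwPCA: three block PCAs plus assembly of the reduced
    table from a 19-feature table (columns per FEATURE_NAMES)."""
    results = {name: block_pca(feature_table, spec) for name, spec in BLOCKS.items()}
    reduced = assemble_reduced(
        feature_table, results["time"], results["frequency"], results["nonlinear"]
    )
    return reduced, results
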