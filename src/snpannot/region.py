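"""Regional association statistics.

Computable pieces of a region browser: a smoothed P-value profile (bins ->
per-bin local maxima -> polynomial regression), linkage disequilibrium r^2
from a genotype dosage matrix, and expression-matrix scaling with
bi-directional hierarchical clustering orders for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .exceptions import ConfigError, DataError


@dataclass
class ProfileFit:
    bin_edges: np.ndarray
    maxima_pos: np.ndarray  # one local maximum per non-empty bin
    maxima_neglogp: np.ndarray
    grid_pos: np.ndarray
    grid_fit: np.ndarray  # fitted curve, clipped below at 0
    degree: int
    n_bins: int


@dataclass
class LdResult:
    target: str
    r2: dict[str, float]  # comparator -> r^2; NaN when undefined


def pvalue_profile(
    pos: np.ndarray,
    neg_log10_p: np.ndarray,
    region: tuple[int, int],
    n_bins: int = 20,
    degree: int = 3,
    grid_points: int = 512,
) -> ProfileFit:
    """Fit a polynomial through per-bin association maxima.

    The region is divided into ``n_bins`` equal-width bins; in each
    non-empty bin the point with the largest -log10(P) is taken (ties go to
    the leftmost position); a least-squares polynomial of ``degree`` is fit
    through the maxima and sampled on an even grid, clipped below at 0.
    """
    pos = np.asarray(pos, dtype=float)
    y = np.asarray(neg_log10_p, dtype=float)
    if pos.shape != y.shape or pos.size == 0:
        raise ConfigError("positions and -log10 P-values must align and be non-empty")
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite -log10 P-values in profile input")
    start, end = region
    if end <= start:
        raise ConfigError("region end must exceed region start")
    edges = np.linspace(start, end, n_bins + 1)
    inside = (pos >= start) & (pos <= end)
    if not inside.any():
        raise DataError("no association points inside the region")
    pos_in, y_in = pos[inside], y[inside]
    idx = np.clip(np.digitize(pos_in, edges) - 1, 0, n_bins - 1)

    max_pos, max_y = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        pb, yb = pos_in[mask], y_in[mask]
        best = np.lexsort((pb, -yb))[0]  # max y, tie -> leftmost pos
        max_pos.append(pb[best])
        max_y.append(yb[best])
    needed = max(degree + 1, 2)
    if len(max_pos) < needed:
        raise DataError(
            f"only {len(max_pos)} non-empty bins, need >= {needed}; "
            "use fewer bins or a lower polynomial degree"
        )
    max_pos = np.asarray(max_pos)
    max_y = np.asarray(max_y)
    # center/scale the predictor for numerical conditioning
    scale = (end - start) or 1.0
    xs = (max_pos - start) / scale
    coeffs = np.polyfit(xs, max_y, deg=degree)
    grid = np.linspace(start, end, grid_points)
    fit = np.polyval(coeffs, (grid - start) / scale)
    return ProfileFit(
        bin_edges=edges,
        maxima_pos=max_pos,
        maxima_neglogp=max_y,
        grid_pos=grid,
        grid_fit=np.clip(fit, 0.0, None),
        degree=degree,
        n_bins=n_bins,
    )


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 2:
        return float("nan")
    x, y = a[mask], b[mask]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_r2(genotypes: pd.DataFrame, target: str) -> LdResult:
    """r^2 between the target variant and every other column of the dosage matrix.

    Dosages are 0/1/2 (or NaN for missing); r^2 is the squared Pearson
    correlation over pairwise-complete samples, which makes it invariant to
    allele-coding swaps (g -> 2 - g).  Monomorphic comparators yield NaN; a
    monomorphic target is an error.
    """
    if target not in genotypes.columns:
        raise DataError(f"target variant {target} absent from genotype matrix")
    tv = genotypes[target].to_numpy(dtype=float)
    finite = tv[~np.isnan(tv)]
    if finite.size < 2 or finite.std() == 0:
        raise DataError(f"target variant {target} is monomorphic; LD undefined")
    r2 = {
        col: _pairwise_r2(tv, genotypes[col].to_numpy(dtype=float))
        for col in genotypes.columns
    }
    return LdResult(target=target, r2=r2)


def expression_heatmap_prep(
    expr: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str], list[str], list[str]]:
    """Per-gene z-scaling plus bi-directional average-linkage leaf orders.

    Returns (scaled matrix, gene order, tissue order, constant-gene flags).
    Constant genes scale to an all-zero row and are flagged rather than
    dropped.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ConfigError("heatmap prep needs at least 2 genes and 2 tissues")
    values = expr.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=0, keepdims=True)
    constant = (sds[:, 0] == 0)
    safe_sds = np.where(sds == 0, 1.0, sds)
    scaled = (values - means) / safe_sds
    scaled[constant, :] = 0.0
    scaled_df = pd.DataFrame(scaled, index=expr.index, columns=expr.columns)

    row_order = leaves_list(linkage(pdist(scaled), method="average"))
    col_order = leaves_list(linkage(pdist(scaled.T), method="average"))
    gene_order = [str(expr.index[i]) for i in row_order]
    tissue_order = [str(expr.columns[i]) for i in col_order]
    flagged = [str(g) for g, c in zip(expr.index, constant) if c]
    return scaled_df, gene_order, tissue_order, flagged
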