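"""Post-registration image-similarity measures and setting ranking.

Implements the relative-validation arm of the protocol: after registering
the same image pair under many candidate settings, each result is scored
with intensity-statistical similarity measures computed from a joint
histogram, and settings are ranked by their per-case mean.  Absolute
similarity values depend on binning and range handling, so only orderings
are comparable across implementations.

Definitions used here:

* NMI (Studholme): ``(H(A) + H(B)) / H(A, B)``, in [1, 2], 2 for
  identical images under shared binning.
* MI: ``H(A) + H(B) - H(A, B)`` in bits.
* Symmetric correlation ratio: the mean of the two directed correlation
  ratios ``eta^2(A|B)`` and ``eta^2(B|A)``, each the fraction of one
  image's intensity variance explained by conditioning on the other's bin.
* CC: Pearson correlation over the overlap; intra-modality only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import GeometryMismatchError, Volume


@dataclass
class SimilarityReport:
    nmi: float
    mi_bits: float
    scr: float
    cc: float | None
    n_voxels_overlap: int
    bins: int


@dataclass
class SettingRanking:
    """Per-setting mean metric values and 1-based ranks (1 = best)."""

    table: pd.DataFrame  # index: setting; columns: mean, rank
    ties: list[tuple[str, str]]


def _as_arrays(a: Volume, b: Volume) -> tuple[np.ndarray, np.ndarray]:
    if not a.same_geometry(b):
        raise GeometryMismatchError("similarity measures require an identical (registered) grid")
    return np.asarray(a.data, float).ravel(), np.asarray(b.data, float).ravel()


def _robust_edges(x: np.ndarray, bins: int, range_policy: str) -> np.ndarray:
    if range_policy == "robust":
        lo, hi = np.percentile(x, [0.5, 99.5])
    elif range_policy == "full":
        lo, hi = float(x.min()), float(x.max())
    else:
        raise ValueError(f"unknown range policy {range_policy!r}")
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, bins + 1)


def _hist2d(a: Volume, b: Volume, bins: int, range_policy: str):
    xa, xb = _as_arrays(a, b)
    if bins < 2:
        raise ValueError("bins must be at least 2")
    ea = _robust_edges(xa, bins, range_policy)
    eb = _robust_edges(xb, bins, range_policy)
    # clip so out-of-range tails land in the edge bins and counts sum to N
    xa = np.clip(xa, ea[0], ea[-1])
    xb = np.clip(xb, eb[0], eb[-1])
    h, _, _ = np.histogram2d(xa, xb, bins=[ea, eb])
    ca = 0.5 * (ea[:-1] + ea[1:])
    cb = 0.5 * (eb[:-1] + eb[1:])
    return h, ca, cb


def joint_histogram(a: Volume, b: Volume, bins: int = 64, range_policy: str = "robust") -> np.ndarray:
    """Equal-width 2D intensity histogram over the overlap grid.

    The per-image range is the robust 0.5th-99.5th percentile span by
    default; values outside it are clipped into the edge bins so the
    counts always sum to the overlap voxel count.
    """
    h, _, _ = _hist2d(a, b, bins, range_policy)
    return h


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _entropies(h: np.ndarray) -> tuple[float, float, float]:
    p = h / h.sum()
    ha = _entropy_bits(p.sum(axis=1))
    hb = _entropy_bits(p.sum(axis=0))
    hab = _entropy_bits(p.ravel())
    return ha, hb, hab


def nmi(a: Volume, b: Volume, bins: int = 64, range_policy: str = "robust") -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B), entropies in bits."""
    h = joint_histogram(a, b, bins, range_policy)
    return nmi_from_histogram(h)


def nmi_from_histogram(h: np.ndarray) -> float:
    ha, hb, hab = _entropies(np.asarray(h, float))
    if ha == 0.0 or hb == 0.0:
        raise ValueError("degenerate (zero-entropy) image; NMI undefined")
    return (ha + hb) / hab


def mutual_information(a: Volume, b: Volume, bins: int = 64, range_policy: str = "robust") -> float:
    """Mutual information in bits; nonnegative, 0 for independent images."""
    h = joint_histogram(a, b, bins, range_policy)
    return mutual_information_from_histogram(h)


def mutual_information_from_histogram(h: np.ndarray) -> float:
    ha, hb, hab = _entropies(np.asarray(h, float))
    if ha == 0.0 or hb == 0.0:
        raise ValueError("degenerate (zero-entropy) image; MI undefined")
    return ha + hb - hab


def correlation_coefficient(a: Volume, b: Volume) -> float:
    """Pearson correlation over the overlap domain (intra-modality use)."""
    xa, xb = _as_arrays(a, b)
    if np.var(xa) == 0.0 or np.var(xb) == 0.0:
        raise ValueError("zero-variance image; correlation coefficient undefined")
    return float(np.corrcoef(xa, xb)[0, 1])


def symmetric_correlation_ratio(a: Volume, b: Volume, bins: int = 64, range_policy: str = "robust") -> float:
    """Mean of the two directed correlation ratios, from the joint histogram.

    eta^2(A|B) = Var(E[A | B-bin]) / Var(A), with intensities represented
    by bin centers; 1 when one image is a deterministic function of the
    other at the binning resolution, 0 in the independence limit.
    """
    h, ca, cb = _hist2d(a, b, bins, range_policy)
    return _scr_from_histogram(h, ca, cb)


def _eta_sq(h: np.ndarray, values: np.ndarray) -> float:
    # h rows indexed by the value-carrying variable, columns by the condition
    n = h.sum()
    pa = h.sum(axis=1)
    mu = float(np.sum(pa * values)) / n
    var = float(np.sum(pa * (values - mu) ** 2)) / n
    if var == 0.0:
        raise ValueError("zero-variance image; correlation ratio undefined")
    nb = h.sum(axis=0)
    nz = nb > 0
    cond_mean = (values @ h[:, nz]) / nb[nz]
    var_between = float(np.sum(nb[nz] * (cond_mean - mu) ** 2)) / n
    return var_between / var


def _scr_from_histogram(h: np.ndarray, ca: np.ndarray, cb: np.ndarray) -> float:
    return 0.5 * (_eta_sq(h, ca) + _eta_sq(h.T, cb))


def similarity_report(a: Volume, b: Volume, bins: int = 64, intra_modality: bool = True,
                      range_policy: str = "robust") -> SimilarityReport:
    """All similarity measures for one registered pair.

    The correlation coefficient is only meaningful when the two images
    share an intensity scale, so it is omitted for inter-modality pairs.
    """
    h, ca, cb = _hist2d(a, b, bins, range_policy)
    cc = correlation_coefficient(a, b) if intra_modality else None
    return SimilarityReport(
        nmi=nmi_from_histogram(h),
        mi_bits=mutual_information_from_histogram(h),
        scr=_scr_from_histogram(h, ca, cb),
        cc=cc,
        n_voxels_overlap=int(h.sum()),
        bins=bins,
    )


def rank_settings(results: pd.DataFrame, value_col: str = "value") -> SettingRanking:
    """Rank registration settings by per-setting mean metric, descending.

    ``results`` is long-form with columns ``setting``, ``case`` and the
    metric value; every setting must cover the same cases.  Ties share the
    metric mean and are broken lexicographically by setting id, flagged in
    the returned ranking.
    """
    required = {"setting", "case", value_col}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    pivot = results.pivot_table(index="setting", columns="case", values=value_col, aggfunc="mean")
    if pivot.isna().any().any():
        cells = [(pivot.index[i], pivot.columns[j]) for i, j in np.argwhere(pivot.isna().values)]
        raise ValueError(f"missing metric cells for (setting, case): {cells}")
    means = pivot.mean(axis=1)
    # stable sort of lexicographically ordered settings => ties break by id
    df = pd.DataFrame({"mean": means}).loc[sorted(means.index)]
    df = df.sort_values("mean", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    ties = []
    vals = df["mean"].values
    idx = list(df.index)
    for i in range(len(df) - 1):
        if vals[i] == vals[i + 1]:
            ties.append((str(idx[i]), str(idx[i + 1])))
    return SettingRanking(table=df, ties=ties)
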