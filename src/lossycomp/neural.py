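"""Neural signatures of lossy compression from trial-wise evoked data.

Two signatures are computed per region. The first is the effective
dimensionality of the evoked voxel population, measured as the
participation ratio of the covariance eigenvalues,

    PR = (sum_i lambda_i)^2 / sum_i lambda_i^2,

and its difference between correct and incorrect lure trials
(delta-dimensionality: negative values mean dimensionality reduction with
correct discrimination). The second is the plug-in mutual information
between concatenated target and lure time courses, estimated by
discretizing each series into fixed equal-width bins.

Because both metrics scale with region size, regional values are computed
under a subsampling protocol: a fixed number of voxels is drawn repeatedly
and the per-iteration values averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import RegionData, ValidationError


class UndefinedSignatureError(ValueError):
    """A signature cannot be computed on the supplied data."""


# --------------------------------------------------------------------------
# time-series reconstruction from trial-wise amplitude estimates


def reconstruct_timeseries(
    betas: np.ndarray,
    hrf: np.ndarray,
    onsets: np.ndarray,
    n_scans: int,
    labels: pd.DataFrame | None = None,
    region: str = "region",
) -> RegionData:
    """Evoked per-trial voxel time series from amplitudes and an HRF kernel.

    ``betas`` is (n_trials, n_voxels): one evoked amplitude per voxel per
    trial. Each trial's series is the outer product amplitude x kernel
    placed at the trial onset on the scan grid; the per-trial matrices are
    returned (n_voxels x len(hrf)), labelled with their onsets.
    """
    betas = np.atleast_2d(np.asarray(betas, float))
    hrf = np.asarray(hrf, float)
    onsets = np.asarray(onsets, int)
    if not np.isfinite(hrf).all():
        raise ValidationError("HRF kernel must be finite")
    if betas.shape[0] != len(onsets):
        raise ValidationError("one onset per trial required")
    if np.any(onsets < 0) or np.any(onsets + len(hrf) > n_scans):
        raise ValidationError("trial onset outside the scan window")
    trials = [np.outer(betas[t], hrf) for t in range(betas.shape[0])]
    if labels is None:
        labels = pd.DataFrame({"role": "target", "outcome": "correct",
                               "onset": onsets})
    else:
        labels = labels.copy()
        labels["onset"] = onsets
    return RegionData(region=region, trials=trials, labels=labels)


# --------------------------------------------------------------------------
# participation ratio


@dataclass
class Spectrum:
    """Descending non-negative covariance eigenvalues."""

    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, float)
        if np.any(lam < -1e-10):
            raise ValidationError("eigenvalues must be >= 0 (numerical floor -1e-10)")
        self.eigenvalues = np.sort(np.clip(lam, 0.0, None))[::-1]

    @property
    def n(self) -> int:
        return len(self.eigenvalues)


def participation_ratio(data) -> float:
    """Effective dimensionality (sum lambda)^2 / sum lambda^2.

    ``data`` is either a voxel x time matrix (covariance taken over time
    points, voxel means removed, 1/(T-1) divisor) or a :class:`Spectrum`.
    Lies in [1, N]; invariant to global scaling and to orthogonal rotations
    of the voxel basis.
    """
    if isinstance(data, Spectrum):
        lam = data.eigenvalues
    else:
        arr = np.asarray(data, float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError("need a matrix with >= 2 voxels and >= 2 time points")
        cov = np.cov(arr, ddof=1)
        lam = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise UndefinedSignatureError("zero covariance: participation ratio undefined")
    return float(total**2 / np.sum(lam**2))


# --------------------------------------------------------------------------
# binned mutual information


@dataclass
class JointHistogram:
    """Fixed-bin joint counts with marginals."""

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def marginal_x(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def joint_histogram(x: np.ndarray, y: np.ndarray, n_bins: int) -> JointHistogram:
    """Equal-width joint histogram spanning each variable's observed range."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValidationError("series must have equal length")
    if n_bins < 2:
        raise ValidationError("need at least 2 bins")
    if len(x) < n_bins:
        raise ValidationError("series shorter than the bin count")
    counts, xe, ye = np.histogram2d(x, y, bins=n_bins)
    return JointHistogram(counts=counts, x_edges=xe, y_edges=ye)


def mi_from_counts(counts: np.ndarray) -> float:
    """Plug-in mutual information (nats) of a joint count table."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    if n <= 0:
        raise ValidationError("empty histogram")
    pxy = counts / n
    # both marginals summed in contiguous order and the final reduction over
    # sorted terms: makes MI(x, y) == MI(y, x) bit-for-bit
    px = pxy.sum(axis=1)[:, None]
    py = np.ascontiguousarray(pxy.T).sum(axis=1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pxy > 0, pxy * np.log(pxy / (px * py)), 0.0)
    return float(max(np.sort(terms, axis=None).sum(), 0.0))


def binned_mutual_information(x, y, n_bins: int = 16) -> float:
    """Mutual information between two series after fixed-bin discretization.

    Non-negative, symmetric in its arguments, in nats. A constant series
    occupies a single bin, so its MI is 0 (a warning is emitted).
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: MI defined as 0", stacklevel=2)
        return 0.0
    return mi_from_counts(joint_histogram(x, y, n_bins).counts)


# --------------------------------------------------------------------------
# regional signatures under voxel subsampling


@dataclass
class NeuralSignature:
    """Per-iteration and averaged regional compression signatures."""

    region: str
    per_iteration: pd.DataFrame   # columns: dim_correct, dim_incorrect, delta_dim,
                                  #          mi_correct, mi_incorrect
    n_voxels: int
    n_iter: int
    seed: int

    @property
    def means(self) -> pd.Series:
        return self.per_iteration.mean()

    @property
    def delta_dimensionality(self) -> float:
        return float(self.per_iteration["delta_dim"].mean())


def region_signatures(
    region: RegionData,
    n_voxels: int = 100,
    n_iter: int = 100,
    seed: int = 0,
    n_bins: int = 16,
) -> NeuralSignature:
    """Dimensionality and MI signatures under the voxel-subsampling protocol.

    Per iteration a fixed-size voxel subset is drawn (without replacement
    when the region is large enough, with replacement otherwise) and

    * the participation ratio of correct-lure and incorrect-lure trial data
      and their difference (delta-dimensionality), and
    * the MI between the concatenated, flattened target and lure series
      within each outcome (series truncated to the shorter length)

    are computed; per-iteration values and their means are returned.
    """
    rng = np.random.default_rng(seed)
    data = {}
    for outcome in ("correct", "incorrect"):
        lure = region.select(role="lure", outcome=outcome)
        target = region.select(role="target", outcome=outcome)
        if not lure:
            raise UndefinedSignatureError(f"no {outcome} lure trials in {region.region}")
        data[outcome] = {
            "lure": np.concatenate(lure, axis=1),
            "target": np.concatenate(target, axis=1) if target else None,
        }
    nv = region.n_voxels
    replace = nv < n_voxels
    if replace:
        warnings.warn(
            f"{region.region}: {nv} voxels < budget {n_voxels}; sampling with replacement",
            stacklevel=2,
        )
    rows = []
    for _ in range(n_iter):
        idx = rng.choice(nv, size=n_voxels, replace=replace)
        rec = {}
        for outcome in ("correct", "incorrect"):
            lure = data[outcome]["lure"][idx]
            rec[f"dim_{outcome}"] = participation_ratio(lure)
            target = data[outcome]["target"]
            if target is not None:
                t = target[idx].ravel()
                l = lure.ravel()
                m = min(len(t), len(l))
                rec[f"mi_{outcome}"] = binned_mutual_information(t[:m], l[:m], n_bins)
            else:
                rec[f"mi_{outcome}"] = np.nan
        rec["delta_dim"] = rec["dim_correct"] - rec["dim_incorrect"]
        rows.append(rec)
    return NeuralSignature(
        region=region.region,
        per_iteration=pd.DataFrame(rows),
        n_voxels=n_voxels,
        n_iter=n_iter,
        seed=seed,
    )


def region_gradient(
    signatures: list[NeuralSignature], order: list[str]
) -> tuple[float, float]:
    """Spearman correlation of delta-dimensionality with hierarchy rank.

    ``order`` lists region names from early to late processing stages; a
    negative correlation means dimensionality reduction strengthens along
    the hierarchy. Ties use average ranks.
    """
    named = {s.region: s.delta_dimensionality for s in signatures}
    missing = [r for r in order if r not in named]
    if missing:
        raise ValidationError(f"signatures missing for regions: {missing}")
    if len(order) < 3:
        raise ValidationError("need >= 3 regions")
    values = [named[r] for r in order]
    if len(set(values)) == 1:
        raise UndefinedSignatureError("all delta-dimensionality values tied")
    rho, p = spearmanr(np.arange(len(order)), values)
    return float(rho), float(p)
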