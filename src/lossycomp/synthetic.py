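"""Synthetic inputs with planted ground truth.

Every generator takes an explicit integer seed and is bitwise reproducible.
The defaults mirror the task designs the pipeline is meant to score: a
128-study / 192-test mnemonic similarity task and a continuous-recognition
design of six 107-stimulus blocks (32 first presentations, 16 repeats of
studied items, 16 similar lures and 43 unrelated foils per block).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    EmbeddingSet,
    ImageSet,
    RegionData,
    TRIAL_COLUMNS,
    ValidationError,
    validate_trial_table,
)


class DesignError(ValueError):
    """Requested task design is infeasible."""


# --------------------------------------------------------------------------
# embeddings


def gen_embedding_pairs(
    n_pairs: int,
    dim: int,
    separation,
    seed: int,
) -> EmbeddingSet:
    """Unit-norm target/lure embedding pairs at controlled angular separation.

    Parameters
    ----------
    separation
        Either a scalar angle in radians, a length-``n_pairs`` sequence of
        angles, or a tuple ``("uniform", lo, hi)`` sampling one angle per
        pair. All angles must lie in the open interval (0, pi).
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    if dim < 2:
        raise ValidationError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    if isinstance(separation, tuple) and separation and separation[0] == "uniform":
        _, lo, hi = separation
        angles = rng.uniform(lo, hi, size=n_pairs)
    else:
        angles = np.broadcast_to(np.atleast_1d(np.asarray(separation, float)), (n_pairs,)).copy()
    if np.any(angles <= 0) or np.any(angles >= math.pi):
        raise ValidationError("pair angles must lie in (0, pi)")

    items = np.empty((2 * n_pairs, dim))
    ids: list[str] = []
    pairs: list[tuple[str, str]] = []
    for i, theta in enumerate(angles):
        t = rng.standard_normal(dim)
        t /= np.linalg.norm(t)
        u = rng.standard_normal(dim)
        u -= (u @ t) * t
        u /= np.linalg.norm(u)
        lure = math.cos(theta) * t + math.sin(theta) * u
        tid, lid = f"pair{i:03d}_target", f"pair{i:03d}_lure"
        items[2 * i] = t
        items[2 * i + 1] = lure
        ids += [tid, lid]
        pairs.append((tid, lid))
    return EmbeddingSet(
        items=items,
        ids=ids,
        pairs=pairs,
        meta={"angles": angles, "seed": seed},
    )


# --------------------------------------------------------------------------
# images

_SHAPES = ("circle", "square", "triangle")
_PALETTE = {
    "red": (0.85, 0.15, 0.15),
    "green": (0.15, 0.7, 0.2),
    "blue": (0.15, 0.3, 0.85),
    "yellow": (0.9, 0.85, 0.1),
    "purple": (0.6, 0.2, 0.7),
}
_BACKGROUND = 0.92


def _shape_mask(shape: str, size: int, cx: float, cy: float, scale: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    r = scale / 2
    if shape == "circle":
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    if shape == "square":
        return (np.abs(xx - cx) <= r) & (np.abs(yy - cy) <= r)
    if shape == "triangle":
        # upright isoceles triangle inscribed in the bounding square
        inside = (yy >= cy - r) & (yy <= cy + r)
        half_width = (yy - (cy - r)) / (2 * r + 1e-12) * r
        return inside & (np.abs(xx - cx) <= half_width)
    raise ValidationError(f"unknown shape {shape!r}")


def render_shape(row: pd.Series | dict, size: int) -> np.ndarray:
    """Render a single (H, W, 3) image from one factor-table row."""
    img = np.full((size, size, 3), _BACKGROUND)
    mask = _shape_mask(row["shape"], size, row["pos_x"], row["pos_y"], row["scale"])
    img[mask] = _PALETTE[row["color"]]
    return img


def gen_shape_images(
    n: int,
    size: int,
    seed: int,
    factor_table: pd.DataFrame | None = None,
) -> ImageSet:
    """Parametric one-shape-per-image stimuli with a ground-truth factor table.

    Each image contains one colored shape on a uniform light background; the
    factors are shape kind, color name, scale (fraction of the image side)
    and center position. Pass ``factor_table`` to render exact factor
    combinations (e.g. a pair differing only in color).
    """
    if n == 0:
        raise ValidationError("empty image set requested")
    if size < 8:
        raise ValidationError("size must be >= 8 pixels")
    rng = np.random.default_rng(seed)
    if factor_table is None:
        factor_table = pd.DataFrame(
            {
                "shape": rng.choice(_SHAPES, size=n),
                "color": rng.choice(list(_PALETTE), size=n),
                "scale": rng.uniform(0.3, 0.8, size=n),
                "pos_x": rng.uniform(0.3, 0.7, size=n),
                "pos_y": rng.uniform(0.3, 0.7, size=n),
            }
        )
    else:
        factor_table = factor_table.reset_index(drop=True)
        if len(factor_table) != n:
            raise ValidationError("factor table must have one row per image")
    images = np.stack([render_shape(row, size) for _, row in factor_table.iterrows()])
    ids = [f"img{i:04d}" for i in range(n)]
    return ImageSet(images=images, ids=ids, factors=factor_table)


# --------------------------------------------------------------------------
# task designs


@dataclass
class MSTParams:
    """Classic study/test mnemonic similarity task design."""

    n_study: int = 128
    n_test: int = 192
    # the split of test trials between repeats / lures / foils
    test_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_bins: int = 5
    participant: str = "p000"
    session: str = "immediate"
    age: float = 22.0


@dataclass
class ContinuousParams:
    """Continuous-recognition design: blocks of interleaved presentations."""

    n_blocks: int = 6
    n_first: int = 32
    n_repeat: int = 16
    n_lure: int = 16
    n_foil: int = 43
    mean_lag: float = 19.0
    n_bins: int = 5
    participant: str = "p000"
    session: str = "immediate"
    age: float = 22.0


def _empty_table(n: int) -> pd.DataFrame:
    table = pd.DataFrame({c: pd.NA for c in TRIAL_COLUMNS}, index=range(n))
    table["rt"] = np.nan
    return table


def gen_task_tables(design: str, params=None, seed: int = 0) -> pd.DataFrame:
    """Generate an unanswered trial table for one simulated participant.

    ``design`` is ``"mst"`` (separate study and test phases) or
    ``"continuous"`` (interleaved blocks; every trial is a test trial).
    Repeats and lures always appear after the first presentation of their
    base item; in the continuous design the gap is drawn from a geometric
    distribution with the configured mean lag, truncated to the block.
    """
    rng = np.random.default_rng(seed)
    if design == "mst":
        params = params or MSTParams()
        return _gen_mst(params, rng)
    if design == "continuous":
        params = params or ContinuousParams()
        return _gen_continuous(params, rng)
    raise ValidationError(f"unknown design {design!r}")


def _gen_mst(p: MSTParams, rng: np.random.Generator) -> pd.DataFrame:
    props = np.asarray(p.test_proportions, float)
    if props.min() < 0 or not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
        raise DesignError("test proportions must be non-negative and sum to 1")
    n_rep = int(round(p.n_test * props[0]))
    n_lure = int(round(p.n_test * props[1]))
    n_foil = p.n_test - n_rep - n_lure
    if n_rep + n_lure > p.n_study:
        raise DesignError("more repeat+lure test trials than studied items")

    study_ids = [f"s{i:04d}" for i in range(p.n_study)]
    studied_order = rng.permutation(p.n_study)
    rep_items = [study_ids[i] for i in studied_order[:n_rep]]
    lure_items = [study_ids[i] for i in studied_order[n_rep : n_rep + n_lure]]
    foil_items = [f"f{i:04d}" for i in range(n_foil)]

    rows = []
    for t, sid in enumerate(study_ids):
        rows.append(("study", t, sid, "first", pd.NA))
    test_events = (
        [(sid, "repeat", rng.integers(1, p.n_bins + 1)) for sid in rep_items]
        + [(f"{sid}_lure", "lure", rng.integers(1, p.n_bins + 1)) for sid in lure_items]
        + [(sid, "foil", pd.NA) for sid in foil_items]
    )
    rng.shuffle(test_events)
    for t, (sid, cond, bin_) in enumerate(test_events):
        rows.append(("test", t, sid, cond, bin_))

    table = _empty_table(len(rows))
    table[["phase", "trial", "stimulus", "condition", "lure_bin"]] = rows
    table["participant"] = p.participant
    table["session"] = p.session
    table["age"] = p.age
    validate_trial_table(table)
    return table


def _gen_continuous(p: ContinuousParams, rng: np.random.Generator) -> pd.DataFrame:
    if p.mean_lag < 1:
        raise DesignError("mean lag must be >= 1 trial")
    block_len = p.n_first + p.n_repeat + p.n_lure + p.n_foil
    if p.n_repeat + p.n_lure > p.n_first:
        raise DesignError("more repeats+lures than first presentations in a block")

    all_rows = []
    for b in range(p.n_blocks):
        firsts = [f"b{b}s{i:03d}" for i in range(p.n_first)]
        foils = [f"b{b}f{i:03d}" for i in range(p.n_foil)]
        base = [(sid, "first", pd.NA) for sid in firsts] + [
            (sid, "foil", pd.NA) for sid in foils
        ]
        rng.shuffle(base)
        seq = list(base)
        chosen = rng.permutation(p.n_first)
        followers = [(firsts[i], "repeat") for i in chosen[: p.n_repeat]] + [
            (firsts[i], "lure") for i in chosen[p.n_repeat : p.n_repeat + p.n_lure]
        ]
        rng.shuffle(followers)
        for base_id, cond in followers:
            first_pos = next(
                i for i, (sid, c, _) in enumerate(seq) if sid == base_id and c == "first"
            )
            lag = 1 + rng.geometric(1.0 / p.mean_lag)
            pos = min(first_pos + lag, len(seq))
            stim = f"{base_id}_lure" if cond == "lure" else base_id
            seq.insert(pos, (stim, cond, rng.integers(1, p.n_bins + 1)))
        if len(seq) != block_len:
            raise DesignError("block assembly failed")  # pragma: no cover
        for t, (sid, cond, bin_) in enumerate(seq):
            all_rows.append(("test", b * block_len + t, sid, cond, bin_))

    table = _empty_table(len(all_rows))
    table[["phase", "trial", "stimulus", "condition", "lure_bin"]] = all_rows
    table["participant"] = p.participant
    table["session"] = p.session
    table["age"] = p.age
    validate_trial_table(table)
    return table


# --------------------------------------------------------------------------
# responses


@dataclass
class ResponsePolicy:
    """Probabilistic three-alternative response policy.

    On a lure trial the simulated participant answers "similar" with
    probability equal to the item's discriminability; otherwise (and on foil
    and first-presentation trials) it guesses from ``bias``, a distribution
    over (old, similar, new). Repeats are answered "old" with probability
    ``p_recognize``, else guessed. Responses go missing at ``p_miss`` and
    RTs are lognormal.
    """

    bias: tuple[float, float, float] = (0.1, 0.1, 0.8)
    p_recognize: float = 0.9
    p_miss: float = 0.02
    rt_log_mean: float = -0.2   # lognormal location, seconds scale
    rt_log_sd: float = 0.35

    def __post_init__(self) -> None:
        b = np.asarray(self.bias, float)
        if b.min() < 0 or b.max() > 1 or not math.isclose(b.sum(), 1.0, abs_tol=1e-9):
            raise ValidationError("bias must be a probability vector over (old, similar, new)")
        for name in ("p_recognize", "p_miss"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")


_CHOICES = np.array(["old", "similar", "new"])


def gen_responses(
    table: pd.DataFrame,
    item_discriminability: dict[str, float],
    policy: ResponsePolicy | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill the response/RT columns of a trial table under a documented policy.

    With discriminability 1 and a bias putting no mass on "similar", every
    lure is answered "similar" (LDI = 1); with discriminability 0 the lure
    and foil response distributions coincide, so the expected LDI is 0.
    P("similar" | lure) = d + (1 - d) * bias_similar is monotone in d.
    """
    policy = policy or ResponsePolicy()
    rng = np.random.default_rng(seed)
    out = table.copy()
    lures = out.loc[out["condition"] == "lure", "stimulus"]
    missing_d = sorted(set(lures) - set(item_discriminability))
    if missing_d:
        raise ValidationError(f"discriminability undefined for lure items: {missing_d[:5]}...")
    bad = [k for k, v in item_discriminability.items() if not 0 <= v <= 1]
    if bad:
        raise ValidationError(f"discriminability outside [0, 1] for {bad[:5]}")

    n = len(out)
    cond = out["condition"].to_numpy(object)
    is_test = (out["phase"] == "test").to_numpy()
    # per-trial response distribution over (old, similar, new)
    probs = np.tile(np.asarray(policy.bias, float), (n, 1))
    lure_mask = cond == "lure"
    if lure_mask.any():
        delta = np.array(
            [item_discriminability[s] for s in out.loc[lure_mask, "stimulus"]]
        )
        probs[lure_mask] = (
            delta[:, None] * np.array([0.0, 1.0, 0.0])
            + (1 - delta)[:, None] * np.asarray(policy.bias, float)
        )
    rep_mask = cond == "repeat"
    probs[rep_mask] = (
        policy.p_recognize * np.array([1.0, 0.0, 0.0])
        + (1 - policy.p_recognize) * np.asarray(policy.bias, float)
    )
    draws = (rng.random(n)[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    responses = pd.array(_CHOICES[np.minimum(draws, 2)], dtype="object")
    rts = rng.lognormal(policy.rt_log_mean, policy.rt_log_sd, size=n)
    missing = ~is_test | (rng.random(n) < policy.p_miss)
    responses[missing] = pd.NA
    rts[missing] = np.nan
    out["response"] = responses
    out["rt"] = rts
    validate_trial_table(out)
    return out


# --------------------------------------------------------------------------
# voxel time series


def planted_spectrum(n: int, effective_rank: float) -> np.ndarray:
    """Eigenvalue spectrum of length ``n`` whose participation ratio equals
    ``effective_rank`` exactly.

    Uses k unit eigenvalues plus one fractional eigenvalue a in (0, 1]
    solving (k + a)^2 / (k + a^2) = effective_rank; remaining eigenvalues 0.
    """
    if effective_rank < 1 or effective_rank > n:
        raise ValidationError("effective rank must lie in [1, n_voxels]")
    k = int(math.floor(effective_rank))
    lam = np.zeros(n)
    if math.isclose(effective_rank, k):
        lam[:k] = 1.0
        return lam
    er = effective_rank
    # a^2 (er - 1) - 2 k a + k (er - k) = 0
    disc = k * k - (er - 1) * k * (er - k)
    a = (k - math.sqrt(max(disc, 0.0))) / (er - 1)
    lam[:k] = 1.0
    lam[k] = a
    return lam


def gen_voxel_timeseries(
    n_voxels: int,
    n_trials_per_class: int,
    effective_rank,
    dependence="independent",
    seed: int = 0,
    n_timepoints: int = 25,
    region: str = "synthetic",
) -> RegionData:
    """Gaussian voxel x time trial matrices with planted covariance geometry.

    ``effective_rank`` is a scalar or a ``{"correct": r1, "incorrect": r2}``
    mapping; the voxel covariance of each outcome class has a participation
    ratio equal to the planted value exactly (spectrum built by
    :func:`planted_spectrum`, rotated into a random orthonormal voxel basis).

    ``dependence`` is ``"independent"`` (target and lure series from disjoint
    random streams) or ``("coupled", level)``: lure latent factors share a
    fraction ``level`` of their variance with the paired target trial's
    factors, creating recoverable target-lure mutual information.
    """
    if isinstance(effective_rank, dict):
        ranks = {k: float(v) for k, v in effective_rank.items()}
    else:
        ranks = {"correct": float(effective_rank), "incorrect": float(effective_rank)}
    for r in ranks.values():
        if r > n_voxels:
            raise ValidationError("effective_rank must not exceed n_voxels")
    if isinstance(dependence, str):
        if dependence != "independent":
            raise ValidationError(f"unknown dependence {dependence!r}")
        level = 0.0
    else:
        kind, level = dependence
        if kind != "coupled" or not 0 <= level <= 1:
            raise ValidationError("dependence must be 'independent' or ('coupled', level)")

    rng = np.random.default_rng(seed)
    # one random orthonormal basis per outcome class, shared by roles so that
    # coupling lives in a common subspace
    trials: list[np.ndarray] = []
    labels = []
    onset = 0
    for outcome in ("correct", "incorrect"):
        lam = planted_spectrum(n_voxels, ranks[outcome])
        q, _ = np.linalg.qr(rng.standard_normal((n_voxels, n_voxels)))
        scale = q * np.sqrt(lam)  # voxel loading matrix, cov = scale @ scale.T
        for i in range(n_trials_per_class):
            f_target = rng.standard_normal((n_voxels, n_timepoints))
            if level > 0:
                g = rng.standard_normal((n_voxels, n_timepoints))
                f_lure = math.sqrt(level) * f_target + math.sqrt(1 - level) * g
            else:
                f_lure = rng.standard_normal((n_voxels, n_timepoints))
            for role, f in (("target", f_target), ("lure", f_lure)):
                trials.append(scale @ f)
                labels.append({"role": role, "outcome": outcome, "onset": onset})
                onset += n_timepoints
    return RegionData(
        region=region,
        trials=trials,
        labels=pd.DataFrame(labels),
        planted={"effective_rank": ranks, "dependence_level": level, "seed": seed},
    )
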