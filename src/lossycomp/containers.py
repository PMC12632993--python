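"""In-memory containers shared across the pipeline.

Behavioral trial tables are plain :class:`pandas.DataFrame` objects with the
column schema documented in :data:`TRIAL_COLUMNS`; embeddings, images and
regional voxel data get light dataclass wrappers that validate their
invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Column schema of a behavioral trial table.
TRIAL_COLUMNS = [
    "participant",  # participant id (str)
    "session",      # {"immediate", "delayed"}
    "phase",        # {"study", "test"}
    "trial",        # trial index within phase (int)
    "stimulus",     # stimulus id (str)
    "condition",    # {"first", "repeat", "lure", "foil"}
    "lure_bin",     # 1..5 on lure/repeat items, else NA
    "response",     # {"old", "similar", "new"} or NA (missing)
    "rt",           # seconds, NaN when missing
    "age",          # years
]

#: Conditions on which a lure bin may appear.
BINNABLE_CONDITIONS = {"lure", "repeat"}


class ValidationError(ValueError):
    """An input violates a documented invariant."""


def validate_trial_table(table: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` if ``table`` breaks the trial schema."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    bad_rt = table["rt"].dropna() < 0
    if bad_rt.any():
        raise ValidationError("negative RTs present")
    binned = table["lure_bin"].notna()
    offenders = table.loc[binned & ~table["condition"].isin(BINNABLE_CONDITIONS)]
    if len(offenders):
        raise ValidationError(
            f"lure bins on non-lure/repeat conditions: {sorted(offenders['condition'].unique())}"
        )


@dataclass
class EmbeddingSet:
    """Item-by-dimension embedding matrix with target<->lure pairing.

    ``items`` holds one row per item id; ``pairs`` lists (target_id, lure_id)
    tuples referencing ``ids``. Cosine geometry must be defined, so all-zero
    rows are rejected.
    """

    items: np.ndarray
    ids: list[str]
    pairs: list[tuple[str, str]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=float)
        if self.items.ndim != 2 or self.items.shape[1] < 2:
            raise ValidationError("items must be 2-D with dimension >= 2")
        if self.items.shape[0] != len(self.ids):
            raise ValidationError("row count must equal id count")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate ids")
        if not np.isfinite(self.items).all():
            raise ValidationError("non-finite embedding values")
        norms = np.linalg.norm(self.items, axis=1)
        if np.any(norms == 0):
            raise ValidationError("all-zero embedding rows (cosine undefined)")
        known = set(self.ids)
        for t, l in self.pairs:
            if t not in known or l not in known:
                raise ValidationError(f"pair ({t}, {l}) references unknown id")

    @property
    def dim(self) -> int:
        return self.items.shape[1]

    def vector(self, item_id: str) -> np.ndarray:
        return self.items[self.ids.index(item_id)]

    def pair_vectors(self, pair: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
        t, l = pair
        return self.vector(t), self.vector(l)

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            items=self.items,
            ids=np.array(self.ids),
            pair_targets=np.array([p[0] for p in self.pairs]),
            pair_lures=np.array([p[1] for p in self.pairs]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingSet":
        with np.load(path, allow_pickle=False) as z:
            pairs = list(zip(z["pair_targets"].tolist(), z["pair_lures"].tolist()))
            return cls(items=z["items"], ids=z["ids"].tolist(), pairs=pairs)


@dataclass
class ImageSet:
    """Small RGB image stack with a per-image generative factor table."""

    images: np.ndarray  # (n, H, W, 3) in [0, 1]
    ids: list[str]
    factors: pd.DataFrame

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 4 or self.images.shape[3] != 3:
            raise ValidationError("images must have shape (n, H, W, 3)")
        if self.images.shape[1] < 8 or self.images.shape[2] < 8:
            raise ValidationError("image side must be >= 8 pixels")
        if self.images.min() < 0 or self.images.max() > 1:
            raise ValidationError("pixel values must lie in [0, 1]")
        if len(self.ids) != self.images.shape[0] or len(self.factors) != self.images.shape[0]:
            raise ValidationError("ids/factor rows must match image count")

    @property
    def n(self) -> int:
        return self.images.shape[0]

    def flat(self) -> np.ndarray:
        """Images flattened row-wise to (n, H*W*3), C order."""
        return self.images.reshape(self.n, -1)


@dataclass
class RegionData:
    """Trial-wise voxel x time matrices for one region.

    ``trials`` is a list of (n_voxels, n_timepoints) arrays; ``labels`` has
    one row per trial with columns ``role`` in {target, lure}, ``outcome`` in
    {correct, incorrect} and ``onset`` (scan-grid sample of trial onset).
    ``planted`` records generator ground truth when the data are synthetic.
    """

    region: str
    trials: list[np.ndarray]
    labels: pd.DataFrame
    planted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.labels):
            raise ValidationError("labels must cover every trial")
        nv = {t.shape[0] for t in self.trials}
        if len(nv) > 1:
            raise ValidationError("all trial matrices must share voxel count")
        if self.n_voxels < 2:
            raise ValidationError("need >= 2 voxels")

    @property
    def n_voxels(self) -> int:
        return self.trials[0].shape[0]

    def select(self, role: str | None = None, outcome: str | None = None) -> list[np.ndarray]:
        """Trial matrices filtered by role/outcome, in onset order."""
        mask = pd.Series(True, index=self.labels.index)
        if role is not None:
            mask &= self.labels["role"] == role
        if outcome is not None:
            mask &= self.labels["outcome"] == outcome
        idx = self.labels.index[mask]
        if "onset" in self.labels.columns:
            idx = self.labels.loc[idx].sort_values("onset").index
        return [self.trials[i] for i in idx]

    def concatenated(self, role: str | None = None, outcome: str | None = None) -> np.ndarray:
        """Voxel x time matrix of the selected trials concatenated in time."""
        mats = self.select(role=role, outcome=outcome)
        if not mats:
            raise ValidationError(f"no trials with role={role}, outcome={outcome}")
        return np.concatenate(mats, axis=1)
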