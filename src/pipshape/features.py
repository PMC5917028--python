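"""The 42-value feature vector, weight schedules and the weighted distance.

Each seed is summarized by six curves (five horizontal sections bottom to
top, then the silhouette), each contributing (r0, r2..r7): a row vector
[v1..v42] in raw millimetres. Positions 1, 8, 15, 22, 29, 36 (1-based)
hold the r0 size parameters, positions 2, 9, 16, 23, 30, 37 the r2
eccentricity parameters.

Seed-to-seed distance is the weighted Euclidean form

    d(alpha, beta) = sqrt( sum_i omega_i (v_alpha_i - v_beta_i)^2 )

with non-negative weights summing to one. Features deliberately stay in
raw millimetre units — the method weights absolute size (r0) on purpose,
and any standardization would silently re-weight it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .curves import SECTION_IDS, SILHOUETTE_ID
from .errors import ContractError, ParameterError
from .fourier import FourierDescriptor

PLANE_ORDER = SECTION_IDS + (SILHOUETTE_ID,)

N_FEATURES = 42

#: 0-based positions of the r0 (size) entries: v1, v8, ..., v36
R0_POSITIONS = tuple(range(0, N_FEATURES, 7))
#: 0-based positions of the r2 (eccentricity) entries: v2, v9, ..., v37
R2_POSITIONS = tuple(range(1, N_FEATURES, 7))
_OTHER_POSITIONS = tuple(
    i for i in range(N_FEATURES) if i not in R0_POSITIONS + R2_POSITIONS
)


@dataclass
class FeatureVector:
    """Per-seed row vector [v1..v42] in millimetres."""

    v: np.ndarray
    seed_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (N_FEATURES,):
            raise ContractError(
                f"feature vector must have exactly {N_FEATURES} values, "
                f"got {self.v.shape}"
            )
        if not np.isfinite(self.v).all():
            raise ContractError(f"{self.seed_id}: non-finite feature values")
        r0 = self.v[list(R0_POSITIONS)]
        if np.any(r0 <= 0):
            raise ContractError(f"{self.seed_id}: r0 entries must be positive")


@dataclass
class WeightSchedule:
    """Per-iteration weight vectors driving the iterative classification."""

    iterations: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.iterations:
            raise ParameterError("schedule needs at least one iteration")
        cleaned = []
        for i, w in enumerate(self.iterations):
            w = np.asarray(w, dtype=float)
            if w.shape != (N_FEATURES,):
                raise ParameterError(f"iteration {i}: weights must be length 42")
            if np.any(w < 0):
                raise ParameterError(f"iteration {i}: negative weight")
            if abs(w.sum() - 1.0) > 1e-12:
                raise ParameterError(
                    f"iteration {i}: weights sum to {w.sum():.15f}, not 1"
                )
            cleaned.append(w)
        self.iterations = cleaned

    def __len__(self) -> int:
        return len(self.iterations)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.iterations[i]


def assemble_features(
    descriptors: Mapping[str, FourierDescriptor],
    seed_id: str = "",
    label: str | None = None,
) -> FeatureVector:
    """Build [v1..v42] from the six per-curve descriptors.

    ``descriptors`` must contain exactly the keys section_1..section_5 and
    silhouette; insertion order is irrelevant.
    """
    missing = [p for p in PLANE_ORDER if p not in descriptors]
    if missing:
        raise ContractError(f"missing plane descriptors: {', '.join(missing)}")
    extra = [p for p in descriptors if p not in PLANE_ORDER]
    if extra:
        raise ContractError(f"unexpected plane descriptors: {', '.join(extra)}")
    v = np.concatenate([descriptors[p].values() for p in PLANE_ORDER])
    return FeatureVector(v=v, seed_id=seed_id, label=label)


def make_weights(w_r0: float, w_r2: float, w_rest: float) -> np.ndarray:
    """Weight vector giving totals w_r0 to the six r0 entries, w_r2 to the
    six r2 entries and w_rest spread equally over the remaining 30."""
    total = w_r0 + w_r2 + w_rest
    if abs(total - 1.0) > 1e-12:
        raise ParameterError(f"weight totals sum to {total}, not 1")
    w = np.empty(N_FEATURES)
    w[list(R0_POSITIONS)] = w_r0 / len(R0_POSITIONS)
    w[list(R2_POSITIONS)] = w_r2 / len(R2_POSITIONS)
    w[list(_OTHER_POSITIONS)] = w_rest / len(_OTHER_POSITIONS)
    return w


def default_weight_schedule() -> WeightSchedule:
    """The three-iteration schedule of the reference analysis.

    Iteration 1: 25% total on size (r0), 25% on eccentricity (r2), 50%
    spread equally over the remaining 30 parameters. Iterations 2 and 3:
    size reduced to 15%, eccentricity kept at 25%, 60% on the rest.
    """
    first = make_weights(0.25, 0.25, 0.50)
    later = make_weights(0.15, 0.25, 0.60)
    return WeightSchedule(iterations=[first, later.copy(), later.copy()])


def weighted_distance(
    alpha: FeatureVector, beta: FeatureVector, omega: np.ndarray
) -> float:
    """d = sqrt( sum_i omega_i (v_alpha_i - v_beta_i)^2 )."""
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (N_FEATURES,):
        raise ContractError("omega must have length 42")
    if np.any(omega < 0) or abs(omega.sum() - 1.0) > 1e-12:
        raise ParameterError("omega must be non-negative and sum to 1")
    diff = alpha.v - beta.v
    return float(np.sqrt(np.sum(omega * diff * diff)))


def feature_matrix(features: Sequence[FeatureVector]) -> pd.DataFrame:
    """Seeds x 42 table with seed_id index and a label column attached
    via ``DataFrame.attrs['labels']``."""
    ids = [f.seed_id or f"seed_{i}" for i, f in enumerate(features)]
    if len(set(ids)) != len(ids):
        raise ContractError("seed_ids are not unique")
    df = pd.DataFrame(
        np.vstack([f.v for f in features]),
        index=ids,
        columns=[f"v{i+1}" for i in range(N_FEATURES)],
    )
    df.attrs["labels"] = {i: f.label for i, f in zip(ids, features)}
    return df


def distance_matrix(
    features: Sequence[FeatureVector], omega: np.ndarray
) -> pd.DataFrame:
    """Symmetric zero-diagonal matrix of pairwise weighted distances."""
    if len(features) < 2:
        raise ContractError("need at least 2 seeds for a distance matrix")
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0) or abs(omega.sum() - 1.0) > 1e-12:
        raise ParameterError("omega must be non-negative and sum to 1")
    df = feature_matrix(features)
    scaled = df.to_numpy() * np.sqrt(omega)
    dense = squareform(pdist(scaled, metric="euclidean"))
    out = pd.DataFrame(dense, index=df.index, columns=df.index)
    out.attrs["labels"] = df.attrs["labels"]
    return out
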