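"""Microbial strain communities and the behavior-dependent resource landscape.

Each strain ``i`` is a point ``m_i`` in the D-dimensional unit ball (the
"microbiome-behavior space"): the closer the host's behavior coordinate sits
to ``m_i``, the more host-derived resources the strain obtains.  A strain may
additionally carry an *effect magnitude* ``d_i`` — its capacity to feed back
on host behavior — and pays a constant growth cost ``c_i`` for producing that
feedback.

The host's contribution to strain growth is

    r_i(b) = floor + max(0, 1 - beta * ||b - m_i||^alpha)

a monotonically decreasing function of the Euclidean distance between the
behavior coordinate ``b`` and the strain's features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "GrowthParams",
    "StrainSet",
    "sample_strains",
    "growth_rate",
    "two_strain_set",
]


@dataclass
class GrowthParams:
    """Parameters of the distance-to-resource growth function.

    ``alpha`` shapes how sharply resources fall off with distance, ``beta``
    scales the maximal distance penalty (and therefore the maximal advantage
    one strain can hold over another), and ``floor`` is the additive base
    growth rate every strain receives regardless of the host state.
    ``independent_rate`` is the constant growth rate given to strains flagged
    as behavior-independent (a robustness variant in which some strains simply
    ignore the host).
    """

    alpha: float = 3.0
    beta: float = 0.1
    floor: float = 0.1
    independent_rate: float = 0.6

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ParameterError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")


@dataclass
class StrainSet:
    """A community of N strains: features, effect magnitudes, costs, flags.

    Invariants: every feature row lies inside the unit ball; effect
    magnitudes and costs are non-negative and are zero for non-affecting
    strains.
    """

    features: np.ndarray
    effect_magnitude: np.ndarray
    cost: np.ndarray
    affecting: np.ndarray
    behavior_independent: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        n = self.features.shape[0]
        self.effect_magnitude = np.asarray(self.effect_magnitude, dtype=float).reshape(n)
        self.cost = np.asarray(self.cost, dtype=float).reshape(n)
        self.affecting = np.asarray(self.affecting, dtype=bool).reshape(n)
        if self.behavior_independent is None:
            self.behavior_independent = np.zeros(n, dtype=bool)
        self.behavior_independent = np.asarray(self.behavior_independent, dtype=bool).reshape(n)
        norms = np.linalg.norm(self.features, axis=1)
        if np.any(norms > 1 + 1e-9):
            raise ParameterError("strain features must lie inside the unit ball")
        if np.any(self.effect_magnitude < 0):
            raise ParameterError("effect magnitudes must be non-negative")
        if np.any(self.effect_magnitude[~self.affecting] != 0):
            raise ParameterError("non-affecting strains must have zero effect magnitude")
        if np.any(self.cost < 0):
            raise ParameterError("costs must be non-negative")
        if np.any(self.cost[~self.affecting] != 0):
            raise ParameterError("non-affecting strains must have zero cost")

    @property
    def n_strains(self) -> int:
        return self.features.shape[0]

    @property
    def dims(self) -> int:
        return self.features.shape[1]

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path, meta: dict | None = None) -> None:
        """Write one row per strain; sampling metadata goes to a JSON sidecar."""
        path = Path(path)
        cols = {f"m{k + 1}": self.features[:, k] for k in range(self.dims)}
        cols["effect_magnitude"] = self.effect_magnitude
        cols["cost"] = self.cost
        cols["affecting"] = self.affecting.astype(int)
        cols["behavior_independent"] = self.behavior_independent.astype(int)
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
        if meta is not None:
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2, sort_keys=True)
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StrainSet":
        df = pd.read_csv(path, sep="\t")
        mcols = sorted((c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
                       key=lambda c: int(c[1:]))
        return cls(
            features=df[mcols].to_numpy(float),
            effect_magnitude=df["effect_magnitude"].to_numpy(float),
            cost=df["cost"].to_numpy(float),
            affecting=df["affecting"].to_numpy(bool),
            behavior_independent=df["behavior_independent"].to_numpy(bool),
        )


def sample_strains(
    n: int,
    dims: int,
    mean_effect: float,
    affecting_fraction: float,
    rng: np.random.Generator,
    cost: float = 0.0,
    behavior_independent_fraction: float = 0.0,
) -> StrainSet:
    """Sample a synthetic strain community.

    Features are uniform over the volume of the ``dims``-dimensional unit
    ball; exactly ``round(n * affecting_fraction)`` strains are flagged as
    affecting, each receiving an effect magnitude drawn from an exponential
    distribution with mean ``mean_effect`` (and the constant growth cost
    ``cost``).  A ``behavior_independent_fraction`` of strains may be flagged
    to ignore the host state entirely.

    The draw order (directions, radii, affecting subset, magnitudes,
    behavior-independent subset) is fixed, so a seeded generator reproduces
    the community bit-for-bit.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if dims < 1:
        raise ParameterError(f"dims must be >= 1, got {dims}")
    if not 0 <= affecting_fraction <= 1:
        raise ParameterError(f"affecting_fraction must be in [0, 1], got {affecting_fraction}")
    if mean_effect < 0:
        raise ParameterError(f"mean_effect must be >= 0, got {mean_effect}")

    direction = rng.standard_normal((n, dims))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = rng.random(n) ** (1.0 / dims)
    features = direction * radius[:, None]

    k = int(round(n * affecting_fraction))
    affecting = np.zeros(n, dtype=bool)
    if k > 0:
        affecting[rng.choice(n, size=k, replace=False)] = True
    d = np.zeros(n)
    if k > 0 and mean_effect > 0:
        d[affecting] = rng.exponential(mean_effect, size=k)
    costs = np.where(affecting, float(cost), 0.0)

    b_indep = np.zeros(n, dtype=bool)
    kb = int(round(n * behavior_independent_fraction))
    if kb > 0:
        b_indep[rng.choice(n, size=kb, replace=False)] = True

    return StrainSet(features, d, costs, affecting, b_indep)


def growth_rate(
    behavior: np.ndarray,
    strains: StrainSet,
    params: GrowthParams | None = None,
) -> np.ndarray:
    """Host-derived growth rate of every strain at behavior coordinate ``b``.

    Returns ``floor + max(0, 1 - beta * dist^alpha)`` per strain; strains
    flagged behavior-independent get the constant ``independent_rate``.
    """
    params = params or GrowthParams()
    behavior = np.asarray(behavior, dtype=float).reshape(-1)
    if behavior.shape[0] != strains.dims:
        raise ParameterError(
            f"behavior has {behavior.shape[0]} dims, strains have {strains.dims}"
        )
    if not np.all(np.isfinite(behavior)):
        raise ParameterError("behavior coordinates must be finite")
    dist = np.linalg.norm(strains.features - behavior, axis=1)
    r = params.floor + np.maximum(0.0, 1.0 - params.beta * dist**params.alpha)
    return np.where(strains.behavior_independent, params.independent_rate, r)


def two_strain_set(effect: float, cost: float, dims: int = 2) -> StrainSet:
    """The canonical two-strain community: an affecting strain at the origin
    and a non-affecting competitor at (1, 0, ...)."""
    features = np.zeros((2, dims))
    features[1, 0] = 1.0
    return StrainSet(
        features=features,
        effect_magnitude=[effect, 0.0],
        cost=[cost, 0.0],
        affecting=[True, False],
    )
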