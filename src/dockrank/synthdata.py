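"""Seeded generators for benchmark-shaped synthetic data.

Two families of fixtures:

* correlated noisy scorer ensembles around a latent true affinity — the
  statistical structure behind the complementary-versus-redundant-views
  argument for consensus scoring.  Each item t carries a latent affinity
  u_t ~ N(0, 1); scorer k emits

      s_k(t) = -alpha_k * u_t + beta_g(k) * eta_g(t) + sigma_k * eps_kt,

  oriented lower-is-better like a docking energy.  alpha_k is the scorer's
  signal weight, eta_g is noise shared within a redundancy group of
  scorers (what makes two scorers near-duplicates), and eps is private
  noise.  The reference ranks items by u descending and carries an
  EC50-like activity 10^(-u) so lower activity = more potent = rank 1.

* pharmacophore fixture libraries of abstract point-set molecules with
  planted hits and decoys, giving the screening engine inputs with known
  ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pharmacophore import (
    FEATURE_TYPES,
    ModelError,
    PharmacophoreModel,
    PointSetMolecule,
    TypedFeaturePoint,
)
from .rank_core import Direction, ScoreTable
from .evaluate import ReferenceRank

__all__ = [
    "SyntheticEnsembleSpec",
    "generate_ensemble",
    "complementary_plus_redundant_spec",
    "generate_screen_fixtures",
]


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Generative description of a correlated noisy scorer ensemble.

    ``groups`` maps a group label to the scorer indices sharing a noise
    component with weight ``betas[label]``; ungrouped scorers have purely
    private noise.
    """

    n_items: int
    n_scorers: int
    seed: int
    alphas: tuple[float, ...] | None = None  # default 0.5 each
    sigmas: tuple[float, ...] | None = None  # default 1.0 each
    groups: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    betas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_items < 2 or self.n_scorers < 1:
            raise ValueError("need n_items >= 2 and n_scorers >= 1")
        alphas = self.alphas or tuple([0.5] * self.n_scorers)
        sigmas = self.sigmas or tuple([1.0] * self.n_scorers)
        if len(alphas) != self.n_scorers or len(sigmas) != self.n_scorers:
            raise ValueError("alphas/sigmas length must equal n_scorers")
        if any(a < 0 for a in alphas) or not any(a > 0 for a in alphas):
            raise ValueError(
                "signal weights must be >= 0 with at least one > 0 "
                "(a meaningful reference needs signal)"
            )
        if any(s <= 0 for s in sigmas):
            raise ValueError("private noise sd must be > 0")
        seen: set[int] = set()
        for g, members in self.groups.items():
            if g not in self.betas or self.betas[g] < 0:
                raise ValueError(f"group {g!r} needs a shared-noise weight >= 0")
            for m in members:
                if not (0 <= m < self.n_scorers) or m in seen:
                    raise ValueError(f"bad or repeated scorer index {m} in groups")
                seen.add(m)
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "sigmas", sigmas)
        object.__setattr__(
            self, "groups", {g: tuple(m) for g, m in self.groups.items()}
        )
        object.__setattr__(self, "betas", dict(self.betas))


def _scorer_names(n: int) -> list[str]:
    # A, B, C ... then S27, S28 ... beyond the alphabet
    names = []
    for i in range(n):
        names.append(chr(ord("A") + i) if i < 26 else f"S{i + 1}")
    return names


def generate_ensemble(
    spec: SyntheticEnsembleSpec,
) -> tuple[ScoreTable, ReferenceRank, np.ndarray]:
    """Draw one ensemble: (score table, reference ranking, latent u).

    Fully reproducible: the random stream is consumed in a fixed order
    (latent u, then group noises in sorted label order, then per-scorer
    private noise in scorer order), so the same spec gives byte-identical
    tables.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_items, spec.n_scorers
    u = rng.standard_normal(n)
    eta = {g: rng.standard_normal(n) for g in sorted(spec.groups)}
    group_of = {
        k: g for g, members in spec.groups.items() for k in members
    }
    scores = np.empty((n, m))
    for k in range(m):
        eps = rng.standard_normal(n)
        shared = 0.0
        if k in group_of:
            g = group_of[k]
            shared = spec.betas[g] * eta[g]
        scores[:, k] = -spec.alphas[k] * u + shared + spec.sigmas[k] * eps

    width = max(4, len(str(n)))
    items = [f"C{i + 1:0{width}d}" for i in range(n)]
    names = _scorer_names(m)
    table = ScoreTable(
        values=pd.DataFrame(scores, index=items, columns=names),
        directions={c: Direction.LOWER for c in names},
    )
    # EC50-like activity: more affine (larger u) -> smaller value -> rank 1
    activities = {t: float(10.0 ** (-u[i])) for i, t in enumerate(items)}
    ref = ReferenceRank.from_activities(activities, name="reference")
    return table, ref, u


def complementary_plus_redundant_spec(
    seed: int, n_items: int = 107
) -> SyntheticEnsembleSpec:
    """The canonical four-scorer study condition: three complementary
    scorers (equal signal 0.5, independent unit noise) plus a redundant
    near-duplicate of the third, over a 107-compound universe (the scale
    of the EC50-ranked benchmark set).

    Scorers C and D share a strong common noise component (beta = 0.9)
    with small private noise (sd 0.45), so their total noise level matches
    A and B (~1.0) while their errors are highly correlated — the
    redundant pair a good consensus subset should avoid double-counting.
    The per-scorer signal-to-noise (0.5 against unit noise, a rank
    correlation of ~0.45 with the latent affinity) emulates the weak
    score-affinity correlation typical of individual docking scoring
    functions.
    """
    return SyntheticEnsembleSpec(
        n_items=n_items,
        n_scorers=4,
        seed=seed,
        alphas=(0.5, 0.5, 0.5, 0.5),
        sigmas=(1.0, 1.0, 0.45, 0.45),
        groups={"cd": (2, 3)},
        betas={"cd": 0.9},
    )


# ---------------------------------------------------------------------------
# pharmacophore fixtures
# ---------------------------------------------------------------------------

_DECOY_CLASSES = ("wrong_type", "displaced", "excluded_volume")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _rigidly_transform(
    points: Sequence[TypedFeaturePoint],
    heavy: np.ndarray,
    rng: np.random.Generator,
) -> tuple[tuple[TypedFeaturePoint, ...], np.ndarray]:
    R = _random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)
    moved = tuple(
        TypedFeaturePoint(
            type=p.type, position=p.position @ R.T + t, source_atoms=p.source_atoms
        )
        for p in points
    )
    return moved, heavy @ R.T + t


def _check_feasible(model: PharmacophoreModel) -> None:
    for fi, f in enumerate(model.features):
        for vol in model.excluded_volumes:
            gap = np.linalg.norm(f.center - vol.center)
            if gap <= vol.radius + f.tolerance:
                raise ModelError(
                    f"impossible geometry: feature {fi} tolerance sphere "
                    f"overlaps an excluded volume; planted hits cannot avoid it"
                )


def _incompatible_type(feature) -> str | None:
    for ftype in FEATURE_TYPES:
        if not feature.accepts(ftype):
            return ftype
    return None


def generate_screen_fixtures(
    n_hits: int,
    n_decoys: int,
    model: PharmacophoreModel,
    seed: int,
) -> tuple[list[PointSetMolecule], list[dict]]:
    """Build a labelled point-set library of planted hits and decoys.

    Hits carry one type-compatible point per model feature, placed inside
    half the tolerance radius of its center, then rigidly transformed to a
    random pose.  Decoys cycle through three failure classes: a point of
    an incompatible type, a point displaced far outside the model's reach,
    and a valid geometry plus one heavy atom planted at an excluded-volume
    center (those hit-points sit exactly on the feature centers so the
    recovered superposition is exact).  Returns ``(molecules, labels)``
    with one label dict per molecule: ``{"id", "is_hit", "decoy_class"}``.
    """
    _check_feasible(model)
    rng = np.random.default_rng(seed)
    k = len(model.features)
    molecules: list[PointSetMolecule] = []
    labels: list[dict] = []

    # Jitter cap guaranteeing acceptance: the Kabsch fit's total squared
    # residual is at most the planted jitter's, so capping each offset at
    # 0.5 * min_tol / sqrt(k) bounds every aligned point within 0.5*min_tol
    # of its center, inside every tolerance sphere.
    min_tol = min(f.tolerance for f in model.features)
    jitter_cap = 0.5 * min_tol / np.sqrt(k)

    def base_points(jitter: bool) -> list[TypedFeaturePoint]:
        pts = []
        for f in model.features:
            ftype = sorted(f.allowed_types)[
                rng.integers(len(f.allowed_types))
            ]
            if jitter:
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                offset = direction * rng.uniform(0.0, jitter_cap)
            else:
                offset = np.zeros(3)
            pts.append(TypedFeaturePoint(type=ftype, position=f.center + offset))
        return pts

    centers = model.centers
    spread = np.linalg.norm(
        centers - centers.mean(axis=0), axis=1
    ).max()
    max_tol = max(f.tolerance for f in model.features)

    for h in range(n_hits):
        pts = base_points(jitter=True)
        heavy = np.stack([p.position for p in pts])
        moved, heavy = _rigidly_transform(pts, heavy, rng)
        mol = PointSetMolecule(id=f"hit{h + 1:03d}", points=moved,
                               heavy_coords=heavy)
        molecules.append(mol)
        labels.append({"id": mol.id, "is_hit": True, "decoy_class": None})

    for d in range(n_decoys):
        cls = _DECOY_CLASSES[d % len(_DECOY_CLASSES)]
        if cls == "wrong_type":
            pts = base_points(jitter=True)
            fi = int(rng.integers(k))
            bad = _incompatible_type(model.features[fi])
            if bad is None:  # feature accepts every type; fall back
                cls = "displaced"
            else:
                pts[fi] = TypedFeaturePoint(
                    type=bad, position=pts[fi].position
                )
        if cls == "displaced":
            pts = base_points(jitter=True)
            fi = int(rng.integers(k))
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            far = centers.mean(axis=0) + direction * (
                2.0 * spread + 4.0 * max_tol + 10.0
            )
            pts[fi] = TypedFeaturePoint(type=pts[fi].type, position=far)
        if cls == "excluded_volume":
            if not model.excluded_volumes:
                raise ModelError(
                    "excluded-volume decoys need a model with excluded volumes"
                )
            pts = base_points(jitter=False)  # exact centers -> exact recovery
            vol = model.excluded_volumes[
                int(rng.integers(len(model.excluded_volumes)))
            ]
            extra = vol.center.copy()
            heavy = np.vstack([np.stack([p.position for p in pts]), extra])
            moved, heavy = _rigidly_transform(pts, heavy, rng)
            mol = PointSetMolecule(
                id=f"decoy{d + 1:03d}", points=moved, heavy_coords=heavy
            )
            molecules.append(mol)
            labels.append(
                {"id": mol.id, "is_hit": False, "decoy_class": cls}
            )
            continue
        heavy = np.stack([p.position for p in pts])
        moved, heavy = _rigidly_transform(pts, heavy, rng)
        mol = PointSetMolecule(
            id=f"decoy{d + 1:03d}", points=moved, heavy_coords=heavy
        )
        molecules.append(mol)
        labels.append({"id": mol.id, "is_hit": False, "decoy_class": cls})

    return molecules, labels
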