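"""Generic ligand-based 3D pharmacophore screening.

A pharmacophore model is a set of typed feature spheres (hydrophobe,
H-bond acceptor/donor and their projected variants, aromatic ring) plus
excluded-volume spheres marking regions the receptor occupies.  A
conformer matches when an injective assignment of its detected feature
points to type-compatible model features exists such that, after
least-squares rigid superposition of the assigned points onto the model
centers, every assigned point lies inside its feature's tolerance sphere
and no heavy atom falls strictly inside any excluded volume.

The matcher is pose-independent by construction: superposition removes the
conformer's frame, so hit decisions are invariant under rigid-body motion
of the input coordinates.

Feature typing is rule-based (SMARTS patterns per type, overridable).  The
``Acc2``/``Don2`` labels denote projected/extended acceptor-donor variants;
chemically they map onto the same substructure patterns as ``Acc``/``Don``
and are kept distinct only for model-type compatibility, where a model
feature allowing ``Acc2`` also accepts a plain ``Acc`` point (and likewise
for ``Don2``/``Don``).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_TYPES",
    "PharmacophoreFeature",
    "ExclusionSphere",
    "PharmacophoreModel",
    "TypedFeaturePoint",
    "PointSetMolecule",
    "ScreenResult",
    "DEFAULT_SMARTS",
    "detect_features",
    "match_pharmacophore",
    "screen_library",
    "load_model",
    "save_model",
    "load_sdf",
    "mol_from_smiles",
]

FEATURE_TYPES = ("Hyd", "Acc", "Acc2", "Don", "Don2", "ARO")

# model type -> point types it accepts
_COMPAT: dict[str, frozenset[str]] = {
    "Hyd": frozenset({"Hyd"}),
    "Acc": frozenset({"Acc"}),
    "Acc2": frozenset({"Acc", "Acc2"}),
    "Don": frozenset({"Don"}),
    "Don2": frozenset({"Don", "Don2"}),
    "ARO": frozenset({"ARO"}),
}

MODEL_SCHEMA_VERSION = 1


class ModelError(ValueError):
    """Invalid pharmacophore model definition."""


def _vec3(x: Sequence[float], what: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,) or not np.isfinite(v).all():
        raise ModelError(f"{what} must be a finite 3-vector, got {x!r}")
    return v


@dataclass(frozen=True)
class PharmacophoreFeature:
    """A typed feature sphere: any of *allowed_types* within *tolerance* Å."""

    allowed_types: frozenset[str]
    center: np.ndarray
    tolerance: float

    def __post_init__(self) -> None:
        types = frozenset(self.allowed_types)
        bad = types - set(FEATURE_TYPES)
        if bad or not types:
            raise ModelError(
                f"feature types must be a non-empty subset of {FEATURE_TYPES}, "
                f"got {sorted(self.allowed_types)}"
            )
        object.__setattr__(self, "allowed_types", types)
        object.__setattr__(self, "center", _vec3(self.center, "feature center"))
        if not self.tolerance > 0:
            raise ModelError("feature tolerance must be > 0")

    def accepts(self, point_type: str) -> bool:
        return any(point_type in _COMPAT[t] for t in self.allowed_types)


@dataclass(frozen=True)
class ExclusionSphere:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _vec3(self.center, "volume center"))
        if not self.radius > 0:
            raise ModelError("excluded-volume radius must be > 0")


@dataclass(frozen=True)
class PharmacophoreModel:
    """Feature spheres plus excluded volumes and a partial-match threshold.

    ``min_features_required`` defaults to *all* features (a molecule must
    fit the complete template); at least 3 points are always required for
    a meaningful rigid 3D superposition.
    """

    features: tuple[PharmacophoreFeature, ...]
    excluded_volumes: tuple[ExclusionSphere, ...] = ()
    min_features_required: int | None = None
    name: str = "pharmacophore"

    def __post_init__(self) -> None:
        feats = tuple(self.features)
        if not feats:
            raise ModelError("model needs at least one feature")
        req = self.min_features_required
        if req is None:
            req = len(feats)
        if req < 3:
            raise ModelError(
                "min_features_required must be >= 3 (3-point minimum for a "
                "meaningful 3D match)"
            )
        if req > len(feats):
            raise ModelError("min_features_required exceeds feature count")
        object.__setattr__(self, "features", feats)
        object.__setattr__(
            self, "excluded_volumes", tuple(self.excluded_volumes)
        )
        object.__setattr__(self, "min_features_required", req)

    @property
    def centers(self) -> np.ndarray:
        return np.stack([f.center for f in self.features])


def save_model(model: PharmacophoreModel, path: str | Path) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "name": model.name,
        "features": [
            {
                "types": sorted(f.allowed_types),
                "center": [round(float(c), 6) for c in f.center],
                "tolerance": float(f.tolerance),
            }
            for f in model.features
        ],
        "excluded_volumes": [
            {
                "center": [round(float(c), 6) for c in v.center],
                "radius": float(v.radius),
            }
            for v in model.excluded_volumes
        ],
        "min_features_required": model.min_features_required,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model(path: str | Path) -> PharmacophoreModel:
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version", 1)
    if version != MODEL_SCHEMA_VERSION:
        raise ModelError(f"unsupported model schema version {version}")
    feats = tuple(
        PharmacophoreFeature(
            allowed_types=frozenset(f["types"]),
            center=np.asarray(f["center"], dtype=float),
            tolerance=float(f["tolerance"]),
        )
        for f in doc["features"]
    )
    vols = tuple(
        ExclusionSphere(
            center=np.asarray(v["center"], dtype=float), radius=float(v["radius"])
        )
        for v in doc.get("excluded_volumes", [])
    )
    return PharmacophoreModel(
        features=feats,
        excluded_volumes=vols,
        min_features_required=doc.get("min_features_required"),
        name=doc.get("name", Path(path).stem),
    )


@dataclass(frozen=True)
class TypedFeaturePoint:
    """A detected chemical feature: type label, 3D position, source atoms.

    Aromatic-ring points sit at the ring centroid; single-atom features sit
    on the atom itself.
    """

    type: str
    position: np.ndarray
    source_atoms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ModelError(f"unknown feature type {self.type!r}")
        object.__setattr__(self, "position", _vec3(self.position, "point"))
        object.__setattr__(self, "source_atoms", tuple(self.source_atoms))


@dataclass(frozen=True)
class PointSetMolecule:
    """An abstract 'molecule': pre-typed feature points plus heavy-atom
    coordinates, bypassing chemistry for matcher tests and fixtures."""

    id: str
    points: tuple[TypedFeaturePoint, ...]
    heavy_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if self.heavy_coords is None:
            coords = np.stack([p.position for p in self.points]) if self.points \
                else np.zeros((0, 3))
            object.__setattr__(self, "heavy_coords", coords)
        else:
            coords = np.asarray(self.heavy_coords, dtype=float).reshape(-1, 3)
            object.__setattr__(self, "heavy_coords", coords)


@dataclass(frozen=True)
class ScreenResult:
    molecule_id: str
    hit: bool
    best_match: Mapping[int, int] = field(default_factory=dict)
    matched_count: int = 0
    rmsd: float | None = None
    conformer_index: int | None = None


# ---------------------------------------------------------------------------
# feature detection
# ---------------------------------------------------------------------------

# Minimal, documented substructure rules.  Acc2/Don2 share the Acc/Don
# chemistry (projected variants); they are produced only by explicit
# point-set inputs or custom rules.
DEFAULT_SMARTS: dict[str, tuple[str, ...]] = {
    "Don": (
        "[$([O;H1;+0]),$([N;H1,H2,H3;+0]),$([n;H1])]",
    ),
    "Acc": (
        "[$([O;H1;+0]),$([O;H0;v2;+0]),$([O;-]),$([N;H0;v3;+0;!$(N=*)]),$([n;H0;+0;X2])]",
    ),
    "Hyd": (
        "[#6;+0;!$([#6]~[#7,#8,#9,#15,#16,#17,#35,#53])]",
    ),
    # ARO handled geometrically from aromatic rings, not by SMARTS
}


def _rdkit():
    from rdkit import Chem  # deferred: keeps matcher importable without 3D deps

    return Chem


def detect_features(
    mol,
    rules: Mapping[str, Sequence[str]] | None = None,
    conf_id: int = 0,
) -> list[TypedFeaturePoint]:
    """Detect typed feature points on a conformer.

    *mol* is either a :class:`PointSetMolecule` (its declared points are
    returned as-is) or an RDKit molecule with explicit 3D coordinates.
    """
    if isinstance(mol, PointSetMolecule):
        return list(mol.points)
    Chem = _rdkit()
    if mol.GetNumConformers() == 0:
        raise ModelError(
            "molecule has no 3D conformer; generate conformers first "
            "(e.g. mol_from_smiles with n_conformers > 0)"
        )
    conf = mol.GetConformer(conf_id)
    coords = np.asarray(conf.GetPositions(), dtype=float)
    rules = dict(DEFAULT_SMARTS if rules is None else rules)
    points: list[TypedFeaturePoint] = []
    for ftype in sorted(rules):
        for smarts in rules[ftype]:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ModelError(f"invalid SMARTS for {ftype!r}: {smarts!r}")
            for match in mol.GetSubstructMatches(patt):
                for atom_idx in match:
                    points.append(
                        TypedFeaturePoint(
                            type=ftype,
                            position=coords[atom_idx],
                            source_atoms=(atom_idx,),
                        )
                    )
    # aromatic rings -> centroid points
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            points.append(
                TypedFeaturePoint(
                    type="ARO",
                    position=coords[list(ring)].mean(axis=0),
                    source_atoms=tuple(sorted(ring)),
                )
            )
    # deduplicate identical (type, source) pairs from overlapping patterns
    seen: set[tuple[str, tuple[int, ...]]] = set()
    unique: list[TypedFeaturePoint] = []
    for p in points:
        key = (p.type, p.source_atoms)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique


# ---------------------------------------------------------------------------
# rigid superposition and matching
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of points P onto points Q.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation such that
    ``P @ R.T + t`` best fits Q.  Reflections are excluded (rigid body
    only) via the usual determinant sign correction.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    aligned = P @ R.T + t
    rmsd = float(np.sqrt(((aligned - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def _violates_excluded_volume(
    coords: np.ndarray, model: PharmacophoreModel, eps: float = 1e-9
) -> bool:
    """True if any heavy atom lies strictly inside any excluded volume."""
    if not model.excluded_volumes or coords.size == 0:
        return False
    for vol in model.excluded_volumes:
        d2 = ((coords - vol.center) ** 2).sum(axis=1)
        if (d2 < (vol.radius - eps) ** 2).any():
            return True
    return False


def _assignments(
    feature_idx: Sequence[int],
    candidates: Mapping[int, Sequence[int]],
    d_model: np.ndarray,
    d_points: np.ndarray,
    tol: Sequence[float],
) -> Iterable[tuple[int, ...]]:
    """Backtracking enumeration of injective, distance-compatible assignments.

    Yields tuples aligned with *feature_idx*: position j holds the point
    index assigned to feature ``feature_idx[j]``.  Pairs are pruned when
    |d_points - d_model| exceeds the sum of the two feature tolerances.
    """
    order = sorted(feature_idx, key=lambda f: len(candidates[f]))
    slot_of = {f: i for i, f in enumerate(feature_idx)}
    assignment: dict[int, int] = {}

    def backtrack(k: int):
        if k == len(order):
            out = [0] * len(feature_idx)
            for f, p in assignment.items():
                out[slot_of[f]] = p
            yield tuple(out)
            return
        f = order[k]
        for p in candidates[f]:
            if p in assignment.values():
                continue
            ok = True
            for f2, p2 in assignment.items():
                limit = tol[f] + tol[f2]
                if abs(d_points[p, p2] - d_model[f, f2]) > limit:
                    ok = False
                    break
            if ok:
                assignment[f] = p
                yield from backtrack(k + 1)
                del assignment[f]

    yield from backtrack(0)


def match_pharmacophore(
    points: Sequence[TypedFeaturePoint],
    model: PharmacophoreModel,
    heavy_coords: np.ndarray | None = None,
    molecule_id: str = "",
    conformer_index: int | None = None,
) -> ScreenResult:
    """Match detected feature points against a pharmacophore model.

    Searches injective assignments of points to type-compatible model
    features, largest assignment size first (down to
    ``min_features_required``), pruning by inter-feature distance
    compatibility, then superposes the assigned points onto the model
    centers (Kabsch).  An assignment is accepted when every assigned point
    lands inside its feature's tolerance sphere and no heavy atom sits
    strictly inside an excluded volume.  Among accepting assignments the
    one with most features, then lowest RMSD, wins.  No match is reported
    as ``hit=False``, never as an error.
    """
    points = list(points)
    if not points:
        return ScreenResult(molecule_id=molecule_id, hit=False)
    if heavy_coords is None:
        heavy_coords = np.stack([p.position for p in points])
    heavy_coords = np.asarray(heavy_coords, dtype=float).reshape(-1, 3)

    k = len(model.features)
    candidates = {
        fi: [pi for pi, p in enumerate(points) if feat.accepts(p.type)]
        for fi, feat in enumerate(model.features)
    }
    pts = np.stack([p.position for p in points])
    centers = model.centers
    d_model = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    d_points = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    tol = [f.tolerance for f in model.features]

    for size in range(k, model.min_features_required - 1, -1):
        best: tuple[float, dict[int, int]] | None = None
        for subset in itertools.combinations(range(k), size):
            if any(not candidates[f] for f in subset):
                continue
            for assign in _assignments(subset, candidates, d_model, d_points, tol):
                P = pts[list(assign)]
                Q = centers[list(subset)]
                R, t, rmsd = kabsch(P, Q)
                aligned = P @ R.T + t
                dists = np.linalg.norm(aligned - Q, axis=1)
                if any(
                    d > model.features[f].tolerance + 1e-9
                    for d, f in zip(dists, subset)
                ):
                    continue
                if _violates_excluded_volume(heavy_coords @ R.T + t, model):
                    continue
                if best is None or rmsd < best[0] - 1e-12:
                    best = (rmsd, dict(zip(subset, assign)))
        if best is not None:
            rmsd, mapping = best
            return ScreenResult(
                molecule_id=molecule_id,
                hit=True,
                best_match=mapping,
                matched_count=size,
                rmsd=rmsd,
                conformer_index=conformer_index,
            )
    return ScreenResult(molecule_id=molecule_id, hit=False,
                        conformer_index=conformer_index)


# ---------------------------------------------------------------------------
# library screening
# ---------------------------------------------------------------------------

def mol_from_smiles(smiles: str, n_conformers: int = 20, seed: int = 2023):
    """Parse SMILES, add hydrogens, embed ETKDG conformers with a fixed seed."""
    Chem = _rdkit()
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
    return Chem.RemoveHs(mol)


def load_sdf(path: str | Path) -> list[tuple[str, object]]:
    """Read an SDF into ``(id, rdkit Mol)`` pairs; unparseable records are
    logged and skipped (the caller sees only the parsed ones)."""
    Chem = _rdkit()
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    out: list[tuple[str, object]] = []
    skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        out.append((name or f"mol{i + 1}", mol))
    if skipped:
        logger.warning("%s: skipped %d unparseable SDF records", path, skipped)
    return out


def _heavy_coords_rdkit(mol, conf_id: int) -> np.ndarray:
    conf = mol.GetConformer(conf_id)
    coords = np.asarray(conf.GetPositions(), dtype=float)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    return coords[heavy]


def screen_library(
    molecules: Sequence,
    model: PharmacophoreModel,
    rules: Mapping[str, Sequence[str]] | None = None,
    n_conformers: int = 20,
    seed: int = 2023,
) -> list[ScreenResult]:
    """Screen a library against a model; a molecule is a hit if any of its
    conformers matches.

    *molecules* may mix :class:`PointSetMolecule` objects, RDKit molecules
    (3D conformers used as-is), ``(id, mol)`` pairs, and SMILES strings
    (conformers generated internally with the fixed *seed*).  Results are
    returned in input order; parse failures are logged skips recorded as
    non-hits.
    """
    logger.info(
        "screening %d molecules against %s (min_features=%d, "
        "n_conformers=%d, seed=%d)",
        len(molecules), model.name, model.min_features_required,
        n_conformers, seed,
    )
    results: list[ScreenResult] = []
    for i, entry in enumerate(molecules):
        mol_id, mol = _normalize_entry(entry, i, n_conformers, seed)
        if mol is None:
            results.append(ScreenResult(molecule_id=mol_id, hit=False))
            continue
        if isinstance(mol, PointSetMolecule):
            res = match_pharmacophore(
                detect_features(mol), model,
                heavy_coords=mol.heavy_coords, molecule_id=mol_id,
                conformer_index=0,
            )
            results.append(res)
            continue
        best: ScreenResult | None = None
        n_conf = mol.GetNumConformers()
        for conf_id in range(n_conf):
            pts = detect_features(mol, rules=rules, conf_id=conf_id)
            res = match_pharmacophore(
                pts, model,
                heavy_coords=_heavy_coords_rdkit(mol, conf_id),
                molecule_id=mol_id, conformer_index=conf_id,
            )
            if res.hit and (
                best is None
                or not best.hit
                or (res.matched_count, -res.rmsd)
                > (best.matched_count, -best.rmsd)
            ):
                best = res
        if best is None:
            best = ScreenResult(molecule_id=mol_id, hit=False)
        results.append(best)
    n_hits = sum(r.hit for r in results)
    logger.info("screen complete: %d/%d hits", n_hits, len(results))
    return results


def _normalize_entry(entry, index: int, n_conformers: int, seed: int):
    if isinstance(entry, PointSetMolecule):
        return entry.id, entry
    if isinstance(entry, str):
        mol = mol_from_smiles(entry, n_conformers=n_conformers, seed=seed)
        if mol is None or mol.GetNumConformers() == 0:
            logger.warning("skipping unparseable/unembeddable SMILES %r", entry)
            return f"mol{index + 1}", None
        return entry, mol
    if isinstance(entry, tuple) and len(entry) == 2:
        return str(entry[0]), entry[1]
    # assume rdkit Mol
    mol = entry
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{index + 1}"
    return name, mol
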