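"""Pharmacophore model validation, feature detection and matching."""

import itertools

import numpy as np
import pytest

from dockrank import (
    ExclusionSphere,
    PharmacophoreFeature,
    PharmacophoreModel,
    PointSetMolecule,
    TypedFeaturePoint,
    detect_features,
    load_model,
    match_pharmacophore,
    save_model,
    screen_library,
)
from dockrank.datasets import pxr_template_model
from dockrank.pharmacophore import ModelError, kabsch
from dockrank.synthdata import generate_screen_fixtures


def small_model(min_required=None, volumes=()):
    feats = (
        PharmacophoreFeature(frozenset({"Don"}), np.array([0.0, 0.0, 0.0]), 1.0),
        PharmacophoreFeature(frozenset({"Acc"}), np.array([4.0, 0.5, 0.0]), 1.0),
        PharmacophoreFeature(frozenset({"Hyd"}), np.array([1.5, 3.5, 1.0]), 1.0),
        PharmacophoreFeature(frozenset({"ARO"}), np.array([3.0, 2.0, 4.0]), 1.0),
    )
    return PharmacophoreModel(
        features=feats,
        excluded_volumes=tuple(volumes),
        min_features_required=min_required,
    )


def exact_points(model, types=None):
    return [
        TypedFeaturePoint(
            type=(types[i] if types else sorted(f.allowed_types)[0]),
            position=f.center,
        )
        for i, f in enumerate(model.features)
    ]


def rigid(points, R, t):
    return [
        TypedFeaturePoint(type=p.type, position=p.position @ R.T + t)
        for p in points
    ]


def random_rotation(rng):
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


class TestModel:
    def test_min_features_below_three_rejected(self):
        with pytest.raises(ModelError, match="3"):
            small_model(min_required=2)

    def test_json_roundtrip(self, tmp_path):
        model = small_model(volumes=[ExclusionSphere(np.array([9.0, 9, 9]), 1.2)])
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert len(back.features) == 4
        assert back.min_features_required == 4
        np.testing.assert_allclose(back.excluded_volumes[0].center, [9, 9, 9])

    def test_bundled_template_has_published_type_signature(self):
        model = pxr_template_model()
        sigs = [sorted(f.allowed_types) for f in model.features]
        assert sigs == [
            ["Acc", "Hyd"],
            ["Acc", "Acc2", "Don2"],
            ["Acc2", "Hyd"],
            ["Acc", "Hyd"],
            ["ARO", "Hyd"],
        ]
        assert len(model.excluded_volumes) == 8


class TestKabsch:
    def test_recovers_random_rigid_motion(self, rng):
        P = rng.random((6, 3)) * 5
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        Rhat, that, rmsd = kabsch(P @ R.T + t, P)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose((P @ R.T + t) @ Rhat.T + that, P, atol=1e-9)

    def test_rejects_reflections(self):
        # mirrored tetrahedron cannot be superposed by a proper rotation
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        Q = P.copy()
        Q[:, 2] *= -1
        _, _, rmsd = kabsch(P, Q)
        assert rmsd > 0.1


class TestMatching:
    def test_exact_coincidence_is_a_zero_rmsd_full_hit(self):
        model = small_model()
        res = match_pharmacophore(exact_points(model), model)
        assert res.hit
        assert res.matched_count == 4
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_heavy_atom_in_excluded_volume_rejects(self):
        vol = ExclusionSphere(np.array([2.0, 1.0, 1.0]), 1.0)
        model = small_model(volumes=[vol])
        pts = exact_points(model)
        heavy = np.vstack(
            [np.stack([p.position for p in pts]), vol.center]
        )
        res = match_pharmacophore(pts, model, heavy_coords=heavy)
        assert not res.hit

    def test_wrong_type_cannot_fill_a_feature(self):
        model = small_model()
        pts = exact_points(model)
        pts[0] = TypedFeaturePoint(type="Hyd", position=pts[0].position)
        assert not match_pharmacophore(pts, model).hit

    def test_hit_invariant_under_30_random_rigid_motions(self, rng):
        model = small_model()
        base = exact_points(model)
        for _ in range(30):
            moved = rigid(base, random_rotation(rng), rng.uniform(-15, 15, 3))
            res = match_pharmacophore(moved, model)
            assert res.hit and res.matched_count == 4

    def test_hit_invariant_under_point_reordering(self, rng):
        model = small_model()
        pts = exact_points(model)
        for _ in range(5):
            perm = rng.permutation(len(pts))
            assert match_pharmacophore([pts[i] for i in perm], model).hit

    def test_projected_types_accept_plain_donors_acceptors(self):
        feats = (
            PharmacophoreFeature(frozenset({"Acc2"}), np.zeros(3), 1.0),
            PharmacophoreFeature(frozenset({"Don2"}), np.array([4.0, 0, 0]), 1.0),
            PharmacophoreFeature(frozenset({"Hyd"}), np.array([2.0, 3, 0.5]), 1.0),
        )
        model = PharmacophoreModel(features=feats)
        pts = [
            TypedFeaturePoint("Acc", feats[0].center),
            TypedFeaturePoint("Don", feats[1].center),
            TypedFeaturePoint("Hyd", feats[2].center),
        ]
        assert match_pharmacophore(pts, model).hit

    def test_raising_min_features_never_creates_hits(self, rng):
        model3 = small_model(min_required=3)
        model4 = small_model(min_required=4)
        for seed in range(10):
            r = np.random.default_rng(seed)
            pts = [
                TypedFeaturePoint(
                    type=r.choice(["Don", "Acc", "Hyd", "ARO"]),
                    position=r.uniform(-1, 5, 3),
                )
                for _ in range(5)
            ]
            strict = match_pharmacophore(pts, model4).hit
            loose = match_pharmacophore(pts, model3).hit
            assert not (strict and not loose)

    def test_shrinking_tolerance_never_creates_hits(self, rng):
        base = small_model()
        tight = PharmacophoreModel(
            features=tuple(
                PharmacophoreFeature(f.allowed_types, f.center, f.tolerance / 3)
                for f in base.features
            )
        )
        for seed in range(10):
            r = np.random.default_rng(seed)
            jitter = r.uniform(-0.9, 0.9, (4, 3))
            pts = [
                TypedFeaturePoint(
                    type=sorted(f.allowed_types)[0], position=f.center + j
                )
                for f, j in zip(base.features, jitter)
            ]
            assert not (
                match_pharmacophore(pts, tight).hit
                and not match_pharmacophore(pts, base).hit
            )

    def test_growing_excluded_volume_never_creates_hits(self, rng):
        center = np.array([2.0, 1.0, 1.0])
        small_v = small_model(volumes=[ExclusionSphere(center, 0.5)])
        big_v = small_model(volumes=[ExclusionSphere(center, 2.5)])
        for seed in range(10):
            r = np.random.default_rng(seed)
            pts = exact_points(small_v)
            heavy = np.vstack(
                [np.stack([p.position for p in pts]), r.uniform(0, 3, 3)]
            )
            hit_small = match_pharmacophore(pts, small_v, heavy_coords=heavy).hit
            hit_big = match_pharmacophore(pts, big_v, heavy_coords=heavy).hit
            assert not (hit_big and not hit_small)

    def test_agrees_with_exhaustive_assignment_oracle(self, rng):
        """Pruned backtracking equals brute-force over all type-compatible
        injective assignments on <=6-feature models."""
        model = small_model(min_required=4)

        def oracle(points):
            pts = np.stack([p.position for p in points])
            for assign in itertools.permutations(range(len(points)), 4):
                if not all(
                    model.features[f].accepts(points[p].type)
                    for f, p in enumerate(assign)
                ):
                    continue
                R, t, rmsd = kabsch(pts[list(assign)], model.centers)
                aligned = pts[list(assign)] @ R.T + t
                d = np.linalg.norm(aligned - model.centers, axis=1)
                if all(
                    di <= model.features[f].tolerance + 1e-9
                    for f, di in enumerate(d)
                ):
                    return True
            return False

        n_hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            if seed % 2:  # fully random decoys
                pts = [
                    TypedFeaturePoint(
                        type=r.choice(["Don", "Acc", "Hyd", "ARO"]),
                        position=r.uniform(-0.5, 4.5, 3),
                    )
                    for _ in range(r.integers(4, 7))
                ]
            else:  # near-model geometries: compatible types, small jitter
                pts = [
                    TypedFeaturePoint(
                        type=sorted(f.allowed_types)[0],
                        position=f.center + r.uniform(-0.6, 0.6, 3),
                    )
                    for f in model.features
                ]
            got = match_pharmacophore(pts, model).hit
            assert got == oracle(pts)
            n_hits += got
        assert 0 < n_hits < 40  # the comparison exercises both outcomes


class TestScreening:
    def test_planted_hits_recovered_and_decoys_rejected(self):
        model = pxr_template_model()
        mols, labels = generate_screen_fixtures(12, 24, model, seed=5)
        results = screen_library(mols, model)
        assert [r.molecule_id for r in results] == [m.id for m in mols]
        by = {r.molecule_id: r for r in results}
        for lab in labels:
            assert by[lab["id"]].hit == lab["is_hit"], lab

    def test_excluded_volume_decoy_class_never_hits(self):
        model = pxr_template_model()
        mols, labels = generate_screen_fixtures(0, 9, model, seed=11)
        results = {r.molecule_id: r for r in screen_library(mols, model)}
        ev = [l for l in labels if l["decoy_class"] == "excluded_volume"]
        assert ev and all(not results[l["id"]].hit for l in ev)

    def test_screening_is_deterministic(self):
        model = pxr_template_model()
        mols, _ = generate_screen_fixtures(5, 5, model, seed=3)
        r1 = screen_library(mols, model)
        r2 = screen_library(mols, model)
        assert [(r.molecule_id, r.hit, r.rmsd) for r in r1] == [
            (r.molecule_id, r.hit, r.rmsd) for r in r2
        ]

    def test_empty_molecule_is_a_non_hit(self):
        model = small_model()
        lib = [
            PointSetMolecule("hit1", tuple(exact_points(model))),
            PointSetMolecule("empty", ()),
        ]
        results = screen_library(lib, model)
        assert [r.hit for r in results] == [True, False]


@pytest.mark.filterwarnings("ignore")
class TestRDKitFeatures:
    def test_benzene_yields_one_aromatic_centroid(self):
        from dockrank.pharmacophore import mol_from_smiles

        mol = mol_from_smiles("c1ccccc1", n_conformers=1, seed=7)
        points = detect_features(mol)
        aro = [p for p in points if p.type == "ARO"]
        assert len(aro) == 1
        conf = np.asarray(mol.GetConformer(0).GetPositions())
        np.testing.assert_allclose(aro[0].position, conf.mean(axis=0), atol=1e-6)

    def test_methanol_hydroxyl_is_donor_and_acceptor(self):
        from dockrank.pharmacophore import mol_from_smiles

        mol = mol_from_smiles("CO", n_conformers=1, seed=7)
        points = detect_features(mol)
        types = {p.type for p in points}
        assert "Don" in types and "Acc" in types
        o_idx = [
            a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O"
        ][0]
        assert any(
            p.type in ("Don", "Acc") and p.source_atoms == (o_idx,)
            for p in points
        )

    def test_point_set_molecule_roundtrips_declared_points(self):
        pts = (
            TypedFeaturePoint("Acc", np.array([1.0, 2, 3])),
            TypedFeaturePoint("Hyd", np.array([4.0, 5, 6])),
        )
        mol = PointSetMolecule("fixture", pts)
        assert detect_features(mol) == list(pts)

    def test_2d_molecule_without_conformer_is_an_error(self):
        from rdkit import Chem

        mol = Chem.MolFromSmiles("CCO")
        with pytest.raises(ModelError, match="conformer"):
            detect_features(mol)

    def test_smiles_screening_is_seed_reproducible(self):
        model = pxr_template_model()
        smiles = ["CCO", "c1ccccc1O", "CC(=O)Nc1ccc(O)cc1"]
        r1 = screen_library(smiles, model, n_conformers=3, seed=9)
        r2 = screen_library(smiles, model, n_conformers=3, seed=9)
        assert [(r.molecule_id, r.hit) for r in r1] == [
            (r.molecule_id, r.hit) for r in r2
        ]
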