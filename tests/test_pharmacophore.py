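import numpy as np
import pytest

from ligandfield import pharmacophore as ph
from ligandfield import synthdata
from ligandfield.pharmacophore import (Feature, PharmacophoreModel,
                                       enrichment, hit_rate, match_conformer,
                                       merge_models, perceive_features,
                                       roc_auc, screen_library)


def rigid_transform(mol, rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-15, 15, size=3)
    out = mol.translated([0, 0, 0])
    for a in out.atoms:
        a.coords = a.coords @ R.T + t
    return out


class TestFeature:
    def test_kind_validated(self):
        with pytest.raises(ValueError):
            Feature("BANANA", [0, 0, 0])

    def test_direction_normalized(self):
        f = Feature("HBD", [0, 0, 0], direction=[0, 0, 5])
        assert np.allclose(f.direction, [0, 0, 1])

    def test_model_json_round_trip(self, toy_model):
        back = PharmacophoreModel.from_json(toy_model.to_json())
        assert len(back.features) == len(toy_model.features)
        for a, b in zip(back.core_features, toy_model.core_features):
            assert a.kind == b.kind
            assert np.allclose(a.center, b.center)


class TestPerception:
    def test_toy_complex_features(self, toy_model):
        kinds = sorted(f.kind for f in toy_model.core_features)
        assert kinds == ["HBA", "HBD", "HY"]
        assert toy_model.screenable
        assert len(toy_model.exclusion_volumes) > 0

    def test_hbd_sits_on_ligand_donor(self, toy_complex, toy_model):
        donor = next(a for a in toy_complex.ligand.atoms
                     if a.is_donor_h_parent)
        hbd = next(f for f in toy_model.core_features if f.kind == "HBD")
        assert np.allclose(hbd.center, donor.coords)

    def test_distance_gate(self):
        cx = synthdata.make_toy_complex(seed=0, hbond_distance=3.8)
        model = perceive_features(cx)
        assert "HBD" not in [f.kind for f in model.core_features]

    def test_angle_gate(self):
        cx = synthdata.make_toy_complex(seed=0, hbond_angle_deg=115.0)
        model = perceive_features(cx)
        assert "HBD" not in [f.kind for f in model.core_features]

    def test_xvols_clear_of_features(self, toy_model):
        centers = np.array([f.center for f in toy_model.core_features])
        for xv in toy_model.exclusion_volumes:
            d = np.linalg.norm(centers - xv.center, axis=1)
            assert (d > ph.XVOL_FEATURE_CLEARANCE).all()


class TestMerge:
    def test_consensus_keeps_shared_features(self, toy_complex):
        m1 = perceive_features(toy_complex)
        m2 = perceive_features(
            synthdata.make_toy_complex(seed=2, hbond_distance=3.1,
                                       hbond_angle_deg=160.0))
        merged = merge_models([m1, m2])
        assert sorted(f.kind for f in merged.core_features) == \
            sorted(f.kind for f in m1.core_features)

    def test_unshared_feature_dropped(self, toy_model):
        lone = PharmacophoreModel(
            [Feature("HBD", [50.0, 50.0, 50.0], 1.5)], ["other"])
        merged = merge_models([toy_model, lone])
        centers = [f.center for f in merged.core_features
                   if f.kind == "HBD"]
        assert not any(np.allclose(c, [50, 50, 50]) for c in centers)

    def test_order_invariance(self, toy_complex):
        m1 = perceive_features(toy_complex)
        m2 = perceive_features(synthdata.make_toy_complex(seed=2))
        a = merge_models([m1, m2])
        b = merge_models([m2, m1])
        ka = sorted((f.kind, *np.round(f.center, 6)) for f in a.core_features)
        kb = sorted((f.kind, *np.round(f.center, 6)) for f in b.core_features)
        assert ka == kb


class TestMatching:
    def test_actives_match_decoys_fail(self, toy_model):
        mols, labels = synthdata.make_actives_decoys(toy_model, 8, 8, seed=5)
        hits = {h.molecule_id for h in screen_library(toy_model, mols)}
        for mid, lab in labels.items():
            assert (mid in hits) == bool(lab)

    def test_fit_score_rigid_invariance(self, toy_model, rng):
        mols, _ = synthdata.make_actives_decoys(toy_model, 1, 0, seed=9,
                                                n_conformers=1)
        hit0 = match_conformer(toy_model, mols[0])
        hit1 = match_conformer(toy_model, rigid_transform(mols[0], rng))
        assert hit0 is not None and hit1 is not None
        assert hit1.fit_score == pytest.approx(hit0.fit_score, abs=1e-6)

    def test_zero_jitter_scores_max(self, toy_model):
        mols, _ = synthdata.make_actives_decoys(toy_model, 3, 0, seed=2,
                                                jitter=1e-9, n_conformers=1)
        n = len(toy_model.core_features)
        for m in mols:
            hit = match_conformer(toy_model, m)
            assert hit.fit_score == pytest.approx(10.0 * n, abs=1e-4)
            assert hit.alignment_rmsd == pytest.approx(0.0, abs=1e-4)

    def test_screen_sorted_by_score(self, toy_model):
        mols, _ = synthdata.make_actives_decoys(toy_model, 6, 0, seed=3)
        hits = screen_library(toy_model, mols)
        scores = [h.fit_score for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_exclusion_volume_clash_vetoes_match(self, toy_model):
        from ligandfield.chemio import AtomRecord, MoleculeRecord, assign_typing
        from ligandfield.synthdata import _feature_atoms
        rng = np.random.default_rng(0)
        # untransformed conformer sitting exactly on the feature centers
        atoms = []
        for f in toy_model.core_features:
            atoms.extend(_feature_atoms(f, f.center, rng))
        clean = assign_typing(MoleculeRecord("clean", [a for a in atoms]))
        assert match_conformer(toy_model, clean) is not None
        # the identical pose plus one atom planted at an exclusion volume
        xv = toy_model.exclusion_volumes[0]
        poisoned = assign_typing(MoleculeRecord(
            "poisoned", atoms + [AtomRecord("C", xv.center, 0.0)]))
        assert match_conformer(toy_model, poisoned) is None

    def test_unscreenable_model(self):
        model = PharmacophoreModel([Feature("HBD", [0, 0, 0])], ["x"])
        assert not model.screenable


class TestValidationMetrics:
    def test_auc_pair_counting_oracle(self, rng):
        a = rng.normal(1.0, 1.0, size=5)
        d = rng.normal(0.0, 1.0, size=5)
        wins = sum((x > y) + 0.5 * (x == y) for x in a for y in d)
        assert roc_auc(a, d) == pytest.approx(wins / 25.0)

    def test_auc_extremes_and_ties(self):
        assert roc_auc([3, 2], [1, 0]) == 1.0
        assert roc_auc([0, 1], [2, 3]) == 0.0
        assert roc_auc([1.0], [1.0]) == 0.5

    def test_enrichment_counting(self):
        ranked = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]   # 3 actives in 10
        # top 20% = ceil(0.2*10) = 2 entries, both active
        assert enrichment(ranked, 0.2) == pytest.approx((2 / 2) / (3 / 10))
        assert enrichment(ranked, 1.0) == pytest.approx(1.0)

    def test_hit_rates_planted_library(self, toy_model):
        mols, labels = synthdata.make_actives_decoys(toy_model, 8, 8, seed=6)
        actives = [m for m in mols if labels[m.id] == 1]
        decoys = [m for m in mols if labels[m.id] == 0]
        assert hit_rate(toy_model, actives) == 1.0
        assert hit_rate(toy_model, decoys) == 0.0
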