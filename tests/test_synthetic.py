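import numpy as np
import pytest
from rdkit import Chem
from scipy.stats import spearmanr

from ecipred import (
    SyntheticConfig,
    aoic,
    aoie,
    compute_statistics,
    generate_dataset,
    load_dataset,
    save_dataset,
)
from ecipred.exceptions import CapacityError, ValidationError
from ecipred.synthetic import generate_activity, generate_chemicals, generate_sequences
from ecipred._smiles_library import SMILES_CLASSES


class TestSequences:
    def test_zero_mutation_identical_members(self):
        cfg = SyntheticConfig(mutation_rate=0.0, seed=1)
        _, seqs, families = generate_sequences(cfg)
        labels = list(families.values())
        for fam in set(labels):
            member_seqs = {s for s, l in zip(seqs, labels) if l == fam}
            assert len(member_seqs) == 1

    def test_full_mutation_erases_family_identity(self):
        cfg = SyntheticConfig(
            n_families=2, enzymes_per_family=5, sequence_length=200,
            mutation_rate=1.0, seed=2,
        )
        _, seqs, families = generate_sequences(cfg)
        labels = np.array(list(families.values()))

        def identity(a, b):
            return np.mean([x == y for x, y in zip(a, b)])

        within, between = [], []
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                (within if labels[i] == labels[j] else between).append(
                    identity(seqs[i], seqs[j])
                )
        assert abs(np.mean(within) - np.mean(between)) < 0.03

    def test_mutation_rate_sweep_raises_similarity(self):
        """Lower mutation rate -> higher within-family sequence similarity."""
        sims = []
        for mu in (0.6, 0.3, 0.1):
            cfg = SyntheticConfig(
                n_families=2, enzymes_per_family=4, sequence_length=80,
                mutation_rate=mu, chemicals_per_class=2, seed=5,
            )
            ds, _ = generate_dataset(cfg)
            stats = compute_statistics(ds, "LOOT")
            sims.append(stats.top5_protein_similarity)
        assert sims[0] < sims[1] < sims[2]


class TestChemicals:
    def test_zero_noise_identical_within_class(self):
        cfg = SyntheticConfig(chemical_noise_sd=0.0, seed=3)
        ids, _, classes, features = generate_chemicals(cfg)
        for cls in set(classes.values()):
            members = [i for i, c in zip(ids, classes.values()) if c == cls]
            rows = features.loc[members].to_numpy()
            assert np.allclose(rows, rows[0])

    def test_class_labels_partition(self):
        cfg = SyntheticConfig(seed=4)
        ids, _, classes, _ = generate_chemicals(cfg)
        assert set(classes) == set(ids)

    def test_packaged_smiles_all_parse(self):
        for group, smiles_list in SMILES_CLASSES.items():
            for s in smiles_list:
                assert Chem.MolFromSmiles(s) is not None, (group, s)

    def test_smiles_mode_capacity_error(self):
        cfg = SyntheticConfig(chemical_mode="smiles", chemicals_per_class=100)
        with pytest.raises(CapacityError):
            generate_chemicals(cfg)

    def test_smiles_mode_yields_parseable_dataset(self):
        cfg = SyntheticConfig(
            chemical_mode="smiles", n_classes=3, chemicals_per_class=4, seed=6,
            sequence_length=50, enzymes_per_family=3,
        )
        ds, _ = generate_dataset(cfg)
        assert all(s is not None for s in ds.smiles)


class TestActivity:
    def test_noise_only_model_order_indices_near_half(self):
        cfg = SyntheticConfig(
            n_families=4, enzymes_per_family=10, n_classes=4,
            chemicals_per_class=8, block_scale=0.0,
            enzyme_effect_sd=0.0, chemical_effect_sd=0.0, noise_sd=1.0, seed=7,
        )
        _, seqs, fam = generate_sequences(cfg)
        ids, _, cls, _ = generate_chemicals(cfg)
        vals = []
        for seed in range(8):
            cfg.seed = seed
            binary, _ = generate_activity(cfg, fam, cls)
            vals.append((aoie(binary), aoic(binary)))
        vals = np.array(vals)
        assert np.mean(vals[:, 0]) == pytest.approx(0.5, abs=0.05)
        assert np.mean(vals[:, 1]) == pytest.approx(0.5, abs=0.05)

    def test_chemical_effect_only_gives_aoic_one(self):
        cfg = SyntheticConfig(
            block_scale=0.0, enzyme_effect_sd=0.0,
            chemical_effect_sd=1.0, noise_sd=0.0, seed=8,
        )
        _, _, fam = generate_sequences(cfg)
        ids, _, cls, _ = generate_chemicals(cfg)
        _, latent = generate_activity(cfg, fam, cls)
        assert aoic(latent) == 1.0

    def test_realized_ratio_hits_target_exactly(self):
        cfg = SyntheticConfig(
            n_families=4, enzymes_per_family=10, n_classes=3,
            chemicals_per_class=10, target_activity_ratio=0.3, seed=9,
        )
        ds, _ = generate_dataset(cfg)
        cells = ds.n_enzymes * ds.n_chemicals
        assert abs(ds.activity.mean() - 0.3) <= 1.0 / cells

    def test_aoic_monotone_in_chemical_effect(self):
        """Sweeping the chemical-effect/noise ratio upward raises AOIC."""
        betas = (0.0, 0.5, 1.0, 2.0, 4.0)
        means = []
        for beta in betas:
            reps = []
            for rep in range(10):
                cfg = SyntheticConfig(
                    n_families=2, enzymes_per_family=10, n_classes=2,
                    chemicals_per_class=10, sequence_length=30,
                    block_scale=0.0, enzyme_effect_sd=0.0,
                    chemical_effect_sd=beta, noise_sd=1.0, seed=100 + rep,
                )
                _, _, fam = generate_sequences(cfg)
                _, _, cls, _ = generate_chemicals(cfg)
                binary, _ = generate_activity(cfg, fam, cls)
                reps.append(aoic(binary))
            means.append(np.mean(reps))
        rho = spearmanr(betas, means).statistic
        assert rho >= 0.9


class TestAssembly:
    def test_dataset_valid_and_deterministic(self):
        cfg = SyntheticConfig(seed=11, sequence_length=50)
        ds1, truth1 = generate_dataset(cfg)
        ds2, truth2 = generate_dataset(cfg)
        assert ds1.sequences == ds2.sequences
        np.testing.assert_array_equal(ds1.activity, ds2.activity)
        np.testing.assert_array_equal(
            truth1.latent_activity, truth2.latent_activity
        )
        assert ds1.is_binary
        assert set(truth1.family_of_enzyme) == set(ds1.enzyme_ids)
        assert set(truth1.class_of_chemical) == set(ds1.chemical_ids)

    def test_roundtrip_then_statistics(self, tmp_path):
        cfg = SyntheticConfig(
            seed=12, sequence_length=40, enzymes_per_family=3,
            chemicals_per_class=3, chemical_mode="smiles",
        )
        ds, _ = generate_dataset(cfg)
        save_dataset(ds, tmp_path / "synth")
        loaded = load_dataset(tmp_path / "synth")
        stats = compute_statistics(loaded, "LOOT")
        assert stats.n_enzymes == ds.n_enzymes
        assert 0.0 <= stats.aoie <= 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(mutation_rate=1.5)
        with pytest.raises(ValidationError):
            SyntheticConfig(target_activity_ratio=0.0)
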