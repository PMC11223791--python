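import numpy as np
import pytest

import ppiddg as pg
from ppiddg.datasets import (
    AugmentationError,
    GroupingError,
    MutationRecord,
    SchemaError,
    augment_with_reverse,
    filter_single_mutations,
    generate_synthetic_complex,
    generate_synthetic_dataset,
    read_skempi_table,
    split_leave_one_binding_site_out,
    split_leave_one_complex_out,
)
from ppiddg.structures import parse_mutation

TABLE = """pdb,partner1,partner2,mutations,ddg,binding_site
1ABC,A,B,A L45G,-1.2,protease_inhibitor
1ABC,A,B,A A46V,0.4,protease_inhibitor
2XYZ,H,L,I D46A; I R48K,-2.1,antibody_antigen
"""


def _records(n, complex_ids=("C1", "C2", "C3"), sites=("s1", "s2"), seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cid = complex_ids[rng.integers(len(complex_ids))]
        out.append(MutationRecord(
            record_id=f"r{i}", complex_id=cid, partner1="A", partner2="B",
            specs=parse_mutation("L45G", default_chain="A"),
            y=float(rng.normal()), binding_site_label=sites[rng.integers(len(sites))],
        ))
    return out


class TestReadTable:
    def test_reads_forward_records(self):
        records = read_skempi_table(TABLE)
        assert len(records) == 3
        assert records[0].y == pytest.approx(-1.2)
        assert records[0].binding_site_label == "protease_inhibitor"

    def test_multi_mutation_cell_becomes_one_record(self):
        records = read_skempi_table(TABLE)
        assert len(records[2].specs) == 2
        assert records[2].is_multi
        assert len(filter_single_mutations(records)) == 2

    def test_missing_required_column(self):
        with pytest.raises(SchemaError, match="ddg"):
            read_skempi_table("pdb,partner1,partner2,mutations\n1ABC,A,B,A L45G\n")

    def test_bad_mutation_row_rejected_with_diagnostics(self, caplog):
        bad = TABLE + "3DEF,A,B,A L45L,0.0,other\n"
        with caplog.at_level("WARNING"):
            records = read_skempi_table(bad)
        assert len(records) == 3
        assert any("rejecting row" in r.message for r in caplog.records)


def test_records_serialize_to_json_lines():
    from ppiddg.datasets import write_records_jsonl
    import json

    records = augment_with_reverse(_records(3))
    lines = write_records_jsonl(records).strip().splitlines()
    assert len(lines) == 6
    parsed = [json.loads(ln) for ln in lines]
    assert parsed[3]["direction"] == "reverse"
    assert parsed[3]["pair_id"] == parsed[0]["record_id"]


class TestAugmentation:
    @pytest.mark.parametrize("n", [0, 1, 7])
    def test_doubles_and_negates(self, n):
        records = _records(n)
        out = augment_with_reverse(records)
        assert len(out) == 2 * n
        forward = {r.record_id: r for r in out if r.direction == "forward"}
        for rev in (r for r in out if r.direction == "reverse"):
            assert rev.y == -forward[rev.pair_id].y
            assert rev.specs[0].wt_aa == forward[rev.pair_id].specs[0].mut_aa

    def test_label_multiset_symmetric_after_augmentation(self):
        out = augment_with_reverse(_records(25))
        ys = sorted(r.y for r in out)
        np.testing.assert_allclose(ys, sorted(-y for y in ys))

    def test_double_augmentation_rejected(self):
        once = augment_with_reverse(_records(3))
        with pytest.raises(AugmentationError):
            augment_with_reverse(once)


class TestSplits:
    def test_one_fold_per_complex(self):
        records = _records(30)
        split = split_leave_one_complex_out(records)
        assert len(split.folds) == len({r.complex_id for r in records})
        all_ids = sorted(rid for fold in split.folds for rid in fold)
        assert all_ids == sorted(r.record_id for r in records)

    def test_complexes_sharing_binding_site_cofold(self):
        records = _records(30)
        split = split_leave_one_binding_site_out(records)
        label_by_id = {r.record_id: r.binding_site_label for r in records}
        for fold in split.folds:
            assert len({label_by_id[rid] for rid in fold}) == 1

    def test_forward_reverse_always_cofold(self):
        augmented = augment_with_reverse(_records(40, seed=5))
        for split in (split_leave_one_complex_out(augmented),
                      split_leave_one_binding_site_out(augmented)):
            fold_of = {rid: i for i, fold in enumerate(split.folds) for rid in fold}
            for r in augmented:
                if r.direction == "reverse":
                    assert fold_of[r.record_id] == fold_of[r.pair_id]

    def test_missing_binding_site_label(self):
        records = _records(3)
        records[1].binding_site_label = None
        with pytest.raises(GroupingError):
            split_leave_one_binding_site_out(records)


class TestSyntheticComplex:
    def test_deterministic_for_seed(self):
        a = generate_synthetic_complex(10, seed=7)
        b = generate_synthetic_complex(10, seed=7)
        assert len(a.atoms) == len(b.atoms)
        for x, y in zip(a.atoms, b.atoms):
            assert np.array_equal(x.coords, y.coords)
            assert x.residue_name == y.residue_name

    def test_contact_target_produces_interface(self):
        s = generate_synthetic_complex(10, seed=0, contact_pairs=4)
        assert len(pg.interface_residues(s)) >= 8

    def test_separated_chains_have_no_interface(self):
        s = generate_synthetic_complex(10, seed=0, separated=True)
        assert pg.interface_residues(s) == set()


class TestSyntheticDataset:
    def test_deterministic_labels(self):
        truth = pg.SyntheticGroundTruth(seed=4)
        r1, _ = generate_synthetic_dataset(40, truth)
        r2, _ = generate_synthetic_dataset(40, truth)
        assert [r.y for r in r1] == [r.y for r in r2]
        assert [str(r.specs[0]) for r in r1] == [str(r.specs[0]) for r in r2]

    def test_zero_truth_gives_zero_labels(self):
        truth = pg.SyntheticGroundTruth(coefficients={}, noise_sd=0.0, seed=1)
        records, _ = generate_synthetic_dataset(10, truth)
        assert all(r.y == 0.0 for r in records)

    def test_noise_level_recovered(self):
        # identical seeds consume identical draws, so the label difference
        # between sd=0.3 and sd=0 runs is exactly the injected noise
        n = 2000
        noisy, _ = generate_synthetic_dataset(
            n, pg.SyntheticGroundTruth(noise_sd=0.3, seed=9))
        clean, _ = generate_synthetic_dataset(
            n, pg.SyntheticGroundTruth(noise_sd=0.0, seed=9))
        noise = np.array([a.y - b.y for a, b in zip(noisy, clean)])
        se = 0.3 / np.sqrt(2 * n)
        assert abs(noise.std() - 0.3) < 3 * se

    def test_records_reference_generated_structures(self):
        records, structures = generate_synthetic_dataset(
            15, pg.SyntheticGroundTruth(seed=2))
        for r in records:
            assert r.complex_id in structures
            key = r.specs[0].residue_key
            assert key in pg.interface_residues(structures[r.complex_id])
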