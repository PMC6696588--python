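import numpy as np
import pandas as pd
import pytest

from probeal import dataset_prep as dp


def rec(cid, tid, ki, smiles="C"):
    return dp.BioactivityRecord(compound_id=cid, smiles=smiles, target_id=tid, ki_nm=ki)


class TestDeriveThresholds:
    def test_mean_1803_gives_1803_60(self):
        s = dp.derive_thresholds([1803.0], "T")
        assert s.inactive_threshold_nm == 1803.0
        assert s.active_threshold_nm == 60.0

    def test_small_mean_readjusted_to_1500_50(self):
        s = dp.derive_thresholds([900.0, 1100.0], "T")
        assert s.inactive_threshold_nm == 1500.0
        assert s.active_threshold_nm == 50.0

    def test_mean_exactly_1500(self):
        s = dp.derive_thresholds([1500.0], "T")
        assert (s.inactive_threshold_nm, s.active_threshold_nm) == (1500.0, 50.0)

    def test_large_mean_kept_unadjusted(self):
        # the cap raises weak-boundary (small) means; large means stay put
        s = dp.derive_thresholds([5000.0], "T")
        assert s.inactive_threshold_nm == 5000.0
        assert s.active_threshold_nm == 167.0  # round(5000/30)

    def test_active_threshold_rounded_to_integer(self):
        s = dp.derive_thresholds([1803.0], "T")
        assert s.active_threshold_nm == round(1803 / 30)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no Ki data"):
            dp.derive_thresholds([], "T")

    def test_nonpositive_ki_errors(self):
        with pytest.raises(ValueError):
            dp.derive_thresholds([100.0, -1.0], "T")


class TestDiscretize:
    SCHEME = dp.DiscretizationScheme("T", 1500.0, 50.0)

    def run_one(self, ki):
        table = dp.discretize([rec("c", "T", ki)], self.SCHEME)
        return table.rows["label"].tolist()

    def test_active(self):
        assert self.run_one(40.0) == [dp.ACTIVE]

    def test_inactive(self):
        assert self.run_one(2000.0) == [dp.INACTIVE]

    def test_indeterminate_dropped(self):
        assert self.run_one(300.0) == []

    def test_boundary_ties_classified(self):
        assert self.run_one(50.0) == [dp.ACTIVE]
        assert self.run_one(1500.0) == [dp.INACTIVE]

    def test_target_mismatch_errors(self):
        with pytest.raises(ValueError, match="does not match"):
            dp.discretize([rec("c", "U", 10.0)], self.SCHEME)

    def test_agrees_with_bruteforce_rule(self, rng):
        # independent pass applying the printed rule directly
        kis = rng.uniform(1.0, 5000.0, size=200)
        records = [rec(f"c{i}", "T", k) for i, k in enumerate(kis)]
        scheme = dp.derive_thresholds(kis, "T")
        table = dp.discretize(records, scheme)
        got = dict(zip(table.rows["compound_id"], table.rows["label"]))
        mean = kis.mean()
        inact = mean if mean > 1500 else 1500.0
        act = round(inact / 30)
        for i, k in enumerate(kis):
            expected = (
                dp.INACTIVE if k >= inact else dp.ACTIVE if k <= act else None
            )
            assert got.get(f"c{i}") == expected


class TestRetentionFilters:
    def test_below_min_pre_dropped(self):
        records = [rec(f"c{i}", "A", 10.0) for i in range(49)]
        assert dp.apply_retention_filters(records) == set()

    def test_indeterminate_zone_removal(self):
        # 59 compounds, 45 inside the indeterminate zone -> 14 classified < 30
        records = [rec(f"c{i}", "B", 25.0) for i in range(14)]
        records += [rec(f"c{i+14}", "B", 700.0) for i in range(45)]
        assert dp.apply_retention_filters(records) == set()

    def test_hand_counted_retention(self):
        # derived by direct enumeration: A fails min_pre, B fails min_post,
        # C passes both
        records = [rec(f"a{i}", "A", 10.0) for i in range(40)]
        records += [rec(f"b{i}", "B", 25.0) for i in range(14)]
        records += [rec(f"b{i+14}", "B", 700.0) for i in range(45)]
        records += [rec(f"c{i}", "C", 10.0 if i % 2 else 2000.0) for i in range(60)]
        assert dp.apply_retention_filters(records) == {"C"}

    def test_thresholds_relaxable(self):
        records = [rec(f"c{i}", "A", 10.0) for i in range(10)]
        assert dp.apply_retention_filters(records, min_pre=5, min_post=5) == {"A"}


def table_from(profiles):
    rows = [
        (cid, tid, label)
        for cid, profile in profiles.items()
        for tid, label in profile.items()
    ]
    return dp.AnnotationTable.from_records(rows)


class TestSplitProbes:
    def test_probe_definition(self):
        table = table_from(
            {
                "p": {"T1": dp.ACTIVE, "T2": dp.INACTIVE},
                "only_active": {"T1": dp.ACTIVE},
                "two_actives": {"T1": dp.ACTIVE, "T2": dp.ACTIVE, "T3": dp.INACTIVE},
                "only_inactive": {"T1": dp.INACTIVE, "T2": dp.INACTIVE},
            }
        )
        split = dp.split_probes(table)
        assert split.probe_compounds == {"p"}
        assert split.nonprobe_compounds == {"only_active", "two_actives", "only_inactive"}

    def test_annotation_counts_partition(self):
        table = table_from(
            {
                "p": {"T1": dp.ACTIVE, "T2": dp.INACTIVE, "T3": dp.INACTIVE},
                "q": {"T1": dp.ACTIVE, "T2": dp.ACTIVE},
            }
        )
        split = dp.split_probes(table)
        assert len(split.probe_annotations) + len(split.nonprobe_annotations) == len(table)
        # all of a probe's annotations travel to the external table
        assert set(split.probe_annotations.rows["compound_id"]) == {"p"}
        assert len(split.probe_annotations) == 3

    def test_probe_profiles_have_one_active(self, small_dataset):
        split = dp.split_probes(small_dataset.annotations)
        counts = split.probe_annotations.label_counts()
        assert (counts[dp.ACTIVE] == 1).all()
        assert (counts[dp.INACTIVE] >= 1).all()

    def test_empty_table(self):
        table = dp.AnnotationTable(pd.DataFrame(columns=list(dp.AnnotationTable.COLUMNS)))
        split = dp.split_probes(table)
        assert split.probe_compounds == set() and split.nonprobe_compounds == set()


class TestPrepareDataset:
    def make_records(self):
        rng = np.random.default_rng(0)
        records = []
        for t in ("T1", "T2"):
            for i in range(40):
                ki = 10.0 if rng.random() < 0.5 else 2000.0
                records.append(rec(f"c{i}", t, ki))
        return records

    def test_deterministic(self):
        records = self.make_records()
        s1, sch1, _ = dp.prepare_dataset(records, min_pre=5, min_post=5)
        s2, sch2, _ = dp.prepare_dataset(records, min_pre=5, min_post=5)
        assert s1.probe_compounds == s2.probe_compounds
        assert s1.nonprobe_annotations.rows.equals(s2.nonprobe_annotations.rows)
        assert sch1 == sch2

    def test_conflicting_duplicates_dropped(self):
        records = self.make_records()
        records += [rec("dup", "T1", 10.0), rec("dup", "T1", 2000.0)]
        _, _, report = dp.prepare_dataset(records, min_pre=5, min_post=5)
        assert report.n_pairs_inconsistent == 1

    def test_identical_duplicates_collapse(self):
        records = self.make_records()
        records += [rec("dup", "T1", 10.0), rec("dup", "T1", 12.0)]  # both active
        split, _, _ = dp.prepare_dataset(records, min_pre=5, min_post=5)
        rows = split.nonprobe_annotations.rows
        dup_rows = rows[(rows.compound_id == "dup") & (rows.target_id == "T1")]
        assert len(dup_rows) == 1

    def test_filter_report_counts(self):
        records = self.make_records()
        _, _, report = dp.prepare_dataset(records, min_pre=5, min_post=5)
        assert report.n_targets_retained == 2
        assert report.n_annotations == 80


class TestIO:
    def test_bioactivity_round_trip(self, tmp_path):
        records = [rec("c1", "T1", 10.0, "CCO"), rec("c2", "T2", 2000.0, "c1ccccc1")]
        path = tmp_path / "bio.tsv"
        pd.DataFrame(
            [
                {"compound_id": r.compound_id, "smiles": r.smiles,
                 "target_id": r.target_id, "ki_nm": r.ki_nm}
                for r in records
            ]
        ).to_csv(path, sep="\t", index=False)
        assert dp.read_bioactivity_table(path) == records

    def test_missing_column_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("compound_id,smiles\nc1,CCO\n")
        with pytest.raises(ValueError, match="missing columns"):
            dp.read_bioactivity_table(path)

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"T1": "MKSLP" * 20, "T2": "ACDEF"}
        path = tmp_path / "t.fasta"
        dp.write_fasta(seqs, path)
        assert dp.read_fasta(path) == seqs

    def test_ki_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            rec("c", "T", 0.0)
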