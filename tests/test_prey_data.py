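"""Unit and property tests for the data model, I/O, filters, and aggregation."""

import random

import pytest

from spongeprey.prey_data import (
    UNKNOWN_FAMILY,
    ContractViolation,
    DataConflictError,
    FamilyAnnotation,
    FamilyUniverse,
    FilterConfig,
    PreyObservation,
    SchemaError,
    apply_filters,
    average_replicates,
    canonical_family,
    pool_counts,
    read_family_annotations,
    read_observations,
    rollup_to_family,
    write_family_annotations,
    write_observations,
)

from conftest import make_obs


class TestPreyObservation:
    def test_transect_requires_transect_id(self):
        with pytest.raises(SchemaError, match="transect_id"):
            make_obs(transect_id=None)

    def test_unidentified_requires_unknown_family(self):
        with pytest.raises(SchemaError, match="UNKNOWN"):
            make_obs(family="Labridae", identified=False)

    def test_unidentified_with_unknown_family_is_valid(self):
        o = make_obs(family=UNKNOWN_FAMILY, identified=False, length_cm=4.0)
        assert not o.identified

    @pytest.mark.parametrize("length", [0.0, -3.0])
    def test_nonpositive_length_rejected(self, length):
        with pytest.raises(SchemaError, match="length_cm"):
            make_obs(length_cm=length)

    def test_family_name_normalization(self):
        assert make_obs(family="  dasyatidae ").family == "Dasyatidae"
        assert canonical_family("UNKNOWN") == UNKNOWN_FAMILY
        assert canonical_family("unknown") == UNKNOWN_FAMILY


class TestObservationIO:
    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "obs.csv"
        write_observations([], path)
        assert read_observations(path) == []

    def test_single_row_round_trips_fields(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text(
            "dive_id,site_kind,transect_id,replicate,mode,family,species,length_cm,identified\n"
            "d1,transect,T1,1,sponging,Pinguipedidae,Parapercis nebulosa,12.6,true\n"
        )
        (obs,) = read_observations(path)
        assert obs.family == "Pinguipedidae"
        assert obs.species == "Parapercis nebulosa"
        assert obs.length_cm == pytest.approx(12.6)
        assert obs.mode == "sponging"
        assert obs.identified

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text("dive_id,site_kind,transect_id,replicate,mode,family,species,length_cm\nx\n")
        with pytest.raises(SchemaError, match="identified"):
            read_observations(path)

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text(
            "dive_id,site_kind,transect_id,replicate,mode,family,species,length_cm,identified\n"
            "d1,transect,T1,1,sponging,Labridae,,not-a-number,true\n"
            "d2,transect,T1,1,sponging,Labridae,,10.0,false\n"
        )
        with pytest.raises(SchemaError) as err:
            read_observations(path)
        assert "line 2" in str(err.value)
        assert "line 3" in str(err.value)

    def test_round_trip_preserves_observations(self, tmp_path):
        obs = [
            make_obs(transect_id=f"T{i % 3 + 1}", replicate=i % 2 + 1, length_cm=5.0 + i)
            for i in range(10)
        ] + [
            make_obs(site_kind="verification", transect_id=None, length_cm=None),
            make_obs(family=UNKNOWN_FAMILY, identified=False, length_cm=3.2),
        ]
        path = write_observations(obs, tmp_path / "obs.csv")
        assert read_observations(path) == obs


class TestFamilyAnnotations:
    def test_universe_from_rows(self, tmp_path):
        path = tmp_path / "fam.csv"
        path.write_text("family,has_swimbladder,evidence\nPinguipedidae,N,dissected\nLabridae,Y,literature\n")
        universe = read_family_annotations(path)
        assert universe.size == 2
        assert universe.n_no_swimbladder == 1
        assert not universe.has_swimbladder("Pinguipedidae")

    def test_duplicate_family_with_same_status_merges(self, tmp_path):
        path = tmp_path / "fam.csv"
        path.write_text("family,has_swimbladder,evidence\nDasyatidae,N,+\nDasyatidae,N,+\n")
        universe = read_family_annotations(path)
        assert universe.size == 1

    def test_conflicting_status_raises(self):
        universe = FamilyUniverse([FamilyAnnotation("Dasyatidae", False)])
        with pytest.raises(DataConflictError, match="Dasyatidae"):
            universe.add(FamilyAnnotation("Dasyatidae", True))

    def test_unparseable_boolean_raises(self, tmp_path):
        path = tmp_path / "fam.csv"
        path.write_text("family,has_swimbladder,evidence\nLabridae,maybe,\n")
        with pytest.raises(SchemaError, match="boolean"):
            read_family_annotations(path)

    def test_universe_round_trip(self, tmp_path, published_universe):
        path = write_family_annotations(published_universe, tmp_path / "fam.csv")
        assert read_family_annotations(path) == published_universe


class TestFilters:
    def test_boundary_length_exactly_at_threshold_retained(self):
        kept = apply_filters([make_obs(length_cm=7.0)], FilterConfig(min_length_cm=7))
        assert len(kept) == 1

    def test_sub_threshold_and_unidentified_removed(self):
        obs = [
            make_obs(length_cm=6.9),
            make_obs(length_cm=None),
            make_obs(family=UNKNOWN_FAMILY, identified=False, length_cm=3.0),
            make_obs(length_cm=12.0),
        ]
        kept = apply_filters(obs)
        assert [o.length_cm for o in kept] == [None, 12.0]

    def test_unidentified_small_prey_all_excluded(self):
        """19 unidentifiable sub-threshold prey among N leave N - 19 retained."""
        unidentified = [
            make_obs(family=UNKNOWN_FAMILY, identified=False, length_cm=4.0)
            for _ in range(19)
        ]
        identified = [make_obs(length_cm=10.0) for _ in range(100)]
        kept = apply_filters(identified + unidentified)
        assert len(kept) == 100

    def test_filtering_is_idempotent_and_monotone(self):
        rng = random.Random(7)
        obs = []
        for _ in range(200):
            identified = rng.random() >= 0.2
            obs.append(
                make_obs(
                    length_cm=rng.choice([None, 3.0, 6.9, 7.0, 15.0]),
                    family="Labridae" if identified else UNKNOWN_FAMILY,
                    identified=identified,
                )
            )
        once = apply_filters(obs)
        assert apply_filters(once) == once
        assert set(once) <= set(obs)
        # order of the two exclusion rules does not matter
        only_len = apply_filters(obs, FilterConfig(drop_unidentified=False))
        both = apply_filters(only_len, FilterConfig())
        assert both == once

    def test_empty_input(self):
        assert apply_filters([]) == []


class TestRollupAndPooling:
    def test_species_collapse_to_family(self):
        obs = [
            make_obs(family="Labridae", species="Choerodon cephalotes", mode="non_sponging"),
            make_obs(family="Labridae", species="Choerodon schoenleinii", mode="non_sponging"),
        ]
        table = rollup_to_family(obs)
        assert len(table.cells) == 1
        assert table.cells["count"].iloc[0] == 2

    def test_unknown_family_violates_contract(self):
        obs = [make_obs(family=UNKNOWN_FAMILY, identified=False, length_cm=3.0)]
        with pytest.raises(ContractViolation):
            rollup_to_family(obs)

    def test_empty_input_gives_empty_table(self):
        assert rollup_to_family([]).cells.empty

    def test_grand_total_equals_input_length(self):
        rng = random.Random(3)
        obs = [
            make_obs(
                family=rng.choice(["Labridae", "Mullidae", "Sepiidae"]),
                mode=rng.choice(["sponging", "non_sponging"]),
                transect_id=f"T{rng.randint(1, 7)}",
                replicate=rng.randint(1, 2),
            )
            for _ in range(153)
        ]
        table = rollup_to_family(obs)
        assert table.total == 153
        pooled = pool_counts(table, "all_dives")
        assert sum(pooled.values()) == 153

    def test_rollup_then_pool_invariant_to_row_order(self):
        rng = random.Random(5)
        obs = [
            make_obs(
                family=rng.choice(["Labridae", "Mullidae"]),
                mode=rng.choice(["sponging", "non_sponging"]),
                transect_id=f"T{rng.randint(1, 3)}",
            )
            for _ in range(60)
        ]
        shuffled = obs[:]
        rng.shuffle(shuffled)
        assert pool_counts(rollup_to_family(obs)) == pool_counts(rollup_to_family(shuffled))


class TestReplicateAveraging:
    def test_arithmetic_mean_of_two_replicates(self):
        obs = [make_obs(replicate=1)] * 3 + [make_obs(replicate=2)]
        table = rollup_to_family(obs)
        avg = average_replicates(table)
        assert avg.cells["count"].tolist() == [2.0]

    def test_family_absent_in_one_replicate_zero_filled(self):
        obs = [make_obs(family="Sepiidae", replicate=1)] * 4 + [
            make_obs(family="Labridae", replicate=2)
        ]
        avg = average_replicates(rollup_to_family(obs))
        counts = dict(zip(avg.cells["family"], avg.cells["count"]))
        assert counts["Sepiidae"] == 2.0
        assert counts["Labridae"] == 0.5

    def test_single_replicate_unchanged(self):
        obs = [make_obs(replicate=1)] * 5
        table = rollup_to_family(obs)
        avg = average_replicates(table)
        assert avg.cells["count"].tolist() == [5.0]

    def test_verification_cells_violate_contract(self):
        obs = [make_obs(site_kind="verification", transect_id=None)]
        with pytest.raises(ContractViolation):
            average_replicates(rollup_to_family(obs))


class TestScopes:
    def test_transect_scope_excludes_verification(self):
        obs = [make_obs()] * 3 + [make_obs(site_kind="verification", transect_id=None)] * 2
        table = rollup_to_family(obs)
        assert sum(pool_counts(table, "transects_only").values()) == 3
        assert sum(pool_counts(table, "all_dives").values()) == 5

    def test_published_counts_reproduced_from_expansion(
        self, published_observations, published_pooled
    ):
        """Expanding the pooled survey table and re-pooling is the identity."""
        table = rollup_to_family(apply_filters(published_observations))
        pooled = pool_counts(table, "all_dives")
        assert pooled == {k: float(v) for k, v in published_pooled.items() if v}

    def test_published_sponging_total_and_whiptail(self, published_observations):
        table = rollup_to_family(published_observations)
        pooled = pool_counts(table, "all_dives")
        sponging_total = sum(v for (f, m), v in pooled.items() if m == "sponging")
        assert sponging_total == 134
        assert pooled.get(("Nemipteridae", "sponging"), 0.0) == 0.0
        assert pooled[("Nemipteridae", "non_sponging")] == 29
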