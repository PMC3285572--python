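import numpy as np
import pytest

from abrkit.consensus import (AlignedAntibodySet, ConsensusError,
                              align_antibody_set, build_column_profiles,
                              derive_abr_boundaries, map_abrs_to_antibody,
                              _merge_runs, _runs_above)
from abrkit.fixtures import FixtureSpec, generate_family

from conftest import rigid_transform_structure


def _single_chain_set(flag_rows, gap_rows=None):
    """An AlignedAntibodySet whose light and heavy chains carry the same
    hand-written contact pattern (list of per-antibody bool rows)."""
    n = len(flag_rows[0])
    ids = [f"ab{i}" for i in range(len(flag_rows))]
    rows, flags = {}, {}
    for role in ("light", "heavy"):
        rows[role] = {}
        flags[role] = {}
        for ab, fr in zip(ids, flag_rows):
            gr = (gap_rows or {}).get(ab, [False] * n)
            rows[role][ab] = [None if g else c for c, g in enumerate(gr)]
            flags[role][ab] = list(fr)
    return AlignedAntibodySet(ids, {"light": n, "heavy": n}, rows, flags)


class TestColumnProfiles:
    def test_single_antibody_fractions(self):
        flags = [[c in (5, 6, 7) for c in range(10)]]
        profiles = build_column_profiles(_single_chain_set(flags))
        light = {p.column: p.contact_fraction for p in profiles
                 if p.chain == "light"}
        assert all(light[c] == 1.0 for c in (5, 6, 7))
        assert all(light[c] == 0.0 for c in range(10) if c not in (5, 6, 7))

    def test_fractions_equal_direct_tally(self):
        rng = np.random.default_rng(0)
        flags = (rng.random((10, 30)) < 0.3).tolist()
        profiles = build_column_profiles(_single_chain_set(flags))
        tally = np.array(flags).sum(axis=0) / 10
        for p in profiles:
            if p.chain == "heavy":
                assert p.contact_fraction == pytest.approx(tally[p.column])

    def test_all_gap_column_zero(self):
        gaps = {"ab0": [True] + [False] * 9}
        flags = [[False] * 10]
        profiles = build_column_profiles(_single_chain_set(flags, gaps))
        p0 = [p for p in profiles if p.chain == "light" and p.column == 0][0]
        assert p0.contact_fraction == 0.0 and p0.occupancy == 0.0

    def test_contact_flag_at_gap_rejected(self):
        gaps = {"ab0": [True] + [False] * 9}
        flags = [[True] + [False] * 9]
        with pytest.raises(ValueError, match="gap column"):
            _single_chain_set(flags, gaps)


def _profiles_from_fractions(fracs):
    flags = []
    n_abs = 10
    for i in range(n_abs):
        flags.append([i < round(f * n_abs) for f in fracs])
    return build_column_profiles(_single_chain_set(flags))


class TestBoundaryDerivation:
    def test_three_separated_runs(self):
        fracs = [0, 0, .5, .6, 0, 0, .3, .4, 0, 0, .9, 0]
        defn = derive_abr_boundaries(_profiles_from_fractions(fracs),
                                     theta=0.10, gap_merge=0)
        assert defn.spans["L1"] == (2, 3)
        assert defn.spans["L2"] == (6, 7)
        assert defn.spans["L3"] == (10, 10)

    def test_threshold_is_inclusive(self):
        # a column at exactly the threshold fraction belongs to a span
        fracs = [0, .5, 0, 0, .1, 0, 0, .5, 0, 0, .5, 0]
        defn = derive_abr_boundaries(_profiles_from_fractions(fracs),
                                     theta=0.10, gap_merge=0,
                                     regions_per_chain=4)
        assert (4, 4) in defn.spans.values() or any(
            s <= 4 <= e for s, e in defn.spans.values())

    def test_too_few_runs_is_error(self):
        fracs = [0, .5, .6, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        with pytest.raises(ConsensusError, match="lower the threshold"):
            derive_abr_boundaries(_profiles_from_fractions(fracs))

    def test_excess_runs_merge_closest(self):
        fracs = [.5, 0, 0, 0, .5, 0, .5, 0, 0, 0, .5, 0]
        defn = derive_abr_boundaries(_profiles_from_fractions(fracs),
                                     gap_merge=0)
        assert defn.spans["L1"] == (0, 0)
        assert defn.spans["L2"] == (4, 6)   # closest pair merged
        assert defn.spans["L3"] == (10, 10)

    def test_gap_merge_bridges_small_gaps(self):
        fracs = [.5, 0, .5, 0, 0, 0, .5, 0, 0, 0, .5]
        defn = derive_abr_boundaries(_profiles_from_fractions(fracs),
                                     gap_merge=1)
        assert defn.spans["L1"] == (0, 2)
        assert defn.spans["L2"] == (6, 6)
        assert defn.spans["L3"] == (10, 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_theta_monotonicity_of_runs(self, seed):
        rng = np.random.default_rng(seed)
        fracs = rng.random(40).round(2).tolist()
        for t1, t2 in [(0.1, 0.3), (0.2, 0.6)]:
            cols1 = {c for s, e in _runs_above(fracs, t1)
                     for c in range(s, e + 1)}
            cols2 = {c for s, e in _runs_above(fracs, t2)
                     for c in range(s, e + 1)}
            assert cols2 <= cols1

    def test_merge_runs_respects_gap(self):
        assert _merge_runs([(0, 1), (4, 5)], 2) == [(0, 5)]
        assert _merge_runs([(0, 1), (5, 6)], 2) == [(0, 1), (5, 6)]


class TestProjection:
    def _defn(self, fracs):
        return derive_abr_boundaries(_profiles_from_fractions(fracs),
                                     gap_merge=0)

    def test_ungapped_row_identity(self):
        fracs = [0, 0, .5, .6, 0, 0, .3, .4, 0, 0, .9, 0]
        defn = self._defn(fracs)
        rows = {r: list(range(12)) for r in ("light", "heavy")}
        ann = map_abrs_to_antibody(defn, rows, "q")
        assert ann.spans["L1"] == (2, 3)
        assert ann.spans["H3"] == (10, 10)

    def test_gaps_before_span_shift_projection(self):
        fracs = [0, 0, .5, .6, 0, 0, .3, .4, 0, 0, .9, 0]
        defn = self._defn(fracs)
        row = [None, None] + list(range(10))   # 2 leading gap columns
        rows = {"light": row, "heavy": list(range(12))}
        ann = map_abrs_to_antibody(defn, rows, "q")
        assert ann.spans["L1"] == (0, 1)       # shifted by -2

    def test_fully_gapped_region_is_empty_and_flagged(self):
        fracs = [0, 0, .5, .6, 0, 0, .3, .4, 0, 0, .9, 0]
        defn = self._defn(fracs)
        row = list(range(10)) + [None, None]   # H3 columns gapped
        rows = {"light": list(range(12)), "heavy": row}
        ann = map_abrs_to_antibody(defn, rows, "q")
        assert ann.spans["H3"] is None
        assert "H3" in ann.meta["empty_regions"]

    def test_round_trip_on_ungapped_rows(self):
        fracs = [0, 0, .5, .6, 0, 0, .3, .4, 0, 0, .9, 0]
        defn = self._defn(fracs)
        rows = {r: list(range(12)) for r in ("light", "heavy")}
        ann = map_abrs_to_antibody(defn, rows, "q")
        lifted = {k: v for k, v in ann.spans.items() if v is not None}
        assert all(lifted[k] == defn.spans[k] for k in lifted)

    def test_column_count_mismatch_rejected(self):
        fracs = [0, 0, .5, .6, 0, 0, .3, .4, 0, 0, .9, 0]
        defn = self._defn(fracs)
        defn.provenance["n_columns"] = {"light": 12, "heavy": 12}
        rows = {"light": list(range(11)), "heavy": list(range(12))}
        with pytest.raises(ConsensusError, match="column count mismatch"):
            map_abrs_to_antibody(defn, rows, "q")


class TestStructuralAlignment:
    def test_identical_structures_align_identity(self, family):
        a = family.members[0].structure
        b = family.members[1].structure
        aligned = align_antibody_set([a, b])
        for role in ("light", "heavy"):
            ra = aligned.rows[role][a.pdb_id]
            rb = aligned.rows[role][b.pdb_id]
            assert ra == rb == [c for c in range(len(ra))]

    def test_rigid_rotation_invariance(self, family):
        rng = np.random.default_rng(3)
        a = family.members[0].structure
        b = family.members[1].structure
        moved = rigid_transform_structure(b, rng)
        ref = align_antibody_set([a, b])
        rot = align_antibody_set([a, moved])
        assert ref.rows == rot.rows

    def test_planted_insertion_gets_dedicated_columns(self):
        fam = generate_family(FixtureSpec(seed=11, indel=("H3", 2)), n=5)
        aligned = align_antibody_set([m.structure for m in fam.members])
        assert aligned.n_columns == fam.n_columns
        for m in fam.members:
            for role in ("light", "heavy"):
                assert aligned.rows[role][m.ab_id] == m.rows[role]

    def test_short_chain_rejected(self, family):
        from abrkit.structure_io import Chain, ComplexStructure
        s = family.members[0].structure
        stub = ComplexStructure(
            "stub", Chain("H", s.heavy.residues[:50]), s.light, s.antigen)
        with pytest.raises(ConsensusError, match="too short to anchor"):
            align_antibody_set([stub, family.members[1].structure])


class TestFamilyRecovery:
    @pytest.mark.parametrize("seed", [7, 42, 123])
    def test_exact_boundary_recovery(self, seed):
        # inside/outside contact densities 0.5 / 0.02, threshold 0.10
        fam = generate_family(FixtureSpec(seed=seed), n=20)
        aligned = align_antibody_set([m.structure for m in fam.members])
        defn = derive_abr_boundaries(build_column_profiles(aligned),
                                     theta=0.10)
        assert defn.spans == fam.column_spans

    def test_projection_matches_planted_spans(self, family, fitted_model):
        for m in family.members:
            rows = {r: fitted_model.aligned_.rows[r][m.ab_id]
                    for r in ("light", "heavy")}
            ann = map_abrs_to_antibody(fitted_model.definition_, rows,
                                       m.ab_id)
            assert ann.spans == m.annotation.spans
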