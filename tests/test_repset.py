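"""Representative selection: cross-group identity scoring, the two-phase
procedure, determinism and phase-1 optimality."""

import numpy as np
import pytest

from mhcdiv.allele_io import AlleleRecord, parse_allele_name
from mhcdiv.repset import (
    GroupedAlleles,
    group_alleles,
    mean_cross_group_identity,
    select_representatives,
)


def rec(raw: str, seq: str) -> AlleleRecord:
    return AlleleRecord(parse_allele_name(raw), protein=seq, aligned=True)


def make_grouped(locus: str, by_group: dict[str, dict[str, str]]) -> GroupedAlleles:
    groups = {
        gid: [rec(raw, seq) for raw, seq in members.items()]
        for gid, members in by_group.items()
    }
    return GroupedAlleles(locus=locus, groups=groups)


class TestIdentity:
    def test_identical(self):
        assert mean_cross_group_identity("AAAA", ["AAAA"]) == 1.0

    def test_half_different(self):
        a = "A" * 91 + "C" * 91
        b = "A" * 182
        assert mean_cross_group_identity(a, [b]) == pytest.approx(0.5)

    def test_gap_columns_excluded(self):
        assert mean_cross_group_identity("AA-C", ["AATC"]) == pytest.approx(1.0)

    def test_empty_others(self):
        with pytest.raises(ValueError):
            mean_cross_group_identity("AAAA", [])


class TestSelection:
    def test_one_per_group_when_groups_match_target(self):
        by_group = {
            f"{g:02d}": {f"X-1*{g:02d}:01": "AC" + format(g, "02d")} for g in range(1, 21)
        }
        rs = select_representatives(make_grouped("X-1", by_group), target=20)
        assert len(rs.chosen) == 20
        assert all(phase == 1 for _, _, phase, _, _ in rs.provenance)
        assert len({r.name.group for r in rs.chosen}) == 20

    def test_phase1_picks_most_divergent_member(self):
        # a is identical to the other group's c; b differs at 10% of columns
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        c = "A" * 100
        rs = select_representatives(
            make_grouped(
                "X-1", {"01": {"X-1*01:01": a, "X-1*01:02": b}, "02": {"X-1*02:01": c}}
            ),
            target=2,
        )
        picked_g1 = next(r for r in rs.chosen if r.name.group == "01")
        assert picked_g1.name.raw == "X-1*01:02"  # the divergent allele b

    def test_phase2_pads_from_redundant_groups(self):
        rng = np.random.default_rng(5)
        by_group = {}
        for g in range(1, 16):
            members = {}
            for p in range(1, 3):
                members[f"X-1*{g:02d}:{p:02d}"] = "".join(
                    rng.choice(list("ACDE"), 30)
                )
            by_group[f"{g:02d}"] = members
        rs = select_representatives(make_grouped("X-1", by_group), target=20)
        assert len(rs.chosen) == 20
        groups_used = [r.name.group for r in rs.chosen]
        assert any(groups_used.count(g) >= 2 for g in set(groups_used))
        assert sum(1 for _, _, phase, _, _ in rs.provenance if phase == 2) == 5
        assert len({r.name.raw for r in rs.chosen}) == 20  # no duplicates

    def test_target_below_groups_requires_flag(self):
        by_group = {f"{g:02d}": {f"X-1*{g:02d}:01": "ACGT"} for g in range(1, 6)}
        grouped = make_grouped("X-1", by_group)
        with pytest.raises(ValueError, match="subsample"):
            select_representatives(grouped, target=3)
        rs = select_representatives(grouped, target=3, allow_subsample=True)
        assert len(rs.chosen) == 3

    def test_deterministic_double_run(self, rng):
        by_group = {}
        for g in range(1, 11):
            members = {}
            for p in range(1, 4):
                members[f"X-1*{g:02d}:{p:02d}"] = "".join(rng.choice(list("ACDEFG"), 40))
            by_group[f"{g:02d}"] = members
        grouped = make_grouped("X-1", by_group)
        rs1 = select_representatives(grouped, target=15)
        rs2 = select_representatives(grouped, target=15)
        assert [r.name.raw for r in rs1.chosen] == [r.name.raw for r in rs2.chosen]
        assert rs1.provenance == rs2.provenance

    def test_phase1_optimality_exhaustive(self, rng):
        """No group member scores strictly lower than the chosen one."""
        by_group = {}
        for g in range(1, 5):
            members = {}
            for p in range(1, 4):
                members[f"X-1*{g:02d}:{p:02d}"] = "".join(rng.choice(list("ACDE"), 25))
            by_group[f"{g:02d}"] = members
        grouped = make_grouped("X-1", by_group)
        rs = select_representatives(grouped, target=4)
        chosen_by_group = {r.name.group: r for r in rs.chosen}
        for gid, members in grouped.groups.items():
            others = [
                m.protein
                for og, ms in grouped.groups.items()
                if og != gid
                for m in ms
            ]
            scores = {
                m.name.raw: mean_cross_group_identity(m.protein, others)
                for m in members
            }
            best = min(scores.values())
            assert scores[chosen_by_group[gid].name.raw] == pytest.approx(best)

    def test_duplicate_allele_does_not_change_selection(self, rng):
        by_group = {}
        for g in range(1, 4):
            members = {}
            for p in range(1, 3):
                members[f"X-1*{g:02d}:{p:02d}"] = "".join(rng.choice(list("ACDE"), 25))
            by_group[f"{g:02d}"] = members
        grouped = make_grouped("X-1", by_group)
        rs1 = select_representatives(grouped, target=3)
        # add an exact copy (new name) of an already-present allele
        dup_of = grouped.groups["01"][0]
        by_group2 = {g: dict(m) for g, m in by_group.items()}
        by_group2["01"]["X-1*01:99"] = dup_of.protein
        rs2 = select_representatives(make_grouped("X-1", by_group2), target=3)
        assert [r.name.raw for r in rs1.chosen] == [r.name.raw for r in rs2.chosen]


class TestGrouping:
    def test_group_alleles_partitions_by_locus_and_group(self):
        records = [
            rec("SLA-1*01:01", "AAAA"),
            rec("SLA-1*01:02", "AAAC"),
            rec("SLA-1*02:01", "AACC"),
            rec("SLA-2*01:01", "ACCC"),
        ]
        grouped = group_alleles(records)
        assert [g.locus for g in grouped] == ["SLA-1", "SLA-2"]
        assert sorted(grouped[0].groups) == ["01", "02"]
        assert grouped[0].n_alleles == 3

    def test_misfiled_record_rejected(self):
        with pytest.raises(ValueError, match="belong"):
            GroupedAlleles(locus="SLA-1", groups={"01": [rec("SLA-2*01:01", "AA")]})
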