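"""Fragment placement, empirical scoring, and score-table I/O."""

import numpy as np
import pytest

from confsel.align import place_anchor
from confsel.docking import (Fragment, PoseRecord, ScoreWeights, builtin_fragment,
                             place_fragment, pocket_axis, read_score_table,
                             score_pose, write_score_table, records_to_table,
                             table_to_records)
from confsel.errors import ConfselError, InvalidConfigError, ScoreTableError
from confsel.frames import ConformationFrame
from confsel.synthetic import build_scaffold, generate_reference_complex, scaffold_n_atoms


@pytest.fixture(scope="module")
def reference():
    return generate_reference_complex()


def dock(frame, fragment_name, reference, **kwargs):
    anchor = place_anchor(reference, frame)
    return place_fragment(frame, anchor, builtin_fragment(fragment_name), **kwargs)


class TestPlacement:
    def test_fully_closed_frame_is_unplaced(self, closed_frame, reference):
        assert not dock(closed_frame, "AM-2", reference).placed

    def test_fully_open_frame_binds_deep(self, open_frame, reference):
        record = dock(open_frame, "AM-2", reference)
        assert record.placed
        assert record.key_distance < 5.0

    def test_intermediate_frame_excludes_bulky_but_not_small(self, intermediate_frame, reference):
        bulky = dock(intermediate_frame, "AM-6", reference)
        small = dock(intermediate_frame, "AM-2", reference)
        assert not bulky.placed
        assert small.placed
        assert small.key_distance >= 5.0          # shallow only

    def test_bulky_fragment_binds_deep_when_fully_open(self, open_frame, reference):
        record = dock(open_frame, "AM-6", reference)
        assert record.placed and record.key_distance < 5.0

    def test_deterministic(self, open_frame, reference):
        a = dock(open_frame, "AM-5", reference)
        b = dock(open_frame, "AM-5", reference)
        assert a.score == b.score and a.depth == b.depth
        assert np.array_equal(a.coords, b.coords)

    def test_unusable_anchor_reports_unplaced(self, open_frame, reference):
        anchor = place_anchor(reference, open_frame)
        anchor.usable = False
        record = place_fragment(open_frame, anchor, builtin_fragment("AM-2"))
        assert not record.placed

    def test_missing_anchor_is_an_error(self, open_frame):
        with pytest.raises(ConfselError):
            place_fragment(open_frame, None, builtin_fragment("AM-2"))

    def test_monotone_gating_never_unplaces_on_widening(self, reference):
        """Widening the aperture can only help placement, per fragment."""
        for name in ("AM-2", "AM-6"):
            placed_before = False
            for gating in np.arange(3.5, 9.01, 0.25):
                placed = dock(build_scaffold(gating), name, reference).placed
                assert not (placed_before and not placed), (
                    f"{name}: placement lost when widening to {gating} Å"
                )
                placed_before = placed

    def test_matches_exhaustive_enumeration(self, reference, rng):
        """Sweep selection equals a naive per-depth argmax (ties → deepest)."""
        weights = ScoreWeights()
        step = 0.25
        for _ in range(25):
            gating = rng.uniform(4.0, 9.0)
            frame = build_scaffold(gating, 0.05 * rng.standard_normal((scaffold_n_atoms(), 3)))
            anchor = place_anchor(reference, frame)
            fragment = builtin_fragment(rng.choice(["AM-2", "AM-5", "AM-6"]))
            record = place_fragment(frame, anchor, fragment, weights, step=step)

            best = None
            env = frame.coords[np.isin(frame.res_names, ("POC", "BOT", "LEU"))]
            radii = np.array([{"POC": 1.1, "BOT": 1.4, "LEU": 1.3}[r]
                              for r in frame.res_names[np.isin(frame.res_names,
                                                               ("POC", "BOT", "LEU"))]])
            zinc, axis = pocket_axis(frame)
            seed_vec = np.array([1.0, 0, 0]) if abs(axis @ [1.0, 0, 0]) <= 0.9 else np.array([0, 1.0, 0])
            u = np.cross(axis, seed_vec); u /= np.linalg.norm(u)
            v = np.cross(axis, u)
            for depth in np.arange(3.0, 9.0 + step / 2, step):
                local = fragment.local_coords
                pose = (zinc + np.outer(depth - local[:, 2], axis)
                        + np.outer(local[:, 0], u) + np.outer(local[:, 1], v))
                dist = np.linalg.norm(pose[:, None] - env[None], axis=2)
                if (dist < fragment.radius + radii[None, :]).any():
                    continue
                s = score_pose(pose, frame, weights, fragment)
                if best is None or s >= best[0]:
                    best = (s, depth)
            if best is None:
                assert not record.placed
            else:
                assert record.placed
                assert record.score == pytest.approx(best[0])
                assert record.depth == pytest.approx(best[1])


class TestScorePose:
    @staticmethod
    def _bare_frame(extra_pocket=(), key_o=None):
        """Minimal frame: zinc + an axis-defining lining + optional extras."""
        names, resnames, resids, coords = ["ZN"], ["ZN"], [1], [(0.0, 0.0, 0.0)]
        # axis-defining lining atoms, far from everything in x/y
        for i, pos in enumerate([(40.0, 0, -6.0), (-40.0, 0, -6.0)]):
            names.append("C1"); resnames.append("POC"); resids.append(7 + i)
            coords.append(pos)
        for i, pos in enumerate(extra_pocket):
            names.append("C1"); resnames.append("POC"); resids.append(30 + i)
            coords.append(pos)
        if key_o is not None:
            names.append("O"); resnames.append("LEU"); resids.append(5)
            coords.append(key_o)
        return ConformationFrame(names, resnames, resids, np.array(coords, dtype=float))

    def test_isolated_fragment_scores_base(self):
        frame = self._bare_frame()
        fragment = Fragment("probe", [(0.0, 0.0, 0.0)], [True], n_rotatable=0)
        weights = ScoreWeights(base=123.0)
        pose = np.array([[0.0, 0.0, -5.0]])
        assert score_pose(pose, frame, weights, fragment) == 123.0

    def test_one_contact_adds_exactly_w_contact(self):
        fragment = Fragment("probe", [(0.0, 0.0, 0.0)], [True], n_rotatable=0)
        weights = ScoreWeights(base=0.0, w_contact=30.0)
        pose = np.array([[0.0, 0.0, -6.0]])
        without = score_pose(pose, self._bare_frame(), weights, fragment)
        with_contact = score_pose(
            pose, self._bare_frame(extra_pocket=[(0.0, 3.0, -6.0)]), weights, fragment)
        assert with_contact - without == 30.0

    def test_hand_built_pose_arithmetic(self):
        """12 contacts, 1 H-bond proxy, 3 rotatable bonds:
        200 + 12·30 + 80 − 3·20 = 580."""
        lip_pos = np.array([0.0, 0.0, -6.0])
        ring = [(lip_pos + 3.0 * np.array([np.cos(a), np.sin(a), 0.0]))
                for a in np.linspace(0, 2 * np.pi, 12, endpoint=False)]
        frame = self._bare_frame(extra_pocket=ring, key_o=(0.0, 2.0, -8.0))
        fragment = Fragment("probe", [(0.0, 0.0, 0.0), (0.0, 0.0, 1.0)],
                            [False, True], n_rotatable=3)
        # pose: tip within 3.5 Å of the key O, lipophilic atom at the ring centre
        pose = np.array([[0.0, 0.0, -7.0], lip_pos])
        weights = ScoreWeights(base=200.0, w_contact=30.0, w_hbond=80.0, w_rot=20.0)
        assert score_pose(pose, frame, weights, fragment) == 580.0

    def test_shallow_lining_atoms_earn_nothing(self):
        # a contact above the burial depth is solvent-exposed: no reward
        fragment = Fragment("probe", [(0.0, 0.0, 0.0)], [True], n_rotatable=0)
        weights = ScoreWeights(base=0.0, w_contact=30.0)
        frame = self._bare_frame(extra_pocket=[(0.0, 3.0, -2.0)])
        assert score_pose(np.array([[0.0, 0.0, -2.0]]), frame, weights, fragment) == 0.0


class TestPoseRecordInvariants:
    def test_unplaced_record_rejects_score(self):
        with pytest.raises(InvalidConfigError):
            PoseRecord(frame_index=0, placed=False, score=10.0)

    def test_negative_key_distance_rejected(self):
        with pytest.raises(InvalidConfigError):
            PoseRecord(frame_index=0, placed=True, score=1.0, key_distance=-0.5)


class TestScoreTables:
    @staticmethod
    def records():
        return [
            PoseRecord(0, True, score=580.0, key_distance=3.2),
            PoseRecord(1, False),
            PoseRecord(2, True, score=312.5, key_distance=6.75),
        ]

    def test_round_trip_is_byte_identical(self, tmp_path):
        first = tmp_path / "scores.tsv"
        second = tmp_path / "again.tsv"
        write_score_table(self.records(), first)
        write_score_table(read_score_table(first), second)
        assert first.read_bytes() == second.read_bytes()

    def test_round_trip_preserves_values(self, tmp_path):
        path = tmp_path / "scores.tsv"
        write_score_table(self.records(), path)
        back = read_score_table(path)
        assert [r.placed for r in back] == [True, False, True]
        assert back[0].score == 580.0 and back[2].key_distance == 6.75
        assert back[1].score is None

    def test_duplicate_frame_index_names_row(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "frame_index\tplaced\tscore\tkey_distance\n"
            "7\t1\t500.0\t3.0\n"
            "7\t1\t400.0\t3.0\n"
        )
        with pytest.raises(ScoreTableError, match="row 3.*duplicate frame index 7"):
            read_score_table(path)

    def test_non_numeric_score_on_placed_row_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "frame_index\tplaced\tscore\tkey_distance\n"
            "0\t1\thigh\t3.0\n"
        )
        with pytest.raises(ScoreTableError, match="row 2"):
            read_score_table(path)

    def test_header_only_file_yields_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("frame_index\tplaced\tscore\tkey_distance\n")
        assert read_score_table(path) == []

    def test_records_table_round_trip(self):
        table = records_to_table(self.records())
        back = table_to_records(table)
        assert [(r.frame_index, r.placed, r.score) for r in back] == [
            (0, True, 580.0), (1, False, None), (2, True, 312.5)]
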