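"""Anchored fragment placement and empirical scoring (docking stand-in).

This is explicitly **not** a re-implementation of any commercial docking
engine.  It is a transparent surrogate with the same interface contract:
a fragment extends rigidly from the anchor link site along the pocket
axis, candidate insertion depths are screened for steric clashes against
the pocket lining, and the best clash-free depth under a simple
Böhm-style additive score is kept.  The score is

    score = base
          + w_contact · (buried lipophilic contact pairs)
          + w_hbond   · (hydrogen-bond proxy pairs)
          − w_rot     · n_rotatable

with a saturation cap on the contact count (buried surface saturates for
bulky fragments).  Default weights are chosen so that deep poses land
in the upper few-hundreds score band and superficial poses around
~300, the bands in which empirical fragment-docking scores of
strong/weak binding typically print for this system class.

Externally computed per-frame score tables can be ingested instead, so
real docking output can drive the downstream statistics unchanged.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AnchorPose
from .errors import ConfselError, InvalidConfigError, ScoreTableError
from .frames import AtomDescriptor, ConformationFrame
from .synthetic import KEY_OXYGEN_DESCRIPTOR

__all__ = [
    "Fragment",
    "ScoreWeights",
    "PoseRecord",
    "builtin_fragment",
    "BUILTIN_FRAGMENTS",
    "place_fragment",
    "score_pose",
    "pocket_axis",
    "read_score_table",
    "write_score_table",
    "records_to_table",
    "table_to_records",
]

# effective radii (Å) of receptor pseudo-atoms, by residue name
_POCKET_RADII = {"POC": 1.1, "BOT": 1.4, "LEU": 1.3}
_CLASH_RESNAMES = ("POC", "BOT", "LEU")     # zinc/His/anchor are the bonded
                                            # linker region: excluded from clash
_CONTACT_RESNAMES = ("POC", "BOT")


@dataclass(frozen=True)
class Fragment:
    """Rigid pseudo-fragment in the anchor-local frame.

    ``local_coords`` rows are (dx, dy, dz) with dz the height of the
    atom above the fragment tip (tip at the origin, inserted first).
    ``lipophilic`` flags the atoms whose burial earns contact score.
    """

    name: str
    local_coords: np.ndarray
    lipophilic: np.ndarray
    radius: float = 1.2
    n_rotatable: int = 3
    bulk: int = 1

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.local_coords, dtype=float))
        object.__setattr__(self, "local_coords", coords)
        object.__setattr__(self, "lipophilic", np.asarray(self.lipophilic, dtype=bool))
        if coords.shape[0] < 1 or coords.shape[1] != 3:
            raise InvalidConfigError("a fragment needs >= 1 atom with 3 coordinates")
        if len(self.lipophilic) != coords.shape[0]:
            raise InvalidConfigError("lipophilic mask must match the atom count")
        if self.radius <= 0:
            raise InvalidConfigError("fragment radius must be positive")

    @property
    def n_atoms(self) -> int:
        return self.local_coords.shape[0]


def _biphenyl() -> Fragment:
    # slim axial shaft (linker + first ring) with a lateral second ring
    return Fragment(
        name="AM-2",
        local_coords=[
            (0.0, 0.0, 0.0),     # tip (H-bond acceptor proxy)
            (0.0, 0.0, 1.5),
            (0.85, 0.0, 2.25),
            (-0.85, 0.0, 2.25),
        ],
        lipophilic=[False, False, True, True],
        n_rotatable=3,
        bulk=1,
    )


def _biphenyl_cyanide() -> Fragment:
    frag = _biphenyl()
    coords = np.vstack([frag.local_coords, [(0.0, 0.0, 0.75)]])
    lip = np.append(frag.lipophilic, False)
    return Fragment("AM-5", coords, lip, n_rotatable=3, bulk=1)


def _triphenyl() -> Fragment:
    # bulky along its whole length: wide near the tip as well as the base
    return Fragment(
        name="AM-6",
        local_coords=[
            (0.0, 0.0, 0.0),
            (0.0, 0.0, 1.5),
            (1.25, 0.0, 0.75),
            (-1.25, 0.0, 0.75),
            (1.25, 0.0, 2.25),
            (-1.25, 0.0, 2.25),
        ],
        lipophilic=[False, False, True, True, True, True],
        n_rotatable=3,
        bulk=3,
    )


BUILTIN_FRAGMENTS = {
    "AM-2": _biphenyl,
    "AM-5": _biphenyl_cyanide,
    "AM-6": _triphenyl,
}


def builtin_fragment(name: str) -> Fragment:
    """The three composite-inhibitor fragments: biphenyl (AM-2),
    biphenyl cyanide (AM-5), triphenyl (AM-6)."""
    try:
        return BUILTIN_FRAGMENTS[name]()
    except KeyError:
        raise InvalidConfigError(f"unknown fragment {name!r}; have {sorted(BUILTIN_FRAGMENTS)}")


@dataclass(frozen=True)
class ScoreWeights:
    """Additive empirical score parameters (score units)."""

    base: float = 250.0
    w_contact: float = 30.0
    w_hbond: float = 100.0
    w_rot: float = 10.0
    contact_margin: float = 1.4      # Å beyond radii-sum counted as contact
    contact_cap: int = 14            # lipophilic term saturates here
    hbond_cutoff: float = 3.5        # Å, tip-to-key-oxygen proxy
    burial_min_depth: float = 4.5    # Å along the axis; shallower lining
                                     # atoms are solvent-exposed, no reward

    def __post_init__(self) -> None:
        if min(self.w_contact, self.w_hbond, self.w_rot) < 0:
            raise InvalidConfigError("score weights must be non-negative")


@dataclass
class PoseRecord:
    """Outcome of one frame's placement attempt."""

    frame_index: int
    placed: bool
    score: float | None = None
    key_distance: float | None = None
    depth: float | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.placed and (self.score is not None or self.key_distance is not None):
            raise InvalidConfigError("an unplaced record cannot carry a score or key distance")
        if self.key_distance is not None and self.key_distance < 0:
            raise InvalidConfigError("key_distance must be >= 0")


# ---------------------------------------------------------------------------
# geometry


def pocket_axis(frame: ConformationFrame) -> tuple[np.ndarray, np.ndarray]:
    """(zinc position, unit axis pointing down the pocket).

    The axis is the line from the catalytic zinc through the centroid of
    the pocket-lining atoms.
    """
    zinc = frame.atom_coord(("ZN", 1, "ZN"))
    lining = frame.coords[frame.residue_mask("POC")]
    if lining.shape[0] == 0:
        raise ConfselError("frame has no pocket-lining (POC) atoms to define an axis")
    direction = lining.mean(axis=0) - zinc
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ConfselError("degenerate pocket axis")
    return zinc, direction / norm


def _axis_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seed = np.array([1.0, 0.0, 0.0])
    if abs(axis @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, seed)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _fragment_world(fragment: Fragment, zinc, axis, u, v, depth: float) -> np.ndarray:
    local = fragment.local_coords
    return (
        zinc
        + np.outer(depth - local[:, 2], axis)
        + np.outer(local[:, 0], u)
        + np.outer(local[:, 1], v)
    )


def _clash_environment(frame: ConformationFrame):
    mask = np.isin(frame.res_names, _CLASH_RESNAMES)
    coords = frame.coords[mask]
    radii = np.array([_POCKET_RADII[r] for r in frame.res_names[mask]])
    return coords, radii


# ---------------------------------------------------------------------------
# placement and scoring


def score_pose(
    pose_coords: np.ndarray,
    frame: ConformationFrame,
    weights: ScoreWeights,
    fragment: Fragment,
    key_atom: AtomDescriptor = KEY_OXYGEN_DESCRIPTOR,
) -> float:
    """Deterministic additive score of a placed pose (see module docs)."""
    zinc, axis = pocket_axis(frame)

    mask = np.isin(frame.res_names, _CONTACT_RESNAMES)
    lining = frame.coords[mask]
    radii = np.array([_POCKET_RADII[r] for r in frame.res_names[mask]])
    depth_along_axis = (lining - zinc) @ axis
    buried = depth_along_axis >= weights.burial_min_depth

    n_contacts = 0
    if buried.any() and fragment.lipophilic.any():
        lip = pose_coords[fragment.lipophilic]
        d = np.linalg.norm(lip[:, None, :] - lining[None, buried, :], axis=2)
        shell = fragment.radius + radii[buried][None, :] + weights.contact_margin
        n_contacts = int(np.count_nonzero(d < shell))
    n_contacts = min(n_contacts, weights.contact_cap)

    n_hbond = 0
    try:
        key = frame.atom_coord(key_atom)
        if np.linalg.norm(pose_coords[0] - key) < weights.hbond_cutoff:
            n_hbond = 1
    except ConfselError:
        pass   # no key oxygen in this frame: no H-bond proxy available

    return float(
        weights.base
        + weights.w_contact * n_contacts
        + weights.w_hbond * n_hbond
        - weights.w_rot * fragment.n_rotatable
    )


def place_fragment(
    frame: ConformationFrame,
    anchor: AnchorPose,
    fragment: Fragment,
    weights: ScoreWeights | None = None,
    step: float = 0.25,
    depth_range: tuple[float, float] = (3.0, 9.0),
    key_atom: AtomDescriptor = KEY_OXYGEN_DESCRIPTOR,
    frame_index: int = 0,
) -> PoseRecord:
    """Sweep the fragment down the pocket axis and keep the best pose.

    Depths are measured from the zinc along the pocket axis (the anchor
    link site sits on that axis) and enumerated in increments of
    ``step`` over ``depth_range``; any candidate with a fragment–pocket
    pairwise distance below the radii sum is rejected.  Among clash-free
    candidates the highest-scoring pose wins, ties going to the deepest
    (the deep binding mode is the physically favoured one).  If no
    candidate survives — or the anchor was unusable — the frame is
    reported unplaced.
    """
    if anchor is None:
        raise ConfselError("place_fragment requires a placed anchor")
    if weights is None:
        weights = ScoreWeights()
    if step <= 0:
        raise InvalidConfigError("step must be positive")
    if not anchor.usable:
        return PoseRecord(frame_index=frame_index, placed=False)

    zinc, axis = pocket_axis(frame)
    u, v = _axis_basis(axis)
    env_coords, env_radii = _clash_environment(frame)

    depths = np.arange(depth_range[0], depth_range[1] + 0.5 * step, step)
    local = fragment.local_coords
    # all candidate poses at once: (depths, atoms, 3)
    world = (
        zinc[None, None, :]
        + (depths[:, None] - local[None, :, 2])[:, :, None] * axis[None, None, :]
        + (local[:, 0][None, :, None] * u[None, None, :])
        + (local[:, 1][None, :, None] * v[None, None, :])
    )
    dists = np.linalg.norm(world[:, :, None, :] - env_coords[None, None, :, :], axis=3)
    clash = (dists < fragment.radius + env_radii[None, None, :]).any(axis=(1, 2))
    if clash.all():
        return PoseRecord(frame_index=frame_index, placed=False)

    # vectorized scoring over all depths (identical to score_pose per pose)
    contact_mask = np.isin(frame.res_names, _CONTACT_RESNAMES)
    lining = frame.coords[contact_mask]
    lining_radii = np.array([_POCKET_RADII[r] for r in frame.res_names[contact_mask]])
    buried = (lining - zinc) @ axis >= weights.burial_min_depth

    contacts = np.zeros(len(depths), dtype=int)
    if buried.any() and fragment.lipophilic.any():
        lip_world = world[:, fragment.lipophilic, :]
        d = np.linalg.norm(
            lip_world[:, :, None, :] - lining[None, None, buried, :], axis=3
        )
        shell = fragment.radius + lining_radii[buried][None, None, :] + weights.contact_margin
        contacts = np.count_nonzero(d < shell, axis=(1, 2))
    contacts = np.minimum(contacts, weights.contact_cap)

    hbond = np.zeros(len(depths), dtype=int)
    try:
        key = frame.atom_coord(key_atom)
        hbond = (np.linalg.norm(world[:, 0, :] - key, axis=1) < weights.hbond_cutoff).astype(int)
    except ConfselError:
        pass

    scores = (
        weights.base
        + weights.w_contact * contacts
        + weights.w_hbond * hbond
        - weights.w_rot * fragment.n_rotatable
    )

    ok = np.flatnonzero(~clash)
    best_score = scores[ok].max()
    winner = ok[np.flatnonzero(scores[ok] == best_score)[-1]]   # ties → deepest
    score, depth, pose = float(best_score), float(depths[winner]), world[winner]
    key_distance = None
    try:
        key = frame.atom_coord(key_atom)
        key_distance = float(np.min(np.linalg.norm(pose - key, axis=1)))
    except ConfselError:
        pass
    return PoseRecord(
        frame_index=frame_index,
        placed=True,
        score=score,
        key_distance=key_distance,
        depth=depth,
        coords=pose,
    )


# ---------------------------------------------------------------------------
# score tables

_TABLE_COLUMNS = ["frame_index", "placed", "score", "key_distance"]


def records_to_table(records: list[PoseRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "frame_index": r.frame_index,
            "placed": int(r.placed),
            "score": np.nan if r.score is None else r.score,
            "key_distance": np.nan if r.key_distance is None else r.key_distance,
        })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def table_to_records(table: pd.DataFrame) -> list[PoseRecord]:
    records = []
    for row in table.itertuples(index=False):
        placed = bool(int(row.placed))
        score = getattr(row, "score", np.nan)
        key = getattr(row, "key_distance", np.nan)
        records.append(PoseRecord(
            frame_index=int(row.frame_index),
            placed=placed,
            score=None if (not placed or pd.isna(score)) else float(score),
            key_distance=None if (not placed or pd.isna(key)) else float(key),
        ))
    return records


def write_score_table(records: list[PoseRecord] | pd.DataFrame, path: str | os.PathLike) -> None:
    """Headered tab-delimited score table (NA for absent values)."""
    table = records if isinstance(records, pd.DataFrame) else records_to_table(records)
    table = table[_TABLE_COLUMNS].copy()
    with open(path, "w") as handle:
        handle.write("\t".join(_TABLE_COLUMNS) + "\n")
        for row in table.itertuples(index=False):
            score = "NA" if pd.isna(row.score) else f"{row.score:.4f}"
            key = "NA" if pd.isna(row.key_distance) else f"{row.key_distance:.4f}"
            handle.write(f"{int(row.frame_index)}\t{int(row.placed)}\t{score}\t{key}\n")


def read_score_table(path: str | os.PathLike) -> list[PoseRecord]:
    """Read an external per-frame score table.

    Expects a header with at least ``frame_index`` and ``placed``
    columns plus ``score`` (and optionally ``key_distance``); frame
    indices must be unique and placed rows must carry a numeric score.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("frame_index", "placed", "score") if c not in table.columns]
    if missing:
        raise ScoreTableError(f"score table is missing columns {missing}")

    records = []
    seen: dict[int, int] = {}
    for pos, row in enumerate(table.itertuples(index=False), start=2):  # data rows start at line 2
        try:
            index = int(row.frame_index)
        except ValueError:
            raise ScoreTableError(f"row {pos}: non-integer frame_index {row.frame_index!r}")
        if index in seen:
            raise ScoreTableError(
                f"row {pos}: duplicate frame index {index} (first seen at row {seen[index]})"
            )
        seen[index] = pos
        placed = str(row.placed).strip().lower() in ("1", "true", "t", "yes")
        score = key = None
        if placed:
            try:
                score = float(row.score)
            except ValueError:
                raise ScoreTableError(f"row {pos}: non-numeric score {row.score!r} on a placed row")
            raw_key = getattr(row, "key_distance", "NA")
            if raw_key not in ("", "NA", "nan"):
                try:
                    key = float(raw_key)
                except ValueError:
                    raise ScoreTableError(f"row {pos}: non-numeric key_distance {raw_key!r}")
        records.append(PoseRecord(frame_index=index, placed=placed,
                                  score=score, key_distance=key))
    return records
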