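"""Synthetic active-site ensembles with controllable pocket gating.

The generator emulates the two dynamic regimes seen in zinc-protease
S1′ pockets so every downstream stage (alignment, anchored placement,
binding-mode classification, ensemble statistics) is testable without MD
trajectories or a commercial docking engine:

* ``two_state`` — the pocket is almost always either fully closed or
  fully open, with few intermediates (stromelysin-like, MMP-3).  Gating
  distances are a two-component Gaussian mixture.
* ``continuous`` — the pocket breathes through a continuum of
  intermediate apertures and is only rarely fully open (gelatinase-like,
  MMP-2).  Gating distances follow a Beta-shaped law on a closed–open
  interval, skewed toward the closed end.

Each frame is a minimal pseudo-atom scaffold (~45 atoms):

* one catalytic zinc at the canonical origin;
* three histidine pseudo-residues (coordinating NE2 ~2.1 Å from the
  zinc, upper hemisphere) — these plus the zinc are the alignment atoms;
* a key carbonyl oxygen (``LEU 5 O``) near the pocket bottom, the
  reference atom of the <5 Å deep-binding rule;
* a stack of pocket-lining rings along the pocket axis (−z) whose
  radius is half the frame's gating distance — the *aperture*.  The two
  x-axis atoms of the mouth ring (the "gate pair") are never jittered,
  so the gating distance is recoverable exactly as their separation;
* one pocket-bottom atom that limits insertion depth.

Every frame then receives an independent random rigid rotation and
translation, so alignment has real work to do.  A single NumPy
``default_rng(seed)`` is consumed in a fixed, documented order (latent
draws, gating draws, atom jitter, rotation quaternions, translations),
making ensembles bit-reproducible for a given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .frames import ConformationFrame
from .pdbio import write_multimodel_pdb

__all__ = [
    "EnsembleConfig",
    "ScoreModel",
    "SyntheticEnsemble",
    "ReferenceComplex",
    "generate_ensemble",
    "generate_reference_complex",
    "generate_scores",
    "build_scaffold",
    "gating_distance_of",
    "GATE_DESCRIPTORS",
    "ALIGNMENT_DESCRIPTORS",
    "KEY_OXYGEN_DESCRIPTOR",
    "STATE_CLOSED",
    "STATE_INTERMEDIATE",
    "STATE_OPEN",
]

# latent (generator-side) state labels; analysis stages never read these
STATE_CLOSED = "closed"
STATE_INTERMEDIATE = "intermediate"
STATE_OPEN = "open"

# ---------------------------------------------------------------------------
# scaffold geometry constants (Å, canonical orientation: pocket along −z)

_HIS_N_DIST = 2.1          # zinc–NE2 coordination distance
_HIS_CB_DIST = 3.6
_HIS_ELEVATION = np.deg2rad(35.0)
_KEY_O_POS = np.array([1.0, 0.0, -11.0])   # key carbonyl O, pocket bottom wall
_RING_Z = np.arange(-3.0, -9.0 - 1e-9, -0.75)   # 9 pocket-lining ring planes
_BOTTOM_POS = np.array([0.0, 0.0, -10.5])
_REFERENCE_GATING = 8.0    # the reference complex is captured fully open

#: alignment fit atoms: catalytic zinc + the three coordinating NE2 nitrogens
ALIGNMENT_DESCRIPTORS = (
    ("ZN", 1, "ZN"),
    ("HIS", 2, "NE2"),
    ("HIS", 3, "NE2"),
    ("HIS", 4, "NE2"),
)

#: the unjittered mouth-ring atom pair whose separation is the gating distance
GATE_DESCRIPTORS = (("POC", 7, "C1"), ("POC", 7, "C2"))

#: the S1′ key carbonyl oxygen used by the deep-binding rule
KEY_OXYGEN_DESCRIPTOR = ("LEU", 5, "O")


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class EnsembleConfig:
    """Study conditions of a synthetic ensemble.

    Defaults are the analysis' reference conditions: 5000 frames; a
    two-state pocket closed at 3.5 ± 0.4 Å and open at 8.0 ± 0.6 Å (the
    modes straddle the apertures at which the reference fragment can
    enter, ~4.6 Å, and fully insert, ~6.3 Å); a continuous regime that
    breathes over 3.5–8.0 Å via a Beta(2, 4) law, i.e. mostly closed to
    semi-open with occasional fully open excursions.
    """

    n_frames: int = 5000
    dynamics_model: str = "two_state"          # "two_state" | "continuous"
    open_fraction: float = 0.5                 # two_state only
    gating_closed_mean: float = 3.5
    gating_closed_sd: float = 0.4
    gating_open_mean: float = 8.0
    gating_open_sd: float = 0.6
    gating_continuous_low: float = 3.5
    gating_continuous_high: float = 8.0
    continuous_shape_a: float = 2.0
    continuous_shape_b: float = 4.0
    rigid_jitter_sd: float = 2.0               # per-frame rigid translation scale
    atom_jitter_sd: float = 0.05               # per-atom Gaussian jitter
    closed_aperture_max: float = 4.6           # latent-label thresholds
    open_aperture_min: float = 6.3             # (continuous regime only)
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_frames, (int, np.integer)) or self.n_frames < 1:
            raise InvalidConfigError(f"n_frames must be a positive integer, got {self.n_frames!r}")
        if self.dynamics_model not in ("two_state", "continuous"):
            raise InvalidConfigError(f"unknown dynamics_model {self.dynamics_model!r}")
        if not 0.0 <= self.open_fraction <= 1.0:
            raise InvalidConfigError(f"open_fraction must lie in [0, 1], got {self.open_fraction}")
        for name in ("gating_closed_sd", "gating_open_sd", "rigid_jitter_sd", "atom_jitter_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.gating_open_mean <= self.gating_closed_mean:
            raise InvalidConfigError("gating_open_mean must exceed gating_closed_mean")
        if self.gating_continuous_high <= self.gating_continuous_low:
            raise InvalidConfigError("gating_continuous_high must exceed gating_continuous_low")
        if self.continuous_shape_a <= 0 or self.continuous_shape_b <= 0:
            raise InvalidConfigError("continuous shape parameters must be positive")


@dataclass(frozen=True)
class ScoreModel:
    """Two-mode empirical score emulator.

    Stands in for a fragment-docking scorer's output statistics: deep
    poses draw from the upper mode, superficial poses from the lower
    one; a fully open frame yields a deep pose with probability
    ``deep_given_open``.  Defaults put the deep mode near 650 ± 60 and
    the superficial mode near 400 ± 70 score units, the bands in which
    empirical docking scores of strong/weak zinc-protease fragment
    binding typically print.
    """

    deep_mean: float = 650.0
    deep_sd: float = 60.0
    superficial_mean: float = 400.0
    superficial_sd: float = 70.0
    deep_given_open: float = 0.7
    key_deep_range: tuple[float, float] = (2.0, 4.5)
    key_superficial_range: tuple[float, float] = (5.5, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deep_mean <= self.superficial_mean:
            raise InvalidConfigError("deep_mean must exceed superficial_mean")
        if self.deep_sd <= 0 or self.superficial_sd <= 0:
            raise InvalidConfigError("score SDs must be positive")
        if not 0.0 <= self.deep_given_open <= 1.0:
            raise InvalidConfigError("deep_given_open must lie in [0, 1]")


@dataclass
class SyntheticEnsemble:
    """Frames plus the latent bookkeeping used only for validation."""

    frames: list[ConformationFrame]
    gating_distances: np.ndarray
    true_states: np.ndarray
    config: EnsembleConfig

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def write_pdb(self, path) -> None:
        write_multimodel_pdb(self.frames, path)


@dataclass
class ReferenceComplex:
    """Idealized open receptor plus the anchor (pseudo-ZBG) template.

    The anchor chelates the catalytic zinc through its ``O1`` oxygen at
    the canonical 2.0 Å and exposes a link-site atom (``HL``) on the
    pocket axis, pointing down the pocket, from which fragments extend.
    """

    receptor: ConformationFrame
    anchor: ConformationFrame
    link_site: int
    chelator: int

    @property
    def chelation_distance(self) -> float:
        zinc = self.receptor.atom_coord(("ZN", 1, "ZN"))
        return float(np.linalg.norm(self.anchor.coords[self.chelator] - zinc))


# ---------------------------------------------------------------------------
# scaffold construction


def _scaffold_template(gating: float) -> tuple[list, list, list, np.ndarray, np.ndarray]:
    """Canonical (unjittered) scaffold for one gating distance.

    Returns (names, resnames, resids, coords, jitter_mask); atoms with a
    False jitter mask (the gate pair) must stay exactly on template so
    the gating distance can be recovered from coordinates.
    """
    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    coords: list[np.ndarray] = []
    jitter: list[bool] = []

    def add(name, resname, resid, pos, jit=True):
        names.append(name)
        resnames.append(resname)
        resids.append(resid)
        coords.append(np.asarray(pos, dtype=float))
        jitter.append(jit)

    add("ZN", "ZN", 1, (0.0, 0.0, 0.0))
    for k, resid in enumerate((2, 3, 4)):
        azimuth = 2.0 * np.pi * k / 3.0
        direction = np.array([
            np.cos(azimuth) * np.cos(_HIS_ELEVATION),
            np.sin(azimuth) * np.cos(_HIS_ELEVATION),
            np.sin(_HIS_ELEVATION),
        ])
        tangent = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
        add("NE2", "HIS", resid, _HIS_N_DIST * direction)
        add("CB", "HIS", resid, _HIS_CB_DIST * direction + 0.8 * tangent)
    add("O", "LEU", 5, _KEY_O_POS)
    half = gating / 2.0
    for plane, z in enumerate(_RING_Z):
        resid = 7 + plane
        is_gate_plane = plane == 0
        add("C1", "POC", resid, (half, 0.0, z), jit=not is_gate_plane)
        add("C2", "POC", resid, (-half, 0.0, z), jit=not is_gate_plane)
        add("C3", "POC", resid, (0.0, half, z))
        add("C4", "POC", resid, (0.0, -half, z))
    add("CB1", "BOT", 16, _BOTTOM_POS)

    return names, resnames, resids, np.array(coords), np.array(jitter, dtype=bool)


def build_scaffold(gating: float, jitter_displacements: np.ndarray | None = None) -> ConformationFrame:
    """Build one canonical-orientation scaffold frame.

    ``jitter_displacements`` — optional (n_atoms, 3) offsets applied to
    the jitterable atoms (the gate pair is pinned regardless).
    """
    names, resnames, resids, coords, jitter_mask = _scaffold_template(gating)
    if jitter_displacements is not None:
        coords = coords + np.where(jitter_mask[:, None], jitter_displacements, 0.0)
    return ConformationFrame(names, resnames, resids, coords)


def scaffold_n_atoms() -> int:
    return len(_scaffold_template(8.0)[0])


def gating_distance_of(frame: ConformationFrame) -> float:
    """Recover a frame's gating distance from its gate-atom pair.

    A distance is rigid-motion invariant, so this works on raw, aligned
    or arbitrarily transformed frames alike.
    """
    a = frame.atom_coord(GATE_DESCRIPTORS[0])
    b = frame.atom_coord(GATE_DESCRIPTORS[1])
    return float(np.linalg.norm(a - b))


def _random_rotations(quats: np.ndarray) -> np.ndarray:
    """Unit-quaternion draws → proper rotation matrices (vectorized)."""
    q = quats / np.linalg.norm(quats, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x**2 + z**2), 2 * (y * z - w * x)], axis=-1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x**2 + y**2)], axis=-1),
    ], axis=1)


# ---------------------------------------------------------------------------
# generators


def generate_ensemble(config: EnsembleConfig) -> SyntheticEnsemble:
    """Sample an ensemble under the configured gating dynamics.

    RNG draw order (one ``default_rng(config.seed)`` stream): state
    uniforms (two_state) or Beta variates (continuous); gating normals
    (two_state); atom jitter; rotation quaternions; translations.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames

    if config.dynamics_model == "two_state":
        u = rng.random(n)
        z = rng.standard_normal(n)
        is_open = u < config.open_fraction
        gating = np.where(
            is_open,
            config.gating_open_mean + config.gating_open_sd * z,
            config.gating_closed_mean + config.gating_closed_sd * z,
        )
        states = np.where(is_open, STATE_OPEN, STATE_CLOSED).astype(object)
    else:
        b = rng.beta(config.continuous_shape_a, config.continuous_shape_b, n)
        low, high = config.gating_continuous_low, config.gating_continuous_high
        gating = low + (high - low) * b
        states = np.full(n, STATE_INTERMEDIATE, dtype=object)
        states[gating < config.closed_aperture_max] = STATE_CLOSED
        states[gating > config.open_aperture_min] = STATE_OPEN

    gating = np.clip(gating, 1.0, None)   # keep apertures physical

    n_atoms = scaffold_n_atoms()
    jitter = config.atom_jitter_sd * rng.standard_normal((n, n_atoms, 3))
    quats = rng.standard_normal((n, 4))
    trans = config.rigid_jitter_sd * rng.standard_normal((n, 3))
    if config.rigid_jitter_sd == 0.0:
        rotations = np.broadcast_to(np.eye(3), (n, 3, 3))
    else:
        rotations = _random_rotations(quats)

    frames = []
    for i in range(n):
        frame = build_scaffold(gating[i], jitter[i])
        frames.append(frame.transformed(rotations[i], trans[i]))

    return SyntheticEnsemble(frames, gating, states, config)


def generate_reference_complex() -> ReferenceComplex:
    """Idealized, unjittered open receptor plus the anchor template.

    Deterministic by construction (no RNG involved).  The anchor mimics
    a maltol-like zinc chelator: ``O1`` 2.0 Å from the zinc, two ring
    carbons, and the link-site pseudo-hydrogen ``HL`` on the pocket axis
    pointing down the pocket.
    """
    receptor = build_scaffold(_REFERENCE_GATING, None)
    anchor = ConformationFrame(
        ["O1", "C2", "C3", "HL"],
        ["MLT"] * 4,
        [20] * 4,
        np.array([
            [1.2, 0.0, -1.6],    # chelating oxygen: |pos| = 2.0 exactly
            [2.0, 0.0, -2.6],
            [1.2, 0.8, -2.4],
            [0.0, 0.0, -1.0],    # link site, on the pocket axis
        ]),
    )
    return ReferenceComplex(receptor=receptor, anchor=anchor, link_site=3, chelator=0)


def generate_scores(ensemble: SyntheticEnsemble, model: ScoreModel) -> pd.DataFrame:
    """Emulate per-frame docking outcomes from the latent states.

    Closed frames produce no pose (``placed`` False, no score); open
    frames draw from the deep mode with probability ``deep_given_open``
    and otherwise from the superficial mode; intermediate frames always
    draw superficial.  Key distances are drawn consistently with the
    mode (deep strictly under, superficial strictly over, the 5 Å rule).

    Returns a DataFrame with columns ``frame_index, placed, score,
    key_distance, latent_mode``.
    """
    if ensemble.n_frames == 0:
        raise InvalidConfigError("ensemble is empty")
    rng = np.random.default_rng(model.seed)
    n = ensemble.n_frames
    u = rng.random(n)
    z = rng.standard_normal(n)
    v = rng.random(n)

    states = ensemble.true_states
    placed = states != STATE_CLOSED
    deep = (states == STATE_OPEN) & (u < model.deep_given_open)
    superficial = placed & ~deep

    score = np.full(n, np.nan)
    key = np.full(n, np.nan)
    score[deep] = model.deep_mean + model.deep_sd * z[deep]
    score[superficial] = model.superficial_mean + model.superficial_sd * z[superficial]
    lo, hi = model.key_deep_range
    key[deep] = lo + (hi - lo) * v[deep]
    lo, hi = model.key_superficial_range
    key[superficial] = lo + (hi - lo) * v[superficial]

    mode = np.where(deep, "deep", np.where(superficial, "superficial", "none")).astype(object)
    return pd.DataFrame({
        "frame_index": np.arange(n),
        "placed": placed,
        "score": score,
        "key_distance": key,
        "latent_mode": mode,
    })
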