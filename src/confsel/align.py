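"""Rigid superposition of ensemble frames and anchor-template transfer.

Frames are superposed onto a common reference by a small set of
active-site atoms — by default the catalytic zinc and the three
coordinating histidine nitrogens, four well-conditioned points.  The fit
is the classical least-squares rigid superposition (Kabsch): SVD of the
cross-covariance with the reflection branch excluded, so the returned
rotation is always proper.  Once a frame is aligned, the zinc-chelating
anchor template of the reference complex is mapped into it through the
residual reference→frame transform, and the chelation geometry is
checked before the frame is declared usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnchorPlacementError, DegenerateGeometryError, SelectionError
from .frames import AtomDescriptor, ConformationFrame
from .synthetic import ALIGNMENT_DESCRIPTORS, ReferenceComplex

__all__ = [
    "AlignmentSelection",
    "RigidTransform",
    "AnchorPose",
    "kabsch_fit",
    "align_ensemble",
    "place_anchor",
]

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class AlignmentSelection:
    """Atom descriptors defining the fit set (≥3 non-collinear atoms)."""

    descriptors: tuple[AtomDescriptor, ...] = ALIGNMENT_DESCRIPTORS

    def __post_init__(self) -> None:
        if len(self.descriptors) < 3:
            raise DegenerateGeometryError("an alignment selection needs at least 3 atoms")

    def resolve(self, frame: ConformationFrame) -> np.ndarray:
        """Selection coordinates in `frame`, in descriptor order."""
        return np.array([frame.atom_coord(d) for d in self.descriptors])


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal within 1e-9")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply `other` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


@dataclass
class AnchorPose:
    """Anchor template mapped into one aligned frame."""

    coords: np.ndarray
    link_site: int
    chelation_distance: float
    usable: bool
    atom_names: np.ndarray = field(default=None)

    @property
    def link_site_coord(self) -> np.ndarray:
        return self.coords[self.link_site]


def kabsch_fit(moving: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns the proper rigid transform minimizing ‖R·moving + t − target‖
    and the post-fit RMSD over the fitted points.  Reflections are
    excluded by flipping the sign of the smallest singular direction
    when the raw SVD solution has a negative determinant.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape:
        raise DegenerateGeometryError(
            f"point sets must pair up; got {moving.shape} vs {target.shape}"
        )
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 three-dimensional points")

    mu_m = moving.mean(axis=0)
    mu_t = target.mean(axis=0)
    X = moving - mu_m
    Y = target - mu_t

    # collinearity: a centered point set with < 2 independent directions
    # leaves a rotation about the line unconstrained
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[1] <= _COLLINEAR_TOL * max(sv[0], 1.0):
        raise DegenerateGeometryError("fit points are collinear (rotation underdetermined)")

    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_m

    residual = moving @ R.T + t - target
    rmsd = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return RigidTransform(R, t), rmsd


def align_ensemble(
    frames: list[ConformationFrame],
    selection: AlignmentSelection | None = None,
    reference: ConformationFrame | None = None,
) -> tuple[list[ConformationFrame], np.ndarray, list[RigidTransform]]:
    """Superpose every frame onto the reference by the selection atoms.

    The reference defaults to the first frame.  All atoms of each frame
    move rigidly with its fitted transform.  Returns (aligned frames,
    per-frame fit RMSDs, per-frame transforms).
    """
    selection = selection or AlignmentSelection()
    if not frames:
        return [], np.empty(0), []
    reference = reference if reference is not None else frames[0]
    try:
        target = selection.resolve(reference)
    except SelectionError as exc:
        raise SelectionError(f"reference frame: {exc.args[0]}") from None

    aligned: list[ConformationFrame] = []
    rmsds = np.empty(len(frames))
    transforms: list[RigidTransform] = []
    for i, frame in enumerate(frames):
        try:
            moving = selection.resolve(frame)
        except SelectionError as exc:
            raise SelectionError(f"frame {i}: {exc.args[0]}") from None
        transform, rmsd = kabsch_fit(moving, target)
        aligned.append(frame.transformed(transform.rotation, transform.translation))
        rmsds[i] = rmsd
        transforms.append(transform)
    return aligned, rmsds, transforms


def place_anchor(
    reference_complex: ReferenceComplex,
    aligned_frame: ConformationFrame,
    selection: AlignmentSelection | None = None,
    chelation_cutoff: float = 3.0,
    site_rmsd_cutoff: float = 1.0,
) -> AnchorPose:
    """Map the anchor template into an aligned frame.

    The anchor coordinates are the template ligand coordinates carried
    through the reference→frame residual transform (identity when the
    frame's fit atoms superpose exactly on the reference's).  The frame
    is recorded unusable — ``usable=False``, never an exception, since a
    failed anchor is a per-frame outcome rather than a pipeline fault —
    when either the chelating atom ends up farther than
    ``chelation_cutoff`` from the frame's zinc, or the site fit itself
    is poor (fit RMSD above ``site_rmsd_cutoff``, e.g. a zinc displaced
    out of its coordination cage).
    """
    selection = selection or AlignmentSelection()
    ref_points = selection.resolve(reference_complex.receptor)
    frame_points = selection.resolve(aligned_frame)
    transform, site_rmsd = kabsch_fit(ref_points, frame_points)
    coords = transform.apply(reference_complex.anchor.coords)

    zinc = aligned_frame.atom_coord(("ZN", 1, "ZN"))
    chelation = float(np.linalg.norm(coords[reference_complex.chelator] - zinc))
    return AnchorPose(
        coords=coords,
        link_site=reference_complex.link_site,
        chelation_distance=chelation,
        usable=chelation <= chelation_cutoff and site_rmsd <= site_rmsd_cutoff,
        atom_names=reference_complex.anchor.atom_names.copy(),
    )
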