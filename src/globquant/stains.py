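"""Stain separation by color deconvolution in optical-density space.

Brightfield RGB intensities follow the Beer-Lambert model: a pixel with
per-stain concentrations ``c`` transmits ``I = I0 * 10**(-(M^T c))`` where
the rows of ``M`` are unit absorbance (OD) vectors of the stains.  The OD
transform ``OD = -log10(I / I0)`` linearises this, and unmixing is a 3x3
linear solve per pixel (Ruifrok & Johnston's color deconvolution).

Built-in vectors cover hematoxylin and DAB (the classical deconvolution
values) and the PAS-D magenta used by this package's synthetic renderer;
:func:`estimate_stain_vectors` calibrates a matrix from user-supplied
pure-stain patches when the defaults do not match a lab's staining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Guard against log of zero intensity.
OD_EPS = 1e-6
#: Optical densities are clipped to [0, OD_MAX].
OD_MAX = 3.0

_MIN_ANGLE_DEG = 1.0  # below this, stain vectors count as collinear


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero stain vector")
    return v / n

# Classical hematoxylin / DAB absorbance directions.
VECTOR_HEMATOXYLIN = _unit([0.650, 0.704, 0.286])
VECTOR_DAB = _unit([0.268, 0.570, 0.776])
#: PAS/PAS-D magenta: absorbs green strongly, transmits red and blue.
VECTOR_PAS_MAGENTA = _unit([0.175, 0.972, 0.155])


class CollinearStainsError(ValueError):
    """Stain vectors are (near-)parallel; the unmixing system is singular."""


@dataclass
class StainMatrix:
    """Named unit OD vectors for 2 or 3 stains.

    A 2-stain matrix is automatically completed with the residual third
    direction (cross product of the two stains) so that unmixing is a
    well-posed 3x3 solve; the residual channel is reported under the name
    ``"residual"`` but carries no biological meaning.
    """

    names: list[str]
    vectors: np.ndarray  # (n_stains, 3), rows unit-norm, RGB order
    provenance: str = "default"  # default | calibrated

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.shape[0] != len(self.names):
            raise ValueError("one vector per stain name required")
        # 1-stain matrices arise from single-stain calibration; unmixing
        # itself needs 2 or 3 stains (enforced in completed())
        if self.vectors.shape[0] not in (1, 2, 3) or self.vectors.shape[1] != 3:
            raise ValueError("need 1-3 stain vectors of length 3")
        if np.any(self.vectors < -1e-12):
            raise ValueError("stain OD vectors must be non-negative")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain vectors must be unit norm, got {norms}")
        n = self.vectors.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                cosang = np.clip(self.vectors[i] @ self.vectors[j], -1, 1)
                if np.degrees(np.arccos(cosang)) < _MIN_ANGLE_DEG:
                    raise CollinearStainsError(
                        f"stains {self.names[i]!r} and {self.names[j]!r} "
                        "are collinear"
                    )

    def completed(self) -> tuple[list[str], np.ndarray]:
        """Names and a full-rank 3x3 matrix (residual row appended if 2-stain)."""
        if self.vectors.shape[0] == 1:
            raise ValueError("unmixing needs a 2- or 3-stain matrix")
        if self.vectors.shape[0] == 3:
            return list(self.names), self.vectors
        residual = np.cross(self.vectors[0], self.vectors[1])
        nrm = np.linalg.norm(residual)
        if nrm < 1e-9:
            raise CollinearStainsError("cannot complete collinear 2-stain matrix")
        # keep the signed orthogonal direction; the residual channel is
        # internal plumbing and may have negative components
        return list(self.names) + ["residual"], np.vstack(
            [self.vectors, residual / nrm]
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "vectors": self.vectors.tolist(),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainMatrix":
        return cls(
            names=list(d["names"]),
            vectors=np.asarray(d["vectors"], dtype=float),
            provenance=d.get("provenance", "default"),
        )


def default_pasd_matrix() -> StainMatrix:
    """Hematoxylin + PAS-D magenta."""
    return StainMatrix(
        names=["hematoxylin", "pasd"],
        vectors=np.vstack([VECTOR_HEMATOXYLIN, VECTOR_PAS_MAGENTA]),
    )


def default_ihc_matrix() -> StainMatrix:
    """Hematoxylin + DAB chromogen."""
    return StainMatrix(
        names=["hematoxylin", "dab"],
        vectors=np.vstack([VECTOR_HEMATOXYLIN, VECTOR_DAB]),
    )


@dataclass
class ODImage:
    """Per-pixel optical densities (H, W, 3) with the background I0 used."""

    od: np.ndarray
    i0: np.ndarray = field(default_factory=lambda: np.full(3, 255.0))


def rgb_to_od(
    rgb: np.ndarray,
    i0: Sequence[float] | float = 255.0,
    od_max: float = OD_MAX,
) -> ODImage:
    """Beer-Lambert transform ``OD = -log10((I + eps) / I0)``.

    OD is clipped to ``[0, od_max]``; a pixel at background intensity maps
    to OD 0 exactly and zero intensity maps to ``od_max`` without overflow.
    """
    i0_arr = np.broadcast_to(np.asarray(i0, dtype=float), (3,)).copy()
    if np.any(i0_arr <= 0):
        raise ValueError("background intensity I0 must be > 0 per channel")
    intensity = np.asarray(rgb, dtype=float)
    od = -np.log10((intensity + OD_EPS) / (i0_arr + OD_EPS))
    return ODImage(od=np.clip(od, 0.0, od_max), i0=i0_arr)


def deconvolve_stains(
    od: ODImage | np.ndarray, matrix: StainMatrix
) -> dict[str, np.ndarray]:
    """Unmix per-pixel OD into per-stain concentration maps.

    Solves ``M^T c = od`` per pixel; negative concentrations (noise or
    model mismatch) are clipped to 0.  Returns ``{stain_name: (H, W)}``
    including the synthetic ``"residual"`` channel of 2-stain matrices.
    """
    od_arr = od.od if isinstance(od, ODImage) else np.asarray(od, dtype=float)
    names, full = matrix.completed()
    try:
        inv = np.linalg.inv(full.T)
    except np.linalg.LinAlgError as exc:
        raise CollinearStainsError("singular stain matrix") from exc
    flat = od_arr.reshape(-1, 3)
    conc = flat @ inv.T  # c = (M^T)^-1 od
    conc = np.clip(conc, 0.0, None)
    shape = od_arr.shape[:-1]
    return {name: conc[:, k].reshape(shape) for k, name in enumerate(names)}


def recompose(
    concentrations: dict[str, np.ndarray], matrix: StainMatrix
) -> np.ndarray:
    """Forward model: rebuild the OD image from unmixed concentrations."""
    names, full = matrix.completed()
    stack = np.stack([concentrations[n] for n in names], axis=-1)
    return stack @ full


def estimate_stain_vectors(
    patches: Sequence[Sequence[np.ndarray]],
    names: Sequence[str],
    i0: Sequence[float] | float = 255.0,
    min_od: float = 0.05,
) -> StainMatrix:
    """Calibrate a stain matrix from pure-stain RGB patches.

    Each entry of ``patches`` is a list of RGB patches dominated by one
    stain; the stain vector is the unit-normalised median OD direction
    over pixels with total OD above ``min_od`` (background excluded).

    Raises
    ------
    ValueError
        if a patch set has essentially no absorbance to calibrate on.
    CollinearStainsError
        if two calibrated stains come out parallel.
    """
    if len(patches) != len(names):
        raise ValueError("one patch set per stain name required")
    vectors = []
    for name, patch_set in zip(names, patches):
        ods = []
        for patch in patch_set:
            od = rgb_to_od(patch, i0=i0).od.reshape(-1, 3)
            strong = od[np.linalg.norm(od, axis=1) > min_od]
            if strong.size:
                ods.append(strong)
        if not ods:
            raise ValueError(
                f"calibration patches for {name!r} contain no stain (OD ~ 0)"
            )
        pooled = np.vstack(ods)
        directions = pooled / np.linalg.norm(pooled, axis=1, keepdims=True)
        vectors.append(_unit(np.median(directions, axis=0)))
    return StainMatrix(
        names=list(names), vectors=np.vstack(vectors), provenance="calibrated"
    )
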