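"""Structural feature vectors for candidate zinc-binding sites.

A candidate's geometry is summarized by nine numbers: mean, maximum, minimum
and standard deviation of all pairwise inter-C-alpha distances; the same four
statistics for inter-C-beta distances; and the hydrophobic-contrast
descriptor evaluated at the centroid of the C-beta atoms with a 4 Angstrom
radius.  A site of k liganding residues contributes C(k,2) distances per
block (an H3 site has 3, a C4 site has 6).

The contrast descriptor captures the hallmark shell structure of metal
centres — an inner shell of hydrophilic atoms (N, O, S ligand atoms)
surrounded by hydrophobic (carbon-rich) packing.  For atoms at distance d
from the probe centre within radius R it sums ``h_atom * (2 d^2 - R^2)/R^2``:
a hydrophobic atom on the sphere surface contributes +h, the same atom at
the centre contributes -h, with the sign crossover at ``R / sqrt(2)``.
Higher values therefore mean "hydrophilic core, hydrophobic rim".
"""

from __future__ import annotations

from typing import Mapping, Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin

from .families import FamilySignature, StructureSiteCandidate

#: Default contrast radius in Angstroms.
DEFAULT_CONTRAST_RADIUS = 4.0

#: Per-element hydrophobicity: carbon is hydrophobic; nitrogen, oxygen and
#: sulphur (the ligand atoms) are hydrophilic; hydrogens/metals are neutral.
DEFAULT_ATOM_HYDROPHOBICITY: dict[str, float] = {
    "C": 1.0,
    "N": -1.0,
    "O": -1.0,
    "S": -1.0,
}

STRUCTURE_FEATURE_NAMES = [
    "ca_mean", "ca_max", "ca_min", "ca_std",
    "cb_mean", "cb_max", "cb_min", "cb_std",
    "contrast",
]


def pairwise_distance_stats(coords: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, max, min, population std) of all pairwise Euclidean distances.

    The statistics are over the complete set of C(n,2) distances, so the
    *population* standard deviation is used (it is 0 for a single pair).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 points for pairwise distances")
    dists = pdist(coords)
    return (
        float(dists.mean()),
        float(dists.max()),
        float(dists.min()),
        float(dists.std(ddof=0)),
    )


def cb_centroid(candidate: StructureSiteCandidate) -> np.ndarray:
    """Arithmetic mean of the binding residues' C-beta coordinates."""
    return candidate.cb_coords.mean(axis=0)


def hydrophobic_contrast(
    elements: Sequence[str],
    coords: np.ndarray,
    center: np.ndarray,
    radius: float = DEFAULT_CONTRAST_RADIUS,
    table: Mapping[str, float] = DEFAULT_ATOM_HYDROPHOBICITY,
) -> float:
    """Hydrophobic contrast at ``center`` over atoms within ``radius``.

    Returns ``sum h_i * (2 d_i^2 - R^2) / R^2`` over atoms with d <= R;
    an empty sphere gives 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] == 0:
        return 0.0
    d2 = ((coords - np.asarray(center, dtype=float)) ** 2).sum(axis=1)
    inside = d2 <= radius ** 2
    if not inside.any():
        return 0.0
    h = np.array([table.get(el.upper(), 0.0) for el in elements], dtype=float)
    weights = (2.0 * d2[inside] - radius ** 2) / radius ** 2
    return float((h[inside] * weights).sum())


def featurize_structure_site(
    candidate: StructureSiteCandidate,
    table: Mapping[str, float] = DEFAULT_ATOM_HYDROPHOBICITY,
    radius: float = DEFAULT_CONTRAST_RADIUS,
) -> np.ndarray:
    """The 9-value structural descriptor, in ``STRUCTURE_FEATURE_NAMES`` order."""
    ca_stats = pairwise_distance_stats(candidate.ca_coords)
    cb_stats = pairwise_distance_stats(candidate.cb_coords)
    contrast = hydrophobic_contrast(
        candidate.atom_elements,
        candidate.atom_coords,
        cb_centroid(candidate),
        radius=radius,
        table=table,
    )
    return np.array([*ca_stats, *cb_stats, contrast], dtype=float)


class StructureSiteFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer mapping structure candidates to the 9-column schema."""

    modality = "structure"

    def __init__(
        self,
        radius: float = DEFAULT_CONTRAST_RADIUS,
        atom_table: Union[Mapping[str, float], None] = None,
    ):
        self.radius = radius
        self.atom_table = atom_table

    def fit(self, X: Sequence[StructureSiteCandidate], y=None):
        return self

    def transform(self, X: Sequence[StructureSiteCandidate]) -> np.ndarray:
        candidates = list(X)
        if not candidates:
            raise ValueError("no candidates to featurize")
        family = candidates[0].family
        if any(c.family != family for c in candidates):
            raise ValueError("all candidates in one transform must share a family")
        table = self.atom_table if self.atom_table is not None else DEFAULT_ATOM_HYDROPHOBICITY
        return np.vstack([
            featurize_structure_site(c, table=table, radius=self.radius)
            for c in candidates
        ])

    def feature_names(self, family: FamilySignature) -> list[str]:
        return list(STRUCTURE_FEATURE_NAMES)
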