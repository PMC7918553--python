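"""Sequence feature vectors for candidate zinc-binding sites.

The sequence descriptor of a candidate site is alignment-free and local to
the binding residues:

* one *gap* per consecutive pair of binding residues — the number of
  residues strictly between them in the primary sequence;
* mean hydrophobicity of the binding residues and their sequence
  neighbourhoods, at windows of 1, 3 and 5 residues (Wimley-White scale);
* mean count of charged residues (D, E, R, H, K) in the same windows.

The full vector is ``gaps + [hydro_w1, hydro_w3, hydro_w5, charge_w1,
charge_w3, charge_w5]`` — length ``site_size - 1 + 6``.  Windows are clipped
at the sequence termini and the hydrophobicity mean divides by the number of
residues actually included; the charge statistic is a mean of per-window
*counts*, so clipping can only lower it.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .families import FamilySignature, SequenceSiteCandidate

#: Residues counted as charged: aspartate, glutamate, arginine, histidine, lysine.
CHARGED_RESIDUES = frozenset("DERHK")

WINDOWS = (1, 3, 5)

_SCALE_FILES = {
    "interface": "wimley_white_interface.tsv",
    "octanol": "wimley_white_octanol.tsv",
}


def load_hydrophobicity_scale(name: str = "interface") -> dict[str, float]:
    """Load a packaged Wimley-White hydrophobicity scale.

    ``"interface"`` (water -> POPC interface, the default) or ``"octanol"``
    (water -> n-octanol).  Returns a complete 20-residue mapping.
    """
    try:
        filename = _SCALE_FILES[name]
    except KeyError:
        raise ValueError(
            f"unknown scale {name!r}; available: {sorted(_SCALE_FILES)}"
        ) from None
    with resources.files("zincsite.data").joinpath(filename).open() as handle:
        table = pd.read_csv(handle, sep="\t", comment="#")
    return dict(zip(table["residue"], table["value"].astype(float)))


def gap_vector(candidate: SequenceSiteCandidate) -> list[int]:
    """Residues strictly between each consecutive pair of binding residues."""
    positions = candidate.positions
    return [positions[i + 1] - positions[i] - 1 for i in range(len(positions) - 1)]


def _window_residues(sequence: str, center: int, window: int) -> str:
    half = window // 2
    return sequence[max(0, center - half): center + half + 1]


def window_mean_hydrophobicity(
    candidate: SequenceSiteCandidate,
    window: int,
    scale: Mapping[str, float],
) -> float:
    """Mean scale value over all residues in all binding-residue windows.

    Each binding residue contributes the residues of the size-``window``
    window centred on it (clipped at the termini); overlapping windows count
    shared residues once per window.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    values = [
        scale[aa]
        for pos in candidate.positions
        for aa in _window_residues(candidate.sequence, pos, window)
    ]
    return float(np.mean(values))


def window_mean_charge(candidate: SequenceSiteCandidate, window: int) -> float:
    """Mean per-window count of charged residues over the binding residues."""
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    counts = [
        sum(aa in CHARGED_RESIDUES
            for aa in _window_residues(candidate.sequence, pos, window))
        for pos in candidate.positions
    ]
    return float(np.mean(counts))


def sequence_feature_names(family: FamilySignature) -> list[str]:
    """Ordered column names of the family's sequence feature schema."""
    names = [f"gap_{i + 1}" for i in range(family.site_size - 1)]
    names += [f"hydrophobicity_w{w}" for w in WINDOWS]
    names += [f"charge_w{w}" for w in WINDOWS]
    return names


def featurize_sequence_site(
    candidate: SequenceSiteCandidate,
    scale: Mapping[str, float],
) -> np.ndarray:
    """Feature vector: gaps, then hydrophobicity w1/w3/w5, then charge w1/w3/w5."""
    gaps = gap_vector(candidate)
    hydro = [window_mean_hydrophobicity(candidate, w, scale) for w in WINDOWS]
    charge = [window_mean_charge(candidate, w) for w in WINDOWS]
    return np.array(gaps + hydro + charge, dtype=float)


class SequenceSiteFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer mapping sequence candidates to the fixed feature schema.

    Parameters
    ----------
    scale:
        Name of a packaged hydrophobicity scale (``"interface"`` or
        ``"octanol"``) or an explicit residue -> value mapping.
    """

    modality = "sequence"

    def __init__(self, scale: Union[str, Mapping[str, float]] = "interface"):
        self.scale = scale

    def _scale_table(self) -> Mapping[str, float]:
        if isinstance(self.scale, str):
            return load_hydrophobicity_scale(self.scale)
        return self.scale

    def fit(self, X: Sequence[SequenceSiteCandidate], y=None):  # noqa: D102 - stateless
        return self

    def transform(self, X: Sequence[SequenceSiteCandidate]) -> np.ndarray:
        candidates = list(X)
        if not candidates:
            raise ValueError("no candidates to featurize")
        family = candidates[0].family
        if any(c.family != family for c in candidates):
            raise ValueError("all candidates in one transform must share a family")
        table = self._scale_table()
        return np.vstack([featurize_sequence_site(c, table) for c in candidates])

    def feature_names(self, family: FamilySignature) -> list[str]:
        return sequence_feature_names(family)
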