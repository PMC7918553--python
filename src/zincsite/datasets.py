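"""Balanced per-family training sets: catalogues, filters, negative sampling.

Positive examples come from a catalogue of known zinc-binding sites; negative
examples are family-matching residue combinations drawn at random from a pool
of sequences or structures assumed not to bind zinc.  Negatives are drawn
until they equal the positives in number (a 1:1 class ratio), each negative
is required not to coincide with any catalogued site, and the combined table
is shuffled deterministically under the run seed.

Filtering rules applied before featurization:

* sequence sites split across multiple chains are discarded;
* structure sites are kept only when the parent structure's resolution is
  strictly better than 2.0 Angstroms (missing resolution excludes the entry,
  with a warning);
* optional redundancy reduction keeps one random representative per
  externally supplied sequence cluster (e.g. CD-HIT assignments read from a
  two-column TSV).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .families import (
    DEFAULT_MAX_CA_DISTANCE,
    DEFAULT_MAX_SPAN,
    FamilySignature,
    SequenceSiteCandidate,
    StructureSiteCandidate,
    enumerate_sequence_candidates,
    enumerate_structure_candidates,
)
from .structures import ProteinStructure

logger = logging.getLogger(__name__)

#: Redraw budget per required negative sample before giving up.
MAX_SAMPLING_ATTEMPTS = 1000

DATASET_FORMAT_VERSION = "1"


class SamplingExhaustedError(RuntimeError):
    """No valid negative candidate found within the attempt budget."""


RngLike = Union[int, np.random.Generator]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Site catalogue

@dataclass(frozen=True)
class SiteCatalogueEntry:
    """One known zinc-binding site from the catalogue."""

    site_id: str
    family: FamilySignature
    source_id: str
    modality: str  # "sequence" | "structure"
    chains: tuple[str, ...]
    positions: Optional[tuple[int, ...]] = None  # 0-based, sequence modality
    residues: Optional[tuple[tuple[str, int, str], ...]] = None  # structure
    resolution: Optional[float] = None


def write_catalogue(entries: Sequence[SiteCatalogueEntry], path: Union[str, Path]) -> None:
    """Write a catalogue TSV (positions reported 1-based)."""
    rows = []
    for e in entries:
        rows.append({
            "site_id": e.site_id,
            "family": e.family.canonical_name,
            "source_id": e.source_id,
            "modality": e.modality,
            "chains": ";".join(e.chains),
            "positions": ",".join(str(p + 1) for p in e.positions) if e.positions else "",
            "residues": ",".join(f"{c}:{n}{i}" for c, n, i in e.residues) if e.residues else "",
            "resolution": "" if e.resolution is None else f"{e.resolution:g}",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalogue(path: Union[str, Path]) -> list[SiteCatalogueEntry]:
    """Read a catalogue TSV written by :func:`write_catalogue`."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for _, row in table.iterrows():
        positions = None
        if row.get("positions"):
            positions = tuple(int(p) - 1 for p in row["positions"].split(","))
        residues = None
        if row.get("residues"):
            parsed = []
            for token in row["residues"].split(","):
                chain, rest = token.split(":", 1)
                num = "".join(ch for ch in rest if ch.isdigit() or ch == "-")
                icode = rest[len(num):]
                parsed.append((chain, int(num), icode))
            residues = tuple(parsed)
        entries.append(SiteCatalogueEntry(
            site_id=row["site_id"],
            family=FamilySignature.parse(row["family"]),
            source_id=row["source_id"],
            modality=row["modality"],
            chains=tuple(row["chains"].split(";")) if row["chains"] else (),
            positions=positions,
            residues=residues,
            resolution=float(row["resolution"]) if row.get("resolution") else None,
        ))
    return entries


# ---------------------------------------------------------------------------
# Filters

def filter_single_chain(entries: Sequence[SiteCatalogueEntry]) -> list[SiteCatalogueEntry]:
    """Keep only sites whose binding residues lie in a single chain."""
    return [e for e in entries if len(set(e.chains)) <= 1]


def filter_resolution(
    entries: Sequence[SiteCatalogueEntry],
    cutoff: float = 2.0,
) -> list[SiteCatalogueEntry]:
    """Keep entries with resolution strictly better (lower) than ``cutoff``.

    Entries without resolution metadata are excluded with a warning.
    """
    kept = []
    for e in entries:
        if e.resolution is None:
            logger.warning("site %s has no resolution metadata; excluded", e.site_id)
            continue
        if e.resolution < cutoff:
            kept.append(e)
    return kept


def read_cluster_assignments(path: Union[str, Path]) -> dict[str, str]:
    """Read entry-id -> cluster-id assignments from a two-column TSV."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col, cluster_col = table.columns[:2]
    return dict(zip(table[id_col], table[cluster_col]))


def apply_redundancy_filter(
    entries: Sequence[SiteCatalogueEntry],
    clusters: Mapping[str, str],
    rng: RngLike = 0,
) -> list[SiteCatalogueEntry]:
    """Keep one uniformly chosen representative per cluster.

    ``clusters`` maps entry ``site_id`` to a cluster id (typically CD-HIT
    output); every entry must be present.  Output preserves the input order
    of the kept entries and is deterministic under the seed.
    """
    rng = _as_rng(rng)
    missing = [e.site_id for e in entries if e.site_id not in clusters]
    if missing:
        raise KeyError(f"entries missing from cluster map: {missing[:5]}")
    by_cluster: dict[str, list[int]] = {}
    for i, e in enumerate(entries):
        by_cluster.setdefault(clusters[e.site_id], []).append(i)
    keep = set()
    for cluster_id in sorted(by_cluster):
        members = by_cluster[cluster_id]
        keep.add(members[int(rng.integers(len(members)))])
    return [e for i, e in enumerate(entries) if i in keep]


# ---------------------------------------------------------------------------
# Candidates from catalogue entries

def sequence_candidates_from_catalogue(
    entries: Sequence[SiteCatalogueEntry],
    sequences: Mapping[str, str],
) -> list[SequenceSiteCandidate]:
    """Materialize catalogued sequence sites as candidates."""
    out = []
    for e in entries:
        if e.positions is None:
            raise ValueError(f"site {e.site_id} has no sequence positions")
        out.append(SequenceSiteCandidate(
            sequence=sequences[e.source_id].upper(),
            positions=e.positions,
            family=e.family,
            source_id=e.source_id,
        ))
    return out


def structure_candidates_from_catalogue(
    entries: Sequence[SiteCatalogueEntry],
    structures: Mapping[str, ProteinStructure],
) -> list[StructureSiteCandidate]:
    """Materialize catalogued structure sites as candidates."""
    out = []
    for e in entries:
        if e.residues is None:
            raise ValueError(f"site {e.site_id} has no structure residues")
        structure = structures[e.source_id]
        chosen = tuple(
            structure.residue_by_label(chain, number, icode)
            for chain, number, icode in e.residues
        )
        out.append(StructureSiteCandidate(
            residues=chosen,
            family=e.family,
            atom_elements=structure.atom_elements,
            atom_coords=structure.atom_coords,
            source_id=e.source_id,
        ))
    return out


def known_sites_by_sequence(
    entries: Sequence[SiteCatalogueEntry],
) -> dict[str, set[tuple[int, ...]]]:
    """Map sequence id -> set of catalogued binding-position tuples."""
    known: dict[str, set[tuple[int, ...]]] = {}
    for e in entries:
        if e.positions is not None:
            known.setdefault(e.source_id, set()).add(tuple(e.positions))
    return known


# ---------------------------------------------------------------------------
# Negative sampling

def sample_negative_sequence(
    pool: Mapping[str, str],
    family: FamilySignature,
    known_sites: Mapping[str, set[tuple[int, ...]]],
    rng: RngLike,
    max_span: int = DEFAULT_MAX_SPAN,
    max_attempts: int = MAX_SAMPLING_ATTEMPTS,
) -> SequenceSiteCandidate:
    """Draw one family-matching combination that is not a catalogued site.

    A pool sequence is chosen uniformly at random, then a family-matching
    combination within it is chosen uniformly among those whose position set
    differs from every catalogued site in that sequence.  Reproducible under
    the generator state.
    """
    rng = _as_rng(rng)
    if not pool:
        raise ValueError("empty sequence pool")
    ids = sorted(pool)
    for _ in range(max_attempts):
        seq_id = ids[int(rng.integers(len(ids)))]
        candidates = enumerate_sequence_candidates(
            pool[seq_id], family, max_span=max_span, source_id=seq_id
        )
        excluded = known_sites.get(seq_id, set())
        valid = [c for c in candidates if c.positions not in excluded]
        if valid:
            return valid[int(rng.integers(len(valid)))]
    raise SamplingExhaustedError(
        f"no valid negative {family.canonical_name} combination found in "
        f"{max_attempts} attempts"
    )


def sample_negative_structure(
    pool: Mapping[str, ProteinStructure],
    family: FamilySignature,
    rng: RngLike,
    max_ca_distance: float = DEFAULT_MAX_CA_DISTANCE,
    max_attempts: int = MAX_SAMPLING_ATTEMPTS,
) -> StructureSiteCandidate:
    """Draw one feasible family-matching combination from non-binding structures.

    A structure is chosen uniformly at random from the pool, then a feasible
    combination (all inter-C-alpha distances <= ``max_ca_distance``) within
    it is chosen uniformly.
    """
    rng = _as_rng(rng)
    if not pool:
        raise ValueError("empty structure pool")
    ids = sorted(pool)
    for _ in range(max_attempts):
        st_id = ids[int(rng.integers(len(ids)))]
        candidates = enumerate_structure_candidates(
            pool[st_id], family, max_ca_distance=max_ca_distance
        )
        if candidates:
            return candidates[int(rng.integers(len(candidates)))]
    raise SamplingExhaustedError(
        f"no feasible negative {family.canonical_name} combination found in "
        f"{max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Labelled datasets

@dataclass
class LabeledDataset:
    """A featurized, labelled, per-family per-modality training table."""

    family: FamilySignature
    modality: str
    X: pd.DataFrame
    y: np.ndarray
    provenance: pd.DataFrame  # columns: source_id, site

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.provenance):
            raise ValueError("X, y and provenance must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_positive(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.y == 0).sum())

    @property
    def class_ratio(self) -> float:
        """Negative:positive ratio."""
        return self.n_negative / self.n_positive

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            family=self.family,
            modality=self.modality,
            X=self.X.iloc[indices].reset_index(drop=True),
            y=self.y[indices],
            provenance=self.provenance.iloc[indices].reset_index(drop=True),
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write the feature table as TSV plus a JSON schema sidecar."""
        path = Path(path)
        table = pd.concat(
            [self.provenance.reset_index(drop=True),
             self.X.reset_index(drop=True)], axis=1
        )
        table["label"] = self.y
        table.to_csv(path, sep="\t", index=False)
        sidecar = {
            "format": "zincsite-dataset",
            "version": DATASET_FORMAT_VERSION,
            "family": self.family.canonical_name,
            "modality": self.modality,
            "columns": list(self.X.columns),
        }
        path.with_suffix(".schema.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "LabeledDataset":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".schema.json").read_text())
        if sidecar.get("format") != "zincsite-dataset":
            raise ValueError(f"{path} is not a zincsite dataset")
        table = pd.read_csv(path, sep="\t")
        columns = sidecar["columns"]
        return cls(
            family=FamilySignature.parse(sidecar["family"]),
            modality=sidecar["modality"],
            X=table[columns].astype(float),
            y=table["label"].to_numpy(dtype=int),
            provenance=table[["source_id", "site"]],
        )


def _candidate_site_label(candidate) -> str:
    if isinstance(candidate, SequenceSiteCandidate):
        return ",".join(str(p + 1) for p in candidate.positions)
    return ",".join(candidate.residue_labels)


def build_balanced_dataset(
    positives: Sequence[Union[SequenceSiteCandidate, StructureSiteCandidate]],
    negative_sampler: Callable[[np.random.Generator], object],
    featurizer,
    rng: RngLike = 0,
    distinct: bool = True,
) -> LabeledDataset:
    """Featurize positives plus an equal number of sampled negatives.

    ``negative_sampler`` is called with the run's random generator once per
    required negative; if it raises :class:`SamplingExhaustedError` the
    dataset is returned partially balanced with a warning (the achieved
    ratio is available as :attr:`LabeledDataset.class_ratio`).  Rows are
    shuffled deterministically under the seed.

    With ``distinct`` (the default) a drawn negative that duplicates an
    earlier one is redrawn, emulating sampling from an effectively unbounded
    non-binding pool: repeated rows from a small pool would otherwise
    straddle any train/test split and let a classifier memorize them.
    """
    if not positives:
        raise ValueError("need at least one positive example")
    rng = _as_rng(rng)
    family = positives[0].family
    negatives = []
    seen: set = set()
    exhausted = None
    for _ in range(len(positives)):
        try:
            for _attempt in range(MAX_SAMPLING_ATTEMPTS):
                candidate = negative_sampler(rng)
                key = (candidate.source_id, _candidate_site_label(candidate))
                if not distinct or key not in seen:
                    seen.add(key)
                    negatives.append(candidate)
                    break
            else:
                exhausted = "no more distinct negative candidates"
        except SamplingExhaustedError as exc:
            exhausted = str(exc)
        if exhausted:
            warnings.warn(
                f"negative sampling exhausted after {len(negatives)} of "
                f"{len(positives)} samples: {exhausted}"
            )
            break
    candidates = list(positives) + negatives
    features = featurizer.transform(candidates)
    columns = featurizer.feature_names(family)
    y = np.array([1] * len(positives) + [0] * len(negatives), dtype=int)
    provenance = pd.DataFrame({
        "source_id": [c.source_id or "" for c in candidates],
        "site": [_candidate_site_label(c) for c in candidates],
    })
    order = rng.permutation(len(candidates))
    return LabeledDataset(
        family=family,
        modality=featurizer.modality,
        X=pd.DataFrame(features, columns=columns).iloc[order].reset_index(drop=True),
        y=y[order],
        provenance=provenance.iloc[order].reset_index(drop=True),
    )
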