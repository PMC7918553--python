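"""Synthetic sequences, structures, catalogues and cluster files.

The generators plant parameterized zinc-site-like signal so the whole
pipeline — enumeration, featurization, balanced dataset building, training,
prediction — runs and can be calibrated with no external downloads.

Sequence fixtures: each *positive* sequence embeds one family-matching
arrangement whose inter-residue gaps are drawn from the positive gap
distribution and whose flanks are biased towards hydrophobic residues;
each *background* sequence embeds one arrangement drawn from a different
(negative) gap distribution with unbiased flanks.  Context residues never
include C/H/D/E, so every generated sequence contains exactly one
family-matching combination.  Setting the negative distribution equal to the
positive one and the bias to zero gives the null regime in which positives
and negatives are statistically indistinguishable.

Structure fixtures: positive structures carry a planted site whose
liganding residues sit on a regular simplex with edge length
``site_distance_scale`` (first-shell-like, default 6 A) plus coordinate
jitter, embedded in a shell of decoy residues; background structures carry
the same residue types at decoy geometry (default 20 A).  Context atoms
around the site centroid exercise the hydrophobic-contrast descriptor.

These fixtures calibrate code, not biology: no claim of statistical realism
of real zinc sites is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .datasets import SiteCatalogueEntry
from .families import FamilySignature
from .structures import ProteinStructure, Residue, write_pdb

#: Residues used for sequence context; never C/H/D/E, so planted
#: arrangements are the only family-matching combinations.
BACKGROUND_ALPHABET = "AFGIKLMNPQRSTVWY"
HYDROPHOBIC_RESIDUES = "ILVFWM"
DECOY_RESIDUE_TYPES = "AGLSTVP"


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the planted-signal generators.

    Distances in Angstroms; gap parameters in residues.  The defaults give
    the strong-signal regime: short, tight positive gaps with hydrophobic
    flanks versus long, loose background gaps, and first-shell-scale site
    geometry (6 A) versus distant decoy geometry (20 A).
    """

    family: str = "C2H2"
    n_positives: int = 250
    n_background: int = 250
    seed: int = 0
    # sequence generation
    sequence_length: int = 120
    pos_gap_mean: float = 3.0
    pos_gap_spread: float = 1.0
    neg_gap_mean: float = 15.0
    neg_gap_spread: float = 4.0
    hydro_bias: float = 0.9
    # structure generation
    site_distance_scale: float = 6.0
    site_jitter: float = 0.4
    decoy_scale: float = 20.0
    decoy_jitter: float = 1.0
    n_decoy_residues: int = 20
    n_context_atoms: int = 40
    resolution_range: tuple[float, float] = (1.2, 1.9)

    def __post_init__(self) -> None:
        if self.n_positives < 1 or self.n_background < 1:
            raise ValueError("counts must be >= 1")
        for name in ("pos_gap_mean", "neg_gap_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("pos_gap_spread", "neg_gap_spread", "site_jitter",
                     "decoy_jitter", "hydro_bias"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.site_distance_scale <= 0 or self.decoy_scale <= 0:
            raise ValueError("distance scales must be positive")
        sig = FamilySignature.parse(self.family)
        if self.sequence_length < sig.site_size + 10:
            raise ValueError("sequence_length too short for the family")

    @property
    def signature(self) -> FamilySignature:
        return FamilySignature.parse(self.family)

    def null_variant(self) -> "FixtureConfig":
        """The no-signal configuration: positives drawn like background."""
        return replace(
            self,
            neg_gap_mean=self.pos_gap_mean,
            neg_gap_spread=self.pos_gap_spread,
            hydro_bias=0.0,
            decoy_scale=self.site_distance_scale,
            decoy_jitter=self.site_jitter,
        )


# ---------------------------------------------------------------------------
# Sequence fixtures

def _plant_arrangement(
    rng: np.random.Generator,
    config: FixtureConfig,
    gap_mean: float,
    gap_spread: float,
    bias: float,
) -> tuple[str, tuple[int, ...]]:
    sig = config.signature
    k = sig.site_size
    length = config.sequence_length
    letters = list(sig.residue_letters)
    order = rng.permutation(k)
    placed_letters = [letters[i] for i in order]

    gap_cap = max(0, (length - k - 2) // max(1, k - 1))
    gaps = [
        int(np.clip(round(rng.normal(gap_mean, gap_spread)), 0, gap_cap))
        for _ in range(k - 1)
    ]
    span = k + sum(gaps)
    start = int(rng.integers(0, length - span + 1))
    positions = [start]
    for gap in gaps:
        positions.append(positions[-1] + gap + 1)

    seq = list(rng.choice(list(BACKGROUND_ALPHABET), size=length))
    for pos, letter in zip(positions, placed_letters):
        seq[pos] = letter
    if bias > 0:
        binding = set(positions)
        for pos in positions:
            for offset in (-2, -1, 1, 2):
                idx = pos + offset
                if 0 <= idx < length and idx not in binding and rng.random() < bias:
                    seq[idx] = str(rng.choice(list(HYDROPHOBIC_RESIDUES)))
    return "".join(seq), tuple(positions)


@dataclass
class SequenceFixtures:
    """Generated sequences plus the catalogue of their planted sites."""

    sequences: dict[str, str]
    catalogue: list[SiteCatalogueEntry]
    positive_ids: list[str]
    background_ids: list[str]

    @property
    def background_pool(self) -> dict[str, str]:
        return {i: self.sequences[i] for i in self.background_ids}


def generate_sequence_fixtures(config: FixtureConfig) -> SequenceFixtures:
    """Generate positive and background sequences with planted arrangements.

    Fully reproducible under ``config.seed``; the catalogue lists exactly
    ``config.n_positives`` sites.
    """
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    catalogue: list[SiteCatalogueEntry] = []
    positive_ids, background_ids = [], []

    for i in range(config.n_positives):
        seq_id = f"pos_{i:04d}"
        seq, positions = _plant_arrangement(
            rng, config, config.pos_gap_mean, config.pos_gap_spread,
            config.hydro_bias,
        )
        sequences[seq_id] = seq
        positive_ids.append(seq_id)
        catalogue.append(SiteCatalogueEntry(
            site_id=f"site_{seq_id}",
            family=config.signature,
            source_id=seq_id,
            modality="sequence",
            chains=("A",),
            positions=positions,
        ))
    for i in range(config.n_background):
        seq_id = f"bg_{i:04d}"
        seq, _ = _plant_arrangement(
            rng, config, config.neg_gap_mean, config.neg_gap_spread, 0.0,
        )
        sequences[seq_id] = seq
        background_ids.append(seq_id)
    return SequenceFixtures(sequences, catalogue, positive_ids, background_ids)


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path]) -> None:
    """Write sequences to FASTA, 60 columns, in mapping order."""
    lines = []
    for seq_id, seq in sequences.items():
        lines.append(f">{seq_id}")
        for i in range(0, len(seq), 60):
            lines.append(seq[i:i + 60])
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Structure fixtures

def _simplex(k: int, edge: float) -> np.ndarray:
    """k points (k in 2..4) with all pairwise distances equal to ``edge``."""
    if k == 2:
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    elif k == 3:
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
    elif k == 4:
        pts = np.array(
            [[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
        ) / (2 * np.sqrt(2))
    else:
        raise ValueError(f"site size {k} not supported (2-4)")
    pts = pts * edge
    return pts - pts.mean(axis=0)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _build_structure(
    rng: np.random.Generator,
    config: FixtureConfig,
    structure_id: str,
    edge: float,
    jitter: float,
) -> tuple[ProteinStructure, tuple[tuple[str, int, str], ...]]:
    sig = config.signature
    k = sig.site_size
    letters = [sig.residue_letters[i] for i in rng.permutation(k)]
    cas = _simplex(k, edge)
    if jitter > 0:
        cas = cas + rng.normal(0.0, jitter, size=cas.shape)
    centroid = cas.mean(axis=0)

    residues: list[Residue] = []
    site_labels = []
    for i, (letter, ca) in enumerate(zip(letters, cas)):
        direction = centroid - ca
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else _random_unit(rng)
        cb = ca + 1.53 * direction
        number = 10 + 2 * i
        residues.append(Residue("A", number, "", letter, ca, cb))
        site_labels.append(("A", number, ""))

    for i in range(config.n_decoy_residues):
        res_type = str(rng.choice(list(DECOY_RESIDUE_TYPES)))
        ca = _random_unit(rng) * rng.uniform(15.0, 30.0)
        cb = ca + 1.53 * _random_unit(rng)
        residues.append(Residue("A", 100 + i, "", res_type, ca, cb))

    elements: list[str] = []
    coords: list[np.ndarray] = []
    for res in residues:  # order must match write_pdb's residue-atom order
        elements.extend(["C", "C"])
        coords.extend([res.ca, res.cb])
    for _ in range(config.n_context_atoms):
        elements.append(str(rng.choice(["C", "N", "O"])))
        offset = _random_unit(rng) * rng.uniform(0.0, 5.0)
        coords.append(centroid + offset)

    resolution = float(rng.uniform(*config.resolution_range))
    structure = ProteinStructure(
        id=structure_id,
        residues=residues,
        atom_elements=tuple(elements),
        atom_coords=np.array(coords, dtype=float),
        resolution=resolution,
    )
    return structure, tuple(site_labels)


@dataclass
class StructureFixtures:
    """Generated structures plus the catalogue of their planted sites."""

    structures: dict[str, ProteinStructure]
    catalogue: list[SiteCatalogueEntry]
    positive_ids: list[str]
    background_ids: list[str]

    @property
    def background_pool(self) -> dict[str, ProteinStructure]:
        return {i: self.structures[i] for i in self.background_ids}

    def write_pdbs(self, directory: Union[str, Path]) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for structure_id, structure in self.structures.items():
            path = directory / f"{structure_id}.pdb"
            write_pdb(structure, path)
            paths.append(path)
        return paths


def generate_structure_fixtures(config: FixtureConfig) -> StructureFixtures:
    """Generate positive and background (decoy-geometry) structures.

    With ``site_jitter == 0`` the planted site's inter-C-alpha distances all
    equal ``site_distance_scale`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    structures: dict[str, ProteinStructure] = {}
    catalogue: list[SiteCatalogueEntry] = []
    positive_ids, background_ids = [], []

    for i in range(config.n_positives):
        structure_id = f"pos_{i:04d}"
        structure, site_labels = _build_structure(
            rng, config, structure_id,
            edge=config.site_distance_scale, jitter=config.site_jitter,
        )
        structures[structure_id] = structure
        positive_ids.append(structure_id)
        catalogue.append(SiteCatalogueEntry(
            site_id=f"site_{structure_id}",
            family=config.signature,
            source_id=structure_id,
            modality="structure",
            chains=("A",),
            residues=site_labels,
            resolution=structure.resolution,
        ))
    for i in range(config.n_background):
        structure_id = f"bg_{i:04d}"
        structure, _ = _build_structure(
            rng, config, structure_id,
            edge=config.decoy_scale, jitter=config.decoy_jitter,
        )
        structures[structure_id] = structure
        background_ids.append(structure_id)
    return StructureFixtures(structures, catalogue, positive_ids, background_ids)


# ---------------------------------------------------------------------------
# Toy clustering (stand-in for externally produced CD-HIT assignments)

def _kmer_set(sequence: str, k: int = 3) -> frozenset:
    return frozenset(sequence[i:i + k] for i in range(len(sequence) - k + 1))


def generate_cluster_file(
    sequences: Mapping[str, str],
    identity_proxy: float,
    seed: int = 0,
    path: Optional[Union[str, Path]] = None,
) -> dict[str, str]:
    """Greedy toy clustering by shared 3-mer fraction (Jaccard similarity).

    A test-only stand-in producing the entry -> cluster TSV format that the
    redundancy filter consumes; real workflows supply CD-HIT assignments.
    Sequences whose 3-mer Jaccard similarity with a cluster representative
    is >= ``identity_proxy`` join that cluster.  Deterministic under seed.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if not 0 <= identity_proxy <= 1:
        raise ValueError("identity_proxy must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = list(sequences)
    order = [ids[i] for i in rng.permutation(len(ids))]

    representatives: list[tuple[str, frozenset]] = []  # (cluster id, kmer set)
    assignment: dict[str, str] = {}
    for seq_id in order:
        kmers = _kmer_set(sequences[seq_id])
        placed = False
        for cluster_id, rep_kmers in representatives:
            union = len(kmers | rep_kmers)
            jaccard = len(kmers & rep_kmers) / union if union else 1.0
            if jaccard >= identity_proxy:
                assignment[seq_id] = cluster_id
                placed = True
                break
        if not placed:
            cluster_id = f"cluster_{len(representatives):04d}"
            representatives.append((cluster_id, kmers))
            assignment[seq_id] = cluster_id

    if path is not None:
        lines = ["entry_id\tcluster_id"]
        lines += [f"{seq_id}\t{assignment[seq_id]}" for seq_id in sorted(assignment)]
        Path(path).write_text("\n".join(lines) + "\n")
    return assignment
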