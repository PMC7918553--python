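"""Scanning sequences, structures and proteomes with trained family models.

Every family-matching candidate in the query is enumerated, featurized with
that family's schema and scored by the family's model; candidates at or
above the probability threshold are reported as hits, best first.  A
proteome is summarized by the fraction of its sequences with at least one
hit in any family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from .families import (
    DEFAULT_MAX_CA_DISTANCE,
    DEFAULT_MAX_SPAN,
    FamilySignature,
    enumerate_sequence_candidates,
    enumerate_structure_candidates,
)
from .model import ModelBundle
from .seqfeatures import SequenceSiteFeaturizer
from .structfeatures import StructureSiteFeaturizer
from .structures import ProteinStructure


@dataclass(frozen=True)
class PredictionHit:
    """One predicted zinc-binding site.

    ``residues`` holds 1-based sequence positions (sequence modality) or
    chain:number labels (structure modality).
    """

    query_id: str
    family: str
    residues: tuple
    probability: float
    modality: str

    def as_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "family": self.family,
            "residues": list(self.residues),
            "probability": self.probability,
            "modality": self.modality,
        }


BundleMap = Mapping[str, ModelBundle]


def _select_bundles(
    bundles: BundleMap,
    families: Optional[Iterable[str]],
    modality: str,
) -> dict[str, ModelBundle]:
    for name, bundle in bundles.items():
        if bundle.modality != modality:
            raise ValueError(
                f"bundle {name} has modality {bundle.modality!r}; expected {modality!r}"
            )
    if families is None:
        return dict(bundles)
    chosen = {}
    for name in families:
        canonical = FamilySignature.parse(name).canonical_name
        if canonical not in bundles:
            raise ValueError(
                f"no model for family {canonical}; available: {sorted(bundles)}"
            )
        chosen[canonical] = bundles[canonical]
    return chosen


def _sorted_hits(hits: list[PredictionHit]) -> list[PredictionHit]:
    return sorted(hits, key=lambda h: (-h.probability, h.family, h.residues))


def predict_sequence(
    sequence: str,
    bundles: BundleMap,
    families: Optional[Iterable[str]] = None,
    threshold: float = 0.5,
    max_span: int = DEFAULT_MAX_SPAN,
    query_id: str = "query",
    scale: str = "interface",
) -> list[PredictionHit]:
    """Scan one sequence against per-family sequence models.

    Returns hits with probability >= ``threshold``, sorted by descending
    probability.  ``families`` restricts the scan to a subset of the loaded
    models (each requested family must have one).
    """
    chosen = _select_bundles(bundles, families, "sequence")
    featurizer = SequenceSiteFeaturizer(scale=scale)
    hits: list[PredictionHit] = []
    for name, bundle in sorted(chosen.items()):
        family = FamilySignature.parse(name)
        candidates = enumerate_sequence_candidates(
            sequence, family, max_span=max_span, source_id=query_id
        )
        if not candidates:
            continue
        probs = bundle.predict_proba_positive(featurizer.transform(candidates))
        for candidate, prob in zip(candidates, probs):
            if prob >= threshold:
                hits.append(PredictionHit(
                    query_id=query_id,
                    family=name,
                    residues=tuple(p + 1 for p in candidate.positions),
                    probability=float(prob),
                    modality="sequence",
                ))
    return _sorted_hits(hits)


def predict_structure(
    structure: ProteinStructure,
    bundles: BundleMap,
    families: Optional[Iterable[str]] = None,
    threshold: float = 0.5,
    max_ca_distance: float = DEFAULT_MAX_CA_DISTANCE,
) -> list[PredictionHit]:
    """Scan one structure against per-family structure models.

    Candidate combinations respect the inter-C-alpha feasibility cutoff.
    """
    chosen = _select_bundles(bundles, families, "structure")
    featurizer = StructureSiteFeaturizer()
    hits: list[PredictionHit] = []
    for name, bundle in sorted(chosen.items()):
        family = FamilySignature.parse(name)
        candidates = enumerate_structure_candidates(
            structure, family, max_ca_distance=max_ca_distance
        )
        if not candidates:
            continue
        probs = bundle.predict_proba_positive(featurizer.transform(candidates))
        for candidate, prob in zip(candidates, probs):
            if prob >= threshold:
                hits.append(PredictionHit(
                    query_id=structure.id,
                    family=name,
                    residues=candidate.residue_labels,
                    probability=float(prob),
                    modality="structure",
                ))
    return _sorted_hits(hits)


def proteome_scan(
    sequences: Union[str, Path, Mapping[str, str]],
    bundles: BundleMap,
    threshold: float = 0.5,
    families: Optional[Iterable[str]] = None,
    max_span: int = DEFAULT_MAX_SPAN,
) -> tuple[dict[str, dict], float]:
    """Scan a proteome FASTA (or id -> sequence mapping) with all models.

    A sequence is labelled zinc-binding if any family's model finds at least
    one site in it.  Returns per-sequence verdicts (with the best hit per
    family) and the fraction of sequences labelled zinc-binding.
    """
    if isinstance(sequences, (str, Path)):
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(sequences), "fasta")}
    else:
        records = dict(sequences)
    if not records:
        raise ValueError("no sequences to scan")
    verdicts: dict[str, dict] = {}
    n_binding = 0
    for seq_id in records:
        hits = predict_sequence(
            records[seq_id], bundles, families=families,
            threshold=threshold, max_span=max_span, query_id=seq_id,
        )
        best: dict[str, PredictionHit] = {}
        for hit in hits:
            if hit.family not in best:  # hits are sorted best-first
                best[hit.family] = hit
        binding = bool(hits)
        n_binding += binding
        verdicts[seq_id] = {
            "zinc_binding": binding,
            "best_hits": {fam: hit.as_dict() for fam, hit in best.items()},
        }
    return verdicts, n_binding / len(records)


def hits_to_tsv(hits: Sequence[PredictionHit], path: Union[str, Path]) -> None:
    """One hit per row: query id, family, residues, probability, modality."""
    lines = ["query_id\tfamily\tresidues\tprobability\tmodality"]
    for hit in hits:
        residues = ",".join(str(r) for r in hit.residues)
        lines.append(
            f"{hit.query_id}\t{hit.family}\t{residues}\t{hit.probability:.6f}\t{hit.modality}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def hits_to_json(hits: Sequence[PredictionHit], path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps([hit.as_dict() for hit in hits], indent=1))


def load_bundles(directory: Union[str, Path], modality: Optional[str] = None) -> dict[str, ModelBundle]:
    """Load every ``*.bundle`` model in a directory, keyed by family name."""
    bundles = {}
    for path in sorted(Path(directory).glob("*.bundle")):
        bundle = ModelBundle.load(path)
        if modality is not None and bundle.modality != modality:
            continue
        bundles[bundle.family] = bundle
    return bundles
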