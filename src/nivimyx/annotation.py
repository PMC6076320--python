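"""Tiered taxonomic assignment of soil OTUs against a reference barcode set.

Assignment rules follow the two-tier scheme used for snowbank-myxomycete
metabarcoding: an OTU is assigned to the best-matching reference
*morphospecies* when its identity is >= 98.0% and a bootstrap confidence
score exceeds 90%; OTUs whose best identity falls in [95%, 98%) are assigned
to the *genus* of the best match; anything below stays unassigned but its
best hit is still reported. The confidence score is a k-mer bootstrap
(resampling 1/k of the query's k-mers, k = 8, 100 replicates): the fraction
of replicates in which the top-scoring species equals the full-data top
species.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError
from .otu import OtuTable
from .sequences import SequenceRecord, global_identity

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchPolicy:
    species_identity: float = 0.98
    species_confidence: float = 0.90
    genus_identity_low: float = 0.95
    near: float = 0.991
    exact: float = 1.0

    def __post_init__(self) -> None:
        if not (self.genus_identity_low < self.species_identity <= self.near <= self.exact):
            raise ContractError("MatchPolicy thresholds must satisfy "
                                "genus_identity_low < species_identity <= near <= exact")


@dataclass
class Reference:
    id: str
    sequence: str
    species: str
    genus: str
    nivicolous: bool = True


@dataclass
class AnnotationResult:
    otu_id: str
    best_ref_id: str
    best_identity: float
    confidence: float | None
    assigned_rank: str  # species | genus | unassigned
    assigned_name: str | None


class ReferenceDB:
    """A set of labelled reference barcodes with 8-mer indices per species."""

    def __init__(self, refs: Sequence[Reference], k: int = 8):
        if not refs:
            raise ContractError("empty reference database")
        self.refs = sorted(refs, key=lambda r: r.id)
        self.k = k
        self._species_kmers: dict[str, set[int]] = {}
        for r in self.refs:
            self._species_kmers.setdefault(r.species, set()).update(_kmer_codes(r.sequence, k))

    @property
    def species(self) -> list[str]:
        return sorted(self._species_kmers)

    def species_kmers(self, species: str) -> set[int]:
        return self._species_kmers[species]

    def nivicolous_species(self) -> set[str]:
        return {r.species for r in self.refs if r.nivicolous}

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord],
                     nivicolous: dict[str, bool] | None = None, k: int = 8) -> "ReferenceDB":
        refs = []
        for r in records:
            if not r.morphospecies or not r.genus:
                raise FormatError(f"reference {r.id} lacks species/genus labels")
            niv = True if nivicolous is None else nivicolous.get(r.morphospecies, True)
            refs.append(Reference(r.id, r.sequence, r.morphospecies, r.genus, niv))
        return cls(refs, k=k)

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = 8) -> "ReferenceDB":
        """Read ``id|species|genus|nivicolous{0,1}`` headers."""
        from Bio import SeqIO

        refs = []
        for bio in SeqIO.parse(str(path), "fasta"):
            parts = bio.description.split("|")
            if len(parts) != 4:
                raise FormatError(f"reference header {bio.description!r} is not id|species|genus|niv")
            refs.append(Reference(parts[0], str(bio.seq).upper(), parts[1], parts[2], parts[3] == "1"))
        return cls(refs, k=k)


_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _kmer_codes(seq: str, k: int) -> list[int]:
    """Integer codes of all A/C/G/T k-mers (windows with ambiguity are skipped)."""
    codes = []
    for i in range(len(seq) - k + 1):
        code = 0
        ok = True
        for ch in seq[i:i + k]:
            b = _BASE.get(ch)
            if b is None:
                ok = False
                break
            code = (code << 2) | b
        if ok:
            codes.append(code)
    return codes


def best_hit(otu_seq: str, refdb: ReferenceDB) -> tuple[str, float]:
    """Best reference by global identity; ties go to the smaller ref id."""
    best_id, best_ident = None, -1.0
    for ref in refdb.refs:  # sorted by id, so first max wins ties
        ident = global_identity(otu_seq, ref.sequence).identity
        if ident > best_ident:
            best_id, best_ident = ref.id, ident
    return best_id, best_ident


def _score_species(kmers: Sequence[int], refdb: ReferenceDB) -> dict[str, int]:
    return {
        sp: sum(1 for km in kmers if km in refdb.species_kmers(sp))
        for sp in refdb.species
    }


def confidence_score(otu_seq: str, refdb: ReferenceDB, n_bootstrap: int = 100,
                     k: int = 8, seed: int | np.random.Generator = 0) -> float:
    """Bootstrap support for the full-data top species of ``otu_seq``.

    Each replicate resamples ceil(n_kmers / k) of the query's k-mers with
    replacement and re-scores every reference species by shared-k-mer count;
    the returned value is the fraction of replicates whose winner equals the
    full-data winner. Deterministic for a fixed seed.
    """
    if k > len(otu_seq):
        raise ContractError("k-mer size exceeds sequence length")
    if n_bootstrap < 1:
        raise ContractError("n_bootstrap must be >= 1")
    kmers = _kmer_codes(otu_seq, k)
    if not kmers:
        return 0.0
    full_winner = _top_species_lex(_score_species(kmers, refdb))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = math.ceil(len(kmers) / k)
    kmer_arr = np.asarray(kmers)
    hits = 0
    for _ in range(n_bootstrap):
        sample = kmer_arr[rng.integers(0, len(kmers), size=m)]
        winner = _top_species_lex(_score_species(sample.tolist(), refdb))
        if winner == full_winner:
            hits += 1
    return hits / n_bootstrap


def _top_species_lex(counts: dict[str, int]) -> str:
    best, best_n = None, -1
    for sp in sorted(counts):
        if counts[sp] > best_n:
            best, best_n = sp, counts[sp]
    return best


@dataclass
class AnnotationSummary:
    n_otus: int
    n_species_rank: int
    n_genus_rank: int
    n_unassigned: int
    annotated_read_fraction: float  # reads of species-ranked OTUs / all reads
    n_morphospecies: int
    n_nivicolous_morphospecies: int
    nivicolous_read_fraction: float


def annotate_otus(otu_table: OtuTable, refdb: ReferenceDB, policy: MatchPolicy | None = None,
                  n_bootstrap: int = 100, seed: int = 0) -> tuple[list[AnnotationResult], AnnotationSummary]:
    """Apply the tiered assignment rules to every OTU in the table."""
    policy = policy or MatchPolicy()
    ref_by_id = {r.id: r for r in refdb.refs}
    rng = np.random.default_rng(seed)
    results: list[AnnotationResult] = []
    for otu_id in otu_table.otu_ids:
        seq = otu_table.rep_seqs.get(otu_id)
        if not seq:
            msg = f"OTU {otu_id} has no representative sequence; skipped"
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        ref_id, ident = best_hit(seq, refdb)
        ref = ref_by_id[ref_id]
        conf = None
        rank, name = "unassigned", None
        if ident >= policy.species_identity:
            conf = confidence_score(seq, refdb, n_bootstrap=n_bootstrap, k=refdb.k, seed=rng)
            if conf > policy.species_confidence:
                rank, name = "species", ref.species
            else:
                rank, name = "genus", ref.genus
        elif ident >= policy.genus_identity_low:
            rank, name = "genus", ref.genus
        results.append(AnnotationResult(otu_id, ref_id, ident, conf, rank, name))

    reads = otu_table.reads_per_otu()
    total = float(reads.sum())
    species_ranked = [r for r in results if r.assigned_rank == "species"]
    niv_species = refdb.nivicolous_species()
    niv_reads = sum(reads[r.otu_id] for r in species_ranked if r.assigned_name in niv_species)
    summary = AnnotationSummary(
        n_otus=len(results),
        n_species_rank=len(species_ranked),
        n_genus_rank=sum(r.assigned_rank == "genus" for r in results),
        n_unassigned=sum(r.assigned_rank == "unassigned" for r in results),
        annotated_read_fraction=(sum(reads[r.otu_id] for r in species_ranked) / total) if total else 0.0,
        n_morphospecies=len({r.assigned_name for r in species_ranked}),
        n_nivicolous_morphospecies=len({r.assigned_name for r in species_ranked
                                        if r.assigned_name in niv_species}),
        nivicolous_read_fraction=(niv_reads / total) if total else 0.0,
    )
    return results, summary


def annotations_to_frame(results: Sequence[AnnotationResult], otu_table: OtuTable) -> pd.DataFrame:
    reads = otu_table.reads_per_otu()
    return pd.DataFrame([
        {
            "otu_id": r.otu_id,
            "best_ref": r.best_ref_id,
            "identity": r.best_identity,
            "confidence": r.confidence,
            "rank": r.assigned_rank,
            "name": r.assigned_name,
            "reads_total": int(reads.get(r.otu_id, 0)),
        }
        for r in results
    ])
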