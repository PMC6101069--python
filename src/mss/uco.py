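"""Ultra-conserved-ortholog (UCO) profiling and species ranking.

UCOs are a panel of 357 single-copy genes conserved across most eukaryotes.
Because each species carries (at most) one representative per UCO, sequence
similarity of matched UCOs is a fast proxy for evolutionary distance: a
query transcriptome's UCO-bearing contigs are aligned against every
candidate species' representative UCOs, each contig votes for the species
holding its best-scoring representative, and species are ranked by votes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import align
from .align import NUCLEOTIDE, PROTEIN, AlignmentHit, SequenceRecord
from .errors import NoUCOContigsError

logger = logging.getLogger(__name__)

TOTAL_UCOS = 357  # size of the canonical eukaryotic UCO panel


@dataclass(frozen=True)
class ProfileEntry:
    """Best-matching protein for one UCO in one species."""

    protein_id: str
    bit_score: float
    e_value: float
    sequence: str  # representative protein sequence, kept for later comparisons


@dataclass
class UCOProfile:
    """Per-species map UCO id -> representative protein (best hit under the
    identification E-value threshold)."""

    species_id: str
    entries: dict[str, ProfileEntry] = field(default_factory=dict)

    @property
    def completeness(self) -> int:
        return len(self.entries)


@dataclass
class UCORanking:
    ranked: list[tuple[str, float]]  # (species id, vote score), best first
    top_k: int
    distinct_ucos: dict[str, int] = field(default_factory=dict)

    @property
    def top(self) -> list[str]:
        return [s for s, _ in self.ranked[: self.top_k]]


def build_uco_profiles(
    uco_proteins: list[SequenceRecord],
    proteomes: dict[str, list[SequenceRecord]],
    evalue_max: float = align.DEFAULT_EVALUE_MAX,
) -> list[UCOProfile]:
    """Identify each UCO's best-matching protein in every proteome.

    For each (species, UCO) pair the proteome is scanned with the local
    aligner; the highest-scoring protein is kept if its E-value against the
    whole proteome passes ``evalue_max``.  Species order of the result
    follows sorted species id.
    """
    if not uco_proteins:
        raise ValueError("empty UCO protein set")
    profiles = []
    for species in sorted(proteomes):
        prots = proteomes[species]
        profile = UCOProfile(species_id=species)
        if not prots:
            logger.warning("species %s: empty proteome, completeness 0", species)
            profiles.append(profile)
            continue
        db_residues = sum(len(p) for p in prots)
        for uco in uco_proteins:
            best: tuple[float, str, AlignmentHit] | None = None
            for prot in prots:
                hit = align.smith_waterman(uco, prot, score_only=True)
                key = (-hit.bit_score, prot.id)
                if best is None or key < best[:2]:
                    best = (*key, hit, prot.sequence)
            _, pid, hit, seq = best
            ev = align.evalue(hit.raw_score, len(uco), db_residues)
            if ev < evalue_max:
                profile.entries[uco.id] = ProfileEntry(
                    protein_id=pid, bit_score=hit.bit_score, e_value=ev, sequence=seq)
        profiles.append(profile)
    return profiles


def find_uco_contigs(
    contigs: list[SequenceRecord],
    uco_proteins: list[SequenceRecord],
    evalue_max: float = align.DEFAULT_EVALUE_MAX,
) -> dict[str, tuple[str, AlignmentHit]]:
    """Assign each contig to at most one UCO by translated search.

    Every contig is translated in all six frames and aligned against every
    UCO protein; the best bit score across frames wins.  Contigs with no
    hit passing ``evalue_max`` are omitted.  The returned hit carries the
    winning frame.
    """
    db_residues = sum(len(u) for u in uco_proteins)
    assignments: dict[str, tuple[str, AlignmentHit]] = {}
    for contig in contigs:
        if contig.alphabet != NUCLEOTIDE:
            raise ValueError(f"contig {contig.id!r} is not nucleotide")
        best: tuple[tuple, str, AlignmentHit, int] | None = None
        for frame_rec in align.six_frame_translate(contig):
            frame = align.frame_of(frame_rec.id)
            for uco in uco_proteins:
                hit = align.smith_waterman(frame_rec, uco, score_only=True)
                key = (-hit.bit_score, uco.id, abs(frame), -frame)
                if best is None or key < best[0]:
                    best = (key, uco.id, hit, frame)
        if best is None:
            continue
        _, uco_id, hit, frame = best
        ev = align.evalue(hit.raw_score, (len(contig) // 3) or 1, db_residues)
        if ev < evalue_max:
            assignments[contig.id] = (uco_id, AlignmentHit(
                query_id=contig.id, subject_id=hit.subject_id,
                bit_score=hit.bit_score, raw_score=hit.raw_score,
                e_value=ev, frame=frame))
    return assignments


def rank_species_by_uco(
    uco_contigs: dict[str, tuple[str, AlignmentHit]],
    contig_records: dict[str, SequenceRecord],
    profiles: list[UCOProfile],
    top_k: int = 3,
) -> UCORanking:
    """Rank candidate species by how many query UCO contigs map best to them.

    Each assigned contig is translated and aligned against every species'
    representative protein for its UCO; the species with the top raw score
    earns one vote (split 1/t across t tied species, so votes always sum to
    the number of voting contigs).  Species ranked by total votes, ties by
    ascending species id.
    """
    if not profiles:
        raise ValueError("no UCO profiles supplied")
    if not uco_contigs:
        raise NoUCOContigsError(
            "no UCO contigs identified; use taxonomy-based selection")
    votes: dict[str, float] = {p.species_id: 0.0 for p in profiles}
    distinct: dict[str, set] = {p.species_id: set() for p in profiles}
    by_species = {p.species_id: p for p in profiles}
    for contig_id, (uco_id, _) in sorted(uco_contigs.items()):
        contig = contig_records[contig_id]
        frames = align.six_frame_translate(contig)
        scores: dict[str, int] = {}
        for species in sorted(by_species):
            entry = by_species[species].entries.get(uco_id)
            if entry is None:
                continue
            rep = SequenceRecord(id=f"{species}|{uco_id}",
                                 sequence=entry.sequence, alphabet=PROTEIN)
            best = max(
                align.smith_waterman(fr, rep, score_only=True).raw_score
                for fr in frames)
            scores[species] = best
        if not scores:
            continue
        top = max(scores.values())
        if top <= 0:
            continue
        winners = sorted(s for s, v in scores.items() if v == top)
        for w in winners:
            votes[w] += 1.0 / len(winners)
            distinct[w].add(uco_id)
    ranked = sorted(votes.items(), key=lambda sv: (-sv[1], sv[0]))
    return UCORanking(ranked=ranked, top_k=top_k,
                      distinct_ucos={s: len(u) for s, u in distinct.items()})


def uco_completeness_summary(profiles: list[UCOProfile],
                             panel_size: int = TOTAL_UCOS) -> pd.DataFrame:
    """Per-species completeness table: UCOs found and fraction of the panel."""
    rows = [(p.species_id, p.completeness, p.completeness / panel_size)
            for p in profiles]
    return pd.DataFrame(rows, columns=["species_id", "completeness", "fraction"])
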