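"""Sequence analysis: (UG)k repeat scanning, regulation mapping, and
amino-acid composition profiling.

The circadian RNA-binding factor CHLAMY1 recognises perfect, uninterrupted
UG dinucleotide repeats of at least seven units in mRNA 3' UTRs and
represses translation of the bound messages during the night.  The scanner
reports maximal UG runs (a nine-unit run is one hit, not three overlapping
seven-unit hits); only the given sense strand is scanned, since the factor
binds mRNA.  T and U are equivalent, case-insensitive.

A reaction counts as regulated only if *every* gene encoding its enzyme
carries the motif; if some same-cofactor isoenzyme genes carry it and
others do not, the reaction is exempted (translation of the motif-free
isoform is unaffected, so the reaction stays active).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .network import MetabolicNetwork

__all__ = [
    "MotifHit",
    "RegulationAnnotation",
    "CompositionProfile",
    "scan_ug_repeats",
    "scan_fasta",
    "build_regulation",
    "amino_acid_composition",
    "write_hits_bed",
]

_UG_RUN = re.compile(r"(?:UG)+")


@dataclass(frozen=True)
class MotifHit:
    """One maximal (UG)k run; coordinates are 0-based, length in nucleotides."""

    sequence_id: str
    start: int
    length: int
    repeat_count: int

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.length


def scan_ug_repeats(
    seq: str, min_repeats: int = 7, sequence_id: str = ""
) -> list[MotifHit]:
    """All maximal runs of >= ``min_repeats`` UG units, left to right.

    A run starting mid-phase (...GUGUG...) is anchored at the first U of the
    maximal UG-phased run; trailing unpaired U is not counted.
    """
    if min_repeats < 1:
        raise ValueError("min_repeats must be >= 1")
    norm = seq.upper().replace("T", "U")
    hits = []
    for m in _UG_RUN.finditer(norm):
        k = (m.end() - m.start()) // 2
        if k >= min_repeats:
            hits.append(MotifHit(sequence_id, m.start(), 2 * k, k))
    return hits


def scan_fasta(path: str | Path, min_repeats: int = 7) -> dict[str, list[MotifHit]]:
    """Scan every record of a (possibly line-wrapped) FASTA file."""
    out: dict[str, list[MotifHit]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = scan_ug_repeats(str(rec.seq), min_repeats, sequence_id=rec.id)
    return out


def write_hits_bed(hits: dict[str, list[MotifHit]], path: str | Path) -> None:
    """BED-like TSV with 0-based half-open coordinates."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tstart\tend\trepeat_count\n")
        for sid in hits:
            for h in hits[sid]:
                fh.write(f"{sid}\t{h.start}\t{h.end}\t{h.repeat_count}\n")


# ---------------------------------------------------------------------------
# Regulation mapping
# ---------------------------------------------------------------------------


@dataclass
class RegulationAnnotation:
    regulated_reactions: frozenset[str]
    evidence: dict[str, list[MotifHit]] = field(default_factory=dict)
    isoenzyme_exempt: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.regulated_reactions & self.isoenzyme_exempt:
            raise ValueError("a reaction cannot be both regulated and exempt")


def read_gene_map(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Rows of (sequence_id, gene_id, reaction_id, isoform_group)."""
    rows = []
    with open(path) as fh:
        header = None
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                continue
            fields += [""] * (4 - len(fields))
            rows.append(tuple(fields[:4]))
    return rows


def build_regulation(
    utr_fasta: str | Path,
    gene_map: str | Path,
    net: MetabolicNetwork,
    min_repeats: int = 7,
) -> RegulationAnnotation:
    """Derive the regulated-reaction set from 3'-UTR motif hits.

    A reaction is regulated iff every gene mapped to it has at least one
    (UG)>=min_repeats hit in its UTR ("entirely encoded" rule); a reaction
    where only some isoform genes carry the motif becomes isoenzyme-exempt.
    Reactions with no mapped genes are unregulated (logged as a warning).
    """
    hits_by_seq = scan_fasta(utr_fasta, min_repeats)
    rows = read_gene_map(gene_map)
    known_reactions = set(net.reaction_ids)
    genes_by_reaction: dict[str, dict[str, bool]] = {}
    evidence: dict[str, list[MotifHit]] = {}
    for sid, gene, rid, _group in rows:
        if rid not in known_reactions:
            warnings.warn(f"gene map references unknown reaction {rid!r}; skipped")
            continue
        if sid not in hits_by_seq:
            warnings.warn(f"no UTR sequence for {sid!r} (gene {gene!r}); skipped")
            continue
        got = bool(hits_by_seq[sid])
        genes_by_reaction.setdefault(rid, {})[gene] = (
            genes_by_reaction.get(rid, {}).get(gene, False) or got
        )
        if got:
            evidence.setdefault(rid, []).extend(hits_by_seq[sid])
    regulated, exempt = set(), set()
    for rid, gene_flags in genes_by_reaction.items():
        flags = list(gene_flags.values())
        if all(flags):
            regulated.add(rid)
        elif any(flags):
            exempt.add(rid)
    for rid in known_reactions - set(genes_by_reaction):
        if net.reaction(rid).gene_ids:
            warnings.warn(f"reaction {rid!r} has genes but no UTR mapping; unregulated")
    return RegulationAnnotation(
        regulated_reactions=frozenset(regulated),
        evidence={r: evidence.get(r, []) for r in sorted(regulated)},
        isoenzyme_exempt=frozenset(exempt),
    )


# ---------------------------------------------------------------------------
# Amino-acid composition
# ---------------------------------------------------------------------------

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class CompositionProfile:
    """Pooled residue counts and percentage shares over a protein FASTA.

    Non-standard letters (B, Z, X, *, ...) are tallied under ``other`` and
    excluded from the percentage base.
    """

    counts: dict[str, int]
    percentages: dict[str, float]

    def top(self, n: int = 5) -> list[tuple[str, float]]:
        return sorted(self.percentages.items(), key=lambda kv: -kv[1])[:n]


def amino_acid_composition(proteome_fasta: str | Path) -> CompositionProfile:
    """Total amino-acid distribution across all sequences of a protein FASTA."""
    counts: dict[str, int] = {aa: 0 for aa in sorted(_STANDARD_AA)}
    counts["other"] = 0
    total_residues = 0
    n_acgtu = 0
    n_records = 0
    for rec in SeqIO.parse(str(proteome_fasta), "fasta"):
        n_records += 1
        for ch in str(rec.seq).upper():
            total_residues += 1
            if ch in _STANDARD_AA:
                counts[ch] += 1
            else:
                counts["other"] += 1
            if ch in "ACGTU":
                n_acgtu += 1
    if n_records == 0 or total_residues == 0:
        raise ValueError(f"{proteome_fasta}: no sequence data")
    if n_acgtu / total_residues > 0.90:
        warnings.warn(
            f"{proteome_fasta}: >90% of residues are ACGTU; input may be nucleotide"
        )
    base = total_residues - counts["other"]
    if base == 0:
        raise ValueError(f"{proteome_fasta}: no standard amino-acid residues")
    percentages = {aa: 100.0 * counts[aa] / base for aa in sorted(_STANDARD_AA)}
    return CompositionProfile(counts=counts, percentages=percentages)
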