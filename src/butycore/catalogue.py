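"""Building the butyrate gene catalogue.

Assembled nucleotide gene sequences are dereplicated, length-filtered
(>= 70% of the median reference length of their gene), clustered by
complete linkage at 95% nucleotide identity, and novel cluster
representatives are annotated against the reference set (alignment
coverage >= 80%; for but/buk additionally >= 75% identity to the top
hit; clusters with fewer than 3 member counts are rejected).  Accepted
representatives are merged with the dereplicated references, and decoy
sequences (paralogs and homologs from non-producer genera) are added so
that reads hitting them can be filtered out downstream.

The fixed processing order — dereplicate, length filter, cluster,
annotate — is part of the contract: filtering after clustering changes
cluster memberships.

Chimera removal and frameshift correction are explicit no-op
pass-throughs with logged warnings; they require dedicated external
tools and fall outside this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CatalogueEntry:
    """One annotated nucleotide entry of the gene catalogue."""

    seq_id: str
    sequence: str
    gene_symbol: str
    taxon_bin: str = "unassigned"
    source: str = "reference"  # or "assembled"
    is_decoy: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceCluster:
    """A complete-linkage cluster of sequences of one gene symbol."""

    member_ids: tuple[str, ...]
    representative_id: str
    count: int  # member count with dereplication multiplicity


@dataclass
class Annotation:
    """Annotation decision for a novel cluster representative."""

    accepted: bool
    gene_symbol: str | None = None
    taxon_bin: str | None = None
    identity: float = float("nan")
    coverage: float = float("nan")
    reason: str = ""


class CatalogueError(Exception):
    pass


# ---------------------------------------------------------------------------
# pairwise identity

def hamming_identity(a: str, b: str) -> float:
    """Identity of two sequences: matches over the longer length.

    Exact (1 - Hamming/length) for equal-length, indel-free sequences;
    unequal lengths are compared over the shared prefix, so truncation
    is penalized.  Swap in another callable for gapped alignments.
    """
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    matches = sum(x == y for x, y in zip(a[:n], b[:n]))
    return matches / max(len(a), len(b))


def alignment_coverage(query: str, reference: str) -> float:
    """Fraction of the reference covered by the (ungapped) alignment."""
    if not reference:
        return 0.0
    return min(len(query), len(reference)) / len(reference)


# ---------------------------------------------------------------------------
# pipeline steps

def dereplicate(sequences: Mapping[str, str]) -> tuple[dict[str, str], dict[str, int]]:
    """Collapse exact duplicates.

    Returns ``(unique, multiplicity)`` where ``unique`` maps the first
    seen id of each distinct sequence to the sequence, and
    ``multiplicity`` counts how many input records it absorbed.
    """
    unique: dict[str, str] = {}
    mult: dict[str, int] = {}
    seen: dict[str, str] = {}  # sequence -> kept id
    for sid, seq in sequences.items():
        if seq in seen:
            mult[seen[seq]] += 1
        else:
            seen[seq] = sid
            unique[sid] = seq
            mult[sid] = 1
    return unique, mult


def length_filter(
    sequences: Mapping[str, str],
    gene_symbols: Mapping[str, str],
    median_lengths: Mapping[str, float],
    *,
    min_fraction: float = 0.70,
) -> tuple[dict[str, str], list[str]]:
    """Keep sequences of length >= ``min_fraction`` × the median
    reference length of their gene.  Returns (kept, rejected ids)."""
    kept, rejected = {}, []
    for sid, seq in sequences.items():
        gene = gene_symbols.get(sid)
        if gene is None or gene not in median_lengths:
            raise CatalogueError(f"no median reference length for {sid!r} (gene {gene!r})")
        if len(seq) >= min_fraction * median_lengths[gene]:
            kept[sid] = seq
        else:
            rejected.append(sid)
    return kept, rejected


def cluster_identity(
    sequences: Mapping[str, str],
    *,
    threshold: float = 0.95,
    multiplicity: Mapping[str, int] | None = None,
    identity_fn: Callable[[str, str], float] = hamming_identity,
) -> list[SequenceCluster]:
    """Complete-linkage agglomeration at a nucleotide-identity threshold.

    Clusters merge only while *every* cross-pair identity stays at or
    above the threshold, so every cluster's minimum internal identity is
    >= threshold.  Deterministic: at each step the pair of clusters with
    the highest complete-linkage identity merges, ties broken
    lexicographically by representative id.  The representative is the
    lexicographically smallest member id.
    """
    ids = sorted(sequences)
    if not ids:
        return []
    mult = dict(multiplicity) if multiplicity else {i: 1 for i in ids}
    ident = {
        (a, b): identity_fn(sequences[a], sequences[b])
        for i, a in enumerate(ids)
        for b in ids[i + 1:]
    }

    def pair_id(a: str, b: str) -> float:
        return ident[(a, b)] if (a, b) in ident else ident[(b, a)]

    clusters: list[list[str]] = [[i] for i in ids]
    while len(clusters) > 1:
        best = None  # (identity, rep_a, rep_b, ia, ib)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                link = min(
                    pair_id(a, b) for a in clusters[i] for b in clusters[j]
                )
                # maximize identity; break ties on lexicographically
                # smallest representative pair
                cand = (link, min(clusters[i]), min(clusters[j]), i, j)
                if best is None or cand[0] > best[0] or (
                    cand[0] == best[0]
                    and sorted(cand[1:3]) < sorted(best[1:3])
                ):
                    best = cand
        link, _, _, i, j = best
        if link < threshold:
            break
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
    out = []
    for members in sorted(clusters, key=min):
        out.append(
            SequenceCluster(
                member_ids=tuple(sorted(members)),
                representative_id=min(members),
                count=sum(mult[m] for m in members),
            )
        )
    return out


def annotate_cluster(
    representative: str,
    cluster: SequenceCluster,
    references: Sequence[CatalogueEntry],
    *,
    gene_symbol: str,
    min_count: int = 3,
    min_coverage: float = 0.80,
    terminal_min_identity: float = 0.75,
    identity_fn: Callable[[str, str], float] = hamming_identity,
) -> Annotation:
    """Annotate a novel (reference-free) cluster representative against
    the reference entries of its gene.

    Accepted iff multiplicity >= ``min_count`` and alignment coverage to
    the best reference >= ``min_coverage``; but/buk additionally require
    identity >= ``terminal_min_identity`` to the top hit.
    """
    refs = [r for r in references if r.gene_symbol == gene_symbol and not r.is_decoy]
    if not refs:
        return Annotation(False, reason=f"no reference of gene {gene_symbol!r}")
    best = max(refs, key=lambda r: (identity_fn(representative, r.sequence), r.seq_id))
    identity = identity_fn(representative, best.sequence)
    coverage = alignment_coverage(representative, best.sequence)
    if cluster.count < min_count:
        return Annotation(False, gene_symbol, best.taxon_bin, identity, coverage,
                          reason=f"cluster count {cluster.count} < {min_count}")
    if coverage < min_coverage:
        return Annotation(False, gene_symbol, best.taxon_bin, identity, coverage,
                          reason=f"coverage {coverage:.2f} < {min_coverage}")
    if gene_symbol in ("but", "buk") and identity < terminal_min_identity:
        return Annotation(False, gene_symbol, best.taxon_bin, identity, coverage,
                          reason=f"identity {identity:.2f} < {terminal_min_identity}")
    return Annotation(True, gene_symbol, best.taxon_bin, identity, coverage)


def remove_chimeras(sequences: Mapping[str, str]) -> Mapping[str, str]:
    """No-op pass-through; chimera detection needs external tooling."""
    warnings.warn("chimera removal is a pass-through (no-op)", stacklevel=2)
    return sequences


def correct_frameshifts(sequences: Mapping[str, str]) -> Mapping[str, str]:
    """No-op pass-through; frameshift correction needs external tooling."""
    warnings.warn("frameshift correction is a pass-through (no-op)", stacklevel=2)
    return sequences


# ---------------------------------------------------------------------------
# catalogue container

class GeneCatalogue:
    """Annotated, non-redundant nucleotide reference set for read counting.

    Holds reference and accepted assembled entries plus decoys, and the
    per-gene median reference lengths used for gene-length correction.
    """

    def __init__(self, entries: Iterable[CatalogueEntry]):
        self.entries: dict[str, CatalogueEntry] = {}
        for e in entries:
            if e.seq_id in self.entries:
                raise CatalogueError(f"duplicate seq_id {e.seq_id!r}")
            self.entries[e.seq_id] = e
        self.median_lengths: dict[str, float] = {}
        nondecoy = [e for e in self.entries.values() if not e.is_decoy]
        for gene in sorted({e.gene_symbol for e in nondecoy}):
            lens = [e.length for e in nondecoy if e.gene_symbol == gene]
            self.median_lengths[gene] = float(np.median(lens))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __getitem__(self, seq_id: str) -> CatalogueEntry:
        return self.entries[seq_id]

    def median_length(self, gene_symbol: str) -> float:
        try:
            return self.median_lengths[gene_symbol]
        except KeyError:
            raise CatalogueError(f"no median length for gene {gene_symbol!r}") from None

    def decoy_ids(self) -> frozenset[str]:
        return frozenset(sid for sid, e in self.entries.items() if e.is_decoy)

    def quantifiable(self) -> list[CatalogueEntry]:
        return [e for e in self.entries.values() if not e.is_decoy]

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "seq_id": e.seq_id,
                "gene_symbol": e.gene_symbol,
                "taxon_bin": e.taxon_bin,
                "length": e.length,
                "source": e.source,
                "is_decoy": e.is_decoy,
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows)

    def write_manifest(self, path) -> None:
        self.manifest().to_csv(path, sep="\t", index=False)

    def write_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(e.sequence), id=e.seq_id,
                      description=f"gene={e.gene_symbol} taxon={e.taxon_bin} decoy={int(e.is_decoy)}")
            for e in self.entries.values()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_files(cls, fasta_path, manifest_path) -> "GeneCatalogue":
        from Bio import SeqIO

        manifest = pd.read_csv(manifest_path, sep="\t")
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
        entries = []
        for row in manifest.itertuples():
            entries.append(
                CatalogueEntry(
                    seq_id=row.seq_id,
                    sequence=seqs[row.seq_id],
                    gene_symbol=row.gene_symbol,
                    taxon_bin=row.taxon_bin,
                    source=row.source,
                    is_decoy=bool(row.is_decoy),
                )
            )
        return cls(entries)


@dataclass
class CatalogueBuildReport:
    """Audit trail of a catalogue build: what each filter removed."""

    n_input: int = 0
    n_dereplicated: int = 0
    length_rejected: list[str] = field(default_factory=list)
    count_rejected: list[str] = field(default_factory=list)
    coverage_rejected: list[str] = field(default_factory=list)
    identity_rejected: list[str] = field(default_factory=list)
    accepted: list[str] = field(default_factory=list)


def build_catalogue(
    assembled: Mapping[str, str],
    gene_symbols: Mapping[str, str],
    references: Sequence[CatalogueEntry],
    decoys: Sequence[CatalogueEntry] = (),
    *,
    identity_threshold: float = 0.95,
    min_count: int = 3,
    min_coverage: float = 0.80,
    terminal_min_identity: float = 0.75,
    length_fraction: float = 0.70,
    identity_fn: Callable[[str, str], float] = hamming_identity,
) -> tuple[GeneCatalogue, CatalogueBuildReport]:
    """Full catalogue construction from assembled sequences + references.

    Order: dereplicate -> length filter -> per-gene complete-linkage
    clustering (references included) -> annotation of reference-free
    clusters -> merge with dereplicated references and decoys.
    """
    report = CatalogueBuildReport(n_input=len(assembled))
    ref_by_id = {r.seq_id: r for r in references}
    median_lengths = GeneCatalogue(list(references)).median_lengths

    unique, mult = dereplicate(dict(assembled))
    report.n_dereplicated = len(unique)
    kept, rejected = length_filter(
        unique, gene_symbols, median_lengths, min_fraction=length_fraction
    )
    report.length_rejected = rejected
    kept = remove_chimeras(kept)
    kept = correct_frameshifts(kept)

    accepted_entries: list[CatalogueEntry] = []
    genes = sorted({gene_symbols[sid] for sid in kept})
    for gene in genes:
        pool = {sid: seq for sid, seq in kept.items() if gene_symbols[sid] == gene}
        gene_refs = {r.seq_id: r.sequence for r in references
                     if r.gene_symbol == gene and not r.is_decoy}
        merged = {**pool, **gene_refs}
        merged_mult = {**{s: mult[s] for s in pool}, **{s: 1 for s in gene_refs}}
        clusters = cluster_identity(
            merged, threshold=identity_threshold,
            multiplicity=merged_mult, identity_fn=identity_fn,
        )
        for cl in clusters:
            if any(m in gene_refs for m in cl.member_ids):
                continue  # reference-containing clusters need no annotation
            rep_seq = merged[cl.representative_id]
            ann = annotate_cluster(
                rep_seq, cl, references, gene_symbol=gene,
                min_count=min_count, min_coverage=min_coverage,
                terminal_min_identity=terminal_min_identity,
                identity_fn=identity_fn,
            )
            if ann.accepted:
                report.accepted.append(cl.representative_id)
                accepted_entries.append(
                    CatalogueEntry(
                        seq_id=cl.representative_id,
                        sequence=rep_seq,
                        gene_symbol=ann.gene_symbol,
                        taxon_bin=ann.taxon_bin,
                        source="assembled",
                    )
                )
            elif ann.reason.startswith("cluster count"):
                report.count_rejected.append(cl.representative_id)
            elif ann.reason.startswith("coverage"):
                report.coverage_rejected.append(cl.representative_id)
            elif ann.reason.startswith("identity"):
                report.identity_rejected.append(cl.representative_id)
    catalogue = GeneCatalogue(list(references) + accepted_entries + list(decoys))
    return catalogue, report
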